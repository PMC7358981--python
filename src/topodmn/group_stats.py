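"""Two-group permutation inference over subject network features.

The group-difference statistic is the absolute difference of group
means (two-sided; the direction of any effect is not pre-specified).
Monte-Carlo p-values use the add-one correction
``p = (1 + #{permuted stat >= observed}) / (1 + n_perm)`` so p is never
exactly zero; the exhaustive variant enumerates every relabelling and
divides the plain count (which includes the identity) by the total.
No multiple-testing correction is applied across the feature-by-scope
grid — the p-values are raw, which is a caveat for interpretation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RoiNode, Scope, load_atlas, scope_indices
from .connectivity import (
    TimeSeriesMatrix,
    WeightedNetwork,
    build_network,
    read_network,
    read_timeseries,
)
from .features import FEATURE_NAMES, compute_subject_features

__all__ = [
    "GROUPS",
    "CohortSubject",
    "Cohort",
    "GroupComparisonResult",
    "permutation_test",
    "cohort_features",
    "compare_groups",
    "load_cohort",
]

GROUPS = ("carrier", "noncarrier")


@dataclass
class CohortSubject:
    subject_id: str
    group: str
    timeseries: TimeSeriesMatrix | None = None
    network: WeightedNetwork | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if (self.timeseries is None) == (self.network is None):
            raise ValueError(
                f"subject {self.subject_id!r} needs exactly one of "
                "timeseries or network"
            )


@dataclass
class Cohort:
    subjects: list[CohortSubject] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        for g in GROUPS:
            if sum(s.group == g for s in self.subjects) < 2:
                raise ValueError(f"need at least 2 subjects in group {g!r}")

    def group_ids(self, group: str) -> list[str]:
        return [s.subject_id for s in self.subjects if s.group == group]


@dataclass
class GroupComparisonResult:
    """Per-(feature, scope) permutation p-values and observed differences."""

    pvalues: pd.DataFrame  # index = scope, columns = features
    details: pd.DataFrame  # long format, one row per cell
    features_table: pd.DataFrame  # one row per subject x scope
    n_permutations: int
    seed: int


def _mean_diff(a: np.ndarray, b: np.ndarray) -> float:
    return abs(float(a.mean() - b.mean()))


def _t_stat(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else math.inf
    return abs(float((a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))))


def permutation_test(
    values_a,
    values_b,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "mean_diff",
    method: str = "monte_carlo",
) -> float:
    """Two-sided permutation p-value for a difference between two samples.

    ``method="exhaustive"`` enumerates all C(n, n_a) relabellings and is
    intended for small samples; ``"monte_carlo"`` draws *n_perm* random
    relabellings with the add-one correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    stat = {"mean_diff": _mean_diff, "t": _t_stat}[statistic]
    observed = stat(a, b)
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size

    if method == "exhaustive":
        total = 0
        hits = 0
        for idx_a in itertools.combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            total += 1
            if stat(pooled[mask], pooled[~mask]) >= observed:
                hits += 1
        return hits / total
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")

    # Draw relabellings from the sorted pool and split at the smaller
    # group size: a random k-subset and its complement give the same
    # statistic distribution as na/nb labelling, and the draw depends
    # only on (multiset, {na, nb}, seed) — so swapping the group labels
    # leaves the p-value exactly unchanged.
    rng = np.random.default_rng(seed)
    canon = np.sort(pooled)
    k = min(na, n - na)
    hits = 0
    if statistic == "mean_diff":
        perm = np.tile(canon, (n_perm, 1))
        perm = rng.permuted(perm, axis=1)
        mean_a = perm[:, :k].mean(axis=1)
        mean_b = perm[:, k:].mean(axis=1)
        hits = int(np.sum(np.abs(mean_a - mean_b) >= observed))
    else:
        for _ in range(n_perm):
            shuffled = rng.permutation(canon)
            if stat(shuffled[:k], shuffled[k:]) >= observed:
                hits += 1
    return (1 + hits) / (1 + n_perm)


def _subject_full_network(
    subject: CohortSubject, atlas: list[RoiNode]
) -> WeightedNetwork:
    if subject.network is not None:
        if subject.network.n_nodes != len(atlas):
            raise ValueError(
                f"subject {subject.subject_id!r}: precomputed network has "
                f"{subject.network.n_nodes} nodes, atlas defines {len(atlas)}"
            )
        return subject.network
    try:
        return build_network(subject.timeseries, Scope.BOTH, atlas=atlas)
    except Exception as exc:
        raise RuntimeError(
            f"feature computation failed for subject {subject.subject_id!r}: {exc}"
        ) from exc


def cohort_features(
    cohort: Cohort,
    scopes: tuple[Scope | str, ...] = (Scope.BOTH, Scope.LEFT, Scope.RIGHT),
    features: tuple[str, ...] = FEATURE_NAMES,
    atlas: list[RoiNode] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature table with one row per subject x scope."""
    if atlas is None:
        atlas = load_atlas()
    scopes = tuple(Scope.coerce(s) for s in scopes)
    rows = []
    for subject in cohort.subjects:
        full = _subject_full_network(subject, atlas)
        for scope in scopes:
            net = (
                full
                if scope is Scope.BOTH
                else full.subnetwork(scope_indices(scope, atlas), scope)
            )
            feats = compute_subject_features(net, features=features, seed=seed)
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "group": subject.group,
                    "scope": scope.value,
                    **{k: v for k, v in feats.as_dict().items() if k in features},
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    cohort: Cohort,
    scopes: tuple[Scope | str, ...] = (Scope.BOTH, Scope.LEFT, Scope.RIGHT),
    n_perm: int = 10_000,
    seed: int = 0,
    features: tuple[str, ...] = FEATURE_NAMES,
    statistic: str = "mean_diff",
    atlas: list[RoiNode] | None = None,
    features_table: pd.DataFrame | None = None,
) -> GroupComparisonResult:
    """Permutation p-values for every feature at every scope.

    With the default three scopes and seven features this is the full
    21-cell grid. Each cell draws its permutations from an independent
    stream spawned deterministically from *seed*.
    """
    scopes = tuple(Scope.coerce(s) for s in scopes)
    if features_table is None:
        features_table = cohort_features(
            cohort, scopes=scopes, features=features, atlas=atlas, seed=seed
        )
    cell_seeds = np.random.SeedSequence(seed).generate_state(
        len(scopes) * len(features)
    ) % (2**31)
    grid = pd.DataFrame(
        index=[s.value for s in scopes], columns=list(features), dtype=float
    )
    grid.index.name = "scope"
    long_rows = []
    k = 0
    for scope in scopes:
        sub = features_table[features_table["scope"] == scope.value]
        a = sub[sub["group"] == "carrier"]
        b = sub[sub["group"] == "noncarrier"]
        for feat in features:
            va, vb = a[feat].to_numpy(), b[feat].to_numpy()
            cell_seed = int(cell_seeds[k])
            k += 1
            p = permutation_test(
                va, vb, n_perm=n_perm, seed=cell_seed, statistic=statistic
            )
            grid.loc[scope.value, feat] = p
            long_rows.append(
                {
                    "scope": scope.value,
                    "feature": feat,
                    "mean_carrier": va.mean(),
                    "mean_noncarrier": vb.mean(),
                    "observed_diff": va.mean() - vb.mean(),
                    "p_value": p,
                    "n_permutations": n_perm,
                    "seed": cell_seed,
                }
            )
    return GroupComparisonResult(
        pvalues=grid,
        details=pd.DataFrame(long_rows),
        features_table=features_table,
        n_permutations=n_perm,
        seed=seed,
    )


def load_cohort(manifest: str | Path) -> Cohort:
    """Read a cohort manifest: TSV/CSV with columns
    ``subject_id  group  path`` (paths relative to the manifest)."""
    manifest = Path(manifest)
    delim = "," if manifest.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(manifest, sep=delim)
    required = {"subject_id", "group", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    subjects = []
    for row in df.itertuples(index=False):
        path = manifest.parent / str(row.path)
        sid = str(row.subject_id)
        kind = getattr(row, "kind", "timeseries")
        if kind == "network":
            subjects.append(
                CohortSubject(sid, str(row.group), network=read_network(path, sid))
            )
        else:
            subjects.append(
                CohortSubject(
                    sid, str(row.group), timeseries=read_timeseries(path, sid)
                )
            )
    return Cohort(subjects)
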