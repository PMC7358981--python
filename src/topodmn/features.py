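"""Persistent-feature statistics of the filtration.

Two scalar summaries quantify how fast a network's components aggregate
as the threshold grows — both are "convergence rate" readings of the
filtration:

* **SIP** — the OLS slope of the integrated persistent feature (IPF)
  curve against the filtration values. The IPF at the i-th filtration
  value is ``(m - i) / (m (m - 1)) * sum_{k > i} lambda_k``: a weighted
  tail sum of the remaining merge costs, a non-increasing curve that
  ends at exactly 0 once everything is one component.
* **BNP slope** — the OLS slope of the beta0 curve against the same
  filtration values. The curve itself is the classic Betti number plot;
  the per-subject scalar used for inference is its fitted slope, chosen
  symmetrically with SIP.

Both slopes are negative for any non-degenerate network: a steeper
(more negative) value means faster aggregation. Slopes are fitted over
all m filtration points, unweighted, on the raw lambda scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import Scope
from .connectivity import WeightedNetwork
from .filtration import betti0_curve, filtration_values, minimum_spanning_tree

__all__ = [
    "IpfProfile",
    "SubjectFeatures",
    "FEATURE_NAMES",
    "ipf_curve",
    "slope_statistic",
    "compute_sip",
    "compute_bnp",
    "compute_subject_features",
]

FEATURE_NAMES = ("sip", "bnp", "cpl", "nr", "ec", "mod", "gc")


@dataclass(frozen=True)
class IpfProfile:
    """The (lambda, IPF) curve of one network."""

    lambdas: np.ndarray
    ipf: np.ndarray


@dataclass(frozen=True)
class SubjectFeatures:
    """All scalar network statistics for one subject at one scope."""

    subject_id: str
    scope: Scope
    sip: float = np.nan
    bnp: float = np.nan
    cpl: float = np.nan
    nr: float = np.nan
    ec: float = np.nan
    mod: float = np.nan
    gc: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def ipf_curve(lambdas: np.ndarray) -> IpfProfile:
    """Integrated persistent feature curve over the filtration values.

    ``ipf[i] = (m - i) / (m (m - 1)) * sum(lambdas[i + 1:])`` for
    ``i <= m - 2`` and ``ipf[m - 1] = 0``. Requires ``lambdas[0] == 0``,
    non-negative and non-decreasing, length >= 2.
    """
    lam = np.asarray(lambdas, dtype=float)
    m = lam.size
    if m < 2:
        raise ValueError("need at least 2 filtration values")
    if lam[0] != 0.0:
        raise ValueError("first filtration value must be 0")
    if np.any(lam < 0) or np.any(np.diff(lam) < 0):
        raise ValueError("filtration values must be non-negative, non-decreasing")
    tail = np.concatenate((np.cumsum(lam[::-1])[::-1][1:], [0.0]))
    factors = (m - np.arange(m)) / (m * (m - 1))
    ipf = factors * tail
    ipf[-1] = 0.0
    return IpfProfile(lam, ipf)


def slope_statistic(xs: np.ndarray, ys: np.ndarray) -> float:
    """Slope of the ordinary least-squares line of *ys* on *xs*."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1 or xs.size < 2:
        raise ValueError("need equal-length 1-D arrays of length >= 2")
    xc = xs - xs.mean()
    sxx = xc @ xc
    if sxx == 0.0:
        raise ValueError("x values are all identical; slope undefined")
    return float((xc @ (ys - ys.mean())) / sxx)


def compute_sip(net: WeightedNetwork) -> float:
    """Slope of the IPF plot. Negative for any non-degenerate network."""
    lams = filtration_values(minimum_spanning_tree(net))
    profile = ipf_curve(lams)
    return slope_statistic(profile.lambdas, profile.ipf)


def compute_bnp(net: WeightedNetwork) -> float:
    """Slope of the Betti number plot over the m filtration points."""
    profile = betti0_curve(net)
    return slope_statistic(profile.lambdas, profile.betti0.astype(float))


def compute_subject_features(
    net: WeightedNetwork,
    features: tuple[str, ...] = FEATURE_NAMES,
    seed: int = 0,
) -> SubjectFeatures:
    """Compute the requested scalar statistics for one network.

    *seed* controls the Louvain restarts behind the modularity score;
    all other statistics are deterministic.
    """
    from . import graph_measures as gm

    unknown = set(features) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    out: dict[str, float] = {}
    if "sip" in features:
        out["sip"] = compute_sip(net)
    if "bnp" in features:
        out["bnp"] = compute_bnp(net)
    if {"cpl", "gc", "nr"} & set(features):
        D = gm.shortest_paths(net)
        if "cpl" in features:
            out["cpl"] = gm.characteristic_path_length(net, D=D)
        if "gc" in features:
            out["gc"] = gm.global_efficiency(net, D=D)
        if "nr" in features:
            out["nr"] = gm.network_radius(net, D=D)
    if "mod" in features:
        out["mod"] = gm.modularity(net, seed=seed)
    if "ec" in features:
        out["ec"] = gm.eigenvector_centrality_score(net)
    return SubjectFeatures(net.subject_id, net.scope, **out)
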