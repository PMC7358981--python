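"""Synthetic rs-fMRI cohort generator.

Emulates the statistical structure the pipeline assumes so every stage
is testable without access-controlled scan data: two groups (defaults
27 carriers, 31 non-carriers), 26 ROIs split into two hemisphere
blocks, 130 timepoints per series. Signals are multivariate normal
draws from a block-structured correlation matrix: homologous-hemisphere
pairs share a higher correlation than cross-hemisphere pairs. The
planted group effect is a uniform correlation boost for the carrier
group — higher correlations mean smaller dissimilarity weights, so
carrier networks aggregate faster under filtration (steeper Betti and
IPF curves), the direction of the effect the analysis is meant to
detect.

On top of the group matrix each subject receives a global coupling
jitter (one N(0, subject_sd^2) draw added to all off-diagonal
correlations). Without it all subjects in a group would be i.i.d. from
one matrix, which no real cohort is, and group tests would saturate;
with it the cohort has a realistic between-subject variance component.

The model deliberately omits hemodynamics, scanner noise spectra and
motion. Signals are temporally white by default (the correlation-based
edge weight is agnostic to autocorrelation); an AR(1) knob exists for
sensitivity checks but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .atlas import load_atlas
from .connectivity import TimeSeriesMatrix, write_timeseries
from .group_stats import Cohort, CohortSubject

__all__ = [
    "CohortConfig",
    "make_group_covariance",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
]

_EIG_FLOOR = 1e-10


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults mirror the study design being emulated."""

    n_carrier: int = 27
    n_noncarrier: int = 31
    n_roi: int = 26
    n_timepoints: int = 130
    within_block_rho: float = 0.4
    between_block_rho: float = 0.15
    coupling_boost: float = 0.15
    noise_sd: float = 1.0
    subject_sd: float = 0.1
    ar_coeff: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_carrier < 2 or self.n_noncarrier < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.n_roi < 2 or self.n_timepoints < 3:
            raise ValueError("need n_roi >= 2 and n_timepoints >= 3")
        if not 0 <= self.within_block_rho < 1:
            raise ValueError("within_block_rho must be in [0, 1)")
        if self.coupling_boost < 0:
            raise ValueError("coupling_boost must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= abs(self.ar_coeff) < 1:
            raise ValueError("ar_coeff must satisfy |ar| < 1")


def _block_parity(n_roi: int) -> np.ndarray:
    """Hemisphere block id per node, matching the atlas interleaved order
    (left at even positions, right at odd)."""
    return np.arange(n_roi) % 2


def _project_psd(C: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at a small floor and restore the unit diagonal."""
    vals, vecs = np.linalg.eigh(C)
    if vals.min() >= -_EIG_FLOOR:
        return C
    vals = np.clip(vals, _EIG_FLOOR, None)
    C = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return (C + C.T) / 2.0


def make_group_covariance(config: CohortConfig, group: str) -> np.ndarray:
    """Block-structured correlation matrix for one group.

    Same-hemisphere pairs get ``within_block_rho``, cross-hemisphere
    pairs ``between_block_rho``; the carrier group's off-diagonals are
    raised uniformly by ``coupling_boost`` (clipped below 1 and
    PSD-projected if needed). With zero boost both groups share one
    matrix.
    """
    if group not in ("carrier", "noncarrier"):
        raise ValueError(f"unknown group {group!r}")
    block = _block_parity(config.n_roi)
    same = block[:, None] == block[None, :]
    C = np.where(same, config.within_block_rho, config.between_block_rho).astype(float)
    np.fill_diagonal(C, 1.0)
    if group == "carrier" and config.coupling_boost > 0:
        off = ~np.eye(config.n_roi, dtype=bool)
        C[off] = np.clip(C[off] + config.coupling_boost, -0.99, 0.99)
    C = _project_psd(C)
    vals = np.linalg.eigvalsh(C)
    if vals.min() < -_EIG_FLOOR:
        raise ValueError(
            f"correlation matrix not PSD after projection "
            f"(min eigenvalue {vals.min():.3e})"
        )
    return C


def _jittered(C: np.ndarray, delta: float) -> np.ndarray:
    off = ~np.eye(C.shape[0], dtype=bool)
    Cs = C.copy()
    Cs[off] = np.clip(Cs[off] + delta, -0.99, 0.99)
    return _project_psd(Cs)


def simulate_subject(
    correlation: np.ndarray,
    n_timepoints: int,
    noise_sd: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "",
    ar_coeff: float = 0.0,
    roi_labels: list[str] | None = None,
) -> TimeSeriesMatrix:
    """Draw one subject's ROI x time block from a correlation matrix.

    Timepoints are independent multivariate normal vectors (eigen
    factorization of the correlation), scaled by *noise_sd*; the sample
    correlation converges to the target as the series lengthens. With
    ``ar_coeff`` nonzero the innovations are passed through a
    stationary AR(1) filter, which leaves the cross-ROI correlation
    structure intact.
    """
    C = np.asarray(correlation, dtype=float)
    m = C.shape[0]
    vals, vecs = np.linalg.eigh(C)
    if vals.min() < -1e-8:
        raise ValueError(f"correlation matrix not PSD (min eig {vals.min():.3e})")
    L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_timepoints, m))
    if ar_coeff:
        scale = np.sqrt(1.0 - ar_coeff**2)
        for t in range(1, n_timepoints):
            Z[t] = ar_coeff * Z[t - 1] + scale * Z[t]
    X = (Z @ L.T).T * noise_sd
    return TimeSeriesMatrix(X, subject_id=subject_id, roi_labels=roi_labels or [])


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full two-group cohort, deterministically from the seed."""
    labels = (
        [n.abbreviation for n in load_atlas()] if config.n_roi == 26 else None
    )
    c_carrier = make_group_covariance(config, "carrier")
    c_noncarrier = make_group_covariance(config, "noncarrier")
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_carrier + config.n_noncarrier
    children = ss.spawn(n_total + 1)
    jitter_rng = np.random.default_rng(children[0])
    subjects = []
    plan = [("carrier", c_carrier, config.n_carrier), ("noncarrier", c_noncarrier, config.n_noncarrier)]
    k = 1
    for group, C, count in plan:
        for i in range(count):
            delta = (
                jitter_rng.normal(0.0, config.subject_sd)
                if config.subject_sd > 0
                else 0.0
            )
            sid = f"sub-{group[0].upper()}{i + 1:02d}"
            ts = simulate_subject(
                _jittered(C, delta) if delta else C,
                config.n_timepoints,
                noise_sd=config.noise_sd,
                seed=children[k],
                subject_id=sid,
                ar_coeff=config.ar_coeff,
                roi_labels=labels,
            )
            subjects.append(CohortSubject(sid, group, timeseries=ts))
            k += 1
    return Cohort(subjects)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write per-subject time-series TSVs plus a manifest; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w", encoding="utf-8") as fh:
        fh.write("subject_id\tgroup\tpath\n")
        for subject in cohort.subjects:
            fname = f"{subject.subject_id}.tsv"
            write_timeseries(subject.timeseries, outdir / fname)
            fh.write(f"{subject.subject_id}\t{subject.group}\t{fname}\n")
    return manifest
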