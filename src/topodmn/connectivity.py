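"""Subject-level weighted network construction from ROI time series.

The edge weight between two regions is ``1 - r`` where ``r`` is the
sample Pearson correlation of their BOLD series, so weights live in
``[0, 2]`` and behave as dissimilarities: strongly coupled regions are
close (weight near 0), anti-correlated regions are far (weight near 2).
Negative correlations are kept as weights above 1 — no absolute value or
thresholding is applied. A constant (zero-variance) series is an error:
it indicates broken upstream preprocessing, not a zero signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .atlas import RoiNode, Scope, load_atlas, scope_indices

__all__ = [
    "DegenerateSignalError",
    "TimeSeriesMatrix",
    "WeightedNetwork",
    "discard_initial_volumes",
    "pearson_dissimilarity",
    "build_network",
    "read_timeseries",
    "write_timeseries",
    "read_network",
    "write_network",
]


class DegenerateSignalError(ValueError):
    """An ROI series has zero variance and no correlation is defined."""


@dataclass
class TimeSeriesMatrix:
    """One subject's ROI-by-timepoint signal block (rows in atlas order)."""

    values: np.ndarray
    subject_id: str = ""
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series block must be 2-D (roi x time)")
        if not np.isfinite(self.values).all():
            raise ValueError(f"non-finite values in series of {self.subject_id!r}")
        if self.roi_labels and len(self.roi_labels) != self.values.shape[0]:
            raise ValueError("roi_labels length does not match row count")

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class WeightedNetwork:
    """Symmetric dissimilarity matrix over labelled nodes."""

    weights: np.ndarray
    node_labels: list[str]
    subject_id: str = ""
    scope: Scope = Scope.BOTH

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if not np.allclose(np.diag(W), 0.0):
            raise ValueError("weight matrix must have zero diagonal")
        if W.min() < -1e-12 or W.max() > 2 + 1e-12:
            raise ValueError("weights must lie in [0, 2]")
        self.weights = W
        if len(self.node_labels) != W.shape[0]:
            raise ValueError("node_labels length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def subnetwork(self, positions: list[int], scope: Scope) -> "WeightedNetwork":
        """Restriction to a subset of node positions (order preserved)."""
        idx = np.asarray(positions, dtype=int)
        return WeightedNetwork(
            weights=self.weights[np.ix_(idx, idx)],
            node_labels=[self.node_labels[i] for i in idx],
            subject_id=self.subject_id,
            scope=scope,
        )


def discard_initial_volumes(raw: TimeSeriesMatrix, n_discard: int) -> TimeSeriesMatrix:
    """Drop the first *n_discard* timepoints (scanner equilibration volumes)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= raw.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {raw.n_timepoints} timepoints"
        )
    if n_discard == 0:
        return raw
    return replace(raw, values=raw.values[:, n_discard:].copy())


def pearson_dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    """``1 - r`` for the sample Pearson correlation of two equal-length series.

    The correlation is the mean-centred cross product normalised by the
    product of root sums of squares; any scale factors cancel, so there
    is no n vs n-1 ambiguity. ``r`` is clipped to [-1, 1] before the
    subtraction to absorb rounding at the boundaries.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("series must have at least 3 timepoints")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.sqrt(ac @ ac)
    nb = np.sqrt(bc @ bc)
    if na == 0.0 or nb == 0.0:
        raise DegenerateSignalError("zero-variance series has no correlation")
    r = float(np.clip((ac @ bc) / (na * nb), -1.0, 1.0))
    return 1.0 - r


def _dissimilarity_matrix(X: np.ndarray, labels: list[str]) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    degenerate = np.flatnonzero(norms == 0.0)
    if degenerate.size:
        bad = ", ".join(labels[i] for i in degenerate)
        raise DegenerateSignalError(f"zero-variance series for ROI: {bad}")
    # per-pair dot products (not one blocked matmul) so that every entry
    # depends only on its two rows: hemisphere submatrices then equal
    # recomputation from the subset series bit-for-bit
    m = Xc.shape[0]
    W = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            r = min(1.0, max(-1.0, float(Xc[i] @ Xc[j]) / (norms[i] * norms[j])))
            W[i, j] = W[j, i] = 1.0 - r
    return W


def build_network(
    ts: TimeSeriesMatrix,
    scope: Scope | str = Scope.BOTH,
    atlas: list[RoiNode] | None = None,
) -> WeightedNetwork:
    """Build the weighted dissimilarity network for one subject and scope.

    Selects the scope's rows of the full-atlas series block, then
    computes all pairwise ``1 - r`` weights.
    """
    scope = Scope.coerce(scope)
    if atlas is None:
        atlas = load_atlas()
    if ts.n_roi != len(atlas):
        raise ValueError(
            f"series has {ts.n_roi} rows but atlas defines {len(atlas)} nodes"
        )
    if ts.roi_labels:
        expected = [n.abbreviation for n in atlas]
        if ts.roi_labels != expected:
            raise ValueError(
                f"ROI labels of {ts.subject_id!r} do not match atlas order"
            )
    pos = scope_indices(scope, atlas)
    labels = [atlas[i].abbreviation for i in pos]
    W = _dissimilarity_matrix(ts.values[pos], labels)
    return WeightedNetwork(W, labels, subject_id=ts.subject_id, scope=scope)


# ---------------------------------------------------------------------------
# Delimited-text I/O


def _sniff_delim(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_timeseries(path: str | Path, subject_id: str | None = None) -> TimeSeriesMatrix:
    """Read one subject's ROI x time block from TSV/CSV.

    Rows are ROIs in atlas order, columns timepoints. If the first field
    of a row is non-numeric it is taken as the ROI label (stored and
    later validated against the atlas by :func:`build_network`).
    """
    path = Path(path)
    delim = _sniff_delim(path)
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split(delim)
            if not parts or parts == [""]:
                continue
            try:
                float(parts[0])
            except ValueError:
                labels.append(parts[0])
                parts = parts[1:]
            rows.append([float(p) for p in parts])
    if labels and len(labels) != len(rows):
        raise ValueError(f"mixed labelled/unlabelled rows in {path}")
    return TimeSeriesMatrix(
        np.array(rows, dtype=float),
        subject_id=subject_id or path.stem,
        roi_labels=labels,
    )


def write_timeseries(ts: TimeSeriesMatrix, path: str | Path) -> None:
    path = Path(path)
    delim = _sniff_delim(path)
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(ts.n_roi):
            prefix = [ts.roi_labels[i]] if ts.roi_labels else []
            fh.write(delim.join(prefix + [repr(float(v)) for v in ts.values[i]]) + "\n")


def read_network(path: str | Path, subject_id: str | None = None) -> WeightedNetwork:
    """Read a square weighted matrix with abbreviation header row/column."""
    path = Path(path)
    delim = _sniff_delim(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delim)
        labels = header[1:]
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split(delim)
            if not parts or parts == [""]:
                continue
            rows.append([float(p) for p in parts[1:]])
    return WeightedNetwork(
        np.array(rows, dtype=float), labels, subject_id=subject_id or path.stem
    )


def write_network(net: WeightedNetwork, path: str | Path) -> None:
    path = Path(path)
    delim = _sniff_delim(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delim.join([""] + net.node_labels) + "\n")
        for label, row in zip(net.node_labels, net.weights):
            fh.write(delim.join([label] + [repr(float(v)) for v in row]) + "\n")
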