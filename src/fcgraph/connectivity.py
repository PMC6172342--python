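"""Functional-connectivity edge estimation.

Four estimator families turn pairs of cluster-mean signals into edge
weights: Pearson correlation (corr), nonlinear correlation from a
piecewise-linear fit (H2), normalized mutual information (MIT), and binned
transfer entropy (TE).  Each family has undirected and directed (delay-
scanning) variants, computed either on the full recording or on sliding
windows whose per-window weights are averaged.  Absolute values are taken
and weights are normalized to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from fcgraph.errors import DegenerateInputError
from fcgraph.parcellation import ClusterTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeMethodSpec",
    "ConnectivityGraph",
    "EDGE_PRESETS",
    "sliding_windows",
    "edge_corr",
    "edge_h2",
    "edge_mit",
    "edge_te",
    "build_graph",
]


@dataclass(frozen=True)
class EdgeMethodSpec:
    """One edge-definition variant.

    ``window_length``/``window_overlap_fraction`` control sliding-window
    estimation (full-length window means a single window), ``max_delay`` the
    lag scan of directed variants, ``n_bins`` the histogram resolution of
    the information-theoretic estimators, and ``te_past_samples`` the length
    of the past blocks entering transfer entropy (5 samples = 15 s at
    TR 3 s).
    """

    name: str
    family: str  # corr | H2 | MIT | TE
    directed: bool
    window_length: int = 130
    window_overlap_fraction: float = 0.0
    max_delay: int = 0
    n_bins: int = 0
    te_past_samples: int = 5

    def __post_init__(self) -> None:
        if self.family not in ("corr", "H2", "MIT", "TE"):
            raise ValueError(f"unknown estimator family {self.family!r}")


def _presets() -> dict[str, EdgeMethodSpec]:
    specs = {}
    for fam, bins in (("corr", 0), ("H2", 10), ("MIT", 5), ("TE", 5)):
        for directed in (False, True):
            for variant, (win, ov) in enumerate(((130, 0.0), (50, 0.2)), start=1):
                d = "D" if directed else "U"
                name = f"B{fam}{d}{variant}"
                # corr/H2/MIT undirected variants use no delay scan; TE and
                # all directed variants scan delays up to 5
                delay = 5 if (directed or fam == "TE") else 0
                specs[name] = EdgeMethodSpec(
                    name=name,
                    family=fam,
                    directed=directed,
                    window_length=win,
                    window_overlap_fraction=ov,
                    max_delay=delay,
                    n_bins=bins,
                )
    return specs


#: The 16 named edge-definition variants (BcorrU1 ... BTED2).
EDGE_PRESETS: dict[str, EdgeMethodSpec] = _presets()


@dataclass
class ConnectivityGraph:
    """Weighted adjacency over clusters with estimator metadata."""

    weights: np.ndarray
    directed: bool
    node_ids: list[int]
    method: EdgeMethodSpec | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if w.shape[0] != len(self.node_ids):
            raise ValueError("node_ids must align with the weight matrix")
        if not np.isfinite(w).all() or (w < 0).any():
            raise ValueError("weights must be finite and non-negative")
        if np.diag(w).any():
            raise ValueError("diagonal must be zero")
        if not self.directed and not np.allclose(w, w.T):
            raise ValueError("undirected graph must have symmetric weights")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def copy_with(self, weights: np.ndarray) -> "ConnectivityGraph":
        return ConnectivityGraph(
            weights=weights,
            directed=self.directed,
            node_ids=list(self.node_ids),
            method=self.method,
        )


def sliding_windows(
    n_timepoints: int, window_length: int, overlap_fraction: float
) -> list[tuple[int, int]]:
    """Half-open index ranges of a sliding window.

    The step is window_length * (1 - overlap_fraction); e.g. 50-point
    windows with 0.2 overlap advance by 40 points, overlapping by 10.
    """
    if window_length > n_timepoints:
        raise ValueError("window_length exceeds the number of time points")
    step = int(round(window_length * (1.0 - overlap_fraction)))
    if step <= 0:
        raise ValueError("window step must be positive")
    return [(s, s + window_length) for s in range(0, n_timepoints - window_length + 1, step)]


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("series must be 1-D, equal length >= 3")
    if x.var() == 0 or y.var() == 0:
        raise DegenerateInputError("constant series")
    return x, y


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise DegenerateInputError("constant series in window")
    return min(abs(float(xc @ yc) / denom), 1.0)


def edge_corr(x, y, directed: bool = False, max_delay: int = 5) -> float:
    """|Pearson correlation|; directed variants scan lags 0..max_delay of the
    target and keep the largest value."""
    x, y = _check_pair(x, y)
    if not directed:
        return _abs_pearson(x, y)
    n = len(x)
    best = 0.0
    for tau in range(0, max_delay + 1):
        if n - tau < 3:
            break
        best = max(best, _abs_pearson(x[: n - tau], y[tau:]))
    return best


def _h2_one(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Explained-variance fraction of y under a piecewise-linear regression
    on x over n_bins equal-count bins; bins with < 2 points merge with their
    neighbour."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    n_bins = max(1, min(n_bins, n // 2))
    bounds = [int(round(i * n / n_bins)) for i in range(n_bins + 1)]
    chunks = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo == 0:
            continue
        if hi - lo < 2 and chunks:
            logger.debug("merging degenerate h2 bin")
            chunks[-1] = (chunks[-1][0], hi)
        else:
            chunks.append((lo, hi))
    knot_x, knot_y = [], []
    for lo, hi in chunks:
        kx = xs[lo:hi].mean()
        ky = ys[lo:hi].mean()
        if knot_x and kx == knot_x[-1]:  # identical x (ties): merge knots
            knot_y[-1] = (knot_y[-1] + ky) / 2
        else:
            knot_x.append(kx)
            knot_y.append(ky)
    knot_x = np.asarray(knot_x)
    knot_y = np.asarray(knot_y)
    yhat = np.interp(x, knot_x, knot_y)
    if len(knot_x) >= 2:
        # linear extrapolation beyond the outer knots (np.interp clamps)
        lo = x < knot_x[0]
        hi = x > knot_x[-1]
        s0 = (knot_y[1] - knot_y[0]) / (knot_x[1] - knot_x[0])
        s1 = (knot_y[-1] - knot_y[-2]) / (knot_x[-1] - knot_x[-2])
        yhat[lo] = knot_y[0] + s0 * (x[lo] - knot_x[0])
        yhat[hi] = knot_y[-1] + s1 * (x[hi] - knot_x[-1])
    var_y = y.var()
    if var_y == 0:
        raise DegenerateInputError("constant target series")
    h2 = 1.0 - float(np.var(y - yhat)) / float(var_y)
    return float(np.clip(h2, 0.0, 1.0))


def edge_h2(x, y, directed: bool = False, max_delay: int = 5, n_bins: int = 10) -> float:
    """Nonlinear correlation h2: undirected takes the larger of the two
    directions at lag zero; directed scans lags of the target."""
    x, y = _check_pair(x, y)
    if not directed:
        return max(_h2_one(x, y, n_bins), _h2_one(y, x, n_bins))
    n = len(x)
    best = 0.0
    for tau in range(0, max_delay + 1):
        if n - tau < 4:
            break
        best = max(best, _h2_one(x[: n - tau], y[tau:], n_bins))
    return best


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log(p)).sum())


def _mi_norm(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    hx = _entropy(joint.sum(axis=1))
    hy = _entropy(joint.sum(axis=0))
    hxy = _entropy(joint)
    if hx == 0 or hy == 0:
        raise DegenerateInputError("constant series under binning")
    mi = hx + hy - hxy
    return float(np.clip(mi / np.sqrt(hx * hy), 0.0, 1.0))


def edge_mit(x, y, directed: bool = False, max_delay: int = 5, n_bins: int = 5) -> float:
    """Mutual information from an n_bins x n_bins joint histogram, normalized
    as I / sqrt(H_X H_Y) so identical series score 1."""
    x, y = _check_pair(x, y)
    if not directed:
        return _mi_norm(x, y, n_bins)
    n = len(x)
    best = 0.0
    for tau in range(0, max_delay + 1):
        if n - tau < 3:
            break
        best = max(best, _mi_norm(x[: n - tau], y[tau:], n_bins))
    return best


def _digitize(v: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateInputError("constant series under binning")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.digitize(v, edges[1:-1])  # right-closed last bin
    return idx


def _te_one(x: np.ndarray, y: np.ndarray, past: int, lag: int, n_bins: int) -> float:
    """Binned transfer entropy x -> y at source lag ``lag``.

    The target's own past block of ``past`` samples is summarized by its
    mean before binning; the source enters as the single sample x_{t-1-lag}
    (the delay scan over lags covers the source's recent past), yielding
    the conditional mutual information I(y_t ; x_{t-1-lag} | y_past)
    normalized by H(y_t | y_past).
    """
    n = len(x)
    start = past + lag
    if n - start < 3:
        return 0.0
    y_t = y[start:]
    y_past = sliding_window_view(y, past).mean(axis=1)[start - past : n - past]
    x_past = x[start - 1 - lag : n - 1 - lag]
    a = _digitize(y_t, n_bins)
    b = _digitize(x_past, n_bins)
    c = _digitize(y_past, n_bins)
    m = len(a)
    flat_abc = (a * n_bins + b) * n_bins + c
    flat_ac = a * n_bins + c
    flat_bc = b * n_bins + c
    h_abc = _entropy(np.bincount(flat_abc, minlength=n_bins**3))
    h_ac = _entropy(np.bincount(flat_ac, minlength=n_bins**2))
    h_bc = _entropy(np.bincount(flat_bc, minlength=n_bins**2))
    h_c = _entropy(np.bincount(c, minlength=n_bins))
    cmi = h_ac + h_bc - h_c - h_abc
    h_y_given_past = h_ac - h_c
    if h_y_given_past <= 0:
        return 0.0
    return float(np.clip(cmi / h_y_given_past, 0.0, 1.0))


def edge_te(
    x,
    y,
    directed: bool = False,
    max_delay: int = 5,
    past_samples: int = 5,
    n_bins: int = 5,
) -> float:
    """Normalized binned transfer entropy.

    Directed: max over source-past lags 0..max_delay of TE(x -> y).
    Undirected: mean of the two directed values.
    """
    x, y = _check_pair(x, y)
    if len(x) <= past_samples + max_delay + 1:
        raise ValueError("series too short for the requested pasts and delays")

    def directed_te(a, b):
        return max(
            _te_one(a, b, past_samples, lag, n_bins) for lag in range(max_delay + 1)
        )

    if directed:
        return directed_te(x, y)
    return 0.5 * (directed_te(x, y) + directed_te(y, x))


def _edge_weight(x: np.ndarray, y: np.ndarray, spec: EdgeMethodSpec) -> float:
    if spec.family == "corr":
        return edge_corr(x, y, spec.directed, spec.max_delay)
    if spec.family == "H2":
        return edge_h2(x, y, spec.directed, spec.max_delay, spec.n_bins)
    if spec.family == "MIT":
        return edge_mit(x, y, spec.directed, spec.max_delay, spec.n_bins)
    return edge_te(
        x, y, spec.directed, spec.max_delay, spec.te_past_samples, spec.n_bins
    )


def build_graph(ts: ClusterTimeSeries, spec: EdgeMethodSpec) -> ConnectivityGraph:
    """Pairwise estimator application per sliding window, averaged across
    windows.

    Degenerate (constant-in-window) cluster series get zero-weight incident
    edges with a logged warning rather than failing the subject.
    """
    series = np.asarray(ts.series, dtype=float)
    k, t = series.shape
    if k < 2:
        raise ValueError("need at least two clusters")
    windows = sliding_windows(t, spec.window_length, spec.window_overlap_fraction)
    acc = np.zeros((k, k))
    for lo, hi in windows:
        win = series[:, lo:hi]
        w = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                if j <= i and not spec.directed:
                    continue
                if j == i:
                    continue
                try:
                    w[i, j] = _edge_weight(win[i], win[j], spec)
                except DegenerateInputError:
                    logger.warning(
                        "degenerate cluster series (window %d:%d); zero edges",
                        lo,
                        hi,
                    )
                    w[i, j] = 0.0
                if not spec.directed:
                    w[j, i] = w[i, j]
        acc += w
    weights = np.abs(acc / len(windows))
    np.fill_diagonal(weights, 0.0)
    if not spec.directed:
        weights = 0.5 * (weights + weights.T)
    return ConnectivityGraph(
        weights=weights,
        directed=spec.directed,
        node_ids=list(ts.cluster_ids),
        method=spec,
    )
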