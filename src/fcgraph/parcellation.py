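"""Voxel parcellation: atlas labels, spatially constrained Ward clustering,
and region growing and selection (RGS) with a broken-stick homogeneity gate.

A parcellation turns a subject's voxel grid into graph nodes.  Atlas
parcellation applies a fixed label volume; Ward clustering agglomerates
spatially adjacent voxels under the minimum-variance criterion; RGS grows a
candidate region around every voxel (adding 6-neighbours whose correlation
with the region mean exceeds a threshold T while the region stays
functionally homogeneous) and then keeps a maximal set of large regions
whose centres do not overlap.

Functional homogeneity is quantified by comparing the eigenvalues of the
within-region covariance against the broken-stick null spectrum
b_n = sum_{i=n}^{N} 1/i: the number n0 of leading eigenvalues exceeding the
baseline estimates the number of independent signals, and an interpolated
heterogeneity index h refines it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import label as cc_label
from sklearn.cluster import AgglomerativeClustering
from sklearn.feature_extraction.image import grid_to_graph

from fcgraph.cohort import LabelVolume, SubjectVolume
from fcgraph.errors import DegenerateInputError, EmptyParcellationError

logger = logging.getLogger(__name__)

__all__ = [
    "Parcellation",
    "Cluster",
    "ClusterTimeSeries",
    "HeterogeneityResult",
    "NodeStats",
    "Region",
    "PARCELLATION_PRESETS",
    "atlas_parcellate",
    "ward_parcellate",
    "rgs_grow",
    "rgs_select",
    "rgs_parcellate",
    "heterogeneity",
    "broken_stick",
    "extract_mean_timeseries",
    "parcellation_summary",
]

#: Parcellation presets: paper-scale parameters plus synthetic-scale variants
#: (prefix "s") sized for the default 12x12x6 grid.
PARCELLATION_PRESETS: dict[str, dict] = {
    "ward1": {"method": "ward", "k": 5000, "p": 10},
    "ward2": {"method": "ward", "k": 5000, "p": 25},
    "ward3": {"method": "ward", "k": 2000, "p": 10},
    "ward4": {"method": "ward", "k": 2000, "p": 25},
    "RGS1": {"method": "rgs", "T": 0.75, "p": 55},
    "RGS2": {"method": "rgs", "T": 0.75, "p": 50},
    "atlas": {"method": "atlas"},
    # synthetic-scale variants for the shipped 864-voxel default grid
    "sward1": {"method": "ward", "k": 8, "p": 4},
    "sward2": {"method": "ward", "k": 16, "p": 8},
    "sRGS1": {"method": "rgs", "T": 0.75, "p": 8},
    "satlas": {"method": "atlas"},
}

_NEIGHBOUR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass
class Cluster:
    cluster_id: int
    voxels: np.ndarray  # (n, 3) integer coordinates
    center: tuple[int, int, int]

    @property
    def size(self) -> int:
        return len(self.voxels)


@dataclass
class Parcellation:
    """Voxel-to-cluster assignment plus explicit per-cluster voxel lists.

    For atlas/Ward parcellations clusters partition the assigned voxels; for
    RGS clusters may overlap, in which case ``assignment`` maps each voxel to
    the lowest cluster id containing it (0 = unassigned).
    """

    assignment: np.ndarray
    clusters: list[Cluster]
    method_tag: str

    def __post_init__(self) -> None:
        if not self.clusters:
            raise EmptyParcellationError(f"{self.method_tag}: no clusters")
        ids = [c.cluster_id for c in self.clusters]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("cluster ids must be contiguous from 1")
        if any(c.size == 0 for c in self.clusters):
            raise ValueError("clusters must be non-empty")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass
class ClusterTimeSeries:
    """Cluster-mean signals, one row per cluster."""

    series: np.ndarray  # (n_clusters, t)
    cluster_ids: list[int]

    def __post_init__(self) -> None:
        if self.series.shape[0] != len(self.cluster_ids):
            raise ValueError("row count must match cluster_ids")
        if not np.isfinite(self.series).all():
            raise ValueError("series must be finite")


@dataclass
class HeterogeneityResult:
    n0: int
    h_interp: float
    eigenvalues: np.ndarray
    baseline: np.ndarray


@dataclass
class NodeStats:
    n_nodes: int
    mean_voxels_per_node: float
    mean_heterogeneity: float


@dataclass
class Region:
    """An RGS candidate region grown from one seed voxel."""

    center: tuple[int, int, int]
    voxels: np.ndarray  # (n, 3)

    @property
    def size(self) -> int:
        return len(self.voxels)


def broken_stick(n: int) -> np.ndarray:
    """Broken-stick baseline b_k = sum_{i=k}^{n} 1/i for k = 1..n."""
    inv = 1.0 / np.arange(1, n + 1)
    return np.cumsum(inv[::-1])[::-1]


def _scaled_eigenvalues(series: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the N x N series covariance, scaled to sum N.

    Uses the Gram matrix on the smaller of the spatial/temporal sides; the
    nonzero spectra coincide and the scaling removes any variance convention.
    """
    n, t = series.shape
    centred = series - series.mean(axis=1, keepdims=True)
    if n <= t:
        gram = centred @ centred.T
    else:
        gram = centred.T @ centred
    ev = np.linalg.eigvalsh(gram)[::-1]
    ev = np.clip(ev, 0.0, None)
    out = np.zeros(n)
    out[: min(n, t)] = ev[: min(n, t)]
    total = out.sum()
    if total <= 0:
        raise DegenerateInputError("all series are constant")
    return out * (n / total)


def heterogeneity(series: np.ndarray) -> HeterogeneityResult:
    """Spatial functional heterogeneity of N voxel time series.

    Compares the eigenvalues e_n of the covariance of the N series (scaled
    so that they sum to N, matching the broken-stick baseline's total)
    against b_n.  n0 is the count of leading eigenvalues with e_n > b_n; the
    interpolated index h refines n0 by where the two curves cross.  h = 1
    indicates a single underlying signal.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 2:
        raise ValueError("need a matrix of at least two series")
    variances = series.var(axis=1)
    if np.any(variances == 0):
        raise DegenerateInputError("constant series in input")
    n = series.shape[0]
    e = _scaled_eigenvalues(series)
    b = broken_stick(n)
    above = e > b
    n0 = 0
    for flag in above:
        if flag:
            n0 += 1
        else:
            break
    n0 = max(n0, 1)  # pure-noise spectra never cross; report one signal
    if n0 >= n:
        h = float(n)
    else:
        num = e[n0 - 1] - b[n0 - 1]
        den = (e[n0 - 1] - e[n0]) - (b[n0 - 1] - b[n0])
        h = n0 + num / den if den > 0 else float(n0)
    return HeterogeneityResult(n0=n0, h_interp=max(h, 1.0), eigenvalues=e, baseline=b)


def _is_homogeneous(series: np.ndarray) -> bool:
    """True when the broken-stick comparison finds a single signal (n0 = 1)."""
    n = series.shape[0]
    if n < 2:
        return True
    try:
        e = _scaled_eigenvalues(series)
    except DegenerateInputError:
        return False
    b = broken_stick(n)
    # n0 (clamped to >= 1) equals 1 unless the two leading eigenvalues both
    # exceed the baseline
    return not (e[0] > b[0] and e[1] > b[1])


def _center_voxel(voxels: np.ndarray) -> tuple[int, int, int]:
    """Cluster representative: voxel nearest the centroid, ties lexicographic."""
    centroid = voxels.mean(axis=0)
    d2 = ((voxels - centroid) ** 2).sum(axis=1)
    order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0], d2))
    return tuple(int(v) for v in voxels[order[0]])


def _build_assignment(
    grid_shape: tuple[int, ...], clusters: list[Cluster]
) -> np.ndarray:
    assignment = np.zeros(grid_shape, dtype=np.int32)
    for cluster in reversed(clusters):  # lowest id wins on overlap
        idx = tuple(cluster.voxels.T)
        assignment[idx] = cluster.cluster_id
    return assignment


def atlas_parcellate(subject: SubjectVolume, labels: LabelVolume) -> Parcellation:
    """One cluster per atlas label, intersected with the subject mask."""
    lab = np.asarray(labels.labels)
    if lab.shape != subject.mask.shape:
        raise ValueError("label volume shape does not match subject grid")
    clusters: list[Cluster] = []
    next_id = 1
    for region in range(1, labels.n_regions + 1):
        voxels = np.argwhere((lab == region) & subject.mask)
        if len(voxels) == 0:
            continue
        clusters.append(
            Cluster(cluster_id=next_id, voxels=voxels, center=_center_voxel(voxels))
        )
        next_id += 1
    if not clusters:
        raise EmptyParcellationError("no atlas region intersects the mask")
    return Parcellation(
        assignment=_build_assignment(subject.mask.shape, clusters),
        clusters=clusters,
        method_tag="atlas",
    )


def ward_parcellate(
    subject: SubjectVolume, k: int, p: int, method_tag: str = "ward"
) -> Parcellation:
    """Spatially constrained Ward clustering into k clusters, then a minimum
    cluster size filter.

    Agglomerative merging under the Ward (minimum intra-cluster variance)
    criterion is restricted to 6-connected neighbours; clusters with fewer
    than p voxels are then discarded and the survivors re-indexed.
    """
    if k < 1 or p < 1:
        raise ValueError("k and p must be >= 1")
    coords = np.argwhere(subject.mask)
    if k > len(coords):
        raise ValueError("k exceeds the number of masked voxels")
    x = subject.data[subject.mask]  # (n_voxels, t)
    if k == 1:
        labels = np.zeros(len(coords), dtype=int)
    else:
        nx, ny, nz = subject.mask.shape
        connectivity = grid_to_graph(nx, ny, nz, mask=subject.mask)
        model = AgglomerativeClustering(
            n_clusters=k, linkage="ward", connectivity=connectivity
        )
        labels = model.fit_predict(x)
    clusters: list[Cluster] = []
    next_id = 1
    for lab in range(labels.max() + 1):
        voxels = coords[labels == lab]
        if len(voxels) < p:
            continue
        clusters.append(
            Cluster(cluster_id=next_id, voxels=voxels, center=_center_voxel(voxels))
        )
        next_id += 1
    if not clusters:
        raise EmptyParcellationError("all Ward clusters fell below p voxels")
    return Parcellation(
        assignment=_build_assignment(subject.mask.shape, clusters),
        clusters=clusters,
        method_tag=method_tag,
    )


def _grow_from_seed(
    seed: tuple[int, int, int],
    series: dict[tuple[int, int, int], np.ndarray],
    threshold: float,
) -> Region:
    """Grow one region: repeatedly add the best-correlated qualifying
    6-neighbour while the merged region stays homogeneous."""
    region = [seed]
    in_region = {seed}
    region_sum = series[seed].copy()

    def neighbours(v):
        for off in _NEIGHBOUR_OFFSETS:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if w in series and w not in in_region:
                yield w

    frontier = set(neighbours(seed))
    while frontier:
        mean_sig = region_sum / len(region)
        ms = mean_sig - mean_sig.mean()
        ms_norm = np.linalg.norm(ms)
        scored = []
        for v in frontier:
            s = series[v]
            sc = s - s.mean()
            denom = ms_norm * np.linalg.norm(sc)
            if denom == 0:
                continue
            r = float(ms @ sc) / denom
            if r > threshold:
                scored.append((-r, v))
        scored.sort()
        added = None
        for _, v in scored:
            candidate = np.vstack([series[w] for w in region] + [series[v]])
            if _is_homogeneous(candidate):
                added = v
                break
        if added is None:
            break
        region.append(added)
        in_region.add(added)
        region_sum += series[added]
        frontier.discard(added)
        frontier.update(neighbours(added))
    return Region(center=seed, voxels=np.array(region, dtype=int))


def rgs_grow(subject: SubjectVolume, T: float) -> list[Region]:
    """Grow a candidate region from every masked voxel.

    A 6-neighbour joins the region when its Pearson correlation with the
    current region-mean signal exceeds T and the merged region remains
    functionally homogeneous (broken-stick n0 = 1, checked per added voxel).
    Zero-variance seed voxels are skipped with a warning.
    """
    if not 0 < T < 1:
        raise ValueError("T must lie in (0, 1)")
    coords = [tuple(int(i) for i in v) for v in np.argwhere(subject.mask)]
    series: dict[tuple[int, int, int], np.ndarray] = {}
    for v in coords:
        s = subject.data[v]
        if s.var() == 0:
            logger.warning("skipping zero-variance voxel %s", v)
            continue
        series[v] = s.astype(float)
    regions = [_grow_from_seed(v, series, T) for v in sorted(series)]
    return regions


def rgs_select(regions: list[Region], p: int) -> Parcellation:
    """Iteratively select the largest region, deleting regions whose centre
    lies inside it; drop surviving clusters smaller than p voxels.

    Selected clusters may overlap spatially but no cluster's centre lies
    inside another selected cluster.  Clusters that end up split into
    disconnected components are kept but counted and logged.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    remaining = sorted(regions, key=lambda r: (-r.size, r.center))
    selected: list[Region] = []
    while remaining:
        largest = remaining.pop(0)
        selected.append(largest)
        covered = {tuple(v) for v in largest.voxels}
        remaining = [r for r in remaining if tuple(r.center) not in covered]
    kept = [r for r in selected if r.size >= p]
    if not kept:
        raise EmptyParcellationError("no RGS region reached p voxels")
    clusters = [
        Cluster(cluster_id=i, voxels=r.voxels, center=tuple(r.center))
        for i, r in enumerate(kept, start=1)
    ]
    # spatial-consistency check: deletion can in principle disrupt clusters
    grid_shape = tuple(np.max([c.voxels.max(axis=0) for c in clusters], axis=0) + 1)
    n_disrupted = 0
    for c in clusters:
        vol = np.zeros(grid_shape, dtype=bool)
        vol[tuple(c.voxels.T)] = True
        _, n_comp = cc_label(vol)
        if n_comp > 1:
            n_disrupted += 1
    if n_disrupted:
        logger.warning("%d RGS cluster(s) are spatially disconnected", n_disrupted)
    assignment_shape = grid_shape
    return Parcellation(
        assignment=_build_assignment(assignment_shape, clusters),
        clusters=clusters,
        method_tag="RGS",
    )


def rgs_parcellate(
    subject: SubjectVolume, T: float, p: int, method_tag: str = "RGS"
) -> Parcellation:
    """Full region-growing-and-selection parcellation (grow then select)."""
    parc = rgs_select(rgs_grow(subject, T), p)
    parc.method_tag = method_tag
    # rebuild assignment on the subject grid (selection used a tight grid)
    parc.assignment = _build_assignment(subject.mask.shape, parc.clusters)
    return parc


def extract_mean_timeseries(
    subject: SubjectVolume, parc: Parcellation
) -> ClusterTimeSeries:
    """Arithmetic mean signal of each cluster; overlapping voxels contribute
    to every cluster that contains them."""
    rows = []
    for cluster in parc.clusters:
        idx = tuple(cluster.voxels.T)
        rows.append(subject.data[idx].mean(axis=0))
    return ClusterTimeSeries(
        series=np.array(rows), cluster_ids=[c.cluster_id for c in parc.clusters]
    )


def parcellation_summary(parc: Parcellation, subject: SubjectVolume) -> NodeStats:
    """Node count, mean cluster size and mean per-cluster heterogeneity."""
    sizes = [c.size for c in parc.clusters]
    hs = []
    for cluster in parc.clusters:
        if cluster.size < 2:
            hs.append(1.0)
            continue
        idx = tuple(cluster.voxels.T)
        try:
            hs.append(heterogeneity(subject.data[idx]).h_interp)
        except DegenerateInputError:
            hs.append(1.0)
    return NodeStats(
        n_nodes=parc.n_clusters,
        mean_voxels_per_node=float(np.mean(sizes)),
        mean_heterogeneity=float(np.mean(hs)),
    )
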