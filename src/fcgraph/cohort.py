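"""Synthetic rfMRI-like cohorts with planted spatial clusters.

The generator emulates preprocessed resting-state data: each subject is a 4D
voxel x time array in which spatially contiguous blocks of voxels share a
latent low-frequency signal, latent signals of different blocks are
correlated according to a condition-specific coupling matrix, and voxels add
independent Gaussian noise.  Three health conditions are modelled (healthy
control C, mild cognitive impairment MCI, Alzheimer's disease AD) whose only
difference is the inter-cluster coupling; the default cohort has 26/16/14
subjects per condition and 130 time points at TR = 3 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONDITIONS: tuple[str, ...] = ("C", "MCI", "AD")

__all__ = [
    "CONDITIONS",
    "SyntheticConfig",
    "SubjectVolume",
    "LabelVolume",
    "coupling_matrix",
    "default_config",
    "null_config",
    "separable_config",
    "simulate_subject",
    "simulate_cohort",
    "make_atlas_labels",
]


@dataclass(frozen=True)
class LabelVolume:
    """Integer label volume; 0 is background, regions are 1..n_regions."""

    labels: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("labels must be a 3D integer array")
        present = np.unique(labels[labels > 0])
        if present.size and (present.min() < 1 or present.max() > self.n_regions):
            raise ValueError("nonzero labels must lie in 1..n_regions")


@dataclass
class SubjectVolume:
    """One subject's 4D voxel time series with mask and condition label."""

    data: np.ndarray
    mask: np.ndarray
    tr_seconds: float
    subject_id: str
    condition: str
    ground_truth: LabelVolume | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")
        if not np.isfinite(self.data).all():
            raise ValueError("data must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    ``coupling`` maps each condition label to a symmetric matrix with unit
    diagonal giving the target correlation between the latent signals of the
    planted clusters.  ``temporal_smoothing`` is the AR(1) coefficient of the
    latent signals; ``noise_sd`` the voxel-level i.i.d. Gaussian noise
    standard deviation (latent signals have unit variance).
    """

    grid_shape: tuple[int, int, int] = (12, 12, 6)
    n_timepoints: int = 130
    tr_seconds: float = 3.0
    n_latent_clusters: int = 4
    coupling: dict[str, np.ndarray] = field(default_factory=dict)
    noise_sd: float = 0.5
    temporal_smoothing: float = 0.4
    cohort_sizes: dict[str, int] = field(
        default_factory=lambda: {"C": 26, "MCI": 16, "AD": 14}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_latent_clusters < 1:
            raise ValueError("n_latent_clusters must be positive")
        if int(np.prod(self.grid_shape)) < self.n_latent_clusters:
            raise ValueError("grid volume must be >= n_latent_clusters")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.temporal_smoothing < 1:
            raise ValueError("temporal_smoothing must lie in [0, 1)")
        if not self.coupling:
            object.__setattr__(
                self,
                "coupling",
                {
                    c: coupling_matrix(self.n_latent_clusters, off)
                    for c, off in zip(CONDITIONS, (0.5, 0.35, 0.2))
                },
            )
        for cond, mat in self.coupling.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (self.n_latent_clusters, self.n_latent_clusters):
                raise ValueError(f"coupling[{cond}] has wrong shape")
            if not np.allclose(mat, mat.T):
                raise ValueError(f"coupling[{cond}] must be symmetric")
            if not np.allclose(np.diag(mat), 1.0):
                raise ValueError(f"coupling[{cond}] must have unit diagonal")
        for cond, n in self.cohort_sizes.items():
            if n < 1:
                raise ValueError(f"cohort size for {cond} must be positive")
            if cond not in self.coupling:
                raise ValueError(f"no coupling matrix for condition {cond}")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.cohort_sizes)


def coupling_matrix(k: int, off_diagonal: float) -> np.ndarray:
    """Symmetric k x k matrix with unit diagonal and constant off-diagonal."""
    m = np.full((k, k), float(off_diagonal))
    np.fill_diagonal(m, 1.0)
    return m


def default_config(**overrides) -> SyntheticConfig:
    """Default three-condition cohort: coupling declines C > MCI > AD."""
    return SyntheticConfig(**overrides)


def null_config(**overrides) -> SyntheticConfig:
    """Cohort in which all conditions share one coupling matrix.

    Conditions are then statistically indistinguishable, so leave-one-out
    negative surprise converges to the chance level ln(1/3).
    """
    k = overrides.pop("n_latent_clusters", 4)
    coupling = {c: coupling_matrix(k, 0.35) for c in CONDITIONS}
    return SyntheticConfig(n_latent_clusters=k, coupling=coupling, **overrides)


def separable_config(gap: float = 0.6, noise_sd: float = 0.3, **overrides) -> SyntheticConfig:
    """Strongly separated conditions: off-diagonal couplings spread by ``gap``.

    ``gap`` is the spread between the C and AD off-diagonal coupling around a
    centre of 0.4; MCI sits midway.  With the default gap the couplings are
    0.7 / 0.4 / 0.1.
    """
    k = overrides.pop("n_latent_clusters", 4)
    centre = 0.4
    offs = (centre + gap / 2, centre, centre - gap / 2)
    if not all(0 <= o <= 1 for o in offs):
        raise ValueError("gap places couplings outside [0, 1]")
    coupling = {c: coupling_matrix(k, o) for c, o in zip(CONDITIONS, offs)}
    return SyntheticConfig(
        n_latent_clusters=k, coupling=coupling, noise_sd=noise_sd, **overrides
    )


def crossing_config(noise_sd: float = 0.5, **overrides) -> SyntheticConfig:
    """Cohort whose C-vs-AD mean-weight difference flips sign with the
    threshold.

    C couples all six latent clusters uniformly at 0.4.  AD couples a hub
    cluster to every other at 0.55 while the remaining pairs couple at only
    0.15: including the weak pairs, AD's mean edge weight sits below C's,
    but thresholding at 0.3 removes exactly those weak edges (leaving the
    star, hence a connected graph) and AD's mean among surviving edges
    rises above C's.  Demonstrates that the sign of a significant group
    difference in mean weight can depend on the thresholding choice.
    """
    k = 6
    c_mat = coupling_matrix(k, 0.4)
    mci = coupling_matrix(k, 0.35)
    ad = coupling_matrix(k, 0.15)
    ad[0, 1:] = ad[1:, 0] = 0.55
    coupling = {"C": c_mat, "MCI": mci, "AD": ad}
    return SyntheticConfig(
        n_latent_clusters=k, coupling=coupling, noise_sd=noise_sd, **overrides
    )


def _ar1(rng: np.random.Generator, k: int, t: int, a: float) -> np.ndarray:
    """k independent stationary unit-variance AR(1) series of length t."""
    innov = rng.standard_normal((k, t))
    z = np.empty((k, t))
    z[:, 0] = innov[:, 0]
    scale = np.sqrt(1.0 - a * a)
    for i in range(1, t):
        z[:, i] = a * z[:, i - 1] + scale * innov[:, i]
    return z


def simulate_subject(
    config: SyntheticConfig, condition: str, seed: int
) -> SubjectVolume:
    """Simulate one subject under ``condition``.

    Latent cluster signals are independent AR(1) processes mixed by the
    Cholesky factor of the condition's coupling matrix, so their correlation
    matrix equals the coupling matrix.  Every voxel of a planted cluster
    carries that cluster's latent signal plus i.i.d. Gaussian noise.
    Deterministic given (config, condition, seed).
    """
    if condition not in config.coupling:
        raise ValueError(f"unknown condition label: {condition!r}")
    labels = make_atlas_labels(config, config.n_latent_clusters)
    rng = np.random.default_rng(seed)
    k, t = config.n_latent_clusters, config.n_timepoints
    z = _ar1(rng, k, t, config.temporal_smoothing)
    chol = np.linalg.cholesky(np.asarray(config.coupling[condition], dtype=float))
    latent = chol @ z  # (k, t), rows correlated per coupling matrix

    mask = np.ones(config.grid_shape, dtype=bool)
    data = np.zeros(config.grid_shape + (t,))
    for c in range(1, k + 1):
        where = labels.labels == c
        n_vox = int(where.sum())
        noise = config.noise_sd * rng.standard_normal((n_vox, t))
        data[where] = latent[c - 1] + noise
    return SubjectVolume(
        data=data,
        mask=mask,
        tr_seconds=config.tr_seconds,
        subject_id=f"{condition}_{seed}",
        condition=condition,
        ground_truth=labels,
    )


def simulate_cohort(config: SyntheticConfig) -> list[SubjectVolume]:
    """Simulate the full cohort; per-subject seeds derive from config.seed."""
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectVolume] = []
    for condition in config.conditions:
        n = config.cohort_sizes[condition]
        seeds = rng.integers(0, 2**31 - 1, size=n)
        for i, s in enumerate(seeds):
            subj = simulate_subject(config, condition, int(s))
            subj.subject_id = f"{condition}{i + 1:02d}"
            subjects.append(subj)
    return subjects


def _bisect_box(
    bounds: tuple[tuple[int, int], ...], n: int
) -> list[tuple[tuple[int, int], ...]]:
    """Recursively split an axis-aligned box into n boxes of near-equal volume."""
    if n == 1:
        return [bounds]
    sizes = [hi - lo for lo, hi in bounds]
    axis = int(np.argmax(sizes))
    lo, hi = bounds[axis]
    n1 = n // 2
    n2 = n - n1
    cut = lo + max(1, min(sizes[axis] - 1, round(sizes[axis] * n1 / n)))
    left = tuple(b if a != axis else (lo, cut) for a, b in enumerate(bounds))
    right = tuple(b if a != axis else (cut, hi) for a, b in enumerate(bounds))
    return _bisect_box(left, n1) + _bisect_box(right, n2)


def make_atlas_labels(config: SyntheticConfig, n_regions: int) -> LabelVolume:
    """Partition the grid into n_regions contiguous rectangular regions.

    Recursive coordinate bisection along the longest axis; every region is a
    box, hence spatially contiguous under 6-connectivity, and the regions
    tile the full mask.  The same label volume serves as a synthetic atlas
    for every subject of a cohort.
    """
    n_vox = int(np.prod(config.grid_shape))
    if n_regions < 1:
        raise ValueError("n_regions must be positive")
    if n_regions > n_vox:
        raise ValueError("n_regions exceeds the number of voxels")
    boxes = _bisect_box(tuple((0, s) for s in config.grid_shape), n_regions)
    labels = np.zeros(config.grid_shape, dtype=np.int32)
    for i, box in enumerate(boxes, start=1):
        (x0, x1), (y0, y1), (z0, z1) = box
        labels[x0:x1, y0:y1, z0:z1] = i
    return LabelVolume(labels=labels, n_regions=n_regions)
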