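"""Synthetic ground truth: grids, network templates, cohorts, motion.

The generator emulates a resting-state cohort whose 4D data are linear
mixtures of spatial sources driven by slow (0.01--0.1 Hz) band-limited
time courses plus Gaussian noise.  Two of the default sources are a
parietal-memory-network-like (PMN) source and a posterior-default-mode
(pDMN) source in close spatial proximity, sharing an overlap fringe of
voxels -- the configuration whose separability under smoothing and model
order the rest of the package studies.

Cluster geometry follows the midline layout of the real networks: the
pDMN has three clusters (one posterior-midline, two lateral), and the
PMN has two midline clusters immediately anterior and posterior of the
pDMN midline cluster, flanking it along the anterior--posterior (y) axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .core import SubjectData, VolumeGrid

__all__ = [
    "SourceSpec",
    "TemplateSet",
    "CohortSimConfig",
    "GroundTruth",
    "GridTooSmallError",
    "make_grid",
    "make_templates",
    "default_sources",
    "simulate_cohort",
    "simulate_motion",
    "bandlimited_timecourses",
]

NETWORK_LABELS = ("PMN", "DMN", "aDMN", "pDMN")


class GridTooSmallError(ValueError):
    """Raised when a grid cannot host all template clusters."""


@dataclass(frozen=True)
class SourceSpec:
    """Geometry of one ground-truth spatial source.

    ``clusters`` is a list of (center voxel (x,y,z), radius in voxels,
    peak weight) triples; each cluster is painted as a solid sphere.
    """

    label: str
    clusters: tuple
    sign: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "clusters", tuple(
            (tuple(int(c) for c in ctr), int(r), float(w))
            for ctr, r, w in self.clusters
        ))
        for ctr, r, w in self.clusters:
            if r < 1:
                raise ValueError(f"cluster radius must be >= 1, got {r}")
            if w <= 0:
                raise ValueError("peak weight must be positive")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")

    def paint(self, grid: VolumeGrid, shift=(0, 0, 0)) -> np.ndarray:
        """Render the source as a 3D weight map on the grid (masked)."""
        vol = np.zeros(grid.dims)
        for ctr, r, w in self.clusters:
            c = tuple(np.asarray(ctr) + np.asarray(shift, dtype=int))
            vol[_sphere(grid.dims, c, r)] = w
        vol *= self.sign
        vol[~grid.brain_mask] = 0.0
        return vol


@dataclass(frozen=True)
class TemplateSet:
    """Binary network masks plus anchor-point voxel coordinates."""

    grid: VolumeGrid
    masks: dict
    anchors: dict

    def __post_init__(self) -> None:
        for label, anchor_list in self.anchors.items():
            m = self.masks[label]
            for ijk in anchor_list:
                if not self.grid.contains(ijk):
                    raise ValueError(f"anchor {ijk} outside grid for {label}")
                if not m[tuple(ijk)]:
                    raise ValueError(f"anchor {ijk} not inside {label} mask")


@dataclass(frozen=True)
class CohortSimConfig:
    """Scale and noise structure of a simulated cohort.

    Defaults are the desk-scale study conditions: 8 subjects, 140
    timepoints at TR 3 s, source time courses band-limited to
    0.01--0.1 Hz, additive Gaussian noise with SD 0.5 relative to a unit
    peak source weight, and half-voxel inter-subject spatial jitter.
    ``baseline`` is a constant in-mask intensity offset emulating the
    large positive mean of real fMRI signal (it makes grand-mean scaling
    well-posed; band-pass filtering later removes it).
    """

    n_subjects: int = 8
    n_timepoints: int = 140
    tr_s: float = 3.0
    noise_sd: float = 0.5
    jitter_sd_voxels: float = 0.5
    tc_band_hz: tuple[float, float] = (0.01, 0.1)
    baseline: float = 100.0
    #: target Pearson correlations between named sources' time courses,
    #: as ((labelA, labelB, rho), ...).  The default couples the
    #: default-mode subsystems and the PMN the way adjacent posterior
    #: midline networks are coupled in vivo -- the very property that
    #: makes low-model-order decompositions absorb the PMN into the DMN.
    #: Pairs naming absent sources are ignored.
    tc_corr: tuple = (("PMN", "pDMN", 0.5), ("aDMN", "pDMN", 0.5),
                      ("PMN", "aDMN", 0.25))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_timepoints < 50:
            raise ValueError("n_timepoints must be >= 50")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.noise_sd < 0 or self.jitter_sd_voxels < 0:
            raise ValueError("noise/jitter SDs must be nonnegative")
        lo, hi = self.tc_band_hz
        nyq = 0.5 / self.tr_s
        if not (0 < lo < hi < nyq):
            raise ValueError(
                f"tc_band_hz must satisfy 0 < low < high < Nyquist ({nyq:.4g} Hz)"
            )


@dataclass
class GroundTruth:
    """Per-subject truth returned alongside a simulated cohort."""

    source_labels: list
    clean_maps: np.ndarray        # (K, V) unjittered masked source maps
    subject_maps: np.ndarray      # (S, K, V) jittered masked source maps
    timecourses: np.ndarray       # (S, K, T) unit-variance time courses
    jitters: np.ndarray           # (S, K, 3) integer shifts applied
    tc_correlations: np.ndarray | None = None  # (S, K, K) empirical Pearson r


def _sphere(dims, center, radius) -> np.ndarray:
    ax = [np.arange(d) for d in dims]
    dx, dy, dz = np.meshgrid(*ax, indexing="ij")
    d2 = ((dx - center[0]) ** 2 + (dy - center[1]) ** 2 + (dz - center[2]) ** 2)
    return d2 <= radius ** 2


def make_grid(dims=(24, 28, 24), voxel_size_mm=(3.0, 3.0, 3.0)) -> VolumeGrid:
    """Build a grid whose brain mask is a centered ellipsoid.

    The ellipsoid semi-axes are 0.45 of each dimension, which occupies
    roughly 38% of the lattice.  Deterministic given its arguments.
    """
    dims = tuple(int(d) for d in dims)
    if any(d < 8 for d in dims):
        raise ValueError("all dims must be >= 8")
    if any(v <= 0 for v in voxel_size_mm):
        raise ValueError("voxel sizes must be positive")
    center = [(d - 1) / 2.0 for d in dims]
    semi = [0.45 * d for d in dims]
    ax = [np.arange(d) for d in dims]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    mask = (
        ((gx - center[0]) / semi[0]) ** 2
        + ((gy - center[1]) / semi[1]) ** 2
        + ((gz - center[2]) / semi[2]) ** 2
    ) <= 1.0
    return VolumeGrid(dims=dims, voxel_size_mm=tuple(voxel_size_mm), brain_mask=mask)


def _template_geometry(grid: VolumeGrid):
    """Cluster centers and radius for the PMN/DMN template layout,
    scaled to the grid.  Raises GridTooSmallError when they do not fit."""
    nx, ny, nz = grid.dims
    r = max(1, min(grid.dims) // 12)
    x0, z0 = nx // 2, nz // 2
    y_mid = int(round(0.32 * ny))           # pDMN posterior-midline cluster
    y_ant = y_mid + 2 * r                   # PMN cluster anterior of it
    y_post = y_mid - 2 * r                  # PMN cluster posterior of it
    dx_lat = int(round(0.25 * nx))          # lateral (angular-gyrus-like) offset
    y_admn = int(round(0.78 * ny))          # anterior (paracingulate-like)
    centers = {
        "pdmn_mid": (x0, y_mid, z0),
        "pdmn_left": (x0 - dx_lat, y_mid, z0),
        "pdmn_right": (x0 + dx_lat, y_mid, z0),
        "pmn_ant": (x0, y_ant, z0),
        "pmn_post": (x0, y_post, z0),
        "admn": (x0, y_admn, z0),
    }
    if dx_lat < 2 * r + 2:
        raise GridTooSmallError("lateral pDMN clusters would touch the midline cluster")
    if y_post - r < 1:
        raise GridTooSmallError("posterior PMN cluster leaves the lattice")
    for name, c in centers.items():
        if not grid.brain_mask[c]:
            raise GridTooSmallError(f"cluster center {name}={c} falls outside the brain mask")
    return centers, r


def make_templates(grid: VolumeGrid) -> TemplateSet:
    """Generate the PMN/DMN/aDMN/pDMN binary templates and anchors.

    Layout (all midline clusters at x = nx//2):

    * pDMN: one posterior-midline sphere plus two lateral spheres
      (3 connected components under 6-connectivity);
    * PMN: two midline spheres placed immediately anterior and posterior
      of the pDMN midline sphere, each sharing a 1-voxel overlap fringe
      with it (the center-to-center spacing of 2r leaves exactly the
      midpoint voxel in both spheres);
    * aDMN: one anterior midline sphere, disjoint from everything else;
    * DMN = aDMN | pDMN (disjoint union).

    Anchors sit at cluster centers: two for PMN (its midline clusters),
    one for pDMN (its midline cluster), one for aDMN, and the DMN anchor
    pair = {pDMN midline anchor, aDMN anchor}.
    """
    centers, r = _template_geometry(grid)
    mask = grid.brain_mask

    def ball(name):
        return _sphere(grid.dims, centers[name], r) & mask

    pdmn = ball("pdmn_mid") | ball("pdmn_left") | ball("pdmn_right")
    pmn = ball("pmn_ant") | ball("pmn_post")
    admn = ball("admn")
    if (admn & pdmn).any() or (admn & pmn).any():
        raise GridTooSmallError("aDMN cluster collides with posterior clusters")
    dmn = admn | pdmn
    masks = {"PMN": pmn, "DMN": dmn, "aDMN": admn, "pDMN": pdmn}
    anchors = {
        "PMN": [centers["pmn_ant"], centers["pmn_post"]],
        "pDMN": [centers["pdmn_mid"]],
        "aDMN": [centers["admn"]],
        "DMN": [centers["pdmn_mid"], centers["admn"]],
    }
    return TemplateSet(grid=grid, masks=masks, anchors=anchors)


def default_sources(grid: VolumeGrid, n_background: int = 5) -> list:
    """The default ground-truth source set: PMN, pDMN and aDMN sources
    built from the template geometry, plus generic background networks
    (visual/motor/frontal/lateral-like blobs) for a realistic source
    count (8 by default)."""
    centers, r = _template_geometry(grid)
    nx, ny, nz = grid.dims
    x0, z0 = nx // 2, nz // 2
    cy = ny // 2

    def inward(c):
        # pull a center toward the grid center until it is in-mask
        c = np.asarray(c, dtype=float)
        mid = np.array([(d - 1) / 2.0 for d in grid.dims])
        for _ in range(max(grid.dims)):
            ijk = tuple(int(round(v)) for v in c)
            if grid.contains(ijk) and grid.brain_mask[ijk]:
                return ijk
            c += 0.15 * (mid - c)
        raise GridTooSmallError("could not place a background source in the mask")

    sources = [
        SourceSpec("PMN", [(centers["pmn_ant"], r, 1.0), (centers["pmn_post"], r, 1.0)]),
        SourceSpec("pDMN", [(centers["pdmn_mid"], r, 1.0),
                            (centers["pdmn_left"], r, 1.0),
                            (centers["pdmn_right"], r, 1.0)]),
        SourceSpec("aDMN", [(centers["admn"], r, 1.0)]),
    ]
    background = [
        ("visual", (x0, round(0.15 * ny), z0 - round(0.25 * nz))),
        ("motor", (x0, cy, z0 + round(0.30 * nz))),
        ("frontal", (x0, round(0.82 * ny), z0 + round(0.15 * nz))),
        ("lateral_left", (x0 - round(0.30 * nx), cy, z0)),
        ("lateral_right", (x0 + round(0.30 * nx), cy, z0)),
    ]
    for label, c in background[:n_background]:
        sources.append(SourceSpec(label, [(inward(c), r, 1.0)]))
    return sources


def bandlimited_timecourses(n_series: int, n_timepoints: int, tr_s: float,
                            band_hz, rng: np.random.Generator) -> np.ndarray:
    """White Gaussian series band-pass filtered to ``band_hz`` (zero-phase
    Butterworth, order 4) and normalized to zero mean, unit variance.
    Returns shape (n_series, n_timepoints)."""
    raw = rng.standard_normal((n_series, n_timepoints))
    sos = signal.butter(4, band_hz, btype="bandpass", fs=1.0 / tr_s, output="sos")
    filt = signal.sosfiltfilt(sos, raw, axis=1)
    filt = filt - filt.mean(axis=1, keepdims=True)
    sd = filt.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return filt / sd


def simulate_cohort(grid: VolumeGrid, sources: Sequence[SourceSpec],
                    config: CohortSimConfig):
    """Simulate a multi-subject cohort of 4D series from spatial sources.

    Each subject's data are ``sum_k map_{k,s} * tc_{k,s} + baseline +
    noise`` inside the brain mask (zero outside), where ``map_{k,s}`` is
    source ``k`` shifted by a per-subject integer jitter (rounded normal,
    SD ``jitter_sd_voxels``) and ``tc_{k,s}`` is a unit-variance time
    course band-limited to ``tc_band_hz``.  A jitter that would push a
    cluster center outside the brain mask is clipped back (with a
    warning).  Fully reproducible from ``config.seed``.

    Returns ``(subjects, truth)`` where ``truth`` is a :class:`GroundTruth`.
    """
    if len(sources) < 1:
        raise ValueError("at least one source is required")
    rng = np.random.default_rng(config.seed)
    S, K, T = config.n_subjects, len(sources), config.n_timepoints
    V = grid.n_voxels
    L = _tc_mixing_chol(sources, config.tc_corr)

    clean = np.stack([grid.extract(src.paint(grid)) for src in sources])
    subj_maps = np.empty((S, K, V))
    tcs = np.empty((S, K, T))
    tc_corrs = np.empty((S, K, K))
    jitters = np.zeros((S, K, 3), dtype=int)
    subjects = []
    for s in range(S):
        indep = bandlimited_timecourses(K, T, config.tr_s, config.tc_band_hz, rng)
        mixed = L @ indep
        mixed -= mixed.mean(axis=1, keepdims=True)
        sd = mixed.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        tcs[s] = mixed / sd
        tc_corrs[s] = np.corrcoef(tcs[s]) if K > 1 else np.ones((1, 1))
        vol4d = np.zeros(grid.dims + (T,))
        for k, src in enumerate(sources):
            shift = np.round(rng.normal(0, config.jitter_sd_voxels, 3)).astype(int)
            shift = _clip_shift(grid, src, shift)
            jitters[s, k] = shift
            m3d = src.paint(grid, shift=tuple(shift))
            subj_maps[s, k] = grid.extract(m3d)
            vol4d += m3d[..., None] * tcs[s, k]
        inside = grid.brain_mask
        vol4d[inside] += config.baseline
        if config.noise_sd > 0:
            vol4d[inside] += rng.normal(0, config.noise_sd, (V, T))
        vol4d[~inside] = 0.0
        subjects.append(SubjectData(grid=grid, series=vol4d, tr_s=config.tr_s,
                                    subject_id=f"sub-{s:02d}"))
    truth = GroundTruth(source_labels=[s.label for s in sources],
                        clean_maps=clean, subject_maps=subj_maps,
                        timecourses=tcs, jitters=jitters,
                        tc_correlations=tc_corrs)
    return subjects, truth


def _tc_mixing_chol(sources, tc_corr) -> np.ndarray:
    """Cholesky factor of the target time-course correlation matrix.

    Pairs referencing labels absent from ``sources`` are ignored; the
    matrix must be positive definite (it is for the defaults).
    """
    labels = [s.label for s in sources]
    K = len(labels)
    C = np.eye(K)
    for a, b, rho in tc_corr:
        if a in labels and b in labels:
            i, j = labels.index(a), labels.index(b)
            C[i, j] = C[j, i] = float(rho)
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("tc_corr does not form a positive-definite "
                         "correlation matrix") from exc


def _clip_shift(grid: VolumeGrid, src: SourceSpec, shift: np.ndarray) -> np.ndarray:
    """Shrink a jitter shift until every cluster center stays in-mask."""
    shift = shift.copy()
    for _ in range(int(np.abs(shift).sum()) + 1):
        ok = all(
            grid.contains(np.asarray(ctr) + shift)
            and grid.brain_mask[tuple(np.asarray(ctr) + shift)]
            for ctr, _, _ in src.clusters
        )
        if ok:
            return shift
        warnings.warn(
            f"jitter {tuple(shift)} pushes source '{src.label}' outside the "
            "brain mask; clipping", stacklevel=3)
        largest = int(np.argmax(np.abs(shift)))
        shift[largest] -= int(np.sign(shift[largest]))
    return shift


def simulate_motion(config: CohortSimConfig, target_mean_fd_mm: float = 0.1) -> list:
    """Simulate per-subject 6-column motion tables (3 translations in mm,
    3 rotations in rad) as smooth random walks, rescaled so each table's
    mean framewise displacement equals ``target_mean_fd_mm``.

    Returns a list of (n_timepoints, 6) arrays, one per subject,
    reproducible from ``config.seed``.
    """
    from .preprocess import mean_fd  # local import: avoids cycle at import time

    if target_mean_fd_mm < 0:
        raise ValueError("target meanFD must be nonnegative")
    rng = np.random.default_rng(config.seed + 104729)
    tables = []
    for _ in range(config.n_subjects):
        steps = rng.standard_normal((config.n_timepoints, 6))
        # low-pass the increments so traces drift smoothly, like real head motion
        sos = signal.butter(2, 0.3, btype="lowpass", output="sos")
        steps = signal.sosfiltfilt(sos, steps, axis=0)
        table = np.cumsum(steps, axis=0)
        table[:, 3:] /= 50.0  # rotations contribute via a 50 mm arm; keep balanced
        if target_mean_fd_mm == 0:
            tables.append(np.zeros_like(table))
            continue
        fd = mean_fd(table)
        tables.append(table * (target_mean_fd_mm / fd))
    return tables
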