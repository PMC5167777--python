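"""Three group-level decomposition schemes for multi-subject fMRI.

All three return the same :class:`Decomposition` contract -- group-level
Z maps plus index-aligned per-subject maps and time courses:

* ``tcgica``  : temporal-concatenation group ICA.  Subjects are variance
  normalized and stacked in time, reduced by group PCA, unmixed by
  spatial fixed-point ICA, and back-projected to subjects with dual
  regression.
* ``raicar_align`` : reproducibility-based alignment.  Each subject is
  decomposed independently; components are greedily matched across
  subjects by absolute spatial correlation, and each aligned group is
  reduced to a similarity-weighted average map.
* ``iva_l`` : independent vector analysis with a multivariate Laplace
  prior on each source component vector (SCV -- the k-th source across
  all subjects).  Per-subject unmixing matrices are optimized jointly by
  natural-gradient ascent, so components come out aligned across
  subjects by construction.

Sign ambiguity is resolved everywhere by flipping each map (and its time
course) so the map's skewness over the brain mask is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core import SubjectData, VolumeGrid, zscore_masked

__all__ = [
    "SubjectICA",
    "Decomposition",
    "fit_single_subject_ica",
    "tcgica",
    "dual_regression",
    "raicar_align",
    "greedy_align",
    "iva_l",
    "decompose",
    "ALGORITHMS",
]

ICA_TOL = 1e-4
ICA_MAX_ITER = 500
ICA_MAX_RESTARTS = 5
RAICAR_SIMILARITY_FLOOR = 0.2
IVA_TOL = 1e-6
IVA_MAX_ITER = 1024

ALGORITHMS = ("TCGICA", "RAICAR", "IVA")


@dataclass
class SubjectICA:
    """A single subject's spatial ICA result (maps are Z-scored)."""

    maps: np.ndarray          # (K, V)
    timecourses: np.ndarray   # (K, T)
    converged: bool
    n_restarts: int


@dataclass
class Decomposition:
    """A group decomposition with index-aligned subject-level results.

    ``group_maps`` (G, V) are Z-scored over the brain mask (zero mean,
    unit SD).  ``subject_maps`` (S, G, V) and ``subject_timecourses``
    (S, G, T) align with group components index-wise.  For RAICAR, G may
    be smaller than the requested model order and ``reproducibility``
    holds the mean within-group pairwise similarity of each component.
    """

    algorithm: str
    model_order: int
    grid: VolumeGrid
    group_maps: np.ndarray
    subject_maps: np.ndarray
    subject_timecourses: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    reproducibility: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.group_maps.shape[0]

    def group_volume(self, k: int) -> np.ndarray:
        return self.grid.embed(self.group_maps[k])


# ---------------------------------------------------------------------------
# helpers

def _skew_flip(vec: np.ndarray) -> int:
    """Sign that makes the vector's skewness positive (+1 on ties)."""
    s = stats.skew(vec)
    return -1 if s < 0 else 1


def _demean_voxels(X: np.ndarray) -> np.ndarray:
    """Remove each voxel's temporal mean from a (T, V) matrix."""
    return X - X.mean(axis=0, keepdims=True)


def _variance_normalize_voxels(X: np.ndarray) -> np.ndarray:
    Xc = _demean_voxels(X)
    sd = Xc.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return Xc / sd


def _whiten_temporal(X: np.ndarray, k: int):
    """PCA-whiten a (T, V) matrix along time to k rows.

    Returns (Y, P) with Y = P @ X of shape (k, V), rows decorrelated with
    unit variance over voxels.  k is reduced (with a warning) if the data
    rank is lower.
    """
    T, V = X.shape
    C = X @ X.T / V
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    usable = int(np.sum(evals > max(evals[0], 1e-300) * 1e-10))
    if k > usable:
        warnings.warn(
            f"model order {k} exceeds data rank {usable}; reducing", stacklevel=3)
        k = usable
    P = (evecs[:, :k] / np.sqrt(evals[:k])).T
    return P @ X, P


def _run_fastica(Y: np.ndarray, seed: int):
    """Fixed-point ICA (logcosh) on pre-whitened (k, V) data.

    Restarts with seed+1 on non-convergence, up to ICA_MAX_RESTARTS times;
    the final attempt is kept and flagged if still not converged.
    Returns (sources (k, V), converged, n_restarts).
    """
    k = Y.shape[0]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    for attempt in range(ICA_MAX_RESTARTS + 1):
        ica = FastICA(n_components=k, whiten=False, fun="logcosh",
                      tol=ICA_TOL, max_iter=ICA_MAX_ITER,
                      random_state=seed + attempt)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            sources = ica.fit_transform(Yc.T).T  # (k, V)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        if converged:
            return sources, True, attempt
    return sources, False, ICA_MAX_RESTARTS


def _zscore_flip_maps(maps: np.ndarray):
    """Z-score rows and flip each to positive skew; returns (maps, signs)."""
    out = np.empty_like(maps)
    signs = np.empty(maps.shape[0], dtype=int)
    for i, m in enumerate(maps):
        z = zscore_masked(m)
        s = _skew_flip(z)
        out[i] = s * z
        signs[i] = s
    return out, signs


# ---------------------------------------------------------------------------
# single-subject ICA

def fit_single_subject_ica(data: SubjectData, model_order: int, seed: int) -> SubjectICA:
    """Spatial ICA of one subject: PCA-whitening of the (time x voxel)
    matrix to ``model_order`` dimensions, then fixed-point ICA with the
    logcosh contrast on the spatial dimension.

    Deterministic given ``seed``; restarts with seed+1 on non-convergence
    (at most 5 times) and flags persistent failure in the result.
    """
    X = _demean_voxels(data.masked_matrix())
    if model_order < 1:
        raise ValueError("model_order must be >= 1")
    if model_order > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError(
            f"model order {model_order} exceeds what {X.shape[0]} timepoints support")
    Y, P = _whiten_temporal(X, model_order)
    sources, converged, n_restarts = _run_fastica(Y, seed)
    maps, signs = _zscore_flip_maps(sources)
    # time course of component k: least-squares fit of X on the sources
    A, *_ = np.linalg.lstsq(sources.T, X.T, rcond=None)  # (k, T)
    tcs = signs[:, None] * A
    return SubjectICA(maps=maps, timecourses=tcs,
                      converged=converged, n_restarts=n_restarts)


# ---------------------------------------------------------------------------
# dual regression

def dual_regression(group_maps: np.ndarray, X: np.ndarray):
    """Two-stage exact least squares from group maps to one subject.

    Stage 1 regresses each timepoint's volume on all group maps at once,
    giving per-component time courses; stage 2 regresses each voxel's
    series on the variance-normalized stage-1 time courses, giving
    per-component subject maps.  No regularization.

    Parameters
    ----------
    group_maps : (K, V) array over brain-mask voxels.
    X : (T, V) subject data matrix over the same voxels.

    Returns
    -------
    (timecourses (T, K), maps (K, V))
    """
    G = np.asarray(group_maps, dtype=float).T       # (V, K)
    X = np.asarray(X, dtype=float)
    if G.shape[0] != X.shape[1]:
        raise ValueError("group maps and data do not share a voxel grid")
    _check_full_rank(G, "group map")
    tcs, *_ = np.linalg.lstsq(G, X.T, rcond=None)   # (K, T)
    tcs = tcs.T                                      # (T, K)
    D = tcs / _safe_sd(tcs)
    _check_full_rank(D, "stage-1 time course")
    maps, *_ = np.linalg.lstsq(D, X, rcond=None)    # (K, V)
    return tcs, maps


def _safe_sd(A: np.ndarray) -> np.ndarray:
    sd = A.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return sd


def _check_full_rank(design: np.ndarray, what: str) -> None:
    sv = np.linalg.svd(design, compute_uv=False)
    if sv[-1] < sv[0] * 1e-10:
        corr = np.corrcoef(design.T)
        np.fill_diagonal(corr, 0.0)
        pairs = [tuple(map(int, ij)) for ij in zip(*np.where(np.abs(corr) > 0.999))
                 if ij[0] < ij[1]]
        raise ValueError(
            f"rank-deficient {what} design; collinear component pairs: {pairs}")


# ---------------------------------------------------------------------------
# TCgICA

def tcgica(cohort, model_order: int, seed: int = 0) -> Decomposition:
    """Temporal-concatenation group ICA with dual-regression back-projection.

    Each subject's masked matrix is voxel-wise variance normalized, the
    subjects are concatenated along time, the stack is reduced to
    ``model_order`` dimensions by group PCA on the temporal covariance,
    and the reduced data are unmixed by spatial fixed-point ICA.  Group
    maps are Z-scored; subject maps and time courses come from dual
    regression of each subject's (demeaned) data on the group maps.
    """
    grid = cohort[0].grid
    Xs = [_variance_normalize_voxels(s.masked_matrix()) for s in cohort]
    Xc = np.concatenate(Xs, axis=0)                  # (sum T, V)
    if Xc.shape[0] <= model_order:
        raise ValueError("total timepoints must exceed the model order")
    Y, _ = _whiten_temporal(Xc, model_order)
    sources, converged, n_restarts = _run_fastica(Y, seed)
    group_maps, _ = _zscore_flip_maps(sources)

    S, K = len(cohort), group_maps.shape[0]
    T = cohort[0].n_timepoints
    subject_maps = np.empty((S, K, grid.n_voxels))
    subject_tcs = np.empty((S, K, T))
    for i, s in enumerate(cohort):
        tcs, maps = dual_regression(group_maps, _demean_voxels(s.masked_matrix()))
        zmaps, signs = _zscore_flip_maps(maps)
        subject_maps[i] = zmaps
        subject_tcs[i] = signs[:, None] * tcs.T
    return Decomposition(
        algorithm="TCGICA", model_order=model_order, grid=grid,
        group_maps=group_maps, subject_maps=subject_maps,
        subject_timecourses=subject_tcs,
        diagnostics={"converged": converged, "ica_restarts": n_restarts,
                     "effective_order": K})


# ---------------------------------------------------------------------------
# RAICAR-style alignment

def greedy_align(similarity: np.ndarray, subject_of: np.ndarray,
                 floor: float = RAICAR_SIMILARITY_FLOOR) -> list:
    """Greedy cross-subject component alignment on a similarity matrix.

    ``similarity`` is (N, N) symmetric with within-subject entries set to
    0; ``subject_of[i]`` is the subject index of component i.  Repeatedly:
    seed a group with the globally most similar available pair, then give
    every other subject its single available component with the highest
    mean similarity to the current group (subjects visited in index
    order).  Stops when components are exhausted or the best available
    pair similarity drops below ``floor``.

    Returns a list of groups, each a list of component indices.
    """
    sim = np.asarray(similarity, dtype=float)
    subject_of = np.asarray(subject_of)
    n = sim.shape[0]
    available = np.ones(n, dtype=bool)
    groups = []
    subjects = np.unique(subject_of)
    while True:
        masked = np.where(np.outer(available, available), sim, -np.inf)
        best = np.unravel_index(np.argmax(masked), masked.shape)
        if not np.isfinite(masked[best]) or masked[best] < floor:
            break
        group = [int(best[0]), int(best[1])]
        available[list(group)] = False
        for s in subjects:
            if s in (subject_of[best[0]], subject_of[best[1]]):
                continue
            cand = np.where(available & (subject_of == s))[0]
            if cand.size == 0:
                continue
            mean_sim = sim[np.ix_(cand, group)].mean(axis=1)
            pick = int(cand[np.argmax(mean_sim)])
            group.append(pick)
            available[pick] = False
        groups.append(sorted(group))
    return groups


def raicar_align(subject_icas, grid: VolumeGrid,
                 floor: float = RAICAR_SIMILARITY_FLOOR) -> Decomposition:
    """Align independently-estimated subject components into group maps.

    Similarity between two components from different subjects is the
    absolute Pearson correlation of their Z-scored maps over the brain
    mask.  Groups come from :func:`greedy_align`; within each group,
    members are sign-aligned to the first member, each subject's weight
    is the mean similarity of its member to the other members, and the
    group map is the weighted average, Z-transformed.  A component's
    reproducibility is its group's mean pairwise similarity.
    """
    if len(subject_icas) < 2:
        raise ValueError("alignment needs at least 2 subjects")
    all_maps = np.concatenate([r.maps for r in subject_icas], axis=0)  # (N, V)
    subject_of = np.concatenate([
        np.full(r.maps.shape[0], i) for i, r in enumerate(subject_icas)])
    signed = np.corrcoef(all_maps)
    sim = np.abs(signed)
    sim[subject_of[:, None] == subject_of[None, :]] = 0.0
    np.fill_diagonal(sim, 0.0)

    groups = greedy_align(sim, subject_of, floor)
    if not groups:
        warnings.warn("no component groups survived the similarity floor; "
                      "empty decomposition", stacklevel=2)
    S = len(subject_icas)
    T = subject_icas[0].timecourses.shape[1]
    G, V = len(groups), all_maps.shape[1]
    group_maps = np.zeros((G, V))
    subject_maps = np.full((S, G, V), np.nan)
    subject_tcs = np.full((S, G, T), np.nan)
    reproducibility = np.zeros(G)
    for g, members in enumerate(groups):
        members = list(members)
        ref = members[0]
        weights, acc = [], np.zeros(V)
        for m in members:
            others = [o for o in members if o != m]
            w = sim[m, others].mean()
            sgn = 1 if signed[ref, m] >= 0 else -1
            acc += w * sgn * all_maps[m]
            weights.append(w)
            s = int(subject_of[m])
            local_k = m - np.flatnonzero(subject_of == s)[0]
            flip = _skew_flip(all_maps[m])
            subject_maps[s, g] = flip * all_maps[m]
            subject_tcs[s, g] = flip * subject_icas[s].timecourses[local_k]
        gm = zscore_masked(acc / max(sum(weights), 1e-12))
        group_maps[g] = _skew_flip(gm) * gm
        pair_sims = [sim[a, b] for i, a in enumerate(members) for b in members[i + 1:]]
        reproducibility[g] = float(np.mean(pair_sims))
    # most reproducible components first
    order = np.argsort(reproducibility)[::-1]
    model_order = subject_icas[0].maps.shape[0]
    return Decomposition(
        algorithm="RAICAR", model_order=model_order, grid=grid,
        group_maps=group_maps[order], subject_maps=subject_maps[:, order],
        subject_timecourses=subject_tcs[:, order],
        reproducibility=reproducibility[order],
        diagnostics={"n_groups": G,
                     "converged": all(r.converged for r in subject_icas),
                     "floor": floor})


def raicar(cohort, model_order: int, seed: int = 0,
           floor: float = RAICAR_SIMILARITY_FLOOR) -> Decomposition:
    """Per-subject spatial ICA followed by :func:`raicar_align`."""
    icas = [fit_single_subject_ica(s, model_order, seed + 37 * i)
            for i, s in enumerate(cohort)]
    return raicar_align(icas, cohort[0].grid, floor=floor)


# ---------------------------------------------------------------------------
# IVA with a multivariate Laplace SCV prior

def iva_l(cohort, model_order: int, seed: int = 0,
          step: float = 0.5, max_iter: int = IVA_MAX_ITER,
          tol: float = IVA_TOL) -> Decomposition:
    """Joint decomposition of all subjects with cross-subject dependence.

    Each subject is PCA-whitened to ``model_order`` dimensions; the
    per-subject unmixing matrices are then optimized together by
    natural-gradient ascent of the IVA log-likelihood under a
    multivariate Laplace prior on each source component vector, whose
    score uses the SCV Euclidean norm across subjects:

        phi_k^(s)(v) = y_k^(s)(v) / ||y_k(v)||_2 .

    With one subject the norm degenerates to |y| and the update is plain
    Laplacian ICA.  The step size is halved and the step retried whenever
    the objective turns non-finite; persistent failure is flagged in the
    diagnostics, never silent.  Components are aligned across subjects by
    construction; the group map of component k is the Z-transform of the
    average of per-subject Z-scored maps.
    """
    grid = cohort[0].grid
    S = len(cohort)
    rng = np.random.default_rng(seed)
    Ys, Ps, Xs = [], [], []
    for s in cohort:
        X = _demean_voxels(s.masked_matrix())
        Y, P = _whiten_temporal(X, model_order)
        Ys.append(Y)
        Ps.append(P)
        Xs.append(X)
    K = min(Y.shape[0] for Y in Ys)
    Ys = [Y[:K] for Y in Ys]
    V = Ys[0].shape[1]
    eps = 1e-12

    # small random rotation away from identity breaks symmetric saddle points
    W = np.stack([_orthonormalize(np.eye(K) + 0.05 * rng.standard_normal((K, K)))
                  for _ in range(S)])
    W0 = W.copy()
    Yst = np.stack(Ys)
    lr = step
    converged = False
    n_iter = 0
    failed = False
    for n_iter in range(1, max_iter + 1):
        Ssrc = np.einsum("skj,sjv->skv", W, Yst)
        R = np.sqrt((Ssrc ** 2).sum(axis=0)) + eps       # (K, V)
        cost = R.sum(axis=0).mean() - sum(
            np.log(np.abs(np.linalg.det(W[s])) + eps) for s in range(S))
        # runaway iterates precede the actual overflow by many steps, so a
        # weight-norm guard catches divergence early; restart small
        if not np.isfinite(cost) or np.abs(W).max() > 1e6:
            lr *= 0.5
            if lr < 1e-8:
                failed = True
                break
            W = W0.copy()
            continue
        phi = Ssrc / R[None]
        G = np.einsum("skv,sjv->skj", phi, Ssrc) / V     # E[phi y^T] per subject
        delta = np.einsum("skj,sjl->skl", np.eye(K)[None] - G, W)
        rel = max(np.linalg.norm(delta[s]) * lr / max(np.linalg.norm(W[s]), eps)
                  for s in range(S))
        W = W + lr * delta
        if rel < tol:
            converged = True
            break
    Ssrc = np.einsum("skj,sjv->skv", W, Yst)

    subject_maps = np.empty((S, K, V))
    subject_tcs = np.empty((S, K, cohort[0].n_timepoints))
    zsum = np.zeros((K, V))
    for s in range(S):
        zmaps, signs = _zscore_flip_maps(Ssrc[s])
        subject_maps[s] = zmaps
        A, *_ = np.linalg.lstsq(Ssrc[s].T, Xs[s].T, rcond=None)
        subject_tcs[s] = signs[:, None] * A
        zsum += zmaps
    group_maps = np.empty((K, V))
    for k in range(K):
        gm = zscore_masked(zsum[k] / S)
        group_maps[k] = _skew_flip(gm) * gm
    return Decomposition(
        algorithm="IVA", model_order=model_order, grid=grid,
        group_maps=group_maps, subject_maps=subject_maps,
        subject_timecourses=subject_tcs,
        diagnostics={"converged": converged, "n_iterations": n_iter,
                     "failed": failed, "final_step": lr,
                     "effective_order": K})


def _orthonormalize(M: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(M)
    return U @ Vt


# ---------------------------------------------------------------------------

def decompose(cohort, algorithm: str, model_order: int, seed: int = 0) -> Decomposition:
    """Dispatch to one of TCGICA / RAICAR / IVA by name."""
    algorithm = algorithm.upper()
    if algorithm == "TCGICA":
        return tcgica(cohort, model_order, seed)
    if algorithm == "RAICAR":
        return raicar(cohort, model_order, seed)
    if algorithm == "IVA":
        return iva_l(cohort, model_order, seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
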