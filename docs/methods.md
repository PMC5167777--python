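# Methods

## The question and the model of the data

The parietal memory network (PMN) and the default mode network (DMN)
occupy adjacent — partly overlapping — posterior midline cortex.  In a
group ICA of resting-state fMRI, whether they come out as separate
components depends on the spatial smoothing kernel applied during
preprocessing and on the decomposition's model order.  `netseg` frames
that dependency as a falsifiable pipeline property and tests it on
synthetic cohorts whose ground truth is known.

Each subject's 4D series is generated as a noisy linear mixture

    x_s(v, t) = Σ_k m_{k,s}(v) · s_{k,s}(t) + b·1[v ∈ mask] + ε_s(v, t)

with `m_{k,s}` a spherical-cluster source map shifted by a per-subject
integer jitter, `s_{k,s}` a unit-variance time course whose power is
confined to 0.01–0.1 Hz, `b` a constant in-mask baseline, and `ε`
i.i.d. Gaussian noise.  The default source set has eight networks:
PMN (two midline spheres), pDMN (posterior midline plus two lateral
spheres), aDMN, and five generic background networks.  The PMN and pDMN
midline clusters share a one-voxel overlap fringe, mirroring the stable
individual-level overlap of the real networks.

### Time-course coupling

Source time courses are white Gaussian series band-passed to the target
band (zero-phase Butterworth, order 4), variance-normalized, then mixed
through the Cholesky factor of a target correlation matrix.  By default
PMN–pDMN and aDMN–pDMN couple at r = 0.5 (PMN–aDMN at 0.25); all other
pairs are independent.  This coupling is essential, not cosmetic: with
fully independent time courses, spatial ICA separates the two networks
at *any* smoothing level and model order, because the mixing-matrix
columns stay distinguishable no matter how blurred the maps are.  What
makes low-model-order decompositions absorb the PMN into the DMN in
practice is that the posterior midline systems fluctuate together; r ≈
0.5 is in the range reported for interacting cortical systems.  The
empirical per-subject correlation matrices are returned with the ground
truth so simulations can be audited.

### Generator defaults (the study conditions)

| parameter | default | rationale |
|---|---|---|
| grid | 24×28×24 voxels @ 3 mm | desk-scale analogue of a whole-brain matrix; ellipsoid mask ≈ 6,200 voxels |
| subjects | 8 | small cohort, enough for alignment/IIS statistics |
| timepoints / TR | 140 / 3 s | ≈ 7 min of rest |
| noise SD | 0.5 (unit peak weight) | peak-SNR 2, mid-range for 3 T rfMRI after band-passing |
| jitter SD | 0.5 voxels | mild residual anatomical misalignment |
| baseline | 100 | makes grand-mean scaling well-posed, as in real data |

What the generator does **not** emulate: anatomy and tissue contrast,
slice-timing and motion artifacts in the images themselves, spatially
correlated (non-white) noise, hemodynamic lag structure, and non-linear
registration error (all maps live on one common grid).  Passing tests
therefore demonstrate that the *pipeline logic* behaves as documented
under the stated statistical structure — not that any particular real
dataset would yield the same condition table.

## Preprocessing

Fixed stage order: volume discard → grand-mean scaling → temporal
band-pass → spatial smoothing.

* Grand-mean scaling rescales so the mean over (brain mask × time)
  equals 10,000.
* Band-pass: Butterworth order 4 applied forward–backward
  (`sosfiltfilt`), so the phase response is zero and the effective
  attenuation is squared.  Measured on sinusoids at TR 3 s: a 0.05 Hz
  tone keeps > 99% amplitude; a 0.2 Hz tone (aliased to 0.133 Hz)
  keeps < 1%.  The filter is not exactly idempotent — a second pass
  re-attenuates band-edge content by ≈ 7% in energy — which is why the
  pipeline applies it exactly once.
* Smoothing: full-lattice 3D Gaussian with σ = FWHM/(2√(2 ln 2)·voxel)
  per axis; FWHM 0 is a bit-exact identity.  No mask-normalized
  smoothing (matches common practice; edge attenuation at the mask
  boundary is accepted).
* Motion QC: scalar framewise displacement FD_t = Σ|Δtrans| +
  50 mm·Σ|Δrot|, flagging subjects with mean FD above 0.2 mm.  The
  synthetic motion generator emits smooth random-walk traces rescaled
  so the realized meanFD equals a requested target exactly.

## Decompositions

All three schemes share conventions: analysis is restricted to
brain-mask voxels; group maps are Z-transformed (zero mean, unit SD
over the mask); every map's sign is fixed by requiring positive
skewness over the mask (a deterministic resolution of ICA's sign
ambiguity, applied before any template matching); non-convergence is
recorded in diagnostics, never silently dropped.

**TCgICA.**  Per-subject voxel-wise variance normalization, temporal
concatenation, group PCA to the model order via the temporal
covariance, then fixed-point spatial ICA (logcosh contrast, tolerance
1e-4, ≤ 500 iterations, up to 5 seeded restarts on non-convergence).
Subject maps and time courses come from dual regression: stage 1
regresses each volume on all group maps; stage 2 regresses each voxel's
series on the variance-normalized stage-1 time courses.  Both stages
are exact least squares with no regularization, and a rank-deficient
design raises an error naming the collinear component pair.

**RAICAR-style alignment.**  Each subject is decomposed independently
(same spatial ICA).  Similarity between components of different
subjects is the absolute Pearson correlation of Z-scored maps;
within-subject similarity is zeroed.  Greedy alignment repeatedly seeds
a group with the globally most similar available pair (stopping below a
similarity floor of 0.2), then gives every other subject its single
available component with the highest mean similarity to the group.
Members are sign-aligned to the seed, weighted by their mean similarity
to the other members, averaged, and Z-transformed; a component's
reproducibility is its group's mean pairwise similarity, and components
are ordered by it.  Greedy matching is used instead of spectral
clustering because it is fully specified and oracle-testable on small
instances; like all greedy matchings it is optimal only when the
similarity structure is block-dominant, which reproducible components
are.

**IVA.**  Each subject is PCA-whitened to the model order; per-subject
unmixing matrices are then optimized jointly by natural-gradient ascent
of the likelihood under a multivariate Laplace prior on each source
component vector (SCV — the k-th source across subjects).  The score
function divides each subject's source by the SCV Euclidean norm, which
is what couples the decompositions; with one subject it reduces to
plain Laplacian ICA.  Stopping: relative unmixing change < 1e-6 or 1024
iterations (flagged).  Divergence handling matters here: runaway
iterates precede floating-point overflow by dozens of steps, so the
optimizer restarts from the whitened initialization with a halved step
whenever the objective turns non-finite *or* the unmixing norms explode
(> 1e6); persistent failure is a flagged result.  The default step of
0.5 converges directly on noisy data and settles at 0.125 after
restarts on noiseless data.  Group maps are the Z-transform of the
average of per-subject Z-scored maps.  This is a deliberate
simplification of two-stage Gaussian-then-Laplacian IVA variants: the
defining property retained is cross-subject SCV dependence.

## Identification and metrics

Candidates are the components maximizing Pearson correlation with the
PMN, DMN and pDMN binary templates (ties to the lower index).  A
network is identified only if *every* anchor voxel of its template is
strictly above the Z threshold in the candidate map — the strictest
reading of anchor inclusion; a lenient mode accepting a suprathreshold
6-neighbor exists behind a config flag, off by default.  Thresholds are
Z > 2 for RAICAR/IVA and Z > 5 for TCgICA (the concatenation scheme's
maps run hotter, a convention kept configurable).  The DMN is reported
`FoundAsPosterior` when only its posterior subsystem passes; if PMN and
DMN/pDMN land on one component, the higher template correlation keeps
it and the other network is `NotFound`.  Both anchor voxels of the full
DMN (posterior-cingulate-like and paracingulate-like) are required for
full-DMN status; the aDMN template is generated and serialized but
plays no role in the main decision.

Metrics per selected component: goodness-of-fit (the candidate's
template correlation, over mask voxels only — whole-lattice correlation
would be inflated by the shared zero background); mean weight (mean of
strictly suprathreshold Z values; empty set → missing, flagged);
inter-individual similarity (mean and *population*-SD of all pairwise
subject-map correlations — the divisor is pinned for reproducibility);
and the overlap percentage, 100·|PMN∩DMN suprathreshold|/|PMN
suprathreshold| at Z > 2 on Z-scored subject maps (asymmetric by
construction: PMN is always the denominator).

## The sweep and the segregation study

`run_sweep` evaluates every (algorithm × FWHM × MO) cell on one cohort,
smoothing the band-passed data fresh per condition (never
cumulatively); failed conditions become rows carrying the error, so a
report always has |algorithms|·|FWHM|·|MO| rows.  The full-size design
is 4 kernels × 5 model orders (20, 40, 60, 80, 100) = 20 conditions per
algorithm; synthetic sweeps default to scaled-down model orders (e.g. 4
and 8 against 8 true sources) because the order must not exceed the
data rank at this scale.  `segregation_study` repeats the sweep over
generator seeds and tabulates the rate at which *both* networks are
identified (PMN `Found`, DMN `Found` or `FoundAsPosterior`).  The
package's headline property, recomputed by `scripts/acceptance.py` and
asserted in the test suite over 10 seeds: the found-both rate at
(FWHM 0, MO 8) strictly exceeds the rate at (FWHM 12 mm, MO 4) for all
three algorithms.

## Numerical choices and edge cases

* Voxel indexing is 0-based, axis order (x, y, z), anterior–posterior
  along y; no registration is modelled.
* A constant map's correlation is reported as 0 with a warning rather
  than NaN; constant subject maps contribute 0-valued pairs to IIS.
* Jitter that would push a cluster center outside the brain mask is
  shrunk component-wise until the center re-enters, with a warning.
* `VolumeGrid` requires ≥ 500 in-mask voxels on realistic grids but
  only 30% lattice occupancy on tiny demo grids (a 500-voxel mask
  cannot exist on 8×8×8).
* Model orders above the data rank are reduced with a warning, never
  silently honored.

## Known limitations

Synthetic sources are uniform solid spheres with hard edges, not
graded cortical maps; noise is white in space and time; the condition
tables are therefore qualitatively, not numerically, comparable to
tables computed on human cohorts.  The RAICAR similarity floor (0.2)
and the IVA step schedule are pragmatic defaults validated by the
recovery oracles, not tuned to any external dataset.  No multi-run
ICA aggregation (ICASSO-style) is performed, and model order is always
user-specified, never estimated.
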