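# netseg

Does group independent component analysis keep the **parietal memory
network (PMN)** apart from the **default mode network (DMN)**?  The two
systems share precuneus/posterior-cingulate territory and are easily
conflated: whether a resting-state decomposition separates them depends
heavily on two analysis choices — the spatial smoothing kernel (SM,
Gaussian FWHM in mm) and the ICA model order (MO, the number of
requested components).

`netseg` implements that methodological experiment as a tested,
fully synthetic pipeline:

* **`netseg.fixtures`** — ground truth: ellipsoidal brain grids,
  PMN/DMN/aDMN/pDMN binary templates with anchor-point voxels (the pDMN
  has three clusters — posterior midline plus two lateral — and the PMN
  two midline clusters flanking the pDMN midline cluster, sharing an
  overlap fringe), and multi-subject 4D cohorts built as linear mixtures
  `x(v,t) = Σ_k m_k(v)·s_k(t) + baseline + ε` of spherical sources
  driven by 0.01–0.1 Hz band-limited time courses, with per-subject
  spatial jitter and temporally coupled posterior-midline sources.
* **`netseg.preprocess`** — volume discard, grand-mean scaling to
  10,000, zero-phase Butterworth band-pass (0.01–0.1 Hz), Gaussian
  smoothing at FWHM ∈ {0, 6, 9, 12} mm, and mean framewise-displacement
  motion QC (flag at 0.2 mm).
* **`netseg.groupica`** — three group-decomposition families with one
  contract (Z-scored group maps + index-aligned subject maps):
  temporal-concatenation group ICA with dual regression (TCgICA),
  reproducibility-based cross-subject component alignment
  (RAICAR-style), and independent vector analysis with a multivariate
  Laplace prior on each source component vector (IVA).
* **`netseg.selection`** — the template-matching identification
  flowchart: best-correlated candidate per template, Z-thresholding
  (Z > 2 for RAICAR/IVA, Z > 5 for TCgICA), anchor-point inclusion,
  posterior-DMN fallback, and same-component conflict resolution by
  higher correlation.
* **`netseg.metrics`** — goodness-of-fit (Pearson r against the binary
  template), mean weights over suprathreshold voxels, inter-individual
  similarity (mean ± SD of pairwise subject-map correlations), and the
  individual-level PMN–DMN overlap percentage.
* **`netseg.experiment`** — the sweep driver: every (algorithm × SM ×
  MO) condition on one cohort, per-condition result tables with “–” for
  networks not found, and the seed-replicated segregation study.

## Worked example

```python
import netseg as ns
from netseg.experiment import SweepConfig, run_sweep
from netseg.preprocess import PreprocessConfig

grid = ns.make_grid()                      # 24x28x24 @ 3 mm, ellipsoid mask
templates = ns.make_templates(grid)
cohort, truth = ns.simulate_cohort(grid, ns.default_sources(grid),
                                   ns.CohortSimConfig(seed=1))
report = run_sweep(cohort, templates,
                   SweepConfig(fwhm_list=(0.0, 12.0), mo_list=(4, 8)),
                   PreprocessConfig(n_discard=0), seed=1)
cols = ["algorithm", "fwhm_mm", "model_order", "PMN_status", "DMN_status",
        "PMN_gof", "PMN_mw", "overlap_pct_mean"]
print(report.to_dataframe()[cols].round(2).to_string(index=False))
```

prints

```
algorithm  fwhm_mm  model_order PMN_status       DMN_status  PMN_gof  PMN_mw  overlap_pct_mean
   TCGICA      0.0            4      Found FoundAsPosterior     0.67    6.63              2.06
   TCGICA      0.0            8      Found FoundAsPosterior     0.67    6.64              2.12
   RAICAR      0.0            4      Found            Found     0.91    8.02             11.37
   RAICAR      0.0            8      Found            Found     0.95    8.07              2.79
      IVA      0.0            4      Found            Found     0.84    5.67             42.65
      IVA      0.0            8      Found            Found     0.90    6.56             12.63
   TCGICA     12.0            4   NotFound         NotFound      NaN     NaN               NaN
   TCGICA     12.0            8   NotFound         NotFound      NaN     NaN               NaN
   RAICAR     12.0            4      Found            Found     0.55    3.59              7.80
   RAICAR     12.0            8      Found FoundAsPosterior     0.65    3.86              8.40
      IVA     12.0            4      Found            Found     0.56    3.50             14.03
      IVA     12.0            8      Found FoundAsPosterior     0.65    3.82             11.48
```

Reading the table: with no smoothing every algorithm identifies the PMN
(its candidate component passes both midline anchor voxels) and the DMN
either in full or as its posterior subsystem (`FoundAsPosterior`, the
high-model-order regime where the DMN splits).  At 12 mm smoothing
TCgICA loses both networks — its merged candidate component fails the
stricter Z > 5 anchor test — and goodness-of-fit (`PMN_gof`) and mean
weights (`PMN_mw`) drop for the other algorithms.  `overlap_pct_mean` is
the share of each subject's suprathreshold PMN voxels also
suprathreshold in their DMN map, averaged over subjects.

A command-line front end mirrors the stages:

```bash
netseg simulate --out study --n-subjects 8 --seed 1
netseg sweep --cohort study/cohort --templates study/templates --out report.json
netseg report --report report.json --out-dir tables/
```

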