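"""Sweep driver: (algorithm x smoothing x model order) condition grids.

Mirrors the study design: a cohort is preprocessed once up to band-pass
filtering, then for every smoothing kernel the smoothed copy is
decomposed at every model order by every algorithm, the PMN/DMN are
identified by template matching, and each condition yields a row of
GoF / MW / IIS / overlap metrics.  The segregation study repeats the
sweep over seeds of the synthetic cohort generator and summarizes, per
condition, how often both networks were identified.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import SubjectData
from .fixtures import CohortSimConfig, TemplateSet, default_sources, make_grid, \
    make_templates, simulate_cohort
from .groupica import ALGORITHMS, decompose
from .metrics import MetricRecord, inter_individual_similarity, mean_weight, \
    overlap_percentage
from .preprocess import PreprocessConfig, bandpass, discard_initial, \
    grand_mean_scale, smooth_spatial
from .selection import FOUND, FOUND_AS_POSTERIOR, NOT_FOUND, SelectionConfig, \
    SelectionResult, default_z_threshold, select_networks

__all__ = [
    "SweepConfig",
    "ConditionResult",
    "SweepReport",
    "enumerate_conditions",
    "run_sweep",
    "segregation_study",
    "render_tables",
]

#: Model orders of the full-size design; synthetic desk-scale sweeps use
#: smaller lists so the order never exceeds the data rank.
DEFAULT_MO_LIST = (20, 40, 60, 80, 100)
DEFAULT_FWHM_LIST = (0.0, 6.0, 9.0, 12.0)


@dataclass(frozen=True)
class SweepConfig:
    fwhm_list: tuple = DEFAULT_FWHM_LIST
    mo_list: tuple = DEFAULT_MO_LIST
    algorithms: tuple = ALGORITHMS
    seeds: tuple = (0,)

    def __post_init__(self) -> None:
        if not self.fwhm_list or not self.mo_list or not self.algorithms:
            raise ValueError("fwhm_list, mo_list and algorithms must be non-empty")
        if any(f < 0 for f in self.fwhm_list):
            raise ValueError("fwhm values must be nonnegative")
        if any(m < 1 for m in self.mo_list):
            raise ValueError("model orders must be positive")
        for a in self.algorithms:
            if a.upper() not in ALGORITHMS:
                raise ValueError(f"unknown algorithm {a!r}")

    @property
    def n_conditions_per_algorithm(self) -> int:
        return len(self.fwhm_list) * len(self.mo_list)


def enumerate_conditions(config: SweepConfig) -> list:
    """All (algorithm, fwhm_mm, model_order) triples of the sweep."""
    return [(a.upper(), float(f), int(m))
            for a in config.algorithms
            for f in config.fwhm_list
            for m in config.mo_list]


@dataclass
class ConditionResult:
    algorithm: str
    fwhm_mm: float
    model_order: int
    seed: int
    selection: Optional[SelectionResult] = None
    metrics: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    error: Optional[str] = None

    @property
    def found_both(self) -> bool:
        """True when PMN is found and DMN is found in full or as its
        posterior subsystem -- i.e. the two networks were segregated."""
        if self.selection is None:
            return False
        return (self.selection.pmn.status == FOUND
                and self.selection.dmn.status in (FOUND, FOUND_AS_POSTERIOR))

    def as_record(self) -> dict:
        rec = {"algorithm": self.algorithm, "fwhm_mm": self.fwhm_mm,
               "model_order": self.model_order, "seed": self.seed,
               "error": self.error, "found_both": self.found_both}
        if self.selection is not None:
            rec.update(self.selection.as_record())
        rec["metrics"] = {
            net: vars(m) for net, m in self.metrics.items()}
        rec["diagnostics"] = {k: v for k, v in self.diagnostics.items()
                              if isinstance(v, (bool, int, float, str))}
        return rec


@dataclass
class SweepReport:
    conditions: list
    provenance: dict

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.conditions:
            row = {"algorithm": c.algorithm, "fwhm_mm": c.fwhm_mm,
                   "model_order": c.model_order, "seed": c.seed,
                   "found_both": c.found_both, "error": c.error}
            for net in ("PMN", "DMN"):
                nr = getattr(c.selection, net.lower(), None) if c.selection else None
                row[f"{net}_status"] = nr.status if nr else None
                row[f"{net}_ic"] = nr.component if nr else None
                row[f"{net}_r"] = nr.r if nr else None
                m = c.metrics.get(net)
                row[f"{net}_gof"] = m.gof if m else None
                row[f"{net}_mw"] = m.mean_weight if m else None
                row[f"{net}_iis_mean"] = m.iis_mean if m else None
                row[f"{net}_iis_sd"] = m.iis_sd if m else None
            pm = c.metrics.get("PMN")
            row["overlap_pct_mean"] = pm.overlap_pct_mean if pm else None
            row["overlap_pct_sd"] = pm.overlap_pct_sd if pm else None
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {"provenance": self.provenance,
                   "conditions": [c.as_record() for c in self.conditions]}
        return json.dumps(payload, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_hash(*parts) -> str:
    blob = json.dumps([repr(p) for p in parts], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _prepare_base(cohort: Sequence[SubjectData], pp: PreprocessConfig) -> list:
    """Discard + grand-mean scale + band-pass (smoothing is per-condition)."""
    out = []
    for s in cohort:
        x = discard_initial(s, pp.n_discard)
        x = grand_mean_scale(x, pp.global_mean_target)
        x = bandpass(x, pp.band_hz)
        out.append(x)
    return out


def _condition_metrics(decomp, sel: SelectionResult, templates: TemplateSet,
                       z_threshold: float) -> dict:
    """GoF / MW / IIS per network, plus the individual-level PMN--DMN
    overlap (attached to the PMN record; the PMN is the denominator)."""
    out = {}
    results = {"PMN": (sel.pmn, "PMN"),
               "DMN": (sel.dmn,
                       "pDMN" if sel.dmn.status == FOUND_AS_POSTERIOR else "DMN")}
    for net, (nr, _tpl) in results.items():
        if nr.status == NOT_FOUND:
            out[net] = MetricRecord()
            continue
        k = nr.component
        subj = decomp.subject_maps[:, k]
        valid = subj[~np.isnan(subj).any(axis=1)]
        iis_mean = iis_sd = None
        if valid.shape[0] >= 2:
            iis_mean, iis_sd = inter_individual_similarity(valid)
        out[net] = MetricRecord(
            gof=nr.r,
            mean_weight=mean_weight(decomp.group_maps[k], z_threshold),
            iis_mean=iis_mean, iis_sd=iis_sd)
    pmn, dmn = sel.pmn, sel.dmn
    if pmn.status != NOT_FOUND and dmn.status != NOT_FOUND:
        overlaps = []
        for s in range(decomp.subject_maps.shape[0]):
            p = decomp.subject_maps[s, pmn.component]
            d = decomp.subject_maps[s, dmn.component]
            if np.isnan(p).any() or np.isnan(d).any():
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                o = overlap_percentage(p, d, z=2.0)
            if o is not None:
                overlaps.append(o)
        if overlaps:
            out["PMN"].overlap_pct_mean = float(np.mean(overlaps))
            out["PMN"].overlap_pct_sd = float(np.std(overlaps))
    return out


def run_sweep(cohort: Sequence[SubjectData], templates: TemplateSet,
              config: SweepConfig,
              preprocess_config: Optional[PreprocessConfig] = None,
              seed: int = 0) -> SweepReport:
    """Run every (algorithm, fwhm, mo) condition of the sweep on a cohort.

    Smoothing is applied per condition to the unsmoothed band-passed
    data, never cumulatively.  Per-condition failures are recorded as
    rows carrying an error message; the sweep continues.
    """
    pp = preprocess_config or PreprocessConfig()
    base = _prepare_base(cohort, pp)
    conditions = []
    for fwhm in config.fwhm_list:
        smoothed = [smooth_spatial(s, fwhm) for s in base]
        for alg in config.algorithms:
            alg = alg.upper()
            sel_cfg_thr = default_z_threshold(alg)
            for mo in config.mo_list:
                cond = ConditionResult(algorithm=alg, fwhm_mm=float(fwhm),
                                       model_order=int(mo), seed=seed)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        decomp = decompose(smoothed, alg, mo, seed=seed)
                        sel = select_networks(
                            decomp, SelectionConfig(templates=templates,
                                                    z_threshold=sel_cfg_thr))
                        cond.selection = sel
                        cond.metrics = _condition_metrics(
                            decomp, sel, templates, sel_cfg_thr)
                        cond.diagnostics = dict(decomp.diagnostics)
                except Exception as exc:  # failures are first-class rows
                    cond.error = f"{type(exc).__name__}: {exc}"
                conditions.append(cond)
    provenance = {"config_hash": _config_hash(config, pp), "seed": seed,
                  "version": __version__,
                  "n_subjects": len(cohort)}
    return SweepReport(conditions=conditions, provenance=provenance)


def segregation_study(fixture_config: CohortSimConfig, sweep_config: SweepConfig,
                      grid=None, sources=None,
                      preprocess_config: Optional[PreprocessConfig] = None):
    """Repeat the sweep over generator seeds and tabulate segregation.

    For every seed a fresh synthetic cohort (with overlapping PMN and
    pDMN ground-truth sources) is generated, swept, and each condition's
    found-both outcome recorded.  Returns a DataFrame with one row per
    (algorithm, fwhm, mo) carrying the found-both rate over seeds, plus
    the full per-seed reports.
    """
    grid = grid if grid is not None else make_grid()
    sources = sources if sources is not None else default_sources(grid)
    templates = make_templates(grid)
    pp = preprocess_config or PreprocessConfig(n_discard=0)
    reports = []
    rows = []
    for seed in sweep_config.seeds:
        cfg = replace(fixture_config, seed=int(seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort, _ = simulate_cohort(grid, sources, cfg)
        report = run_sweep(cohort, templates, sweep_config, pp, seed=int(seed))
        reports.append(report)
        for c in report.conditions:
            rows.append({"algorithm": c.algorithm, "fwhm_mm": c.fwhm_mm,
                         "model_order": c.model_order, "seed": c.seed,
                         "found_both": c.found_both})
    per_run = pd.DataFrame(rows)
    if per_run.empty:
        return pd.DataFrame(columns=["algorithm", "fwhm_mm", "model_order",
                                     "found_both_rate", "n_seeds"]), reports
    rates = (per_run.groupby(["algorithm", "fwhm_mm", "model_order"])
             ["found_both"].agg(["mean", "size"]).reset_index()
             .rename(columns={"mean": "found_both_rate", "size": "n_seeds"}))
    return rates, reports


def iis_smoothing_trend(fixture_config: CohortSimConfig,
                        fwhm_list=(0.0, 6.0, 12.0), model_order: int = 8,
                        seeds=(0,), algorithm: str = "TCGICA",
                        grid=None, sources=None) -> pd.DataFrame:
    """Inter-individual similarity of the PMN-matched component as a
    function of smoothing kernel, per generator seed.

    The component is the one whose group map correlates best with the
    PMN template (no anchor gating -- the trend concerns map similarity,
    not identification).  Returns a tidy frame (seed, fwhm_mm, iis_mean).
    """
    from .metrics import inter_individual_similarity
    from .selection import pick_candidates

    grid = grid if grid is not None else make_grid()
    sources = sources if sources is not None else default_sources(grid)
    templates = make_templates(grid)
    rows = []
    for seed in seeds:
        cfg = replace(fixture_config, seed=int(seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort, _ = simulate_cohort(grid, sources, cfg)
            base = _prepare_base(cohort, PreprocessConfig(n_discard=0))
            for fwhm in fwhm_list:
                smoothed = [smooth_spatial(s, fwhm) for s in base]
                decomp = decompose(smoothed, algorithm, model_order, seed=int(seed))
                k = pick_candidates(decomp, templates)["PMN"][0]
                subj = decomp.subject_maps[:, k]
                subj = subj[~np.isnan(subj).any(axis=1)]
                iis_mean, _ = inter_individual_similarity(subj)
                rows.append({"seed": int(seed), "fwhm_mm": float(fwhm),
                             "iis_mean": iis_mean})
    return pd.DataFrame(rows)


NOT_FOUND_CELL = "–"  # en dash, the tables' not-found marker


def render_tables(report: SweepReport) -> dict:
    """Per-algorithm condition tables shaped like the study's tables.

    Rows are (model order x metric), column groups are smoothing kernels
    x network; cells hold GoF / MW as numbers and IIS as
    "mean (SD)" strings, with an en dash for networks not found.
    """
    tables = {}
    df = report.to_dataframe()
    if df.empty:
        return tables
    for alg, sub in df.groupby("algorithm"):
        fwhms = sorted(sub["fwhm_mm"].unique())
        mos = sorted(sub["model_order"].unique())
        cols = pd.MultiIndex.from_product(
            [[f"SM {g:g}" for g in fwhms], ["PMN", "DMN"]])
        idx = pd.MultiIndex.from_product([[f"MO {m}" for m in mos],
                                          ["GoF", "MWs", "IIS"]])
        table = pd.DataFrame(NOT_FOUND_CELL, index=idx, columns=cols)
        for _, row in sub.iterrows():
            for net in ("PMN", "DMN"):
                col = (f"SM {row['fwhm_mm']:g}", net)
                mo = f"MO {row['model_order']}"
                if row[f"{net}_status"] in (FOUND, FOUND_AS_POSTERIOR):
                    gof, mw = row[f"{net}_gof"], row[f"{net}_mw"]
                    table.loc[(mo, "GoF"), col] = (
                        f"{gof:.2f}" if gof is not None else NOT_FOUND_CELL)
                    table.loc[(mo, "MWs"), col] = (
                        f"{mw:.2f}" if mw is not None else NOT_FOUND_CELL)
                    im, isd = row[f"{net}_iis_mean"], row[f"{net}_iis_sd"]
                    if im is not None and not pd.isna(im):
                        table.loc[(mo, "IIS"), col] = f"{im:.2f} ({isd:.2f})"
        tables[alg] = table
    return tables
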