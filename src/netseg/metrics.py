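"""Quantitative characterization of selected components.

Goodness-of-fit (GoF): Pearson correlation between a selected component
map and its binary template, over brain-mask voxels.  Mean weight (MW):
mean of the Z-scored map over its suprathreshold voxels.  Inter-
individual similarity (IIS): mean and SD of pairwise Pearson
correlations between subjects' unthresholded component maps.  Overlap
percentage: the share of a subject's suprathreshold PMN voxels also
suprathreshold in their DMN map (asymmetric by construction -- the
denominator is always the PMN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .selection import template_correlation

__all__ = [
    "MetricRecord",
    "goodness_of_fit",
    "mean_weight",
    "inter_individual_similarity",
    "overlap_percentage",
]


@dataclass
class MetricRecord:
    """GoF / MW / IIS for one selected network in one condition."""

    gof: Optional[float] = None
    mean_weight: Optional[float] = None
    iis_mean: Optional[float] = None
    iis_sd: Optional[float] = None
    overlap_pct_mean: Optional[float] = None
    overlap_pct_sd: Optional[float] = None


def goodness_of_fit(selected_map: np.ndarray, template_mask: np.ndarray,
                    brain_mask: np.ndarray | None = None) -> float:
    """Pearson r between the selected map and the template indicator
    (shared implementation with the selection stage)."""
    return template_correlation(selected_map, template_mask, brain_mask)


def mean_weight(selected_map: np.ndarray, z_threshold: float) -> Optional[float]:
    """Mean of the map values strictly above ``z_threshold``.

    Returns None (with a warning) when no voxel survives the threshold.
    """
    vals = np.asarray(selected_map, dtype=float)
    supra = vals[vals > z_threshold]
    if supra.size == 0:
        warnings.warn("no suprathreshold voxel; mean weight undefined", stacklevel=2)
        return None
    return float(supra.mean())


def inter_individual_similarity(subject_maps: np.ndarray):
    """Mean and SD of pairwise Pearson correlations between subjects'
    unthresholded maps of one component.

    ``subject_maps`` is (S, V) over brain-mask voxels, S >= 2.  The SD is
    the population SD (n divisor) over the S(S-1)/2 pair correlations.
    A constant subject map contributes 0-valued pairs, with a warning.
    """
    M = np.asarray(subject_maps, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need at least 2 subject maps")
    sds = M.std(axis=1)
    if np.any(sds == 0):
        warnings.warn("constant subject map; its pair correlations set to 0",
                      stacklevel=2)
    pair_r = []
    for i in range(M.shape[0]):
        for j in range(i + 1, M.shape[0]):
            if sds[i] == 0 or sds[j] == 0:
                pair_r.append(0.0)
            else:
                pair_r.append(float(np.corrcoef(M[i], M[j])[0, 1]))
    pair_r = np.asarray(pair_r)
    return float(pair_r.mean()), float(pair_r.std())


def overlap_percentage(subject_pmn_map: np.ndarray, subject_dmn_map: np.ndarray,
                       z: float = 2.0) -> Optional[float]:
    """PMN--DMN overlap as a percentage of the PMN extent.

    Both maps must be Z-transformed (zero mean, unit SD) over the same
    voxel set; each is thresholded at Z > ``z`` and the count of shared
    suprathreshold voxels is divided by the count of PMN suprathreshold
    voxels, times 100.  Returns None (with a warning) when the PMN
    suprathreshold set is empty.
    """
    p = np.asarray(subject_pmn_map, dtype=float)
    d = np.asarray(subject_dmn_map, dtype=float)
    if p.shape != d.shape:
        raise ValueError("maps are not on the same voxel set")
    p_set = p > z
    n_p = int(p_set.sum())
    if n_p == 0:
        warnings.warn("empty PMN suprathreshold set; overlap undefined", stacklevel=2)
        return None
    n_shared = int((p_set & (d > z)).sum())
    return 100.0 * n_shared / n_p
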