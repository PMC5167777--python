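"""Template-matching identification of PMN and DMN components.

The decision procedure, per decomposition:

1. pick, for each of the PMN / DMN / pDMN templates, the group component
   with the highest Pearson correlation to the binary template;
2. threshold the candidate maps (Z > 2 for RAICAR and IVA, Z > 5 for
   TCGICA by convention of the respective algorithms' map scales);
3. a network counts as identified only if every one of its anchor
   voxels is suprathreshold in its candidate map.  PMN failing its two
   anchors is NotFound.  DMN failing its anchor pair falls back to the
   pDMN candidate and its single anchor (FoundAsPosterior); failing
   that, NotFound;
4. if PMN and DMN/pDMN end up on the same component, the component goes
   to the network with the higher template correlation and the other
   becomes NotFound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fixtures import TemplateSet
from .groupica import Decomposition

__all__ = [
    "SelectionConfig",
    "NetworkResult",
    "SelectionResult",
    "template_correlation",
    "pick_candidates",
    "anchors_included",
    "select_networks",
    "default_z_threshold",
]

FOUND = "Found"
FOUND_AS_POSTERIOR = "FoundAsPosterior"
NOT_FOUND = "NotFound"

#: Candidate-map Z thresholds by algorithm.
Z_THRESHOLDS = {"RAICAR": 2.0, "IVA": 2.0, "TCGICA": 5.0}


def default_z_threshold(algorithm: str) -> float:
    return Z_THRESHOLDS[algorithm.upper()]


@dataclass(frozen=True)
class SelectionConfig:
    templates: TemplateSet
    z_threshold: float
    #: lenient mode: an anchor also counts as included when any of its
    #: 6-neighbors is suprathreshold (off by default; the strict reading
    #: requires the anchor voxel itself to pass).
    cluster_membership: bool = False

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")


@dataclass
class NetworkResult:
    status: str
    component: Optional[int]
    r: Optional[float]
    n_suprathreshold: Optional[int]

    def __post_init__(self) -> None:
        if (self.status == NOT_FOUND) != (self.component is None):
            raise ValueError("NotFound iff component index is None")


@dataclass
class SelectionResult:
    pmn: NetworkResult
    dmn: NetworkResult
    candidates: dict = field(default_factory=dict)

    def as_record(self) -> dict:
        def net(nr):
            return {"status": nr.status, "ic": nr.component, "r": nr.r}
        rec = {"PMN": net(self.pmn), "DMN": net(self.dmn)}
        rec["DMN"]["as_posterior"] = self.dmn.status == FOUND_AS_POSTERIOR
        return rec


def template_correlation(map_vec: np.ndarray, template_mask: np.ndarray,
                         brain_mask: np.ndarray | None = None) -> float:
    """Pearson r between a Z-scored map and a binary template indicator.

    Both are restricted to brain-mask voxels; ``map_vec`` may be a masked
    vector (then ``template_mask`` must already be masked too) or a 3D
    volume with ``brain_mask`` given.  A constant map has undefined r,
    reported as 0 with a warning.
    """
    if brain_mask is not None:
        map_vec = np.asarray(map_vec)[brain_mask]
        template_mask = np.asarray(template_mask)[brain_mask]
    x = np.asarray(map_vec, dtype=float)
    t = np.asarray(template_mask, dtype=float)
    if x.shape != t.shape:
        raise ValueError("map and template are not on the same voxel set")
    if x.std() == 0 or t.std() == 0:
        warnings.warn("constant map or template; correlation undefined, "
                      "reporting 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(x, t)[0, 1])


def pick_candidates(decomp: Decomposition, templates: TemplateSet) -> dict:
    """Best-correlated component per template (PMN, DMN, pDMN).

    Ties are broken toward the lower component index (argmax on the raw
    correlation array already does this).
    """
    mask = decomp.grid.brain_mask
    out = {}
    for label in ("PMN", "DMN", "pDMN"):
        tvec = templates.masks[label][mask].astype(float)
        rs = np.array([template_correlation(m, tvec) for m in decomp.group_maps])
        idx = int(np.argmax(rs))
        out[label] = (idx, float(rs[idx]))
    return out


def anchors_included(map_volume: np.ndarray, z_threshold: float, anchors,
                     cluster_membership: bool = False) -> bool:
    """True iff every anchor voxel exceeds the Z threshold (strict >).

    With ``cluster_membership`` the check passes when the anchor or any
    of its 6-neighbors is suprathreshold.
    """
    vol = np.asarray(map_volume, dtype=float)
    for ijk in anchors:
        ijk = tuple(int(c) for c in ijk)
        if any(not 0 <= c < d for c, d in zip(ijk, vol.shape)):
            raise ValueError(f"anchor {ijk} outside the grid")
        if vol[ijk] > z_threshold:
            continue
        if cluster_membership and _neighbor_above(vol, ijk, z_threshold):
            continue
        return False
    return True


def _neighbor_above(vol, ijk, thr) -> bool:
    for ax in range(3):
        for step in (-1, 1):
            n = list(ijk)
            n[ax] += step
            if 0 <= n[ax] < vol.shape[ax] and vol[tuple(n)] > thr:
                return True
    return False


def select_networks(decomp: Decomposition, config: SelectionConfig) -> SelectionResult:
    """Run the full PMN/DMN identification procedure on a decomposition."""
    if decomp.n_components == 0:
        nf = NetworkResult(NOT_FOUND, None, None, None)
        return SelectionResult(pmn=nf, dmn=NetworkResult(NOT_FOUND, None, None, None),
                               candidates={})
    templates = config.templates
    thr = config.z_threshold
    cands = pick_candidates(decomp, templates)

    def n_supra(idx):
        return int((decomp.group_maps[idx] > thr).sum())

    def passes(label, idx):
        vol = decomp.group_volume(idx)
        return anchors_included(vol, thr, templates.anchors[label],
                                config.cluster_membership)

    pmn_idx, pmn_r = cands["PMN"]
    if passes("PMN", pmn_idx):
        pmn = NetworkResult(FOUND, pmn_idx, pmn_r, n_supra(pmn_idx))
    else:
        pmn = NetworkResult(NOT_FOUND, None, pmn_r, None)

    dmn_idx, dmn_r = cands["DMN"]
    pdmn_idx, pdmn_r = cands["pDMN"]
    if passes("DMN", dmn_idx):
        dmn = NetworkResult(FOUND, dmn_idx, dmn_r, n_supra(dmn_idx))
    elif passes("pDMN", pdmn_idx):
        dmn = NetworkResult(FOUND_AS_POSTERIOR, pdmn_idx, pdmn_r, n_supra(pdmn_idx))
    else:
        dmn = NetworkResult(NOT_FOUND, None, dmn_r, None)

    # same-component conflict: the higher template correlation wins
    if (pmn.status != NOT_FOUND and dmn.status != NOT_FOUND
            and pmn.component == dmn.component):
        if pmn.r >= dmn.r:
            dmn = NetworkResult(NOT_FOUND, None, dmn.r, None)
        else:
            pmn = NetworkResult(NOT_FOUND, None, pmn.r, None)
    return SelectionResult(pmn=pmn, dmn=dmn, candidates=cands)
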