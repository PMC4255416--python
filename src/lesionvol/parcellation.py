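"""Plane-based 26-region volume-of-interest (VOI) parcellation.

A geometric analog of landmark-based lobar parcellation: the intracranial
mask is cut by a sagittal midline into hemispheres, by coronal planes at
configurable fractions of the anterior-posterior extent into frontal /
middle / posterior bands, by axial planes into inferior (temporal) and
superior strata, and by a lateral-distance plane into medial versus lateral
territory.  Thirteen named regions per hemisphere yield exactly 26 VOIs
covering the mask, disjoint by construction.  Anatomical fidelity to any
published atlas is explicitly not the goal; the interface (26 named regions
with lobar groupings, regional volumes additive to whole-brain volumes) is.

Axis conventions: axis 0 = left-right (x), axis 1 = anterior(low index) to
posterior, axis 2 = inferior(low index) to superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError

__all__ = ["ParcellationLandmarks", "VOIAtlas", "build_atlas", "regionalize",
           "REGION_DEFS", "LOBE_OF_REGION"]

# (short name, lobe); 13 per hemisphere, mirrored L/R.
REGION_DEFS = [
    ("medial superior frontal", "frontal"),
    ("medial middle frontal", "frontal"),
    ("medial inferior frontal", "frontal"),
    ("superior lateral frontal", "frontal"),
    ("inferior lateral frontal", "frontal"),
    ("anterior temporal", "temporal"),
    ("posterior temporal", "temporal"),
    ("basal ganglia-thalamus", "central"),
    ("superior parietal", "parietal"),
    ("inferior parietal", "parietal"),
    ("superior occipital", "occipital"),
    ("inferior occipital", "occipital"),
    ("occipito-temporal", "occipital"),
]
LOBE_OF_REGION = {name: lobe for name, lobe in REGION_DEFS}


@dataclass
class ParcellationLandmarks:
    """Midline plus boundary fractions of the mask extents.

    ``coronal_fractions`` (f1, f2) bound the frontal and occipital bands of
    the anterior-posterior extent; ``temporal_split`` divides anterior from
    posterior temporal inside (f1, f2); ``axial_fractions`` are the temporal
    roof, the superior/inferior stratum cut, and the top frontal cut of the
    inferior-superior extent; ``medial_fraction`` is the half-width fraction
    bounding medial territory.
    """

    midline_x: float | None = None       # voxel index; None -> mask centroid
    coronal_fractions: tuple[float, float] = (0.35, 0.75)
    temporal_split: float = 0.55
    axial_fractions: tuple[float, float, float] = (0.40, 0.62, 0.80)
    medial_fraction: float = 0.30

    def validate(self) -> None:
        f1, f2 = self.coronal_fractions
        if not (0.0 < f1 < f2 < 1.0):
            raise GeometryError("coronal fractions must be strictly increasing in (0,1)")
        if not (f1 < self.temporal_split < f2):
            raise GeometryError("temporal_split must lie between the coronal fractions")
        zt, zs1, zs2 = self.axial_fractions
        if not (0.0 < zt < zs1 < zs2 < 1.0):
            raise GeometryError("axial fractions must be strictly increasing in (0,1)")
        if not (0.0 < self.medial_fraction < 1.0):
            raise GeometryError("medial_fraction must be in (0,1)")


@dataclass
class VOIAtlas:
    region_grid: np.ndarray              # region id 1..26 inside the mask, 0 outside
    region_table: pd.DataFrame           # id, name, hemisphere, lobe
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.region_grid == region_id

    def ids_for_lobe(self, lobe: str, hemisphere: str | None = None) -> list[int]:
        t = self.region_table
        sel = t["lobe"] == lobe
        if hemisphere:
            sel &= t["hemisphere"] == hemisphere
        return t.loc[sel, "id"].tolist()


def build_atlas(mask: np.ndarray,
                landmarks: ParcellationLandmarks | None = None,
                voxel_size_mm=(1.0, 1.0, 1.0)) -> VOIAtlas:
    """Deterministic 26-region partition of the intracranial mask."""
    lm = landmarks or ParcellationLandmarks()
    lm.validate()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GeometryError("empty mask")
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    if np.any(lo == hi):
        raise GeometryError("mask is degenerate (flat along an axis)")
    mid_x = lm.midline_x if lm.midline_x is not None else float(idx[:, 0].mean())
    if not (lo[0] < mid_x < hi[0]):
        raise GeometryError("midline lies outside the mask extent")

    X, Y, Z = np.meshgrid(*[np.arange(n) for n in mask.shape], indexing="ij")
    yext, zext = hi[1] - lo[1], hi[2] - lo[2]
    f1 = lo[1] + lm.coronal_fractions[0] * yext
    f2 = lo[1] + lm.coronal_fractions[1] * yext
    ft = lo[1] + lm.temporal_split * yext
    zt = lo[2] + lm.axial_fractions[0] * zext
    zs1 = lo[2] + lm.axial_fractions[1] * zext
    zs2 = lo[2] + lm.axial_fractions[2] * zext
    half_width = max(mid_x - lo[0], hi[0] - mid_x)
    med = lm.medial_fraction * half_width

    frontal = Y < f1
    middle = (Y >= f1) & (Y < f2)
    posterior = Y >= f2
    inferior = Z < zt
    stratum1 = (Z >= zt) & (Z < zs1)
    medial = np.abs(X - mid_x) <= med

    # per-hemisphere region index 0..12, matching REGION_DEFS
    ridx = np.zeros(mask.shape, dtype=np.int8)
    ridx[frontal & medial & (Z >= zs2)] = 0
    ridx[frontal & medial & (Z >= zs1) & (Z < zs2)] = 1
    ridx[frontal & medial & (Z < zs1)] = 2
    ridx[frontal & ~medial & (Z >= zs1)] = 3
    ridx[frontal & ~medial & (Z < zs1)] = 4
    ridx[middle & inferior & (Y < ft)] = 5
    ridx[middle & inferior & (Y >= ft)] = 6
    ridx[middle & ~inferior & medial] = 7
    ridx[middle & ~inferior & ~medial & (Z >= zs1)] = 8
    ridx[middle & ~inferior & ~medial & (Z < zs1)] = 9
    ridx[posterior & (Z >= zs1)] = 10
    ridx[posterior & stratum1] = 11
    ridx[posterior & inferior] = 12

    left = X < mid_x
    region = np.zeros(mask.shape, dtype=np.uint8)
    region[mask] = (ridx[mask] + 1).astype(np.uint8)
    region[mask & ~left] += 13

    rows = [{"id": i + 1 + 13 * h, "name": f"{hemi} {name}",
             "hemisphere": hemi, "lobe": lobe}
            for h, hemi in enumerate(("left", "right"))
            for i, (name, lobe) in enumerate(REGION_DEFS)]
    table = pd.DataFrame(rows)
    return VOIAtlas(region, table, tuple(voxel_size_mm))


def regionalize(label_map: np.ndarray, atlas: VOIAtlas) -> pd.DataFrame:
    """Region x class contingency of voxel counts.

    Rows are the 26 region ids, columns the label values present in the
    map; marginals reproduce whole-brain class counts exactly.
    """
    label_map = np.asarray(label_map)
    if label_map.shape != atlas.region_grid.shape:
        raise GeometryError("label map and atlas grids differ")
    inside = atlas.region_grid > 0
    r = atlas.region_grid[inside].astype(np.int64)
    c = label_map[inside].astype(np.int64)
    classes = np.unique(c)
    ncls = len(classes)
    flat = (r - 1) * ncls + np.searchsorted(classes, c)
    counts = np.bincount(flat, minlength=26 * ncls).reshape(26, ncls)
    return pd.DataFrame(counts, index=pd.RangeIndex(1, 27, name="region_id"),
                        columns=pd.Index(classes, name="class"))
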