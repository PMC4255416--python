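"""Subcortical hyperintensity (SH) and lacune segmentation.

SH voxels are detected jointly on PD and T2 as intensities exceeding the
fitted white-matter mean by a configurable number of SDs on *both*
modalities (the joint requirement suppresses single-modality noise spikes).
Detected components are split into periventricular (pvSH) versus deep white
(dwSH) by 3D connectivity: a component is periventricular iff it comes
within a Chebyshev distance of the ventricular CSF mask.  Lacunes are then
carved out of the SH mask as voxels that are CSF-dark on T1 — cystic
fluid-filled cores inside hyperintense tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, GeometryError, PipelineError
from .synthetic_data import DWSH, GM, LACUNE, PVSH, SCSF, VCSF, WM
from .tissue_segmentation import GaussianFieldModel, TissueLabelMap

__all__ = ["SHDetectionParams", "LesionLabelMap", "segment_sh",
           "classify_pv_dw", "extract_lacunes"]

_CONN_STRUCT = {6: ndimage.generate_binary_structure(3, 1),
                18: ndimage.generate_binary_structure(3, 2),
                26: ndimage.generate_binary_structure(3, 3)}


@dataclass
class SHDetectionParams:
    z_threshold: float = 3.0          # SDs above the WM mean, on PD and on T2
    min_component_voxels: int = 5     # speckle suppression
    connectivity: int = 26            # 3D neighbourhood order
    pv_distance_voxels: int = 1       # max Chebyshev gap to vCSF for pv status
    gm_neighbourhood_exclusion: bool = True

    def validate(self) -> None:
        if self.z_threshold <= 0:
            raise ConfigError("z_threshold must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")
        if self.pv_distance_voxels < 0:
            raise ConfigError("pv_distance_voxels must be nonnegative")


@dataclass
class LesionLabelMap:
    """Lesion classes {pvSH, dwSH, lacune} plus a per-component table."""

    labels: np.ndarray
    components: pd.DataFrame   # id, class, voxels, volume_cc, centroid, parent_id
    voxel_size_mm: tuple[float, float, float]

    def class_volume_cc(self, code: int) -> float:
        voxvol = float(np.prod(self.voxel_size_mm))
        return int(np.count_nonzero(self.labels == code)) * voxvol / 1000.0


def _exterior_csf(tissue: TissueLabelMap) -> np.ndarray:
    """CSF connected (26-wise) to the intracranial boundary: sulcal/subdural
    fluid, as opposed to interior fluid islands such as lacune cores."""
    csf = tissue.class_mask(SCSF, VCSF)
    border = csf & ndimage.binary_dilation(~tissue.mask, structure=_CONN_STRUCT[26])
    cc, _ = ndimage.label(csf, structure=_CONN_STRUCT[26])
    exterior_ids = np.unique(cc[border])
    exterior_ids = exterior_ids[exterior_ids > 0]
    return np.isin(cc, exterior_ids)


def _robust_stats(values: np.ndarray) -> tuple[float, float]:
    mean = float(values.mean())
    sd = float(values.std())
    return mean, max(sd, 1e-9)


def segment_sh(pd_grid: np.ndarray, t2_grid: np.ndarray,
               tissue: TissueLabelMap, model: GaussianFieldModel,
               params: SHDetectionParams | None = None) -> np.ndarray:
    """Binary SH mask from the joint PD/T2 hyperintensity criterion.

    WM reference statistics are the mean/SD of PD and T2 intensities over
    WM-labelled voxels.  Ventricular CSF and exterior (boundary-connected)
    sulcal CSF are never candidates; interior CSF-labelled islands remain
    eligible because cystic lesion cores are CSF-dark on T1 yet bright on
    PD/T2.  Components smaller than ``min_component_voxels`` are discarded.
    """
    params = params or SHDetectionParams()
    params.validate()
    wm = tissue.class_mask(WM)
    if not wm.any():
        raise PipelineError("white-matter class is empty; cannot calibrate SH detection")
    pd_grid = np.asarray(pd_grid, dtype=float)
    t2_grid = np.asarray(t2_grid, dtype=float)
    if pd_grid.shape != tissue.labels.shape or t2_grid.shape != tissue.labels.shape:
        raise GeometryError("PD/T2 grids are not co-registered with the tissue labels")

    m_pd, s_pd = _robust_stats(pd_grid[wm])
    m_t2, s_t2 = _robust_stats(t2_grid[wm])
    candidate = (tissue.mask
                 & ~tissue.class_mask(VCSF)
                 & ~_exterior_csf(tissue)
                 & (pd_grid > m_pd + params.z_threshold * s_pd)
                 & (t2_grid > m_t2 + params.z_threshold * s_t2))
    if params.gm_neighbourhood_exclusion:
        # cortical false-positive control: drop voxels sitting in
        # majority-GM neighbourhoods
        gm_frac = ndimage.uniform_filter(
            tissue.class_mask(GM).astype(np.float32), size=3)
        candidate &= gm_frac <= 0.5

    struct = _CONN_STRUCT[params.connectivity]
    cc, n = ndimage.label(candidate, structure=struct)
    if n:
        sizes = np.bincount(cc.ravel())
        small = np.flatnonzero(sizes < params.min_component_voxels)
        candidate[np.isin(cc, small[small > 0])] = False
    return candidate


def _component_table(labels: np.ndarray, cc: np.ndarray, ids: np.ndarray,
                     classes: list[str], voxvol: float,
                     parents: list | None = None) -> pd.DataFrame:
    rows = []
    coms = ndimage.center_of_mass(np.ones_like(cc), cc, ids) if len(ids) else []
    sizes = ndimage.sum_labels(np.ones_like(cc), cc, ids) if len(ids) else []
    for i, cid in enumerate(ids):
        rows.append({
            "id": int(cid), "class": classes[i], "voxels": int(sizes[i]),
            "volume_cc": float(sizes[i]) * voxvol / 1000.0,
            "centroid_i": float(coms[i][0]), "centroid_j": float(coms[i][1]),
            "centroid_k": float(coms[i][2]),
            "parent_id": (parents[i] if parents else pd.NA),
        })
    return pd.DataFrame(rows, columns=["id", "class", "voxels", "volume_cc",
                                       "centroid_i", "centroid_j", "centroid_k",
                                       "parent_id"])


def classify_pv_dw(sh_mask: np.ndarray, vcsf_mask: np.ndarray,
                   params: SHDetectionParams | None = None,
                   voxel_size_mm=(1.0, 1.0, 1.0)) -> LesionLabelMap:
    """Label SH components periventricular or deep white by 3D connectivity.

    A component is pvSH iff its minimum Chebyshev (chessboard) distance to
    ventricular CSF is at most ``pv_distance_voxels``; otherwise dwSH.
    Deterministic; an empty SH mask yields an empty map.
    """
    params = params or SHDetectionParams()
    params.validate()
    sh_mask = np.asarray(sh_mask, dtype=bool)
    vcsf_mask = np.asarray(vcsf_mask, dtype=bool)
    if sh_mask.shape != vcsf_mask.shape:
        raise GeometryError("SH and vCSF masks are not co-registered")
    voxvol = float(np.prod(voxel_size_mm))
    labels = np.zeros(sh_mask.shape, dtype=np.uint8)

    struct = _CONN_STRUCT[params.connectivity]
    cc, n = ndimage.label(sh_mask, structure=struct)
    if n == 0:
        return LesionLabelMap(labels, _component_table(labels, cc, np.array([], int),
                                                       [], voxvol), tuple(voxel_size_mm))
    if vcsf_mask.any():
        dist = ndimage.distance_transform_cdt(~vcsf_mask, metric="chessboard")
        min_dist = ndimage.minimum(dist, labels=cc, index=np.arange(1, n + 1))
    else:
        min_dist = np.full(n, np.inf)
    ids = np.arange(1, n + 1)
    is_pv = np.asarray(min_dist) <= params.pv_distance_voxels
    labels[np.isin(cc, ids[is_pv])] = PVSH
    labels[np.isin(cc, ids[~is_pv])] = DWSH
    classes = ["pvSH" if p else "dwSH" for p in is_pv]
    table = _component_table(labels, cc, ids, classes, voxvol)
    return LesionLabelMap(labels, table, tuple(voxel_size_mm))


def extract_lacunes(lesions: LesionLabelMap, t1: np.ndarray,
                    model: GaussianFieldModel,
                    params: SHDetectionParams | None = None) -> LesionLabelMap:
    """Relabel CSF-dark SH voxels (T1 below CSF mean + 2 SD) as lacunes.

    Lacune voxels are reassigned, never created, so pvSH + dwSH + lacune
    volume is conserved.  Each lacune component records the id of the SH
    component it was carved from.
    """
    params = params or SHDetectionParams()
    t1 = np.asarray(t1, dtype=float)
    if t1.shape != lesions.labels.shape:
        raise GeometryError("T1 grid is not co-registered with the lesion labels")
    csf_mean, csf_sd = model.global_class_stats()["CSF"]
    labels = lesions.labels.copy()
    sh = labels > 0
    dark = sh & (t1 < csf_mean + 2.0 * csf_sd)
    labels[dark] = LACUNE

    voxvol = float(np.prod(lesions.voxel_size_mm))
    struct = _CONN_STRUCT[params.connectivity]
    parent_cc, _ = ndimage.label(lesions.labels > 0, structure=struct)
    # refresh the SH component rows (volumes shrink where cores were carved)
    table = lesions.components.copy()
    remaining_counts = np.bincount(parent_cc[sh & ~dark].ravel(),
                                   minlength=int(parent_cc.max()) + 1)
    for idx, row in table.iterrows():
        nvox = int(remaining_counts[int(row["id"])])
        table.at[idx, "voxels"] = nvox
        table.at[idx, "volume_cc"] = nvox * voxvol / 1000.0
    cc, n = ndimage.label(dark, structure=struct)
    if n:
        ids = np.arange(1, n + 1)
        parents = [int(ndimage.maximum(parent_cc, labels=cc, index=i)) for i in ids]
        offset = int(table["id"].max()) if len(table) else 0
        lac = _component_table(labels, cc, ids, ["lacune"] * n, voxvol, parents)
        lac["id"] = lac["id"] + offset
        table = pd.concat([table, lac], ignore_index=True)
    return LesionLabelMap(labels, table, lesions.voxel_size_mm)
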