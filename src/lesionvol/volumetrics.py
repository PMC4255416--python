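"""Per-subject volumetric profiles, head-size normalization and z-scores.

A profile is a tidy table of raw volumes (cc) per tissue/lesion class per
VOI plus whole-brain rows, together with ST-TIV, brain parenchymal fraction
BPF = 100 * (GM + WM) / ST-TIV, and the ventricular atrophy ratio
vCSF / ST-TIV.  For cohort analyses every volumetric variable is first
expressed as a proportion of ST-TIV, log-transformed when its
reference-sample skewness is high, and converted to a z-score against a
reference (by default control-only) sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError
from .parcellation import VOIAtlas, regionalize
from .synthetic_data import CLASS_NAMES, DWSH, GM, LACUNE, PVSH, SCSF, VCSF, WM
from .lesion_segmentation import LesionLabelMap
from .tissue_segmentation import TissueLabelMap

__all__ = ["VolumetricProfile", "compute_profile", "normalize_and_zscore",
           "combined_label_map"]

PROFILE_CLASSES = (GM, WM, SCSF, VCSF, PVSH, DWSH, LACUNE)


@dataclass
class VolumetricProfile:
    subject_id: str
    st_tiv_cc: float
    table: pd.DataFrame        # columns: region_id, region, class, voxels, raw_cc
    bpf_percent: float
    vcsf_ratio: float

    def class_total_cc(self, class_name: str) -> float:
        t = self.table
        row = t[(t["region"] == "whole_brain") & (t["class"] == class_name)]
        return float(row["raw_cc"].iloc[0]) if len(row) else 0.0

    @property
    def sh_total_cc(self) -> float:
        """Total detected hyperintensity load: pvSH + dwSH + lacune."""
        return sum(self.class_total_cc(c) for c in ("pvSH", "dwSH", "lacune"))


def combined_label_map(tissue: TissueLabelMap, lesions: LesionLabelMap) -> np.ndarray:
    """Tissue labels with lesion classes overriding — the pipeline's final
    per-voxel answer, directly comparable to phantom ground truth."""
    out = tissue.labels.copy()
    lesional = lesions.labels > 0
    out[lesional] = lesions.labels[lesional]
    return out


def compute_profile(tissue: TissueLabelMap, lesions: LesionLabelMap,
                    atlas: VOIAtlas, st_tiv_cc: float,
                    subject_id: str = "subject") -> VolumetricProfile:
    """Count voxels per class per VOI and derive BPF and vCSF/ST-TIV."""
    if st_tiv_cc <= 0:
        raise InputError("ST-TIV must be positive")
    labels = combined_label_map(tissue, lesions)
    voxvol = float(np.prod(tissue.voxel_size_mm))
    contingency = regionalize(labels, atlas)
    names = dict(zip(atlas.region_table["id"], atlas.region_table["name"]))
    rows = []
    for code in PROFILE_CLASSES:
        cname = CLASS_NAMES[code]
        col = contingency[code] if code in contingency.columns else pd.Series(0, index=contingency.index)
        for rid, nvox in col.items():
            rows.append({"region_id": rid, "region": names[rid], "class": cname,
                         "voxels": int(nvox), "raw_cc": nvox * voxvol / 1000.0})
        total = int(col.sum())
        rows.append({"region_id": 0, "region": "whole_brain", "class": cname,
                     "voxels": total, "raw_cc": total * voxvol / 1000.0})
    table = pd.DataFrame(rows)
    wb = table[table["region"] == "whole_brain"].set_index("class")["raw_cc"]
    bpf = 100.0 * (wb["GM"] + wb["WM"]) / st_tiv_cc
    vcsf_ratio = wb["vCSF"] / st_tiv_cc
    return VolumetricProfile(subject_id, float(st_tiv_cc), table,
                             float(bpf), float(vcsf_ratio))


def _sample_skewness(x: np.ndarray) -> float:
    # adjusted Fisher-Pearson coefficient
    if np.ptp(x) == 0:
        return 0.0
    return float(sps.skew(x, bias=False))


def normalize_and_zscore(values: pd.DataFrame, st_tiv: pd.Series,
                         reference_ids, skew_threshold: float = 1.0,
                         normalize: bool = True):
    """Head-size-normalize, optionally log-transform, and z-score variables.

    ``values`` is subjects x variables (raw cc); ``st_tiv`` is indexed like
    ``values``.  Each variable is divided by ST-TIV; if its reference-sample
    skewness exceeds ``skew_threshold`` it is transformed as
    log(value + offset) with offset the smallest positive observed value
    (zero-heavy lesion variables stay finite); z-scores use reference-sample
    mean and SD.  Returns (z table, per-variable transform log).
    """
    if len(reference_ids) == 0:
        raise InputError("reference subset is empty")
    values = values.astype(float)
    if normalize:
        values = values.div(st_tiv, axis=0)
    zs = {}
    transform_log = {}
    ref = values.loc[reference_ids]
    for var in values.columns:
        col = values[var]
        skew_before = _sample_skewness(ref[var].to_numpy())
        logged = abs(skew_before) > skew_threshold
        if logged:
            positive = col[col > 0]
            offset = float(positive.min()) if len(positive) else 1.0
            col = np.log(col + offset)
            skew_after = _sample_skewness(col.loc[reference_ids].to_numpy())
        else:
            skew_after = skew_before
        mu = float(col.loc[reference_ids].mean())
        sd = float(col.loc[reference_ids].std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            transform_log[var] = {"log": logged, "excluded": True,
                                  "reason": "zero reference variance"}
            continue
        zs[var] = (col - mu) / sd
        transform_log[var] = {"log": logged, "excluded": False,
                              "skew_before": skew_before, "skew_after": skew_after}
    return pd.DataFrame(zs, index=values.index), transform_log
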