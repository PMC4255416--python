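"""End-to-end orchestration: phantom -> segmentation -> profile -> statistics.

All stages are deterministic given the phantom spec (which carries the
seed), so two runs with the same seed write byte-identical CSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import statistics as st
from .brain_extraction import BrainExtractionParams, IntracranialMask, extract_brain
from .lesion_segmentation import (LesionLabelMap, SHDetectionParams,
                                  classify_pv_dw, extract_lacunes, segment_sh)
from .parcellation import ParcellationLandmarks, VOIAtlas, build_atlas
from .synthetic_data import (GroundTruth, MultiModalVolume, PhantomSpec,
                             default_phantom_spec, demographics_cohort_spec,
                             generate_cohort, generate_phantom,
                             standardized_effects_spec, VCSF)
from .tissue_segmentation import (GaussianFieldModel, TissueLabelMap, WindowSpec,
                                  classify_tissue, fit_local_gaussians, split_csf)
from .volumetrics import VolumetricProfile, combined_label_map, compute_profile

__all__ = ["PhantomPipelineResult", "run_phantom_pipeline", "run_study", "dice"]

_FLOAT_FMT = "%.6g"


@dataclass
class PhantomPipelineResult:
    spec: PhantomSpec
    volume: MultiModalVolume
    truth: GroundTruth
    intracranial: IntracranialMask
    model: "GaussianFieldModel"
    tissue: TissueLabelMap
    sh_mask: np.ndarray
    lesions: LesionLabelMap
    atlas: VOIAtlas
    profile: VolumetricProfile

    @property
    def combined_labels(self) -> np.ndarray:
        return combined_label_map(self.tissue, self.lesions)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both are empty)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def run_phantom_pipeline(spec: PhantomSpec | None = None,
                         extraction: BrainExtractionParams | None = None,
                         window_spec: WindowSpec | None = None,
                         sh_params: SHDetectionParams | None = None,
                         landmarks: ParcellationLandmarks | None = None,
                         subject_id: str = "phantom") -> PhantomPipelineResult:
    """Generate a phantom and run every imaging stage on it.

    Ventricle seeds for the CSF split come from the phantom ground truth,
    which stands in for the operator-supplied seed coordinates used on real
    data.
    """
    spec = spec or default_phantom_spec()
    volume, truth = generate_phantom(spec)
    icm = extract_brain(volume, extraction)
    model = fit_local_gaussians(volume.t1, icm.mask, window_spec)
    tissue = classify_tissue(model, volume.t1, icm.mask, spec.voxel_size_mm)
    tissue = split_csf(tissue, truth.ventricle_seed_voxels)
    sh = segment_sh(volume.pd, volume.t2, tissue, model, sh_params)
    lesions = classify_pv_dw(sh, tissue.labels == VCSF, sh_params, spec.voxel_size_mm)
    lesions = extract_lacunes(lesions, volume.t1, model, sh_params)
    atlas = build_atlas(icm.mask, landmarks, spec.voxel_size_mm)
    profile = compute_profile(tissue, lesions, atlas, icm.st_tiv_cc, subject_id)
    return PhantomPipelineResult(spec, volume, truth, icm, model, tissue, sh,
                                 lesions, atlas, profile)


def run_study(seed: int, out_dir, *, small: bool = True) -> dict[str, Path]:
    """Full desk-scale study: one phantom through the imaging pipeline plus
    a synthetic cohort through the statistical stage; writes CSV outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = run_phantom_pipeline(default_phantom_spec(noise_frac=0.1, seed=seed,
                                                    small=small))
    paths = {}
    paths["profile"] = out / "profile.csv"
    res.profile.table.to_csv(paths["profile"], index=False, float_format=_FLOAT_FMT)
    paths["components"] = out / "components.csv"
    res.lesions.components.to_csv(paths["components"], index=False,
                                  float_format=_FLOAT_FMT)

    demo = demographics_cohort_spec(seed=seed)
    cohort = generate_cohort(demo)
    paths["cohort"] = out / "cohort.csv"
    cohort.to_csv(paths["cohort"], index=False, float_format=_FLOAT_FMT)

    est, t, p, _ = st.ancova_group_difference(cohort, "mmse")
    ancova = pd.DataFrame([{"outcome": "mmse", "adjusted_difference": est,
                            "t": t, "p": p}])
    paths["ancova"] = out / "ancova.csv"
    ancova.to_csv(paths["ancova"], index=False, float_format=_FLOAT_FMT)

    spec = standardized_effects_spec("bpf", {"pvsh": -0.14, "education": -0.16},
                                    seed=seed)
    table = generate_cohort(spec)
    result = st.backwards_elimination(table, "bpf", ["pvsh", "education"])
    paths["regression"] = out / "regression.csv"
    result.retained.to_csv(paths["regression"], index=False, float_format=_FLOAT_FMT)
    return paths
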