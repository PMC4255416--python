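"""Phantom and cohort generators: geometry, quantization, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from lesionvol.errors import ConfigError, PlacementError
from lesionvol.synthetic_data import (
    BACKGROUND, CohortSpec, DWSH, GM, LACUNE, PVSH, PhantomSpec, SCSF, VCSF, WM,
    CLASS_NAMES, default_intensity_model, demographics_cohort_spec,
    generate_cohort, generate_phantom,
)
from conftest import tiny_phantom_spec


class TestPhantomGeometry:
    def test_zero_lesion_phantom_has_zero_lesion_volumes(self):
        spec = tiny_phantom_spec(pv_lesion_spec=[], dw_lesion_spec=[], lacune_spec=[])
        _, truth = generate_phantom(spec)
        for cls in ("pvSH", "dwSH", "lacune"):
            assert truth.true_volumes_cc[cls] == 0.0

    def test_label_partition_and_volume_identity(self):
        spec = tiny_phantom_spec(seed=3)
        _, truth = generate_phantom(spec)
        voxvol = spec.voxel_volume_mm3
        counts = np.bincount(truth.label_map.ravel(), minlength=8)
        # volumes are voxel count x voxel volume, and classes tile the brain
        for code in range(8):
            assert truth.true_volumes_cc[CLASS_NAMES[code]] == pytest.approx(
                counts[code] * voxvol / 1000.0)
        brain = truth.label_map != BACKGROUND
        assert counts[1:].sum() == brain.sum()

    def test_dw_lesion_volume_quantization_at_1mm(self):
        # 1 mm^3 voxels: a 2.0 cc request maps to exactly 2000 voxels
        spec = PhantomSpec(
            grid_shape=(56, 64, 52), voxel_size_mm=(1.0, 1.0, 1.0),
            brain_semiaxes_mm=(24.0, 28.0, 22.0),
            ventricle_semiaxes_mm=(3.5, 7.0, 3.5),
            ventricle_offset_mm=(6.0, 1.0, 0.0),
            subdural_csf_thickness_mm=1.5, cortical_gm_thickness_mm=2.5,
            pv_lesion_spec=[], lacune_spec=[],
            dw_lesion_spec=[(2.0, (12.0, -9.0, 5.0))])
        _, truth = generate_phantom(spec)
        assert truth.true_volumes_cc["dwSH"] == pytest.approx(2.0, abs=0.001)

    def test_every_lesion_within_one_voxel_of_target(self, tiny_spec):
        _, truth = generate_phantom(tiny_spec)
        voxvol_cc = tiny_spec.voxel_volume_mm3 / 1000.0
        assert abs(truth.true_volumes_cc["pvSH"] - 1.5) <= voxvol_cc
        assert abs(truth.true_volumes_cc["dwSH"] - 0.8) <= voxvol_cc

    def test_pv_contact_and_dw_separation_from_ventricles(self):
        from scipy import ndimage
        spec = tiny_phantom_spec()
        _, truth = generate_phantom(spec)
        lab = truth.label_map
        dist = ndimage.distance_transform_cdt(lab != VCSF, metric="chessboard")
        assert dist[lab == PVSH].min() <= 1
        assert dist[lab == DWSH].min() > spec.dw_ventricle_gap_voxels

    def test_lacune_cores_carved_from_parent_lesions(self):
        # lacune voxels must lie inside the pv/dw lesions as originally placed
        with_lac = tiny_phantom_spec(lacune_spec=[(1, 0.1)])
        without = tiny_phantom_spec(lacune_spec=[])
        _, t_with = generate_phantom(with_lac)
        _, t_without = generate_phantom(without)
        lac = t_with.label_map == LACUNE
        assert lac.sum() > 0
        assert np.all(np.isin(t_without.label_map[lac], (PVSH, DWSH)))
        assert np.array_equal(t_with.label_map[~lac], t_without.label_map[~lac])

    def test_ventricle_seed_voxels_are_ventricular(self, tiny_spec):
        _, truth = generate_phantom(tiny_spec)
        for s in truth.ventricle_seed_voxels:
            assert truth.label_map[s] == VCSF

    def test_same_seed_bit_identical_different_seed_not(self, tiny_spec):
        spec_a = tiny_phantom_spec(noise_frac=0.2, seed=5)
        spec_b = tiny_phantom_spec(noise_frac=0.2, seed=5)
        spec_c = tiny_phantom_spec(noise_frac=0.2, seed=6)
        va, _ = generate_phantom(spec_a)
        vb, _ = generate_phantom(spec_b)
        vc, _ = generate_phantom(spec_c)
        assert np.array_equal(va.t1, vb.t1)
        assert np.array_equal(va.pd, vb.pd)
        assert not np.array_equal(va.t1, vc.t1)

    def test_empirical_t1_intensity_ordering(self):
        vol, truth = generate_phantom(tiny_phantom_spec(noise_frac=0.2, seed=2))
        lab = truth.label_map
        csf = vol.t1[np.isin(lab, (SCSF, VCSF))].mean()
        gm = vol.t1[lab == GM].mean()
        wm = vol.t1[lab == WM].mean()
        assert csf < gm < wm

    def test_oversized_lesion_raises_placement_error(self):
        spec = tiny_phantom_spec(dw_lesion_spec=[(500.0, (26.0, -20.0, 8.0))])
        with pytest.raises(PlacementError, match="dw lesion 0"):
            generate_phantom(spec)

    def test_lesion_centroid_in_ventricle_raises(self):
        spec = tiny_phantom_spec(dw_lesion_spec=[(0.5, (12.0, 3.0, 1.0))])
        with pytest.raises(PlacementError):
            generate_phantom(spec)

    @pytest.mark.parametrize("mutate", [
        dict(ventricle_offset_mm=(40.0, 3.0, 1.0)),          # leaves the brain
        dict(noise_sd=-1.0),
        dict(pv_lesion_spec=[(-1.0, (1.0, 0.0, 0.0))]),
    ])
    def test_invalid_specs_rejected(self, mutate):
        spec = tiny_phantom_spec(**mutate)
        with pytest.raises((ConfigError, PlacementError)):
            generate_phantom(spec)

    def test_t1_mean_ordering_enforced(self):
        model = default_intensity_model()
        model["t1"]["CSF"] = (150.0, 0.0)
        spec = tiny_phantom_spec(intensity_model=model)
        with pytest.raises(ConfigError, match="CSF < GM < WM"):
            generate_phantom(spec)


class TestCohortGeneration:
    def test_zero_coefficients_zero_noise_gives_constant_intercept(self):
        spec = CohortSpec(
            n_per_group={"AD": 10},
            variables={"x": {"AD": (0.0, 1.0)}},
            effects=[("y", "x", 0.0)],
            intercepts={"y": {"AD": 3.5}},
            noise_sd={"y": 0.0}, seed=0)
        df = generate_cohort(spec)
        assert np.allclose(df["y"], 3.5)

    def test_group_means_match_study_demographics(self):
        # AD age 72.8 (9.0) n=265, NC 69.5 (8.0) n=100: sample means within 3 SE
        df = generate_cohort(demographics_cohort_spec(seed=11))
        for group, mean, sd, n in [("AD", 72.8, 9.0, 265), ("NC", 69.5, 8.0, 100)]:
            got = df.loc[df["group"] == group, "age"].mean()
            assert abs(got - mean) < 3 * sd / np.sqrt(n)
        assert len(df) == 365

    def test_ols_recovers_planted_slope(self):
        spec = CohortSpec(
            n_per_group={"AD": 1000},
            variables={"x": {"AD": (0.0, 1.0)}},
            effects=[("y", "x", 0.5)],
            noise_sd={"y": 0.1}, seed=4)
        df = generate_cohort(spec)
        x = df["x"] - df["x"].mean()
        slope = float((x * df["y"]).sum() / (x * x).sum())
        assert abs(slope - 0.5) < 0.05

    def test_undefined_predictor_raises_config_error(self):
        spec = CohortSpec(n_per_group={"AD": 5},
                          variables={"x": {"AD": (0.0, 1.0)}},
                          effects=[("y", "nope", 1.0)], noise_sd={"y": 0.1})
        with pytest.raises(ConfigError, match="nope"):
            generate_cohort(spec)

    def test_chained_outcomes_and_reproducibility(self):
        spec = CohortSpec(
            n_per_group={"NC": 50},
            variables={"x": {"NC": (1.0, 0.5)}},
            effects=[("y", "x", 2.0), ("z", "y", -1.0)],
            noise_sd={"y": 0.0, "z": 0.0}, seed=9)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        pd.testing.assert_frame_equal(a, b)
        assert np.allclose(a["z"], -2.0 * a["x"])
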