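"""Synthetic brain phantoms and synthetic AD/NC cohorts with known ground truth.

The phantom is an analytic nested-ellipsoid head: a brain ellipsoid whose
outermost shell is subdural/sulcal CSF, then a cortical grey-matter shell,
then deep white matter carrying two mirrored ventricular ellipsoids.
Hyperintense lesions are implanted into the white matter either grown from a
seed on the ventricle surface (periventricular) or as compact blobs kept at a
configurable distance from the ventricles (deep white), and cystic lacune
cores are carved out of lesion interiors.  Each tissue class has a
class-conditional Gaussian intensity model per modality (T1, PD, T2), so the
label map is exact ground truth for every downstream segmentation stage.

The cohort generator draws per-group demographics and volumetric variables
and builds cognitive/atrophy outcomes from an explicit linear-Gaussian
effect structure, so regression stages can be tested against planted
coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import stream
from .errors import ConfigError, PlacementError

__all__ = [
    "BACKGROUND", "SCSF", "VCSF", "GM", "WM", "PVSH", "DWSH", "LACUNE",
    "CLASS_NAMES", "MultiModalVolume", "PhantomSpec", "GroundTruth",
    "CohortSpec", "generate_phantom", "generate_cohort",
    "default_intensity_model", "default_phantom_spec",
    "demographics_cohort_spec", "standardized_effects_spec", "voi_cohort_spec",
]

# Label codes shared by ground truth and every segmentation product.
BACKGROUND, SCSF, VCSF, GM, WM, PVSH, DWSH, LACUNE = range(8)
CLASS_NAMES = {
    BACKGROUND: "background", SCSF: "sCSF", VCSF: "vCSF", GM: "GM",
    WM: "WM", PVSH: "pvSH", DWSH: "dwSH", LACUNE: "lacune",
}
NAME_TO_CLASS = {v: k for k, v in CLASS_NAMES.items()}

# Intensity classes: lesions look WM-like on T1, bright on PD/T2; lacune
# cores are fluid (CSF-like on T1) but sit inside hyperintense tissue on
# PD/T2 so they are first captured by the hyperintensity detector.
_LABEL_TO_INTENSITY = {
    SCSF: "CSF", VCSF: "CSF", GM: "GM", WM: "WM",
    PVSH: "SH", DWSH: "SH", LACUNE: "lacune",
}
MODALITIES = ("t1", "pd", "t2")


def default_intensity_model(noise_frac: float = 0.0) -> dict:
    """Class-conditional (mean, sd) per modality, in arbitrary scanner units.

    ``noise_frac`` sets every class SD to that fraction of the smallest
    adjacent gap between distinct class means of the modality, which is the
    natural difficulty axis for segmentation benchmarks.
    """
    means = {
        "t1": {"CSF": 40.0, "GM": 100.0, "WM": 140.0, "SH": 140.0, "lacune": 40.0},
        "pd": {"CSF": 80.0, "GM": 110.0, "WM": 95.0, "SH": 135.0, "lacune": 135.0},
        "t2": {"CSF": 180.0, "GM": 100.0, "WM": 80.0, "SH": 140.0, "lacune": 160.0},
    }
    model = {}
    for mod, mu in means.items():
        vals = np.unique(np.array(sorted(mu.values())))
        gap = float(np.min(np.diff(vals))) if len(vals) > 1 else 1.0
        sd = noise_frac * gap
        model[mod] = {cls: (m, sd) for cls, m in mu.items()}
    return model


@dataclass
class MultiModalVolume:
    """Co-registered T1/PD/T2 intensity grids over one voxel lattice."""

    t1: np.ndarray
    pd: np.ndarray
    t2: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t1.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff


@dataclass
class GroundTruth:
    """Exact per-voxel labels and per-class volumes of a phantom."""

    label_map: np.ndarray
    true_volumes_cc: dict[str, float]
    ventricle_seed_voxels: list[tuple[int, int, int]]
    voxel_size_mm: tuple[float, float, float]


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (100, 114, 92)
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    brain_semiaxes_mm: tuple[float, float, float] = (60.0, 72.0, 54.0)
    ventricle_semiaxes_mm: tuple[float, float, float] = (10.0, 22.0, 10.0)
    ventricle_offset_mm: tuple[float, float, float] = (16.0, 4.0, 2.0)
    subdural_csf_thickness_mm: float = 3.0
    cortical_gm_thickness_mm: float = 5.0
    # (target volume cc, outward direction from the ventricle surface);
    # lesion i is seeded on ventricle i % 2.
    pv_lesion_spec: list[tuple[float, tuple[float, float, float]]] = field(
        default_factory=lambda: [(3.0, (1.0, 0.3, 0.2)), (1.5, (-1.0, -0.3, 0.4))])
    # (target volume cc, centroid in mm relative to the volume centre)
    dw_lesion_spec: list[tuple[float, tuple[float, float, float]]] = field(
        default_factory=lambda: [(0.5, (34.0, -26.0, 10.0)), (0.4, (-32.0, 24.0, -8.0))])
    # (parent lesion index in [pv..., dw...] order, core volume cc)
    lacune_spec: list[tuple[int, float]] = field(
        default_factory=lambda: [(0, 0.06), (2, 0.05)])
    dw_ventricle_gap_voxels: int = 3
    intensity_model: dict = field(default_factory=default_intensity_model)
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def validate(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ConfigError("grid_shape too small")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigError("voxel dimensions must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        for cc, _ in list(self.pv_lesion_spec) + list(self.dw_lesion_spec):
            if cc <= 0:
                raise ConfigError("lesion volumes must be positive")
        for _, cc in self.lacune_spec:
            if cc <= 0:
                raise ConfigError("lacune volumes must be positive")
        for mod in MODALITIES:
            for cls, (_, sd) in self.intensity_model[mod].items():
                if sd < 0:
                    raise ConfigError(f"negative SD for {cls}/{mod}")
        t1 = {c: m for c, (m, _) in self.intensity_model["t1"].items()}
        if not (t1["CSF"] < t1["GM"] < t1["WM"]):
            raise ConfigError("T1 class means must satisfy CSF < GM < WM")
        if abs(t1["SH"] - t1["WM"]) > abs(t1["SH"] - t1["GM"]):
            raise ConfigError("SH must have a WM-like T1 mean")
        if abs(t1["lacune"] - t1["CSF"]) > abs(t1["lacune"] - t1["GM"]):
            raise ConfigError("lacune cores must have a CSF-like T1 mean")
        for mod in ("pd", "t2"):
            mm = {c: m for c, (m, _) in self.intensity_model[mod].items()}
            if not mm["SH"] > mm["WM"]:
                raise ConfigError(f"SH mean must exceed WM mean on {mod}")
        # ventricles strictly inside the brain ellipsoid (axis-aligned bound)
        a = np.asarray(self.brain_semiaxes_mm)
        va = np.asarray(self.ventricle_semiaxes_mm)
        off = np.abs(np.asarray(self.ventricle_offset_mm))
        if np.any(off + va >= a):
            raise ConfigError("ventricle ellipsoids must lie strictly inside the brain")


def default_phantom_spec(noise_frac: float = 0.0, seed: int = 0, *,
                         small: bool = False) -> PhantomSpec:
    """A ready-to-run phantom; ``small=True`` uses a coarse 2 mm lattice."""
    spec = PhantomSpec(intensity_model=default_intensity_model(noise_frac), seed=seed)
    if small:
        spec.grid_shape = (64, 76, 64)
        spec.voxel_size_mm = (2.0, 2.0, 2.0)
        spec.brain_semiaxes_mm = (54.0, 66.0, 48.0)
        spec.ventricle_semiaxes_mm = (8.0, 18.0, 8.0)
        spec.ventricle_offset_mm = (14.0, 4.0, 2.0)
        spec.cortical_gm_thickness_mm = 6.0
        spec.subdural_csf_thickness_mm = 4.0
        spec.pv_lesion_spec = [(2.0, (1.0, 0.3, 0.2)), (1.5, (-1.0, -0.3, 0.4))]
        spec.dw_lesion_spec = [(0.8, (30.0, -24.0, 10.0)), (0.6, (-28.0, 22.0, -8.0))]
        spec.lacune_spec = [(0, 0.15), (2, 0.12)]
    return spec


def _mm_grids(shape, voxel):
    """Per-axis coordinate arrays in mm, origin at the volume centre."""
    return np.meshgrid(
        *[(np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(shape, voxel)],
        indexing="ij", sparse=True)


def _ellipsoid(grids, center_mm, semiaxes_mm):
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center_mm, semiaxes_mm))
    return q <= 1.0


def _voxels_for(cc: float, voxel_volume_mm3: float) -> int:
    return max(1, int(round(cc * 1000.0 / voxel_volume_mm3)))


def _grow_nearest(candidates: np.ndarray, seed_mm, voxel, k: int, what: str):
    """Pick the k candidate voxels nearest (in mm) to a seed point."""
    idx = np.argwhere(candidates)
    if len(idx) < k:
        raise PlacementError(f"{what}: only {len(idx)} eligible voxels for {k} requested")
    d2 = np.zeros(len(idx))
    for ax in range(3):
        ctr = (candidates.shape[ax] - 1) / 2.0
        d2 += ((idx[:, ax] - ctr) * voxel[ax] - seed_mm[ax]) ** 2
    chosen = idx[np.argpartition(d2, k - 1)[:k]]
    return tuple(chosen.T)


def generate_phantom(spec: PhantomSpec) -> tuple[MultiModalVolume, GroundTruth]:
    """Voxelize the phantom geometry, implant lesions, and synthesize images.

    Identical spec and seed give bit-identical output.  Each implanted
    structure's realized volume differs from its target by at most one voxel
    volume (the lattice quantization step).
    """
    spec.validate()
    shape, voxel = tuple(spec.grid_shape), tuple(spec.voxel_size_mm)
    voxvol = spec.voxel_volume_mm3
    grids = _mm_grids(shape, voxel)

    brain = _ellipsoid(grids, (0.0, 0.0, 0.0), spec.brain_semiaxes_mm)
    labels = np.zeros(shape, dtype=np.uint8)

    # Shells by exact Euclidean depth from the brain surface.
    depth = ndimage.distance_transform_edt(brain, sampling=voxel)
    labels[brain] = WM
    labels[brain & (depth <= spec.subdural_csf_thickness_mm + spec.cortical_gm_thickness_mm)] = GM
    labels[brain & (depth <= spec.subdural_csf_thickness_mm)] = SCSF

    # Mirrored ventricles, required to sit in deep white matter.
    off = np.asarray(spec.ventricle_offset_mm)
    vent_centers = [off * np.array([+1.0, 1.0, 1.0]), off * np.array([-1.0, 1.0, 1.0])]
    seeds = []
    for c in vent_centers:
        vent = _ellipsoid(grids, c, spec.ventricle_semiaxes_mm)
        if not np.all(labels[vent] == WM):
            raise ConfigError("ventricle ellipsoid leaves the deep white matter")
        labels[vent] = VCSF
        sv = tuple(int(round(c[ax] / voxel[ax] + (shape[ax] - 1) / 2.0)) for ax in range(3))
        if labels[sv] != VCSF:
            raise ConfigError("ventricle centre voxel is not ventricular CSF")
        seeds.append(sv)

    vcsf = labels == VCSF
    cheb_to_vent = ndimage.distance_transform_cdt(~vcsf, metric="chessboard")

    placed = np.zeros(shape, dtype=bool)
    struct = np.ones((3, 3, 3), dtype=bool)
    lesion_masks: list[np.ndarray] = []

    def _free_wm():
        # keep implanted components 26-disconnected from each other
        buffer = ndimage.binary_dilation(placed, structure=struct, iterations=2)
        return (labels == WM) & ~buffer

    for i, (cc, direction) in enumerate(spec.pv_lesion_spec):
        c = vent_centers[i % 2]
        d = np.asarray(direction, dtype=float)
        if not np.any(d):
            raise PlacementError(f"pv lesion {i}: zero direction")
        # point on the ventricle surface along `direction`, then step outward
        # in half-voxel increments to the first white-matter voxel.
        t = 1.0 / math.sqrt(sum((d[ax] / spec.ventricle_semiaxes_mm[ax]) ** 2 for ax in range(3)))
        step = d / np.linalg.norm(d) * (min(voxel) / 2.0)
        p = c + d * t
        seed_mm = None
        for _ in range(40):
            p = p + step
            iv = tuple(int(round(p[ax] / voxel[ax] + (shape[ax] - 1) / 2.0)) for ax in range(3))
            if any(not (0 <= iv[ax] < shape[ax]) for ax in range(3)):
                break
            if labels[iv] == WM:
                seed_mm = p
                break
        if seed_mm is None:
            raise PlacementError(f"pv lesion {i}: no white matter outward of the ventricle surface")
        k = _voxels_for(cc, voxvol)
        where = _grow_nearest(_free_wm(), seed_mm, voxel, k, f"pv lesion {i}")
        labels[where] = PVSH
        m = np.zeros(shape, dtype=bool)
        m[where] = True
        lesion_masks.append(m)
        placed |= m
        if int(cheb_to_vent[m].min()) > 1:
            raise PlacementError(f"pv lesion {i}: lost contact with the ventricle")

    for j, (cc, centroid) in enumerate(spec.dw_lesion_spec):
        k = _voxels_for(cc, voxvol)
        eligible = _free_wm() & (cheb_to_vent > spec.dw_ventricle_gap_voxels)
        iv = tuple(int(round(centroid[ax] / voxel[ax] + (shape[ax] - 1) / 2.0)) for ax in range(3))
        if any(not (0 <= iv[ax] < shape[ax]) for ax in range(3)) or not eligible[iv]:
            raise PlacementError(
                f"dw lesion {j}: centroid is not in eligible deep white matter")
        where = _grow_nearest(eligible, centroid, voxel, k, f"dw lesion {j}")
        labels[where] = DWSH
        m = np.zeros(shape, dtype=bool)
        m[where] = True
        lesion_masks.append(m)
        placed |= m

    for (parent, cc) in spec.lacune_spec:
        if not (0 <= parent < len(lesion_masks)):
            raise PlacementError(f"lacune parent index {parent} out of range")
        # keep the fluid core 26-disconnected from ventricular CSF so the
        # periventricular ground truth stays unambiguous
        pm = lesion_masks[parent] & (cheb_to_vent >= 2)
        k = _voxels_for(cc, voxvol)
        if k >= int(pm.sum()):
            raise PlacementError(
                f"lacune core ({cc} cc) does not fit strictly inside lesion {parent}")
        com_idx = np.argwhere(pm).mean(axis=0)
        com_mm = [(com_idx[ax] - (shape[ax] - 1) / 2.0) * voxel[ax] for ax in range(3)]
        where = _grow_nearest(pm, com_mm, voxel, k, f"lacune in lesion {parent}")
        labels[where] = LACUNE

    counts = np.bincount(labels.ravel(), minlength=8)
    true_volumes = {CLASS_NAMES[c]: counts[c] * voxvol / 1000.0 for c in range(8)}

    # Class-conditional intensities plus global additive noise, one RNG
    # stream per modality.
    images = {}
    for mod in MODALITIES:
        mean_lut = np.zeros(8)
        sd_lut = np.zeros(8)
        for code, icls in _LABEL_TO_INTENSITY.items():
            mean_lut[code], sd_lut[code] = spec.intensity_model[mod][icls]
        rng = stream(spec.seed, f"phantom.{mod}")
        img = mean_lut[labels]
        if np.any(sd_lut > 0):
            img = img + sd_lut[labels] * rng.standard_normal(shape)
        if spec.noise_sd > 0:
            img = img + spec.noise_sd * rng.standard_normal(shape)
        images[mod] = img.astype(np.float64)

    volume = MultiModalVolume(images["t1"], images["pd"], images["t2"], voxel)
    truth = GroundTruth(labels, true_volumes, seeds, voxel)
    return volume, truth


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Linear-Gaussian generative model for an AD/NC cohort table.

    ``variables`` holds per-group (mean, sd) for base variables; ``effects``
    is a list of (outcome, predictor, coefficient) edges; each outcome is
    intercept + sum(coef * predictor) + Gaussian noise.  Binary variables
    (e.g. sex) are drawn Bernoulli(mean).
    """

    n_per_group: Mapping[str, int] = field(default_factory=lambda: {"AD": 265, "NC": 100})
    variables: Mapping[str, Mapping[str, tuple[float, float]]] = field(default_factory=dict)
    binary_vars: frozenset[str] = frozenset()
    effects: Sequence[tuple[str, str, float]] = ()
    intercepts: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    noise_sd: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not self.n_per_group or any(n <= 0 for n in self.n_per_group.values()):
            raise ConfigError("subject counts must be positive")
        for var, per_group in self.variables.items():
            for g, (_, sd) in per_group.items():
                if sd < 0:
                    raise ConfigError(f"negative SD for {var}/{g}")
        outcomes = {o for o, _, _ in self.effects} | set(self.noise_sd)
        defined = set(self.variables) | outcomes
        for o, p, _ in self.effects:
            if p not in defined:
                raise ConfigError(f"effect for '{o}' references undefined variable '{p}'")
        for sd in self.noise_sd.values():
            if sd < 0:
                raise ConfigError("outcome noise SDs must be nonnegative")


def _outcome_order(spec: CohortSpec) -> list[str]:
    outcomes = sorted({o for o, _, _ in spec.effects} | set(spec.noise_sd))
    deps = {o: {p for oo, p, _ in spec.effects if oo == o} for o in outcomes}
    order, done = [], set(spec.variables)
    remaining = list(outcomes)
    while remaining:
        progress = False
        for o in list(remaining):
            if deps[o] <= done:
                order.append(o)
                done.add(o)
                remaining.remove(o)
                progress = True
        if not progress:
            raise ConfigError(f"cyclic effect structure among {remaining}")
    return order


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per subject; reproducible under ``spec.seed``."""
    spec.validate()
    rng = stream(spec.seed, "cohort")
    frames = []
    for group in spec.n_per_group:
        n = int(spec.n_per_group[group])
        cols: dict[str, np.ndarray] = {}
        for var in spec.variables:
            mean, sd = spec.variables[var].get(group, (0.0, 0.0))
            if var in spec.binary_vars:
                cols[var] = (rng.random(n) < mean).astype(float)
            else:
                cols[var] = mean + sd * rng.standard_normal(n)
        for out in _outcome_order(spec):
            y = np.full(n, float(spec.intercepts.get(out, {}).get(group, 0.0)))
            for o, p, coef in spec.effects:
                if o == out:
                    y = y + coef * cols[p]
            sd = float(spec.noise_sd.get(out, 0.0))
            if sd > 0:
                y = y + sd * rng.standard_normal(n)
            cols[out] = y
        df = pd.DataFrame(cols)
        df.insert(0, "group", group)
        df.insert(0, "subject_id", [f"{group}{i + 1:04d}" for i in range(n)])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def demographics_cohort_spec(seed: int = 0) -> CohortSpec:
    """AD/NC demographics with the study's group means and spreads.

    Age 72.8 (9.0) vs 69.5 (8.0) years, education 13.8 (3.8) vs 15.5 (3.0)
    years, MMSE 23.2 (4.5) vs 29.0 (1.1), 57%/55% female, ST-TIV 1211.8
    (140.1) vs 1227.7 (112.5) cc, at n = 265 AD / 100 NC.
    """
    return CohortSpec(
        n_per_group={"AD": 265, "NC": 100},
        variables={
            "age": {"AD": (72.8, 9.0), "NC": (69.5, 8.0)},
            "education": {"AD": (13.8, 3.8), "NC": (15.5, 3.0)},
            "mmse": {"AD": (23.2, 4.5), "NC": (29.0, 1.1)},
            "sex": {"AD": (0.57, 0.0), "NC": (0.55, 0.0)},
            "st_tiv": {"AD": (1211.8, 140.1), "NC": (1227.7, 112.5)},
        },
        binary_vars=frozenset({"sex"}),
        seed=seed,
    )


def standardized_effects_spec(outcome: str, betas: Mapping[str, float],
                              n: int = 265, group: str = "AD",
                              seed: int = 0) -> CohortSpec:
    """Z-scale cohort: predictors are N(0,1) and the outcome has unit
    variance, so the planted coefficients are standardized betas."""
    resid = 1.0 - sum(b * b for b in betas.values())
    if resid <= 0:
        raise ConfigError("planted standardized betas imply negative residual variance")
    return CohortSpec(
        n_per_group={group: n},
        variables={p: {group: (0.0, 1.0)} for p in betas},
        effects=[(outcome, p, b) for p, b in betas.items()],
        noise_sd={outcome: math.sqrt(resid)},
        seed=seed,
    )


def voi_cohort_spec(lobes: Mapping[str, Sequence[str]],
                    planted: Mapping[str, float],
                    outcome: str = "cognition",
                    within_lobe_corr: float = 0.5,
                    covariate_betas: Mapping[str, float] | None = None,
                    n: int = 250, group: str = "AD", seed: int = 0) -> CohortSpec:
    """Cohort of per-region lesion z-scores with a shared lobe factor.

    Regions of a lobe share a latent factor with loading sqrt(rho), giving
    pairwise within-lobe correlation ``within_lobe_corr`` — neighbouring
    regions of real lesion maps are strongly correlated, and the lobar
    screening stage relies on that.  ``planted`` maps region names to
    standardized effects on the outcome.
    """
    rho = float(within_lobe_corr)
    variables: dict = {}
    effects: list[tuple[str, str, float]] = []
    noise: dict[str, float] = {}
    for lobe, regions in lobes.items():
        factor = f"_factor_{lobe}"
        variables[factor] = {group: (0.0, 1.0)}
        for r in regions:
            effects.append((r, factor, math.sqrt(rho)))
            noise[r] = math.sqrt(1.0 - rho)
    covariate_betas = dict(covariate_betas or {})
    for c in covariate_betas:
        variables[c] = {group: (0.0, 1.0)}
    total = sum(b * b for b in list(planted.values()) + list(covariate_betas.values()))
    if total >= 1.0:
        raise ConfigError("planted effects imply negative residual variance")
    for r, b in planted.items():
        effects.append((outcome, r, b))
    for c, b in covariate_betas.items():
        effects.append((outcome, c, b))
    noise[outcome] = math.sqrt(1.0 - total)
    return CohortSpec(n_per_group={group: n}, variables=variables,
                      effects=effects, noise_sd=noise, seed=seed)
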