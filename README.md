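# lesionvol

Volumetric analysis of subcortical hyperintensities (SH) — the bright
white-matter lesions seen on proton-density/T2 MRI in aging and dementia —
implemented as a tested, desk-scale Python pipeline.  The package covers the
whole chain a small-vessel-disease imaging study needs:

1. **Brain extraction** — supratentorial intracranial mask and total
   intracranial volume (ST-TIV) by threshold + morphology on T1.
2. **Tissue segmentation** — CSF / grey matter / white matter from T1 by
   localized four-Gaussian mixture (EM) fitting, with ventricular vs sulcal
   CSF separated by 26-connected flood fill from ventricle seeds.
3. **Lesion segmentation** — SH detected jointly on PD and T2 as voxels more
   than *z* SDs above the fitted WM mean on both modalities; components
   split into periventricular (pvSH) versus deep-white (dwSH) by 3D
   connectivity to ventricular CSF; cystic **lacunes** extracted as
   CSF-intensity voxels on T1 inside SH.
4. **Parcellation** — a plane-based 26-region volume-of-interest (VOI)
   atlas (left/right × lateral/medial frontal, temporal, parietal,
   occipital subdivisions) so every volume can be regionalized.
5. **Volumetrics** — raw cc per class per VOI, brain parenchymal fraction
   `BPF = 100·(GM+WM)/ST-TIV`, ventricular atrophy `vCSF/ST-TIV`,
   head-size-normalized values and z-scores (log-transformed when skewed).
6. **Statistics** — cognitive composite z-scores against a normal-control
   reference, ANCOVA group contrasts, pooled-SD Cohen's
   `d = (m₁−m₂)/s_p` with `s_p = √(((n₁−1)s₁²+(n₂−1)s₂²)/(n₁+n₂−2))`,
   OLS with backwards elimination of non-significant predictors, and
   two-stage lobar-then-subregion VOI screening.

Because no subject-level data can ship with a method package, everything is
exercised on **synthetic brain phantoms** (nested-ellipsoid anatomy with
implanted lesions and exact voxel-level ground truth) and **synthetic
cohorts** (linear-Gaussian generative models with planted coefficients).
The generators are first-class, tested modules: every downstream stage is
validated against analytic volumes, implanted label maps, brute-force
oracles, or known generative parameters.

## Worked example

```python
from lesionvol import default_phantom_spec, run_phantom_pipeline, cohens_d_pooled

res = run_phantom_pipeline(default_phantom_spec(noise_frac=0.1, seed=42, small=True))
p = res.profile
print(f"ST-TIV {p.st_tiv_cc:.1f} cc | BPF {p.bpf_percent:.1f}% | vCSF/ST-TIV {p.vcsf_ratio:.4f}")
print(f"SH load {p.sh_total_cc:.2f} cc (pvSH {p.class_total_cc('pvSH'):.2f}, "
      f"dwSH {p.class_total_cc('dwSH'):.2f}, lacune {p.class_total_cc('lacune'):.2f})")
print(res.lesions.components[["id", "class", "voxels", "volume_cc", "parent_id"]]
      .to_string(index=False))

es = cohens_d_pooled(73.1, 4.6, 265, 79.0, 3.7, 100)
print(f"BPF group contrast: |d| = {es.magnitude:.2f} (pooled SD {es.pooled_sd:.2f})")
```

prints

```
ST-TIV 716.9 cc | BPF 80.0% | vCSF/ST-TIV 0.0137
SH load 4.90 cc (pvSH 3.36, dwSH 1.28, lacune 0.26)
 id  class  voxels  volume_cc parent_id
  1   dwSH      75      0.600      <NA>
  2   pvSH     188      1.504      <NA>
  3   pvSH     232      1.856      <NA>
  4   dwSH      85      0.680      <NA>
  5 lacune      18      0.144         3
  6 lacune      15      0.120         4
BPF group contrast: |d| = 1.35 (pooled SD 4.37)
```

The phantom carried two periventricular lesions (1.5 and 2.0 cc requested),
two deep-white lesions (0.8 and 0.6 cc) and two lacune cores; at 10% noise
the pipeline recovers each component, its pv/dw status, and the lacune
cores with their parent linkage.  The effect size reproduces a group BPF
contrast from printed summary statistics alone.

A command-line interface mirrors the stages:

```sh
lesionvol simulate-phantom --out phantom/ --seed 1
lesionvol extract --t1 phantom/t1.nii --out mask.nii
lesionvol parcellate --mask mask.nii --out-regions atlas.nii --out-table atlas.csv
lesionvol pipeline --out study/ --seed 1
```

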