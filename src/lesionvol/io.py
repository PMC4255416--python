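"""NIfTI and config-file helpers."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .errors import ConfigError
from .synthetic_data import CohortSpec, PhantomSpec

__all__ = ["save_volume", "load_volume", "phantom_spec_from_yaml",
           "cohort_spec_from_yaml", "spec_to_yaml"]


def save_volume(array: np.ndarray, voxel_size_mm, path) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), zooms


def _tuplify(value):
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    return value


def phantom_spec_from_yaml(path) -> PhantomSpec:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(PhantomSpec)}
    unknown = set(raw) - fields
    if unknown:
        raise ConfigError(f"unknown phantom spec keys: {sorted(unknown)}")
    return PhantomSpec(**{k: _tuplify(v) for k, v in raw.items()})


def cohort_spec_from_yaml(path) -> CohortSpec:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(CohortSpec)}
    unknown = set(raw) - fields
    if unknown:
        raise ConfigError(f"unknown cohort spec keys: {sorted(unknown)}")
    if "binary_vars" in raw:
        raw["binary_vars"] = frozenset(raw["binary_vars"])
    if "effects" in raw:
        raw["effects"] = [tuple(e) for e in raw["effects"]]
    if "variables" in raw:
        raw["variables"] = {v: {g: tuple(ms) for g, ms in per.items()}
                            for v, per in raw["variables"].items()}
    return CohortSpec(**raw)


def spec_to_yaml(spec, path) -> None:
    d = dataclasses.asdict(spec)
    if "binary_vars" in d:
        d["binary_vars"] = sorted(d["binary_vars"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
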