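"""T1 tissue segmentation by localized four-Gaussian mixture fitting.

The intracranial T1 histogram is modelled with four Gaussian components
fitted by EM, both globally and inside overlapping cubic windows tiling the
mask (local fits absorb slow spatial intensity drift).  Three of the four
components carry the tissue classes CSF / GM / WM; the fourth models the
partial-volume shoulder between the closest pair of components and is folded
into the nearest class.  Per-voxel posteriors from overlapping windows are
blended with trilinear (hat) weights; the voxel takes the maximum-posterior
class.  Ventricular CSF is then separated from sulcal CSF by 26-connected
flood fill from ventricle seed voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import logsumexp

from .errors import InputError, SeedError
from .synthetic_data import GM, SCSF, VCSF, WM

__all__ = [
    "WindowSpec", "GaussianFieldModel", "TissueLabelMap",
    "fit_gmm_1d", "fit_local_gaussians", "classify_tissue", "split_csf",
]

log = logging.getLogger(__name__)

CLASS_ORDER = ("CSF", "GM", "WM")
_CLASS_CODE = {"CSF": SCSF, "GM": GM, "WM": WM}
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class WindowSpec:
    size: int = 32          # cubic window edge, voxels
    stride: int = 16        # 50% overlap
    min_voxels: int = 500   # smaller windows fall back to the global fit

    def validate(self) -> None:
        if self.size < 8:
            raise InputError("window size must be at least 8 voxels per side")
        if not (0 < self.stride <= self.size):
            raise InputError("stride must be in (0, size]")


@dataclass
class GaussianFieldModel:
    """Per-window 4-component Gaussian parameters plus a global fallback."""

    window_spec: WindowSpec
    origin: tuple[int, int, int]            # bbox corner of the window grid
    n_windows: tuple[int, int, int]
    windows: dict                           # (i,j,k) -> (means, sds, weights) or None
    global_params: tuple                    # (means, sds, weights), mean-sorted
    sd_floor: float
    fallback_windows: list = field(default_factory=list)
    grid_shape: tuple[int, int, int] = (0, 0, 0)

    def class_means(self) -> np.ndarray:
        """CSF/GM/WM centroids from the global fit after the partial merge."""
        means, sds, weights = self.global_params
        keep = _drop_partial(means, weights)
        return means[keep]

    def global_class_stats(self) -> dict[str, tuple[float, float]]:
        means, sds, weights = self.global_params
        keep = _drop_partial(means, weights)
        return {cls: (float(means[k]), float(sds[k]))
                for cls, k in zip(CLASS_ORDER, keep)}


def _drop_partial(means: np.ndarray, weights: np.ndarray) -> list[int]:
    """Indices of the three class-bearing components (mean-ascending).

    The partial-volume component is taken as the lighter member of the
    closest pair of component means; dropping it leaves the three most
    separated components to carry CSF, GM and WM.
    """
    order = np.argsort(means)
    gaps = np.diff(means[order])
    p = int(np.argmin(gaps))
    pair = (order[p], order[p + 1])
    partial = pair[0] if weights[pair[0]] <= weights[pair[1]] else pair[1]
    keep = [i for i in order if i != partial]
    return keep


def _em_hist(values: np.ndarray, init_means: np.ndarray, sd_floor: float,
             tol: float, max_iter: int):
    """Weighted EM for a 1-D Gaussian mixture on a 256-bin histogram."""
    k = len(init_means)
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= 0:
        means = np.full(k, lo)
        return means, np.full(k, sd_floor), np.full(k, 1.0 / k)
    counts, edges = np.histogram(values, bins=256, range=(lo, hi))
    x = 0.5 * (edges[:-1] + edges[1:])
    sel = counts > 0
    x, counts = x[sel], counts[sel].astype(float)
    n = counts.sum()

    means = init_means.astype(float).copy()
    sds = np.full(k, max((hi - lo) / (2.0 * k), sd_floor))
    weights = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    for _ in range(max_iter):
        logp = (np.log(weights)[:, None] - np.log(sds)[:, None]
                - 0.5 * ((x[None, :] - means[:, None]) / sds[:, None]) ** 2)
        norm = logsumexp(logp, axis=0)
        resp = np.exp(logp - norm[None, :]) * counts[None, :]
        ll = float(np.sum(norm * counts))
        nk = resp.sum(axis=1)
        safe = nk > 1e-10 * n
        means[safe] = resp[safe] @ x / nk[safe]
        for j in range(k):
            if safe[j]:
                v = float(resp[j] @ (x - means[j]) ** 2 / nk[j])
                sds[j] = max(np.sqrt(v), sd_floor)
        weights = np.maximum(nk / n, 1e-12)
        weights = weights / weights.sum()
        if prev_ll > -np.inf and abs(ll - prev_ll) <= tol * max(abs(prev_ll), 1.0):
            break
        prev_ll = ll
    order = np.argsort(means)
    return means[order], sds[order], weights[order]


def fit_gmm_1d(values: np.ndarray, n_components: int = 4,
               init_means: np.ndarray | None = None,
               sd_floor: float | None = None,
               tol: float = 1e-6, max_iter: int = 200):
    """Fit a 1-D Gaussian mixture; returns mean-sorted (means, sds, weights).

    Initialization is deterministic, from evenly spread sample quantiles
    (5..95%), so repeated fits are identical.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise InputError("cannot fit a mixture to an empty sample")
    if sd_floor is None:
        rng_ = np.ptp(values)
        sd_floor = max(1e-9, 1e-3 * rng_) if rng_ > 0 else 1e-9
    if init_means is None:
        qs = np.linspace(5, 95, n_components)
        init_means = np.percentile(values, qs)
    return _em_hist(values, np.asarray(init_means, float), sd_floor, tol, max_iter)


def _window_grid(mask: np.ndarray, spec: WindowSpec):
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    n = [max(1, -(-(hi[a] - lo[a] - spec.size) // spec.stride) + 1) for a in range(3)]
    return tuple(int(v) for v in lo), tuple(int(v) for v in n)


def fit_local_gaussians(t1: np.ndarray, mask: np.ndarray,
                        window_spec: WindowSpec | None = None,
                        tol: float = 1e-6, max_iter: int = 200) -> GaussianFieldModel:
    """Fit the global 4-component model plus one model per window.

    Windows with fewer in-mask voxels than ``min_voxels`` inherit the global
    fit and are recorded in ``fallback_windows``.
    """
    spec = window_spec or WindowSpec()
    spec.validate()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("empty intracranial mask")
    t1 = np.asarray(t1, dtype=float)
    inside = t1[mask]
    rng_ = np.ptp(inside)
    sd_floor = max(1e-9, 1e-3 * rng_) if rng_ > 0 else 1e-9
    init = np.percentile(inside, [5, 35, 65, 95])
    global_params = _em_hist(inside, init, sd_floor, tol, max_iter)

    origin, n_windows = _window_grid(mask, spec)
    windows: dict = {}
    fallback = []
    for i in range(n_windows[0]):
        for j in range(n_windows[1]):
            for k in range(n_windows[2]):
                start = [origin[a] + (i, j, k)[a] * spec.stride for a in range(3)]
                sl = tuple(slice(max(0, start[a]), min(mask.shape[a], start[a] + spec.size))
                           for a in range(3))
                m = mask[sl]
                vals = t1[sl][m]
                if vals.size < spec.min_voxels:
                    windows[(i, j, k)] = None
                    fallback.append((i, j, k))
                    continue
                windows[(i, j, k)] = _em_hist(vals, init, sd_floor, tol, max_iter)
    if fallback:
        log.info("fit_local_gaussians: %d/%d windows below %d voxels, using global fit",
                 len(fallback), len(windows), spec.min_voxels)
    return GaussianFieldModel(spec, origin, n_windows, windows, global_params,
                              sd_floor, fallback, tuple(t1.shape))


@dataclass
class TissueLabelMap:
    """Per-voxel tissue class {sCSF, vCSF, GM, WM} with class posteriors."""

    labels: np.ndarray               # class codes, 0 outside the mask
    posteriors: np.ndarray           # (3, *grid) in CLASS_ORDER, sum to 1 in-mask
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def class_mask(self, *codes: int) -> np.ndarray:
        return np.isin(self.labels, codes)


def _accumulate_window(post, wsum, t1, mask, params, class_means, sl, center, stride):
    m = mask[sl]
    if not m.any():
        return
    means, sds, weights = params
    x = t1[sl][m]
    logp = (np.log(weights)[:, None] - np.log(sds)[:, None]
            - 0.5 * ((x[None, :] - means[:, None]) / sds[:, None]) ** 2)
    logp -= logp.max(axis=0, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=0, keepdims=True)
    # snap each component to the nearest global class centroid
    assign = np.argmin(np.abs(means[:, None] - class_means[None, :]), axis=1)
    coords = np.argwhere(m)
    w = np.ones(len(coords))
    for a in range(3):
        pos = coords[:, a] + sl[a].start
        w *= np.clip(1.0 - np.abs(pos - center[a]) / stride, 0.0, None)
    if not np.any(w):
        return
    flat = tuple((coords + [s.start for s in sl]).T)
    for c in range(3):
        mass = p[assign == c].sum(axis=0) if np.any(assign == c) else 0.0
        post[(c,) + flat] += w * mass
    wsum[flat] += w


def classify_tissue(model: GaussianFieldModel, t1: np.ndarray,
                    mask: np.ndarray,
                    voxel_size_mm=(1.0, 1.0, 1.0)) -> TissueLabelMap:
    """Blend window posteriors and assign each in-mask voxel its MAP class.

    All CSF is initially labelled sulcal; :func:`split_csf` separates the
    ventricular compartment afterwards.
    """
    mask = np.asarray(mask, dtype=bool)
    t1 = np.asarray(t1, dtype=float)
    if t1.shape != mask.shape:
        raise InputError("T1 grid and mask shapes differ")
    spec = model.window_spec
    class_means = model.class_means()
    post = np.zeros((3,) + t1.shape)
    wsum = np.zeros(t1.shape)
    for (i, j, k), params in model.windows.items():
        if params is None:
            params = model.global_params
        start = [model.origin[a] + (i, j, k)[a] * spec.stride for a in range(3)]
        center = [start[a] + (spec.size - 1) / 2.0 for a in range(3)]
        sl = tuple(slice(max(0, start[a]), min(t1.shape[a], start[a] + spec.size))
                   for a in range(3))
        _accumulate_window(post, wsum, t1, mask, params, class_means, sl,
                           center, spec.stride)

    # voxels missed by every window support use the global fallback directly
    orphan = mask & (wsum <= 0)
    if orphan.any():
        means, sds, weights = model.global_params
        x = t1[orphan]
        logp = (np.log(weights)[:, None] - np.log(sds)[:, None]
                - 0.5 * ((x[None, :] - means[:, None]) / sds[:, None]) ** 2)
        logp -= logp.max(axis=0, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=0, keepdims=True)
        assign = np.argmin(np.abs(means[:, None] - class_means[None, :]), axis=1)
        for c in range(3):
            post[(c,) + np.nonzero(orphan)] = p[assign == c].sum(axis=0)
        wsum[orphan] = 1.0

    with np.errstate(invalid="ignore"):
        post = np.where(wsum[None] > 0, post / np.maximum(wsum[None], 1e-300), 0.0)
    total = post.sum(axis=0)
    inmask = mask & (total > 0)
    post[:, inmask] /= total[inmask]

    labels = np.zeros(t1.shape, dtype=np.uint8)
    best = np.argmax(post, axis=0)
    for c, cls in enumerate(CLASS_ORDER):
        labels[mask & (best == c)] = _CLASS_CODE[cls]
    return TissueLabelMap(labels, post, mask, tuple(voxel_size_mm))


def split_csf(tissue: TissueLabelMap,
              ventricle_seed_voxels) -> TissueLabelMap:
    """Relabel as vCSF every 26-connected CSF component containing a seed."""
    labels = tissue.labels.copy()
    csf = np.isin(labels, (SCSF, VCSF))
    labels[csf] = SCSF
    seeds = [tuple(int(v) for v in s) for s in (ventricle_seed_voxels or [])]
    if not seeds:
        log.warning("split_csf: no ventricle seeds supplied; all CSF labelled sulcal")
        return TissueLabelMap(labels, tissue.posteriors, tissue.mask, tissue.voxel_size_mm)
    cc, _ = ndimage.label(csf, structure=_STRUCT26)
    vent_ids = set()
    for s in seeds:
        if not csf[s]:
            raise SeedError(f"ventricle seed {s} does not lie in CSF")
        vent_ids.add(int(cc[s]))
    labels[np.isin(cc, sorted(vent_ids))] = VCSF
    return TissueLabelMap(labels, tissue.posteriors, tissue.mask, tissue.voxel_size_mm)
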