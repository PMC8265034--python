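"""Seeded digital brain phantoms with MS-like white-matter lesions.

The phantom stands in for patient data: it supplies every ground-truth map
the pipeline trains on and evaluates against — quantitative T1/T2* maps, M0,
a smooth B1+ transmit-field scale, soft tissue-probability maps for
normal-appearing white matter (NAWM), gray matter (GM) and CSF, and a binary
lesion mask.

Geometry is a concentric-ellipsoid brain: an ellipsoidal brain envelope whose
outer morphological shell is the GM ribbon, an interior WM compartment, and
central ellipsoidal CSF ventricles.  Focal lesions are smooth ellipsoidal
blobs placed inside deep WM with T1 and T2* elevated by a random factor, so
lesions are always hyperintense relative to NAWM in both relaxation times.
Soft probability maps are produced by Gaussian-blurring the hard labels and
renormalizing inside the brain, emulating the 0-100% soft output of a tissue
segmenter and providing partial-volume boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dictionary import T1_RANGE_MS, T2S_RANGE_MS

__all__ = [
    "PhantomConfig",
    "PhantomVolume",
    "generate_phantom",
    "perturb_lesion_mask",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Tissue values, geometry and lesion statistics of the digital phantom.

    Default tissue relaxation times are typical 3 T literature values, all
    inside the dictionary ranges (T1 300-3500 ms, T2* 10-2500 ms).  Lesions
    elevate NAWM T1 and T2* by a factor drawn uniformly from
    ``lesion_elevation`` (10-60%).
    """

    shape: tuple[int, int, int] = (240, 240, 40)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 2.0)
    # (T1 ms, T2* ms, M0 a.u.) per tissue class
    nawm: tuple[float, float, float] = (850.0, 50.0, 0.75)
    gm: tuple[float, float, float] = (1400.0, 55.0, 0.85)
    csf: tuple[float, float, float] = (3300.0, 1500.0, 1.0)
    n_lesions: int | None = None  # None -> Poisson draw with mean lesion_rate
    lesion_rate: float = 8.0
    lesion_radius_vox: tuple[float, float] = (2.0, 10.0)  # in-plane, voxels
    lesion_elevation: tuple[float, float] = (0.10, 0.60)  # fractional T1/T2* increase
    prob_blur_sigma_vox: float = 1.0
    b1_amplitude: float = 0.25  # peak deviation of the smooth B1+ field from 1
    gm_shell_vox: int = 3  # thickness of the cortical ribbon, in-plane voxels

    def validate(self) -> None:
        for name, (t1, t2s, m0) in (("nawm", self.nawm), ("gm", self.gm), ("csf", self.csf)):
            if not (T1_RANGE_MS[0] <= t1 <= T1_RANGE_MS[1]):
                raise ValueError(f"{name} T1 {t1} ms outside dictionary range {T1_RANGE_MS}")
            if not (T2S_RANGE_MS[0] <= t2s <= T2S_RANGE_MS[1]):
                raise ValueError(f"{name} T2* {t2s} ms outside dictionary range {T2S_RANGE_MS}")
            if m0 < 0:
                raise ValueError(f"{name} M0 must be non-negative")
        if self.n_lesions is not None and self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if not 0 < self.lesion_radius_vox[0] <= self.lesion_radius_vox[1]:
            raise ValueError("lesion radii must satisfy 0 < min <= max")
        if self.lesion_elevation[0] < 0:
            raise ValueError("lesion elevation must be non-negative")
        hi = 1.0 + self.lesion_elevation[1]
        if self.nawm[0] * hi > T1_RANGE_MS[1] or self.nawm[1] * hi > T2S_RANGE_MS[1]:
            raise ValueError("maximum lesion elevation pushes NAWM outside dictionary range")


@dataclass
class PhantomVolume:
    """Voxelized ground truth for one synthetic subject."""

    t1_map: np.ndarray  # ms
    t2s_map: np.ndarray  # ms
    m0_map: np.ndarray  # a.u. >= 0; 0 outside the head
    b1_map: np.ndarray  # dimensionless flip-angle scale
    prob_nawm: np.ndarray
    prob_gm: np.ndarray
    prob_csf: np.ndarray
    lesion_mask: np.ndarray  # bool
    brain_mask: np.ndarray  # bool
    voxel_size: tuple[float, float, float]
    seed: int
    config: PhantomConfig

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1_map.shape


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return r2 <= 1.0


def _smooth_blob(shape, center, semiaxes) -> np.ndarray:
    """Soft ellipsoidal bump: plateau core, cosine roll-off rim.

    The weight is 1 for normalized radius r <= 0.75, rolls off through 0.5 at
    r = 1 (so the half-height core has the drawn radius) and reaches 0 at
    r = 1.25.
    """
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r = np.sqrt(sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes)))
    t = np.clip((r - 0.75) / 0.5, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def generate_phantom(config: PhantomConfig | None = None, seed: int = 0) -> PhantomVolume:
    """Generate one seeded phantom.

    The lesion count is the configured value, or a Poisson draw with mean
    ``config.lesion_rate`` when ``config.n_lesions`` is ``None``; a count of
    zero yields a healthy phantom.  Identical (config, seed) gives a
    bit-identical volume.
    """
    config = config or PhantomConfig()
    config.validate()
    # independent seeded streams so e.g. changing the lesion count leaves the
    # B1+ field (and everything else) untouched
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    rng_b1 = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    nx, ny, nz = config.shape
    aspect = config.voxel_size[2] / config.voxel_size[0]  # z voxels are thicker

    center = ((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2)
    brain_ax = (0.42 * nx, 0.46 * ny, max(0.42 * nz, 1.0))
    brain = _ellipsoid(config.shape, center, brain_ax)

    shell = config.gm_shell_vox
    # in-plane erosion only: slices are thick, the ribbon is an in-plane shell
    struct = ndimage.generate_binary_structure(3, 1).copy()
    struct[:, :, 0] = struct[:, :, 2] = False
    interior = ndimage.binary_erosion(brain, structure=struct, iterations=shell)
    gm = brain & ~interior

    vent_ax = (0.10 * nx, 0.16 * ny, max(0.18 * nz, 0.8))
    csf = _ellipsoid(config.shape, center, vent_ax) & interior
    wm = interior & ~csf

    # lesions live in deep WM: away from both the GM ribbon and the ventricles
    deep_wm = ndimage.binary_erosion(wm, structure=struct, iterations=2)
    n_lesions = (
        int(config.n_lesions)
        if config.n_lesions is not None
        else int(rng.poisson(config.lesion_rate))
    )
    lesion_weight = np.zeros(config.shape)
    lesion_mask = np.zeros(config.shape, dtype=bool)
    placed_lesions: list[tuple[np.ndarray, float]] = []
    candidates = np.argwhere(deep_wm)
    attempts = 0
    placed = 0
    while placed < n_lesions and attempts < 200 * max(n_lesions, 1):
        attempts += 1
        c = candidates[rng.integers(len(candidates))]
        r = rng.uniform(*config.lesion_radius_vox)
        rz = max(r / aspect, 0.6)
        # keep blobs apart so lesion components stay countable
        if any(
            np.linalg.norm((c - p) * (1, 1, aspect)) < 1.4 * (r + rp)
            for p, rp in placed_lesions
        ):
            continue
        blob = _smooth_blob(config.shape, c, (r, r, rz))
        core = (blob > 0.5) & wm
        if core.sum() == 0 or (blob > 0.5).sum() != core.sum() or np.any((blob > 0) & csf):
            continue  # lesion must stay inside WM and clear of CSF
        lesion_weight = np.maximum(lesion_weight, np.where(wm, blob, 0.0))
        lesion_mask |= core
        placed_lesions.append((c, r))
        placed += 1
    if placed < n_lesions:
        warnings.warn(
            f"placed only {placed}/{n_lesions} lesions before exhausting attempts",
            stacklevel=2,
        )

    # soft probability maps: blur hard labels, renormalize inside the brain
    sigma = (config.prob_blur_sigma_vox,) * 2 + (config.prob_blur_sigma_vox / aspect,)
    probs = []
    for hard in (wm, gm, csf):
        probs.append(ndimage.gaussian_filter(hard.astype(np.float64), sigma))
    total = probs[0] + probs[1] + probs[2]
    p_wm = np.where(brain, probs[0] / np.where(total > 0, total, 1.0), 0.0)
    p_gm = np.where(brain, probs[1] / np.where(total > 0, total, 1.0), 0.0)
    p_csf = np.where(brain, probs[2] / np.where(total > 0, total, 1.0), 0.0)

    # quantitative maps: partial-volume mixture in relaxation-rate space
    # (rates add across compartments; a linear T mixture would let a thin
    # CSF partial-volume rim dominate the white-matter T2* distribution)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = p_wm / config.nawm[0] + p_gm / config.gm[0] + p_csf / config.csf[0]
        r2 = p_wm / config.nawm[1] + p_gm / config.gm[1] + p_csf / config.csf[1]
        t1 = np.where(r1 > 0, 1.0 / np.where(r1 > 0, r1, 1.0), 0.0)
        t2s = np.where(r2 > 0, 1.0 / np.where(r2 > 0, r2, 1.0), 0.0)
    m0 = p_wm * config.nawm[2] + p_gm * config.gm[2] + p_csf * config.csf[2]

    # lesion elevation: multiplicative bump with a smooth (partial-volume) edge
    if placed:
        lab, nlab = ndimage.label(lesion_mask, structure=np.ones((3, 3, 3)))
        elev = np.zeros(config.shape)
        factors = rng.uniform(*config.lesion_elevation, size=nlab)
        # reuse the continuous weight for the edge profile of every component
        for i in range(1, nlab + 1):
            comp = lab == i
            w = np.where(comp, 1.0, 0.0)
            w = np.maximum(w, np.where(ndimage.binary_dilation(comp) , lesion_weight, 0.0))
            elev = np.maximum(elev, factors[i - 1] * w)
        t1 = t1 * (1.0 + elev)
        t2s = t2s * (1.0 + elev)

    inside = brain
    t1 = np.where(inside, np.clip(t1, *T1_RANGE_MS), 0.0)
    t2s = np.where(inside, np.clip(t2s, *T2S_RANGE_MS), 0.0)
    m0 = np.where(inside, m0, 0.0)

    # smooth low-order polynomial B1+ field, clipped to the dictionary's range
    gx = (np.arange(nx) - center[0]) / (nx / 2)
    gy = (np.arange(ny) - center[1]) / (ny / 2)
    gz = (np.arange(nz) - center[2]) / max(nz / 2, 1)
    coef = rng_b1.uniform(-1, 1, size=6)
    b1 = (
        1.0
        + config.b1_amplitude
        * (
            coef[0] * gx[:, None, None]
            + coef[1] * gy[None, :, None]
            + coef[2] * gz[None, None, :]
            + coef[3] * gx[:, None, None] * gy[None, :, None]
            + coef[4] * (gx[:, None, None] ** 2 - 0.5)
            + coef[5] * (gy[None, :, None] ** 2 - 0.5)
        )
        / 2.0
    )
    b1 = np.clip(b1, 0.6, 1.4) * np.ones(config.shape)

    return PhantomVolume(
        t1_map=t1.astype(np.float32),
        t2s_map=t2s.astype(np.float32),
        m0_map=m0.astype(np.float32),
        b1_map=b1.astype(np.float32),
        prob_nawm=p_wm.astype(np.float32),
        prob_gm=p_gm.astype(np.float32),
        prob_csf=p_csf.astype(np.float32),
        lesion_mask=lesion_mask,
        brain_mask=brain,
        voxel_size=config.voxel_size,
        seed=int(seed),
        config=config,
    )


def perturb_lesion_mask(mask: np.ndarray, seed: int, severity: float) -> np.ndarray:
    """Emulate a second independent manual annotation of a lesion mask.

    The mask boundary is jittered by adding a smooth random field to the
    signed Euclidean distance of the mask and re-thresholding at zero, so the
    expected overlap (dice) with the input decreases monotonically as
    ``severity`` grows; ``severity = 0`` returns the input unchanged.  The
    internal noise scale is calibrated so that ``severity = 1`` on default
    phantom lesions lands near the ~0.68 dice typical of repeated human
    annotations.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    mask = np.asarray(mask, dtype=bool)
    if severity == 0.0:
        return mask.copy()
    if not mask.any():
        warnings.warn("perturb_lesion_mask: empty input mask returned unchanged",
                      stacklevel=2)
        return mask.copy()
    rng = np.random.default_rng(seed)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    signed = inside - outside  # > 0 inside the lesion
    noise = ndimage.gaussian_filter(rng.standard_normal(mask.shape), 1.5)
    noise /= max(noise.std(), 1e-12)
    # calibration constant: boundary displacement in voxels at severity 1,
    # set so severity 1 on default phantom lesions gives dice ~0.68
    out = (signed + 1.26 * severity * noise) > 0
    return out
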