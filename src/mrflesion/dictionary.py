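"""Fingerprint dictionary construction and voxel-wise pattern matching.

The conventional MRF reconstruction: simulate one magnitude fingerprint per
(T1, T2*, B1-scale) grid point, L2-normalize each into a dictionary atom, and
assign every measured voxel the grid parameters of the atom with the highest
normalized inner product.  T1 and T2* grids are geometric with a 5% relative
step (T1 300-3500 ms, T2* 10-2500 ms); the flip-angle scale factor grid is
arithmetic, 0.6-1.4 in steps of 0.1, and corrects transmit-field (B1+)
inhomogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import FingerprintSchedule
from .signal import BaselineStack, simulate_magnitude

__all__ = [
    "ParameterGrid",
    "Dictionary",
    "QuantitativeMaps",
    "build_grid",
    "default_grid",
    "build_dictionary",
    "match_voxel",
    "match_fingerprints",
    "reconstruct_maps",
    "save_dictionary",
    "load_dictionary",
]

T1_RANGE_MS = (300.0, 3500.0)
T2S_RANGE_MS = (10.0, 2500.0)
B1_RANGE = (0.6, 1.4)
B1_STEP = 0.1
REL_STEP = 0.05


def build_grid(vmin: float, vmax: float, rel_step: float = REL_STEP) -> np.ndarray:
    """Geometric parameter grid ``vmin * (1 + rel_step)**k``.

    Consecutive entries differ by exactly ``rel_step`` relative spacing.  The
    sequence is extended until it covers ``vmax``, so the last entry may
    exceed ``vmax`` by less than one step; this guarantees every in-range
    value has a grid neighbour within half a step in log space.
    """
    if vmin <= 0 or vmin >= vmax:
        raise ValueError("require 0 < vmin < vmax")
    if rel_step <= 0:
        raise ValueError("rel_step must be positive")
    n = int(np.ceil(np.log(vmax / vmin) / np.log1p(rel_step))) + 1
    k = np.arange(n)
    grid = vmin * (1.0 + rel_step) ** k
    # ceil round-off: drop a trailing entry if the one before already covers vmax
    while n >= 2 and grid[n - 2] >= vmax:
        n -= 1
    return grid[:n]


@dataclass(frozen=True)
class ParameterGrid:
    """The (T1, T2*, B1-scale) grid the dictionary is simulated on."""

    t1_values: np.ndarray
    t2s_values: np.ndarray
    b1_values: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t1_values", "t2s_values", "b1_values"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if arr.size == 0:
                raise ValueError(f"{name} must be non-empty")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly ascending")
            object.__setattr__(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return self.t1_values.size * self.t2s_values.size * self.b1_values.size


def default_grid(rel_step: float = REL_STEP) -> ParameterGrid:
    """Default grids: 5% geometric T1/T2* steps, B1 0.6-1.4 in steps of 0.1."""
    n_b1 = int(round((B1_RANGE[1] - B1_RANGE[0]) / B1_STEP)) + 1
    return ParameterGrid(
        t1_values=build_grid(*T1_RANGE_MS, rel_step),
        t2s_values=build_grid(*T2S_RANGE_MS, rel_step),
        b1_values=np.round(np.linspace(*B1_RANGE, n_b1), 10),
    )


@dataclass
class Dictionary:
    """Unit-norm simulated fingerprints indexed by (T1, T2*, B1-scale).

    ``atoms`` is (n_atoms, n_frames) with every row L2-normalized; ``index``
    is (n_atoms, 3) holding the (t1, t2s, b1) triple of each atom;
    ``atom_norms`` holds the pre-normalization Euclidean norm of each
    simulated fingerprint (the m0 = 1 signal scale).
    """

    atoms: np.ndarray
    index: np.ndarray
    atom_norms: np.ndarray
    schedule: FingerprintSchedule
    grid: ParameterGrid

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_frames(self) -> int:
        return self.atoms.shape[1]


@dataclass
class QuantitativeMaps:
    """Voxel-wise pattern-matching output: grid-valued parameter maps."""

    t1_ms: np.ndarray
    t2s_ms: np.ndarray
    b1_scale: np.ndarray
    m0: np.ndarray
    correlation: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 2.0)


def build_dictionary(schedule: FingerprintSchedule, grid: ParameterGrid) -> Dictionary:
    """Simulate and normalize one atom per grid point (m0 = 1)."""
    t1g, t2g, b1g = np.meshgrid(
        grid.t1_values, grid.t2s_values, grid.b1_values, indexing="ij"
    )
    t1f, t2f, b1f = t1g.ravel(), t2g.ravel(), b1g.ravel()
    atoms = simulate_magnitude(t1f, t2f, 1.0, b1f, schedule)
    norms = np.linalg.norm(atoms, axis=1)
    bad = norms <= 0
    if np.any(bad):
        j = int(np.argmax(bad))
        raise ValueError(
            "degenerate all-zero fingerprint at "
            f"(t1={t1f[j]:g} ms, t2s={t2f[j]:g} ms, b1={b1f[j]:g})"
        )
    # float64 throughout: adjacent long-TR/short-T1 atoms differ at the 1e-5
    # level, below single-precision inner-product resolution
    atoms = atoms / norms[:, None]
    index = np.column_stack([t1f, t2f, b1f])
    return Dictionary(
        atoms=atoms, index=index, atom_norms=norms, schedule=schedule, grid=grid
    )


def match_fingerprints(fingerprints: np.ndarray, dictionary: Dictionary,
                       chunk: int = 4096) -> QuantitativeMaps:
    """Match a batch of fingerprints (n, n_frames) against the dictionary.

    Returns per-fingerprint grid-valued t1/t2s/b1, the projection coefficient
    m0 = <fingerprint, best atom> and the normalized correlation.  All-zero
    fingerprints are flagged as background (all outputs 0).  The argmax is
    computed chunk-wise purely for memory; results are independent of chunk
    size, and ties break toward the lowest atom index.
    """
    fp = np.atleast_2d(np.asarray(fingerprints, dtype=np.float64))
    if fp.shape[1] != dictionary.n_frames:
        raise ValueError(
            f"fingerprint length {fp.shape[1]} != dictionary frames {dictionary.n_frames}"
        )
    n = fp.shape[0]
    norms = np.linalg.norm(fp, axis=1)
    t1 = np.zeros(n)
    t2s = np.zeros(n)
    b1 = np.zeros(n)
    m0 = np.zeros(n)
    corr = np.zeros(n)
    valid = norms > 0
    atoms_t = dictionary.atoms.T  # (n_frames, n_atoms)
    idx_valid = np.flatnonzero(valid)
    for start in range(0, idx_valid.size, chunk):
        sel = idx_valid[start : start + chunk]
        inner = fp[sel] @ atoms_t  # (chunk, n_atoms)
        best = np.argmax(inner, axis=1)
        picked = inner[np.arange(sel.size), best]
        t1[sel], t2s[sel], b1[sel] = dictionary.index[best].T
        m0[sel] = picked
        corr[sel] = picked / norms[sel]
    np.clip(corr, 0.0, 1.0, out=corr)
    return QuantitativeMaps(t1_ms=t1, t2s_ms=t2s, b1_scale=b1, m0=m0, correlation=corr)


def match_voxel(fingerprint: np.ndarray, dictionary: Dictionary):
    """Match a single fingerprint; returns (t1, t2s, b1, m0, correlation)."""
    fp = np.asarray(fingerprint, dtype=float)
    if fp.ndim != 1:
        raise ValueError("match_voxel expects a 1-D fingerprint")
    res = match_fingerprints(fp[None, :], dictionary)
    return (
        float(res.t1_ms[0]),
        float(res.t2s_ms[0]),
        float(res.b1_scale[0]),
        float(res.m0[0]),
        float(res.correlation[0]),
    )


def reconstruct_maps(
    stack: BaselineStack, dictionary: Dictionary, brain_mask: np.ndarray
) -> QuantitativeMaps:
    """Voxel-wise pattern matching inside a brain mask.

    Outside the mask every output is zero.  Deterministic: the result does
    not depend on voxel traversal order.
    """
    if stack.n_frames != dictionary.n_frames:
        raise ValueError(
            f"stack has {stack.n_frames} frames, dictionary {dictionary.n_frames}"
        )
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != stack.shape:
        raise ValueError("brain_mask shape must match the stack's spatial shape")
    shape = stack.shape
    # float64 so matched grid values are stored exactly
    out = {k: np.zeros(shape, dtype=np.float64) for k in
           ("t1_ms", "t2s_ms", "b1_scale", "m0", "correlation")}
    if np.any(mask):
        res = match_fingerprints(stack.data[mask], dictionary)
        for k in out:
            out[k][mask] = getattr(res, k)
    return QuantitativeMaps(voxel_size=stack.voxel_size, **out)


def save_dictionary(dictionary: Dictionary, path) -> None:
    """Persist a dictionary (atoms + grid + schedule) as a single .npz."""
    np.savez_compressed(
        path,
        atoms=dictionary.atoms,
        index=dictionary.index,
        atom_norms=dictionary.atom_norms,
        t1_values=dictionary.grid.t1_values,
        t2s_values=dictionary.grid.t2s_values,
        b1_values=dictionary.grid.b1_values,
        flip_deg=dictionary.schedule.flip_deg,
        te_ms=dictionary.schedule.te_ms,
        tr_ms=dictionary.schedule.tr_ms,
        ti_ms=dictionary.schedule.ti_ms,
        inversion=np.array(dictionary.schedule.inversion),
    )


def load_dictionary(path) -> Dictionary:
    with np.load(path) as z:
        schedule = FingerprintSchedule(
            flip_deg=z["flip_deg"], te_ms=z["te_ms"], tr_ms=z["tr_ms"],
            ti_ms=z["ti_ms"], inversion=bool(z["inversion"]),
        )
        grid = ParameterGrid(
            t1_values=z["t1_values"], t2s_values=z["t2s_values"], b1_values=z["b1_values"]
        )
        return Dictionary(
            atoms=z["atoms"], index=z["index"], atom_norms=z["atom_norms"],
            schedule=schedule, grid=grid,
        )
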