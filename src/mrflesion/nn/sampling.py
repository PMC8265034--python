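"""Patch sampling and lesion-slice augmentation for patch-wise training.

Training is 2-D and patch-based: every epoch enumerates the axial slices of
all training cases, lists slices whose in-slice lesion volume reaches the
augmentation threshold ``augment_factor`` times (lesions occupy a tiny
fraction of the brain, so qualifying slices are oversampled), and draws
``patches_per_slice`` random patches from every listed slice.  All draws are
seeded; the same seed yields the identical patch coordinate stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TrainingConfig", "TrainingCase", "PatchSampler", "build_training_set"]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of patch-wise U-net training."""

    patches_per_slice: int = 64
    patch_size: int = 64
    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 1e-4
    augment_factor: int = 5
    lesion_volume_min_ul: float = 100.0  # in-slice lesion volume threshold, microliters
    seed: int = 0
    encoder_depth: int = 3
    base_channels: int = 32

    def validate(self) -> None:
        for name in ("patches_per_slice", "patch_size", "batch_size", "epochs",
                     "augment_factor", "encoder_depth", "base_channels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.patch_size % 2**self.encoder_depth:
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by 2^{self.encoder_depth}"
            )


@dataclass
class TrainingCase:
    """One subject: network input, regression targets and the lesion mask.

    ``inputs`` is (nx, ny, nz, n_in) — normalized baseline frames (or the
    two quantitative maps for the reference variant); ``targets`` is
    (nx, ny, nz, n_out) in normalized units; ``lesion_mask`` is boolean
    (nx, ny, nz).
    """

    inputs: np.ndarray
    targets: np.ndarray
    lesion_mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 2.0)

    def __post_init__(self) -> None:
        if self.inputs.shape[:3] != self.targets.shape[:3]:
            raise ValueError("inputs and targets must share the spatial shape")
        if self.lesion_mask.shape != self.inputs.shape[:3]:
            raise ValueError("lesion_mask must match the spatial shape")


class PatchSampler:
    """Seeded slice/patch enumerator over a list of training cases."""

    def __init__(self, cases: list[TrainingCase], config: TrainingConfig):
        config.validate()
        if not cases:
            raise ValueError("no training cases")
        self.cases = cases
        self.config = config
        self.slice_list: list[tuple[int, int]] = []  # (case index, z), augmented
        for ci, case in enumerate(cases):
            nx, ny, nz = case.inputs.shape[:3]
            if nx < config.patch_size or ny < config.patch_size:
                raise ValueError(
                    f"case {ci} in-plane matrix {(nx, ny)} smaller than patch size"
                )
            voxel_ul = float(np.prod(case.voxel_size))  # 1 mm^3 == 1 microliter
            for z in range(nz):
                lesion_ul = case.lesion_mask[:, :, z].sum() * voxel_ul
                repeats = (
                    config.augment_factor
                    if lesion_ul >= config.lesion_volume_min_ul
                    else 1
                )
                self.slice_list += [(ci, z)] * repeats
        if not self.slice_list:
            raise ValueError("training cases contain no slices")

    @property
    def n_slices(self) -> int:
        return len(self.slice_list)

    def patches_per_epoch(self) -> int:
        return self.n_slices * self.config.patches_per_slice

    def epoch_coords(self, epoch: int) -> np.ndarray:
        """Seeded patch coordinates for one epoch: array of (case, z, x0, y0)."""
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.config.seed, spawn_key=(epoch,))
        )
        ps = self.config.patch_size
        coords = []
        for ci, z in self.slice_list:
            nx, ny = self.cases[ci].inputs.shape[:2]
            x0 = rng.integers(0, nx - ps + 1, size=self.config.patches_per_slice)
            y0 = rng.integers(0, ny - ps + 1, size=self.config.patches_per_slice)
            coords.append(
                np.column_stack(
                    [np.full_like(x0, ci), np.full_like(x0, z), x0, y0]
                )
            )
        coords = np.concatenate(coords)
        rng.shuffle(coords, axis=0)
        return coords

    def iter_batches(self, epoch: int):
        """Yield (x, y) float32 NCHW batches for one epoch."""
        ps = self.config.patch_size
        coords = self.epoch_coords(epoch)
        bs = self.config.batch_size
        for start in range(0, len(coords), bs):
            chunk = coords[start : start + bs]
            xs, ys = [], []
            for ci, z, x0, y0 in chunk:
                case = self.cases[ci]
                xs.append(case.inputs[x0 : x0 + ps, y0 : y0 + ps, z, :])
                ys.append(case.targets[x0 : x0 + ps, y0 : y0 + ps, z, :])
            # (b, H, W, C) -> (b, C, H, W)
            x = np.stack(xs).transpose(0, 3, 1, 2).astype(np.float32)
            y = np.stack(ys).transpose(0, 3, 1, 2).astype(np.float32)
            yield x, y


def build_training_set(cases: list[TrainingCase], config: TrainingConfig) -> PatchSampler:
    """Build the seeded slice/patch sampler (see :class:`PatchSampler`)."""
    return PatchSampler(cases, config)
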