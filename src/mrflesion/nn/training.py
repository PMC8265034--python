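"""Training, inference and normalization for the lesion-probability U-net.

Channel conventions (fixed order):

==========  =======================  ===================
channel     meaning                  normalization
==========  =======================  ===================
0           T1 map                   divided by 3500 ms
1           T2* map                  divided by 2500 ms
2           NAWM probability         native [0, 1]
3           GM probability           native [0, 1]
4           lesion probability       native [0, 1]
==========  =======================  ===================

One-output variants use only the lesion channel.  Inputs are scaled by the
per-case mean within-brain signal so every channel is O(1) — required for a
joint unweighted multi-channel loss.  The final activation is linear;
probability channels are clipped to [0, 1] only at evaluation time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .losses import loss_and_grad
from .sampling import PatchSampler, TrainingCase, TrainingConfig
from .unet import UNet2D
from .layers import Adam
from .variants import NetworkVariant, get_variant

__all__ = [
    "OutputMaps",
    "TrainResult",
    "T1_SCALE_MS",
    "T2S_SCALE_MS",
    "CHANNEL_NAMES",
    "normalize_inputs",
    "make_targets",
    "build_unet",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

T1_SCALE_MS = 3500.0
T2S_SCALE_MS = 2500.0
CHANNEL_NAMES = ("t1_norm", "t2s_norm", "prob_nawm", "prob_gm", "prob_lesion")
LESION_THRESHOLD = 0.33
_EMPTY_TOL = 1e-30


@dataclass
class OutputMaps:
    """Network output volume, channel-last, in normalized units."""

    channels: np.ndarray  # (nx, ny, nz, n_out)
    channel_names: tuple[str, ...]
    channel_scales: tuple[float, float] = (T1_SCALE_MS, T2S_SCALE_MS)

    @property
    def lesion_prob(self) -> np.ndarray:
        i = self.channel_names.index("prob_lesion")
        return np.clip(self.channels[..., i], 0.0, 1.0)

    def quantitative(self) -> tuple[np.ndarray, np.ndarray]:
        """Denormalized (T1 ms, T2* ms) maps; only for five-channel outputs."""
        i1 = self.channel_names.index("t1_norm")
        i2 = self.channel_names.index("t2s_norm")
        return (
            self.channels[..., i1] * self.channel_scales[0],
            self.channels[..., i2] * self.channel_scales[1],
        )

    def probability(self, name: str) -> np.ndarray:
        return np.clip(self.channels[..., self.channel_names.index(name)], 0.0, 1.0)


@dataclass
class TrainResult:
    model: UNet2D
    variant: NetworkVariant
    config: TrainingConfig
    history: dict[str, list[float]]
    best_epoch: int
    collapsed: bool  # lesion channel converged to an empty prediction
    collapse_message: str = ""


def normalize_inputs(data: np.ndarray) -> np.ndarray:
    """Scale a (nx, ny, nz, n_frames) stack by its mean within-brain signal."""
    brain = data[..., 0] > 0
    scale = float(data[brain].mean()) if brain.any() else 1.0
    return (data / max(scale, 1e-12)).astype(np.float32)


def make_targets(
    variant: NetworkVariant,
    t1_ms: np.ndarray,
    t2s_ms: np.ndarray,
    prob_nawm: np.ndarray,
    prob_gm: np.ndarray,
    lesion_mask: np.ndarray,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Stack the (normalized) regression targets for a variant.

    Returns (targets (nx, ny, nz, n_out), channel names).  Round-trips with
    :meth:`OutputMaps.quantitative` exactly.
    """
    lesion = lesion_mask.astype(np.float32)
    if variant.n_outputs == 5:
        channels = np.stack(
            [
                t1_ms / T1_SCALE_MS,
                t2s_ms / T2S_SCALE_MS,
                prob_nawm,
                prob_gm,
                lesion,
            ],
            axis=-1,
        ).astype(np.float32)
        return channels, CHANNEL_NAMES
    return lesion[..., None].astype(np.float32), ("prob_lesion",)


def build_unet(variant: NetworkVariant | str, config: TrainingConfig) -> UNet2D:
    """Instantiate the 2-D U-net for a variant (seeded, deterministic)."""
    if isinstance(variant, str):
        variant = get_variant(variant)
    config.validate()
    return UNet2D(
        in_ch=variant.n_inputs,
        out_ch=variant.n_outputs,
        base_channels=config.base_channels,
        depth=config.encoder_depth,
        seed=config.seed,
    )


def _lesion_channel_index(variant: NetworkVariant) -> int:
    return 4 if variant.n_outputs == 5 else 0


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    if not a.any() and not b.any():
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def train(
    variant: NetworkVariant | str,
    sampler: PatchSampler,
    config: TrainingConfig | None = None,
    val_cases: list[TrainingCase] | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Train a variant with Adam on the sampler's seeded patch stream.

    Per epoch the mean training loss is recorded and, when validation cases
    are given, the dice of the lesion channel binarized at the 33% threshold;
    the weights with the best validation dice (falling back to best training
    loss) are restored at the end.  A lesion channel that ends empty while
    the reference masks are not is flagged as a collapse to the all-zero
    local minimum.
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    config = config or sampler.config
    model = build_unet(variant, config)
    opt = Adam(model.params, lr=config.learning_rate)
    history: dict[str, list[float]] = {"loss": [], "val_dice": []}
    best_metric = -np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    lesion_ix = _lesion_channel_index(variant)

    for epoch in range(config.epochs):
        losses = []
        for x, y in sampler.iter_batches(epoch):
            pred = model.forward(x, train=True)
            loss, grad = loss_and_grad(variant.loss, pred, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite {variant.loss} loss at "
                    f"epoch {epoch} (variant {variant.name})"
                )
            model.backward(grad.astype(np.float32))
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))

        if val_cases:
            dices = []
            for case in val_cases:
                out = predict(model, case.inputs, variant)
                pred_mask = out.channels[..., lesion_ix] >= LESION_THRESHOLD
                dices.append(_dice(pred_mask, case.lesion_mask))
            val_dice = float(np.mean(dices))
            history["val_dice"].append(val_dice)
            metric = val_dice
        else:
            metric = -history["loss"][-1]
        if metric > best_metric:
            best_metric = metric
            best_weights = model.get_weights()
            best_epoch = epoch
        if verbose:
            msg = f"epoch {epoch + 1}/{config.epochs} loss {history['loss'][-1]:.5f}"
            if val_cases:
                msg += f" val_dice {history['val_dice'][-1]:.3f}"
            print(msg)

    model.set_weights(best_weights)

    collapsed = False
    message = ""
    check_cases = val_cases or sampler.cases
    any_gt = any(c.lesion_mask.any() for c in check_cases)
    if any_gt:
        empty = True
        for case in check_cases:
            out = predict(model, case.inputs, variant)
            if np.any(out.channels[..., lesion_ix] >= LESION_THRESHOLD):
                empty = False
                break
        if empty:
            collapsed = True
            message = (
                f"{variant.name} converged to empty prediction: all lesion "
                f"probabilities below {LESION_THRESHOLD:.2f} despite non-empty "
                "reference lesion masks"
            )
    return TrainResult(
        model=model,
        variant=variant,
        config=config,
        history=history,
        best_epoch=best_epoch,
        collapsed=collapsed,
        collapse_message=message,
    )


def predict(model: UNet2D, inputs: np.ndarray, variant: NetworkVariant | str) -> OutputMaps:
    """Full-slice inference on a (nx, ny, nz, n_in) volume.

    Slices are reflect-padded to a multiple of 2^depth, pushed through the
    network whole (not patch-wise) and cropped back.  Deterministic given the
    model.
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    if inputs.ndim != 4:
        raise ValueError("inputs must be 4-D (nx, ny, nz, channels)")
    if inputs.shape[-1] != model.in_ch:
        raise ValueError(
            f"input has {inputs.shape[-1]} channels, model expects {model.in_ch}"
        )
    nx, ny, nz, _ = inputs.shape
    mult = 2**model.depth
    px = (-nx) % mult
    py = (-ny) % mult
    out = np.empty((nx, ny, nz, model.out_ch), dtype=np.float32)
    for z in range(nz):
        x = inputs[:, :, z, :].transpose(2, 0, 1)[None]  # (1, C, H, W)
        if px or py:
            x = np.pad(x, ((0, 0), (0, 0), (0, px), (0, py)), mode="reflect")
        y = model.forward(x.astype(np.float32), train=False)
        out[:, :, z, :] = y[0, :, :nx, :ny].transpose(1, 2, 0)
    names = CHANNEL_NAMES if variant.n_outputs == 5 else ("prob_lesion",)
    return OutputMaps(channels=out, channel_names=names)


def save_checkpoint(result: TrainResult, path) -> None:
    """Persist trained weights plus variant/config metadata as one .npz."""
    meta = {
        "variant": result.variant.name,
        "config": result.config.__dict__,
        "best_epoch": result.best_epoch,
        "collapsed": result.collapsed,
        "collapse_message": result.collapse_message,
        "history": result.history,
    }
    arrays = {f"w{i}": w for i, w in enumerate(result.model.get_weights())}
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> TrainResult:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        weights = [z[f"w{i}"] for i in range(len(z.files) - 1)]
    variant = get_variant(meta["variant"])
    config = TrainingConfig(**meta["config"])
    model = build_unet(variant, config)
    model.set_weights(weights)
    return TrainResult(
        model=model,
        variant=variant,
        config=config,
        history=meta["history"],
        best_epoch=meta["best_epoch"],
        collapsed=meta["collapsed"],
        collapse_message=meta["collapse_message"],
    )
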