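"""MRF-EPI acquisition schedules.

An MRF-EPI acquisition acquires a train of spoiled gradient-echo EPI frames
whose flip angle, echo time and repetition time vary from frame to frame, so
that every (T1, T2*, B1+) combination traces out a distinctive magnitude
signal evolution ("fingerprint").  The default schedule spans 35 frames with
flip angles 34-86 degrees, TE 16-76.5 ms and TR 3530-6370 ms.

T1 encoding follows the slice-shuffled inversion-recovery scheme of
IR-prepared multi-slice EPI: every repetition starts with an inversion pulse
and the imaging slice is read out at a different delay ``ti_ms`` inside its
TR, so the frame train samples the inversion-recovery curve at delays
spanning tens of milliseconds to several seconds.  Without this per-frame
delay variation the long repetition times (3.5-6.4 s) would let short-T1
spins relax completely between frames, leaving T1 below ~1 s unidentifiable.

The default frame ordering of the TI delays and the TE values is a fixed,
deliberately de-correlated pair of permutations: it was chosen (once, by a
discrete search minimizing the worst-case alignment between the T2*
signal-derivative direction and the span of the T1 and B1 derivative
directions over the dictionary domain) so that dictionary matching cannot
trade a T2* mismatch against an off-grid T1 or B1 residual.  With smooth
monotone orderings the long-T2* entries of the dictionary are nearly
collinear with T1 perturbations and matching precision degrades severalfold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FingerprintSchedule", "default_schedule", "load_schedule", "save_schedule"]

DEFAULT_N_FRAMES = 35
DEFAULT_FLIP_RANGE = (34.0, 86.0)  # degrees
DEFAULT_TE_RANGE = (16.0, 76.5)  # ms
DEFAULT_TR_RANGE = (3530.0, 6370.0)  # ms

# Frozen frame orderings for the default 35-frame schedule (see module
# docstring).  TE_ORDER[i] is the rank of frame i's TE within the linearly
# spaced TE values; TI_ORDER[i] the rank of its inversion delay within the TR.
DEFAULT_TE_ORDER = (
    10, 8, 3, 12, 17, 15, 11, 13, 33, 29, 25, 9, 30, 2, 27, 7, 19, 34, 16, 4,
    24, 31, 21, 20, 23, 5, 18, 6, 0, 14, 26, 32, 1, 28, 22,
)
DEFAULT_TI_ORDER = (
    0, 30, 9, 22, 31, 4, 25, 12, 33, 20, 7, 29, 15, 2, 21, 10, 17, 18, 5, 26,
    13, 34, 8, 23, 28, 16, 3, 24, 11, 32, 19, 6, 27, 14, 1,
)
DEFAULT_FLIP_CYCLES = 2  # raised-cosine cycles of the flip-angle envelope


@dataclass(frozen=True)
class FingerprintSchedule:
    """Per-frame acquisition parameters of an MRF-EPI train.

    Parameters
    ----------
    flip_deg, te_ms, tr_ms
        Arrays of length ``n_frames`` with the nominal flip angle (degrees),
        echo time (ms) and repetition time (ms) of each frame.
    ti_ms
        Per-frame inversion delay: the time between the inversion pulse that
        opens the frame's repetition and the slice excitation.  Ignored when
        ``inversion`` is False.
    inversion
        Whether every repetition is preceded by a 180 degree inversion pulse.
    """

    flip_deg: np.ndarray
    te_ms: np.ndarray
    tr_ms: np.ndarray
    ti_ms: np.ndarray | None = None
    inversion: bool = True

    def __post_init__(self) -> None:
        for name in ("flip_deg", "te_ms", "tr_ms"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            object.__setattr__(self, name, arr)
        n = self.flip_deg.size
        if self.te_ms.size != n or self.tr_ms.size != n:
            raise ValueError("flip_deg, te_ms and tr_ms must have equal length")
        if n == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(self.flip_deg < 0):
            raise ValueError("flip angles must be non-negative")
        if np.any(self.te_ms <= 0) or np.any(self.tr_ms <= 0):
            raise ValueError("TE and TR must be positive")
        if np.any(self.te_ms >= self.tr_ms):
            raise ValueError("TE must be shorter than TR in every frame")
        if self.ti_ms is None:
            # mid-TR readout when no explicit inversion delays are given
            object.__setattr__(self, "ti_ms", 0.5 * self.tr_ms)
        else:
            ti = np.atleast_1d(np.asarray(self.ti_ms, dtype=float))
            if ti.size != n:
                raise ValueError("ti_ms must have the same length as the other arrays")
            if np.any(ti <= 0) or np.any(ti >= self.tr_ms):
                raise ValueError("inversion delays must satisfy 0 < TI < TR")
            object.__setattr__(self, "ti_ms", ti)

    @property
    def n_frames(self) -> int:
        return int(self.flip_deg.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FingerprintSchedule):
            return NotImplemented
        return (
            self.inversion == other.inversion
            and np.array_equal(self.flip_deg, other.flip_deg)
            and np.array_equal(self.te_ms, other.te_ms)
            and np.array_equal(self.tr_ms, other.tr_ms)
            and np.array_equal(self.ti_ms, other.ti_ms)
        )


def default_schedule(inversion: bool = True) -> FingerprintSchedule:
    """Build the default 35-frame schedule.

    The flip-angle train is a smooth raised-cosine envelope with two cycles,
    rescaled so the printed 34-86 degree endpoints are attained exactly.  TE
    takes the 35 linearly spaced values in 16-76.5 ms and TR the 35 linearly
    spaced values in 3530-6370 ms (TR ascending with frame index); the TE
    values and the inversion delays are assigned to frames in the frozen
    de-correlated orderings described in the module docstring.
    """
    n = DEFAULT_N_FRAMES
    i = np.arange(n, dtype=float)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * DEFAULT_FLIP_CYCLES * i / (n - 1)))
    w /= w.max()
    lo, hi = DEFAULT_FLIP_RANGE
    flip = lo + (hi - lo) * w
    te_values = np.linspace(*DEFAULT_TE_RANGE, n)
    te = te_values[np.asarray(DEFAULT_TE_ORDER)]
    tr = np.linspace(*DEFAULT_TR_RANGE, n)
    ti = (np.asarray(DEFAULT_TI_ORDER) + 0.5) / n * tr
    return FingerprintSchedule(flip_deg=flip, te_ms=te, tr_ms=tr, ti_ms=ti,
                               inversion=inversion)


def load_schedule(path, inversion: bool = True) -> FingerprintSchedule:
    """Read a schedule from a plain-text table.

    The table must have a header with columns ``frame flip_deg te_ms tr_ms``
    and optionally ``ti_ms`` (comma- or whitespace-separated); rows are
    sorted by frame index.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    required = {"frame", "flip_deg", "te_ms", "tr_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"schedule table missing columns: {sorted(missing)}")
    df = df.sort_values("frame")
    return FingerprintSchedule(
        flip_deg=df["flip_deg"].to_numpy(float),
        te_ms=df["te_ms"].to_numpy(float),
        tr_ms=df["tr_ms"].to_numpy(float),
        ti_ms=df["ti_ms"].to_numpy(float) if "ti_ms" in df.columns else None,
        inversion=inversion,
    )


def save_schedule(schedule: FingerprintSchedule, path) -> None:
    """Write a schedule as a plain-text table (see :func:`load_schedule`)."""
    import pandas as pd

    pd.DataFrame(
        {
            "frame": np.arange(schedule.n_frames),
            "flip_deg": schedule.flip_deg,
            "te_ms": schedule.te_ms,
            "tr_ms": schedule.tr_ms,
            "ti_ms": schedule.ti_ms,
        }
    ).to_csv(path, index=False, float_format="%.17g")
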