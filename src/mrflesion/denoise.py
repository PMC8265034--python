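"""Marchenko-Pastur PCA (MPPCA) denoising of multi-frame magnitude stacks.

For every sliding in-plane window the (window-voxels x n_frames) Casorati
matrix is eigen-decomposed and the eigenvalue spectrum split into signal
components and a noise bulk.  The split uses the random-matrix criterion of
Veraart et al.: for a pure-noise matrix with R = min(N, M) retained
dimensions and L = max(N, M) samples the eigenvalues of the scaled Gram
matrix follow the Marchenko-Pastur distribution, whose support width is
4 * sigma^2 * sqrt(gamma) with gamma = (R - p) / L once p signal components
are removed.  The largest p for which the remaining bulk is wider than that
support is taken as the signal rank; the noise variance is the mean of the
bulk eigenvalues.  Noise components are suppressed and the window
reconstruction written back either at the center voxel only or averaged over
all overlapping windows (default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .signal import BaselineStack

__all__ = ["DenoiseResult", "mppca_denoise"]

logger = logging.getLogger(__name__)


@dataclass
class DenoiseResult:
    denoised: BaselineStack
    sigma_map: np.ndarray  # estimated noise standard deviation per voxel
    rank_map: np.ndarray  # retained signal components per voxel
    n_clipped: int  # negative reconstructed values clipped to zero


def _mp_split(eigvals: np.ndarray, n_large: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized signal/noise split of batched eigenvalue spectra.

    ``eigvals``: (nwin, R) ascending eigenvalues of the Gram matrix divided by
    L = max(N, M).  Returns (rank, sigma2) per window: the number of signal
    components and the noise variance estimated from the bulk.
    """
    nwin, R = eigvals.shape
    lam = np.maximum(eigvals[:, ::-1], 0.0)  # descending: lam[:, 0] largest
    # candidate p = number of signal components, 0..R-1
    # tail mean over the (R - p) smallest eigenvalues:
    csum = np.cumsum(lam[:, ::-1], axis=1)[:, ::-1]  # csum[:, p] = sum(lam[:, p:])
    p = np.arange(R)
    tail_mean = csum / (R - p)  # (nwin, R)
    gamma = (R - p) / n_large
    lam_min = lam[:, -1][:, None]
    bulk_width = (lam - lam_min) / (4.0 * np.sqrt(gamma))[None, :]
    # bulk consistent with MP once its width fits inside the MP support;
    # the round-off floor keeps an exactly-zero bulk (noiseless input) from
    # being rejected because its width exceeds its vanishing mean
    tol = 1e-8 * lam[:, :1]
    noise_like = bulk_width <= tail_mean + tol
    rank = np.argmax(noise_like, axis=1)  # first p where the tail is MP-consistent
    all_signal = ~noise_like.any(axis=1)
    rank[all_signal] = R - 1
    sigma2 = tail_mean[np.arange(nwin), rank]
    sigma2[all_signal] = 0.0
    return rank, np.maximum(sigma2, 0.0)


def mppca_denoise(
    stack: BaselineStack, window: int = 5, mode: str = "average"
) -> DenoiseResult:
    """Denoise a 4-D magnitude stack with sliding-window MPPCA.

    Parameters
    ----------
    stack
        Input magnitude stack, shape (nx, ny, nz, n_frames).
    window
        Odd in-plane window extent; the Casorati matrix of each window is
        (window**2, n_frames).  Windows are 2-D because slices are thick
        relative to the in-plane resolution.
    mode
        ``"average"`` reconstructs every voxel as the uniform average of all
        overlapping window reconstructions; ``"center"`` writes back only the
        window's center voxel.
    """
    if window % 2 == 0 or window < 2:
        raise ValueError("window must be odd and >= 3")
    nx, ny, nz, M = stack.data.shape
    if M < 2:
        raise ValueError("need at least 2 frames to denoise")
    if window > nx or window > ny:
        raise ValueError(f"window {window} larger than in-plane matrix ({nx}, {ny})")
    if mode not in ("average", "center"):
        raise ValueError("mode must be 'average' or 'center'")

    N = window * window
    R = min(N, M)
    L = max(N, M)
    half = window // 2

    out = np.zeros((nx, ny, nz, M), dtype=np.float64)
    weight = np.zeros((nx, ny, nz), dtype=np.float64)
    sigma_acc = np.zeros((nx, ny, nz), dtype=np.float64)
    rank_acc = np.zeros((nx, ny, nz), dtype=np.float64)

    for z in range(nz):
        sl = stack.data[:, :, z, :].astype(np.float64)  # (nx, ny, M)
        win = sliding_window_view(sl, (window, window), axis=(0, 1))
        # win: (nx-w+1, ny-w+1, M, window, window)
        wx, wy = win.shape[0], win.shape[1]
        X = win.transpose(0, 1, 3, 4, 2).reshape(wx * wy, N, M)
        if N <= M:
            gram = X @ X.transpose(0, 2, 1)  # (nwin, N, N)
        else:
            gram = X.transpose(0, 2, 1) @ X  # (nwin, M, M)
        vals, vecs = np.linalg.eigh(gram / L)
        rank, sigma2 = _mp_split(vals, L)

        # keep only the top-`rank` eigencomponents of each window
        keep = np.arange(R)[None, :] >= (R - rank)[:, None]  # ascending order
        vk = vecs * keep[:, None, :]
        if N <= M:
            # X ~= P X with P the projector onto the kept left singular space
            rec = vk @ (vk.transpose(0, 2, 1) @ X)
        else:
            rec = (X @ vk) @ vk.transpose(0, 2, 1)
        rec = rec.reshape(wx, wy, window, window, M)

        sig = np.sqrt(sigma2).reshape(wx, wy)
        rk = rank.reshape(wx, wy).astype(np.float64)
        if mode == "center":
            out[half : half + wx, half : half + wy, z, :] = rec[
                :, :, half, half, :
            ]
            weight[half : half + wx, half : half + wy, z] = 1.0
            sigma_acc[half : half + wx, half : half + wy, z] = sig
            rank_acc[half : half + wx, half : half + wy, z] = rk
            # borders fall back to the input
            border = weight[:, :, z] == 0
            out[:, :, z, :][border] = sl[border]
            weight[:, :, z][border] = 1.0
        else:
            for dx in range(window):
                for dy in range(window):
                    out[dx : dx + wx, dy : dy + wy, z, :] += rec[:, :, dx, dy, :]
                    weight[dx : dx + wx, dy : dy + wy, z] += 1.0
            sigma_acc[half : half + wx, half : half + wy, z] = sig
            rank_acc[half : half + wx, half : half + wy, z] = rk
            # fill sigma/rank borders from nearest interior window
            sigma_acc[:, :, z] = _extend_border(sigma_acc[:, :, z], half, wx, wy)
            rank_acc[:, :, z] = _extend_border(rank_acc[:, :, z], half, wx, wy)

    out /= weight[..., None]
    n_clipped = int(np.sum(out < 0))
    if n_clipped:
        logger.info("mppca_denoise: clipped %d negative values to zero", n_clipped)
    np.clip(out, 0.0, None, out=out)
    denoised = BaselineStack(
        data=out.astype(np.float32), voxel_size=stack.voxel_size, schedule=stack.schedule
    )
    return DenoiseResult(
        denoised=denoised,
        sigma_map=sigma_acc.astype(np.float32),
        rank_map=np.rint(rank_acc).astype(np.int32),
        n_clipped=n_clipped,
    )


def _extend_border(plane: np.ndarray, half: int, wx: int, wy: int) -> np.ndarray:
    """Replicate the outermost interior estimates into the window border."""
    interior = plane[half : half + wx, half : half + wy]
    padded = np.pad(interior, ((half, plane.shape[0] - half - wx),
                               (half, plane.shape[1] - half - wy)), mode="edge")
    return padded
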