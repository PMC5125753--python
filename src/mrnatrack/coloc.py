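"""Two-channel colocalisation analysis.

Combines rolling-ball background subtraction, the van Steensel
cross-correlation function (Pearson coefficient of the two channels as
a function of integer pixel displacement along one axis) and Costes
block-randomisation, which estimates significance by scrambling
channel 2 in blocks of roughly the PSF size and recomputing the
zero-shift correlation.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from skimage.restoration import rolling_ball

from .datatypes import CCFResult, ParameterError

__all__ = [
    "rolling_ball_subtract",
    "van_steensel_ccf",
    "costes_randomization",
    "colocalization_analysis",
]


def rolling_ball_subtract(image: np.ndarray, radius_px: int = 8) -> np.ndarray:
    """Subtract a rolling-ball background estimate; clip the result at 0."""
    image = np.asarray(image, dtype=float)
    if radius_px < 1:
        raise ParameterError("radius must be >= 1")
    if radius_px >= min(image.shape):
        raise ParameterError("rolling-ball radius must be smaller than the image")
    background = rolling_ball(image, radius=radius_px)
    return np.clip(image - background, 0.0, None)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def van_steensel_ccf(img1: np.ndarray, img2: np.ndarray, max_shift_px: int = 20,
                     axis: Literal["x", "y"] = "x") -> CCFResult:
    """Pearson correlation versus pixel displacement of channel 2.

    For each shift δ in ``-max_shift_px ... +max_shift_px``, channel 2
    is displaced by δ along ``axis`` and r is computed over the
    overlapping region (no wrap-around).  A zero-variance overlap yields
    a missing (NaN) r at that shift.
    """
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    if img1.shape != img2.shape:
        raise ParameterError("channels must have equal shapes")
    extent = img1.shape[1] if axis == "x" else img1.shape[0]
    if max_shift_px >= extent / 2:
        raise ParameterError("max_shift must be < half the image extent")
    shifts = np.arange(-max_shift_px, max_shift_px + 1)
    rs = np.empty(shifts.size)
    for i, d in enumerate(shifts):
        # shift +d pairs img1[x] with img2[x + d], so a channel-2 copy of
        # channel 1 displaced by +d peaks at +d
        if axis == "x":
            if d >= 0:
                a = img1[:, :img1.shape[1] - d] if d else img1
                b = img2[:, d:]
            else:
                a, b = img1[:, -d:], img2[:, :d]
        else:
            if d >= 0:
                a = img1[:img1.shape[0] - d, :] if d else img1
                b = img2[d:, :]
            else:
                a, b = img1[-d:, :], img2[:d, :]
        rs[i] = _pearson(a, b)
    r_zero = rs[max_shift_px]
    finite = np.where(np.isfinite(rs), rs, -np.inf)
    peak_shift = int(shifts[int(np.argmax(finite))])
    return CCFResult(shifts=shifts, r=rs, r_zero=float(r_zero), peak_shift=peak_shift)


def costes_randomization(img1: np.ndarray, img2: np.ndarray, block_px: int,
                         n_rand: int = 100, seed: int = 0) -> float:
    """Costes block-randomisation p-value for the zero-shift correlation.

    Channel 2 is tiled into ``block_px`` squares which are randomly
    permuted ``n_rand`` times; the p-value is
    ``(1 + #{r_rand >= r_observed}) / (n_rand + 1)``.  ``block_px``
    should be about the PSF FWHM in pixels so that blocks are
    approximately independent.
    """
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    if img1.shape != img2.shape:
        raise ParameterError("channels must have equal shapes")
    if block_px < 1:
        raise ParameterError("block_px must be >= 1")
    if n_rand < 20:
        raise ParameterError("n_rand must be >= 20")
    h, w = img1.shape
    nby, nbx = h // block_px, w // block_px
    if nby < 1 or nbx < 1:
        raise ParameterError("image smaller than one block")
    H, W = nby * block_px, nbx * block_px
    a = img1[:H, :W]
    b = img2[:H, :W]
    r_obs = _pearson(a, b)
    if not np.isfinite(r_obs):
        raise ParameterError("zero-variance channel; correlation undefined")
    # (n_blocks, block, block) view for fast permutation
    blocks = b.reshape(nby, block_px, nbx, block_px).swapaxes(1, 2).reshape(
        nby * nbx, block_px, block_px)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_rand):
        perm = rng.permutation(len(blocks))
        shuffled = blocks[perm].reshape(nby, nbx, block_px, block_px).swapaxes(
            1, 2).reshape(H, W)
        if _pearson(a, shuffled) >= r_obs:
            count += 1
    return (1 + count) / (n_rand + 1)


def colocalization_analysis(img1: np.ndarray, img2: np.ndarray,
                            max_shift_px: int = 20, axis: Literal["x", "y"] = "x",
                            ball_radius_px: Optional[int] = 8,
                            block_px: int = 8, n_rand: int = 100,
                            seed: int = 0) -> CCFResult:
    """Full pipeline: background subtraction, CCF, Costes significance."""
    if ball_radius_px is not None:
        img1 = rolling_ball_subtract(img1, ball_radius_px)
        img2 = rolling_ball_subtract(img2, ball_radius_px)
    result = van_steensel_ccf(img1, img2, max_shift_px, axis)
    result.costes_p = costes_randomization(img1, img2, block_px, n_rand, seed)
    result.n_randomizations = n_rand
    return result
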