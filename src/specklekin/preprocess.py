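"""Separation of a speckle image into envelope and normalized speckle.

A recorded frame ``I`` is modelled as a slowly varying diffuse envelope
``E`` carrying a fine speckle texture: ``I = E * S`` with ``S`` fluctuating
about 1.  ``E`` is obtained by radial low-pass filtering in the Fourier
domain; ``S = I / E`` is the spatially normalized speckle that feeds the
pairwise overlap computation, while ``E`` alone carries the object's
translation and feeds displacement estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import tukey

__all__ = [
    "EnvelopeField",
    "NormalizedSpeckle",
    "separate",
    "speckle_band",
    "speckle_contrast",
]

ENVELOPE_FLOOR = 1e-3  # floor, as a fraction of max(E), that makes I/E safe


@dataclass
class EnvelopeField:
    """Strictly positive low-frequency component E_i of a frame."""

    values: np.ndarray
    cutoff: float  # cycles per image length
    floored: np.ndarray | None = None  # pixels clamped at the floor


@dataclass
class NormalizedSpeckle:
    """Frame divided by its envelope; spatial mean ~ 1 over valid pixels."""

    values: np.ndarray
    mean_value: float
    valid: np.ndarray | None = None  # False where the envelope was floored


def _lowpass_window(
    shape: tuple[int, int], cutoff: float, flat_through_cutoff: bool = False
) -> np.ndarray:
    """Radial raised-cosine low-pass mask; ``cutoff`` in cycles per image.

    Fully open below ``cutoff / 2`` with a cosine roll-off reaching zero at
    ``cutoff``, so the envelope carries no energy above the cutoff.  The
    envelope must stay clear of the speckle band: the speckle pattern does
    not translate with the object (shared sources reproduce identical
    speckle at identical detector positions), so speckle leaking into the
    envelope plants a spurious zero-lag peak in the displacement
    cross-correlations.

    With ``flat_through_cutoff`` the window is instead fully open through
    ``cutoff`` and rolls off to zero at ``1.5 * cutoff``; subtracting that
    low-pass removes *everything* below the cutoff, which is what the
    speckle-band extraction needs (a partially attenuated roll-off band
    would otherwise leak into both components).
    """
    ny, nx = shape
    fy = np.fft.fftfreq(ny) * ny  # cycles per image length
    fx = np.fft.fftfreq(nx) * nx
    r = np.hypot(fy[:, None], fx[None, :])
    roll = 0.5 * cutoff
    lo = cutoff + roll if flat_through_cutoff else cutoff
    win = np.clip((lo - r) / roll, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * win)


def separate(
    image: np.ndarray,
    cutoff: float,
    floor: float = ENVELOPE_FLOOR,
    tukey_alpha: float = 0.2,
) -> tuple[EnvelopeField, NormalizedSpeckle]:
    """Split ``image`` into (envelope, normalized speckle).

    The envelope is the inverse transform of the spectrum masked by a radial
    raised-cosine window at ``cutoff`` (cycles per image length).  A Tukey
    window limits wrap-around leakage; the taper is divided back out via
    normalized convolution, so the envelope is unbiased away from the very
    edge.  The envelope is floored at ``floor * max(E)``; floored pixels are
    flagged and should be excluded from overlap sums.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("separate expects a 2D image")
    if not np.all(np.isfinite(img)) or img.min() < 0:
        raise ValueError("image must be finite and nonnegative")
    if img.max() == 0:
        raise ValueError("degenerate input: all-zero image")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    ny, nx = img.shape
    w = np.outer(tukey(ny, tukey_alpha), tukey(nx, tukey_alpha))
    mask = _lowpass_window(img.shape, cutoff)
    smooth = np.fft.ifft2(mask * np.fft.fft2(img * w)).real
    # clamp the taper correction: at the extreme edge the Tukey window (and
    # hence its low-passed version) approaches zero and the ratio is unstable
    norm = np.fft.ifft2(mask * np.fft.fft2(w)).real
    env = smooth / np.clip(norm, 0.05, None)

    lo = floor * env.max()
    floored = env < lo
    env = np.maximum(env, lo)

    s = img / env
    # the envelope (hence S) is unreliable wherever the analysis window
    # tapers or the floor engaged; both are excluded from overlap sums
    valid = ~floored & (w >= 0.95)
    mean = float(s[valid].mean()) if valid.any() else float(s.mean())
    return (
        EnvelopeField(values=env, cutoff=float(cutoff), floored=floored),
        NormalizedSpeckle(values=s, mean_value=mean, valid=valid),
    )


def speckle_band(
    values: np.ndarray, cutoff: float, valid: np.ndarray | None = None
) -> np.ndarray:
    """Remove everything below the envelope cutoff from a normalized speckle.

    Envelope division is never perfect: where the true envelope curves, a
    smooth residual survives in ``S`` and, because it translates with the
    object, its autocorrelation would ride on the overlap values as a
    bell-shaped background.  The overlap information lives in the speckle
    band above the cutoff, so the residual is filtered out before the
    Hadamard product.

    Pixels flagged invalid (floored envelope, window taper) are replaced by
    the valid-region mean before filtering: their values can be enormous
    (division by a collapsing envelope) and would otherwise ring across the
    whole field through the Fourier filter.
    """
    vals = np.asarray(values, dtype=np.float64)
    if valid is not None:
        fill = vals[valid].mean() if valid.any() else 0.0
        vals = np.where(valid, vals, fill)
    mask = _lowpass_window(vals.shape, cutoff, flat_through_cutoff=True)
    return vals - np.fft.ifft2(mask * np.fft.fft2(vals)).real


def speckle_contrast(speckle: NormalizedSpeckle | np.ndarray, support_mask: np.ndarray) -> float:
    """std/mean of the normalized speckle over ``support_mask``.

    The contrast is the standard diagnostic for how developed the speckle
    is: ~1 for narrowband fully developed speckle, falling as
    ``1/sqrt(n_bands)`` under broadband illumination and further with
    medium thickness.  It bounds the achievable imaging depth.
    """
    vals = speckle.values if isinstance(speckle, NormalizedSpeckle) else np.asarray(speckle)
    mask = np.asarray(support_mask, dtype=bool)
    if mask.shape != vals.shape:
        raise ValueError("support mask shape mismatch")
    n = int(mask.sum())
    if n < 100:
        raise ValueError(f"support mask covers {n} pixels; >= 100 required")
    sel = vals[mask]
    return float(sel.std() / sel.mean())
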