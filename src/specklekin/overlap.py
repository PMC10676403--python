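"""Pairwise measurables: overlap values and relative displacements.

For every pair of frames ``(i, j)`` two numbers are extracted:

* the *overlap value* ``C_ij`` — the sum of the Hadamard product of the two
  normalized speckles.  Because impulse responses of distinct sources are
  (nearly) uncorrelated and each carries unit energy, ``C_ij`` is
  proportional to the number of object points shared by the two motion
  states, i.e. to the object autocorrelation ``O (x) O`` at the frames'
  relative displacement.  In practice the normalized speckles fluctuate
  about 1, so the masked means are subtracted before the product: the
  covariance term is what carries the overlap signal, and the subtraction
  removes the large N-dependent offset of the raw sum.
* the *relative displacement* ``(dy_ij, dx_ij)`` — the argmax of the
  mean-subtracted, zero-padded cross-correlation of the two envelopes,
  which translate rigidly with the object.

Displacements use (row, col) order on the integer lattice throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.fft import fft2, ifft2, next_fast_len

from .preprocess import EnvelopeField, NormalizedSpeckle, separate, speckle_band
from .synthetic import SpeckleStack

__all__ = [
    "OverlapRecord",
    "overlap_value",
    "displacement_estimate",
    "pairwise_overlaps",
    "records_to_table",
]


@dataclass(frozen=True)
class OverlapRecord:
    """One pairwise measurement: C_ij and the displacement of j relative to i."""

    i: int
    j: int
    overlap_value: float
    displacement: tuple[int, int]  # (drow, dcol), integer lattice
    peak_quality: float


def overlap_value(
    s_i: NormalizedSpeckle | np.ndarray,
    s_j: NormalizedSpeckle | np.ndarray,
    valid_mask: np.ndarray,
) -> float:
    """Masked, mean-subtracted Hadamard-product sum of two normalized speckles."""
    a = s_i.values if isinstance(s_i, NormalizedSpeckle) else np.asarray(s_i)
    b = s_j.values if isinstance(s_j, NormalizedSpeckle) else np.asarray(s_j)
    mask = np.asarray(valid_mask, dtype=bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("speckle and mask shapes must match")
    if not mask.any():
        raise ValueError("valid mask is empty")
    av = a[mask]
    bv = b[mask]
    return float(np.dot(av - av.mean(), bv - bv.mean()))


def _xcorr_full(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-padded cross-correlation c(k) = sum_x a(x + k) b(x).

    Returns the correlation on the padded FFT grid together with the grid
    shape; lags are recovered with ``np.fft.fftfreq``-style wrapping.
    """
    ny, nx = a.shape
    py, px = next_fast_len(2 * ny - 1), next_fast_len(2 * nx - 1)
    fa = fft2(a, (py, px))
    fb = fft2(b, (py, px))
    c = ifft2(fa * np.conj(fb)).real
    return c, (py, px)


def _peak_and_quality(
    corr: np.ndarray, pad_shape: tuple[int, int], max_lag: tuple[int, int]
) -> tuple[tuple[int, int], float]:
    """Argmax lag of a padded correlation plus its peak prominence.

    peak_quality = (peak - second_peak) / peak, where the second peak is the
    highest value outside the connected half-maximum region around the main
    peak.  The half-max region (rather than a fixed radius) makes the score
    meaningful for the broad, smooth peaks of envelope correlations.  Ties
    at the maximum break to the smallest row, then smallest column lag.
    """
    py, px = pad_shape
    my, mx = max_lag
    # valid linear-correlation lags live in [-my, my] x [-mx, mx] (wrapped)
    sh = np.roll(corr, (my, mx), axis=(0, 1))[: 2 * my + 1, : 2 * mx + 1]
    # sh[r, c] is lag (r - my, c - mx)
    flat = np.argmax(sh)
    r, c = np.unravel_index(flat, sh.shape)
    peak = sh[r, c]
    if peak <= 0:
        raise ValueError("degenerate correlation surface: non-positive peak")
    region = sh >= 0.5 * peak
    labels, _ = ndimage.label(region)
    main = labels == labels[r, c]
    outside = sh[~main]
    second = outside.max() if outside.size else -np.inf
    quality = float(np.clip((peak - second) / peak, 0.0, 1.0))
    return (int(r - my), int(c - mx)), quality


def displacement_estimate(
    e_i: EnvelopeField | np.ndarray, e_j: EnvelopeField | np.ndarray
) -> tuple[tuple[int, int], float]:
    """Displacement of envelope j relative to envelope i, with peak quality.

    Returns ``d`` such that ``E_j(x) ~ E_i(x - d)`` (the object moved by
    ``+d`` between the two detections), read off as the argmax of the
    mean-subtracted, zero-padded cross-correlation relative to zero lag and
    rounded to the integer lattice.
    """
    a = e_i.values if isinstance(e_i, EnvelopeField) else np.asarray(e_i, float)
    b = e_j.values if isinstance(e_j, EnvelopeField) else np.asarray(e_j, float)
    if a.shape != b.shape:
        raise ValueError("envelope shapes must match")
    a0 = a - a.mean()
    b0 = b - b.mean()
    if a0.std() == 0 or b0.std() == 0:
        raise ValueError("degenerate input: flat envelope (zero variance)")
    corr, pad = _xcorr_full(b0, a0)
    ny, nx = a.shape
    return _peak_and_quality(corr, pad, (ny - 1, nx - 1))


def pairwise_overlaps(
    stack: SpeckleStack,
    cutoff: float,
    max_pairs: int | None = None,
    subsample_seed: int = 0,
) -> list[OverlapRecord]:
    """All-pairs overlap records for a speckle stack (N^2 ordered records).

    Each frame is preprocessed once.  Overlap values use the intersection of
    all frames' envelope-floor masks so every pair is summed over one common
    pixel set; displacements come from envelope cross-correlations.  Both
    orders ``(i, j)`` and ``(j, i)`` are emitted (value symmetric,
    displacement negated) together with the self records ``(i, i)``, so the
    autocorrelation grid is filled symmetrically.  ``max_pairs`` caps the
    number of distinct unordered off-diagonal pairs by seeded subsampling.
    """
    n = len(stack)
    if n < 2:
        raise ValueError("need at least 2 frames")
    envs: list[np.ndarray] = []
    spks: list[np.ndarray] = []
    mask = None
    for idx in range(n):
        try:
            env, spk = separate(stack.frames[idx], cutoff)
        except ValueError as exc:
            raise ValueError(f"frame {idx}: {exc}") from exc
        envs.append(env.values)
        spks.append(speckle_band(spk.values, cutoff, valid=spk.valid))
        mask = spk.valid if mask is None else (mask & spk.valid)
    if not mask.any():
        raise ValueError("no valid pixels after envelope flooring")

    x = np.stack([s[mask] for s in spks])
    x -= x.mean(axis=1, keepdims=True)
    gram = x @ x.T  # overlap values for every ordered pair

    pairs = list(combinations(range(n), 2))
    if max_pairs is not None and max_pairs < len(pairs):
        rng = np.random.default_rng(subsample_seed)
        keep = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in sorted(keep)]

    ny, nx = stack.frames.shape[1:]
    e0 = [e - e.mean() for e in envs]
    for idx, e in enumerate(e0):
        if e.std() == 0:
            raise ValueError(f"frame {idx}: degenerate input, flat envelope")
    py, px = next_fast_len(2 * ny - 1), next_fast_len(2 * nx - 1)
    ffts = [fft2(e, (py, px)) for e in e0]

    records = [
        OverlapRecord(i, i, float(gram[i, i]), (0, 0), 1.0) for i in range(n)
    ]
    for i, j in pairs:
        corr = ifft2(ffts[j] * np.conj(ffts[i])).real
        d, q = _peak_and_quality(corr, (py, px), (ny - 1, nx - 1))
        v = float(gram[i, j])
        records.append(OverlapRecord(i, j, v, d, q))
        records.append(OverlapRecord(j, i, v, (-d[0], -d[1]), q))
    return records


def records_to_table(records: list[OverlapRecord]) -> pd.DataFrame:
    """Flat table (i, j, dy, dx, value, quality) for serialization."""
    return pd.DataFrame(
        {
            "i": [r.i for r in records],
            "j": [r.j for r in records],
            "dy": [r.displacement[0] for r in records],
            "dx": [r.displacement[1] for r in records],
            "value": [r.overlap_value for r in records],
            "quality": [r.peak_quality for r in records],
        }
    )
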