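"""Phase retrieval: invert the autocorrelation into an object image.

By the Wiener–Khinchin theorem the Fourier transform of the (centred)
autocorrelation is the object's power spectrum, so its square root is the
Fourier modulus of the object.  The object is then recovered by Fienup-type
iteration: hybrid input-output (HIO) runs with random phase starts, each
finished with an error-reduction (ER) refinement, under object-domain
constraints of realness, non-negativity and a fixed support box of half the
autocorrelation support per axis.  Translation and 180-degree rotation
twins are inherent to the problem and are treated as equivalent solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft2, ifft2
from skimage.feature import match_template

from .assembly import AutocorrGrid, support_extent

__all__ = [
    "ModulusField",
    "ReconstructionResult",
    "autocorr_to_modulus",
    "support_from_grid",
    "fienup_reconstruct",
    "align_and_score",
]


@dataclass(frozen=True)
class ModulusField:
    """Fourier modulus derived from an autocorrelation grid."""

    values: np.ndarray
    clipped_energy_fraction: float  # spectral energy lost to negativity clipping


@dataclass(frozen=True)
class ReconstructionResult:
    image: np.ndarray  # nonnegative object estimate
    residual: float  # relative Fourier-modulus error of the best run
    restarts_used: int
    seed: int


def autocorr_to_modulus(grid: AutocorrGrid | np.ndarray) -> ModulusField:
    """sqrt of the (clipped) power spectrum of the centred autocorrelation.

    Negative spectral values — measurement noise, since a true power
    spectrum is nonnegative — are clipped to zero and reported as a
    fraction of total spectral energy.
    """
    vals = grid.values if isinstance(grid, AutocorrGrid) else np.asarray(grid, float)
    if not np.any(vals):
        raise ValueError("degenerate input: all-zero autocorrelation grid")
    spectrum = fft2(np.fft.ifftshift(vals)).real
    neg = np.clip(-spectrum, 0.0, None)
    denom = np.abs(spectrum).sum()
    frac = float(neg.sum() / denom) if denom > 0 else 0.0
    return ModulusField(np.sqrt(np.clip(spectrum, 0.0, None)), frac)


def support_from_grid(grid: AutocorrGrid, frac: float = 0.10) -> tuple[int, int]:
    """Support-box size implied by the autocorrelation extent.

    The autocorrelation of an object of extent ``h`` spans ``2h - 1`` lags
    (half-extent ``h - 1``), so a half-extent of ``a`` per axis bounds the
    object by ``a + 1`` cells; one extra cell of slack absorbs the slight
    under-reach of the thresholded extent on noisy grids.
    """
    ay, ax = support_extent(grid.values, frac)
    return (ay + 2, ax + 2)


def _support_mask(shape: tuple[int, int], box: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    ny, nx = shape
    by = min(int(box[0]), ny)
    bx = min(int(box[1]), nx)
    y0 = (ny - by) // 2
    x0 = (nx - bx) // 2
    mask[y0 : y0 + by, x0 : x0 + bx] = True
    return mask


def fienup_reconstruct(
    modulus: ModulusField | np.ndarray,
    support_shape: tuple[int, int],
    n_iter: int = 500,
    beta: float = 0.9,
    restarts: int = 50,
    seed: int = 0,
    er_iters: int = 50,
) -> ReconstructionResult:
    """Best-of-``restarts`` HIO + ER phase retrieval.

    Each restart draws uniform random Fourier phases from a stream derived
    from ``(seed, restart)``, runs ``n_iter`` HIO iterations with feedback
    ``beta`` and an ER tail of ``er_iters``, and is scored by the relative
    Fourier-modulus error; the lowest-residual run wins.  Fully
    deterministic for a fixed seed.
    """
    m = modulus.values if isinstance(modulus, ModulusField) else np.asarray(modulus, float)
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    if n_iter < 1 or restarts < 1:
        raise ValueError("n_iter and restarts must be >= 1")
    mask = _support_mask(m.shape, support_shape)
    m_norm = np.linalg.norm(m)

    best_img = None
    best_res = np.inf
    for k in range(restarts):
        rng = np.random.default_rng([seed, k])
        phase = rng.uniform(0.0, 2.0 * np.pi, m.shape)
        g = ifft2(m * np.exp(1j * phase)).real
        for _ in range(n_iter):
            gp = ifft2(m * np.exp(1j * np.angle(fft2(g)))).real
            bad = (~mask) | (gp < 0)
            g = np.where(bad, g - beta * gp, gp)
        for _ in range(er_iters):
            gp = ifft2(m * np.exp(1j * np.angle(fft2(g)))).real
            g = np.where((~mask) | (gp < 0), 0.0, gp)
        res = float(np.linalg.norm(np.abs(fft2(g)) - m) / m_norm) if m_norm else 0.0
        if res < best_res:
            best_res = res
            best_img = g
    return ReconstructionResult(
        image=np.clip(best_img, 0.0, None),
        residual=best_res,
        restarts_used=restarts,
        seed=seed,
    )


def align_and_score(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Alignment-invariant normalized cross-correlation in [-1, 1].

    The score is the maximum zero-normalized correlation over all integer
    translations of the estimate and of its 180-degree rotation — the two
    ambiguities phase retrieval cannot resolve.
    """
    a = np.asarray(estimate, float)
    b = np.asarray(truth, float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate input: zero-variance field")
    # windowed zero-normalized cross-correlation (classic template matching):
    # at every shift the overlap window is mean-subtracted and normalized,
    # so a pure translate scores exactly 1 while unrelated fields score ~0
    canvas = np.pad(b, ((a.shape[0],) * 2, (a.shape[1],) * 2))
    best = -1.0
    for cand in (a, a[::-1, ::-1]):
        r = match_template(canvas, cand, pad_input=False)
        best = max(best, float(np.nanmax(r)))
    return min(best, 1.0)
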