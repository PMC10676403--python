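"""Forward simulator of incoherent speckle image sequences.

A hidden object of intensity transmittance ``O(x, y)`` sits inside a
scattering medium.  Each point source on the object plane produces a unique
speckle intensity pattern (an impulse response) on the back surface of the
medium, and the recorded image is the *incoherent* superposition of the
impulse responses of all points inside the object, weighted by the
illumination.  Photons that fail to interfere form a slowly varying diffuse
envelope that translates together with the object.

The simulator realizes exactly those assumptions, with no wave-optics
propagation:

* an impulse response is the squared modulus of band-limited complex white
  noise (fully developed speckle whose grain size is set by the band limit),
  plus a Gaussian diffuse halo centred at the source's detector projection;
* every impulse response is normalized to unit total energy — the
  equal-energy assumption that makes the pairwise overlap sum proportional
  to the object autocorrelation;
* broadband illumination is modelled as the mean of ``n_bands`` independent
  speckle realizations per source, which lowers the speckle contrast by
  ``1/sqrt(n_bands)`` without any explicit spectral physics;
* frames are optionally corrupted with additive Gaussian sensor noise and
  quantized to a fixed bit depth, mimicking an 8-bit monochrome camera.

Impulse responses are reproducible from ``(seed, source position, band)``
via independent counter-style random streams, so the full bank never needs
to be materialized eagerly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ObjectMask",
    "IlluminationField",
    "MediumRealization",
    "SpeckleStack",
    "make_medium",
    "impulse_response",
    "render_frame",
    "render_sequence",
    "two_bar_object",
    "point_object",
]

# FWHM of the speckle intensity autocovariance equals
# GRAIN_BAND_FACTOR / (band limit in cycles per pixel); the constant comes
# from the half-max point of the squared jinc (Airy) profile of a disk pupil.
GRAIN_BAND_FACTOR = 0.5144


@dataclass(frozen=True)
class ObjectMask:
    """Nonnegative intensity transmittance O(x, y) on the source lattice."""

    values: np.ndarray
    pixel_pitch: float = 1.0  # physical length per lattice step (um)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("ObjectMask requires a 2D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("ObjectMask values must be finite")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("ObjectMask values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def support(self) -> np.ndarray:
        return self.values > 0


@dataclass(frozen=True)
class IlluminationField:
    """Relative irradiance I_S(x, y): positive, nearly uniform over the object.

    The method assumes the illumination within the small region containing
    the object is close to uniform; ``max_cv`` bounds the allowed
    coefficient of variation when validated against an object support.
    """

    values: np.ndarray
    max_cv: float = 0.05

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or not np.all(np.isfinite(v)) or v.min() <= 0:
            raise ValueError("IlluminationField must be 2D, finite and positive")
        object.__setattr__(self, "values", v)

    def check_uniform(self, support: np.ndarray) -> float:
        """Return the CV over ``support`` and raise if it exceeds ``max_cv``."""
        vals = self.values[support]
        cv = float(vals.std() / vals.mean())
        if cv > self.max_cv:
            raise ValueError(
                f"illumination CV {cv:.3g} over the object support exceeds "
                f"the uniformity bound {self.max_cv:.3g}"
            )
        return cv


@dataclass
class MediumRealization:
    """Seeded, lazily evaluated bank of unit-energy impulse responses."""

    seed: int
    out_shape: tuple[int, int]
    grain_size: float
    halo_sigma: float
    diffuse_fraction: float
    n_bands: int
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def _speckle_part(self, source: tuple[int, int], band: int) -> np.ndarray:
        """Unit-energy fully developed speckle for one (source, band) pair."""
        r, c = source
        rng = np.random.default_rng([self.seed, band, r, c])
        ny, nx = self.out_shape
        z = rng.standard_normal((ny, nx)) + 1j * rng.standard_normal((ny, nx))
        fy = np.fft.fftfreq(ny)[:, None]
        fx = np.fft.fftfreq(nx)[None, :]
        f0 = GRAIN_BAND_FACTOR / self.grain_size  # cycles per pixel
        pupil = (fy * fy + fx * fx) <= f0 * f0
        fld = np.fft.ifft2(np.where(pupil, z, 0))
        inten = np.abs(fld) ** 2
        return inten / inten.sum()

    def _halo_part(self, source: tuple[int, int]) -> np.ndarray:
        r, c = source
        ny, nx = self.out_shape
        yy = (np.arange(ny)[:, None] - r) ** 2
        xx = (np.arange(nx)[None, :] - c) ** 2
        h = np.exp(-(yy + xx) / (2.0 * self.halo_sigma**2))
        return h / h.sum()

    def _check_source(self, source: tuple[int, int]) -> None:
        r, c = source
        ny, nx = self.out_shape
        if not (0 <= r < ny and 0 <= c < nx):
            raise ValueError(f"source {source} outside the {self.out_shape} source grid")

    def band_mean_response(self, source: tuple[int, int]) -> np.ndarray:
        """Mean over bands of the impulse response; cached, float32."""
        key = (int(source[0]), int(source[1]))
        out = self._cache.get(key)
        if out is None:
            self._check_source(key)
            spk = self._speckle_part(key, 0)
            for b in range(1, self.n_bands):
                spk += self._speckle_part(key, b)
            spk /= self.n_bands
            out = (1.0 - self.diffuse_fraction) * spk
            if self.diffuse_fraction > 0:
                out += self.diffuse_fraction * self._halo_part(key)
            out = out.astype(np.float32)
            self._cache[key] = out
        return out


def make_medium(
    seed: int,
    out_shape: tuple[int, int] = (256, 256),
    grain_size: float = 4.0,
    halo_sigma: float = 40.0,
    diffuse_fraction: float = 0.5,
    n_bands: int = 1,
) -> MediumRealization:
    """Create a reproducible scattering-medium realization.

    Parameters
    ----------
    seed
        Base seed; impulse responses derive from ``(seed, source, band)``.
    out_shape
        Detector grid (pixels); the source lattice shares it (unit
        magnification inside the simulator).
    grain_size
        Speckle correlation length in pixels (autocovariance FWHM), >= 2.
    halo_sigma
        Width (pixels) of the per-source diffuse Gaussian envelope.
    diffuse_fraction
        Fraction of each source's unit energy carried by the envelope.
    n_bands
        Number of incoherently summed spectral bands (1 = narrowband).
    """
    ny, nx = out_shape
    if ny <= 0 or nx <= 0:
        raise ValueError("out_shape dimensions must be positive")
    if grain_size < 2:
        raise ValueError("grain_size must be >= 2 pixels")
    if not 0 <= diffuse_fraction < 1:
        raise ValueError("diffuse_fraction must lie in [0, 1)")
    if halo_sigma <= 0:
        raise ValueError("halo_sigma must be positive")
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    return MediumRealization(
        seed=int(seed),
        out_shape=(int(ny), int(nx)),
        grain_size=float(grain_size),
        halo_sigma=float(halo_sigma),
        diffuse_fraction=float(diffuse_fraction),
        n_bands=int(n_bands),
    )


def impulse_response(
    medium: MediumRealization, source: tuple[int, int], band: int = 0
) -> np.ndarray:
    """Unit-energy impulse response s(xi, eta; x, y) for one source and band."""
    medium._check_source((int(source[0]), int(source[1])))
    if not 0 <= band < medium.n_bands:
        raise ValueError(f"band {band} out of range for n_bands={medium.n_bands}")
    spk = medium._speckle_part((int(source[0]), int(source[1])), int(band))
    out = (1.0 - medium.diffuse_fraction) * spk
    if medium.diffuse_fraction > 0:
        out += medium.diffuse_fraction * medium._halo_part(
            (int(source[0]), int(source[1]))
        )
    return out


@dataclass
class SpeckleStack:
    """Ordered speckle frames with optional ground-truth offsets."""

    frames: np.ndarray  # (n, ny, nx)
    bit_depth: int | None = None
    truth_offsets: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("frames must be a (n, ny, nx) array")
        self.frames = f

    def __len__(self) -> int:
        return self.frames.shape[0]


def _object_sources(
    medium: MediumRealization, obj: ObjectMask, offset: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Source-lattice coordinates and weights of the shifted object support."""
    ny, nx = medium.out_shape
    h, w = obj.values.shape
    base = ((ny - h) // 2 + int(offset[0]), (nx - w) // 2 + int(offset[1]))
    rows, cols = np.nonzero(obj.values)
    src_r = rows + base[0]
    src_c = cols + base[1]
    if src_r.size == 0:
        raise ValueError("object mask has empty support")
    if src_r.min() < 0 or src_r.max() >= ny or src_c.min() < 0 or src_c.max() >= nx:
        raise ValueError(
            f"object shifted by {tuple(offset)} leaves the source grid"
        )
    return np.stack([src_r, src_c], axis=1), obj.values[rows, cols]


def _render_raw(
    medium: MediumRealization,
    obj: ObjectMask,
    illum: IlluminationField | None,
    offset: tuple[int, int],
) -> np.ndarray:
    sources, weights = _object_sources(medium, obj, offset)
    if illum is not None:
        if illum.values.shape != medium.out_shape:
            raise ValueError("illumination field must match the source grid shape")
        illum.check_uniform(
            tuple(np.transpose(sources))  # fancy-index the support pixels
        )
        weights = weights * illum.values[sources[:, 0], sources[:, 1]]
    frame = np.zeros(medium.out_shape, dtype=np.float64)
    for (r, c), w in zip(sources, weights):
        frame += w * medium.band_mean_response((int(r), int(c)))
    return frame


def _quantize(
    frame: np.ndarray,
    noise_sigma: float,
    bit_depth: int | None,
    scale: float | None,
    rng: np.random.Generator,
) -> np.ndarray:
    if bit_depth is None:
        out = frame.copy()
        if noise_sigma > 0:
            out += rng.normal(0.0, noise_sigma, size=frame.shape)
        return np.clip(out, 0.0, None)
    top = 2**bit_depth - 1
    if scale is None:
        scale = 0.9 * top / frame.max()
    out = frame * scale
    if noise_sigma > 0:
        out += rng.normal(0.0, noise_sigma, size=frame.shape)
    return np.clip(np.rint(out), 0, top)


def render_frame(
    medium: MediumRealization,
    obj: ObjectMask,
    illum: IlluminationField | None = None,
    offset: tuple[int, int] = (0, 0),
    noise_sigma: float = 0.0,
    bit_depth: int | None = None,
    scale: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one speckle image of the object shifted by ``offset``.

    The frame is the incoherent sum, over every lattice point of the shifted
    object support, of transmittance x illumination x (band-mean impulse
    response), then noise-corrupted, clipped and quantized.  ``bit_depth``
    of ``None`` keeps the frame in floating point (pre-quantization physics);
    ``noise_sigma`` is in counts when quantizing, else in raw frame units.
    """
    if rng is None:
        rng = np.random.default_rng(
            [medium.seed, 7_001, int(offset[0]) % 2**20, int(offset[1]) % 2**20]
        )
    frame = _render_raw(medium, obj, illum, offset)
    return _quantize(frame, noise_sigma, bit_depth, scale, rng)


def render_sequence(
    medium: MediumRealization,
    obj: ObjectMask,
    illum: IlluminationField | None,
    trajectory: Sequence[tuple[int, int]],
    noise_sigma: float = 0.0,
    bit_depth: int | None = None,
) -> SpeckleStack:
    """Render the frame sequence along a trajectory of lattice offsets.

    Frames share one quantization scale (the brightest raw frame maps to
    ~90% of the dynamic range) so pairwise overlap values remain comparable.
    Frame order equals trajectory order; the downstream reconstruction is
    order-invariant.
    """
    trajectory = [
        (int(p[0]), int(p[1])) for p in np.asarray(trajectory).reshape(-1, 2)
    ]
    if len(trajectory) == 0:
        raise ValueError("trajectory must contain at least one position")
    raw = np.stack([_render_raw(medium, obj, illum, off) for off in trajectory])
    scale = None
    if bit_depth is not None:
        scale = 0.9 * (2**bit_depth - 1) / raw.max()
    frames = np.stack(
        [
            _quantize(
                raw[i],
                noise_sigma,
                bit_depth,
                scale,
                np.random.default_rng([medium.seed, 7_002, i]),
            )
            for i in range(len(trajectory))
        ]
    )
    return SpeckleStack(frames=frames, bit_depth=bit_depth, truth_offsets=trajectory)


def two_bar_object(
    bar_width: int = 5,
    gap: int = 5,
    bar_height: int = 20,
    shape: tuple[int, int] = (64, 64),
    pixel_pitch: float = 1.0,
) -> ObjectMask:
    """Binary object of two parallel vertical bars (the standard fixture)."""
    vals = np.zeros(shape)
    h, w = shape
    width = 2 * bar_width + gap
    r0 = (h - bar_height) // 2
    c0 = (w - width) // 2
    vals[r0 : r0 + bar_height, c0 : c0 + bar_width] = 1.0
    vals[r0 : r0 + bar_height, c0 + bar_width + gap : c0 + width] = 1.0
    return ObjectMask(vals, pixel_pitch)


def point_object(shape: tuple[int, int] = (9, 9)) -> ObjectMask:
    """Single-point object (degenerate case: frame = one impulse response)."""
    vals = np.zeros(shape)
    vals[shape[0] // 2, shape[1] // 2] = 1.0
    return ObjectMask(vals)
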