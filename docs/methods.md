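# Methods

`specklekin` implements imaging of an object moving inside a static
scattering medium from a sequence of incoherent speckle images — no memory
effect, no prior knowledge of the medium, no trajectory across a whole
plane.  This note records the model, the algorithmic choices where the
design was genuinely open, and what the synthetic tests do and do not
demonstrate.

## Physical model

An object with intensity transmittance `O(x, y)` is illuminated
incoherently (irradiance `I_S(x, y)`, assumed nearly uniform over the
object).  Each point source behind the medium produces a unique speckle
intensity pattern `s(ξ, η; x, y)` — its impulse response — of unit total
energy (equal-energy assumption), plus a slowly varying diffuse envelope
from photons that did not interfere.  A recorded frame is the incoherent
sum of the impulse responses over the shifted object support.

Two facts carry all the information:

1. **Overlap.**  Impulse responses of distinct sources are uncorrelated, so
   for two frames at relative displacement `Δ` the covariance of their
   spatially normalized speckles is proportional to the number of shared
   sources, i.e. to the object autocorrelation `O⊗O(Δ)`.
2. **Displacement.**  The diffuse envelope translates rigidly with the
   object, so `Δ` is the argmax of the cross-correlation of the two
   envelopes.

Accumulating one overlap value per frame pair at its measured lag samples
`O⊗O` wherever the *trajectory's* autocorrelation is positive; Fienup-type
phase retrieval then inverts `O⊗O` into the object (up to translation and a
180° rotation, which are fundamental ambiguities).

## Forward simulator

* **Impulse response** = |band-limited complex white noise|², the standard
  fully developed speckle model; the disk band limit is set so the
  intensity autocovariance FWHM equals `grain_size` (constant 0.5144 from
  the half-max of the squared-jinc profile).  Responses are reproducible
  from independent streams keyed by `(seed, band, row, col)`, so the bank
  is never materialized eagerly.
* **Envelope** = per-source Gaussian halo centred at the source's detector
  projection (unit magnification), carrying `diffuse_fraction` of the unit
  energy.  Defaults: `diffuse_fraction = 0.5`, `halo_sigma = 10 px` on a
  192×192 detector — wide enough to be "slowly varying" against a 4-px
  grain, narrow enough that no halo mass is truncated at the detector edge
  for the standard trajectory (truncation would distort the envelope
  cross-correlation peaks).
* **Broadband light** = mean of `n_bands` independent speckle realizations
  per source; single-source contrast scales as `1/sqrt(n_bands)` exactly,
  with no spectral physics.
* **Sensor**: optional additive Gaussian noise, then clipping and rounding
  to `bit_depth` with one common scale per sequence placing the brightest
  frame at ~90% of range (8-bit monochrome camera behaviour).  Float frames
  (`bit_depth=None`) expose the pre-quantization physics.

What the simulator does **not** emulate: wave propagation, the memory
effect, genuine spectral dispersion, impulse-response sparsity (speckle
here is spatially stationary across the detector rather than a sparse
bundle of grains), polarization, and medium dynamics.  Consequently the
per-pixel speckle contrast of an object frame is `~1/sqrt(n_sources)`
rather than the higher contrast sparse responses would give; passing tests
demonstrate the algorithm under these statistics, not performance on any
particular tissue.

## Inverse pipeline choices

* **Envelope extraction**: radial raised-cosine low-pass, fully open below
  `cutoff/2` and zero at `cutoff`; default cutoff `4·N/(2π·halo_sigma)`
  cycles per image (four spectral sigmas of the halo).  The envelope must
  stay clear of the speckle band: speckle is detector-locked (shared
  sources reproduce identical grains at identical pixels), so any leak
  plants a spurious zero-lag peak in the displacement cross-correlations.
  A Tukey window (α=0.2) with normalized-convolution correction limits
  wrap-around; pixels where the window tapers (w < 0.95) or where the
  envelope hits its floor (10⁻³ of max) are flagged invalid and excluded
  from overlap sums — division by a collapsing envelope there produces
  ~50× spikes identical across frames.
* **Speckle-band restriction**: before the Hadamard/Gram product the
  normalized speckles are high-passed with the *complement* of a window
  fully open through the cutoff (zero at 1.5×cutoff).  Envelope division is
  never exact; its smooth residual translates with the object and its
  autocorrelation would ride on the overlap values as a bell-shaped
  background (the same kind of term broadband illumination produces).  The
  overlap information lives in the speckle band, so the residual is
  removed there.  Invalid pixels are replaced by the valid-region mean
  first so they cannot ring through the Fourier filter.
* **Overlap value**: masked, mean-subtracted Hadamard-product sum
  (covariance reading): normalized speckles fluctuate about 1 and the raw
  sum would carry a large N-dependent offset.
* **Displacement**: argmax of the zero-padded cross-correlation of
  mean-subtracted envelopes, snapped to the integer lattice (the grid is
  integer-indexed; no subpixel refinement).  Peak quality is
  `(peak − second_peak)/peak` with the second peak taken outside the
  connected half-maximum region of the main peak — envelope correlation
  peaks are broad, so a fixed exclusion radius would misfire.  Records
  below quality 0.05 are dropped.
* **Assembly**: values landing on one lag are *averaged* — per-lag counts
  are trajectory geometry, and summing would imprint the trajectory's
  autocorrelation on the object's.  The grid is then symmetrized
  (count-weighted merge with its mirror; idempotent).  Background
  subtraction runs before gap filling: interpolated corner lags are
  single-record copies that would bias the edge-baseline annulus median.
  `edge_baseline` removes the median of the outermost sampled annulus;
  `bell_fit` fits an even radial polynomial to sampled lags outside the
  estimated autocorrelation support and subtracts its inward
  extrapolation.  Negatives are clipped (a true autocorrelation is
  nonnegative).  Unsampled interior lags are filled by nearest neighbour
  only if they are <5% of the box, else a coverage error is raised.
* **Support extent**: per-axis scan of a 3×3-smoothed grid at 10% of max,
  from the outside in to the first line with ≥2 strong cells.  Connected
  components and marginal profiles both fail structurally here — the
  two-bar autocorrelation is exactly zero along the full column at the bar
  pitch.  Pair families that share frames have correlated overlap noise
  (blocks of zero-overlap lags move together by a few percent of the
  peak), which bounds the precision of any extent estimate; the support
  box therefore gets one extra cell of slack per axis beyond the tight
  `half-extent + 1` bound.  HIO tolerates the slack (≲0.02 NCC per cell).
* **Phase retrieval**: best-of-restarts HIO (β=0.9, 500 iterations, 50
  restarts) each finished by 50 error-reduction iterations, under
  realness, non-negativity and the fixed support box; no shrinkwrap, to
  keep behaviour reproducible.  Phases start uniform-random from streams
  keyed by `(seed, restart)`; the lowest relative Fourier-modulus residual
  wins.
* **Scoring**: windowed zero-normalized cross-correlation (template
  matching) maximized over all integer translations and the 180° rotation;
  a pure translate scores exactly 1, unrelated fields score ≈0.

## Problem sizes

The standard fixture is a 64×64 two-bar object (bars 5 cells wide and 5
apart, 20 tall) moved along a U trajectory of 30 positions per side (90
frames) over a 192×192 detector, narrowband and 8-band broadband.  With
these conditions the assembled grid correlates with the brute-force
autocorrelation at r ≈ 0.98 and end-to-end reconstructions score NCC ≈
0.91–0.96 against truth across seeds.  Unit tests use 64–128 px grids and
short trajectories.

## Resolution rule

The recovered image has one pixel per motion interval, so the resolution
is `R_obj` (the optics/medium limit on the object plane, supplied by the
user) when `R_obj > T_obj`, else the interval `T_obj`.  At the boundary the
rule assigns `T_obj`.  `R_obj`'s dependence on system resolution and medium
thickness is outside this package's scope; it is treated as an input.

## Known limitations

* Displacements are integer-lattice; subpixel motion aliases to the
  nearest cell.
* The overlap SNR per pair scales with the number of independent speckle
  cells in the frame; small detectors make single-count lags noisy and the
  measured autocorrelation support correspondingly fuzzy.
* Objects must translate rigidly; rotation or deformation invalidates the
  overlap reading.
* The trajectory's autocorrelation must cover the object's; otherwise the
  pipeline stops with a coverage error rather than inventing unsampled
  structure.
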