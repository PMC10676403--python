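"""Assembly of pairwise overlap records into the object autocorrelation.

Every reliable record contributes its overlap value at its displacement
lag.  Values landing on the same lag are *averaged*, not summed: each pair
measures (a noisy multiple of) the object autocorrelation at that lag, and
the number of pairs per lag is pure trajectory geometry — summing would
imprint the trajectory's autocorrelation onto the object's.

The assembled grid may ride on a smooth bell-shaped background (broadband
illumination, low speckle contrast); ``subtract_background`` removes it
either as a flat edge baseline or as a fitted radial bell, clipping
negatives since a true autocorrelation is nonnegative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .overlap import OverlapRecord

__all__ = [
    "AutocorrGrid",
    "CoverageError",
    "accumulate",
    "symmetrize",
    "subtract_background",
    "fill_unsampled",
    "strong_support",
    "RELIABILITY_THRESHOLD",
]

RELIABILITY_THRESHOLD = 0.05  # records below this peak quality are dropped


class CoverageError(RuntimeError):
    """The trajectory's autocorrelation does not cover the object's."""


@dataclass(frozen=True)
class AutocorrGrid:
    """Accumulated autocorrelation values per integer lag, zero lag centred."""

    values: np.ndarray  # (2R+1, 2R+1) float
    counts: np.ndarray  # records per lag
    step: float = 1.0  # physical displacement per grid cell (um)

    @property
    def radius(self) -> int:
        return (self.values.shape[0] - 1) // 2

    def lag_index(self, lag: tuple[int, int]) -> tuple[int, int]:
        r = self.radius
        return (lag[0] + r, lag[1] + r)

    @property
    def sampled(self) -> np.ndarray:
        return self.counts > 0


def accumulate(
    records: list[OverlapRecord],
    grid_radius: int,
    reliability_threshold: float = RELIABILITY_THRESHOLD,
    step: float = 1.0,
) -> AutocorrGrid:
    """Mean overlap value per displacement lag over all reliable records."""
    reliable = [r for r in records if r.peak_quality >= reliability_threshold]
    if not reliable:
        raise ValueError("no reliable records to accumulate")
    radius = int(grid_radius)
    worst = max(max(abs(r.displacement[0]), abs(r.displacement[1])) for r in reliable)
    if radius < worst:
        raise ValueError(
            f"grid_radius {radius} smaller than the largest reliable displacement {worst}"
        )
    size = 2 * radius + 1
    total = np.zeros((size, size))
    counts = np.zeros((size, size), dtype=np.int64)
    for rec in reliable:
        iy, ix = rec.displacement[0] + radius, rec.displacement[1] + radius
        total[iy, ix] += rec.overlap_value
        counts[iy, ix] += 1
    values = np.divide(total, counts, out=np.zeros_like(total), where=counts > 0)
    return AutocorrGrid(values=values, counts=counts, step=float(step))


def symmetrize(grid: AutocorrGrid) -> AutocorrGrid:
    """Enforce the centrosymmetry every true autocorrelation has.

    Each lag is merged with its mirror by a count-weighted mean; lags
    sampled on only one side are mirrored across.  Idempotent: a grid that
    is already symmetric is returned unchanged.
    """
    v, c = grid.values, grid.counts
    vm, cm = v[::-1, ::-1], c[::-1, ::-1]
    ctot = c + cm
    merged = np.divide(v * c + vm * cm, ctot, out=np.zeros_like(v), where=ctot > 0)
    new_counts = np.maximum(c, cm)
    return replace(grid, values=merged, counts=new_counts)


def _radii(grid: AutocorrGrid) -> np.ndarray:
    r = grid.radius
    ax = np.arange(-r, r + 1)
    return np.hypot(ax[:, None], ax[None, :])


def subtract_background(grid: AutocorrGrid, method: str = "edge_baseline") -> AutocorrGrid:
    """Remove the smooth background under the assembled autocorrelation.

    ``edge_baseline`` subtracts the median value of the outermost sampled
    annulus (lags at >= 90% of the largest sampled radius), assuming the
    grid extends beyond the object autocorrelation support.  ``bell_fit``
    fits a low-order even radial polynomial to the sampled lags *outside*
    the estimated autocorrelation support — where the overlap term vanishes
    and only the bell remains — and subtracts its inward extrapolation.
    Both clip negatives to zero afterwards.
    """
    sampled = grid.sampled
    if not sampled.any():
        return replace(grid, values=np.zeros_like(grid.values))
    rad = _radii(grid)
    if method == "edge_baseline":
        rmax = rad[sampled].max()
        annulus = sampled & (rad >= 0.9 * rmax)
        if annulus.sum() < 8:
            warnings.warn(
                "sparse outer annulus; using the 10% largest sampled radii",
                stacklevel=2,
            )
            thresh = np.quantile(rad[sampled], 0.9)
            annulus = sampled & (rad >= thresh)
        baseline = np.median(grid.values[annulus])
        new = grid.values - baseline
    elif method == "bell_fit":
        rmax = rad[sampled].max()
        edge = sampled & (rad >= 0.9 * rmax)
        rough = grid.values - (np.median(grid.values[edge]) if edge.any() else 0.0)
        ay, ax = support_extent(rough)
        rr = grid.radius
        yy, xx = np.mgrid[-rr : rr + 1, -rr : rr + 1]
        outside = sampled & ((np.abs(yy) > ay) | (np.abs(xx) > ax))
        if outside.sum() < 6:
            outside = sampled  # degenerate: support fills the grid
        r = rad[outside]
        v = grid.values[outside]
        design = np.stack([np.ones_like(r), r**2, r**4], axis=1)
        coef, *_ = np.linalg.lstsq(design, v, rcond=None)
        full = np.stack([np.ones_like(rad), rad**2, rad**4], axis=2).reshape(-1, 3)
        bell = (full @ coef).reshape(rad.shape)
        new = grid.values - bell
    else:
        raise ValueError("method must be 'edge_baseline' or 'bell_fit'")
    new = np.where(sampled, np.clip(new, 0.0, None), 0.0)
    return replace(grid, values=new)


def strong_support(values: np.ndarray, frac: float = 0.05) -> np.ndarray:
    """Estimate the autocorrelation's support as a mask around the zero lag.

    Cells above ``frac`` of the maximum are thresholded, cleaned by a 3x3
    binary opening (isolated noise lags and one-cell bridges would otherwise
    stretch the estimate), and the connected component containing the zero
    lag is returned.  Falls back gracefully for degenerate tiny supports.
    """
    vals = np.asarray(values)
    strong = vals > frac * vals.max()
    centre = tuple(s // 2 for s in vals.shape)
    opened = ndimage.binary_opening(strong, structure=np.ones((3, 3)))
    if not opened[centre]:
        opened = strong  # support too small for the opening: keep raw mask
    labels, _ = ndimage.label(opened)
    if labels[centre] > 0:
        return labels == labels[centre]
    return opened


def support_extent(values: np.ndarray, frac: float = 0.10) -> tuple[int, int]:
    """Per-axis half-extent (in lags) of the autocorrelation around zero lag.

    A structured autocorrelation can be exactly zero on interior lines (the
    two-bar object's is zero along the whole column at the bar pitch), so
    neither a connected component nor a contiguous marginal run measures
    the bounding box reliably.  Instead, the grid is lightly smoothed
    (3x3 mean, suppressing isolated noise lags), cells above ``frac`` of
    the smoothed maximum are thresholded, and each axis is scanned from
    the outside inwards to the first line holding at least two strong
    cells — interior zero lines cannot shrink the estimate and lone noise
    lags cannot inflate it.
    """
    sm = ndimage.uniform_filter(np.asarray(values, dtype=float), size=3)
    strong = sm > frac * sm.max()

    def half_extent(line_counts: np.ndarray) -> int:
        c = line_counts.size // 2
        hits = np.nonzero(line_counts >= 2)[0]
        if hits.size == 0:
            hits = np.nonzero(line_counts > 0)[0]
        if hits.size == 0:
            return 0
        return int(max(c - hits.min(), hits.max() - c))

    return (half_extent(strong.sum(axis=1)), half_extent(strong.sum(axis=0)))


def fill_unsampled(grid: AutocorrGrid, max_fraction: float = 0.05) -> AutocorrGrid:
    """Nearest-neighbour fill of unsampled lags inside the sampled bounding box.

    Gaps are only tolerated when they amount to less than ``max_fraction``
    of the box; otherwise the trajectory genuinely failed to cover the
    object's autocorrelation and a :class:`CoverageError` is raised.
    """
    sampled = grid.sampled
    rows = np.nonzero(sampled.any(axis=1))[0]
    cols = np.nonzero(sampled.any(axis=0))[0]
    if rows.size == 0:
        raise ValueError("empty grid: nothing sampled")
    box = np.zeros_like(sampled)
    box[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1] = True
    holes = box & ~sampled
    frac = holes.sum() / box.sum()
    if frac == 0:
        return grid
    if frac >= max_fraction:
        raise CoverageError(
            f"{holes.sum()} unsampled lags ({frac:.1%} of the autocorrelation box); "
            "the trajectory's autocorrelation does not cover the object's"
        )
    _, (iy, ix) = ndimage.distance_transform_edt(~sampled, return_indices=True)
    values = grid.values.copy()
    values[holes] = grid.values[iy[holes], ix[holes]]
    counts = grid.counts.copy()
    counts[holes] = 1
    return replace(grid, values=values, counts=counts)
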