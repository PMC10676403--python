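"""Motion trajectories: generation, recovery, coverage and counting.

The object's autocorrelation can only be sampled at lags that occur as a
difference of two trajectory positions, i.e. on the positive support of the
*trajectory's* autocorrelation.  Simple paths suffice: a U (or T) samples a
full square of lags with ~3n (2n) detections instead of the n^2 a
whole-plane raster would need; an L suffices for axisymmetric and a straight
line for centrosymmetric objects.  Detection order is immaterial — the
trajectory is recovered afterwards from envelope cross-correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .overlap import displacement_estimate

__all__ = [
    "TrajectoryPath",
    "make_trajectory",
    "whole_plane_count",
    "recover_trajectory",
    "trajectory_autocorr",
    "check_coverage",
]

SHAPE_TAGS = ("U", "T", "L", "line", "custom")


@dataclass(frozen=True)
class TrajectoryPath:
    """Ordered integer lattice positions with a physical step size."""

    positions: tuple[tuple[int, int], ...]
    step: float = 1.0  # physical displacement per lattice unit (um)
    shape_tag: str = "custom"

    def __len__(self) -> int:
        return len(self.positions)

    def centered(self) -> "TrajectoryPath":
        """Same path translated so its centroid is near the lattice origin."""
        arr = np.asarray(self.positions)
        mid = np.round(arr.mean(axis=0)).astype(int)
        return TrajectoryPath(
            tuple((int(r - mid[0]), int(c - mid[1])) for r, c in arr),
            self.step,
            self.shape_tag,
        )


def make_trajectory(
    shape_tag: str,
    side_length: int,
    step: float = 1.0,
    positions: Sequence[tuple[int, int]] | None = None,
) -> TrajectoryPath:
    """Generate a standard motion path.

    Corner positions belong to exactly one side, so the counts are exact:
    |U| = 3n, |T| = 2n, |L| = 2n, |line| = n for side length n.  A U with 30
    positions per side therefore means 90 detections in total.  For
    ``custom``, ``positions`` is used verbatim after deduplication.
    """
    n = int(side_length)
    if shape_tag not in SHAPE_TAGS:
        raise ValueError(f"unknown shape_tag {shape_tag!r}; choose from {SHAPE_TAGS}")
    if shape_tag == "custom":
        if positions is None:
            raise ValueError("custom trajectory requires positions")
        seen: dict[tuple[int, int], None] = {}
        for p in positions:
            seen.setdefault((int(p[0]), int(p[1])), None)
        return TrajectoryPath(tuple(seen), float(step), "custom")
    if n < 2:
        raise ValueError("side_length must be >= 2")

    pts: list[tuple[int, int]] = []
    if shape_tag == "line":
        pts = [(0, c) for c in range(n)]
    elif shape_tag == "L":
        pts = [(r, 0) for r in range(n)] + [(n, c) for c in range(n)]
    elif shape_tag == "U":
        pts = (
            [(r, 0) for r in range(n)]  # down the left side
            + [(n, c) for c in range(n)]  # across the bottom
            + [(r, n) for r in range(n, 0, -1)]  # up the right side
        )
    elif shape_tag == "T":
        mid = (n - 1) // 2
        pts = [(0, c) for c in range(n)] + [(r, mid) for r in range(1, n + 1)]
    return TrajectoryPath(tuple(pts), float(step), shape_tag)


def whole_plane_count(side_length: int) -> int:
    """Detections a whole-plane raster scan would need at equal resolution."""
    n = int(side_length)
    if n < 1:
        raise ValueError("side_length must be >= 1")
    return n * n


def recover_trajectory(
    envelopes: Sequence[np.ndarray], anchor: int = 0
) -> TrajectoryPath:
    """Recover the motion path from envelopes, up to a global translation.

    Position ``i`` is the displacement of envelope ``i`` relative to the
    anchor frame; any anchor yields the same path up to translation.
    """
    if len(envelopes) < 2:
        raise ValueError("need at least 2 envelopes")
    positions = []
    for idx, env in enumerate(envelopes):
        try:
            d, _ = displacement_estimate(envelopes[anchor], env)
        except ValueError as exc:
            raise ValueError(f"frame {idx}: {exc}") from exc
        positions.append(d)
    return TrajectoryPath(tuple(positions), shape_tag="custom")


def trajectory_autocorr(path: TrajectoryPath) -> np.ndarray:
    """Counts of ordered position pairs per displacement lag.

    The returned integer field is indexed by lag with the zero lag at the
    centre; its value at (0, 0) is N and it is exactly centrosymmetric.
    """
    arr = np.asarray(path.positions)
    ry = int(np.ptp(arr[:, 0])) if len(arr) else 0
    rx = int(np.ptp(arr[:, 1])) if len(arr) else 0
    field = np.zeros((2 * ry + 1, 2 * rx + 1), dtype=np.int64)
    diffs = arr[None, :, :] - arr[:, None, :]
    np.add.at(field, (diffs[..., 0].ravel() + ry, diffs[..., 1].ravel() + rx), 1)
    return field


def check_coverage(
    path: TrajectoryPath, required_extent: tuple[int, int]
) -> tuple[bool, dict]:
    """Does the trajectory sample every lag within the required extent?

    ``required_extent = (a, b)`` asks for positive pair counts on the full
    box of lags ``[-a, a] x [-b, b]`` — the bounding box of the object
    autocorrelation that must be covered for reconstruction.  Returns the
    verdict and a report listing any missing lags.
    """
    a, b = int(required_extent[0]), int(required_extent[1])
    field = trajectory_autocorr(path)
    ry = (field.shape[0] - 1) // 2
    rx = (field.shape[1] - 1) // 2
    missing = []
    for dr in range(-a, a + 1):
        for dc in range(-b, b + 1):
            if abs(dr) > ry or abs(dc) > rx or field[dr + ry, dc + rx] == 0:
                missing.append((dr, dc))
    ok = not missing
    report = {
        "covered": ok,
        "required_extent": (a, b),
        "n_required": (2 * a + 1) * (2 * b + 1),
        "n_missing": len(missing),
        "missing_lags": missing,
    }
    return ok, report
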