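"""Bull's eye coordinate system: circular validity mask and segment partition.

The polar map is a square grid with the left-ventricle apex at the center and
the base at the rim.  All downstream stages share one :class:`Geometry` and,
for segmental summaries, one :class:`SegmentMasks` partition consisting of an
apical disc, four equal angular quadrants and an excluded basal ring.

Orientation follows the standard clinical bull's eye display: anterior wall at
the top of the image, inferior at the bottom, septal left, lateral right.
Angles are measured counterclockwise with 90 degrees at the top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "Geometry",
    "SegmentMasks",
    "SEGMENT_NAMES",
    "QUADRANT_SPANS",
    "make_geometry",
    "radial_angular",
    "make_segments",
]

#: Names of the five scored segments, in conventional reporting order.
SEGMENT_NAMES = ("apical", "anterior", "lateral", "inferior", "septal")

#: Angular spans (degrees, half-open) of the four non-apical quadrants.
#: The lateral quadrant wraps around 0 degrees.
QUADRANT_SPANS = {
    "anterior": (45.0, 135.0),
    "septal": (135.0, 225.0),
    "inferior": (225.0, 315.0),
    "lateral": (315.0, 45.0),
}

#: Integer labels used by CSV export: 0 outside the disc, then segments.
SEGMENT_LABELS = {
    "apical": 1,
    "anterior": 2,
    "lateral": 3,
    "inferior": 4,
    "septal": 5,
    "basal_excluded": 6,
}


@dataclass(frozen=True)
class Geometry:
    """Square polar-map grid with an inscribed circular validity disc.

    Attributes
    ----------
    grid_size:
        Pixels per side (odd, so a center pixel exists).
    center:
        (row, col) of the center pixel, 0-based.
    radius:
        Disc radius in pixel units (``grid_size / 2``).
    valid_mask:
        Boolean grid, true exactly where the pixel center lies within
        ``radius`` of ``center`` (boundary included).
    """

    grid_size: int
    center: tuple[int, int]
    radius: float
    valid_mask: np.ndarray

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def same_as(self, other: "Geometry") -> bool:
        return (
            self.grid_size == other.grid_size
            and self.center == other.center
            and self.radius == other.radius
        )


@dataclass(frozen=True)
class SegmentMasks:
    """Disjoint partition of the validity disc into scored segments.

    The five segment masks plus ``basal_excluded`` are pairwise disjoint and
    their union equals the geometry's ``valid_mask``.
    """

    apical: np.ndarray
    anterior: np.ndarray
    lateral: np.ndarray
    inferior: np.ndarray
    septal: np.ndarray
    basal_excluded: np.ndarray
    apical_fraction: float = 0.30
    basal_exclusion_fraction: float = 0.10

    @property
    def segments(self) -> dict[str, np.ndarray]:
        """The five scored segment masks (basal ring excluded), by name."""
        return {name: getattr(self, name) for name in SEGMENT_NAMES}

    def labels(self) -> np.ndarray:
        """Integer label grid: 0 outside, 1..5 segments, 6 basal-excluded."""
        out = np.zeros(self.apical.shape, dtype=int)
        for name, label in SEGMENT_LABELS.items():
            out[getattr(self, name)] = label
        return out


def make_geometry(grid_size: int = 65) -> Geometry:
    """Build the polar-map geometry for an odd ``grid_size``.

    Raises
    ------
    InvalidArgumentError
        If ``grid_size`` is even or smaller than 9.
    """
    if not isinstance(grid_size, (int, np.integer)):
        raise InvalidArgumentError(f"grid_size must be an integer, got {grid_size!r}")
    if grid_size % 2 == 0 or grid_size < 9:
        raise InvalidArgumentError(
            f"grid_size must be odd and >= 9, got {grid_size}"
        )
    c = (grid_size - 1) // 2
    radius = grid_size / 2.0
    rows, cols = np.mgrid[0:grid_size, 0:grid_size]
    dist = np.hypot(rows - c, cols - c)
    valid = dist <= radius
    return Geometry(
        grid_size=int(grid_size),
        center=(c, c),
        radius=radius,
        valid_mask=valid,
    )


def radial_angular(geometry: Geometry) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel normalized radius and angle grids.

    Returns
    -------
    radius_norm:
        0 at the center pixel (apex), 1 at the disc edge (base).
    angle_deg:
        Degrees in [0, 360), counterclockwise, 90 at the top of the image
        and 180 at the left edge.  The center pixel gets angle 0.
    """
    c_row, c_col = geometry.center
    rows, cols = np.mgrid[0 : geometry.grid_size, 0 : geometry.grid_size]
    dy = c_row - rows  # image row axis points down; flip so angles go CCW
    dx = cols - c_col
    radius_norm = np.hypot(dy, dx) / geometry.radius
    angle_deg = np.degrees(np.arctan2(dy, dx)) % 360.0
    return radius_norm, angle_deg


def _quadrant_mask(angle_deg: np.ndarray, span: tuple[float, float]) -> np.ndarray:
    lo, hi = span
    if lo < hi:
        return (angle_deg >= lo) & (angle_deg < hi)
    return (angle_deg >= lo) | (angle_deg < hi)  # wraps through 0


def make_segments(
    geometry: Geometry,
    apical_fraction: float = 0.30,
    basal_exclusion_fraction: float = 0.10,
) -> SegmentMasks:
    """Partition the valid disc into apical + four quadrants + basal ring.

    The apical segment is every valid pixel with normalized radius at most
    ``apical_fraction``; the basal ring is every valid pixel with normalized
    radius strictly above ``1 - basal_exclusion_fraction``; the remainder is
    split into four equal angular quadrants (anterior, septal, inferior,
    lateral) per :data:`QUADRANT_SPANS`.

    Raises
    ------
    InvalidArgumentError
        Unless ``0 < apical_fraction < 1 - basal_exclusion_fraction < 1``.
    """
    if not (0.0 < apical_fraction < 1.0 - basal_exclusion_fraction < 1.0):
        raise InvalidArgumentError(
            "fractions must satisfy 0 < apical_fraction < "
            f"1 - basal_exclusion_fraction < 1; got apical_fraction="
            f"{apical_fraction}, basal_exclusion_fraction={basal_exclusion_fraction}"
        )
    radius_norm, angle_deg = radial_angular(geometry)
    valid = geometry.valid_mask
    apical = valid & (radius_norm <= apical_fraction)
    basal = valid & (radius_norm > 1.0 - basal_exclusion_fraction)
    mid = valid & ~apical & ~basal
    quads = {
        name: mid & _quadrant_mask(angle_deg, span)
        for name, span in QUADRANT_SPANS.items()
    }
    return SegmentMasks(
        apical=apical,
        anterior=quads["anterior"],
        lateral=quads["lateral"],
        inferior=quads["inferior"],
        septal=quads["septal"],
        basal_excluded=basal,
        apical_fraction=float(apical_fraction),
        basal_exclusion_fraction=float(basal_exclusion_fraction),
    )
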