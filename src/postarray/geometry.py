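"""Physical layout of the well array and conversion to image pixels.

The device is a grid of square nanoliter wells (default 300 um wide, 39 um
deep, 50 um apart) each holding a handful of square hydrogel posts
(default 40 um) whose sub-position inside the well encodes the capture
probe.  Scans are read at a fixed resolution (default 5 um/pixel), so the
well pitch is (300 + 50) / 5 = 70 px and a post spans 8 px.

Coordinates are 0-based ``(x, y)`` with ``x`` the column axis, origin at the
image upper-left; all well/post windows are half-open pixel rectangles.  The
grid model is a rigid translation at uniform pitch: the scanner stage does
not rotate the slide appreciably, and the two anchor points the protocol
records cannot constrain a rotation anyway, so residual vertical skew between
anchors is surfaced as a diagnostic rather than corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "ArrayGeometry",
    "GridAnchorWarning",
    "infer_pitch",
    "well_origin",
    "well_rect",
    "post_rect",
]

SKEW_TOLERANCE_PX = 3.0


class GridAnchorWarning(UserWarning):
    """Anchor pair implies a skewed or otherwise suspect grid."""


def _default_post_offsets(
    well_size_um: float, post_size_um: float, posts_per_well: int
) -> list[tuple[float, float]]:
    # Evenly spaced horizontal row, vertically centered.  The probe layout
    # inside a well is a convention of this package: sub-position encodes
    # probe identity, but the physical arrangement is configurable.
    dy = (well_size_um - post_size_um) / 2.0
    step = well_size_um / posts_per_well
    margin = (step - post_size_um) / 2.0
    return [(margin + i * step, dy) for i in range(posts_per_well)]


@dataclass(frozen=True)
class ArrayGeometry:
    """Physical and pixel layout of the well/post array.

    All physical fields are in micrometres; pixel quantities are derived
    through ``pixel_size_um``.  Defaults describe the reference device: a
    28 x 28 grid of 300 um wells, 50 um spacing, 39 um depth, 40 um posts,
    scanned at 5 um/pixel.
    """

    well_size_um: float = 300.0
    well_spacing_um: float = 50.0
    well_depth_um: float = 39.0
    post_size_um: float = 40.0
    n_rows: int = 28
    n_cols: int = 28
    pixel_size_um: float = 5.0
    posts_per_well: int = 5
    post_offsets_um: tuple[tuple[float, float], ...] = field(default=())

    def __post_init__(self) -> None:
        if min(self.well_size_um, self.post_size_um, self.pixel_size_um) <= 0:
            raise ValueError("well, post and pixel sizes must be positive")
        if self.well_spacing_um < 0:
            raise ValueError("well_spacing_um must be non-negative")
        if self.n_rows < 1 or self.n_cols < 1 or self.posts_per_well < 1:
            raise ValueError("grid counts must be >= 1")
        if not self.post_offsets_um:
            object.__setattr__(
                self,
                "post_offsets_um",
                tuple(
                    _default_post_offsets(
                        self.well_size_um, self.post_size_um, self.posts_per_well
                    )
                ),
            )
        if len(self.post_offsets_um) != self.posts_per_well:
            raise ValueError(
                f"expected {self.posts_per_well} post offsets, "
                f"got {len(self.post_offsets_um)}"
            )
        side = self.post_side_px * self.pixel_size_um
        for i, (dx, dy) in enumerate(self.post_offsets_um):
            if dx < 0 or dy < 0 or dx + side > self.well_size_um or dy + side > self.well_size_um:
                raise ValueError(
                    f"post offset {i} ({dx}, {dy}) places its window outside "
                    f"the {self.well_size_um} um well footprint"
                )
        if self.pitch_px <= 0:
            raise ValueError("well pitch must be positive")

    @property
    def pitch_px(self) -> float:
        """Well pitch (center-to-center) in pixels."""
        return (self.well_size_um + self.well_spacing_um) / self.pixel_size_um

    @property
    def well_side_px(self) -> int:
        return int(round(self.well_size_um / self.pixel_size_um))

    @property
    def post_side_px(self) -> int:
        side = int(round(self.post_size_um / self.pixel_size_um))
        return max(side, 1)

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def post_offsets_px(self) -> list[tuple[int, int]]:
        return [
            (int(round(dx / self.pixel_size_um)), int(round(dy / self.pixel_size_um)))
            for dx, dy in self.post_offsets_um
        ]


def well_origin(
    geometry: ArrayGeometry,
    row: int,
    col: int,
    grid_anchor: Sequence[float],
    pitch_px: float | None = None,
) -> tuple[int, int]:
    """Upper-left pixel ``(x, y)`` of well ``(row, col)``.

    ``grid_anchor`` is the upper-left pixel of well (0, 0); ``pitch_px``
    defaults to the geometry's nominal pitch.  Raises ``IndexError`` naming
    the offending axis for out-of-range wells.
    """
    if pitch_px is None:
        pitch_px = geometry.pitch_px
    if pitch_px <= 0:
        raise ValueError("pitch_px must be positive")
    if not 0 <= row < geometry.n_rows:
        raise IndexError(f"row {row} outside [0, {geometry.n_rows})")
    if not 0 <= col < geometry.n_cols:
        raise IndexError(f"col {col} outside [0, {geometry.n_cols})")
    ax, ay = grid_anchor
    return int(round(ax + col * pitch_px)), int(round(ay + row * pitch_px))


def well_rect(
    geometry: ArrayGeometry,
    row: int,
    col: int,
    grid_anchor: Sequence[float],
    pitch_px: float | None = None,
) -> tuple[int, int, int, int]:
    """Half-open pixel rectangle ``(x0, y0, x1, y1)`` of a well footprint."""
    x0, y0 = well_origin(geometry, row, col, grid_anchor, pitch_px)
    side = geometry.well_side_px
    return x0, y0, x0 + side, y0 + side


def post_rect(
    geometry: ArrayGeometry,
    row: int,
    col: int,
    post_index: int,
    grid_anchor: Sequence[float],
    pitch_px: float | None = None,
) -> tuple[int, int, int, int]:
    """Half-open pixel rectangle of one post's nominal window."""
    if not 0 <= post_index < geometry.posts_per_well:
        raise IndexError(
            f"post_index {post_index} outside [0, {geometry.posts_per_well})"
        )
    x0, y0 = well_origin(geometry, row, col, grid_anchor, pitch_px)
    dx, dy = geometry.post_offsets_px()[post_index]
    side = geometry.post_side_px
    return x0 + dx, y0 + dy, x0 + dx + side, y0 + dy + side


def infer_pitch(
    anchor_a: Sequence[float],
    anchor_b: Sequence[float],
    wells_between: int,
    skew_tolerance_px: float = SKEW_TOLERANCE_PX,
) -> tuple[float, float]:
    """Well pitch from two same-row, same-sub-position post corners.

    The protocol records the upper-left pixel of the same post in two wells
    of one row; the horizontal separation divided by the number of wells
    between them is the pitch.  Returns ``(pitch_px, skew_px)`` where
    ``skew_px`` is the vertical residual between the anchors — a diagnostic
    for slide rotation, warned about above ``skew_tolerance_px`` but never
    corrected.
    """
    if wells_between < 1:
        raise ValueError("wells_between must be >= 1")
    dx = float(anchor_b[0]) - float(anchor_a[0])
    if dx == 0:
        raise ValueError(
            "degenerate anchors: zero horizontal separation between anchor points"
        )
    pitch = abs(dx) / wells_between
    skew = abs(float(anchor_b[1]) - float(anchor_a[1]))
    if skew > skew_tolerance_px:
        warnings.warn(
            f"anchor pair implies {skew:.1f} px vertical skew "
            f"(tolerance {skew_tolerance_px} px); grid model assumes no rotation",
            GridAnchorWarning,
            stacklevel=2,
        )
    return pitch, skew
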