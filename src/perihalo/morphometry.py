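"""Cell-shape morphometrics on closed polygonal contours."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import Polygon

from .tracks import GroupComparison, group_compare

__all__ = ["CellContour", "circularity", "circularity_series", "mask_to_contours"]


@dataclass(frozen=True)
class CellContour:
    """Closed simple polygon outlining one cell, vertices in micrometres.

    The polygon is stored open (last vertex != first); closure is implicit.
    """

    contour_id: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise ValueError(f"contour {self.contour_id!r}: vertices must be (n, 2)")
        if np.allclose(verts[0], verts[-1]) and len(verts) > 1:
            verts = verts[:-1]
        if len(verts) < 3:
            raise ValueError(f"contour {self.contour_id!r}: needs >= 3 distinct vertices")
        if not np.all(np.isfinite(verts)):
            raise ValueError(f"contour {self.contour_id!r}: non-finite vertices")
        poly = Polygon(verts)
        if not poly.is_valid or poly.area == 0.0:
            raise ValueError(f"contour {self.contour_id!r}: degenerate or self-intersecting polygon")
        object.__setattr__(self, "vertices", verts)

    @property
    def area(self) -> float:
        """Shoelace area, always positive."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.vertices, self.vertices[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


def circularity(contour: CellContour) -> float:
    """4*pi*Area/Perimeter^2 — 1 for a disk, lower for protrusive shapes."""
    perimeter = contour.perimeter
    if perimeter == 0.0:
        raise ValueError("degenerate contour with zero perimeter")
    return 4.0 * math.pi * contour.area / perimeter**2


def circularity_series(
    contours_by_group: Mapping[str, Sequence[CellContour]],
    reference: str | None = None,
) -> list[GroupComparison]:
    """Per-group circularity summaries compared by Welch's t-test."""
    metrics = {
        group: [{"circularity": circularity(c)} for c in contours]
        for group, contours in contours_by_group.items()
    }
    return group_compare(metrics, reference=reference, metrics=["circularity"])


def mask_to_contours(mask: np.ndarray, pixel_size_um: float = 1.0) -> list[CellContour]:
    """Convert a binary raster mask into polygonal contours.

    Iso-contours are extracted at the 0.5 level; each closed contour of at
    least 3 vertices becomes a :class:`CellContour` in physical units.  This
    keeps the downstream circularity free of pixel-perimeter bias.
    """
    from skimage import measure  # local import: raster path is optional

    found = measure.find_contours(np.asarray(mask, dtype=float), 0.5)
    contours = []
    for i, rc in enumerate(found):
        if len(rc) < 4 or not np.allclose(rc[0], rc[-1]):
            continue  # open contour touching the border
        xy = np.column_stack([rc[:-1, 1], rc[:-1, 0]]) * pixel_size_um
        try:
            contours.append(CellContour(contour_id=f"mask_{i}", vertices=xy))
        except ValueError:
            continue
    return contours
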