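"""Bounding-box geometry: IoU, tiling plans and tile<->image coordinate maps.

Boxes use 0-based pixel coordinates with half-open intervals: a box occupies
``[x_min, x_min + width) x [y_min, y_min + height)`` with the origin at the
image's top-left corner.  This is the COCO ``(x, y, w, h)`` convention and is
the package-wide canonical form; YOLO normalized center boxes are converted
on read (see :mod:`trapdiv.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

__all__ = ["Box", "Tile", "iou", "tile_to_image", "image_to_tile", "slice_plan"]


@dataclass(frozen=True)
class Box:
    """An axis-aligned bounding box in pixel coordinates.

    Attributes
    ----------
    x_min, y_min:
        Top-left corner, 0-based.
    width, height:
        Strictly positive extents in pixels.
    """

    x_min: float
    y_min: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"degenerate box: width={self.width}, height={self.height} "
                "(both must be > 0)"
            )

    @property
    def x_max(self) -> float:
        return self.x_min + self.width

    @property
    def y_max(self) -> float:
        return self.y_min + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    def clip(self, image_width: float, image_height: float) -> "Box":
        """Clip to image bounds; raises if nothing remains."""
        x0 = min(max(self.x_min, 0.0), image_width)
        y0 = min(max(self.y_min, 0.0), image_height)
        x1 = min(max(self.x_max, 0.0), image_width)
        y1 = min(max(self.y_max, 0.0), image_height)
        if x1 - x0 <= 0 or y1 - y0 <= 0:
            raise ValueError("box lies entirely outside the image")
        return Box(x0, y0, x1 - x0, y1 - y0)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes.

    Symmetric; 1 iff the boxes are identical, 0 iff they are disjoint.
    Degenerate (zero-area) boxes are rejected at construction time.
    """
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


@dataclass(frozen=True)
class Tile:
    """One tile of a sliced image: its origin and size in image coordinates."""

    index: int
    x_origin: int
    y_origin: int
    width: int
    height: int


def slice_plan(
    image_width: int,
    image_height: int,
    tile_size: int = 500,
    overlap: int = 0,
) -> list[Tile]:
    """Plan the tiling of a ``W x H`` image into ``tile_size`` squares.

    With ``overlap == 0`` the tiles partition the image exactly (edge tiles are
    smaller than ``tile_size`` when the image size is not a multiple).  With a
    positive overlap the stride is ``tile_size - overlap`` and interior pixels
    may belong to several tiles.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    if not 0 <= overlap < tile_size:
        raise ValueError("overlap must satisfy 0 <= overlap < tile_size")
    stride = tile_size - overlap
    tiles: list[Tile] = []
    idx = 0
    y = 0
    while y < image_height:
        h = min(tile_size, image_height - y)
        x = 0
        while x < image_width:
            w = min(tile_size, image_width - x)
            tiles.append(Tile(idx, x, y, w, h))
            idx += 1
            x += stride
        y += stride
    return tiles


def tile_to_image(tile: Tile, box_in_tile: Box) -> Box:
    """Map a box from tile-local coordinates to full-image coordinates.

    Raises if the box exceeds the tile's bounds.
    """
    if (
        box_in_tile.x_min < 0
        or box_in_tile.y_min < 0
        or box_in_tile.x_max > tile.width
        or box_in_tile.y_max > tile.height
    ):
        raise ValueError(
            f"box {box_in_tile} exceeds tile bounds {tile.width}x{tile.height}"
        )
    return replace(
        box_in_tile,
        x_min=box_in_tile.x_min + tile.x_origin,
        y_min=box_in_tile.y_min + tile.y_origin,
    )


def image_to_tile(tile: Tile, box_in_image: Box) -> Box:
    """Inverse of :func:`tile_to_image`; raises if the box leaves the tile."""
    out = replace(
        box_in_image,
        x_min=box_in_image.x_min - tile.x_origin,
        y_min=box_in_image.y_min - tile.y_origin,
    )
    if out.x_min < 0 or out.y_min < 0 or out.x_max > tile.width or out.y_max > tile.height:
        raise ValueError("box does not lie within the tile")
    return out


def iter_pixels(tile: Tile) -> Iterator[tuple[int, int]]:
    """Yield the image-coordinate pixels a tile covers (test oracle helper)."""
    for yy in range(tile.y_origin, tile.y_origin + tile.height):
        for xx in range(tile.x_origin, tile.x_origin + tile.width):
            yield xx, yy
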