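"""Fuse semantic-segmentation maps with instance detections into one cell table.

Whole-slide prediction works patch to patch: a 500x500 region at 10x
magnification is classified semantically, and the co-located 2000x2000 region
at 40x is covered by partially overlapping 500x500 sub-windows of instance
segmentation.  Sub-window rims suffer edge effects, so a margin is discarded
and every point of the slide is *owned* by exactly one sub-window of exactly
one tile.  Each surviving detection keeps its geometry but takes its class
from the semantic map under its centroid.  Finally, pseudo-points are laid on
a hexagonal grid inside background and stratum-corneum regions — no real
nuclei exist there, yet the layer-counting graph needs nodes on the far side
of the epithelial surface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .cell_model import (
    SEMANTIC_TO_CELL,
    CellClass,
    CellRecord,
    InstanceRecord,
    SemanticClass,
    SemanticMap,
)
from .errors import FormatError, ParameterError

__all__ = [
    "Rect",
    "SubWindow",
    "Tile",
    "TilePlan",
    "plan_tiles",
    "reclassify_by_center",
    "generate_pseudo_points",
    "fuse_slide",
    "DEFAULT_MARGIN",
    "DEFAULT_PSEUDO_SPACING",
    "TILE_SIZE_40X",
    "WINDOW_SIZE_40X",
]

logger = logging.getLogger(__name__)

TILE_SIZE_40X = 2000   # one 10x patch (500 px) seen at 40x
WINDOW_SIZE_40X = 500  # instance-model input at 40x
DEFAULT_MARGIN = 50    # discarded rim of each sub-window, 40x px
DEFAULT_PSEUDO_SPACING = 60.0  # hex-grid pitch of pseudo-points, 40x px


@dataclass(frozen=True)
class Rect:
    """Axis-aligned half-open rectangle in 40x pixels."""

    x: float
    y: float
    w: float
    h: float

    def contains(self, px: float, py: float) -> bool:
        return self.x <= px < self.x + self.w and self.y <= py < self.y + self.h


@dataclass(frozen=True)
class SubWindow:
    rect: Rect      # full 500x500 window
    interior: Rect  # retained ownership region after margin discard


@dataclass(frozen=True)
class Tile:
    key: tuple[int, int]  # (row, col) in the tile lattice
    rect40: Rect          # 2000x2000 at 40x
    rect10: Rect          # co-located 500x500 in 10x pixel units
    own: Rect             # ownership region at the tile level
    windows: tuple[SubWindow, ...]


@dataclass(frozen=True)
class TilePlan:
    roi: Rect
    margin: int
    tiles: tuple[Tile, ...]

    def owner_of(self, x: float, y: float) -> tuple[tuple[int, int], int] | None:
        """(tile key, window index) owning a point, or None outside the ROI."""
        for tile in self.tiles:
            if tile.own.contains(x, y):
                for widx, win in enumerate(tile.windows):
                    if win.interior.contains(x, y):
                        return tile.key, widx
                return None  # unreachable when interiors tile the region
        return None


def _axis_windows(extent: float, win: float, margin: float) -> list[tuple[float, float, float]]:
    """1-D window origins and ownership intervals along one axis.

    Windows of width ``win`` step by ``win - 2*margin`` so retained interiors
    abut exactly; the last window clamps to the extent and keeps its outer
    rim, as does the first.  Returns (origin, interior_start, interior_end).
    """
    step = win - 2 * margin
    n = 1 if extent <= win else math.ceil((extent - win) / step) + 1
    bounds = [0.0] + [margin + i * step for i in range(1, n)] + [extent]
    out = []
    for i in range(n):
        origin = min(i * step, extent - win)
        out.append((origin, bounds[i], bounds[i + 1]))
    return out


def plan_tiles(roi: Rect | tuple[float, float, float, float], margin: int = DEFAULT_MARGIN) -> TilePlan:
    """Lay out aligned 10x/40x tiles and overlapping sub-windows over a region.

    ``roi`` is at 40x.  Sub-windows within each 2000x2000 tile step by
    ``500 - 2*margin``; after discarding the ``margin``-px rim, the retained
    interiors tile the region with no gaps and no double-assignment (boundary
    windows keep their outer rim).
    """
    if not isinstance(roi, Rect):
        roi = Rect(*roi)
    if roi.w < TILE_SIZE_40X or roi.h < TILE_SIZE_40X:
        raise ParameterError(
            f"region {roi.w}x{roi.h} is smaller than one {TILE_SIZE_40X}x{TILE_SIZE_40X} tile "
            "at 40x: pad the region before planning"
        )
    if not 0 <= margin < WINDOW_SIZE_40X / 2:
        raise ParameterError(
            f"margin must be in [0, {WINDOW_SIZE_40X // 2}), got {margin}"
        )

    tiles = []
    rows = _axis_windows(roi.h, TILE_SIZE_40X, 0)
    cols = _axis_windows(roi.w, TILE_SIZE_40X, 0)
    for ti, (oy, iy0, iy1) in enumerate(rows):
        for tj, (ox, ix0, ix1) in enumerate(cols):
            rect40 = Rect(roi.x + ox, roi.y + oy, TILE_SIZE_40X, TILE_SIZE_40X)
            windows = []
            wpos = _axis_windows(TILE_SIZE_40X, WINDOW_SIZE_40X, margin)
            for wy, wy0, wy1 in wpos:
                for wx, wx0, wx1 in wpos:
                    windows.append(
                        SubWindow(
                            rect=Rect(rect40.x + wx, rect40.y + wy, WINDOW_SIZE_40X, WINDOW_SIZE_40X),
                            interior=Rect(rect40.x + wx0, rect40.y + wy0, wx1 - wx0, wy1 - wy0),
                        )
                    )
            tiles.append(
                Tile(
                    key=(ti, tj),
                    rect40=rect40,
                    rect10=Rect(rect40.x / 4, rect40.y / 4, WINDOW_SIZE_40X, WINDOW_SIZE_40X),
                    own=Rect(roi.x + ix0, roi.y + iy0, ix1 - ix0, iy1 - iy0),
                    windows=tuple(windows),
                )
            )
    return TilePlan(roi=roi, margin=margin, tiles=tuple(tiles))


def reclassify_by_center(
    instances: Sequence[InstanceRecord],
    smap: SemanticMap,
    start_id: int = 0,
    slide_id: str = "",
) -> tuple[list[CellRecord], list[InstanceRecord]]:
    """Turn detections into cell records classed by the semantic map.

    The class of each cell is read from the semantic map at the detection
    centroid (the region model decides the class; the instance model's own
    label is ignored); centroid, polygon area and geometry are untouched.
    Detections whose centroid falls off the map are dropped, logged and
    returned separately.
    """
    cells: list[CellRecord] = []
    dropped: list[InstanceRecord] = []
    next_id = start_id
    for inst in instances:
        if not smap.contains(inst.x, inst.y):
            logger.warning("dropping detection at (%.1f, %.1f): centroid outside map", inst.x, inst.y)
            dropped.append(inst)
            continue
        sem = smap.class_at(inst.x, inst.y)
        cells.append(
            CellRecord(
                id=next_id,
                x=inst.x,
                y=inst.y,
                cell_class=SEMANTIC_TO_CELL[sem],
                area=inst.polygon_area(),
                is_pseudo=False,
                slide_id=slide_id,
            )
        )
        next_id += 1
    return cells, dropped


def generate_pseudo_points(
    smap: SemanticMap,
    spacing: float = DEFAULT_PSEUDO_SPACING,
    region: Rect | None = None,
    start_id: int = 0,
    slide_id: str = "",
) -> list[CellRecord]:
    """Hexagonal-grid pseudo-points inside BACKGROUND and CORNEUM regions.

    Points are laid at the given pitch (40x px, offset rows) across the map
    footprint, restricted to ``region`` when given, and kept only where the
    semantic class is BACKGROUND or CORNEUM; nearest-neighbor distance is at
    least ``spacing * sqrt(3)/2``.
    """
    if not spacing > 0:
        raise ParameterError(f"spacing must be > 0, got {spacing}")
    x0, y0, w, h = smap.footprint_40x()
    dy = spacing * math.sqrt(3) / 2
    cells: list[CellRecord] = []
    next_id = start_id
    n_rows = int(h / dy) + 1
    n_cols = int(w / spacing) + 1
    for row in range(n_rows):
        y = y0 + (row + 0.5) * dy
        if y >= y0 + h:
            break
        xoff = 0.25 * spacing if row % 2 == 0 else 0.75 * spacing
        for col in range(n_cols):
            x = x0 + xoff + col * spacing
            if x >= x0 + w:
                break
            if region is not None and not region.contains(x, y):
                continue
            sem = smap.class_at(x, y)
            if sem is SemanticClass.BACKGROUND:
                cls = CellClass.BACKGROUND
            elif sem is SemanticClass.CORNEUM:
                cls = CellClass.CORNEUM
            else:
                continue
            cells.append(
                CellRecord(id=next_id, x=x, y=y, cell_class=cls, is_pseudo=True, slide_id=slide_id)
            )
            next_id += 1
    return cells


def fuse_slide(
    plan: TilePlan,
    maps: Mapping[tuple[int, int], SemanticMap],
    instances: Mapping[tuple[tuple[int, int], int], Sequence[InstanceRecord]],
    spacing: float = DEFAULT_PSEUDO_SPACING,
    slide_id: str = "",
) -> list[CellRecord]:
    """Assemble the slide-level cell table from per-tile/per-window predictions.

    ``maps`` is keyed by tile key; ``instances`` by (tile key, window index) —
    absent window keys mean no detections there.  A detection survives only if
    its centroid lies in the retained interior of the window it came from
    *and* in its tile's ownership region, so duplicates across overlapping
    windows resolve to exactly one record.  Pseudo-points are appended per
    tile over each tile's ownership region.  Output ids are assigned after a
    deterministic (is_pseudo, y, x) sort.
    """
    kept_instances: list[InstanceRecord] = []
    per_instance_tile: list[tuple[int, int]] = []
    for tile in plan.tiles:
        if tile.key not in maps:
            raise FormatError(f"missing semantic map for tile {tile.key}")
        for widx, win in enumerate(tile.windows):
            for inst in instances.get((tile.key, widx), ()):
                if win.interior.contains(inst.x, inst.y) and tile.own.contains(inst.x, inst.y):
                    kept_instances.append(inst)
                    per_instance_tile.append(tile.key)

    records: list[CellRecord] = []
    for inst, tkey in zip(kept_instances, per_instance_tile):
        cells, _ = reclassify_by_center([inst], maps[tkey], start_id=0, slide_id=slide_id)
        records.extend(cells)
    for tile in plan.tiles:
        records.extend(
            generate_pseudo_points(maps[tile.key], spacing, region=tile.own, slide_id=slide_id)
        )

    records.sort(key=lambda c: (c.is_pseudo, c.y, c.x))
    return [
        CellRecord(
            id=i, x=c.x, y=c.y, cell_class=c.cell_class,
            area=c.area, is_pseudo=c.is_pseudo, slide_id=c.slide_id,
        )
        for i, c in enumerate(records)
    ]
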