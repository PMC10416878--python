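"""Domain types and file I/O for cell tables, semantic label maps and results.

The shared vocabulary of the package: every cell (nucleus or pseudo-point) is a
:class:`CellRecord` with a position in 40x-magnification pixels and one of six
:class:`CellClass` values; region-level tissue classes live on a
:class:`SemanticMap`, a label grid at 10x magnification.  Coordinate convention
throughout the package: x = column index, y = row index, 0-based, raster order
(y grows downward), units = pixels at 40x.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError, ParameterError, RowError

__all__ = [
    "CellClass",
    "EPITHELIAL_CLASSES",
    "CellRecord",
    "SemanticClass",
    "SemanticMap",
    "InstanceRecord",
    "LayerCountResult",
    "DIAGNOSIS_GROUPS",
    "COHORT_COLUMNS",
    "is_epithelial",
    "read_cell_table",
    "write_cell_table",
    "read_results",
    "write_results",
    "read_semantic_map",
    "write_semantic_map",
    "read_cohort_table",
    "validate_cohort_table",
]


class CellClass(str, Enum):
    """Nucleus-level classes carried by every cell record.

    BASAL, EPITHELIAL_OTHER and LYMPHOCYTE are the classes found inside the
    epithelium; STROMA marks connective-tissue nuclei below the basal layer;
    CORNEUM and BACKGROUND have no true nuclei and are populated by synthetic
    grid points (``is_pseudo``) so that the neighbor graph can see across the
    epithelial surface.
    """

    BASAL = "basal"
    EPITHELIAL_OTHER = "epithelial_other"
    LYMPHOCYTE = "lymphocyte"
    STROMA = "stroma"
    CORNEUM = "corneum"
    BACKGROUND = "background"


#: Classes considered part of the epithelium for edge classification and
#: traversal.  Lymphocytes inside the epithelium occupy layer positions, so
#: they count as epithelial; this is a predicate, not a stored class.
EPITHELIAL_CLASSES = frozenset(
    {CellClass.BASAL, CellClass.EPITHELIAL_OTHER, CellClass.LYMPHOCYTE}
)


def is_epithelial(cell_class: CellClass) -> bool:
    return cell_class in EPITHELIAL_CLASSES


@dataclass(frozen=True)
class CellRecord:
    """One nucleus (or pseudo-point): position, class, provenance.

    Coordinates are continuous pixels at 40x magnification; ``area`` (when
    present) is in squared 40x pixels.  ``is_pseudo`` marks grid points
    synthesized in BACKGROUND/CORNEUM regions, where no real nuclei exist.
    """

    id: int
    x: float
    y: float
    cell_class: CellClass
    area: float | None = None
    is_pseudo: bool = False
    slide_id: str = ""

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ParameterError(
                f"cell {self.id}: coordinates must be non-negative, got ({self.x}, {self.y})"
            )
        if self.area is not None and not self.area > 0:
            raise ParameterError(f"cell {self.id}: area must be > 0, got {self.area}")
        if self.is_pseudo and self.cell_class not in (
            CellClass.BACKGROUND,
            CellClass.CORNEUM,
        ):
            raise ParameterError(
                f"cell {self.id}: is_pseudo is only valid for BACKGROUND/CORNEUM, "
                f"got {self.cell_class.value}"
            )


class SemanticClass(Enum):
    """Region classes of the semantic label map (10x magnification)."""

    EPI_BASAL = 0
    EPI_OTHER = 1
    CORNEUM = 2
    NON_EPI = 3
    BACKGROUND = 4


#: How region classes become cell classes when an instance centroid is
#: reclassified against the semantic map (the semantic model decides the
#: class; the instance model only contributes geometry).
SEMANTIC_TO_CELL: dict[SemanticClass, CellClass] = {
    SemanticClass.EPI_BASAL: CellClass.BASAL,
    SemanticClass.EPI_OTHER: CellClass.EPITHELIAL_OTHER,
    SemanticClass.CORNEUM: CellClass.CORNEUM,
    SemanticClass.NON_EPI: CellClass.STROMA,
    SemanticClass.BACKGROUND: CellClass.BACKGROUND,
}


@dataclass
class SemanticMap:
    """Label grid at 10x magnification anchored in 40x pixel coordinates.

    ``labels[r, c]`` holds ``SemanticClass(value).value`` codes.  A 40x point
    (x, y) falls in grid cell (floor((y - y0)/scale), floor((x - x0)/scale));
    the map is only ever sampled at 40x coordinates, never resampled.
    """

    labels: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    scale: int = 4

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("semantic map must be a 2-D label grid")
        valid = {c.value for c in SemanticClass}
        present = set(np.unique(self.labels).tolist())
        bad = present - valid
        if bad:
            raise FormatError(f"semantic map contains invalid label values {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def grid_index(self, x: float, y: float) -> tuple[int, int]:
        return (
            int(math.floor((y - self.y0) / self.scale)),
            int(math.floor((x - self.x0) / self.scale)),
        )

    def contains(self, x: float, y: float) -> bool:
        r, c = self.grid_index(x, y)
        return 0 <= r < self.labels.shape[0] and 0 <= c < self.labels.shape[1]

    def class_at(self, x: float, y: float) -> SemanticClass:
        """Region class under a 40x-coordinate point."""
        if not self.contains(x, y):
            raise ParameterError(f"point ({x}, {y}) lies outside the semantic map footprint")
        r, c = self.grid_index(x, y)
        return SemanticClass(int(self.labels[r, c]))

    def footprint_40x(self) -> tuple[float, float, float, float]:
        """(x0, y0, width, height) of the map footprint at 40x."""
        h, w = self.labels.shape
        return (self.x0, self.y0, w * self.scale, h * self.scale)


@dataclass(frozen=True)
class InstanceRecord:
    """One instance-segmentation detection: geometry only, class discarded.

    The source class label (whatever string the instance model emitted) is
    kept for bookkeeping but ignored after fusion; the final cell class comes
    from the semantic map at the centroid.
    """

    x: float
    y: float
    source_label: str = ""
    polygon: tuple[tuple[float, float], ...] | None = None

    def polygon_area(self) -> float | None:
        """Shoelace area of the boundary polygon, if one is attached."""
        if self.polygon is None or len(self.polygon) < 3:
            return None
        pts = np.asarray(self.polygon, dtype=float)
        x, y = pts[:, 0], pts[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


@dataclass
class LayerCountResult:
    """Per-node layer counts over inner-edge nodes plus slide-level summary.

    ``counts`` maps inner-edge node id -> layer count (positive integer, the
    first wave index at which the node was reached).  Inner-edge nodes the
    wave never reaches (e.g. beyond a full-thickness crack) are listed in
    ``unreachable_ids`` and excluded from the summary statistics.
    """

    counts: dict[int, int]
    unreachable_ids: frozenset[int] = frozenset()
    median_layers: float | None = None
    sd_layers: float | None = None
    n_inner: int = 0
    slide_id: str = ""

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[int, int],
        unreachable_ids: Iterable[int] = (),
        slide_id: str = "",
    ) -> "LayerCountResult":
        counts = dict(counts)
        for node, k in counts.items():
            if not (isinstance(k, (int, np.integer)) and k >= 1):
                raise ParameterError(f"layer count for node {node} must be a positive integer, got {k}")
        if counts:
            values = np.fromiter(counts.values(), dtype=float)
            median = float(np.quantile(values, 0.5))
            sd = float(np.std(values, ddof=0))
        else:
            median = sd = None
        return cls(
            counts=counts,
            unreachable_ids=frozenset(int(i) for i in unreachable_ids),
            median_layers=median,
            sd_layers=sd,
            n_inner=len(counts),
            slide_id=slide_id,
        )


#: The three diagnosis severity groups of the cohort table.
DIAGNOSIS_GROUPS = ("hyperkeratosis_hyperplasia", "mild_moderate", "severe_carcinoma")

COHORT_COLUMNS = (
    "slide_id",
    "median_layers",
    "sd_layers",
    "diagnosis_group",
    "pfi_time",
    "pfi_event",
)


def validate_cohort_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, group labels and survival fields of a cohort."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise FormatError(f"cohort table missing column(s): {', '.join(missing)}")
    bad_groups = set(cohort["diagnosis_group"]) - set(DIAGNOSIS_GROUPS)
    if bad_groups:
        raise FormatError(f"unknown diagnosis group(s): {sorted(bad_groups)}")
    if not (cohort["pfi_time"] > 0).all():
        raise FormatError("pfi_time must be > 0 for every slide")
    if not cohort["pfi_event"].isin([0, 1]).all():
        raise FormatError("pfi_event must be 0 or 1")
    return cohort


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return validate_cohort_table(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Cell-table I/O
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "id": "id",
    "x": "x",
    "y": "y",
    "cell_class": "cell_class",
    "area": "area",
    "is_pseudo": "is_pseudo",
    "slide_id": "slide_id",
}

_DEFAULT_CLASS_MAP = {c.value: c for c in CellClass}


def read_cell_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    class_map: Mapping[str, CellClass] | None = None,
) -> list[CellRecord]:
    """Read a CSV of segmented nuclei into cell records.

    ``columns`` maps canonical field names (``x``, ``y``, ``cell_class``,
    optionally ``id``/``area``/``is_pseudo``/``slide_id``) to the column names
    actually present, so tables from external segmentation tools can be
    ingested without rewriting the file.  ``class_map`` maps the file's class
    strings onto :class:`CellClass`; unknown strings are rejected, never
    silently defaulted.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    cmap = dict(_DEFAULT_CLASS_MAP)
    if class_map:
        cmap.update(class_map)

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for field_name in ("x", "y", "cell_class"):
        if colmap[field_name] not in df.columns:
            raise FormatError(
                f"cell table {path}: missing mandatory column '{colmap[field_name]}' (field '{field_name}')"
            )

    has = {f: colmap[f] in df.columns for f in colmap}
    records: list[CellRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            x = float(row[colmap["x"]])
            y = float(row[colmap["y"]])
        except (TypeError, ValueError) as exc:
            raise RowError(i, f"unparseable coordinate: {exc}") from exc
        if math.isnan(x) or math.isnan(y):
            raise RowError(i, f"coordinate is NaN ({row[colmap['x']]}, {row[colmap['y']]})")
        raw_class = str(row[colmap["cell_class"]]).strip()
        if raw_class not in cmap:
            raise RowError(i, f"unknown cell class {raw_class!r}")
        area_val = None
        if has["area"]:
            raw_area = str(row[colmap["area"]]).strip()
            if raw_area not in ("", "nan"):
                try:
                    area_val = float(raw_area)
                except ValueError as exc:
                    raise RowError(i, f"unparseable area {raw_area!r}") from exc
        try:
            records.append(
                CellRecord(
                    id=int(float(row[colmap["id"]])) if has["id"] else i,
                    x=x,
                    y=y,
                    cell_class=cmap[raw_class],
                    area=area_val,
                    is_pseudo=(
                        str(row[colmap["is_pseudo"]]).strip().lower() in ("true", "1")
                        if has["is_pseudo"]
                        else False
                    ),
                    slide_id=str(row[colmap["slide_id"]]) if has["slide_id"] else "",
                )
            )
        except ParameterError as exc:
            raise RowError(i, str(exc)) from exc
    return records


def write_cell_table(cells: Sequence[CellRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [c.id for c in cells],
            "x": [c.x for c in cells],
            "y": [c.y for c in cells],
            "cell_class": [c.cell_class.value for c in cells],
            "area": [c.area for c in cells],
            "is_pseudo": [c.is_pseudo for c in cells],
            "slide_id": [c.slide_id for c in cells],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result I/O: per-node CSV + JSON summary sidecar
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def write_results(result: LayerCountResult, path: str | Path) -> None:
    """Write per-node counts as CSV plus a JSON sidecar with the summary."""
    path = Path(path)
    df = pd.DataFrame(
        {"node_id": sorted(result.counts), "layer_count": [result.counts[i] for i in sorted(result.counts)]}
    )
    df.to_csv(path, index=False)
    sidecar = {
        "slide_id": result.slide_id,
        "median_layers": result.median_layers,
        "sd_layers": result.sd_layers,
        "n_inner": result.n_inner,
        "unreachable_count": len(result.unreachable_ids),
        "unreachable_ids": sorted(result.unreachable_ids),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_results(path: str | Path) -> LayerCountResult:
    path = Path(path)
    df = pd.read_csv(path) if path.stat().st_size > 0 else pd.DataFrame(columns=["node_id", "layer_count"])
    counts = {int(r.node_id): int(r.layer_count) for r in df.itertuples(index=False)} if len(df) else {}
    meta = json.loads(_sidecar_path(path).read_text())
    return LayerCountResult.from_counts(
        counts, unreachable_ids=meta.get("unreachable_ids", ()), slide_id=meta.get("slide_id", "")
    )


# ---------------------------------------------------------------------------
# Semantic-map I/O: single-channel PNG + JSON sidecar
# ---------------------------------------------------------------------------

_DEFAULT_PALETTE = {c.value: c for c in SemanticClass}


def read_semantic_map(
    path: str | Path,
    palette: Mapping[int, SemanticClass] | None = None,
    x0: float | None = None,
    y0: float | None = None,
    scale: int | None = None,
) -> SemanticMap:
    """Read a single-channel PNG label image into a :class:`SemanticMap`.

    Geometry (origin, scale) and palette come from the JSON sidecar written by
    :func:`write_semantic_map` when present; explicit arguments override.
    Pixel values outside the palette are rejected.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    meta: dict = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if palette is None:
        if "palette" in meta:
            palette = {int(k): SemanticClass[v] for k, v in meta["palette"].items()}
        else:
            palette = _DEFAULT_PALETTE
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel label image, got shape {arr.shape}")
    bad = set(np.unique(arr).tolist()) - set(palette)
    if bad:
        raise FormatError(f"{path}: pixel value(s) {sorted(bad)} not in palette {sorted(palette)}")
    lut = np.zeros(max(palette) + 1, dtype=np.uint8)
    for value, sem in palette.items():
        lut[value] = sem.value
    return SemanticMap(
        labels=lut[arr],
        x0=float(meta.get("x0", 0.0)) if x0 is None else x0,
        y0=float(meta.get("y0", 0.0)) if y0 is None else y0,
        scale=int(meta.get("scale", 4)) if scale is None else scale,
    )


def write_semantic_map(
    smap: SemanticMap, path: str | Path, palette: Mapping[int, SemanticClass] | None = None
) -> None:
    path = Path(path)
    palette = dict(palette or _DEFAULT_PALETTE)
    inverse = {sem: value for value, sem in palette.items()}
    lut = np.zeros(len(SemanticClass), dtype=np.uint8)
    for sem in SemanticClass:
        if sem in inverse:
            lut[sem.value] = inverse[sem]
        elif sem.value in set(np.unique(smap.labels).tolist()):
            raise FormatError(f"palette has no value for class {sem.name}")
    Image.fromarray(lut[smap.labels.astype(np.uint8)], mode="L").save(path)
    sidecar = {
        "x0": smap.x0,
        "y0": smap.y0,
        "scale": smap.scale,
        "palette": {str(value): sem.name for value, sem in palette.items()},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
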