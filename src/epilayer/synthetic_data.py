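"""Seedable generators of epithelium-like cell tables with known layer number.

The generator emulates the point pattern a segmentation pipeline extracts
from a stratified squamous epithelium: K rows (or rings) of epithelial
nuclei on a hexagonal lattice — the row touching the stroma is the basal
layer — with stroma nuclei beneath, and stratum-corneum / background
pseudo-points above.  A hexagonal (offset-row) lattice is used because its
Delaunay triangulation has no ambiguous cocircular quadruples, so row
adjacency is stable and row count = hop count + 1 exactly.  Positional
jitter, cracks, and intraepithelial lymphocytes provide the departures from
ideal geometry that the counting algorithm must tolerate.

A cohort generator produces slide-level summary tables with group-dependent
thickness and thickness-dependent survival for the statistics stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cell_model import (
    CellClass,
    CellRecord,
    DIAGNOSIS_GROUPS,
    InstanceRecord,
    SemanticClass,
    SemanticMap,
    is_epithelial,
)
from .errors import ParameterError

__all__ = [
    "CrackSpec",
    "EpitheliumSpec",
    "GroupSpec",
    "CohortSpec",
    "generate_epithelium",
    "generate_semantic_fixture",
    "generate_cohort",
]

_ROW_DY = math.sqrt(3) / 2  # vertical pitch of a hex lattice, in units of spacing


@dataclass(frozen=True)
class CrackSpec:
    """Axis-aligned rectangular deletion of epithelial cells.

    ``x_center``/``width`` are 40x pixels in lattice coordinates (before
    jitter); ``depth_fraction`` is the fraction of the epithelial thickness
    removed, measured from the corneum side — 1.0 splits the sheet through
    its full thickness and detaches a fragment.
    """

    x_center: float
    width: float
    depth_fraction: float = 1.0


@dataclass(frozen=True)
class EpitheliumSpec:
    geometry: Literal["strip", "annulus"] = "strip"
    n_layers: int = 5
    cell_spacing: float = 60.0  # 40x px, nucleus scale; far below the 500-px prune
    jitter_sd: float = 0.0      # 40x px
    length: int = 40            # cells along the boundary (columns / ring points)
    cracks: tuple[CrackSpec, ...] = ()
    stroma_rows: int = 2
    corneum_rows: int = 2
    background_rows: int = 2
    lymphocyte_fraction: float = 0.0
    seed: int = 0
    slide_id: str = "synthetic"

    def validate(self) -> None:
        if self.n_layers < 1:
            raise ParameterError(f"n_layers must be >= 1, got {self.n_layers}")
        if not self.cell_spacing > 0:
            raise ParameterError(f"cell_spacing must be > 0, got {self.cell_spacing}")
        if self.jitter_sd < 0:
            raise ParameterError(f"jitter_sd must be >= 0, got {self.jitter_sd}")
        if self.length < 3:
            raise ParameterError(f"length must be >= 3, got {self.length}")
        if not 0 <= self.lymphocyte_fraction < 1:
            raise ParameterError("lymphocyte_fraction must be in [0, 1)")
        for crack in self.cracks:
            if crack.width < 0 or not 0 < crack.depth_fraction <= 1:
                raise ParameterError(f"invalid crack spec {crack}")
        if self.geometry not in ("strip", "annulus"):
            raise ParameterError(f"unknown geometry {self.geometry!r}")
        if min(self.stroma_rows, self.corneum_rows, self.background_rows) < 1:
            raise ParameterError("stroma/corneum/background bands need >= 1 row each")


def _strip_lattice(spec: EpitheliumSpec) -> list[tuple[float, float, float, CellClass, bool, int]]:
    """(x, y, lattice_x, class, is_pseudo, epi_row_from_top) for a flat strip.

    Row order, top (small y) to bottom: background, corneum, K epithelial
    (last = basal), stroma.  Raster convention — the lumen faces up.
    """
    s = spec.cell_spacing
    dy = s * _ROW_DY
    bands: list[tuple[CellClass, int]] = (
        [(CellClass.BACKGROUND, spec.background_rows), (CellClass.CORNEUM, spec.corneum_rows)]
        + [(CellClass.EPITHELIAL_OTHER, spec.n_layers - 1), (CellClass.BASAL, 1)]
        + [(CellClass.STROMA, spec.stroma_rows)]
    )
    pts = []
    r = 0
    epi_row = 0
    for cls, n_rows in bands:
        for _ in range(n_rows):
            y = s + r * dy
            for c in range(spec.length):
                x = s + (c + 0.5 * (r % 2)) * s
                pseudo = cls in (CellClass.BACKGROUND, CellClass.CORNEUM)
                row_idx = epi_row if cls in (CellClass.EPITHELIAL_OTHER, CellClass.BASAL) else -1
                pts.append((x, y, x, cls, pseudo, row_idx))
            if cls in (CellClass.EPITHELIAL_OTHER, CellClass.BASAL):
                epi_row += 1
            r += 1
    return pts


def _annulus_lattice(spec: EpitheliumSpec) -> list[tuple[float, float, float, CellClass, bool, int]]:
    """Same zonation bent into concentric rings: stroma inside, lumen outside.

    Each ring carries as many points as keep the arc pitch at the cell
    spacing (so the lattice stays locally hexagonal at every radius and no
    ring-skipping Delaunay edges arise); ``length`` sets the innermost ring.
    ``lattice_x`` is the arc coordinate used by crack specs.
    """
    s = spec.cell_spacing
    dr = s * _ROW_DY
    n_rings = spec.stroma_rows + spec.n_layers + spec.corneum_rows + spec.background_rows
    r_base = spec.length * s / (2 * math.pi)
    center = r_base + n_rings * dr + s  # keep all coordinates positive
    # ring order, inside out: stroma, basal, epithelial-other, corneum, background
    bands = (
        [(CellClass.STROMA, spec.stroma_rows), (CellClass.BASAL, 1)]
        + [(CellClass.EPITHELIAL_OTHER, spec.n_layers - 1)]
        + [(CellClass.CORNEUM, spec.corneum_rows), (CellClass.BACKGROUND, spec.background_rows)]
    )
    pts = []
    ring = 0
    epi_ring_from_inside = 0
    for cls, n_rings_band in bands:
        for _ in range(n_rings_band):
            radius = r_base + ring * dr
            n = max(3, int(round(2 * math.pi * radius / s)))
            for j in range(n):
                theta = 2 * math.pi * (j + 0.5 * (ring % 2)) / n
                x = center + radius * math.cos(theta)
                y = center + radius * math.sin(theta)
                pseudo = cls in (CellClass.BACKGROUND, CellClass.CORNEUM)
                if cls in (CellClass.BASAL, CellClass.EPITHELIAL_OTHER):
                    # crack depth is measured from the corneum (outer) side
                    row_idx = spec.n_layers - 1 - epi_ring_from_inside
                else:
                    row_idx = -1
                pts.append((x, y, radius * theta, cls, pseudo, row_idx))
            if cls in (CellClass.BASAL, CellClass.EPITHELIAL_OTHER):
                epi_ring_from_inside += 1
            ring += 1
    return pts


def generate_epithelium(spec: EpitheliumSpec) -> tuple[list[CellRecord], dict]:
    """Generate a cell table with known ground-truth layer number.

    Returns the records plus a ground-truth dict with ``n_layers`` and basic
    composition counts.  Deterministic for a fixed spec and seed: identical
    inputs give byte-identical tables.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lattice = _strip_lattice(spec) if spec.geometry == "strip" else _annulus_lattice(spec)

    # cracks: remove epithelial cells in the x-band, outermost rows first
    kept = []
    for x, y, lat_x, cls, pseudo, epi_row in lattice:
        removed = False
        for crack in spec.cracks:
            if epi_row < 0:
                continue
            rows_removed = int(round(crack.depth_fraction * spec.n_layers))
            if epi_row < rows_removed and abs(lat_x - crack.x_center) <= crack.width / 2:
                removed = True
                break
        if not removed:
            kept.append((x, y, cls, pseudo))

    # jitter real nuclei only; pseudo-points are synthesized on a clean grid
    records: list[CellRecord] = []
    classes = [cls for *_xy, cls, _p in kept]
    n_epi = sum(1 for c in classes if is_epithelial(c))
    lymph = np.zeros(len(kept), dtype=bool)
    if spec.lymphocyte_fraction > 0 and n_epi:
        epi_idx = [i for i, (_, _, c, _) in enumerate(kept) if is_epithelial(c)]
        n_pick = int(round(spec.lymphocyte_fraction * len(epi_idx)))
        lymph[rng.choice(epi_idx, size=n_pick, replace=False)] = True
    for i, (x, y, cls, pseudo) in enumerate(kept):
        if spec.jitter_sd > 0 and not pseudo:
            x = max(0.0, x + rng.normal(0, spec.jitter_sd))
            y = max(0.0, y + rng.normal(0, spec.jitter_sd))
        if lymph[i]:
            cls = CellClass.LYMPHOCYTE
        records.append(
            CellRecord(id=i, x=x, y=y, cell_class=cls, is_pseudo=pseudo, slide_id=spec.slide_id)
        )

    truth = {
        "n_layers": spec.n_layers,
        "n_cells": len(records),
        "n_epithelial": sum(1 for rec in records if is_epithelial(rec.cell_class)),
    }
    return records, truth


def generate_semantic_fixture(spec: EpitheliumSpec) -> tuple[SemanticMap, list[InstanceRecord]]:
    """Rasterized label map plus instance detections for the fusion stage.

    Strip geometry only.  The 10x label grid paints the horizontal zonation
    bands (background / corneum / epithelium-other / basal / non-epithelium);
    instance centroids sit at the real-nucleus lattice points (epithelial and
    stroma rows).  Fusing the two then counting layers recovers ``n_layers``.
    """
    spec.validate()
    if spec.geometry != "strip":
        raise ParameterError("semantic fixtures support strip geometry only")
    cells, _ = generate_epithelium(spec)

    s = spec.cell_spacing
    dy = s * _ROW_DY
    # band boundaries in 40x y, halfway between adjacent lattice rows
    def band_edge(row_index: float) -> float:
        return s + (row_index - 0.5) * dy

    y_corneum = band_edge(spec.background_rows)
    y_epi = band_edge(spec.background_rows + spec.corneum_rows)
    y_basal = band_edge(spec.background_rows + spec.corneum_rows + spec.n_layers - 1)
    y_stroma = band_edge(spec.background_rows + spec.corneum_rows + spec.n_layers)
    height_40 = 2 * s + dy * (
        spec.background_rows + spec.corneum_rows + spec.n_layers + spec.stroma_rows
    )
    width_40 = s * (spec.length + 1.5)

    scale = 4
    rows10 = int(math.ceil(height_40 / scale))
    cols10 = int(math.ceil(width_40 / scale))
    yy = (np.arange(rows10) + 0.5) * scale  # pixel centers in 40x coords
    labels = np.full((rows10, cols10), SemanticClass.BACKGROUND.value, dtype=np.uint8)
    labels[(yy >= y_corneum) & (yy < y_epi), :] = SemanticClass.CORNEUM.value
    labels[(yy >= y_epi) & (yy < y_basal), :] = SemanticClass.EPI_OTHER.value
    if spec.n_layers == 1:
        labels[(yy >= y_epi) & (yy < y_stroma), :] = SemanticClass.EPI_BASAL.value
    else:
        labels[(yy >= y_basal) & (yy < y_stroma), :] = SemanticClass.EPI_BASAL.value
    labels[yy >= y_stroma, :] = SemanticClass.NON_EPI.value
    smap = SemanticMap(labels=labels, x0=0.0, y0=0.0, scale=scale)

    instances = [
        InstanceRecord(x=c.x, y=c.y, source_label=c.cell_class.value)
        for c in cells
        if not c.is_pseudo
    ]
    return smap, instances


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_slides: int
    mean_layers: float
    sd_layers: float


@dataclass(frozen=True)
class CohortSpec:
    """Cohort with group-dependent thickness and thickness-dependent survival.

    Per-slide median layer counts are drawn from each group's normal
    distribution (clipped to >= 1).  Progression-free-interval times are
    exponential with log-hazard ``intercept + beta * median_layers``;
    censoring is independent: with probability ``censor_rate`` a slide is
    censored at a uniform fraction of its event time.
    """

    groups: tuple[GroupSpec, ...] = (
        GroupSpec(DIAGNOSIS_GROUPS[0], 45, 8.0, 2.0),
        GroupSpec(DIAGNOSIS_GROUPS[1], 82, 11.0, 2.0),
        GroupSpec(DIAGNOSIS_GROUPS[2], 8, 15.0, 2.0),
    )
    beta: float = 0.15           # log-hazard per layer
    intercept: float = -7.5      # log baseline hazard per day
    censor_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ParameterError("cohort needs at least one group")
        for g in self.groups:
            if g.n_slides < 1:
                raise ParameterError(f"group {g.label}: n_slides must be >= 1")
        if not 0 <= self.censor_rate < 1:
            raise ParameterError("censor_rate must be in [0, 1)")


def generate_cohort(
    spec: CohortSpec, with_cell_tables: bool = False, slide_spec: EpitheliumSpec | None = None
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, list[CellRecord]]]:
    """Generate a slide-level cohort table (optionally with per-slide cells).

    With ``with_cell_tables=True`` each slide also gets a strip cell table
    whose true layer number is the slide's drawn thickness rounded to an
    integer, so the full pipeline can recompute the summaries; ``slide_spec``
    provides the strip geometry template (jitter, length, ...).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    tables: dict[str, list[CellRecord]] = {}
    idx = 0
    for g in spec.groups:
        for _ in range(g.n_slides):
            slide_id = f"slide_{idx:04d}"
            median = float(np.clip(rng.normal(g.mean_layers, g.sd_layers), 1.0, None))
            sd = float(abs(rng.normal(0.2 * median, 0.3)))
            hazard = math.exp(spec.intercept + spec.beta * median)
            t_event = float(rng.exponential(1.0 / hazard))
            censored = rng.uniform() < spec.censor_rate
            time = t_event * rng.uniform() if censored else t_event
            rows.append(
                {
                    "slide_id": slide_id,
                    "median_layers": median,
                    "sd_layers": sd,
                    "diagnosis_group": g.label,
                    "pfi_time": max(time, 1e-3),
                    "pfi_event": 0 if censored else 1,
                }
            )
            if with_cell_tables:
                k = int(np.clip(round(median), 1, None))
                template = slide_spec or EpitheliumSpec()
                tables[slide_id] = generate_epithelium(
                    replace(template, n_layers=k, seed=int(rng.integers(2**31)), slide_id=slide_id)
                )[0]
                rows[-1]["median_layers"] = float(k)
            idx += 1
    cohort = pd.DataFrame(rows)
    return (cohort, tables) if with_cell_tables else cohort
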