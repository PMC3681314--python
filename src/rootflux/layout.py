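"""Minimal-root tissue template and mechanism-specific PIN permeability maps.

The layout is a rectangular "minimal root": mirror-symmetric columns of
cell files (epidermis, cortex, endodermis, pericycle, vascular on each
side of the midline) running shootward from a distal cap of columella
tiers and a quiescent-centre (QC) row.  Cells are axis-aligned
rectangles; every cell is surrounded by a 0.5 µm wall (apoplast).  Cell
lengths are 16 µm in the meristem zone (MZ) and 60 µm in the elongation
zone (EZ).  Coordinates: y is the root axis with the distal tip at 0
and proximal (shootward) increasing; x is the lateral axis.

Permeability maps assign one efflux permeability per cell membrane side
(strong PIN 20 µm/s, weak PIN 5 µm/s, or background 1 µm/s) and an
apolar influx permeability (AUX1/LAX, 20 µm/s everywhere).  Four maps
are provided: ``source_decay`` (strong PIN on all sides, cancelling
polarity), ``unidirectional`` (basal PINs in the central files),
``unidirectional_backengineered`` (apical PINs added at 85% of basal),
and ``reflux_loop`` (rootward pumping in the centre, shootward in the
outer files, and a lateral inward flux through the ground tissue).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from enum import Enum

import numpy as np

__all__ = [
    "CellType",
    "Cell",
    "LayoutConfig",
    "RootLayout",
    "PermeabilityMap",
    "SIDES",
    "P_PIN_STRONG",
    "P_PIN_WEAK",
    "P_BG",
    "P_AUX",
    "MECHANISMS",
    "build_root_layout",
    "assign_pin_map",
    "ablate_cells",
    "scale_permeabilities",
    "set_polarity_ratio",
]

P_PIN_STRONG = 20.0  # µm/s, strong PIN expression
P_PIN_WEAK = 5.0     # µm/s, weak PIN expression
P_BG = 1.0           # µm/s, background efflux without PINs
P_AUX = 20.0         # µm/s, apolar influx (AUX1/LAX + passive)

MECHANISMS = (
    "source_decay",
    "unidirectional",
    "unidirectional_backengineered",
    "reflux_loop",
)

SIDES = ("apical", "basal", "lateral_inner", "lateral_outer")


class CellType(str, Enum):
    VASCULAR = "vascular"
    PERICYCLE = "pericycle"
    ENDODERMIS = "endodermis"
    CORTEX = "cortex"
    EPIDERMIS = "epidermis"
    QUIESCENT_CENTRE = "quiescent_centre"
    COLUMELLA = "columella"


GROUND_TISSUE = (CellType.ENDODERMIS, CellType.CORTEX, CellType.EPIDERMIS)


@dataclass(frozen=True)
class Cell:
    """Axis-aligned rectangular cell footprint."""

    id: int
    cell_type: CellType
    file_index: int      # column index, 0 = leftmost file
    row: int             # axial row index, 0 = most distal
    x0: float
    x1: float
    y0: float
    y1: float
    zone: str            # "distal", "MZ" or "EZ"

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def length(self) -> float:
        return self.y1 - self.y0

    @property
    def centre(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))


@dataclass(frozen=True)
class LayoutConfig:
    """Configuration of the minimal-root template.

    ``half_widths`` lists per-file widths (µm) from the midline outward;
    the full layout mirrors them about the root midline.  The defaults
    follow the minimal-root template: a 3 mm segment, 16 µm MZ cells,
    60 µm EZ cells, 0.5 µm walls, three columella tiers below a QC row
    (a 1200 µm desk-scale segment is a single-parameter change).
    ``reduced=True`` keeps only the vascular and pericycle files plus
    the QC (the template of the unidirectional mechanism).
    """

    segment_length: float = 3000.0
    mz_cell_length: float = 16.0
    ez_cell_length: float = 60.0
    mz_boundary: float = 352.0          # MZ→EZ transition, µm from the tip
    wall_thickness: float = 0.5
    columella_tiers: int = 3
    columella_tier_length: float = 16.0
    qc_length: float = 16.0
    half_widths: tuple[tuple[str, float], ...] = (
        ("vascular", 10.0),
        ("pericycle", 7.0),
        ("endodermis", 9.0),
        ("cortex", 12.0),
        ("epidermis", 10.0),
    )
    reduced: bool = False
    resolution: float = 4.0             # µm/pixel target for the cytosol grid
    interface_walls: bool = True        # sub-grid 0.5 µm wall compartments


@dataclass
class RootLayout:
    """Cell-resolution root geometry.

    ``cells`` hold the live protoplasts; ``obstacles`` hold footprints of
    ablated cells (no-flux regions).  ``file_types`` gives the body cell
    type of each column, left to right.
    """

    cells: list[Cell]
    obstacles: list[Cell]
    width: float
    length: float
    wall_thickness: float
    resolution: float
    interface_walls: bool
    file_edges: list[float]           # column boundaries, len = n_files + 1
    file_types: list[CellType]
    config: LayoutConfig

    @property
    def n_files(self) -> int:
        return len(self.file_types)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def midline(self) -> float:
        return 0.5 * self.width

    def cells_of_type(self, cell_type: CellType | str) -> list[Cell]:
        ct = CellType(cell_type)
        return [c for c in self.cells if c.cell_type is ct]

    def file_of_type(self, cell_type: CellType | str, *, side: str = "left") -> int:
        """Column index of the file of the given body type nearest the
        midline on the requested side ('left' or 'right')."""
        ct = CellType(cell_type)
        idx = [i for i, t in enumerate(self.file_types) if t is ct]
        if not idx:
            raise KeyError(f"no file of type {ct.value!r} in this layout")
        half = self.n_files // 2
        left = [i for i in idx if i < half]
        right = [i for i in idx if i >= half]
        if side == "left" and left:
            return max(left)
        if side == "right" and right:
            return min(right)
        return idx[0]

    def mirrored(self) -> "RootLayout":
        """The left-right reflection of this layout (same ids re-sorted)."""
        def flip(c: Cell, new_id: int) -> Cell:
            return replace(
                c,
                id=new_id,
                x0=self.width - c.x1,
                x1=self.width - c.x0,
                file_index=self.n_files - 1 - c.file_index,
            )
        key = lambda c: (c.row, c.x0)
        cells = sorted((flip(c, 0) for c in self.cells), key=key)
        cells = [replace(c, id=i) for i, c in enumerate(cells)]
        obstacles = sorted((flip(c, 0) for c in self.obstacles), key=key)
        return RootLayout(
            cells=cells,
            obstacles=obstacles,
            width=self.width,
            length=self.length,
            wall_thickness=self.wall_thickness,
            resolution=self.resolution,
            interface_walls=self.interface_walls,
            file_edges=[self.width - e for e in reversed(self.file_edges)],
            file_types=list(reversed(self.file_types)),
            config=self.config,
        )

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        def celld(c: Cell) -> dict:
            d = asdict(c)
            d["cell_type"] = c.cell_type.value
            return d
        return {
            "cells": [celld(c) for c in self.cells],
            "obstacles": [celld(c) for c in self.obstacles],
            "width": self.width,
            "length": self.length,
            "wall_thickness": self.wall_thickness,
            "resolution": self.resolution,
            "interface_walls": self.interface_walls,
            "file_edges": self.file_edges,
            "file_types": [t.value for t in self.file_types],
            "config": asdict(self.config),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RootLayout":
        def cell(cd: dict) -> Cell:
            cd = dict(cd)
            cd["cell_type"] = CellType(cd["cell_type"])
            return Cell(**cd)
        cfg = dict(d["config"])
        cfg["half_widths"] = tuple((t, w) for t, w in cfg["half_widths"])
        return cls(
            cells=[cell(c) for c in d["cells"]],
            obstacles=[cell(c) for c in d["obstacles"]],
            width=d["width"],
            length=d["length"],
            wall_thickness=d["wall_thickness"],
            resolution=d["resolution"],
            interface_walls=d["interface_walls"],
            file_edges=list(d["file_edges"]),
            file_types=[CellType(t) for t in d["file_types"]],
            config=LayoutConfig(**cfg),
        )

    @classmethod
    def from_json(cls, source: str) -> "RootLayout":
        if "\n" not in source and source.endswith(".json"):
            with open(source) as fh:
                return cls.from_dict(json.load(fh))
        return cls.from_dict(json.loads(source))


def _axial_rows(cfg: LayoutConfig) -> list[tuple[float, float, str]]:
    """(y0, y1, zone) for every cell row, distal to proximal."""
    rows: list[tuple[float, float, str]] = []
    y = 0.0
    if not cfg.reduced:
        for _ in range(cfg.columella_tiers):
            rows.append((y, y + cfg.columella_tier_length, "distal"))
            y += cfg.columella_tier_length
    rows.append((y, y + cfg.qc_length, "distal"))  # QC row
    y += cfg.qc_length
    if cfg.segment_length < y + cfg.mz_cell_length:
        raise ValueError("segment_length too short for the distal region")
    # MZ rows of mz_cell_length up to the zone boundary (clamped to the
    # segment: short segments are all-meristem)
    boundary = min(cfg.mz_boundary, cfg.segment_length)
    n_mz = max(1, int(round((boundary - y) / cfg.mz_cell_length)))
    n_mz = min(n_mz, int((cfg.segment_length - y) // cfg.mz_cell_length))
    for _ in range(n_mz):
        rows.append((y, y + cfg.mz_cell_length, "MZ"))
        y += cfg.mz_cell_length
    # EZ rows of ez_cell_length; the last row absorbs the remainder
    remaining = cfg.segment_length - y
    if remaining > 1e-9:
        n_ez = int(remaining // cfg.ez_cell_length)
        ez = [cfg.ez_cell_length] * n_ez
        rem = remaining - n_ez * cfg.ez_cell_length
        if rem > 0.5 * cfg.ez_cell_length or not ez:
            ez.append(rem)
        else:
            ez[-1] += rem
        for h in ez:
            rows.append((y, y + h, "EZ"))
            y += h
    return rows


def build_root_layout(config: LayoutConfig | None = None) -> RootLayout:
    """Generate the minimal-root tissue template.

    The returned layout is mirror-symmetric about the midline, every
    cell is typed, rows are 16 µm long in the MZ and 60 µm in the EZ,
    and (in the full layout) three columella tiers sit distal to a QC
    row whose central cells are quiescent-centre type.
    """
    cfg = config or LayoutConfig()
    if cfg.resolution > cfg.wall_thickness and not cfg.interface_walls:
        raise ValueError(
            f"resolution {cfg.resolution} µm is coarser than the wall "
            f"thickness {cfg.wall_thickness} µm; enable interface_walls "
            "or refine the grid"
        )
    half = list(cfg.half_widths)
    if cfg.reduced:
        half = [(t, w) for t, w in half if t in ("vascular", "pericycle")]
    # columns from left (outer) to right (outer): reversed half, then half
    col_types = [CellType(t) for t, _ in reversed(half)] + [CellType(t) for t, _ in half]
    col_widths = [w for _, w in reversed(half)] + [w for _, w in half]
    edges = [0.0]
    for w in col_widths:
        edges.append(edges[-1] + w)
    width = edges[-1]
    rows = _axial_rows(cfg)

    qc_row = cfg.columella_tiers if not cfg.reduced else 0
    central = (CellType.VASCULAR, CellType.PERICYCLE)
    cells: list[Cell] = []
    cid = 0
    for r, (y0, y1, zone) in enumerate(rows):
        for f, body in enumerate(col_types):
            if not cfg.reduced and r < qc_row:
                ct = CellType.COLUMELLA
            elif r == qc_row and (cfg.reduced or body in central):
                ct = CellType.QUIESCENT_CENTRE
            else:
                ct = body
            cells.append(
                Cell(
                    id=cid, cell_type=ct, file_index=f, row=r,
                    x0=edges[f], x1=edges[f + 1], y0=y0, y1=y1, zone=zone,
                )
            )
            cid += 1
    return RootLayout(
        cells=cells,
        obstacles=[],
        width=width,
        length=rows[-1][1],
        wall_thickness=cfg.wall_thickness,
        resolution=cfg.resolution,
        interface_walls=cfg.interface_walls,
        file_edges=edges,
        file_types=col_types,
        config=cfg,
    )


@dataclass
class PermeabilityMap:
    """Per-membrane-side efflux and influx permeabilities (µm/s).

    Keys are ``(cell_id, side)`` with side one of ``SIDES``.  Every side
    of every live cell is assigned exactly one efflux and one influx
    value; influx is apolar (uniform P_aux) in all shipped maps.
    """

    efflux: dict[tuple[int, str], float]
    influx: dict[tuple[int, str], float]
    mechanism: str = ""

    def copy(self) -> "PermeabilityMap":
        return PermeabilityMap(dict(self.efflux), dict(self.influx), self.mechanism)

    def validate(self, layout: RootLayout) -> None:
        for c in layout.cells:
            for s in SIDES:
                if (c.id, s) not in self.efflux:
                    raise ValueError(f"membrane ({c.id}, {s}) lacks an efflux value")
                if (c.id, s) not in self.influx:
                    raise ValueError(f"membrane ({c.id}, {s}) lacks an influx value")


def assign_pin_map(layout: RootLayout, mechanism: str) -> PermeabilityMap:
    """Tissue-dependent PIN placement for one of the four mechanisms.

    * ``source_decay`` — strong PIN on every side of every cell, so
      polar transport cancels and only diffusion+decay shape the field.
    * ``unidirectional`` — basal (rootward) strong PINs on the vascular
      and pericycle files; everything else background.
    * ``unidirectional_backengineered`` — as above plus apical PINs at
      85% of the basal strength, weakening net downward transport.
    * ``reflux_loop`` — basal strong PINs in vascular/pericycle, apical
      PINs in the outer files (epidermis strong, cortex weak), strong
      lateral inward-facing PINs on the ground tissue (cortex and
      endodermis, weak apical there), apolar strong PINs in the
      columella, background in the QC.
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}; expected one of {MECHANISMS}")
    eff: dict[tuple[int, str], float] = {}
    inf: dict[tuple[int, str], float] = {}
    for c in layout.cells:
        base = {s: P_BG for s in SIDES}
        if mechanism == "source_decay":
            base = {s: P_PIN_STRONG for s in SIDES}
        elif mechanism in ("unidirectional", "unidirectional_backengineered"):
            if c.cell_type in (CellType.VASCULAR, CellType.PERICYCLE):
                base["basal"] = P_PIN_STRONG
                if mechanism == "unidirectional_backengineered":
                    base["apical"] = 0.85 * P_PIN_STRONG
        else:  # reflux_loop
            if c.cell_type in (CellType.VASCULAR, CellType.PERICYCLE):
                base["basal"] = P_PIN_STRONG
            elif c.cell_type is CellType.EPIDERMIS:
                base["apical"] = P_PIN_STRONG
            elif c.cell_type is CellType.CORTEX:
                base["apical"] = P_PIN_WEAK
                base["lateral_inner"] = P_PIN_STRONG
            elif c.cell_type is CellType.ENDODERMIS:
                base["apical"] = P_PIN_WEAK
                base["lateral_inner"] = P_PIN_STRONG
            elif c.cell_type is CellType.COLUMELLA:
                base = {s: P_PIN_STRONG for s in SIDES}
            # QC keeps background on all sides
        for s in SIDES:
            eff[(c.id, s)] = base[s]
            inf[(c.id, s)] = P_AUX
    return PermeabilityMap(eff, inf, mechanism)


def ablate_cells(layout: RootLayout, cell_selector=None) -> RootLayout:
    """Turn the selected cells into no-flux obstacles.

    ``cell_selector`` may be ``None`` (default: the QC cells), a cell
    type / type name, an iterable of cell ids, or a predicate
    ``Cell -> bool``.  The selected protoplast areas become impermeable;
    the surrounding wall ring persists.  Raises on an empty selection.
    """
    if cell_selector is None:
        cell_selector = CellType.QUIESCENT_CENTRE
    if isinstance(cell_selector, (CellType, str)):
        ct = CellType(cell_selector)
        pred = lambda c: c.cell_type is ct
    elif callable(cell_selector):
        pred = cell_selector
    else:
        ids = set(cell_selector)
        pred = lambda c: c.id in ids
    selected = [c for c in layout.cells if pred(c)]
    if not selected:
        raise ValueError("ablation selector matched no cells")
    sel_ids = {c.id for c in selected}
    return RootLayout(
        cells=[c for c in layout.cells if c.id not in sel_ids],
        obstacles=layout.obstacles + selected,
        width=layout.width,
        length=layout.length,
        wall_thickness=layout.wall_thickness,
        resolution=layout.resolution,
        interface_walls=layout.interface_walls,
        file_edges=list(layout.file_edges),
        file_types=list(layout.file_types),
        config=layout.config,
    )


def scale_permeabilities(
    pmap: PermeabilityMap, factor_efflux: float, factor_influx: float = None
) -> PermeabilityMap:
    """Multiply every efflux (and influx) permeability by a factor.

    ``factor_influx`` defaults to ``factor_efflux`` (uniform scaling of
    all membrane permeabilities, as in the robustness scan).
    """
    if factor_influx is None:
        factor_influx = factor_efflux
    if factor_efflux <= 0 or factor_influx <= 0:
        raise ValueError("scaling factors must be > 0")
    return PermeabilityMap(
        {k: v * factor_efflux for k, v in pmap.efflux.items()},
        {k: v * factor_influx for k, v in pmap.influx.items()},
        pmap.mechanism,
    )


def set_polarity_ratio(
    pmap: PermeabilityMap,
    layout: RootLayout,
    lateral_to_apical_factor: float,
    file_types=(CellType.EPIDERMIS, CellType.CORTEX),
) -> PermeabilityMap:
    """Rescale the lateral-inner : apical efflux ratio on ground-tissue files.

    The apical values stay fixed; the lateral-inner efflux of cells of
    the selected types is multiplied by the factor, so the ratio changes
    by exactly that factor.  Only ground-tissue files may be selected.
    """
    if lateral_to_apical_factor <= 0:
        raise ValueError("factor must be > 0")
    types = {CellType(t) for t in (
        file_types if not isinstance(file_types, (str, CellType)) else [file_types]
    )}
    bad = types - set(GROUND_TISSUE)
    if bad:
        raise ValueError(f"not ground-tissue files: {sorted(t.value for t in bad)}")
    new = pmap.copy()
    for c in layout.cells:
        if c.cell_type in types:
            key = (c.id, "lateral_inner")
            new.efflux[key] = pmap.efflux[key] * lateral_to_apical_factor
    return new
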