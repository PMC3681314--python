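"""Scenario runner: mechanism presets, establishment dynamics, influx-cut +
QC-ablation experiments, robustness scans, and threshold zonation.

A :class:`Scenario` bundles a mechanism preset (layout + PIN map +
kinetic parameters), an initial condition, a list of time-stamped
events (influx cut, ablation, permeability rescaling, polarity-ratio
change) and an output schedule.  All runs are deterministic given the
configuration; the recorded seed exists only for provenance.

Mechanism presets (the study conditions)
----------------------------------------
``source_decay``                   full layout, PINs on all sides, QC production,
                                   D_cyt=600 µm²/s, d=1e-6/s, J=1000 a.u./s
``source_decay_fast_decay``        d=0.06/s with production raised by the same
                                   factor (6e4), keeping total content J/d fixed
``source_decay_slow_diffusion``    D_cyt=0.01 µm²/s (wall 15× lower), d=1e-6/s
``unidirectional``                 reduced layout (vascular+pericycle+QC),
                                   basal PINs, shootward influx
``unidirectional_backengineered``  + apical PINs at 85% of basal
``reflux_loop``                    full layout, reflux PIN map, shootward influx
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import (
    CellType,
    LayoutConfig,
    PermeabilityMap,
    RootLayout,
    assign_pin_map,
    ablate_cells,
    build_root_layout,
    scale_permeabilities,
    set_polarity_ratio,
)
from .tissue import (
    ConcentrationField,
    GradientFit,
    LongitudinalProfile,
    TissueSystem,
    TransportParams,
    build_system,
    default_fit_window,
    fit_exponential,
)

__all__ = [
    "MECHANISM_PRESETS",
    "effective_axial_diffusivity",
    "source_decay_vs_1d",
    "Scenario",
    "Event",
    "ScenarioResult",
    "ZonationResult",
    "build_mechanism",
    "run_scenario",
    "scenario_from_dict",
    "run_ablation_experiment",
    "run_robustness_scan",
    "threshold_zonation",
    "width_averaged_profile",
]

_FAST_DECAY = 0.06  # 1/s, back-engineered for λ = 100 µm at D = 600
_SLOW_D = 0.01      # µm²/s, back-engineered for λ = 100 µm at d = 1e-6

MECHANISM_PRESETS: dict[str, dict] = {
    "source_decay": {
        "map": "source_decay",
        "reduced": False,
        "params": TransportParams(influx_mode="qc_source"),
    },
    "source_decay_fast_decay": {
        "map": "source_decay",
        "reduced": False,
        "params": TransportParams(
            d=_FAST_DECAY,
            J_in=1000.0 * (_FAST_DECAY / 1e-6),  # keeps total content J/d fixed
            influx_mode="qc_source",
        ),
    },
    "source_decay_slow_diffusion": {
        "map": "source_decay",
        "reduced": False,
        "params": TransportParams(
            D_cyt=_SLOW_D, D_wall=_SLOW_D / 15.0, influx_mode="qc_source"
        ),
    },
    "unidirectional": {
        "map": "unidirectional",
        "reduced": True,
        "params": TransportParams(),
    },
    "unidirectional_backengineered": {
        "map": "unidirectional_backengineered",
        "reduced": True,
        "params": TransportParams(),
    },
    "reflux_loop": {
        "map": "reflux_loop",
        "reduced": False,
        "params": TransportParams(proximal_outflow="outer_files"),
    },
}


def build_mechanism(
    mechanism: str,
    layout_config: LayoutConfig | None = None,
    params: TransportParams | None = None,
) -> TissueSystem:
    """Assemble the tissue system for a mechanism preset."""
    if mechanism not in MECHANISM_PRESETS:
        raise ValueError(
            f"unknown mechanism {mechanism!r}; expected one of "
            f"{sorted(MECHANISM_PRESETS)}"
        )
    preset = MECHANISM_PRESETS[mechanism]
    cfg = layout_config or LayoutConfig(reduced=preset["reduced"])
    if cfg.reduced != preset["reduced"]:
        cfg = replace(cfg, reduced=preset["reduced"])
    layout = build_root_layout(cfg)
    pmap = assign_pin_map(layout, preset["map"])
    return build_system(layout, pmap, params or preset["params"])


def effective_axial_diffusivity(
    D_cyt: float,
    D_wall: float,
    P_efflux: float = 20.0,
    P_influx: float = 20.0,
    cell_length: float = 16.0,
    wall_thickness: float = 0.5,
) -> float:
    """Composite axial diffusivity of a file of cells.

    Transport along a file crosses, per cell pitch, the cytosol
    (ℓ/D_cyt), the wall (t/D_wall) and two membranes (1/P each); the
    harmonic composite D_eff = ℓ / (ℓ/D_cyt + t/D_wall + 1/P_eff +
    1/P_aux) is the 1D diffusivity a rod model must use to represent
    the cellularised tissue.  With fast auxin kinetics (D_cyt = 600,
    P = 20) the membranes dominate; with a slow hypothetical morphogen
    (D_cyt = 0.01) the cytosol does and D_eff ≈ D_cyt.
    """
    R = (
        cell_length / D_cyt
        + wall_thickness / D_wall
        + 1.0 / P_efflux
        + 1.0 / P_influx
    )
    return cell_length / R


def source_decay_vs_1d(
    variant: str = "source_decay_slow_diffusion",
    layout_config: LayoutConfig | None = None,
    window: tuple[float, float] = (16.0, 350.0),
) -> dict:
    """Cross-validate the tissue source-decay run against its 1D rod model.

    Runs the tissue simulation to steady state, width-averages it, and
    compares with the closed-form rod solution (production band over
    the QC row at the distal end) using the documented 1D reduction:
    mean concentration over the total compartment volume, rod
    cross-section W_eff = total volume / length, composite effective
    diffusivity, and the full influx J as the band source.  Returns the
    relative L2 deviation over the window plus both profiles.
    """
    from .analytic import steady_state_band_source

    cfg = layout_config or LayoutConfig(columella_tiers=0)
    if cfg.columella_tiers != 0:
        raise ValueError(
            "the 1D comparison places the production band at the distal "
            "end; use a layout without columella tiers"
        )
    system = build_mechanism(variant, cfg)
    par = system.params
    steady, _ = system.run_to_steady_state()
    prof = width_averaged_profile(steady)
    L = system.layout.length
    W_eff = float(system.volumes.sum()) / L
    D_eff = effective_axial_diffusivity(
        par.D_cyt,
        par.D_wall,
        cell_length=cfg.mz_cell_length,
        wall_thickness=cfg.wall_thickness,
    )
    band = cfg.qc_length
    pred = steady_state_band_source(
        D_eff, par.d, par.J_in / W_eff, L, band, prof.positions
    )
    sel = (prof.positions >= window[0]) & (prof.positions <= window[1])
    rel_l2 = float(
        np.linalg.norm(prof.concentrations[sel] - pred[sel]) / np.linalg.norm(pred[sel])
    )
    return {
        "rel_l2": rel_l2,
        "profile": prof,
        "prediction": pred,
        "D_eff": D_eff,
        "W_eff": W_eff,
        "window": window,
    }


@dataclass(frozen=True)
class Event:
    """A time-stamped intervention applied atomically during a run.

    kind ∈ {"cut_influx", "ablate", "rescale_permeabilities",
    "set_polarity_ratio"}; ``payload`` carries the selector/factor.
    """

    time: float
    kind: str
    payload: dict = field(default_factory=dict)

    _KINDS = ("cut_influx", "ablate", "rescale_permeabilities", "set_polarity_ratio")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.time < 0:
            raise ValueError("event time must be >= 0")


@dataclass
class Scenario:
    """Mechanism + layout + parameters + events + output schedule."""

    mechanism: str
    layout_config: LayoutConfig | None = None
    params: TransportParams | None = None
    initial: str = "zero"                 # "zero" or "steady"
    events: list[Event] = field(default_factory=list)
    output_times: list[float] = field(default_factory=list)
    profile_files: tuple[str, ...] = ("vascular",)
    dt: float = 5.0
    seed: int | None = None               # recorded only; runs are deterministic

    def validate(self) -> None:
        if not self.output_times:
            raise ValueError("output schedule must be non-empty")
        if list(self.output_times) != sorted(self.output_times):
            raise ValueError("output_times must be sorted")
        if [e.time for e in self.events] != sorted(e.time for e in self.events):
            raise ValueError("events must be sorted by time")
        if self.initial not in ("zero", "steady"):
            raise ValueError(f"unknown initial condition {self.initial!r}")


@dataclass
class ScenarioResult:
    """Time-indexed outputs of one scenario run."""

    times: list[float]
    fields: list[ConcentrationField]
    profiles: list[dict[str, LongitudinalProfile]]
    fits: list[dict[str, GradientFit | None]]
    scenario: Scenario


def _apply_event(
    system: TissueSystem, fld: ConcentrationField, ev: Event
) -> tuple[TissueSystem, ConcentrationField]:
    layout, pmap, params = system.layout, system.pmap, system.params
    if ev.kind == "cut_influx":
        params = replace(params, J_in=0.0)
        new = build_system(layout, pmap, params)
        return new, new.field_from(fld.values, fld.time)
    if ev.kind == "ablate":
        selector = ev.payload.get("selector", None)
        new_layout = ablate_cells(layout, selector)
        keep = {c.id for c in new_layout.cells}
        new_map = PermeabilityMap(
            {k: v for k, v in pmap.efflux.items() if k[0] in keep},
            {k: v for k, v in pmap.influx.items() if k[0] in keep},
            pmap.mechanism,
        )
        new = build_system(new_layout, new_map, params)
        return new, new.map_field(fld)
    if ev.kind == "rescale_permeabilities":
        new_map = scale_permeabilities(
            pmap, ev.payload["factor_efflux"], ev.payload.get("factor_influx")
        )
        new = build_system(layout, new_map, params)
        return new, new.field_from(fld.values, fld.time)
    # set_polarity_ratio
    new_map = set_polarity_ratio(
        pmap,
        layout,
        ev.payload["factor"],
        ev.payload.get("file_types", (CellType.EPIDERMIS, CellType.CORTEX)),
    )
    new = build_system(layout, new_map, params)
    return new, new.field_from(fld.values, fld.time)


def scenario_from_dict(d: dict) -> Scenario:
    """Build a Scenario from a plain (YAML/JSON-loaded) mapping.

    Recognised keys: mechanism (required), initial, output_times
    (required), profile_files, dt, seed, segment_length / reduced /
    layout (LayoutConfig fields), params (TransportParams fields),
    events (list of {time, kind, ...payload}).  Unknown keys raise,
    naming the offending key.
    """
    d = dict(d)
    known = {
        "mechanism", "initial", "output_times", "profile_files", "dt",
        "seed", "layout", "segment_length", "params", "events",
    }
    for key in d:
        if key not in known:
            raise ValueError(f"unknown scenario key {key!r}")
    if "mechanism" not in d:
        raise ValueError("scenario config must name a 'mechanism'")
    if d["mechanism"] not in MECHANISM_PRESETS:
        raise ValueError(
            f"unknown mechanism {d['mechanism']!r}; expected one of "
            f"{sorted(MECHANISM_PRESETS)}"
        )
    layout_kwargs = dict(d.get("layout") or {})
    if "segment_length" in d:
        layout_kwargs["segment_length"] = float(d["segment_length"])
    layout_config = LayoutConfig(**layout_kwargs) if layout_kwargs else None
    params = None
    if d.get("params"):
        base = MECHANISM_PRESETS[d["mechanism"]]["params"]
        params = replace(base, **d["params"])
    events = []
    for ed in d.get("events", []):
        ed = dict(ed)
        t = float(ed.pop("time"))
        kind = ed.pop("kind")
        events.append(Event(t, kind, ed))
    return Scenario(
        mechanism=d["mechanism"],
        layout_config=layout_config,
        params=params,
        initial=d.get("initial", "zero"),
        events=events,
        output_times=[float(t) for t in d.get("output_times", [])],
        profile_files=tuple(d.get("profile_files", ("vascular",))),
        dt=float(d.get("dt", 5.0)),
        seed=d.get("seed"),
    )


def run_scenario(scenario: Scenario) -> ScenarioResult:
    """Run a scenario: deterministic, events applied atomically at their
    times, outputs recorded at every scheduled time.

    Validation happens before any stepping: a malformed schedule or an
    ablation selector that resolves to no cells fails fast.
    """
    scenario.validate()
    system = build_mechanism(scenario.mechanism, scenario.layout_config, scenario.params)
    for ev in scenario.events:  # validate selectors before the run starts
        if ev.kind == "ablate":
            ablate_cells(system.layout, ev.payload.get("selector", None))

    if scenario.initial == "steady":
        fld, _ = system.run_to_steady_state()
        fld = ConcentrationField(fld.values, 0.0, system)
    else:
        fld = system.zero_field()

    pending = list(scenario.events)
    out_times: list[float] = []
    out_fields: list[ConcentrationField] = []
    out_profiles: list[dict] = []
    out_fits: list[dict] = []

    def record(f: ConcentrationField) -> None:
        profs = {name: system.extract_profile(f, name) for name in scenario.profile_files}
        fits = {}
        for name, prof in profs.items():
            try:
                fits[name] = fit_exponential(prof, default_fit_window(prof))
            except ValueError:
                fits[name] = None
        out_times.append(f.time)
        out_fields.append(f)
        out_profiles.append(profs)
        out_fits.append(fits)

    for t_out in scenario.output_times:
        while pending and pending[0].time <= t_out:
            ev = pending.pop(0)
            if ev.time > fld.time + 1e-9:
                fld = system.simulate(fld, [ev.time], dt=scenario.dt)[-1]
            system, fld = _apply_event(system, fld, ev)
        if t_out > fld.time + 1e-9:
            fld = system.simulate(fld, [t_out], dt=scenario.dt)[-1]
        record(fld)
    return ScenarioResult(out_times, out_fields, out_profiles, out_fits, scenario)


def run_ablation_experiment(
    mechanism: str,
    params: TransportParams | None = None,
    layout_config: LayoutConfig | None = None,
    *,
    output_times=(60.0, 300.0, 600.0, 1200.0),
    dt: float = 5.0,
) -> dict:
    """Influx cut + QC ablation from the steady state.

    At t = 0 the influx/production is switched off and the QC cells —
    the cells containing (or adjacent to) the maximum — become no-flux
    obstacles.  Returns the time series of fields plus a per-cell
    summary: the maximum fold-change of each cell's mean concentration
    after the event, and the cells just above the ablated region whose
    concentration *rises* (fold-change > 1), the signature response of
    the reflux loop.
    """
    scenario = Scenario(
        mechanism=mechanism,
        layout_config=layout_config,
        params=params,
        initial="steady",
        events=[
            Event(0.0, "cut_influx"),
            Event(0.0, "ablate", {"selector": CellType.QUIESCENT_CENTRE}),
        ],
        output_times=list(output_times),
        dt=dt,
    )
    system0 = build_mechanism(mechanism, scenario.layout_config, params)
    steady, _ = system0.run_to_steady_state()
    initial_means = steady.cell_means()
    initial_total = steady.total_mass

    result = run_scenario(scenario)
    surviving = result.fields[-1].system.layout.cells
    max_fold: dict[int, float] = {c.id: 0.0 for c in surviving}
    for f in result.fields:
        means = f.cell_means()
        for cid, m in means.items():
            base = initial_means[cid]
            if base > 0:
                max_fold[cid] = max(max_fold[cid], m / base)
    ablated = system0.layout.cells_of_type(CellType.QUIESCENT_CENTRE)
    y_abl = max(c.y1 for c in ablated)
    increased = sorted(
        cid for cid, fc in max_fold.items() if fc > 1.0 + 1e-9
    )
    cell_by_id = {c.id: c for c in surviving}
    increased_above = [
        cid for cid in increased
        if cell_by_id[cid].y0 >= y_abl - 1e-9 and cell_by_id[cid].y0 <= y_abl + 64
    ]
    return {
        "result": result,
        "initial_total_mass": initial_total,
        "final_total_mass": result.fields[-1].total_mass,
        "max_fold_change": max_fold,
        "increased_cells": increased,
        "increased_cells_above_ablation": increased_above,
        "ablation_top": y_abl,
    }


def run_robustness_scan(
    factors,
    knob: str = "uniform_permeability",
    *,
    mechanism: str = "reflux_loop",
    layout_config: LayoutConfig | None = None,
    params: TransportParams | None = None,
    profile_file: str = "epidermis",
) -> pd.DataFrame:
    """Steady-state robustness of the reflux gradient.

    ``knob="uniform_permeability"`` multiplies every efflux permeability
    (PIN-mediated and background alike) by each factor while the influx
    carrier permeability and the net influx from the shoot are held
    constant — the defaults sit at the biophysical maximum, so the
    scan spans downward; ``knob="polarity_ratio"`` rescales the
    lateral:apical efflux ratio of the epidermis+cortex files.  One
    steady-state run per factor; returns a table
    (factor, lambda_fit, C_max) sorted by factor.  λ is fitted on the
    distal window [100, 300] µm of the epidermal profile, the region
    the loop controls, so the same window is compared across factors.
    """
    if knob not in ("uniform_permeability", "polarity_ratio"):
        raise ValueError(f"unknown knob {knob!r}")
    factors = sorted(float(f) for f in factors)
    if any(f <= 0 for f in factors):
        raise ValueError("scan factors must be > 0")
    base = build_mechanism(mechanism, layout_config, params)
    rows = []
    for f in factors:
        if f == 1.0:
            pmap = base.pmap
        elif knob == "uniform_permeability":
            pmap = scale_permeabilities(base.pmap, f, 1.0)
        else:
            pmap = set_polarity_ratio(base.pmap, base.layout, f)
        system = build_system(base.layout, pmap, base.params)
        steady, _ = system.run_to_steady_state()
        prof = system.extract_profile(steady, profile_file)
        fit = fit_exponential(prof, (100.0, 300.0))
        rows.append(
            {
                "factor": f,
                "lambda_fit": fit.lambda_fit,
                "C_max": float(np.max(steady.values)),
            }
        )
    return pd.DataFrame(rows).sort_values("factor").reset_index(drop=True)


@dataclass
class ZonationResult:
    """Zone boundaries read off a profile by concentration thresholds."""

    thresholds: tuple[float, ...]
    boundaries: tuple[float | None, ...]   # most proximal x with C >= threshold
    labels: tuple[str, ...]


def threshold_zonation(profile: LongitudinalProfile, thresholds) -> ZonationResult:
    """Positional information by the French-flag rule.

    For each threshold (strictly decreasing) the boundary is the most
    proximal position where the concentration still reaches the
    threshold, linearly interpolated between samples.  A threshold
    above the profile maximum yields an empty zone (boundary ``None``),
    not an error.
    """
    th = [float(t) for t in thresholds]
    if any(b >= a for a, b in zip(th, th[1:])):
        raise ValueError("thresholds must be strictly decreasing")
    if np.any(profile.concentrations < 0):
        raise ValueError("profile must be non-negative")
    x = profile.positions
    c = profile.concentrations
    boundaries: list[float | None] = []
    for t in th:
        above = c >= t
        if not above.any():
            boundaries.append(None)
            continue
        i = int(np.max(np.nonzero(above)))
        if i == len(x) - 1 or c[i] == t:
            boundaries.append(float(x[i]))
        else:
            # crossing between samples i (>= t) and i+1 (< t)
            f = (c[i] - t) / (c[i] - c[i + 1])
            boundaries.append(float(x[i] + f * (x[i + 1] - x[i])))
    labels = [f">= {t:g}" for t in th] + [f"< {th[-1]:g}"]
    return ZonationResult(tuple(th), tuple(boundaries), tuple(labels))


def width_averaged_profile(
    fld: ConcentrationField, *, include_walls: bool = True
) -> LongitudinalProfile:
    """Laterally averaged axial concentration profile.

    One bin per cell row; each bin's value is total mass over total
    compartment volume in that row (wall faces included by default,
    horizontal faces split between adjacent rows).  This is the 1D
    reduction used to compare tissue runs with the rod model: the
    matching rod cross-section is W_eff = total volume / length.
    """
    system = fld.system
    lay = system.layout
    edges = sorted({c.y0 for c in lay.cells} | {c.y1 for c in lay.cells})
    edges = np.asarray(edges)
    centres = 0.5 * (edges[:-1] + edges[1:])
    mass = np.zeros(len(centres))
    volume = np.zeros(len(centres))

    def bin_of(y: float) -> int:
        return int(np.clip(np.searchsorted(edges, y, side="right") - 1, 0, len(centres) - 1))

    for k in range(system.n_pixels):
        x0, x1, y0, y1 = system.pixel_box[k]
        b = bin_of(0.5 * (y0 + y1))
        mass[b] += system.volumes[k] * fld.values[k]
        volume[b] += system.volumes[k]
    if include_walls:
        for j, (orient, pos, a0, a1) in enumerate(system._face_geom):
            k = system.n_pixels + j
            if orient == "v":
                targets = [(bin_of(0.5 * (a0 + a1)), 1.0)]
            else:
                lo = bin_of(pos - 1e-9)
                hi = bin_of(pos + 1e-9)
                targets = [(lo, 0.5), (hi, 0.5)] if lo != hi else [(lo, 1.0)]
            for b, wgt in targets:
                mass[b] += wgt * system.volumes[k] * fld.values[k]
                volume[b] += wgt * system.volumes[k]
    keep = volume > 0
    return LongitudinalProfile(
        centres[keep], mass[keep] / volume[keep], "width_average"
    )
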