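"""Finite-volume auxin transport on a cell-resolution root layout.

Compartments
------------
* **Cytosol pixels** — each cell footprint is subdivided into an
  nx × ny grid of well-mixed pixels (target size ``layout.resolution``,
  µm).  Neighbouring pixels inside a cell exchange by diffusion with
  ``D_cyt``.
* **Wall (apoplast) faces** — every shared face between two cell
  footprints (and every cell face on the domain boundary) carries one
  sub-grid wall compartment of nominal thickness 0.5 µm.  Wall
  compartments meeting at cell corners exchange by diffusion with
  ``D_wall``, forming a connected apoplast network.

Membrane flux between a boundary pixel and its wall face follows the
carrier law: the outward flux density is ``P_efflux·C_in − P_aux·C_out``
(µm/s × a.u./µm²), with ``P_efflux`` the PIN-dependent efflux
permeability of that cell side and ``P_aux`` the apolar influx
permeability.  First-order decay ``d`` acts everywhere; auxin enters
either as influx over the proximal (shootward) boundary of the
vascular/pericycle files or as production inside the QC cells.

The full system is linear, ``dc/dt = M c + s``; steady states are
obtained by a direct sparse solve and transients by implicit Euler with
a factorised operator (both preserve positivity because M is a
compartment rate matrix), with an explicit-Euler :meth:`TissueSystem.step`
for stepwise use under a hard stability check.  The outer domain
boundary is zero-flux everywhere except the influx segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix, identity
from scipy.sparse.linalg import spsolve, splu

from .layout import CellType, PermeabilityMap, RootLayout, SIDES

__all__ = [
    "TransportParams",
    "ConcentrationField",
    "LongitudinalProfile",
    "GradientFit",
    "TissueSystem",
    "build_system",
    "fit_exponential",
    "detect_elbow",
    "default_fit_window",
]


@dataclass(frozen=True)
class TransportParams:
    """Kinetic parameters of the tissue model.

    D_cyt, D_wall in µm²/s (defaults 600 and its 15-fold reduction 40);
    d in 1/s (default 1e-6, a half-life of 8 days); J_in the total
    auxin input in a.u./s (default 1000); influx_mode selects where it
    enters: ``proximal_vascular_boundary`` (transport mechanisms) or
    ``qc_source`` (source-decay mechanism).

    ``proximal_outflow="outer_files"`` opens the proximal cut of the
    ground-tissue/epidermis files: the shootward stream carried by
    apical PINs leaves the segment there (the root continues into the
    shoot), instead of heaping against an artificial closed end.  The
    default ``"none"`` keeps the whole boundary zero-flux.
    """

    D_cyt: float = 600.0
    D_wall: float = 40.0
    d: float = 1e-6
    J_in: float = 1000.0
    influx_mode: str = "proximal_vascular_boundary"
    proximal_outflow: str = "none"

    def __post_init__(self) -> None:
        if self.D_cyt <= 0 or self.D_wall <= 0:
            raise ValueError("D_cyt and D_wall must be > 0")
        if self.d < 0 or self.J_in < 0:
            raise ValueError("d and J_in must be >= 0")
        if self.influx_mode not in ("proximal_vascular_boundary", "qc_source"):
            raise ValueError(f"unknown influx_mode {self.influx_mode!r}")
        if self.proximal_outflow not in ("none", "outer_files"):
            raise ValueError(f"unknown proximal_outflow {self.proximal_outflow!r}")


@dataclass
class ConcentrationField:
    """Per-compartment concentrations (a.u./µm²) with a time stamp."""

    values: np.ndarray
    time: float
    system: "TissueSystem"

    def copy(self) -> "ConcentrationField":
        return ConcentrationField(self.values.copy(), self.time, self.system)

    @property
    def total_mass(self) -> float:
        return float(self.system.volumes @ self.values)

    def cell_means(self) -> dict[int, float]:
        """Volume-weighted mean cytosol concentration per cell id."""
        out: dict[int, float] = {}
        for cid, idx in self.system.cell_pixels.items():
            v = self.system.volumes[idx]
            out[cid] = float((v * self.values[idx]).sum() / v.sum())
        return out


@dataclass
class LongitudinalProfile:
    """1D cross-section through a named cell file, distal → proximal."""

    positions: np.ndarray      # µm, strictly increasing
    concentrations: np.ndarray
    file: str

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.positions.shape != self.concentrations.shape:
            raise ValueError("positions and concentrations must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class GradientFit:
    """Log-linear exponential fit of a longitudinal profile."""

    lambda_fit: float          # µm
    C0_fit: float              # a.u., extrapolated amplitude at x = 0
    window: tuple[float, float]
    residual: float            # RMS residual of log C
    elbow_position: float | None = None

    @property
    def alpha(self) -> float:
        """Log-slope 1/λ (the lateral-reflux slope parameter)."""
        return 1.0 / self.lambda_fit


class TissueSystem:
    """Assembled transport operator for one (layout, map, params) triple."""

    def __init__(self, layout: RootLayout, pmap: PermeabilityMap, params: TransportParams):
        pmap.validate(layout)
        self.layout = layout
        self.pmap = pmap
        self.params = params
        self._assemble()

    # -- assembly ------------------------------------------------------

    def _assemble(self) -> None:
        lay, pmap, par = self.layout, self.pmap, self.params
        t_wall = lay.wall_thickness
        res = lay.resolution

        # cytosol pixels
        pix_vol: list[float] = []
        pix_cell: list[int] = []
        pix_box: list[tuple[float, float, float, float]] = []
        self.cell_pixels: dict[int, np.ndarray] = {}
        self.cell_grid: dict[int, tuple[int, int]] = {}
        rows_i: list[int] = []
        cols_j: list[int] = []
        vals: list[float] = []
        idx = 0
        pix_index: dict[tuple[int, int, int], int] = {}
        for c in lay.cells:
            nx = max(1, int(round(c.width / res)))
            ny = max(1, int(round(c.length / res)))
            wx, hy = c.width / nx, c.length / ny
            ids = []
            for j in range(ny):
                for i in range(nx):
                    pix_index[(c.id, i, j)] = idx
                    pix_vol.append(wx * hy)
                    pix_cell.append(c.id)
                    pix_box.append(
                        (c.x0 + i * wx, c.x0 + (i + 1) * wx,
                         c.y0 + j * hy, c.y0 + (j + 1) * hy)
                    )
                    ids.append(idx)
                    idx += 1
            self.cell_pixels[c.id] = np.asarray(ids)
            self.cell_grid[c.id] = (nx, ny)
        n_pix = idx

        # wall faces: shared faces of the (rows × files) footprint grid,
        # generated from live cells and obstacles alike
        everything = {(c.row, c.file_index): c for c in lay.cells}
        obstacles = {(c.row, c.file_index): c for c in lay.obstacles}
        grid = dict(everything)
        grid.update(obstacles)
        if not grid:
            raise ValueError("empty layout")
        n_rows = max(r for r, _ in grid) + 1
        n_files = lay.n_files
        live = set(everything)

        face_vol: list[float] = []
        face_geom: list[tuple[str, float, float, float]] = []  # orient, pos, a0, a1
        face_of: dict[tuple, list[int]] = {}

        def new_face(orient: str, pos: float, a0: float, a1: float, nseg: int) -> list[int]:
            # one wall compartment per pixel-aligned segment, so the
            # apoplast is properly resistive along its own length
            ids = []
            edges = np.linspace(a0, a1, nseg + 1)
            for s0, s1 in zip(edges[:-1], edges[1:]):
                ids.append(n_pix + len(face_vol))
                face_vol.append((s1 - s0) * t_wall)
                face_geom.append((orient, pos, float(s0), float(s1)))
            return ids

        def nseg_of(extent: float) -> int:
            return max(1, int(round(extent / res)))

        # faces adjacent to an ablated (obstacle) footprint are sealed:
        # the no-flux region includes the walls the ablated cells owned
        # horizontal faces (between rows, plus bottom/top boundary)
        for f in range(n_files):
            for r in range(n_rows + 1):
                if (r - 1, f) in obstacles or (r, f) in obstacles:
                    continue
                below = grid.get((r - 1, f))
                above = grid.get((r, f))
                if below is None and above is None:
                    continue
                ref = above if above is not None else below
                y = ref.y0 if above is not None else below.y1
                face_of[("h", f, r)] = new_face(
                    "h", y, ref.x0, ref.x1, nseg_of(ref.x1 - ref.x0)
                )
        # vertical faces (between files, plus left/right boundary)
        for r in range(n_rows):
            for f in range(n_files + 1):
                if (r, f - 1) in obstacles or (r, f) in obstacles:
                    continue
                left = grid.get((r, f - 1))
                right = grid.get((r, f))
                if left is None and right is None:
                    continue
                ref = right if right is not None else left
                x = ref.x0 if right is not None else left.x1
                face_of[("v", r, f)] = new_face(
                    "v", x, ref.y0, ref.y1, nseg_of(ref.y1 - ref.y0)
                )
        n_face = len(face_vol)
        n = n_pix + n_face
        self.n_pixels, self.n_faces, self.n = n_pix, n_face, n
        vol = np.concatenate([np.asarray(pix_vol), np.asarray(face_vol)])
        self.volumes = vol
        self.pixel_cell = np.asarray(pix_cell)
        self.pixel_box = np.asarray(pix_box)
        self._face_geom = face_geom
        self._face_of = face_of

        couplings_sym: list[tuple[int, int, float]] = []        # (a, b, g)
        membranes: list[tuple[int, int, float, float, int, str]] = []
        # (pixel, face, g_out=e*P_eff, g_in=e*P_aux, cell_id, side)

        # intracellular diffusion
        for c in lay.cells:
            nx, ny = self.cell_grid[c.id]
            wx, hy = c.width / nx, c.length / ny
            for j in range(ny):
                for i in range(nx):
                    a = pix_index[(c.id, i, j)]
                    if i + 1 < nx:
                        couplings_sym.append(
                            (a, pix_index[(c.id, i + 1, j)], par.D_cyt * hy / wx)
                        )
                    if j + 1 < ny:
                        couplings_sym.append(
                            (a, pix_index[(c.id, i, j + 1)], par.D_cyt * wx / hy)
                        )

        # membrane exchange pixel <-> wall face
        def side_of(cell, orient: str, is_low_side: bool) -> str:
            if orient == "h":
                return "basal" if is_low_side else "apical"
            # is_low_side=True means the face at cell.x0 (left of the cell)
            cx = 0.5 * (cell.x0 + cell.x1)
            faces_midline = (cx > lay.midline) if is_low_side else (cx < lay.midline)
            return "lateral_inner" if faces_midline else "lateral_outer"

        sinks: list[tuple[int, float, int]] = []  # (pixel, g_out, cell_id)
        outer_types = (CellType.ENDODERMIS, CellType.CORTEX, CellType.EPIDERMIS)
        for c in lay.cells:
            nx, ny = self.cell_grid[c.id]
            wx, hy = c.width / nx, c.length / ny
            open_apical = (
                par.proximal_outflow == "outer_files"
                and c.row == n_rows - 1
                and lay.file_types[c.file_index] in outer_types
            )
            for (orient, key, is_low) in (
                ("h", ("h", c.file_index, c.row), True),       # basal face
                ("h", ("h", c.file_index, c.row + 1), False),  # apical face
                ("v", ("v", c.row, c.file_index), True),       # left face
                ("v", ("v", c.row, c.file_index + 1), False),  # right face
            ):
                if key not in face_of:
                    continue  # sealed: the face borders an ablated region
                fids = face_of[key]
                side = side_of(c, orient, is_low)
                p_eff = pmap.efflux[(c.id, side)]
                p_aux = pmap.influx[(c.id, side)]
                if orient == "h":
                    j = 0 if is_low else ny - 1
                    edge = wx
                    pixels = [pix_index[(c.id, i, j)] for i in range(nx)]
                else:
                    i = 0 if is_low else nx - 1
                    edge = hy
                    pixels = [pix_index[(c.id, i, j)] for j in range(ny)]
                if len(fids) != len(pixels):  # pragma: no cover - defensive
                    raise AssertionError("wall segments misaligned with pixel grid")
                # series resistances around the membrane: half-pixel of
                # cytosol (second-order accuracy) and half-wall thickness
                # of apoplast (the physical 0.5 µm crossing)
                h_perp = hy if orient == "h" else wx
                gd_p = par.D_cyt * edge / (0.5 * h_perp)
                gd_w = par.D_wall * edge / (0.5 * t_wall)
                if side == "apical" and open_apical:
                    # open proximal cut: efflux leaves the segment for good
                    for p in pixels:
                        a = edge * p_eff
                        sinks.append((p, a / (1.0 + a / gd_p), c.id))
                    continue
                a = edge * p_eff
                b = edge * p_aux
                delta = 1.0 + a / gd_p + b / gd_w
                for p, fid in zip(pixels, fids):
                    membranes.append((p, fid, a / delta, b / delta, c.id, side))

        # wall-wall diffusion at face junctions
        endpoint_map: dict[tuple[float, float], list[int]] = {}
        for k, (orient, pos, a0, a1) in enumerate(face_geom):
            fid = n_pix + k
            pts = (
                [(a0, pos), (a1, pos)] if orient == "h" else [(pos, a0), (pos, a1)]
            )
            for pt in pts:
                keypt = (round(pt[0], 6), round(pt[1], 6))
                endpoint_map.setdefault(keypt, []).append(fid)
        for flist in endpoint_map.values():
            for a_i in range(len(flist)):
                for b_i in range(a_i + 1, len(flist)):
                    fa, fb = flist[a_i], flist[b_i]
                    la = face_geom[fa - n_pix][3] - face_geom[fa - n_pix][2]
                    lb = face_geom[fb - n_pix][3] - face_geom[fb - n_pix][2]
                    g = par.D_wall * t_wall / (0.5 * (la + lb))
                    couplings_sym.append((fa, fb, g))

        self._membranes = membranes
        self._sinks = sinks
        self._couplings = couplings_sym

        # rate matrix M (dc/dt = M c + s), concentration units a.u./µm²
        def add(i: int, j: int, v: float) -> None:
            rows_i.append(i)
            cols_j.append(j)
            vals.append(v)

        for a, b, g in couplings_sym:
            add(a, a, -g / vol[a])
            add(a, b, g / vol[a])
            add(b, b, -g / vol[b])
            add(b, a, g / vol[b])
        for p, f, g_out, g_in, _cid, _side in membranes:
            add(p, p, -g_out / vol[p])
            add(p, f, g_in / vol[p])
            add(f, f, -g_in / vol[f])
            add(f, p, g_out / vol[f])
        for p, g_out, _cid in sinks:
            add(p, p, -g_out / vol[p])
        if par.d > 0:
            for i in range(n):
                add(i, i, -par.d)
        self.M = coo_matrix((vals, (rows_i, cols_j)), shape=(n, n)).tocsr()

        # influx / production source (a.u./s per compartment, /vol → conc rate)
        s = np.zeros(n)
        self.influx_compartments: np.ndarray
        if par.J_in > 0:
            if par.influx_mode == "qc_source":
                qc = [c for c in lay.cells if c.cell_type is CellType.QUIESCENT_CENTRE]
                if not qc:
                    raise ValueError("qc_source influx but the layout has no QC cells")
                tgt = np.concatenate([self.cell_pixels[c.id] for c in qc])
            else:
                top_faces = []
                for c in lay.cells:
                    if c.cell_type in (CellType.VASCULAR, CellType.PERICYCLE):
                        if (c.row, c.file_index) in live and c.row == n_rows - 1:
                            top_faces.extend(face_of[("h", c.file_index, c.row + 1)])
                if not top_faces:
                    raise ValueError("no proximal vascular/pericycle boundary found")
                tgt = np.asarray(top_faces)
            w = vol[tgt] / vol[tgt].sum()
            s[tgt] = par.J_in * w / vol[tgt]
            self.influx_compartments = tgt
        else:
            self.influx_compartments = np.asarray([], dtype=int)
        self.source = s
        self._diag = self.M.diagonal()
        self._lu_cache: dict[float, object] = {}

    # -- fields --------------------------------------------------------

    def zero_field(self) -> ConcentrationField:
        return ConcentrationField(np.zeros(self.n), 0.0, self)

    def field_from(self, values: np.ndarray, time: float = 0.0) -> ConcentrationField:
        v = np.asarray(values, dtype=float)
        if v.shape != (self.n,):
            raise ValueError(f"expected {self.n} compartments, got {v.shape}")
        if np.any(v < 0) or np.any(~np.isfinite(v)):
            raise ValueError("concentrations must be finite and >= 0")
        return ConcentrationField(v.copy(), time, self)

    def map_field(self, other: ConcentrationField) -> ConcentrationField:
        """Carry a field from another system over matching compartments.

        Used when the geometry changes mid-run (ablation): cytosol
        pixels of surviving cells and wall faces at identical positions
        keep their concentrations; everything else starts at zero.
        Mass inside removed cells is discarded with the cells.
        """
        src = other.system
        v = np.zeros(self.n)
        for cid, idx in self.cell_pixels.items():
            if cid in src.cell_pixels and len(src.cell_pixels[cid]) == len(idx):
                v[idx] = other.values[src.cell_pixels[cid]]
        src_faces = {g: i for i, g in enumerate(src._face_geom)}
        for k, g in enumerate(self._face_geom):
            j = src_faces.get(g)
            if j is not None:
                v[self.n_pixels + k] = other.values[src.n_pixels + j]
        return ConcentrationField(v, other.time, self)

    # -- stepping ------------------------------------------------------

    @property
    def dt_stable(self) -> float:
        """Largest explicit-Euler step that keeps the update positive."""
        return float(1.0 / np.max(-self._diag))

    def step(self, fld: ConcentrationField, dt: float) -> ConcentrationField:
        """One explicit Euler step.  Raises on instability or negativity."""
        if fld.system is not self:
            raise ValueError("field belongs to a different system")
        if dt <= 0:
            raise ValueError("dt must be > 0")
        if dt > self.dt_stable * (1 + 1e-12):
            raise ValueError(
                f"dt={dt:.3g} s exceeds the explicit stability limit "
                f"{self.dt_stable:.3g} s"
            )
        v = fld.values + dt * (self.M @ fld.values + self.source)
        if np.any(v < 0):
            k = int(np.argmin(v))
            raise FloatingPointError(
                f"negative concentration in compartment {k} "
                f"({self.describe_compartment(k)})"
            )
        return ConcentrationField(v, fld.time + dt, self)

    def _lu(self, dt: float):
        lu = self._lu_cache.get(dt)
        if lu is None:
            A = identity(self.n, format="csc") - dt * csc_matrix(self.M)
            lu = splu(A)
            self._lu_cache[dt] = lu
        return lu

    def step_implicit(self, fld: ConcentrationField, dt: float) -> ConcentrationField:
        """One implicit (backward) Euler step; unconditionally stable
        and positivity-preserving."""
        lu = self._lu(dt)
        v = lu.solve(fld.values + dt * self.source)
        v[v < 0] = 0.0  # clip roundoff-level negatives
        return ConcentrationField(v, fld.time + dt, self)

    def simulate(self, fld: ConcentrationField, time_points, dt: float = 5.0):
        """Implicit-Euler trajectory; returns one field per output time."""
        times = np.asarray(list(time_points), dtype=float)
        if np.any(np.diff(times) <= 0) or times[0] < fld.time - 1e-9:
            raise ValueError("time_points must be increasing and >= field time")
        out = []
        cur = fld
        for t in times:
            while cur.time < t - 1e-9:
                step = min(dt, t - cur.time)
                cur = self.step_implicit(cur, step)
            out.append(cur.copy())
        return out

    # -- steady state --------------------------------------------------

    def steady_state(self) -> ConcentrationField:
        """Direct steady-state solve of M c = -s (requires d > 0 or an
        otherwise non-singular operator)."""
        if self.params.d == 0 and self.params.J_in > 0 and not self._sinks:
            raise ValueError(
                "no steady state: constant influx with zero decay in a "
                "closed domain grows without bound"
            )
        c = spsolve(csc_matrix(self.M), -self.source)
        if np.any(~np.isfinite(c)):
            raise FloatingPointError("steady-state solve produced non-finite values")
        c[c < 0] = 0.0
        return ConcentrationField(c, math.inf, self)

    def run_to_steady_state(
        self,
        fld: ConcentrationField | None = None,
        tolerance: float = 1e-5,
        *,
        method: str = "direct",
        dt: float = 30.0,
        max_time: float = 1e7,
    ) -> tuple[ConcentrationField, dict]:
        """Steady state plus convergence diagnostics.

        ``method="direct"`` (default) solves the linear system exactly
        and reports the residual rate.  ``method="timestep"`` integrates
        implicitly until the maximum relative concentration change per
        simulated minute drops below ``tolerance``; non-convergence
        within ``max_time`` simulated seconds raises with diagnostics.
        Note that with the default slow decay (1e-6/s) the absolute
        levels approach equilibrium on the 1/d time-scale (days) even
        though the gradient shape settles within minutes; the direct
        method is therefore the practical default.
        """
        if tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if method == "direct":
            out = self.steady_state()
            rate = self.M @ out.values + self.source
            scale = max(float(np.max(np.abs(out.values))), 1e-300)
            info = {
                "method": "direct",
                "residual_per_min": float(np.max(np.abs(rate)) * 60.0 / scale),
                "simulated_time": None,
            }
            return out, info
        if method != "timestep":
            raise ValueError(f"unknown method {method!r}")
        cur = fld if fld is not None else self.zero_field()
        t0 = cur.time
        while cur.time - t0 < max_time:
            nxt = self.step_implicit(cur, dt)
            denom = np.maximum(np.abs(nxt.values), 1e-300 + np.max(nxt.values) * 1e-12)
            change = float(np.max(np.abs(nxt.values - cur.values) / denom))
            cur = nxt
            if change * (60.0 / dt) < tolerance:
                return cur, {
                    "method": "timestep",
                    "residual_per_min": change * (60.0 / dt),
                    "simulated_time": cur.time - t0,
                }
        raise RuntimeError(
            f"no steady state within {max_time:.3g} s simulated "
            f"(last relative change/min = {change * (60.0 / dt):.3g}, "
            f"tolerance {tolerance:.3g}); with slow decay consider "
            "method='direct' or a larger max_time"
        )

    # -- diagnostics & extraction -------------------------------------

    def describe_compartment(self, k: int) -> str:
        if k < self.n_pixels:
            return f"cytosol pixel of cell {int(self.pixel_cell[k])}"
        orient, pos, a0, a1 = self._face_geom[k - self.n_pixels]
        return f"wall face ({orient}, pos={pos:g}, span=[{a0:g},{a1:g}])"

    def mass_rate(self, fld: ConcentrationField) -> tuple[float, float, float, float]:
        """(d(total)/dt, influx, decay, proximal outflow) in a.u./s.

        The ledger identity d(total)/dt = influx − decay − outflow holds
        to solver precision by construction and is asserted in tests.
        """
        rate = self.M @ fld.values + self.source
        dtot = float(self.volumes @ rate)
        influx = float(self.volumes @ self.source)
        decay = float(self.params.d * (self.volumes @ fld.values))
        outflow = float(sum(g * fld.values[p] for p, g, _ in self._sinks))
        return dtot, influx, decay, outflow

    def membrane_net_flux(self, fld: ConcentrationField, cell_id: int, side: str) -> float:
        """Net outward flux (a.u./s) across one membrane side of a cell."""
        if side not in SIDES:
            raise ValueError(f"unknown side {side!r}")
        tot = 0.0
        for p, f, g_out, g_in, cid, s in self._membranes:
            if cid == cell_id and s == side:
                tot += g_out * fld.values[p] - g_in * fld.values[f]
        return tot

    def compute_flux_field(self, fld: ConcentrationField):
        """Per-coupling fluxes (a.u./s) plus a discrete continuity check.

        Returns a dict with ``diffusive`` (a, b, flow a→b) for every
        symmetric coupling, ``membrane`` (pixel, face, outward flow,
        cell id, side), and ``divergence_residual`` — the maximum
        relative mismatch between the surface flux of each compartment
        and its volume-integrated accumulation + decay − production.
        """
        v = fld.values
        diffusive = [(a, b, g * (v[a] - v[b])) for a, b, g in self._couplings]
        membrane = [
            (p, f, g_out * v[p] - g_in * v[f], cid, s)
            for p, f, g_out, g_in, cid, s in self._membranes
        ]
        net = np.zeros(self.n)
        for a, b, flow in diffusive:
            net[a] -= flow
            net[b] += flow
        for p, f, flow, _cid, _s in membrane:
            net[p] -= flow
            net[f] += flow
        for p, g, _cid in self._sinks:
            net[p] -= g * v[p]
        lhs = net + self.source * self.volumes - self.params.d * self.volumes * v
        rhs = self.volumes * (self.M @ v + self.source)
        scale = max(np.max(np.abs(rhs)), np.max(np.abs(lhs)), 1e-300)
        resid = float(np.max(np.abs(lhs - rhs)) / scale)
        return {"diffusive": diffusive, "membrane": membrane, "divergence_residual": resid}

    def extract_profile(self, fld: ConcentrationField, file_selector) -> LongitudinalProfile:
        """Cytosol concentrations along the midline of a cell file.

        ``file_selector`` is a cell-type name (picks the file of that
        type nearest the midline) or a column index.  Samples are the
        lateral means of each axial pixel row, ordered distal→proximal;
        wall compartments are excluded.
        """
        lay = self.layout
        if isinstance(file_selector, (int, np.integer)):
            fidx = int(file_selector)
            if not 0 <= fidx < lay.n_files:
                raise KeyError(f"file index {fidx} out of range")
            name = f"file{fidx}"
        else:
            fidx = lay.file_of_type(file_selector)
            name = str(CellType(file_selector).value)
        cells = sorted(
            (c for c in lay.cells if c.file_index == fidx), key=lambda c: c.y0
        )
        if not cells:
            raise KeyError(f"file {file_selector!r} has no live cells")
        pos, conc = [], []
        for c in cells:
            nx, ny = self.cell_grid[c.id]
            hy = c.length / ny
            vals = fld.values[self.cell_pixels[c.id]].reshape(ny, nx)
            for j in range(ny):
                pos.append(c.y0 + (j + 0.5) * hy)
                conc.append(float(vals[j].mean()))
        return LongitudinalProfile(np.asarray(pos), np.asarray(conc), name)


def build_system(
    layout: RootLayout, perm_map: PermeabilityMap, params: TransportParams
) -> TissueSystem:
    """Assemble the finite-volume transport operator."""
    return TissueSystem(layout, perm_map, params)


def fit_exponential(
    profile: LongitudinalProfile, window: tuple[float, float]
) -> GradientFit:
    """Log-linear least-squares fit C(x) ≈ C0·e^(−x/λ) on a window.

    Requires at least 5 samples with strictly positive concentrations
    inside the window; raises otherwise.
    """
    x0, x1 = window
    mask = (profile.positions >= x0) & (profile.positions <= x1)
    if mask.sum() < 5:
        raise ValueError(f"window [{x0}, {x1}] contains fewer than 5 samples")
    x = profile.positions[mask]
    c = profile.concentrations[mask]
    if np.any(c <= 0):
        raise ValueError("non-positive concentrations in the fit window")
    slope, intercept = np.polyfit(x, np.log(c), 1)
    if slope >= 0:
        raise ValueError(
            "profile is non-decreasing over the window; no decay length to fit"
        )
    resid = float(np.sqrt(np.mean((np.log(c) - (slope * x + intercept)) ** 2)))
    return GradientFit(
        lambda_fit=float(-1.0 / slope),
        C0_fit=float(np.exp(intercept)),
        window=(float(x0), float(x1)),
        residual=resid,
    )


def detect_elbow(
    profile: LongitudinalProfile,
    *,
    min_points: int = 4,
    slope_contrast: float = 4.0,
) -> float | None:
    """Change-point between the distal exponential and the proximal flat part.

    Fits two straight lines to log C(x) with a scanned breakpoint and
    returns the breakpoint minimising the total squared residual,
    provided the distal slope magnitude exceeds ``slope_contrast`` times
    the proximal one (otherwise the profile is a single exponential and
    ``None`` is returned — absence is a valid result).
    """
    x = profile.positions
    c = profile.concentrations
    ok = c > 0
    x, c = x[ok], c[ok]
    n = len(x)
    if n < 2 * min_points + 1:
        return None
    y = np.log(c)
    best = None  # (sse, k, s1, s2)
    for k in range(min_points, n - min_points):
        s1, i1 = np.polyfit(x[: k + 1], y[: k + 1], 1)
        s2, i2 = np.polyfit(x[k:], y[k:], 1)
        sse = float(
            np.sum((y[: k + 1] - (s1 * x[: k + 1] + i1)) ** 2)
            + np.sum((y[k:] - (s2 * x[k:] + i2)) ** 2)
        )
        if best is None or sse < best[0]:
            best = (sse, k, s1, s2)
    _, k, s1, s2 = best
    if abs(s1) < slope_contrast * abs(s2):
        return None
    return float(x[k])


def default_fit_window(
    profile: LongitudinalProfile, cell_length: float = 16.0
) -> tuple[float, float]:
    """Window from 2 cell lengths above the maximum to the elbow (or end).

    Excludes the accumulation spike at the maximum and the proximal
    influx-driven flat region.
    """
    imax = int(np.argmax(profile.concentrations))
    x_lo = profile.positions[imax] + 2.0 * cell_length
    # cut before any proximal re-rise (influx-driven region fed from the shoot)
    tail = profile.concentrations[imax:]
    imin = imax + int(np.argmin(tail))
    x_cut = profile.positions[imin] if imin > imax else profile.positions[-1]
    mask = (profile.positions >= x_lo) & (profile.positions <= x_cut)
    elbow = None
    if mask.sum() >= 9 and np.all(profile.concentrations[mask] > 0):
        elbow = detect_elbow(
            LongitudinalProfile(
                profile.positions[mask], profile.concentrations[mask], profile.file
            )
        )
    x_hi = elbow if elbow is not None and elbow > x_lo + 2 * cell_length else x_cut
    return (float(x_lo), float(x_hi))
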