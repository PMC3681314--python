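"""Unidirectional polar transport along a file of cells.

A single file of well-mixed cells 0..N transports morphogen towards a
dead end (cell N).  Every cell leaks into both neighbours with rate
``q`` (background permeability); polar efflux carriers on the
tip-facing membrane add ``p`` on top, so the downward rate is p + q.
Cell 0 is held at a fixed concentration C0 (the source).  The dynamics
are

    dC_n/dt = (p+q)·C_{n-1} + q·C_{n+1} - (p+2q)·C_n - d·C_n ,

with dC_0/dt = 0 and dC_N/dt = (p+q)·C_{N-1} - q·C_N - d·C_N at the
dead end.  Without decay the steady state is the geometric profile
C_n = C0·((p+q)/q)^n — an exponential *increase* towards the dead end
("heaping up") with characteristic length 1/ln((p+q)/q) cell lengths.
With decay, the per-cell ratio R_n = C_n/C_{n-1} interpolates between
an influx-driven asymptote far from the dead end and (p+q)/q near it.

p and q are first-order exchange rates between cell compartments (the
membrane permeability in µm/s times membrane area over cell volume is
absorbed into the constant); every reported ratio and λ-in-cells
depends only on p/q and d/q and is independent of that scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded
from scipy.sparse import diags

__all__ = [
    "CellFileParams",
    "CellFileState",
    "equilibrium_ratio",
    "characteristic_length_cells",
    "equilibrium_profile",
    "log10_equilibrium_profile",
    "steady_ratios_with_decay",
    "steady_profile_with_decay",
    "asymptotic_source_ratio",
    "simulate_cellfile",
]


@dataclass(frozen=True)
class CellFileParams:
    """Parameters of the unidirectional cell-file model.

    p : additional polar (tip-ward) efflux rate; q : background leakage
    rate (both directions, same units as p); d : decay rate 1/s (0
    allowed); N : number of cells beyond the source cell; C0 : fixed
    source-cell concentration; cell_length : µm per cell.
    """

    p: float
    q: float
    d: float = 0.0
    N: int = 60
    C0: float = 1.0
    cell_length: float = 16.0

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError(f"q must be > 0, got {self.q}")
        if self.p < 0:
            raise ValueError(f"p must be >= 0, got {self.p}")
        if self.d < 0:
            raise ValueError(f"d must be >= 0, got {self.d}")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.C0 < 0:
            raise ValueError(f"C0 must be >= 0, got {self.C0}")


@dataclass
class CellFileState:
    """Concentrations of cells 0..N at one time point."""

    concentrations: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)


def equilibrium_ratio(p: float, q: float) -> float:
    """Per-cell concentration ratio (p+q)/q at the no-decay equilibrium."""
    if q == 0:
        raise ZeroDivisionError("q = 0: equilibrium ratio is undefined")
    if q < 0 or p < 0:
        raise ValueError("p and q must be non-negative")
    return (p + q) / q


def characteristic_length_cells(
    p: float, q: float, cell_length: float = 16.0
) -> tuple[float, float]:
    """Characteristic length λ = 1/ln((p+q)/q), in (cells, µm).

    Depends only on p/q; raises :class:`ZeroDivisionError` via the ratio
    when q = 0 and ValueError when p = 0 (flat profile, infinite λ).
    """
    r = equilibrium_ratio(p, q)
    if p == 0:
        raise ValueError("p = 0: profile is flat, characteristic length infinite")
    lam_cells = 1.0 / math.log(r)
    return lam_cells, lam_cells * cell_length


def log10_equilibrium_profile(params: CellFileParams) -> np.ndarray:
    """log10 of the no-decay equilibrium C_n = C0·((p+q)/q)^n, cells 0..N.

    Computed in log space so that files with large per-cell ratios
    (e.g. 20^15 ≈ 3×10^19) never overflow.
    """
    if params.C0 <= 0:
        raise ValueError("C0 must be > 0 for a log profile")
    n = np.arange(params.N + 1)
    return math.log10(params.C0) + n * math.log10(equilibrium_ratio(params.p, params.q))


def equilibrium_profile(params: CellFileParams) -> np.ndarray:
    """No-decay equilibrium concentrations C_n = C0·((p+q)/q)^n, cells 0..N.

    May overflow to inf for very long files with large ratios; use
    :func:`log10_equilibrium_profile` for those.
    """
    n = np.arange(params.N + 1)
    with np.errstate(over="ignore"):
        return params.C0 * equilibrium_ratio(params.p, params.q) ** n.astype(float)


def steady_ratios_with_decay(params: CellFileParams) -> np.ndarray:
    """Steady-state consecutive ratios R_n = C_n/C_{n-1}, n = 1..N, with decay.

    Backward recursion from the dead end: the steady state of the
    dead-end row gives R_N = (p+q)/(q+d), and the interior rows give

        R_n = (p+q) / (p + 2q + d - q·R_{n+1}) ,

    which is algebraically equivalent to the nested-sum form but
    numerically stable.  With d = 0 every R_n equals (p+q)/q.
    """
    p, q, d, N = params.p, params.q, params.d, params.N
    if N < 1:
        raise ValueError("N must be >= 1")
    R = np.empty(N + 1)
    R[0] = np.nan  # R_0 undefined (cell -1 does not exist)
    R[N] = (p + q) / (q + d)
    for n in range(N - 1, 0, -1):
        R[n] = (p + q) / (p + 2.0 * q + d - q * R[n + 1])
    return R[1:]


def steady_profile_with_decay(params: CellFileParams, *, log10: bool = False) -> np.ndarray:
    """Steady-state concentrations reconstructed from the ratio recursion."""
    R = steady_ratios_with_decay(params)
    if log10:
        if params.C0 <= 0:
            raise ValueError("C0 must be > 0 for a log profile")
        return math.log10(params.C0) + np.concatenate(([0.0], np.cumsum(np.log10(R))))
    with np.errstate(over="ignore"):
        return params.C0 * np.concatenate(([1.0], np.cumprod(R)))


def asymptotic_source_ratio(p: float, q: float, d: float, *, simplified: bool = False) -> float:
    """Far-from-the-dead-end steady ratio of the decaying cell file.

    Closed form R = (p + d + 2q − sqrt((p+d)² + 4dq)) / (2q); the fixed
    point of the interior recursion.  With ``simplified=True`` returns
    the q ≪ p approximation p/(p+d).  d = 0 gives exactly 1 (the
    influx-driven region is flat without decay).
    """
    if q <= 0:
        raise ValueError("q must be > 0")
    if simplified:
        return p / (p + d)
    if d == 0:
        return 1.0
    return (p + d + 2.0 * q - math.sqrt((p + d) ** 2 + 4.0 * d * q)) / (2.0 * q)


def _rate_matrix(params: CellFileParams):
    """Tridiagonal rate matrix for cells 1..N (cell 0 fixed) and source term."""
    p, q, d, N = params.p, params.q, params.d, params.N
    lower = np.full(N - 1, p + q)          # from cell n-1
    upper = np.full(N - 1, q)              # from cell n+1
    main = np.full(N, -(p + 2.0 * q) - d)
    main[-1] = -q - d                      # dead end: no downward efflux
    b = np.zeros(N)
    b[0] = (p + q) * params.C0             # inflow from the fixed source cell
    return lower, main, upper, b


def steady_state_ode(params: CellFileParams) -> np.ndarray:
    """Steady state of the ODE system by direct tridiagonal solve (cells 0..N).

    Steep files are badly conditioned (the solution spans ratio^N), so
    the solve is polished with two steps of iterative refinement using
    extended-precision residuals; per-cell relative accuracy is then
    limited by ratio^N · 1e-19 (≈1e-8 for a 20-fold ratio over 8 cells).
    """
    lower, main, upper, b = _rate_matrix(params)
    N = params.N
    ab = np.zeros((3, N))
    ab[0, 1:] = upper
    ab[1] = main
    ab[2, :-1] = lower
    c = solve_banded((1, 1), ab, -b)
    lo, mn, up, bl = (a.astype(np.longdouble) for a in (lower, main, upper, b))
    for _ in range(2):
        cl = c.astype(np.longdouble)
        r = -bl - mn * cl
        r[:-1] -= up * cl[1:]
        r[1:] -= lo * cl[:-1]
        c = c + solve_banded((1, 1), ab, r.astype(float))
    return np.concatenate(([params.C0], c))


def simulate_cellfile(
    params: CellFileParams,
    initial_state: CellFileState | np.ndarray | None,
    time_points,
) -> list[CellFileState]:
    """Integrate the cell-file ODEs, returning one state per output time.

    Cell 0 is held at C0 throughout.  Uses a stiff implicit integrator
    (BDF) with the analytic tridiagonal Jacobian; integration failures
    are raised, never silently truncated.
    """
    N = params.N
    if initial_state is None:
        c0 = np.zeros(N + 1)
        c0[0] = params.C0
    else:
        arr = initial_state.concentrations if isinstance(initial_state, CellFileState) else initial_state
        c0 = np.array(arr, dtype=float)
        if c0.shape != (N + 1,):
            raise ValueError(f"initial state must have {N + 1} cells")
        if np.any(c0 < 0):
            raise ValueError("initial concentrations must be >= 0")
        c0[0] = params.C0
    times = np.asarray(list(time_points), dtype=float)
    if times.size == 0 or np.any(np.diff(times) < 0) or times[0] < 0:
        raise ValueError("time_points must be non-empty, non-negative, non-decreasing")

    lower, main, upper, b = _rate_matrix(params)
    jac = diags([lower, main, upper], offsets=[-1, 0, 1], format="csc")

    def rhs(_t, y):
        out = main * y
        out[:-1] += upper * y[1:]
        out[1:] += lower * y[:-1]
        return out + b

    t_end = float(times[-1]) if times[-1] > 0 else 0.0
    if t_end == 0.0:
        return [CellFileState(c0.copy(), float(t)) for t in times]
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        c0[1:],
        method="BDF",
        jac=jac,
        t_eval=times[times > 0],
        rtol=1e-8,
        atol=1e-12 * max(params.C0, 1.0),
    )
    if not sol.success:
        raise RuntimeError(f"stiff integrator failed: {sol.message}")
    states = []
    i = 0
    for t in times:
        if t == 0.0:
            states.append(CellFileState(c0.copy(), 0.0))
        else:
            conc = np.concatenate(([params.C0], np.maximum(sol.y[:, i], 0.0)))
            states.append(CellFileState(conc, float(t)))
            i += 1
    return states
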