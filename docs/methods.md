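# Methods

## Scope and model hierarchy

The package treats one morphogen (auxin unless stated otherwise) at
three levels of description:

1. **Analytic rod** (`rootflux.analytic`): the 1D source-decay PDE
   `∂C/∂t = D C'' − d C` with an influx boundary at the distal end and
   zero flux at the proximal end, its closed-form steady states, and
   derived metrics (characteristic length λ = √(D/d), maximum
   C₀ = J/√(Dd), Thiele modulus L/λ, RMS travel √(2D/d), diffusive
   spread √(2Dt), half-life ln2/d).
2. **Cell file** (`rootflux.cellfile`): N well-mixed cells with polar
   pumping rate `p` and bidirectional leak `q` (plus optional decay
   `d`), the geometric equilibrium profile, and the two-regime steady
   state under decay obtained by backward recursion from the dead end
   (`R_N = (p+q)/(q+d)`, `R_n = (p+q)/(p+2q+d−q·R_{n+1})`), which is
   numerically stable where the equivalent nested-sum form is not.
3. **Cellular tissue** (`rootflux.layout`, `rootflux.tissue`): a
   mirror-symmetric rectangular "minimal root" and a finite-volume
   transport model on it.

All concentrations are in arbitrary units, lengths in µm, times in s.

## Tissue geometry

The default layout is a 3 mm segment with ten files (epidermis,
cortex, endodermis, pericycle, vascular, mirrored about the midline;
half-widths 10/12/9/7/10 µm), three columella tiers (16 µm each) distal
to a QC row whose central (vascular + pericycle) cells are QC type.
Rows are 16 µm up to the meristem/elongation boundary at 352 µm and
60 µm beyond it (the proximal terminal row absorbs the remainder). Cell
widths are not prescribed by measurement here; they are a modelling
choice and fully configurable. Every cell is surrounded by a 0.5 µm
wall. The *reduced* layout (vascular + pericycle + QC row only) is the
template of the unidirectional mechanism. A 1200 µm desk-scale segment
is a single configuration parameter; the 3 mm default is used
throughout because the linear-algebra backend makes it equally cheap,
and because with the very slow decay a shorter segment lets the
shootward stream interact with the proximal cut.

## PIN permeability maps

Efflux permeabilities take three values: strong PIN 20 µm/s, weak PIN
5 µm/s, background 1 µm/s; influx (AUX1/LAX + passive uptake) is
apolar at 20 µm/s everywhere. Four maps ship:

* `source_decay` — strong PIN on *all* sides of every cell, cancelling
  polarity so only diffusion and decay shape the field;
* `unidirectional` — basal (rootward) strong PIN on vascular and
  pericycle files;
* `unidirectional_backengineered` — additionally apical PINs at 85% of
  the basal strength;
* `reflux_loop` — basal strong PIN in vascular/pericycle; apical
  strong PIN in the epidermis and weak in cortex and endodermis;
  strong *lateral inward* PIN on the ground tissue (cortex and
  endodermis); apolar strong PIN in the columella; background only in
  the QC.

The reflux map is a reconstruction: published imaging constrains the
qualitative placement (rootward in the stele, shootward outside,
inward through the ground tissue, apolar in the columella) but not a
unique strong/weak assignment per file. The shipped default was chosen,
by a series-resistance estimate of the shootward conduit against its
lateral leak, so that the emergent gradient length falls in the
empirically inferred 100–200 µm band; every assignment is overridable.
With it, λ is an *output*: nothing in the model prescribes the
exponential or its length.

## Finite-volume transport model

Compartments are cytosol pixels (each cell subdivided to a target
resolution, default 4 µm) and wall segments: one sub-grid apoplast
compartment of nominal thickness 0.5 µm per pixel-aligned piece of
every cell face ("interface wall" discretisation — walls occupy no
geometric area but carry volume, storage and resistance). Couplings:

* pixel–pixel within a cell: Fickian, `g = D_cyt·A/Δ`;
* wall–wall along faces and across corner junctions:
  `g = D_wall·t/Δ` with `t = 0.5 µm`;
* pixel–wall across the membrane: the carrier law
  `F = P_efflux·C_in − P_influx·C_out`, combined in series with the
  half-pixel cytosolic path and the half-wall crossing, i.e.
  `F = (a·C_p − b·C_w)/(1 + a/g_p + b/g_w)` with `a = e·P_efflux`,
  `b = e·P_influx`, `g_p = D_cyt·e/(h/2)`, `g_w = D_wall·e/(t/2)`.
  The series terms make the scheme second-order at membranes and give
  the physically correct composite axial resistance
  `ℓ/D_cyt + t/D_wall + 1/P_eff + 1/P_aux` per cell pitch.

Decay `−d·C` acts in every compartment. Influx enters either as
production distributed over the QC pixels (`qc_source`, the
source-decay mechanism) or over the proximal boundary walls of the
vascular/pericycle files (`proximal_vascular_boundary`, the transport
mechanisms), total 1000 a.u./s by default.

The assembled system is linear, `dc/dt = M c + s` with `M` a
compartment (Metzler) rate matrix, which guarantees positivity and an
exact discrete mass ledger `d(total)/dt = influx − decay − outflow`.
Steady states are computed by a direct sparse LU solve; transients by
implicit Euler with a cached factorisation (default `dt = 5–30 s`); an
explicit-Euler `step` with a hard stability bound
`dt ≤ 1/max|M_ii|` is provided for stepwise use. All runs are
deterministic.

**Proximal boundary.** The whole domain boundary is zero-flux except
(i) the influx segments and (ii), for the reflux mechanism, the
proximal cut of the outer files, where the shootward PIN stream exits
the segment (`proximal_outflow="outer_files"`). The segment is a
window on a longer organ; closing that cut would pile the shootward
stream against an artificial dead end which, with a 10⁻⁶/s decay,
would eventually dominate the whole field. With the open cut the
reflux system has a genuine steady state (influx = decay + outflow)
whose gradient properties match the quasi-steady gradient observed
during establishment.

**Ablation** converts the selected cells (default: the QC) into
no-flux obstacles. The sealed region includes the walls those cells
own: faces adjacent to an obstacle are removed, so neither the
protoplast nor its wall ring exchanges mass afterwards. Stored mass in
the removed compartments is discarded with them.

## Profile analysis

Longitudinal profiles are the lateral means of each axial pixel row of
one cell file, distal → proximal, walls excluded; width-averaged
profiles (mass over volume per row, walls included) are used for 1D
comparisons. λ is fitted by log-linear least squares. The default fit
window runs from two cell lengths above the profile maximum (excluding
the accumulation spike) to the detected elbow, or to the proximal
minimum where the profile re-rises into the influx-driven region. The
elbow detector fits a two-piece linear model to log C and reports the
breakpoint only when the distal slope exceeds the proximal by a
contrast factor (default 4); a pure exponential therefore reports *no*
elbow, which is a valid result. Robustness scans fit the fixed distal
window 100–300 µm of the epidermal file so that identical windows are
compared across factors. Threshold zonation reports, per threshold,
the most proximal position (linear interpolation) where the profile
still reaches it; thresholds above the maximum give empty zones.

## 1D reduction used for cross-validation

The cellularised source-decay run is compared against the analytic rod
with three documented mappings: (i) the rod concentration is the
tissue mean over *total* compartment volume per axial bin (walls
included), with cross-section `W_eff = total volume / length`; (ii)
the rod influx is the full `J` as a production band over the QC row
(`steady_state_band_source`, the piecewise cosh closed form); (iii)
the rod diffusivity is the composite
`D_eff = ℓ/(ℓ/D_cyt + t/D_wall + 1/P_eff + 1/P_aux)`. With the
slow-diffusion morphogen (`D_cyt = 0.01`, wall 15× lower) the cytosol
and wall dominate, `D_eff ≈ 0.0068 µm²/s`, and the tissue matches the
rod to ≈2% (relative L2 over the distal 350 µm). With auxin kinetics
membranes dominate the composite (`D_eff ≈ 118` rather than 600
µm²/s); the profile is flat either way at these λ ≫ L scales, and the
comparison is again at the percent level. Without the composite — i.e.
comparing against a rod using the bare cytosolic `D` — any
cell-resolution model of this kind disagrees at the tens-of-percent
level, which is invisible on a figure but real.

## Mechanism presets (study conditions)

| preset | layout | map | parameters |
|---|---|---|---|
| `source_decay` | full | source_decay | D=600, D_wall=40, d=1e-6, J=1000, QC production |
| `source_decay_fast_decay` | full | source_decay | d=0.06 and J scaled by the same factor (6×10⁴), keeping total content J/d fixed |
| `source_decay_slow_diffusion` | full | source_decay | D=0.01, D_wall=D/15, d=1e-6 |
| `unidirectional` | reduced | unidirectional | defaults, shootward influx |
| `unidirectional_backengineered` | reduced | + apical 85% | defaults |
| `reflux_loop` | full | reflux_loop | defaults, shootward influx, open proximal cut of the outer files |

## Robustness scans

`uniform_permeability` multiplies every *efflux* permeability
(PIN-mediated and background alike) by the factor, holding the influx
carrier permeability and the net shootward influx fixed; the defaults
sit at the biophysical maximum, so the 1000-fold range spans downward
(factors 1 → 10⁻³). In that regime λ is set by the ratio of shootward
to lateral conductance and barely moves (≈6% over the full range),
while scaling *upward* past `P ≈ D_wall/t = 80 µm/s` would saturate
the wall crossing and break the ratio — a physical ceiling, not an
implementation artifact. `polarity_ratio` rescales the lateral:apical
efflux ratio of the epidermis and cortex; both factor 2 and factor ½
are 2-fold polarity changes and the response is reported for both
(≈−40% and ≈+55%).

## Ablation summaries

Fold-changes are per-cell volume-weighted mean concentrations relative
to the pre-event steady state, maximised over the output schedule. A
cell "increases" when its fold-change exceeds 1.1; the 10% guard band
excludes small transient redistribution ripples (after the influx cut
the draining influx-driven region transiently piles a few percent onto
the cells at the heap boundary of the unidirectional mechanism) from
the qualitative contrast, which is unambiguous: the reflux loop
refills cells just above the wound several-fold within 20 simulated
minutes, the other mechanisms nowhere exceed ~3%.

## Numerical choices and degenerate inputs

* Steep cell files are ill-conditioned (the solution spans ratioᴺ);
  the tridiagonal steady solve is polished with extended-precision
  iterative refinement, good to ≈ ratioᴺ·10⁻¹⁹ relative (≈10⁻⁸ for a
  20-fold ratio over 8 cells). Profiles with larger dynamic range are
  computed in log space from the ratio recursion instead.
* `d = 0` makes λ, C₀ and the RMS travel infinite; these raise a
  dedicated `InfiniteLengthScale` rather than returning inf.
* A constant-influx closed system with `d = 0` has no steady state;
  the direct solver refuses it explicitly.
* The 1D solver warns when the grid resolves λ with fewer than 10
  nodes and rejects explicit steps beyond the stability bound.
* Steady-state detection: the direct solve reports its residual rate;
  the time-stepping fallback uses a max relative change per simulated
  minute below 10⁻⁵ (configurable) and raises with diagnostics if the
  cap is hit — with `d = 10⁻⁶/s` and constant influx the *absolute
  levels* of a closed system approach equilibrium only on the 1/d
  (≈11 day) scale even when the gradient shape is long settled, which
  is why the direct method is the default.

## Problem sizes

The default 3 mm layout assembles to ≈26 000 compartments at 4 µm
resolution (≈7 000 for the reduced layout); a steady solve takes well
under a second and a 20-minute implicit transient a few seconds on one
core, so every shipped analysis — including the full test suite — runs
on a laptop in well under a minute per experiment.

## What the simulations do and do not show

The tissue model is a rectangular, static caricature: no growth, cell
division or deformation; no curved root-cap geometry; no auxin-driven
PIN regulation (the ablation experiment deliberately freezes the
transport map); no intracellular signalling; influx and production are
constant, not fluctuating. Passing the shipped checks shows that the
*transport architecture alone* reproduces the contrasting gradient
properties of the three mechanisms on an idealised root — it does not
validate kinetic parameter values against images of real roots, nor
address stochasticity in morphogen readout, which is discussed only
conceptually here. High trans-QC fluxes in the reflux loop produce
intracellular gradients in the simulation output; their magnitudes are
reported but not calibrated against measurements.
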