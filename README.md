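# rootflux

Morphogen-gradient formation in the plant root, compared across three
mechanisms: **source–decay** (localised production, diffusion, uniform
turnover), **unidirectional polar transport** (PIN-driven pumping
toward a dead end), and the **PIN-mediated reflux loop** (opposed
rootward and shootward streams coupled by a lateral flux, acting as an
auxin capacitor with its maximum at the quiescent centre, QC).

The package is for quantitative developmental biologists who want to
ask, for a given transport architecture and measured kinetics, what
gradient a root can actually build: its characteristic length, its
maximum, how fast it forms, and how it responds to wounding or
parameter changes.

## The models

**Source–decay.** `∂C/∂t = D ∇²C − d·C` with influx `J` at the distal
boundary. At steady state `C(x) = C₀·e^(−x/λ)` with

```
λ = √(D/d),   C₀ = J/√(D·d),   Thiele modulus = L/λ
```

For auxin (`D = 600 µm²/s`, `d = 10⁻⁶/s`, half-life 8 days) this gives
λ ≈ 2.4 cm — far longer than the ~1 mm patterning zone. Back-engineering
λ = 100 µm needs either `d ≈ 0.06/s` (half-life 12 s, a 250-fold lower
maximum) or `D = 0.01 µm²/s` (spreading only 8.5 µm/h); either way the
RMS distance travelled before decay, `√(2D/d) = √2·λ`, caps
communication at ~140 µm.

**Unidirectional transport.** A file of cells pumping with polar rate
`p` on top of a bidirectional leak `q` reaches the geometric profile
`Cₙ = C₀·((p+q)/q)ⁿ`, i.e. λ = 1/ln((p+q)/q) cell lengths. Vascular
permeabilities (`p = 19`, `q = 1 µm/s`) give a 20-fold jump per cell —
λ ≈ 0.33 cells ≈ 5 µm, over 19 orders of magnitude in 15 cells. With
decay the file splits into an influx-driven region (per-cell ratio
`≈ (p+d+2q−√((p+d)²+4dq))/(2q)`) and a heaping-up region at the dead
end (ratio `(p+q)/q`), with a transition only a few cells wide.

**Reflux loop.** On a cell-resolution "minimal root" (ten files of
rectangular cells, 16 µm long in the meristem and 60 µm in the
elongation zone, each wrapped in a 0.5 µm wall), PINs pump rootward in
the stele, shootward in the outer files, and inward through the ground
tissue. A finite-volume simulator (cytosol pixels + sub-grid apoplast
compartments, carrier-law membrane fluxes
`F = P_efflux·C_in − P_influx·C_out`) shows that this loop alone, at
measured auxin kinetics, yields an exponential gradient with
λ ≈ 100–200 µm, its maximum inside the QC, forming within minutes and
robust to 1000-fold permeability changes — while a 2-fold change in the
lateral:apical PIN ratio redraws it.

## Worked example

```bash
python examples/03_mechanism_comparison.py
```

prints (abridged):

```
source-decay (auxin):  profile varies 2% over 3 mm (flat)
slow-diffusion variant: tissue vs 1D rod rel. L2 = 2.1% (D_eff = 0.0068 um^2/s)
unidirectional:        per-cell ratio at the tip = 18.1 (steep heap)
reflux loop:           vascular  lambda = 166 um
reflux loop:           epidermis lambda = 149 um
reflux loop:           maximum in the quiescent_centre (row 3)
```

Reading: with auxin's kinetics the source-decay gradient is flat (2%
variation over the whole segment — no positional information), the
cellularised source-decay run agrees with its 1D rod reduction to ~2%,
unidirectional pumping produces an ~20-fold concentration jump per cell
(all information compressed into ~5 cells at the tip), and only the
reflux loop delivers a usable gradient: λ of ~150 µm shared by the
vascular and epidermal files, with the maximum in the QC. The other
examples (`examples/0*.py`) cover the analytic calculators, the
cell-file model, ablation recovery and the robustness scans.

A thin CLI mirrors the library:

```bash
rootflux analytic -D 600 -d 0.06          # λ, C0, time-scales
rootflux cellfile -p 19 -q 1 -N 15        # per-cell profile + λ
rootflux simulate --mechanism reflux_loop --out run/
rootflux scan --knob polarity_ratio --factors 0.5,1,2 --out scan.tsv
```

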