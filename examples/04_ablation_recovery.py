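"""Influx cut + QC ablation: which mechanism can restore a maximum?

From each mechanism's steady state the shootward influx is cut and the
QC cells become a no-flux obstacle.  Only the reflux loop, with its
continuously high recirculating fluxes, refills the cells just above
the wound within minutes; the other mechanisms only lose morphogen.
"""

from rootflux.experiments import run_ablation_experiment

for mech in ("source_decay_fast_decay", "unidirectional", "reflux_loop"):
    out = run_ablation_experiment(mech, output_times=(300.0, 600.0, 1200.0))
    kept = 100.0 * out["final_total_mass"] / out["initial_total_mass"]
    n_up = len(out["increased_cells_above_ablation"])
    fold = max(out["max_fold_change"].values())
    print(f"{mech:24s}: {kept:6.2f}% of morphogen left after 20 min, "
          f"{n_up:2d} cells above the wound increased "
          f"(max fold-change {fold:.2f})")
print("\n-> the reflux loop is the only mechanism that *raises* auxin "
      "next to the ablated QC, seeding a new maximum")
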