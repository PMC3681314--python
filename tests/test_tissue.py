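"""Finite-volume tissue simulator: conservation, flux law, extraction, fits."""

import numpy as np
import pytest

from rootflux.experiments import build_mechanism
from rootflux.layout import (
    CellType,
    LayoutConfig,
    assign_pin_map,
    build_root_layout,
)
from rootflux.tissue import (
    LongitudinalProfile,
    TransportParams,
    build_system,
    default_fit_window,
    detect_elbow,
    fit_exponential,
)


class TestConservationAndPositivity:
    def test_closed_system_conserves_mass_explicitly(self, small_closed_system):
        sys_ = small_closed_system
        rng = np.random.default_rng(1)
        f = sys_.field_from(rng.uniform(0.5, 2.0, sys_.n))
        m0 = f.total_mass
        dt = 0.9 * sys_.dt_stable
        for _ in range(500):
            f = sys_.step(f, dt)
        assert abs(f.total_mass - m0) / m0 < 1e-8
        assert np.all(f.values >= 0.0)

    def test_zero_field_stays_zero(self, small_closed_system):
        f = small_closed_system.zero_field()
        f = small_closed_system.simulate(f, [100.0], dt=10.0)[0]
        assert np.all(f.values == 0.0)

    def test_mass_ledger_with_influx_decay_outflow(self, small_reflux_system):
        sys_ = small_reflux_system
        f = sys_.simulate(sys_.zero_field(), [60.0], dt=5.0)[0]
        dtot, influx, decay, outflow = sys_.mass_rate(f)
        assert influx == pytest.approx(1000.0, rel=1e-12)
        assert dtot == pytest.approx(influx - decay - outflow, rel=1e-8)

    def test_explicit_step_rejects_unstable_dt(self, small_closed_system):
        f = small_closed_system.field_from(np.ones(small_closed_system.n))
        with pytest.raises(ValueError, match="stability"):
            small_closed_system.step(f, small_closed_system.dt_stable * 10.0)

    def test_implicit_step_preserves_positivity(self, small_reflux_system):
        f = small_reflux_system.zero_field()
        for dt in (1.0, 10.0, 100.0, 1000.0):
            f = small_reflux_system.step_implicit(f, dt)
            assert np.all(f.values >= 0.0)


class TestMembraneFluxLaw:
    def test_closed_equilibrium_ratio_is_influx_over_efflux(self):
        # uniform efflux 5 / influx 20 everywhere: at equilibrium every
        # cytosol:wall concentration ratio equals P_aux/P_efflux = 4
        lay = build_root_layout(LayoutConfig(segment_length=200.0, reduced=True))
        pmap = assign_pin_map(lay, "source_decay")
        for k in pmap.efflux:
            pmap.efflux[k] = 5.0
        sys_ = build_system(lay, pmap, TransportParams(d=0.0, J_in=0.0))
        f = sys_.field_from(np.ones(sys_.n))
        for dt in [10.0] * 5 + [1e3] * 10 + [1e5] * 10:
            f = sys_.step_implicit(f, dt)
        c_in = f.values[: sys_.n_pixels]
        c_wall = f.values[sys_.n_pixels:]
        assert np.mean(c_in) / np.mean(c_wall) == pytest.approx(4.0, rel=1e-3)


class TestSymmetry:
    def test_mirror_symmetric_evolution(self, small_closed_system):
        sys_ = small_closed_system
        lay = sys_.layout
        vals = np.zeros(sys_.n)
        for cid, idx in sys_.cell_pixels.items():
            c = next(cc for cc in lay.cells if cc.id == cid)
            vals[idx] = 1.0 + abs(c.centre[0] - lay.midline)
        vals[sys_.n_pixels:] = 0.5
        f = sys_.simulate(sys_.field_from(vals), [50.0], dt=1.0)[0]
        means = f.cell_means()
        by_pos = {(c.row, c.file_index): c for c in lay.cells}
        nf = lay.n_files
        for (r, fi), c in by_pos.items():
            twin = by_pos[(r, nf - 1 - fi)]
            assert means[c.id] == pytest.approx(means[twin.id], rel=1e-10)


class TestSteadyState:
    def test_direct_solve_has_vanishing_residual(self, small_reflux_system):
        steady, info = small_reflux_system.run_to_steady_state()
        assert info["residual_per_min"] < 1e-6
        assert np.all(steady.values >= 0.0)

    def test_timestep_method_converges_for_fast_decay(self):
        sys_ = build_mechanism(
            "source_decay_fast_decay", LayoutConfig(segment_length=400.0)
        )
        fld, info = sys_.run_to_steady_state(method="timestep", dt=10.0, tolerance=1e-4)
        direct, _ = sys_.run_to_steady_state()
        err = np.linalg.norm(fld.values - direct.values) / np.linalg.norm(direct.values)
        assert err < 1e-3
        assert info["simulated_time"] > 0

    def test_timestep_nonconvergence_raises_with_diagnostics(self, small_reflux_system):
        with pytest.raises(RuntimeError, match="steady state"):
            small_reflux_system.run_to_steady_state(
                method="timestep", dt=10.0, tolerance=1e-12, max_time=100.0
            )

    def test_no_steady_state_without_decay_or_outflow(self):
        lay = build_root_layout(LayoutConfig(segment_length=400.0, reduced=True))
        pmap = assign_pin_map(lay, "unidirectional")
        sys_ = build_system(lay, pmap, TransportParams(d=0.0))
        with pytest.raises(ValueError, match="steady state"):
            sys_.steady_state()


class TestFluxField:
    def test_uniform_closed_field_has_zero_flux(self, small_closed_system):
        f = small_closed_system.field_from(np.ones(small_closed_system.n))
        ff = small_closed_system.compute_flux_field(f)
        assert all(abs(flow) < 1e-12 for _, _, flow in ff["diffusive"])
        # membrane flux vanishes only where efflux == influx; check the
        # discrete continuity identity instead, which must always hold
        assert ff["divergence_residual"] < 1e-6

    def test_continuity_on_a_driven_state(self, small_reflux_system):
        f = small_reflux_system.simulate(small_reflux_system.zero_field(), [120.0], dt=5.0)[0]
        ff = small_reflux_system.compute_flux_field(f)
        assert ff["divergence_residual"] < 1e-6

    def test_reflux_axial_flux_directions(self, small_reflux_system):
        sys_ = small_reflux_system
        steady, _ = sys_.run_to_steady_state()
        lay = sys_.layout
        by_pos = {(c.row, c.file_index): c for c in lay.cells}
        fv = lay.file_of_type("vascular")
        fe = lay.file_of_type("epidermis")
        for r in (6, 10, 14):  # distal MZ rows
            vc = by_pos[(r, fv)]
            ec = by_pos[(r, fe)]
            # vasculature transports rootward (out of the basal side),
            # epidermis shootward (out of the apical side)
            assert sys_.membrane_net_flux(steady, vc.id, "basal") > 0
            assert sys_.membrane_net_flux(steady, ec.id, "apical") > 0


class TestProfileExtraction:
    def test_uniform_field_gives_constant_profile(self, small_closed_system):
        f = small_closed_system.field_from(np.full(small_closed_system.n, 2.5))
        prof = small_closed_system.extract_profile(f, "vascular")
        assert np.allclose(prof.concentrations, 2.5)

    def test_profile_spans_the_segment(self, small_closed_system):
        f = small_closed_system.zero_field()
        prof = small_closed_system.extract_profile(f, "epidermis")
        lay = small_closed_system.layout
        assert prof.positions[0] < 8.0
        assert prof.positions[-1] > lay.length - 8.0
        assert np.all(np.diff(prof.positions) > 0)

    def test_unknown_file_raises(self, small_closed_system):
        f = small_closed_system.zero_field()
        with pytest.raises(KeyError):
            small_closed_system.extract_profile(f, "columella")

    def test_vascular_and_epidermal_lambda_agree(self, small_reflux_system):
        # both files share the exponential set by the lateral reflux
        steady, _ = small_reflux_system.run_to_steady_state()
        window = (100.0, 300.0)
        lam_v = fit_exponential(
            small_reflux_system.extract_profile(steady, "vascular"), window
        ).lambda_fit
        lam_e = fit_exponential(
            small_reflux_system.extract_profile(steady, "epidermis"), window
        ).lambda_fit
        assert lam_v == pytest.approx(lam_e, rel=0.10)


class TestExponentialFit:
    def test_exact_recovery(self):
        x = np.arange(0.0, 300.0, 4.0)
        prof = LongitudinalProfile(x, 2.0 * np.exp(-x / 30.0), "syn")
        fit = fit_exponential(prof, (0.0, 300.0))
        assert fit.lambda_fit == pytest.approx(30.0, rel=1e-12)
        assert fit.C0_fit == pytest.approx(2.0, rel=1e-12)
        assert fit.alpha == pytest.approx(1.0 / 30.0, rel=1e-12)

    def test_noisy_recovery_within_five_percent(self, rng):
        x = np.arange(0.0, 400.0, 8.0)
        for _ in range(100):
            c = np.exp(-x / 120.0) * (1.0 + 0.01 * rng.standard_normal(x.size))
            fit = fit_exponential(LongitudinalProfile(x, c, "syn"), (0.0, 400.0))
            assert abs(fit.lambda_fit - 120.0) / 120.0 < 0.05

    def test_too_few_samples_rejected(self):
        x = np.arange(0.0, 300.0, 4.0)
        prof = LongitudinalProfile(x, np.exp(-x / 30.0), "syn")
        with pytest.raises(ValueError, match="fewer than 5"):
            fit_exponential(prof, (0.0, 10.0))

    def test_nonpositive_concentrations_rejected(self):
        x = np.arange(0.0, 100.0, 4.0)
        c = np.exp(-x / 30.0)
        c[3] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            fit_exponential(LongitudinalProfile(x, c, "syn"), (0.0, 100.0))


class TestElbowDetection:
    def test_recovers_constructed_changepoint(self):
        x = np.arange(0.0, 600.0, 4.0)
        c = np.where(x < 300.0, np.exp(-x / 30.0), np.exp(-10.0))
        elbow = detect_elbow(LongitudinalProfile(x, c, "syn"))
        assert elbow is not None
        assert abs(elbow - 300.0) <= 16.0  # within one cell length

    def test_pure_exponential_has_no_elbow(self):
        x = np.arange(0.0, 600.0, 4.0)
        prof = LongitudinalProfile(x, np.exp(-x / 50.0), "syn")
        assert detect_elbow(prof) is None

    def test_default_window_excludes_flat_region(self):
        x = np.arange(0.0, 600.0, 4.0)
        c = np.where(x < 300.0, np.exp(-x / 30.0), np.exp(-10.0))
        lo, hi = default_fit_window(LongitudinalProfile(x, c, "syn"))
        assert lo == pytest.approx(32.0)
        assert 250.0 <= hi <= 350.0


class TestGridRefinement:
    def test_fitted_lambda_converged_in_resolution(self):
        from rootflux.experiments import width_averaged_profile

        lams = {}
        for res in (8.0, 2.0):
            cfg = LayoutConfig(
                segment_length=600.0, columella_tiers=0, resolution=res
            )
            sys_ = build_mechanism("source_decay_slow_diffusion", cfg)
            steady, _ = sys_.run_to_steady_state()
            prof = width_averaged_profile(steady)
            lams[res] = fit_exponential(prof, (40.0, 300.0)).lambda_fit
        assert lams[8.0] == pytest.approx(lams[2.0], rel=0.01)
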