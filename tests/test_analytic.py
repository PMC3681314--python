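"""Closed-form source-decay calculators against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rootflux.analytic import (
    InfiniteLengthScale,
    SourceDecayParams,
    back_engineer_decay,
    back_engineer_diffusion,
    characteristic_length,
    diffusive_spread,
    half_life,
    max_concentration,
    rms_displacement,
    simulate_source_decay_1d,
    steady_state_band_source,
    steady_state_concentration,
    steady_state_concentration_exact,
    summarise,
    thiele_modulus,
)

positive = st.floats(min_value=1e-8, max_value=1e8, allow_nan=False)


class TestCharacteristicLength:
    @pytest.mark.parametrize(
        "D, d, expected, rel",
        [
            (600.0, 1e-6, 2.4e4, 0.03),   # default auxin kinetics
            (600.0, 0.06, 100.0, 1e-9),   # fast-decay morphogen X
            (0.01, 1e-6, 100.0, 1e-9),    # slow-diffusion morphogen X
            (7.0, 7.0, 1.0, 1e-12),       # identity case D = d
        ],
    )
    def test_values(self, D, d, expected, rel):
        assert characteristic_length(D, d) == pytest.approx(expected, rel=rel)

    def test_zero_decay_is_signalled_distinctly(self):
        with pytest.raises(InfiniteLengthScale):
            characteristic_length(600.0, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(D=positive, lam=positive)
    def test_round_trip_decay(self, D, lam):
        d = back_engineer_decay(D, lam)
        assert characteristic_length(D, d) == pytest.approx(lam, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(d=positive, lam=positive)
    def test_round_trip_diffusion(self, d, lam):
        D = back_engineer_diffusion(d, lam)
        assert characteristic_length(D, d) == pytest.approx(lam, rel=1e-9)


class TestBackEngineering:
    def test_decay_for_100um(self):
        assert back_engineer_decay(600.0, 100.0) == pytest.approx(0.06)

    def test_diffusion_for_100um(self):
        assert back_engineer_diffusion(1e-6, 100.0) == pytest.approx(0.01)

    def test_decay_inverse_of_default_lambda(self):
        assert back_engineer_decay(600.0, 24495.0) == pytest.approx(1.0e-6, rel=0.01)

    def test_diffusion_recovers_default(self):
        assert back_engineer_diffusion(0.06, 100.0) == pytest.approx(600.0)


class TestSteadyState:
    def test_distal_millimetre_variation_is_four_percent(self):
        p = SourceDecayParams(D=600.0, d=1e-6, J=1000.0, L=1000.0)
        drop = 100.0 * (
            1.0 - steady_state_concentration(p, 1000.0) / steady_state_concentration(p, 0.0)
        )
        assert round(drop) == 4

    def test_limit_matches_C0(self):
        p = SourceDecayParams(D=600.0, d=0.06, J=1000.0, L=5000.0)
        assert steady_state_concentration(p, 0.0) == pytest.approx(
            max_concentration(1000.0, 600.0, 0.06), rel=1e-3
        )

    def test_strictly_decreasing_and_positive(self):
        p = SourceDecayParams(D=600.0, d=0.06, J=1000.0, L=800.0)
        x = np.linspace(0.0, 800.0, 200)
        c = steady_state_concentration(p, x)
        assert np.all(c > 0)
        assert np.all(np.diff(c) < 0)

    def test_domain_error_outside_interval(self):
        p = SourceDecayParams(D=600.0, d=0.06, J=1.0, L=100.0)
        with pytest.raises(ValueError):
            steady_state_concentration(p, -1.0)
        with pytest.raises(ValueError):
            steady_state_concentration(p, 101.0)

    def test_semi_infinite_limit_for_long_domains(self):
        # for L > 10λ the finite-domain form collapses onto C0·e^(−x/λ)
        p = SourceDecayParams(D=600.0, d=0.06, J=1000.0, L=1200.0)
        lam = characteristic_length(600.0, 0.06)
        C0 = max_concentration(1000.0, 600.0, 0.06)
        x = np.linspace(0.0, 600.0, 100)  # x < L/2
        err = np.abs(steady_state_concentration(p, x) - C0 * np.exp(-x / lam)) / C0
        assert np.max(err) < 1e-4


class TestMaxConcentration:
    def test_250_fold_drop_with_fast_decay(self):
        ratio = max_concentration(1.0, 600.0, 1e-6) / max_concentration(1.0, 600.0, 0.06)
        assert ratio == pytest.approx(math.sqrt(0.06 / 1e-6), rel=1e-12)
        assert 240 < ratio < 250  # the printed value rounds to "250-fold"

    def test_zero_influx(self):
        assert max_concentration(0.0, 600.0, 0.06) == 0.0

    def test_no_finite_maximum_without_decay(self):
        with pytest.raises(InfiniteLengthScale):
            max_concentration(1.0, 600.0, 0.0)


class TestDisplacementMetrics:
    def test_rms_before_decay(self):
        assert rms_displacement(600.0, 0.06) == pytest.approx(141.4, abs=0.1)

    def test_rms_is_sqrt2_lambda(self):
        assert rms_displacement(9.0, 0.25) == pytest.approx(
            math.sqrt(2.0) * characteristic_length(9.0, 0.25), rel=1e-12
        )

    def test_rms_against_random_walk_oracle(self, rng):
        # walkers diffuse until an exponentially distributed decay time
        D, d, n = 600.0, 0.06, 100_000
        lifetimes = rng.exponential(1.0 / d, size=n)
        final = rng.standard_normal(n) * np.sqrt(2.0 * D * lifetimes)
        assert np.sqrt(np.mean(final**2)) == pytest.approx(
            rms_displacement(D, d), rel=0.02
        )

    def test_spread_at_slow_diffusion(self):
        assert diffusive_spread(0.01, 3600.0) == pytest.approx(8.5, abs=0.05)

    def test_spread_zero_diffusion(self):
        assert diffusive_spread(0.0, 3600.0) == 0.0

    def test_spread_against_walk_oracle(self, rng):
        D, t, n = 0.01, 3600.0, 100_000
        final = rng.standard_normal(n) * np.sqrt(2.0 * D * t)
        assert np.sqrt(np.mean(final**2)) == pytest.approx(
            diffusive_spread(D, t), rel=0.02
        )

    def test_unbounded_displacement_signalled(self):
        with pytest.raises(InfiniteLengthScale):
            rms_displacement(600.0, 0.0)


class TestTimescales:
    def test_half_life_slow_decay_is_eight_days(self):
        assert round(half_life(1e-6) / 86400.0) == 8

    def test_half_life_fast_decay_is_12_seconds(self):
        assert round(half_life(0.06)) == 12

    def test_half_life_scaling(self):
        assert half_life(0.2) == pytest.approx(half_life(0.1) / 2.0, rel=1e-12)

    def test_thiele_modulus_fly_embryo(self):
        assert thiele_modulus(480.0, 120.0) == pytest.approx(4.0)

    def test_thiele_modulus_identity(self):
        assert thiele_modulus(37.0, 37.0) == 1.0

    def test_thiele_modulus_root_default(self):
        lam = characteristic_length(600.0, 1e-6)
        assert thiele_modulus(1000.0, lam) == pytest.approx(0.041, abs=0.001)

    def test_summarise(self):
        s = summarise(SourceDecayParams(D=600.0, d=0.06, J=1000.0, L=1000.0))
        assert s.lambda_char == pytest.approx(100.0)
        assert s.thiele == pytest.approx(10.0)


class TestSolver1D:
    def test_zero_influx_stays_zero(self):
        p = SourceDecayParams(D=600.0, d=0.06, J=0.0, L=400.0)
        _, C = simulate_source_decay_1d(p, 4.0, [10.0, 100.0])
        assert np.all(C == 0.0)

    def test_steady_state_matches_exact_solution(self):
        p = SourceDecayParams(D=600.0, d=0.06, J=1000.0, L=1000.0)
        x, C = simulate_source_decay_1d(p, 2.0, [600.0], dt=0.05)
        exact = steady_state_concentration_exact(p, x)
        assert np.max(np.abs(C[0] - exact)) / np.max(exact) < 1e-4

    def test_fast_decay_reaches_steady_state_within_five_minutes(self):
        p = SourceDecayParams(D=600.0, d=0.06, J=1000.0, L=1000.0)
        x, C = simulate_source_decay_1d(p, 2.0, [300.0])
        exact = steady_state_concentration_exact(p, x)
        assert np.linalg.norm(C[0] - exact) / np.linalg.norm(exact) < 0.01

    def test_well_mixed_relaxation_amplitude(self):
        # L ≪ λ: the whole domain relaxes as (1 − e^(−d·t))·steady
        d = 0.06
        p = SourceDecayParams(D=600.0, d=d, J=10.0, L=10.0)
        t_half_relax = 0.5 / d
        x, C = simulate_source_decay_1d(p, 1.0, [t_half_relax], dt=0.001)
        steady = steady_state_concentration_exact(p, x[0])
        expected = (1.0 - math.exp(-0.5)) * steady
        assert C[0][0] == pytest.approx(expected, rel=0.02)

    def test_conservation_ledger_per_step(self):
        p = SourceDecayParams(D=600.0, d=0.06, J=1000.0, L=400.0)
        h = 2.0
        # one CN step per output: the discrete ledger
        # Δtotal = J·dt − d·dt·(total_prev + total)/2 holds to roundoff
        x, C = simulate_source_decay_1d(p, h, [1.0, 2.0, 3.0], dt=1.0)
        for k in range(1, 3):
            total_prev, total = C[k - 1].sum() * h, C[k].sum() * h
            influx = p.J * 1.0
            decay = p.d * 0.5 * (total_prev + total) * 1.0
            assert total - total_prev == pytest.approx(influx - decay, rel=1e-6)

    def test_second_order_spatial_convergence(self):
        p = SourceDecayParams(D=600.0, d=0.06, J=1000.0, L=1000.0)
        errs = []
        for h in (8.0, 4.0, 2.0):
            x, C = simulate_source_decay_1d(p, h, [600.0], dt=0.05)
            exact = steady_state_concentration_exact(p, x)
            errs.append(np.max(np.abs(C[0] - exact)) / np.max(exact))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.15)

    def test_explicit_scheme_rejects_unstable_step(self):
        p = SourceDecayParams(D=600.0, d=0.06, J=1000.0, L=400.0)
        with pytest.raises(ValueError, match="unstable"):
            simulate_source_decay_1d(p, 2.0, [10.0], dt=1.0, scheme="explicit")

    def test_coarse_grid_warns(self):
        p = SourceDecayParams(D=600.0, d=0.06, J=1.0, L=1000.0)
        with pytest.warns(UserWarning, match="fewer than 10 nodes"):
            simulate_source_decay_1d(p, 50.0, [1.0])


class TestBandSource:
    def test_reduces_to_point_source_for_narrow_band(self):
        D, d, J, L = 0.01, 1e-6, 5.0, 2000.0
        x = np.linspace(50.0, 500.0, 40)
        narrow = steady_state_band_source(D, d, J, L, 0.5, x)
        point = steady_state_concentration_exact(
            SourceDecayParams(D=D, d=d, J=J, L=L), x
        )
        assert np.allclose(narrow, point, rtol=1e-3)

    def test_total_mass_is_influx_over_decay(self):
        D, d, J, L, w = 0.01, 1e-6, 5.0, 2000.0, 16.0
        x = np.linspace(0.0, L, 20001)
        c = steady_state_band_source(D, d, J, L, w, x)
        assert np.trapezoid(c, x) == pytest.approx(J / d, rel=1e-6)
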