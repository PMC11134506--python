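"""Competitive equilibria and kinetics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bindkin import (
    CompetitionSystem,
    RateConstants,
    dilution_state,
    motulsky_mahan_pl,
    pl_eq_pseudo,
    pl_eq_second_order,
    simulate_competition,
    wang_equilibrium,
)

from conftest import brute_force_competition_equilibrium, ode_competition

RATES = RateConstants(kon=1e5, koff=0.01)  # Kd = 100 nM


class TestWangEquilibrium:
    def test_no_inhibitor_reduces_to_binary_equilibrium(self):
        eq = wang_equilibrium(100.0, 150.0, 0.0, 100.0, 100.0)
        assert eq.pl == pytest.approx(pl_eq_second_order(100.0, 150.0, 100.0), rel=1e-12)
        assert eq.pi == 0.0

    def test_symmetric_ligand_and_inhibitor(self):
        eq = wang_equilibrium(100.0, 150.0, 150.0, 100.0, 100.0)
        assert eq.pl == pytest.approx(eq.pi, rel=1e-12)

    def test_default_scenario_matches_brute_force(self):
        eq = wang_equilibrium(100.0, 150.0, 100.0, 100.0, 100.0)
        ref = brute_force_competition_equilibrium(100.0, 150.0, 100.0, 100.0, 100.0)
        for name in ("p", "l", "i", "pl", "pi"):
            assert getattr(eq, name) == pytest.approx(ref[name], rel=1e-10)

    def test_mass_balance_and_equilibrium_identities(self):
        eq = wang_equilibrium(80.0, 40.0, 900.0, 7.0, 55.0)
        assert eq.p + eq.pl + eq.pi == pytest.approx(80.0, rel=1e-12)
        assert eq.l + eq.pl == pytest.approx(40.0, rel=1e-12)
        assert eq.i + eq.pi == pytest.approx(900.0, rel=1e-12)
        assert eq.p * eq.l / eq.pl == pytest.approx(7.0, rel=1e-9)
        assert eq.p * eq.i / eq.pi == pytest.approx(55.0, rel=1e-9)

    def test_closed_form_matches_brute_force_over_random_draws(self):
        # wide log-uniform parameter sweep; this is the precision claim
        # the closed form is trusted for everywhere else in the package
        rng = np.random.default_rng(20260921)
        worst = 0.0
        for _ in range(1000):
            p, l, i = 10.0 ** rng.uniform(-2, 4.5, size=3)
            kd, ki = 10.0 ** rng.uniform(-2, 5, size=2)
            eq = wang_equilibrium(p, l, i, kd, ki)
            ref = brute_force_competition_equilibrium(p, l, i, kd, ki)
            for name in ("p", "l", "i", "pl", "pi"):
                a, b = getattr(eq, name), ref[name]
                if b > 1e-12 * max(p, l, i):
                    worst = max(worst, abs(a - b) / b)
        assert worst < 1e-9

    def test_vectorized_grid_matches_scalar_calls(self):
        i_grid = np.linspace(0.0, 500.0, 7)
        eq = wang_equilibrium(100.0, 150.0, i_grid, 100.0, 50.0)
        for k, i0 in enumerate(i_grid):
            scalar = wang_equilibrium(100.0, 150.0, i0, 100.0, 50.0)
            assert eq.pl[k] == pytest.approx(scalar.pl, rel=1e-12)

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            wang_equilibrium(-1.0, 150.0, 100.0, 100.0, 100.0)
        with pytest.raises(ValueError):
            wang_equilibrium(100.0, 150.0, 100.0, 0.0, 100.0)


class TestMotulskyMahan:
    def test_no_competitor_reduces_to_pseudo_first_order(self):
        t = np.linspace(0.0, 400.0, 50)
        got = motulsky_mahan_pl(t, 10.0, 1000.0, 0.0, RATES, RATES)
        kobs = RATES.kobs(1000.0)
        expected = pl_eq_pseudo(10.0, 1000.0, RATES.kd) * (1.0 - np.exp(-kobs * t))
        np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-12)

    def test_starts_at_zero(self):
        assert motulsky_mahan_pl(0.0, 10.0, 1000.0, 1000.0, RATES, RATES) == pytest.approx(0.0)

    def test_matches_ode_in_pseudo_first_order_regime(self):
        # <10% of ligand and inhibitor ever bound: p0 = 10 nM against 1 uM
        p0, l0, i0 = 10.0, 1000.0, 1000.0
        t = np.linspace(1.0, 500.0, 40)
        got = motulsky_mahan_pl(t, p0, l0, i0, RATES, RATES)
        ref = ode_competition((p0, l0, i0, 0.0, 0.0), RATES, RATES, t)[3]
        np.testing.assert_allclose(got, ref, rtol=5e-3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            motulsky_mahan_pl(-1.0, 10.0, 1000.0, 1000.0, RATES, RATES)


class TestDilution:
    def test_two_to_one_mixing_factors(self):
        st_ = dilution_state(p_eq=60.0, l_eq=90.0, pl_eq=30.0, i0=300.0, r=2.0)
        assert st_.p == pytest.approx(40.0)
        assert st_.l == pytest.approx(60.0)
        assert st_.pl == pytest.approx(20.0)
        assert st_.i == pytest.approx(100.0)
        assert st_.pi == 0.0

    def test_equal_volumes_halve_everything(self):
        st_ = dilution_state(60.0, 90.0, 30.0, 300.0, r=1.0)
        assert (st_.p, st_.l, st_.pl, st_.i) == (30.0, 45.0, 15.0, 150.0)

    def test_infinite_ratio_leaves_premix_untouched(self):
        st_ = dilution_state(60.0, 90.0, 30.0, 300.0, r=1e12)
        assert st_.p == pytest.approx(60.0, rel=1e-9)
        assert st_.i == pytest.approx(0.0, abs=1e-9)


def make_system(p0=100.0, l0=150.0, i0=100.0, r=1.0):
    return CompetitionSystem(
        p0=p0, l0=l0, i0=i0,
        ligand_rates=RATES, inhibitor_rates=RATES, volume_ratio=r,
    )


class TestSimulator:
    def test_degenerate_competition_matches_binary_equilibrium(self):
        tc = simulate_competition(make_system(i0=0.0), "association")
        expected = pl_eq_second_order(100.0, 150.0, 100.0)
        assert tc.final.pl == pytest.approx(expected, rel=1e-3)
        assert tc.converged

    def test_association_converges_to_wang_equilibrium(self):
        tc = simulate_competition(make_system(), "association")
        assert tc.converged
        assert tc.final.pl == pytest.approx(tc.equilibrium.pl, rel=1e-3)
        assert tc.final.pi == pytest.approx(tc.equilibrium.pi, rel=1e-3)

    def test_association_trajectory_tracks_adaptive_ode(self):
        tc = simulate_competition(make_system(), "association")
        pick = np.linspace(1, len(tc.t) - 1, 40, dtype=int)
        t_eval = tc.t[pick]
        ref = ode_competition((100.0, 150.0, 100.0, 0.0, 0.0), RATES, RATES, t_eval)
        scale = tc.equilibrium.pl
        assert np.max(np.abs(tc.pl[pick] - ref[3]) / scale) < 2e-3
        assert np.max(np.abs(tc.pi[pick] - ref[4]) / scale) < 2e-3

    def test_mass_balance_and_positivity_along_trajectory(self):
        tc = simulate_competition(make_system(), "association")
        np.testing.assert_allclose(tc.p + tc.pl + tc.pi, 100.0, rtol=1e-6)
        np.testing.assert_allclose(tc.l + tc.pl, 150.0, rtol=1e-6)
        np.testing.assert_allclose(tc.i + tc.pi, 100.0, rtol=1e-6)
        for series in (tc.p, tc.l, tc.i, tc.pl, tc.pi):
            assert np.all(series >= -1e-12)
        assert np.all(np.diff(tc.t) > 0)

    def test_dissociation_converges_to_postmix_wang_equilibrium(self):
        tc = simulate_competition(make_system(i0=300.0, r=2.0), "dissociation")
        assert tc.converged
        # totals after 2:1 mixing
        pl_eq = pl_eq_second_order(100.0, 150.0, 100.0)
        assert tc.equilibrium.p_total == pytest.approx(100.0 * 2 / 3, rel=1e-9)
        assert tc.t[0] == 0.0
        assert tc.pl[0] == pytest.approx(pl_eq * 2 / 3, rel=1e-12)

    def test_dissociation_trajectory_tracks_adaptive_ode(self):
        system = make_system(i0=300.0, r=2.0)
        tc = simulate_competition(system, "dissociation")
        pl_eq = pl_eq_second_order(100.0, 150.0, 100.0)
        state0 = (
            (100.0 - pl_eq) * 2 / 3, (150.0 - pl_eq) * 2 / 3,
            300.0 / 3, pl_eq * 2 / 3, 0.0,
        )
        pick = np.linspace(1, len(tc.t) - 1, 40, dtype=int)
        ref = ode_competition(state0, RATES, RATES, tc.t[pick])
        scale = tc.equilibrium.pl
        assert np.max(np.abs(tc.pl[pick] - ref[3]) / scale) < 2e-3

    def test_slow_decline_when_free_protein_large_at_mixing(self):
        # excess free protein after dilution soaks up the inhibitor and
        # buffers the complex, so [PL] barely declines; at stoichiometric
        # protein the same inhibitor dose displaces far more
        buffered = simulate_competition(
            make_system(p0=5000.0, l0=150.0, i0=1000.0, r=2.0),
            "dissociation", steps_per_phase=1000,
        )
        drop_buffered = 1.0 - buffered.pl[-1] / buffered.pl[0]
        control = simulate_competition(
            make_system(p0=150.0, l0=150.0, i0=1000.0, r=2.0),
            "dissociation", steps_per_phase=1000,
        )
        drop_control = 1.0 - control.pl[-1] / control.pl[0]
        assert drop_buffered < 0.05
        assert drop_control > 5 * drop_buffered

    def test_halving_dt_shifts_final_state_by_under_0p01_percent(self):
        coarse = simulate_competition(make_system(), "association", steps_per_phase=100_000)
        fine = simulate_competition(make_system(), "association", steps_per_phase=200_000)
        assert abs(fine.final.pl - coarse.final.pl) < 1e-4 * fine.final.pl

    def test_motulsky_mahan_agreement_degrades_with_depletion(self):
        # pseudo-first-order regime: closed form within 1% of simulation
        sys_ok = make_system(p0=10.0, l0=1000.0, i0=1000.0)
        tc = simulate_competition(sys_ok, "association", steps_per_phase=50_000)
        mm = np.asarray(motulsky_mahan_pl(tc.t[1:], 10.0, 1000.0, 1000.0, RATES, RATES))
        err_ok = np.max(np.abs(mm - tc.pl[1:]) / tc.equilibrium.pl)
        assert err_ok < 0.01
        # strong depletion: the closed form must visibly overshoot
        tc2 = simulate_competition(make_system(), "association", steps_per_phase=50_000)
        mm2 = np.asarray(motulsky_mahan_pl(tc2.t[1:], 100.0, 150.0, 100.0, RATES, RATES))
        err_bad = np.max(np.abs(mm2 - tc2.pl[1:]) / tc2.equilibrium.pl)
        assert err_bad > err_ok

    def test_step_floor_enforced(self):
        with pytest.raises(ValueError):
            simulate_competition(make_system(), "association", steps_per_phase=10)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    p=st.floats(0.1, 5000.0),
    l=st.floats(0.1, 5000.0),
    i=st.floats(0.0, 5000.0),
    log_kd=st.floats(-1.0, 4.0),
    log_ki=st.floats(-1.0, 4.0),
)
def test_wang_equilibrium_properties(p, l, i, log_kd, log_ki):
    """Admissibility of the closed-form root across random conditions."""
    kd, ki = 10.0**log_kd, 10.0**log_ki
    eq = wang_equilibrium(p, l, i, kd, ki)
    assert 0.0 <= eq.p <= p
    assert 0.0 <= eq.pl <= min(p, l) + 1e-12
    assert 0.0 <= eq.pi <= min(p, i) + 1e-12
    ref = brute_force_competition_equilibrium(p, l, i, kd, ki)
    assert eq.pl == pytest.approx(ref["pl"], rel=1e-9, abs=1e-12)
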