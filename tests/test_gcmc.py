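"""GCMC sampler against its analytic oracles: ideal gas, Langmuir lattice,
Widom-Henry consistency, energy bookkeeping, seed determinism."""

import math

import numpy as np
import pytest

from mofscreen.gcmc import (
    BOLTZMANN_J_PER_K,
    ForceField,
    GCMCConfig,
    lattice_isotherm,
    lj_pair_energy,
    loading_conversions,
    run_gcmc,
    run_lattice_gcmc,
    widom_henry,
)
from mofscreen.structures import PeriodicStructure, UnitCell
from mofscreen.synth import make_cubic_framework, make_dense_block


@pytest.fixture(scope="module")
def empty_box():
    return PeriodicStructure(UnitCell(30, 30, 30), [], name="empty_box")


def beta_f_v(fugacity, temperature, volume_a3):
    return fugacity * volume_a3 * 1e-30 / (BOLTZMANN_J_PER_K * temperature)


class TestLjPair:
    def test_zero_at_sigma(self, ff):
        assert lj_pair_energy("lj_sphere", "lj_sphere", 3.73, ff) == pytest.approx(0.0)

    def test_minimum_depth_at_rmin(self, ff):
        r_min = 2 ** (1 / 6) * 3.73
        assert lj_pair_energy("lj_sphere", "lj_sphere", r_min, ff) == pytest.approx(-148.0)

    def test_truncated_beyond_cutoff(self, ff):
        assert lj_pair_energy("lj_sphere", "lj_sphere", ff.cutoff + 0.001, ff) == 0.0

    def test_overlap_is_infinite_not_an_exception(self, ff):
        assert lj_pair_energy("lj_sphere", "lj_sphere", 0.0, ff) == math.inf

    def test_lorentz_berthelot_mixing(self, ff):
        eps, sig = ff.mixed("lj_sphere", "gem_bead")
        assert eps == pytest.approx(math.sqrt(148.0 * 300.0))
        assert sig == pytest.approx((3.73 + 5.2) / 2)

    def test_shifted_variant_vanishes_at_cutoff(self):
        sf = ForceField(params={"x": (100.0, 3.0)}, cutoff=10.0, shifted=True)
        assert lj_pair_energy("x", "x", 9.999999, sf) == pytest.approx(0.0, abs=1e-6)


class TestIdealGasLimit:
    def test_mean_n_equals_beta_f_v(self, empty_box, guests, ff):
        cfg = GCMCConfig(temperature=300.0, fugacity=1e5, cycles=40000,
                         equilibration=4000, seed=3)
        r = run_gcmc(empty_box, guests["ideal_sphere"], ff, cfg)
        expect = beta_f_v(1e5, 300.0, 27000.0)
        assert expect == pytest.approx(0.652, abs=0.001)  # the closed form itself
        assert abs(r.mean_n - expect) <= 3 * r.mean_n_se

    def test_poisson_variance(self, empty_box, guests, ff):
        cfg = GCMCConfig(temperature=300.0, fugacity=3e5, cycles=60000,
                         equilibration=4000, seed=9)
        r = run_gcmc(empty_box, guests["ideal_sphere"], ff, cfg)
        # Var(N) = <N> for the grand-canonical ideal gas
        assert r.var_n == pytest.approx(r.mean_n, rel=0.15)

    def test_energy_bookkeeping_has_no_drift(self, empty_box, guests, ff):
        cfg = GCMCConfig(cycles=5000, equilibration=500, seed=1)
        r = run_gcmc(empty_box, guests["lj_sphere"], ff, cfg)
        assert r.energy_drift <= 1e-6


class TestLatticeGas:
    def test_half_filling_at_unit_activity_factor(self):
        mean, se = run_lattice_gcmc(100, 0.0, 1.0, steps=40000, seed=2)
        assert abs(mean - 50.0) <= max(3 * se, 1.0)

    @pytest.mark.parametrize("z", [0.2, 0.5, 1.0, 2.0, 5.0])
    def test_isotherm_matches_closed_form(self, z):
        beta_eps = -0.3
        mean, se = run_lattice_gcmc(80, beta_eps, z, steps=40000, seed=7)
        expected = lattice_isotherm(80, beta_eps, z)
        assert abs(mean - expected) <= max(3 * se, 1.0)

    def test_closed_form_limits(self):
        assert lattice_isotherm(100, 0.0, 1.0) == pytest.approx(50.0)
        z = 1e-6
        assert lattice_isotherm(100, 0.0, z) == pytest.approx(100 * z, rel=1e-4)
        assert lattice_isotherm(100, 0.0, 1e9) == pytest.approx(100.0, rel=1e-6)


class TestWidomHenry:
    def test_empty_box_henry_equals_beta(self, empty_box, guests, ff):
        kh, se = widom_henry(empty_box, guests["ideal_sphere"], ff, 300.0,
                             insertions=10000, seed=1)
        expected = 1.0 / (BOLTZMANN_J_PER_K * 300.0) * 1e-30
        assert kh == pytest.approx(expected, rel=1e-12)
        # converted: 2.4146e20 molecules m^-3 Pa^-1
        assert kh * 1e30 == pytest.approx(2.4146e20, rel=1e-3)

    def test_mostly_repulsive_framework_suppresses_henry(self, guests, ff):
        dense = make_dense_block(5.0, "Zr")
        kh, _ = widom_henry(dense, guests["gemcitabine_like"], ff, 300.0,
                            insertions=10000, seed=2)
        beta = 1.0 / (BOLTZMANN_J_PER_K * 300.0) * 1e-30
        assert kh < beta

    def test_gcmc_matches_henry_at_low_fugacity(self, guests, ff):
        s = make_cubic_framework(14.0, "C")
        kh, kh_se = widom_henry(s, guests["lj_sphere"], ff, 300.0,
                                insertions=40000, seed=4)
        f = 2e3  # low enough that mean_n << 1
        cfg = GCMCConfig(temperature=300.0, fugacity=f, cycles=60000,
                         equilibration=6000, seed=4)
        r = run_gcmc(s, guests["lj_sphere"], ff, cfg)
        assert r.mean_n < 0.2
        v_box = r.box_volume
        predicted = kh * f * v_box
        combined_se = 3 * (r.mean_n_se + kh_se * f * v_box)
        assert abs(r.mean_n - predicted) <= combined_se

    def test_too_few_insertions_rejected(self, empty_box, guests, ff):
        with pytest.raises(ValueError):
            widom_henry(empty_box, guests["lj_sphere"], ff, 300.0, insertions=100)


class TestGcmcBehavior:
    def test_insertion_into_overlap_always_rejected(self, guests, ff):
        dense = make_dense_block(4.5, "Zr")
        cfg = GCMCConfig(cycles=3000, equilibration=1000, seed=0)
        r = run_gcmc(dense, guests["gemcitabine_like"], ff, cfg)
        assert r.mean_n == 0.0
        assert r.inaccessible
        assert r.loading_mg_per_g == 0.0

    def test_uptake_monotone_in_fugacity(self, guests, ff):
        s = make_cubic_framework(14.0, "C")
        means = []
        for f in (1e4, 1e5, 1e6):
            cfg = GCMCConfig(temperature=298.0, fugacity=f, cycles=12000,
                             equilibration=3000, seed=5)
            means.append(run_gcmc(s, guests["lj_sphere"], ff, cfg).mean_n)
        assert means[0] <= means[1] <= means[2]

    def test_seed_determinism(self, guests, ff):
        s = make_cubic_framework(14.0, "C")
        cfg = GCMCConfig(cycles=4000, equilibration=1000, seed=11)
        a = run_gcmc(s, guests["lj_sphere"], ff, cfg)
        b = run_gcmc(s, guests["lj_sphere"], ff, cfg)
        assert a.mean_n == b.mean_n
        assert a.mean_energy == b.mean_energy
        assert a.acceptance_rates == b.acceptance_rates

    def test_pairwise_insertion_delta_matches_lj(self, guests, ff):
        """Second guest at the LJ minimum distance: dU = -epsilon."""
        from mofscreen.gcmc import _State, _System

        box = PeriodicStructure(UnitCell(40, 40, 40), [], name="box")
        system = _System(box, guests["lj_sphere"], ff)
        state = _State(system)
        p1 = np.array([[10.0, 10.0, 10.0]])
        assert state.guest_energy(p1) == 0.0  # empty, atom-free box
        state.guests.append(p1)
        r_min = 2 ** (1 / 6) * 3.73
        p2 = np.array([[10.0 + r_min, 10.0, 10.0]])
        assert state.guest_energy(p2) == pytest.approx(-148.0)

    def test_incremental_energy_matches_full_recomputation(self, guests, ff):
        s = make_cubic_framework(16.0, "C")
        cfg = GCMCConfig(temperature=250.0, fugacity=5e5, cycles=8000,
                         equilibration=2000, seed=13)
        r = run_gcmc(s, guests["lj_sphere"], ff, cfg)
        assert r.final_n > 0  # the check is vacuous on an empty state
        assert r.energy_drift <= 1e-6

    def test_move_probability_validation(self):
        with pytest.raises(ValueError):
            GCMCConfig(move_probabilities=(0.4, 0.2, 0.3, 0.1))
        with pytest.raises(ValueError):
            GCMCConfig(move_probabilities=(0.3, 0.3, 0.3, 0.2))


class TestLoadingConversions:
    def test_one_gram_per_gram_is_fifty_weight_percent(self):
        mg_g, wt = loading_conversions(10.0, 100.0, 1000.0)
        assert mg_g == pytest.approx(1000.0)
        assert wt == pytest.approx(50.0)

    def test_zero_loading(self):
        assert loading_conversions(0.0, 263.2, 2632.0) == (0.0, 0.0)

    def test_direct_arithmetic_example(self):
        mg_g, wt = loading_conversions(1.0, 263.2, 2632.0)
        assert mg_g == pytest.approx(100.0)
        assert wt == pytest.approx(100.0 * 100.0 / 1100.0)  # 9.09 wt.%

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            loading_conversions(1.0, 100.0, 0.0)
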