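"""Unit and property tests for the ternary-complex binding engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trimersim import (
    BispecificMolecule,
    FourOneBBProfile,
    InVitroSystem,
    bell_curve,
    colon_median_system,
    constant_profile,
    equilibrium_tc,
    optimal_concentration,
    receptors_to_concentration,
    reference_molecule,
    simulate_binding,
)


class TestUnitConversion:
    @pytest.mark.parametrize("count, volume, expected", [
        (6.02214076e14, 1.0, 1.0),          # definition of nanomolar
        (0.0, 0.5, 0.0),
        (2.96e7, 2e-4, 2.458e-4),           # 10,000 fibroblasts x 2,960 FAP
    ])
    def test_examples(self, count, volume, expected):
        assert receptors_to_concentration(count, volume) == pytest.approx(
            expected, rel=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            receptors_to_concentration(1.0, 0.0)
        with pytest.raises(ValueError):
            receptors_to_concentration(-1.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(count=st.floats(1e3, 1e20), volume=st.floats(1e-6, 1e3),
           k=st.floats(0.5, 100.0))
    def test_linearity(self, count, volume, k):
        base = receptors_to_concentration(count, volume)
        assert receptors_to_concentration(k * count, volume) == pytest.approx(
            k * base, rel=1e-12)
        assert receptors_to_concentration(count, k * volume) == pytest.approx(
            base / k, rel=1e-12)


class TestOptimalConcentration:
    @pytest.mark.parametrize("kd_fap, kd_41bb, expected", [
        (0.7, 0.2, 0.3742),
        (0.07, 0.2, 0.1183),
        (0.5, 0.5, 0.5),
    ])
    def test_geometric_mean_rule(self, kd_fap, kd_41bb, expected):
        mol = BispecificMolecule(kd_fap=kd_fap, kd_41bb=kd_41bb)
        assert optimal_concentration(mol) == pytest.approx(expected, rel=1e-3)


class TestMoleculeInvariants:
    def test_koff_recovered_from_kon_and_kd(self):
        mol = BispecificMolecule(kd_fap=0.7, kd_41bb=0.2, kon_fap=3.6,
                                 kon_41bb=1.8)
        assert mol.koff_fap == pytest.approx(3.6 * 0.7)
        assert mol.koff_41bb == pytest.approx(1.8 * 0.2)

    @pytest.mark.parametrize("field", ["kd_fap", "kd_41bb", "kon_fap",
                                       "avidity_factor", "mw"])
    def test_positivity_enforced(self, field):
        kwargs = {"kd_fap": 0.7, field: 0.0}
        with pytest.raises(ValueError):
            BispecificMolecule(**kwargs)

    def test_profile_ordering_enforced(self):
        with pytest.raises(ValueError):
            FourOneBBProfile(t_peak_lo=48.0, t_peak_hi=24.0)


class TestSimulateBinding:
    def test_zero_concentration_gives_no_trimer(self, colon_system):
        state = simulate_binding(reference_molecule(2.0), colon_system, 0.0)
        assert np.all(state.tc_per_tcell == 0.0)

    def test_zero_fap_gives_no_trimer(self, colon_system):
        system = colon_system.with_fap(0.0)
        state = simulate_binding(reference_molecule(2.0), system, 0.37)
        assert np.all(state.tc_per_tcell == 0.0)

    def test_antibody_mass_conserved_and_species_nonnegative(self):
        mol = reference_molecule(3.0)
        system = colon_median_system()  # dynamic pulse incl. persistence
        conc = 0.37
        state = simulate_binding(mol, system, conc)
        total = state.free_ab + state.ab_fap + state.ab_41bb + state.trimer
        assert np.allclose(total, conc, rtol=1e-6)
        for arr in (state.free_ab, state.ab_fap, state.ab_41bb, state.trimer):
            assert np.all(arr >= -1e-15)

    def test_receptor_pools_never_overdrawn(self):
        mol = reference_molecule(3.0)
        system = colon_median_system(constant_profile(150.0))
        state = simulate_binding(mol, system, 0.37)
        f_tot = system.fap_total_nm
        b_tot = float(system.r41bb_total_nm(0.0))
        assert np.all(state.ab_fap + state.trimer <= f_tot * (1 + 1e-9))
        assert np.all(state.ab_41bb + state.trimer <= b_tot * (1 + 1e-9))

    def test_dynamic_pulse_decays_after_downregulation(self):
        """After the 4-1BB pulse returns to baseline the trimer declines
        with the slow persistence half-life instead of vanishing."""
        mol = reference_molecule(3.0)
        state = simulate_binding(mol, colon_median_system(), 0.37,
                                 duration=120.0)
        tc = state.tc_per_tcell
        t = state.t
        peak = tc.max()
        end = tc[-1]
        assert 0.0 < end < peak
        # decline from 48 h consistent with a 48 h half-life (one decade max)
        i48 = np.searchsorted(t, 48.0)
        expected = tc[i48] * 2 ** (-(t[-1] - t[i48]) / 48.0)
        assert end == pytest.approx(expected, rel=0.05)


class TestEquilibriumOracle:
    def test_ode_steady_state_matches_root_finding(self):
        """Long-time ODE limit vs the independent equilibrium solver on a
        (KD, concentration) grid at constant 4-1BB."""
        system = colon_median_system(constant_profile(150.0))
        for kd in (0.07, 0.7, 5.0):
            mol = BispecificMolecule(kd_fap=kd, avidity_factor=4.0)
            for conc in (0.01, 0.37, 10.0):
                ode = simulate_binding(mol, system, conc, duration=500.0,
                                       n_eval=9).terminal_tc_per_tcell
                eq = equilibrium_tc(mol, system, conc)
                assert ode == pytest.approx(eq, rel=1e-6)

    def test_equilibrium_is_kon_independent(self):
        """Steady-state trimer levels depend on KDs only, not on kinetics."""
        system = colon_median_system(constant_profile(150.0))
        slow = BispecificMolecule(kd_fap=0.7, kon_fap=0.9, kon_41bb=1.2,
                                  avidity_factor=4.0)
        fast = BispecificMolecule(kd_fap=0.7, kon_fap=7.2, kon_41bb=3.6,
                                  avidity_factor=4.0)
        for conc in (0.05, 0.37, 5.0):
            tc_slow = simulate_binding(slow, system, conc,
                                       duration=800.0).terminal_tc_per_tcell
            tc_fast = simulate_binding(fast, system, conc,
                                       duration=800.0).terminal_tc_per_tcell
            assert tc_slow == pytest.approx(tc_fast, rel=1e-6)
            assert equilibrium_tc(slow, system, conc) == pytest.approx(
                equilibrium_tc(fast, system, conc), rel=1e-12)

    def test_hook_effect_at_high_concentration(self):
        system = colon_median_system(constant_profile(150.0))
        mol = reference_molecule(4.0)
        at_opt = equilibrium_tc(mol, system, optimal_concentration(mol))
        at_high = equilibrium_tc(mol, system, 1e4)
        assert at_high < 1e-3 * at_opt

    def test_no_depletion_concentration_dependence(self):
        """With scarce receptors the trimer level is proportional to
        conc / ((kd_fap + conc)(kd_41bb + conc))."""
        system = InVitroSystem(fap_per_fibroblast=100.0,
                               r41bb_profile=constant_profile(150.0))
        mol = BispecificMolecule(kd_fap=0.7, avidity_factor=1.0)
        concs = np.array([0.01, 0.1, 0.374, 1.0, 10.0])
        tc = np.array([equilibrium_tc(mol, system, c) for c in concs])
        shape = concs / ((mol.kd_fap + concs) * (mol.kd_41bb + concs))
        ratios = tc / shape
        assert np.all(np.abs(ratios / ratios.mean() - 1) < 1e-3)

    def test_avidity_linearity_in_no_depletion_regime(self):
        system = InVitroSystem(fap_per_fibroblast=100.0,
                               r41bb_profile=constant_profile(150.0))
        base = BispecificMolecule(kd_fap=0.7, avidity_factor=0.5)
        doubled = base.with_avidity(1.0)
        conc = optimal_concentration(base)
        assert equilibrium_tc(doubled, system, conc) == pytest.approx(
            2.0 * equilibrium_tc(base, system, conc), rel=1e-2)


def _count_local_maxima(y: np.ndarray, rel_tol: float = 1e-9) -> int:
    scale = np.max(np.abs(y))
    d = np.diff(y)
    d[np.abs(d) < rel_tol * scale] = 0.0
    signs = np.sign(d)
    signs = signs[signs != 0]
    return int(np.sum(np.diff(signs) < 0)) + (1 if signs.size and
                                              signs[0] < 0 else 0)


class TestBellCurve:
    @pytest.mark.parametrize("kd_fap", [0.07, 0.7, 5.0])
    def test_unimodal_with_interior_maximum(self, kd_fap):
        mol = BispecificMolecule(kd_fap=kd_fap, avidity_factor=4.0)
        grid = np.geomspace(2e-5, 50.0, 40)
        table = bell_curve(mol, colon_median_system(constant_profile(150.0)),
                           grid)
        tc = table["tc_per_tcell"].to_numpy()
        assert _count_local_maxima(tc) == 1
        assert 0 < int(np.argmax(tc)) < len(grid) - 1

    def test_argmax_at_geometric_mean_of_kds(self):
        mol = reference_molecule(2.0)
        grid = np.geomspace(2e-5, 50.0, 60)
        table = bell_curve(mol, colon_median_system(constant_profile(150.0)),
                           grid)
        i = int(table["tc_per_tcell"].idxmax())
        log_step = math.log(grid[1] / grid[0])
        assert abs(math.log(grid[i] / optimal_concentration(mol))) <= \
            log_step * 1.001

    def test_trimer_monotone_in_fap_affinity(self):
        """Lower FAP KD means more trimer at every tested concentration."""
        system = colon_median_system(constant_profile(150.0))
        grid = [0.01, 0.1, 0.374, 2.0, 20.0]
        kds = [5.0, 0.7, 0.07, 0.007]
        prev = None
        for kd in kds:
            mol = BispecificMolecule(kd_fap=kd, avidity_factor=4.0)
            tc = np.array([equilibrium_tc(mol, system, c) for c in grid])
            if prev is not None:
                assert np.all(tc > prev)
            prev = tc

    def test_dynamic_profile_bell_is_unimodal(self, ref_mol):
        grid = np.geomspace(2e-5, 50.0, 25)
        table = bell_curve(ref_mol, colon_median_system(), grid)
        assert _count_local_maxima(table["tc_per_tcell"].to_numpy()) == 1
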