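"""Kinetic scheme construction, equilibrium occupancy, and ligand modifiers."""

import numpy as np
import pytest
from scipy.linalg import null_space

import gatekin as gk
from gatekin.scheme import Mechanism, StateClass, read_scheme, write_scheme

from conftest import saturating


class TestEquilibrium:
    def test_two_state_closed_form(self, two_state_scheme):
        # Po = beta/(alpha+beta) for C<->O
        eq = gk.equilibrium_occupancy(two_state_scheme)
        assert eq.open_probability == pytest.approx(10.0 / 510.0, rel=1e-12)

    def test_normalisation_and_bounds(self, task_scheme):
        eq = gk.equilibrium_occupancy(task_scheme)
        assert eq.occupancy.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(eq.occupancy >= 0) and np.all(eq.occupancy <= 1)
        assert eq.open_probability == pytest.approx(
            eq.occupancy[task_scheme.open_mask].sum()
        )

    def test_against_null_space_oracle(self, task_scheme):
        # independent dense linear-algebra route: pi spans null(Q^T)
        q = task_scheme.generator
        ns = null_space(q.T)
        assert ns.shape[1] == 1
        pi_oracle = ns[:, 0] / ns[:, 0].sum()
        pi = gk.equilibrium_occupancy(task_scheme).occupancy
        assert np.max(np.abs(pi - pi_oracle)) < 1e-10

    def test_reducible_scheme_names_states(self):
        rates = np.array([[0.0, 5.0, 0.0], [100.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="X"):
            gk.KineticScheme(("C", "O", "X"), ("CLOSED", "OPEN", "CLOSED"), rates)

    def test_non_square_rates_rejected(self):
        with pytest.raises(ValueError, match="matrix"):
            gk.KineticScheme(("C", "O"), ("CLOSED", "OPEN"), np.ones((2, 3)))

    def test_generator_rows_sum_to_zero_after_modification(self, task_scheme):
        for mech in Mechanism:
            mod = saturating(mech.value, 7.0)
            out = gk.apply_modifier(task_scheme, mod)
            assert np.max(np.abs(out.generator.sum(axis=1))) < 1e-12


class TestModifier:
    def test_effective_factor_range_and_monotonicity(self):
        xs = np.linspace(0, 1000, 50)
        fs = [
            gk.ModifierSpec("OPEN_DESTABILIZE", 10.0, 5.0, x).effective_factor
            for x in xs
        ]
        assert fs[0] == 1.0
        assert all(1.0 <= f <= 10.0 for f in fs)
        assert np.all(np.diff(fs) >= 0)

    def test_zero_dose_identity(self, task_scheme):
        for mech in Mechanism:
            mod = gk.ModifierSpec(mech, 10.0, 1.0, 0.0)
            out = gk.apply_modifier(task_scheme, mod)
            assert np.array_equal(out.rates, task_scheme.rates)
            eq0 = gk.equilibrium_occupancy(task_scheme).occupancy
            eq1 = gk.equilibrium_occupancy(out).occupancy
            assert np.array_equal(eq0, eq1)

    def test_open_destabilize_scales_closing_rate(self, two_state_scheme):
        mod = saturating("OPEN_DESTABILIZE", 10.0)
        out = gk.apply_modifier(two_state_scheme, mod)
        i_c, i_o = 0, 1
        assert out.rates[i_o, i_c] == pytest.approx(
            10.0 * two_state_scheme.rates[i_o, i_c], rel=1e-8
        )
        assert out.rates[i_c, i_o] == two_state_scheme.rates[i_c, i_o]

    def test_closed_stabilize_element_wise(self, task_scheme):
        # only the two closed->open entries change, each divided by f
        f = 5.0
        mod = gk.ModifierSpec("CLOSED_STABILIZE", f, 1.0, 1e12)
        f_eff = mod.effective_factor
        out = gk.apply_modifier(task_scheme, mod)
        expected = task_scheme.rates.copy()
        i = task_scheme.index
        expected[i("Cinter"), i("O")] /= f_eff
        expected[i("Cflick"), i("O")] /= f_eff
        np.testing.assert_allclose(out.rates, expected, rtol=0, atol=0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gk.ModifierSpec("OPEN_DESTABILIZE", 1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            gk.ModifierSpec("OPEN_DESTABILIZE", 2.0, -1.0, 0.0)
        with pytest.raises(ValueError):
            gk.ModifierSpec("NOT_A_MECHANISM", 2.0, 1.0, 0.0)


class TestPredictedInhibition:
    def test_two_state_closed_form(self):
        # Po=0.5, saturating f=10: I = 1 - (alpha+beta)/(f*alpha+beta) = 1 - 2/11
        scheme = gk.two_state_for_po(0.5)
        inh = gk.predicted_inhibition(scheme, saturating("OPEN_DESTABILIZE", 10.0))
        assert inh == pytest.approx(1.0 - 2.0 / 11.0, rel=1e-9)

    def test_limiting_cases(self):
        lo = gk.predicted_inhibition(
            gk.two_state_for_po(1e-5), saturating("OPEN_DESTABILIZE", 10.0)
        )
        hi = gk.predicted_inhibition(
            gk.two_state_for_po(1 - 1e-5), saturating("OPEN_DESTABILIZE", 10.0)
        )
        assert lo == pytest.approx(0.9, abs=1e-4)
        assert hi == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize("f", [2.0, 10.0, 100.0])
    def test_equilibrium_degeneracy(self, f):
        """Open destabilisation and closed stabilisation are macroscopically
        indistinguishable: both give Po' = beta/(f*alpha + beta)."""
        scheme = gk.two_state_for_po(0.3)
        i_open = gk.predicted_inhibition(scheme, saturating("OPEN_DESTABILIZE", f))
        i_closed = gk.predicted_inhibition(scheme, saturating("CLOSED_STABILIZE", f))
        assert abs(i_open - i_closed) < 1e-12

    def test_independent_mechanism_is_dose_only(self, task_scheme):
        mod = gk.ModifierSpec("INDEPENDENT", 10.0, 5.0, 5.0)
        assert gk.predicted_inhibition(task_scheme, mod) == pytest.approx(0.5)

    def test_inhibition_decreases_with_baseline_po(self):
        """The model counterpart of the inverse Po-inhibition correlation."""
        grid = np.linspace(0.01, 0.99, 25)
        mod = saturating("OPEN_DESTABILIZE", 10.0)
        inh = [gk.predicted_inhibition(gk.two_state_for_po(p), mod) for p in grid]
        assert np.all(np.diff(inh) < 0)
        mod_i = gk.ModifierSpec("INDEPENDENT", 10.0, 5.0, 5.0)
        flat = [gk.predicted_inhibition(gk.two_state_for_po(p), mod_i) for p in grid]
        assert np.ptp(flat) == 0.0


class TestPresets:
    def test_task_like_target_regime(self, task_scheme):
        eq = gk.equilibrium_occupancy(task_scheme)
        assert 0.01 <= eq.open_probability <= 0.02
        i = task_scheme.index
        q = task_scheme.generator
        assert 1.0 / -q[i("O"), i("O")] == pytest.approx(1.5e-3, rel=0.01)
        assert 1.0 / -q[i("Cflick"), i("Cflick")] == pytest.approx(0.3e-3, rel=0.01)
        assert 1.0 / -q[i("Cinter"), i("Cinter")] == pytest.approx(50e-3, rel=0.01)
        assert 1.0 / -q[i("Cdeep"), i("Cdeep")] == pytest.approx(1.0, rel=0.01)

    def test_n133s_like_po(self):
        po = gk.equilibrium_occupancy(gk.n133s_like()).open_probability
        assert po == pytest.approx(0.2, abs=0.05)

    def test_two_state_for_po_roundtrip(self):
        for po in (0.01, 0.2, 0.7):
            got = gk.equilibrium_occupancy(gk.two_state_for_po(po)).open_probability
            assert got == pytest.approx(po, rel=1e-10)


class TestSchemeFile:
    def test_round_trip(self, task_scheme, tmp_path):
        p = tmp_path / "scheme.txt"
        write_scheme(task_scheme, p)
        back = read_scheme(p)
        assert back.state_labels == task_scheme.state_labels
        assert back.state_class == task_scheme.state_class
        np.testing.assert_allclose(back.rates, task_scheme.rates, rtol=1e-12)

    def test_duplicate_edge_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text(
            "[states]\nC CLOSED\nO OPEN\n[rates]\nC O 10\nO C 500\nC O 20\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_scheme(p)
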