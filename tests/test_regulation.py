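"""Differentiation rules: stimuli, event classification, updates, convergence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from osteosim import (
    Event,
    LoadCase,
    RegenerationSimulator,
    RegulationRuleSet,
    TissueComposition,
    apply_event,
    check_convergence,
    classify_event,
    homogenize_material,
    hydrostatic_strain,
    make_fixture,
    octahedral_shear_strain,
)


class TestStrainInvariants:
    @pytest.mark.parametrize(
        "strains,expected_ed,expected_eh",
        [
            ((0.01, 0.01, 0.01), 0.0, 0.01),  # hydrostatic state
            ((0.01, 0.0, 0.0), 2 / 3 * np.sqrt(2e-4), 0.01 / 3),
            ((0.02, -0.01, -0.01), 2 / 3 * np.sqrt(1.8e-3), 0.0),
        ],
    )
    def test_known_values(self, strains, expected_ed, expected_eh):
        assert octahedral_shear_strain(*strains) == pytest.approx(expected_ed, abs=1e-12)
        assert hydrostatic_strain(*strains) == pytest.approx(expected_eh, abs=1e-12)

    @given(
        st.tuples(*[st.floats(-0.1, 0.1) for _ in range(3)]),
        st.permutations([0, 1, 2]),
    )
    def test_octahedral_shear_permutation_invariant_and_nonnegative(self, e, perm):
        e = np.asarray(e)
        ed = octahedral_shear_strain(*e)
        assert ed >= 0.0
        assert octahedral_shear_strain(*e[list(perm)]) == pytest.approx(float(ed))


def _oracle_classify(eH, ed, m_cart, m_bone, nb, vasc=True):
    """Brute-force re-derivation of the rule table (kept independent of the
    implementation: plain scalar membership tests in priority order)."""
    if eH > 5 or ed > 15:
        return Event.DESTRUCTION
    if (-1 < eH < 5 and 5 < ed < 15) or (1 < eH < 5 and ed < 15):
        return Event.FIBROUS
    if -5 < eH < -1 and 5 < ed < 15 and m_cart < 0.25 and m_bone < 0.75:
        return Event.CARTILAGE
    if -5 < eH < -0.1 and ed < 5 and vasc and nb and m_cart > 0.25:
        return Event.ENDOCHONDRAL
    if (
        ((-0.1 < eH < 1 and 1 < ed < 5) or (0.1 < eH < 1 and ed < 1))
        and vasc and nb and m_cart < 0.25
    ):
        return Event.INTRAMEMBRANOUS
    if -0.1 < eH < 0.1 and ed < 1:
        return Event.RESORPTION
    return Event.NONE


class TestClassifier:
    @pytest.mark.parametrize(
        "eH,ed,cart,bone,nb,expected",
        [
            (6.0, 2.0, 0.0, 0.0, False, Event.DESTRUCTION),
            (2.0, 10.0, 0.0, 0.0, False, Event.FIBROUS),
            (-2.0, 8.0, 0.1, 0.2, False, Event.CARTILAGE),
            (-1.0, 2.0, 0.3, 0.0, True, Event.ENDOCHONDRAL),
            (0.5, 0.5, 0.1, 0.0, True, Event.INTRAMEMBRANOUS),
            (0.0, 0.5, 0.0, 0.0, False, Event.RESORPTION),
            (-6.0, 2.0, 0.0, 0.0, True, Event.NONE),  # below every window
        ],
    )
    def test_reference_cases(self, eH, ed, cart, bone, nb, expected, default_rules):
        comp = np.array([[1 - cart - bone, 0.0, cart, bone]])
        assert classify_event(eH, ed, comp, nb, True, default_rules) == expected

    def test_agrees_with_brute_force_oracle_on_dense_grid(self, default_rules):
        eH = np.linspace(-8, 8, 321)
        ed = np.linspace(0, 20, 321)
        EH, ED = np.meshgrid(eH, ed, indexing="ij")
        EH, ED = EH.ravel(), ED.ravel()
        cases = [
            (0.10, 0.20, True), (0.10, 0.20, False),
            (0.30, 0.10, True), (0.30, 0.10, False),
            (0.10, 0.80, True), (0.26, 0.74, True),
        ]
        for m_cart, m_bone, nb in cases:
            comp = np.tile([1 - m_cart - m_bone, 0.0, m_cart, m_bone], (EH.size, 1))
            got = np.asarray(
                classify_event(EH, ED, comp, nb, True, default_rules), dtype=int
            )
            want = np.array(
                [int(_oracle_classify(h, d, m_cart, m_bone, nb)) for h, d in zip(EH, ED)]
            )
            np.testing.assert_array_equal(got, want)

    def test_ossification_requires_bone_neighbor(self, default_rules):
        comp = np.array([[0.9, 0.0, 0.1, 0.0]])
        assert classify_event(0.5, 0.5, comp, False, True, default_rules) == Event.NONE
        assert classify_event(0.5, 0.5, comp, True, True, default_rules) == Event.INTRAMEMBRANOUS


class TestApplyEvent:
    def test_fibrous_formation_rate(self):
        out = apply_event(np.array([1.0, 0.0, 0.0, 0.0]), Event.FIBROUS)
        np.testing.assert_allclose(out, [0.8, 0.2, 0.0, 0.0])

    def test_destruction_resets_to_granulation(self):
        out = apply_event(np.array([0.1, 0.3, 0.2, 0.4]), Event.DESTRUCTION)
        np.testing.assert_allclose(out, [1.0, 0.0, 0.0, 0.0])

    def test_resorption_proportional_to_bone(self):
        out = apply_event(np.array([0.6, 0.0, 0.0, 0.4]), Event.RESORPTION)
        np.testing.assert_allclose(out, [0.62, 0.0, 0.0, 0.38])

    def test_endochondral_proportional_to_cartilage(self):
        out = apply_event(np.array([0.7, 0.0, 0.3, 0.0]), Event.ENDOCHONDRAL)
        np.testing.assert_allclose(out, [0.7, 0.0, 0.27, 0.03])

    def test_formation_clamped_to_available_granulation(self):
        out = apply_event(np.array([0.05, 0.95, 0.0, 0.0]), Event.FIBROUS)
        np.testing.assert_allclose(out, [0.0, 1.0, 0.0, 0.0])

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
        st.sampled_from(list(Event)),
    )
    def test_mass_conservation(self, raw, event):
        comp = np.asarray(raw) / np.sum(raw)
        out = apply_event(comp, event)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out >= -1e-15) and np.all(out <= 1 + 1e-15)


class TestHomogenization:
    @pytest.mark.parametrize(
        "comp,expected_E,expected_nu",
        [
            ((0, 0, 0, 1), 1000.0, 0.325),
            ((1, 0, 0, 0), 0.2, 0.167),
            ((0.5, 0.5, 0, 0), 0.275, 0.167),
            ((0.25, 0.25, 0.25, 0.25), 15.815625, 0.2065),
        ],
    )
    def test_rule_of_mixtures(self, comp, expected_E, expected_nu):
        E, nu = homogenize_material(np.asarray(comp, dtype=float))
        assert E == pytest.approx(expected_E, rel=1e-12)
        assert nu == pytest.approx(expected_nu, rel=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4).filter(lambda r: sum(r) > 0))
    def test_bounds(self, raw):
        comp = np.asarray(raw) / np.sum(raw)
        E, nu = homogenize_material(comp)
        assert 0 < E <= 1000.0
        assert 0.167 - 1e-12 <= nu <= 0.325 + 1e-12


class TestConvergence:
    def test_small_relative_change_converges(self, default_rules):
        assert check_convergence([0.10, 0.104], default_rules, iteration=200)

    def test_equal_samples_converge(self, default_rules):
        assert check_convergence([0.07, 0.07], default_rules, iteration=200)
        assert check_convergence([0.0, 0.0], default_rules, iteration=200)

    def test_large_relative_change_does_not(self, default_rules):
        assert not check_convergence([0.05, 0.10], default_rules, iteration=200)

    def test_iteration_floor_blocks_early_stop(self, default_rules):
        assert not check_convergence([0.10, 0.10], default_rules, iteration=100)


class TestSimulation:
    def _quick_rules(self, **overrides):
        return RegulationRuleSet(
            min_iterations=overrides.pop("min_iterations", 10),
            max_iterations=overrides.pop("max_iterations", 30),
            **overrides,
        )

    def test_zero_load_resorbs_to_zero_bone(self):
        model, _, _ = make_fixture("plate_sandwich", n=3)
        sim = RegenerationSimulator(
            model, rules=self._quick_rules(), load=LoadCase(pressure_mpa=0.0)
        )
        trace, final = sim.run()
        assert trace.converged
        assert final["composition"].m_bone.max() == 0.0
        assert np.all(trace.event_counts[:, int(Event.RESORPTION)] == sim.n_healing)

    def test_emptied_windows_leave_tissue_unchanged(self):
        # push every window far outside physical stimuli: nothing can happen
        rules = self._quick_rules(
            destruction_eH=1e9, destruction_ed=1e9,
            fibrous_eH_lo=1e8, fibrous_eH_hi=2e8, fibrous_alt_eH_lo=1.5e8,
            cartilage_eH_lo=-2e8, cartilage_eH_hi=-1e8,
            endochondral_eH_lo=-2e8, endochondral_eH_hi=-1e8,
            intramembranous_eH_lo=1e8, intramembranous_eH_hi=2e8,
            intramembranous_alt_eH_lo=1.5e8,
            resorption_eH=1e-9, resorption_ed=1e-9,
        )
        model, _, _ = make_fixture("plate_sandwich", n=3)
        sim = RegenerationSimulator(model, rules=rules, load=LoadCase(pressure_mpa=0.5))
        trace, final = sim.run()
        assert trace.converged and trace.stop_iteration == 20
        np.testing.assert_array_equal(
            final["composition"].fractions,
            TissueComposition.granulation(sim.n_healing).fractions,
        )
        assert np.all(trace.event_counts[:, int(Event.NONE)] == sim.n_healing)

    def test_runs_are_deterministic(self, tiny_gyroid_model):
        model, _ = tiny_gyroid_model
        traces = []
        for _ in range(2):
            sim = RegenerationSimulator(model, rules=self._quick_rules(max_iterations=8))
            with pytest.warns(RuntimeWarning):
                trace, _ = sim.run()
            traces.append(trace)
        np.testing.assert_array_equal(
            traces[0].tissue_fractions, traces[1].tissue_fractions
        )
        np.testing.assert_array_equal(traces[0].event_counts, traces[1].event_counts)

    def test_mass_conserved_every_iteration(self, tiny_gyroid_model):
        model, _ = tiny_gyroid_model
        sim = RegenerationSimulator(model, rules=self._quick_rules(max_iterations=6))
        with pytest.warns(RuntimeWarning):
            trace, final = sim.run()
        np.testing.assert_allclose(trace.tissue_fractions.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(final["composition"].fractions.sum(axis=1), 1.0, atol=1e-9)

    def test_neighbor_seeding_from_plates(self):
        model, _, _ = make_fixture("plate_sandwich", n=3)
        sim = RegenerationSimulator(model)
        comp = TissueComposition.granulation(sim.n_healing)
        nb = sim.neighbor_bone_ok(comp)
        ijk = sim._healing_ijk
        adjacent = (ijk[:, 2] == 1) | (ijk[:, 2] == model.shape[2] - 2)
        np.testing.assert_array_equal(nb, adjacent)

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            RegulationRuleSet(rate_fibrous=0.0)
        with pytest.raises(ValueError):
            RegulationRuleSet(fibrous_eH_lo=5.0, fibrous_eH_hi=-1.0)
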