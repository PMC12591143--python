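import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from nsphase import stoichiometry as st
from nsphase.errors import CompositionInfeasibleError, DegenerateMappingError


class TestComponentFractions:
    @pytest.mark.parametrize(
        "fa, fab, expected",
        [
            (0.5, 0.0, {"F_B": 0.5, "F_aa": 0.5, "F_bb": 0.5}),
            (0.6, 0.2, {"F_B": 0.4, "F_aa": 0.5, "F_bb": 0.3}),
            (1.0, 0.0, {"F_B": 0.0, "F_aa": 1.0, "F_bb": 0.0}),
        ],
    )
    def test_examples(self, fa, fab, expected):
        out = st.component_fractions(fa, fab)
        for key, val in expected.items():
            assert out[key] == pytest.approx(val)

    def test_infeasible_raises_with_bound(self):
        with pytest.raises(CompositionInfeasibleError, match="2\\*F_A"):
            st.component_fractions(0.1, 0.5)
        with pytest.raises(CompositionInfeasibleError):
            st.component_fractions(0.9, 0.5)

    def test_fractions_sum_to_one_on_grid(self):
        # exhaustive feasibility grid, step 0.01
        for fa in np.arange(0.0, 1.0001, 0.01):
            for fab in np.arange(0.0, 1.0001, 0.01):
                if fab <= 2 * fa and fab <= 2 * (1 - fa):
                    out = st.component_fractions(fa, fab)
                    assert out["F_aa"] + out["F_bb"] + fab == pytest.approx(1.0)
                    assert out["F_aa"] >= -1e-12 and out["F_bb"] >= -1e-12


class TestConcentrations:
    def test_symmetric_no_crosslinker(self):
        conc = st.concentrations(st.MixtureComposition(0.5, 0.0))
        assert conc.conc_A == pytest.approx(0.25)
        assert conc.conc_B == pytest.approx(0.25)
        assert conc.conc_aa == pytest.approx(0.5)
        assert conc.conc_bb == pytest.approx(0.5)
        assert conc.conc_ab == 0.0

    def test_single_species_limit(self):
        conc = st.concentrations(st.MixtureComposition(1.0, 0.0))
        assert conc.conc_B == 0.0
        assert conc.conc_bb == 0.0
        assert conc.conc_aa == pytest.approx(1.0)

    def test_neutrality_exact_on_grid(self):
        # the two sticky-end balance identities hold to machine precision
        for fa in np.arange(0.0, 1.0001, 0.05):
            for fab in np.arange(0.0, 1.0001, 0.05):
                if fab <= 2 * fa + 1e-12 and fab <= 2 * (1 - fa) + 1e-12:
                    conc = st.concentrations(
                        st.MixtureComposition(fa, min(fab, 2 * fa, 2 * (1 - fa)))
                    )
                    r_alpha, r_beta = conc.neutrality_residuals()
                    assert abs(r_alpha) < 1e-12
                    assert abs(r_beta) < 1e-12
                    assert conc.linker_total / conc.ns_total == pytest.approx(2.0)


class TestOrderParameter:
    @pytest.mark.parametrize(
        "fa, fab, expected",
        [
            (0.5, 0.25, 0.5),
            (0.75, 0.1875, 0.5),
            (0.3, 0.0, 0.0),
        ],
    )
    def test_examples(self, fa, fab, expected):
        assert st.order_parameter(fa, fab).order_param == pytest.approx(expected)

    def test_components_sum(self):
        op = st.order_parameter(0.6, 0.3)
        assert op.order_param == pytest.approx(op.f_alpha_ab + op.f_beta_ab)

    def test_undefined_when_species_absent(self):
        with pytest.raises(CompositionInfeasibleError):
            # F_A = 0 with F_ab > 0 is already infeasible (F_aa < 0)
            st.order_parameter(0.0, 0.2)

    def test_equivalence_half_order_equals_fab_at_symmetric_composition(self):
        for fab in np.arange(0.0, 1.0001, 0.05):
            op = st.order_parameter(0.5, fab)
            assert 0.5 * op.order_param == pytest.approx(fab)

    @given(
        fa=hst.floats(0.05, 0.95),
        fab1=hst.floats(0.001, 0.099),
        fab2=hst.floats(0.1, 0.11),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_fab_and_symmetric_in_fa(self, fa, fab1, fab2):
        fab_cap = min(2 * fa, 2 * (1 - fa))
        fab1, fab2 = min(fab1, 0.9 * fab_cap), min(fab2, 0.95 * fab_cap)
        if fab2 <= fab1:
            return
        assert (
            st.order_parameter(fa, fab2).order_param
            > st.order_parameter(fa, fab1).order_param
        )
        a = st.order_parameter(fa, fab2)
        b = st.order_parameter(1 - fa, fab2)
        assert a.f_alpha_ab == pytest.approx(b.f_beta_ab)
        assert a.order_param == pytest.approx(b.order_param)


class TestPhaseClassification:
    @pytest.mark.parametrize(
        "op, expected",
        [(0.2, "biphasic"), (0.5, "monophasic"), (0.0, "biphasic"), (0.7, "monophasic")],
    )
    def test_threshold_convention(self, op, expected):
        assert st.classify_phase(op) == expected

    def test_custom_threshold(self):
        assert st.classify_phase(0.45, threshold=0.4) == "monophasic"


class TestChiMapping:
    def test_printed_constants(self):
        assert st.chi_from_order(0.0) == pytest.approx(4.1)
        assert st.chi_from_order(1.0) == pytest.approx(0.7)
        assert st.order_from_chi(4.1) == pytest.approx(0.0)
        assert st.order_from_chi(2.4) == pytest.approx(0.5)
        assert st.order_from_chi(0.7) == pytest.approx(1.0)

    def test_round_trip(self):
        for x in np.linspace(0, 1, 11):
            assert st.order_from_chi(st.chi_from_order(x)) == pytest.approx(x)

    def test_degenerate_mapping(self):
        with pytest.raises(DegenerateMappingError):
            st.order_from_chi(2.0, c1=0.0)

    def test_pure_species_without_crosslinker_is_defined(self):
        # F_A = 1 with F_ab > 0 is already infeasible; with F_ab = 0 the
        # order parameter is zero by convention
        assert st.order_parameter(1.0, 0.0).order_param == 0.0
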