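import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mfa2s.core_network import ValidationError
from mfa2s.labeling import (
    EMU,
    MDV,
    FeedLabeling,
    SingularBalanceError,
    add_natural_abundance,
    convolve,
    correct_natural_abundance,
    emu_decompose,
    feed_mdv,
    full_emu,
    isotopomer_oracle,
    labeling_fluxes,
    simulate_labeling,
)
from mfa2s.synthetic_data import (
    branch_feed,
    build_branch_fixture,
    build_condensation_fixture,
    build_linear_chain,
    build_mini_tca,
    default_feed,
    mini_tca_feed,
)

GLC_FEED = default_feed(6, "glc__D_e")


class TestFeedMdv:
    def test_study_feed_full_glucose_emu(self):
        feed = FeedLabeling("glc__D_e",
                            [("100000", 0.8), ("111111", 0.2)])
        mdv = feed_mdv(feed, full_emu("glc__D_e", 6))
        assert np.allclose(mdv.fractions, [0, 0.8, 0, 0, 0, 0, 0.2])

    def test_unlabeled_substrate_is_all_m0(self):
        feed = FeedLabeling("glc__D_e", [("000000", 1.0)])
        mdv = feed_mdv(feed, EMU("glc__D_e", (1, 2, 3)))
        assert np.allclose(mdv.fractions, [1, 0, 0, 0])

    def test_positions_excluding_position_one(self):
        # only the uniformly labeled component labels carbons 2-3
        mdv = feed_mdv(GLC_FEED, EMU("glc__D_e", (2, 3)))
        assert np.allclose(mdv.fractions, [0.8, 0, 0.2])

    def test_position_out_of_range(self):
        with pytest.raises(ValidationError):
            feed_mdv(GLC_FEED, EMU("glc__D_e", (7,)))

    def test_purity_dilutes_labeled_positions(self):
        feed = FeedLabeling("glc__D_e", [("100000", 1.0)], purity=0.99)
        mdv = feed_mdv(feed, EMU("glc__D_e", (1,)))
        assert np.allclose(mdv.fractions, [0.01, 0.99])


class TestConvolve:
    def test_half_half(self):
        out = convolve(np.array([0.5, 0.5]), np.array([0.5, 0.5]))
        assert np.allclose(out, [0.25, 0.5, 0.25])

    def test_unlabeled_carbon_pads(self):
        m = np.array([0.3, 0.7])
        out = convolve(np.array([1.0, 0.0]), m)
        assert np.allclose(out, [0.3, 0.7, 0.0])

    def test_fully_labeled_shifts(self):
        out = convolve(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert np.allclose(out, [0, 0, 1])

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5),
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5),
    )
    def test_convolution_preserves_normalization(self, a, b):
        a = np.array(a) / np.sum(a)
        b = np.array(b) / np.sum(b)
        out = convolve(a, b)
        assert len(out) == len(a) + len(b) - 1
        assert abs(out.sum() - 1.0) < 1e-9
        assert (out >= -1e-12).all()


class TestEmuDecomposition:
    def test_feed_target_network_is_source_only(self):
        split = build_linear_chain()
        net = emu_decompose(split, [full_emu("a_e", 2)])
        assert net.emus_by_size == {2: [full_emu("a_e", 2)]}

    def test_linear_chain_three_size2_emus(self):
        split = build_linear_chain()
        net = emu_decompose(split, [full_emu("c_c", 2)])
        # c{1,2} <- b{1,2} <- a_c{1,2} <- a_e{1,2}
        assert len(net.emus_by_size[2]) == 4
        assert all(e.size == 2 for e in net.emus_by_size[2])

    def test_condensation_creates_convolution_of_size1(self):
        split = build_condensation_fixture()
        net = emu_decompose(split, [full_emu("d_c", 2)])
        terms = net.terms[full_emu("d_c", 2)]
        assert any(len(t.precursors) == 2
                   and all(p.size == 1 for p in t.precursors)
                   for t in terms)

    def test_target_off_core_rejected(self):
        split = build_linear_chain()
        with pytest.raises(ValidationError):
            emu_decompose(split, [EMU("nope_c", (1,))])


def _chain_fluxes(split, uptake=10.0):
    return {rid: (-uptake if rid.startswith("EX") else uptake)
            for rid in split.model.reactions}


class TestSimulateLabeling:
    def test_transport_only_propagates_feed(self):
        split = build_linear_chain()
        feed = FeedLabeling("a_e", [("10", 0.5), ("11", 0.5)])
        out = simulate_labeling(split, _chain_fluxes(split), feed,
                                [full_emu("c_c", 2)])
        assert np.allclose(out[full_emu("c_c", 2)].fractions, [0, 0.5, 0.5])

    def test_flux_weighted_mixing_of_two_routes(self):
        # two feeds merging 50/50: one unlabeled, one fully labeled
        split = build_branch_fixture()
        feed = FeedLabeling("s_e", [("11", 0.5), ("00", 0.5)])
        v = {"EX_s": -10, "U": 10, "R1": 5, "R2": 5, "CLV": 10,
             "DP": 10, "DQ": 10}
        out = simulate_labeling(split, v, feed, [full_emu("x_c", 2)])
        assert np.allclose(out[full_emu("x_c", 2)].fractions, [0.5, 0, 0.5])

    def test_scale_invariance_of_labeling(self):
        split = build_mini_tca()
        feed = mini_tca_feed()
        v = {"EX_ac": -2, "ACS": 2, "CS": 2, "IDH": 2, "FUM": 2, "MDH": 2,
             "EX_co2": 4}
        targets = [full_emu("mal_c", 4), full_emu("oaa_c", 4)]
        out1 = simulate_labeling(split, v, feed, targets,
                                 exchange={"FUM": 1.0})
        v2 = {k: 7.3 * x for k, x in v.items()}
        out2 = simulate_labeling(split, v2, feed, targets,
                                 exchange={"FUM": 7.3})
        for t in targets:
            assert np.allclose(out1[t].fractions, out2[t].fractions,
                               atol=1e-12)

    def test_reaction_order_does_not_matter(self):
        split = build_mini_tca()
        feed = mini_tca_feed()
        v = {"EX_ac": -2, "ACS": 2, "CS": 2, "IDH": 2, "FUM": 2, "MDH": 2,
             "EX_co2": 4}
        targets = [full_emu("oaa_c", 4)]
        out1 = simulate_labeling(split, v, feed, targets)

        from mfa2s.core_network import NetworkModel, split_core

        reordered = NetworkModel(
            metabolites=dict(split.model.metabolites),
            reactions={rid: split.model.reactions[rid]
                       for rid in reversed(list(split.model.reactions))},
        )
        split2 = split_core(reordered, split.core_reaction_ids, "ac_e")
        out2 = simulate_labeling(split2, v, feed, targets)
        assert np.allclose(out1[targets[0]].fractions,
                           out2[targets[0]].fractions, atol=1e-12)

    def test_zero_influx_with_demand_is_diagnosed(self):
        split = build_linear_chain()
        v = {"EX_a": 0.0, "U": 0.0, "AB": 10.0, "BC": 10.0, "DC": 10.0}
        with pytest.raises(SingularBalanceError, match="a_c|b_c"):
            simulate_labeling(split, v, GLC_FEED_CHAIN,
                              [full_emu("c_c", 2)])

    def test_flux_free_network_is_diagnosed(self):
        split = build_linear_chain()
        v = {rid: 0.0 for rid in split.model.reactions}
        with pytest.raises(SingularBalanceError):
            simulate_labeling(split, v, GLC_FEED_CHAIN,
                              [full_emu("c_c", 2)])

    def test_every_simulated_mdv_is_normalized(self):
        split = build_mini_tca()
        feed = mini_tca_feed()
        v = {"EX_ac": -2, "ACS": 2, "CS": 2, "IDH": 2, "FUM": 2, "MDH": 2,
             "EX_co2": 4}
        targets = [full_emu(m, split.model.metabolites[m].n_carbons)
                   for m in ["accoa_c", "oaa_c", "cit_c", "succ_c", "mal_c"]]
        out = simulate_labeling(split, v, feed, targets)
        for t, mdv in out.items():
            assert abs(mdv.fractions.sum() - 1.0) < 1e-9
            assert (mdv.fractions >= -1e-12).all()


GLC_FEED_CHAIN = FeedLabeling("a_e", [("10", 1.0)])


class TestIsotopomerOracle:
    def test_single_transport_returns_feed_distribution(self):
        split = build_linear_chain()
        feed = FeedLabeling("a_e", [("10", 0.7), ("11", 0.3)])
        out = isotopomer_oracle(split, _chain_fluxes(split), feed,
                                [full_emu("c_c", 2)])
        assert np.allclose(out[full_emu("c_c", 2)].fractions, [0, 0.7, 0.3])

    def test_flux_free_network_is_diagnosed(self):
        split = build_linear_chain()
        v = {rid: 0.0 for rid in split.model.reactions}
        with pytest.raises(SingularBalanceError):
            isotopomer_oracle(split, v, GLC_FEED_CHAIN)

    def test_oversized_network_refused(self):
        from mfa2s.labeling import NetworkSizeError
        from mfa2s.synthetic_data import build_toy_yeast_network

        split = build_toy_yeast_network("WRY2")
        v = {rid: 1.0 for rid in split.model.reactions}
        with pytest.raises(NetworkSizeError):
            isotopomer_oracle(split, v, GLC_FEED)


class TestJacobian:
    def test_analytic_jacobian_matches_finite_differences(self):
        split = build_mini_tca()
        feed = mini_tca_feed()
        targets = [full_emu("oaa_c", 4), full_emu("succ_c", 4)]
        net = emu_decompose(split, targets)
        v = {"EX_ac": -2, "ACS": 2, "CS": 2, "IDH": 2, "FUM": 2, "MDH": 2,
             "EX_co2": 4}
        w = labeling_fluxes(split, v, net.directed, {"FUM": 0.8})
        vals, dvals = net.simulate_with_jac(w, feed)
        eps = 1e-6
        for k in range(len(w)):
            wp = w.copy()
            wp[k] += eps
            vp = net.simulate(wp, feed)
            for t in targets:
                fd = (vp[t] - vals[t]) / eps
                assert np.allclose(fd, dvals[t][k], atol=2e-5)


class TestNaturalAbundance:
    ALA = "C3H7NO2"

    def test_identity_abundances_change_nothing(self):
        pure = {"H": (1.0,), "N": (1.0,), "O": (1.0,), "S": (1.0,)}
        mdv = MDV("x", np.array([0.2, 0.5, 0.2, 0.1]))
        out = add_natural_abundance(mdv, self.ALA, abundances=pure)
        assert np.allclose(out.fractions, mdv.fractions)

    def test_round_trip_contaminate_then_correct(self, rng):
        raw = rng.dirichlet(np.ones(4))
        mdv = MDV("x", raw)
        contaminated = add_natural_abundance(mdv, self.ALA)
        recovered = correct_natural_abundance(contaminated, self.ALA)
        assert np.allclose(recovered.fractions, mdv.fractions, atol=1e-10)

    def test_correction_moves_mass_down(self):
        # natural abundance inflates M1; correction must deflate it
        mdv = MDV("x", np.array([1.0, 0.0, 0.0, 0.0]))
        contaminated = add_natural_abundance(mdv, self.ALA)
        assert contaminated.fractions[1] > 0
        recovered = correct_natural_abundance(contaminated, self.ALA)
        assert recovered.fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_size_zero_fragment_rejected(self):
        with pytest.raises(ValidationError):
            correct_natural_abundance(MDV("x", np.array([1.0])), "H2O")

    def test_formula_fragment_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            add_natural_abundance(MDV("x", np.array([1.0, 0.0])), self.ALA)


class TestMdvInvariants:
    def test_negative_fraction_rejected(self):
        with pytest.raises(ValidationError):
            MDV("x", np.array([1.1, -0.1]))

    def test_unnormalized_rejected(self):
        with pytest.raises(ValidationError):
            MDV("x", np.array([0.5, 0.4]))
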