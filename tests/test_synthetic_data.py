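import numpy as np
import pytest

from mfa2s.core_network import ValidationError, load_sbml, validate_atom_maps
from mfa2s.labeling import full_emu, isotopomer_oracle
from mfa2s.synthetic_data import (
    VARIANTS,
    build_linear_chain,
    build_mini_tca,
    build_parallel_routes,
    build_toy_yeast_network,
    emit_input_files,
    generate_measurements,
    mini_tca_feed,
    sample_ground_truth,
)


class TestToyNetwork:
    def test_wry2_has_no_acl(self):
        split = build_toy_yeast_network("WRY2")
        assert "ACL" not in split.model.reactions

    def test_acl_variants_carry_acl_with_published_stoichiometry(self):
        split = build_toy_yeast_network("WRY2_ACL")
        acl = split.model.reactions["ACL"]
        assert acl.stoichiometry == {
            "cit_c": -1, "atp_c": -1, "coa_c": -1, "h2o_c": -1,
            "oaa_c": 1, "accoa_c": 1, "adp_c": 1, "pi_c": 1,
        }

    def test_gpd1_knockout_pins_bounds_to_zero(self):
        split = build_toy_yeast_network("WRY2_dGPD1")
        rxn = split.model.reactions["GPD1ir"]
        assert rxn.lower_bound == rxn.upper_bound == 0.0

    def test_mls_downregulation_lowers_upper_bound(self):
        full = build_toy_yeast_network("WRY2_ACL")
        down = build_toy_yeast_network("WRY2_ACL_MLS")
        assert down.model.reactions["MALS"].upper_bound < \
            full.model.reactions["MALS"].upper_bound

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_all_variants_pass_atom_map_validation(self, variant):
        split = build_toy_yeast_network(variant)
        assert validate_atom_maps(split) == []

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValidationError, match="WRY2"):
            build_toy_yeast_network("WRY3")

    def test_compartments_cover_cytosol_mito_extracellular(self):
        split = build_toy_yeast_network("WRY2")
        comps = {m.compartment for m in split.model.metabolites.values()}
        assert {"c", "m", "e"} <= comps


class TestGroundTruth:
    @pytest.mark.parametrize("variant", ["WRY2", "WRY2_dGPD1_ACL_MLS"])
    def test_truth_satisfies_steady_state_and_bounds(self, variant):
        split = build_toy_yeast_network(variant)
        gt = sample_ground_truth(split, seed=4)
        S, mets, rids = split.model.stoichiometric_matrix()
        v = np.array([gt.v_true[r] for r in rids])
        assert np.abs(S @ v).max() < 1e-9
        for rid in rids:
            rxn = split.model.reactions[rid]
            assert rxn.lower_bound - 1e-9 <= gt.v_true[rid] \
                <= rxn.upper_bound + 1e-9

    def test_uptake_normalized_to_default(self, ground_truth):
        assert ground_truth.v_true["EX_glc__D_e"] == pytest.approx(-3.0)

    def test_fixed_seed_reproducible(self, toy_wry2):
        gt1 = sample_ground_truth(toy_wry2, seed=9)
        gt2 = sample_ground_truth(toy_wry2, seed=9)
        assert gt1.v_true == gt2.v_true
        for fid in gt1.mdv_true:
            assert np.array_equal(gt1.mdv_true[fid], gt2.mdv_true[fid])

    def test_gpd1_knockout_truth_secretes_no_glycerol(self):
        split = build_toy_yeast_network("WRY2_dGPD1")
        gt = sample_ground_truth(split, seed=4)
        assert gt.v_true["EX_glyc_e"] == pytest.approx(0.0, abs=1e-12)

    def test_mdv_truth_matches_isotopomer_oracle_on_small_fixture(self):
        split = build_mini_tca()
        gt = sample_ground_truth(
            split, seed=2, fragments=[("oaa", "oaa_c", (1, 2, 3, 4))],
            measured_exchange_ids=(), feed=mini_tca_feed(),
            uptake_reaction=None,
        )
        oracle = isotopomer_oracle(split, gt.v_true, gt.feed,
                                   [full_emu("oaa_c", 4)],
                                   exchange=gt.exchange_true)
        assert np.allclose(gt.mdv_true["oaa"],
                           oracle[full_emu("oaa_c", 4)].fractions, atol=1e-8)


class TestGenerateMeasurements:
    def test_zero_noise_reproduces_truth_exactly(self, ground_truth):
        ms = generate_measurements(ground_truth, noise_sd=0.0, seed=0)
        for m in ms.mdv_measurements:
            assert np.allclose(m.values.fractions,
                               ground_truth.mdv_true[m.fragment_id],
                               atol=1e-12)
        for em in ms.exchange_measurements:
            assert em.rate == ground_truth.exchange_rates[em.reaction_id]
        assert ms.growth_rate[0] == ground_truth.growth_rate

    def test_different_seeds_different_draws(self, ground_truth):
        m1 = generate_measurements(ground_truth, noise_sd=0.01, seed=1)
        m2 = generate_measurements(ground_truth, noise_sd=0.01, seed=2)
        a = m1.mdv_measurements[0].values.fractions
        b = m2.mdv_measurements[0].values.fractions
        assert not np.allclose(a, b)

    def test_noise_is_centered_on_truth(self, ground_truth):
        """Mean over many draws approaches the noiseless channel values."""
        frag = ground_truth.fragments[0][0]
        truth = ground_truth.mdv_true[frag]
        draws = np.array([
            generate_measurements(ground_truth, noise_sd=0.01, seed=s)
            .mdv_measurements[0].values.fractions
            for s in range(400)
        ])
        se = 0.01 / np.sqrt(len(draws))
        # clipping+renormalization introduce O(sd^2) bias; allow 3 SE + bias
        assert np.abs(draws.mean(axis=0) - truth).max() < 3 * se + 2e-3

    def test_negative_noise_rejected(self, ground_truth):
        with pytest.raises(ValidationError):
            generate_measurements(ground_truth, noise_sd=-0.1, seed=0)


class TestEmitInputFiles:
    def test_emitted_sbml_reloads_identically(self, tmp_path, toy_wry2,
                                              ground_truth):
        ms = generate_measurements(ground_truth, noise_sd=0.0, seed=0)
        paths = emit_input_files(ms, toy_wry2, tmp_path, ground_truth.feed)
        with pytest.warns(UserWarning):
            model2 = load_sbml(paths["sbml"])
        for rid, rxn in toy_wry2.model.reactions.items():
            assert model2.reactions[rid].stoichiometry == \
                pytest.approx(rxn.stoichiometry)

    def test_emitted_tables_round_trip(self, tmp_path, toy_wry2, ground_truth):
        from mfa2s.measurements import read_exchange_table, read_mdv_table

        ms = generate_measurements(ground_truth, noise_sd=0.01, seed=3)
        paths = emit_input_files(ms, toy_wry2, tmp_path, ground_truth.feed)
        mdvs = read_mdv_table(paths["mdv_table"])
        assert len(mdvs) == len(ms.mdv_measurements)
        for a, b in zip(ms.mdv_measurements, mdvs):
            assert np.allclose(a.values.fractions, b.values.fractions,
                               atol=1e-9)
        exch = read_exchange_table(paths["exchange_table"])
        assert {e.reaction_id for e in exch} == \
            {e.reaction_id for e in ms.exchange_measurements}

    def test_emitted_config_is_complete(self, tmp_path, toy_wry2,
                                        ground_truth):
        import yaml

        ms = generate_measurements(ground_truth, noise_sd=0.0, seed=0)
        paths = emit_input_files(ms, toy_wry2, tmp_path, ground_truth.feed)
        cfg = yaml.safe_load(open(paths["config"]))
        for key in ("paths", "feed_metabolite", "fit", "alpha",
                    "elva_threshold", "min_flux", "balance_metabolite"):
            assert key in cfg
        for rel in cfg["paths"].values():
            assert (tmp_path / rel).exists()


class TestSmallFixtures:
    def test_linear_chain_is_fully_pinned(self):
        split = build_linear_chain()
        rxn = split.model.reactions["EX_a"]
        assert rxn.lower_bound == rxn.upper_bound == -10.0

    def test_parallel_routes_share_carbon_maps(self):
        split = build_parallel_routes()
        m1 = split.model.reactions["R1"].atom_map
        m2 = split.model.reactions["R2"].atom_map
        assert m1.reactant_slots[0][1] == m2.reactant_slots[0][1]
        assert m1.product_slots[0][1] == m2.product_slots[0][1]

    def test_small_fixtures_pass_atom_validation(self):
        for build in (build_linear_chain, build_parallel_routes,
                      build_mini_tca):
            assert validate_atom_maps(build()) == []
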