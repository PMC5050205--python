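import numpy as np
import pytest

from mfa2s.core_network import (
    AtomMap,
    Metabolite,
    NetworkModel,
    Reaction,
    ValidationError,
    apply_atom_maps,
    load_sbml,
    read_atom_maps,
    split_core,
    validate_atom_maps,
    write_atom_maps,
    write_sbml,
)
from mfa2s.synthetic_data import build_toy_yeast_network


def _two_met_model():
    mets = {
        "a_c": Metabolite("a_c", n_carbons=2, compartment="c"),
        "b_c": Metabolite("b_c", n_carbons=2, compartment="c"),
    }
    rxns = {"AB": Reaction("AB", {"a_c": -1, "b_c": 1})}
    return NetworkModel(mets, rxns)


class TestMetabolite:
    def test_compartment_suffix_must_match(self):
        with pytest.raises(ValidationError):
            Metabolite("mal_m", n_carbons=4, compartment="c")

    def test_negative_carbons_rejected(self):
        with pytest.raises(ValidationError):
            Metabolite("a_c", n_carbons=-1, compartment="c")

    def test_unknown_compartment_rejected(self):
        with pytest.raises(ValidationError):
            Metabolite("a_q", n_carbons=1, compartment="q")


class TestStoichiometry:
    def test_minimal_model_matrix(self):
        model = _two_met_model()
        S, mets, rids = model.stoichiometric_matrix()
        assert rids == ["AB"]
        assert S[mets.index("a_c"), 0] == -1
        assert S[mets.index("b_c"), 0] == 1

    def test_missing_species_is_validation_error(self):
        model = _two_met_model()
        model.reactions["BAD"] = Reaction("BAD", {"ghost_c": -1, "b_c": 1})
        with pytest.raises(ValidationError, match="ghost_c"):
            model.check()

    def test_bounds_ordering_checked(self):
        model = _two_met_model()
        model.reactions["AB"].lower_bound = 5.0
        model.reactions["AB"].upper_bound = 1.0
        assert any("bound" in p for p in model.validate())

    def test_toy_model_has_no_dead_stoichiometric_rows(self):
        split = build_toy_yeast_network("WRY2")
        S, mets, _ = split.model.stoichiometric_matrix()
        nonzero = np.abs(S).sum(axis=1) > 0
        assert nonzero.all()


class TestAtomMapValidation:
    def test_cleavage_map_valid(self):
        model = _two_met_model()
        model.metabolites["p_c"] = Metabolite("p_c", n_carbons=1,
                                              compartment="c")
        model.metabolites["q_c"] = Metabolite("q_c", n_carbons=1,
                                              compartment="c")
        model.reactions["CLV"] = Reaction(
            "CLV", {"a_c": -1, "p_c": 1, "q_c": 1},
            atom_map=AtomMap("CLV", (("a_c", "ab"),),
                             (("p_c", "a"), ("q_c", "b"))),
        )
        split = split_core(model, ["CLV"], "a_c")
        assert validate_atom_maps(split) == []

    def test_length_mismatch_reported(self):
        model = _two_met_model()
        model.metabolites["t_c"] = Metabolite("t_c", n_carbons=3,
                                              compartment="c")
        model.reactions["GROW"] = Reaction(
            "GROW", {"a_c": -1, "t_c": 1},
            atom_map=AtomMap("GROW", (("a_c", "ab"),), (("t_c", "abc"),)),
        )
        split = split_core(model, ["GROW"], "a_c")
        report = validate_atom_maps(split)
        assert any("letters" in p or "conserved" in p for p in report)

    def test_acl_carbon_routing_is_conservative(self):
        """Citrate cleavage hands the citrate-synthase acetyl carbons back."""
        split = build_toy_yeast_network("WRY2_ACL")
        assert validate_atom_maps(split) == []
        acl = split.model.reactions["ACL"].atom_map
        cs = split.model.reactions["CSm"].atom_map
        # CS: positions of citrate that came from acetyl-CoA
        cit_letters = cs.product_slots[0][1]
        acc_letters = dict(cs.reactant_slots)["accoa_m"]
        from_acetyl = {i for i, ch in enumerate(cit_letters)
                       if ch in acc_letters}
        # ACL: positions of citrate handed to the acetyl-CoA product
        cit_in = acl.reactant_slots[0][1]
        acc_out = dict(acl.product_slots)["accoa_c"]
        to_acetyl = {i for i, ch in enumerate(cit_in) if ch in acc_out}
        assert from_acetyl == to_acetyl


class TestCoreSplit:
    def test_core_reaction_without_map_names_offender(self):
        model = _two_met_model()
        with pytest.raises(ValidationError, match="AB"):
            split_core(model, ["AB"], "a_c")

    def test_empty_core_set_rejected(self):
        model = _two_met_model()
        with pytest.raises(ValidationError, match="empty core"):
            split_core(model, [], "a_c")

    def test_unknown_core_id_rejected(self):
        model = _two_met_model()
        with pytest.raises(ValidationError, match="NOPE"):
            split_core(model, ["NOPE"], "a_c")


class TestSbmlRoundTrip:
    def test_round_trip_preserves_structure(self, tmp_path):
        split = build_toy_yeast_network("WRY2_ACL")
        path = tmp_path / "model.xml"
        with pytest.warns(UserWarning):  # cofactors carry no formula
            write_sbml(split.model, path)
            model2 = load_sbml(path)
        m1 = split.model
        assert set(m1.reactions) == set(model2.reactions)
        assert set(m1.metabolites) == set(model2.metabolites)
        assert model2.biomass_reaction_id == m1.biomass_reaction_id
        for rid, r1 in m1.reactions.items():
            r2 = model2.reactions[rid]
            assert r1.stoichiometry == pytest.approx(r2.stoichiometry)
            assert r1.lower_bound == pytest.approx(r2.lower_bound)
            assert r1.upper_bound == pytest.approx(r2.upper_bound)
            assert (r1.lower_bound < 0) == r2.reversible
        for mid, met1 in m1.metabolites.items():
            met2 = model2.metabolites[mid]
            assert met1.n_carbons == met2.n_carbons
            assert met1.compartment == met2.compartment

    def test_cobra_reads_emitted_sbml_identically(self, tmp_path):
        """Independent SBML consumer sees the same stoichiometry."""
        cobra = pytest.importorskip("cobra")
        split = build_toy_yeast_network("WRY2")
        path = tmp_path / "model.xml"
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            write_sbml(split.model, path)
            cm = cobra.io.read_sbml_model(str(path))
        assert len(cm.reactions) == len(split.model.reactions)
        for rxn in split.model.reactions.values():
            crxn = cm.reactions.get_by_id(rxn.id)
            got = {m.id: c for m, c in crxn.metabolites.items()}
            assert got == pytest.approx(rxn.stoichiometry)
            assert crxn.lower_bound == pytest.approx(rxn.lower_bound)

    def test_unparseable_file_raises_format_error(self, tmp_path):
        from mfa2s.core_network import FormatError

        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml this is not valid xml")
        with pytest.raises(FormatError):
            load_sbml(bad)


class TestAtomMapTsv:
    def test_round_trip_with_symmetric_directive(self, tmp_path):
        split = build_toy_yeast_network("WRY2")
        maps = {
            rid: split.model.reactions[rid].atom_map
            for rid in split.core_reaction_ids
        }
        path = tmp_path / "maps.tsv"
        write_atom_maps(maps, path, symmetric=["succ_c", "succ_m", "fum_m"])
        maps2, symmetric = read_atom_maps(path)
        assert symmetric == {"succ_c", "succ_m", "fum_m"}
        assert maps2 == maps

    def test_apply_atom_maps_round_trip_preserves_validity(self, tmp_path):
        split = build_toy_yeast_network("WRY2")
        maps = {
            rid: split.model.reactions[rid].atom_map
            for rid in split.core_reaction_ids
        }
        path = tmp_path / "maps.tsv"
        write_atom_maps(maps, path, symmetric=["succ_c", "succ_m", "fum_m"])
        maps2, symmetric = read_atom_maps(path)
        bare = split.model.copy()
        for rxn in bare.reactions.values():
            rxn.atom_map = None
        model2 = apply_atom_maps(bare, maps2, symmetric)
        split2 = split_core(model2, split.core_reaction_ids, "glc__D_e")
        assert validate_atom_maps(split2) == []
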