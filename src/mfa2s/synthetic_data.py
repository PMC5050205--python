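"""Synthetic study inputs: toy yeast network, ground-truth fluxes, noisy data.

The toy network is a compartmentalized (cytosol/mitochondrion/extracellular)
central-carbon model of S. cerevisiae covering glycolysis, the pentose
phosphate pathway, pyruvate decarboxylation and the PDH route, ethanol/acetate
/glycerol secretion, acetyl-CoA synthetase, an optional heterologous ATP
citrate lyase, citrate/malate shuttling, the TCA cycle, the glyoxylate-shunt
malate synthase, GPD1, and an acetyl-CoA carboxylase gateway into a lumped
fatty-acid drain.  Every carbon-carrying internal reaction is atom-mapped, so
the whole central network is core; peripheral demands (biomass, fatty-acid
drain, cofactor sinks) are non-core.  The peroxisome is deliberately omitted:
no reported flux in the balances needs it.

Strain variants toggle the engineering interventions studied in the source
system: presence of ATP citrate lyase (ACL), downregulated malate synthase
(MALS upper bound), and the GPD1 knockout (bounds pinned to zero).

Ground truths are random interior points of the variant's flux polytope with
glucose uptake normalized to 3.0 mmol/gDW/h (the order of magnitude of
glucose-limited shake-flask cultures); the feed is 80% [1-13C] + 20% [U-13C]
glucose.  Measurement noise is additive Gaussian on MDV channels (default sd
0.01 mole fraction, the conventional assumption for LC-MS amino-acid data)
and 5% relative on exchange fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .core_network import (
    AtomMap,
    CoreSplit,
    Metabolite,
    NetworkModel,
    Reaction,
    ValidationError,
    split_core,
    write_atom_maps,
    write_sbml,
)
from .labeling import EMU, MDV, FeedLabeling, emu_decompose
from .measurements import (
    ExchangeMeasurement,
    MDVMeasurement,
    MeasurementSet,
    map_aa_to_precursor,
    resolve_fragment,
    supported_amino_acids,
    write_exchange_table,
    write_feed_yaml,
    write_mdv_table,
)
from .polytope import build_directed_space

#: default glucose uptake the ground truth is normalized to, mmol/gDW/h
DEFAULT_GLUCOSE_UPTAKE = 3.0

#: default Gaussian noise on MDV channels, mole fraction
DEFAULT_NOISE_SD = 0.01

#: relative noise on exchange fluxes and growth rate
EXCHANGE_REL_NOISE = 0.05

VARIANTS = (
    "WRY2",
    "WRY2_ACL",
    "WRY2_ACL_MLS",
    "WRY2_dGPD1",
    "WRY2_dGPD1_ACL",
    "WRY2_dGPD1_ACL_MLS",
)

#: upper bound on malate synthase under promoter downregulation, mmol/gDW/h
MLS_DOWN_UB = 0.3

_UB = 20.0


def _met(mid: str, n_c: int, symmetric: bool = False) -> Metabolite:
    return Metabolite(
        id=mid,
        n_carbons=n_c,
        compartment=mid.rsplit("_", 1)[-1],
        symmetric=symmetric,
    )


def _rxn(rid, stoich, amap=None, lb=0.0, ub=_UB, name=""):
    return Reaction(
        id=rid,
        name=name,
        stoichiometry=stoich,
        reversible=lb < 0,
        lower_bound=lb,
        upper_bound=ub,
        atom_map=amap,
    )


def _amap(rid, reactants, products):
    return AtomMap(rid, tuple(reactants), tuple(products))


# ---------------------------------------------------------------------------
# toy yeast network
# ---------------------------------------------------------------------------


def build_toy_yeast_network(variant: str = "WRY2") -> CoreSplit:
    """Compartmentalized toy yeast central-carbon network for one strain.

    All internal carbon-carrying reactions are atom-mapped (core); succinate
    and fumarate are symmetric.  The ATP citrate lyase reaction (present in
    the ACL variants) is ``cit_c + atp + coa + h2o → oaa_c + accoa_c + adp +
    pi`` with the acetyl-CoA product receiving the two carbons that entered
    citrate from acetyl-CoA in citrate synthase.
    """
    if variant not in VARIANTS:
        raise ValidationError(
            f"unknown variant {variant!r}; known: {', '.join(VARIANTS)}"
        )
    with_acl = "ACL" in variant
    mls_down = "MLS" in variant
    gpd1_ko = "dGPD1" in variant

    mets = [
        _met("glc__D_e", 6), _met("etoh_e", 2), _met("ac_e", 2),
        _met("glyc_e", 3), _met("co2_e", 1),
        _met("glc__D_c", 6), _met("g6p_c", 6), _met("f6p_c", 6),
        _met("dhap_c", 3), _met("g3p_c", 3), _met("3pg_c", 3),
        _met("pep_c", 3), _met("pyr_c", 3), _met("acald_c", 2),
        _met("etoh_c", 2), _met("ac_c", 2), _met("accoa_c", 2),
        _met("co2_c", 1), _met("ru5p_c", 5), _met("xu5p_c", 5),
        _met("r5p_c", 5), _met("s7p_c", 7), _met("e4p_c", 4),
        _met("oaa_c", 4), _met("cit_c", 6), _met("glx_c", 2),
        _met("mal_c", 4), _met("succ_c", 4, symmetric=True),
        _met("akg_c", 5), _met("malcoa_c", 3), _met("glyc3p_c", 3),
        _met("glyc_c", 3),
        _met("pyr_m", 3), _met("accoa_m", 2), _met("oaa_m", 4),
        _met("cit_m", 6), _met("akg_m", 5),
        _met("succ_m", 4, symmetric=True), _met("fum_m", 4, symmetric=True),
        _met("mal_m", 4), _met("co2_m", 1),
        _met("atp_c", 0), _met("adp_c", 0), _met("pi_c", 0),
        _met("coa_c", 0), _met("h2o_c", 0), _met("biomass_e", 0),
    ]

    R: list[Reaction] = [
        # glycolysis
        _rxn("GLCt", {"glc__D_e": -1, "glc__D_c": 1},
             _amap("GLCt", [("glc__D_e", "abcdef")], [("glc__D_c", "abcdef")])),
        _rxn("HEX1", {"glc__D_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1},
             _amap("HEX1", [("glc__D_c", "abcdef")], [("g6p_c", "abcdef")])),
        _rxn("PGI", {"g6p_c": -1, "f6p_c": 1},
             _amap("PGI", [("g6p_c", "abcdef")], [("f6p_c", "abcdef")]),
             lb=-_UB),
        _rxn("FBA", {"f6p_c": -1, "atp_c": -1, "dhap_c": 1, "g3p_c": 1,
                     "adp_c": 1},
             _amap("FBA", [("f6p_c", "abcdef")],
                   [("dhap_c", "abc"), ("g3p_c", "def")])),
        _rxn("TPI", {"dhap_c": -1, "g3p_c": 1},
             _amap("TPI", [("dhap_c", "abc")], [("g3p_c", "cba")])),
        _rxn("GAPD", {"g3p_c": -1, "adp_c": -1, "3pg_c": 1, "atp_c": 1},
             _amap("GAPD", [("g3p_c", "abc")], [("3pg_c", "abc")])),
        _rxn("ENO", {"3pg_c": -1, "pep_c": 1},
             _amap("ENO", [("3pg_c", "abc")], [("pep_c", "abc")])),
        _rxn("PYK", {"pep_c": -1, "adp_c": -1, "pyr_c": 1, "atp_c": 1},
             _amap("PYK", [("pep_c", "abc")], [("pyr_c", "abc")])),
        # fermentation branches
        _rxn("PDC", {"pyr_c": -1, "acald_c": 1, "co2_c": 1},
             _amap("PDC", [("pyr_c", "abc")],
                   [("acald_c", "bc"), ("co2_c", "a")])),
        _rxn("ALCD2x", {"acald_c": -1, "etoh_c": 1},
             _amap("ALCD2x", [("acald_c", "ab")], [("etoh_c", "ab")])),
        _rxn("ALDD2y", {"acald_c": -1, "ac_c": 1},
             _amap("ALDD2y", [("acald_c", "ab")], [("ac_c", "ab")])),
        _rxn("ACS", {"ac_c": -1, "atp_c": -1, "coa_c": -1, "accoa_c": 1,
                     "adp_c": 1, "pi_c": 1},
             _amap("ACS", [("ac_c", "ab")], [("accoa_c", "ab")])),
        # glycerol branch
        _rxn("GPD1ir", {"dhap_c": -1, "glyc3p_c": 1},
             _amap("GPD1ir", [("dhap_c", "abc")], [("glyc3p_c", "abc")]),
             lb=0.0, ub=0.0 if gpd1_ko else _UB),
        _rxn("G3PP", {"glyc3p_c": -1, "glyc_c": 1, "pi_c": 1},
             _amap("G3PP", [("glyc3p_c", "abc")], [("glyc_c", "abc")])),
        # pentose phosphate pathway (oxidative branch lumped)
        _rxn("GND", {"g6p_c": -1, "ru5p_c": 1, "co2_c": 1},
             _amap("GND", [("g6p_c", "abcdef")],
                   [("ru5p_c", "bcdef"), ("co2_c", "a")])),
        _rxn("RPI", {"ru5p_c": -1, "r5p_c": 1},
             _amap("RPI", [("ru5p_c", "abcde")], [("r5p_c", "abcde")])),
        _rxn("RPE", {"ru5p_c": -1, "xu5p_c": 1},
             _amap("RPE", [("ru5p_c", "abcde")], [("xu5p_c", "abcde")])),
        _rxn("TKT1", {"xu5p_c": -1, "r5p_c": -1, "s7p_c": 1, "g3p_c": 1},
             _amap("TKT1", [("xu5p_c", "abcde"), ("r5p_c", "fghij")],
                   [("s7p_c", "abfghij"), ("g3p_c", "cde")])),
        _rxn("TALA", {"s7p_c": -1, "g3p_c": -1, "e4p_c": 1, "f6p_c": 1},
             _amap("TALA", [("s7p_c", "abcdefg"), ("g3p_c", "hij")],
                   [("e4p_c", "defg"), ("f6p_c", "abchij")])),
        _rxn("TKT2", {"xu5p_c": -1, "e4p_c": -1, "f6p_c": 1, "g3p_c": 1},
             _amap("TKT2", [("xu5p_c", "abcde"), ("e4p_c", "fghi")],
                   [("f6p_c", "abfghi"), ("g3p_c", "cde")])),
        # anaplerosis and mitochondrial import
        _rxn("PYC", {"pyr_c": -1, "co2_c": -1, "atp_c": -1, "oaa_c": 1,
                     "adp_c": 1, "pi_c": 1},
             _amap("PYC", [("pyr_c", "abc"), ("co2_c", "d")],
                   [("oaa_c", "abcd")])),
        _rxn("PYRt2m", {"pyr_c": -1, "pyr_m": 1},
             _amap("PYRt2m", [("pyr_c", "abc")], [("pyr_m", "abc")])),
        _rxn("PDHm", {"pyr_m": -1, "accoa_m": 1, "co2_m": 1},
             _amap("PDHm", [("pyr_m", "abc")],
                   [("accoa_m", "bc"), ("co2_m", "a")])),
        # TCA cycle
        _rxn("CSm", {"accoa_m": -1, "oaa_m": -1, "cit_m": 1, "coa_c": 1},
             _amap("CSm", [("oaa_m", "abcd"), ("accoa_m", "ef")],
                   [("cit_m", "dcbfea")])),
        _rxn("ICDHm", {"cit_m": -1, "akg_m": 1, "co2_m": 1},
             _amap("ICDHm", [("cit_m", "abcdef")],
                   [("akg_m", "abcde"), ("co2_m", "f")])),
        _rxn("AKGDm", {"akg_m": -1, "succ_m": 1, "co2_m": 1},
             _amap("AKGDm", [("akg_m", "abcde")],
                   [("succ_m", "bcde"), ("co2_m", "a")])),
        _rxn("SUCDm", {"succ_m": -1, "fum_m": 1},
             _amap("SUCDm", [("succ_m", "abcd")], [("fum_m", "abcd")])),
        _rxn("FUMm", {"fum_m": -1, "mal_m": 1},
             _amap("FUMm", [("fum_m", "abcd")], [("mal_m", "abcd")])),
        _rxn("MDHm", {"mal_m": -1, "oaa_m": 1},
             _amap("MDHm", [("mal_m", "abcd")], [("oaa_m", "abcd")])),
        # shuttles
        _rxn("OAAtm", {"oaa_c": -1, "oaa_m": 1},
             _amap("OAAtm", [("oaa_c", "abcd")], [("oaa_m", "abcd")])),
        _rxn("CITtcm", {"cit_m": -1, "cit_c": 1},
             _amap("CITtcm", [("cit_m", "abcdef")], [("cit_c", "abcdef")])),
        _rxn("AKGtm", {"akg_m": -1, "akg_c": 1},
             _amap("AKGtm", [("akg_m", "abcde")], [("akg_c", "abcde")])),
        _rxn("MALtm", {"mal_c": -1, "mal_m": 1},
             _amap("MALtm", [("mal_c", "abcd")], [("mal_m", "abcd")])),
        # glyoxylate shunt (cytosolic)
        _rxn("ICL", {"cit_c": -1, "glx_c": 1, "succ_c": 1},
             _amap("ICL", [("cit_c", "abcdef")],
                   [("glx_c", "ab"), ("succ_c", "edcf")])),
        _rxn("SUCCtm", {"succ_c": -1, "succ_m": 1},
             _amap("SUCCtm", [("succ_c", "abcd")], [("succ_m", "abcd")])),
        _rxn("MALS", {"accoa_c": -1, "glx_c": -1, "mal_c": 1, "coa_c": 1},
             _amap("MALS", [("glx_c", "ab"), ("accoa_c", "cd")],
                   [("mal_c", "abdc")]),
             ub=MLS_DOWN_UB if mls_down else _UB),
        # fatty-acid gateway
        _rxn("ACCOACr", {"accoa_c": -1, "co2_c": -1, "atp_c": -1,
                         "malcoa_c": 1, "adp_c": 1, "pi_c": 1},
             _amap("ACCOACr", [("accoa_c", "ab"), ("co2_c", "c")],
                   [("malcoa_c", "abc")])),
        _rxn("CO2tm", {"co2_m": -1, "co2_c": 1},
             _amap("CO2tm", [("co2_m", "a")], [("co2_c", "a")])),
        # non-core transport / exchange / drains
        _rxn("ETOHt", {"etoh_c": -1, "etoh_e": 1}),
        _rxn("ACt", {"ac_c": -1, "ac_e": 1}),
        _rxn("GLYCt", {"glyc_c": -1, "glyc_e": 1}),
        _rxn("CO2t", {"co2_c": -1, "co2_e": 1}, ub=50.0),
        _rxn("EX_glc__D_e", {"glc__D_e": -1}, lb=-10.0, ub=0.0),
        _rxn("EX_etoh_e", {"etoh_e": -1}),
        _rxn("EX_ac_e", {"ac_e": -1}),
        _rxn("EX_glyc_e", {"glyc_e": -1}),
        _rxn("EX_co2_e", {"co2_e": -1}, ub=50.0),
        _rxn("DM_malcoa_c", {"malcoa_c": -1}),
        _rxn("BIOMASS", {"g6p_c": -0.8, "r5p_c": -0.35, "e4p_c": -0.25,
                         "3pg_c": -1.0, "pep_c": -0.6, "pyr_c": -1.9,
                         "accoa_c": -1.1, "oaa_c": -1.0, "akg_c": -1.1,
                         "coa_c": 1.1, "biomass_e": 1.0},
             ub=2.0),
        _rxn("EX_biomass_e", {"biomass_e": -1}, ub=2.0),
        _rxn("SK_atp_c", {"atp_c": -1}, lb=-1000.0, ub=1000.0),
        _rxn("SK_adp_c", {"adp_c": -1}, lb=-1000.0, ub=1000.0),
        _rxn("SK_pi_c", {"pi_c": -1}, lb=-1000.0, ub=1000.0),
        _rxn("SK_coa_c", {"coa_c": -1}, lb=-1000.0, ub=1000.0),
        _rxn("SK_h2o_c", {"h2o_c": -1}, lb=-1000.0, ub=1000.0),
    ]
    if with_acl:
        R.append(
            _rxn("ACL", {"cit_c": -1, "atp_c": -1, "coa_c": -1, "h2o_c": -1,
                         "oaa_c": 1, "accoa_c": 1, "adp_c": 1, "pi_c": 1},
                 _amap("ACL", [("cit_c", "abcdef")],
                       [("oaa_c", "fcba"), ("accoa_c", "ed")]))
        )

    model = NetworkModel(
        metabolites={m.id: m for m in mets},
        reactions={r.id: r for r in R},
        biomass_reaction_id="BIOMASS",
    )
    model.check()
    core = [r.id for r in R if r.atom_map is not None]
    return split_core(model, core, "glc__D_e")


def default_feed(n_carbons: int = 6, metabolite_id: str = "glc__D_e"
                 ) -> FeedLabeling:
    """The study feed: 80% [1-13C] plus 20% [U-13C] glucose."""
    return FeedLabeling(
        metabolite_id,
        [("1" + "0" * (n_carbons - 1), 0.8), ("1" * n_carbons, 0.2)],
    )


#: exchange reactions measured in the toy study design
TOY_MEASURED_EXCHANGES = ("EX_glc__D_e", "EX_etoh_e", "EX_ac_e", "EX_glyc_e")


def amino_acid_fragments() -> list[tuple[str, str, tuple[int, ...]]]:
    """(fragment_id, metabolite_id, positions) for the 12 measured amino acids."""
    out = []
    for aa in supported_amino_acids():
        n = sum(e.size for e in map_aa_to_precursor(aa))
        out.append((aa, aa, tuple(range(1, n + 1))))
    return out


# ---------------------------------------------------------------------------
# ground truth and measurement generation
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Known fluxes, feed, and noiseless fragment MDVs for a fixture."""

    split: CoreSplit
    v_true: dict[str, float]
    exchange_true: dict[str, float]
    feed: FeedLabeling
    fragments: list[tuple[str, str, tuple[int, ...]]]
    mdv_true: dict[str, np.ndarray]
    exchange_rates: dict[str, float]
    growth_rate: float | None


def sample_ground_truth(
    split: CoreSplit,
    seed: int,
    fragments: list[tuple[str, str, tuple[int, ...]]] | None = None,
    measured_exchange_ids: tuple[str, ...] | None = None,
    feed: FeedLabeling | None = None,
    glucose_uptake: float = DEFAULT_GLUCOSE_UPTAKE,
    uptake_reaction: str | None = "EX_glc__D_e",
) -> GroundTruth:
    """Random interior flux vector plus the noiseless labeling it generates.

    Sampling runs seeded hit-and-run on the polytope with the glucose exchange
    pinned to the configured uptake, so the ground truth sits at a realistic
    flux scale without post-hoc rescaling.
    """
    model = split.model
    if fragments is None:
        fragments = amino_acid_fragments()
    if measured_exchange_ids is None:
        measured_exchange_ids = tuple(
            r for r in TOY_MEASURED_EXCHANGES if r in model.reactions
        )
    if feed is None:
        n = model.metabolites[split.feed_metabolite_id].n_carbons
        feed = default_feed(n, split.feed_metabolite_id)

    sample_model = model.copy()
    if uptake_reaction and uptake_reaction in sample_model.reactions:
        rxn = sample_model.reactions[uptake_reaction]
        rxn.lower_bound = -glucose_uptake
        rxn.upper_bound = -glucose_uptake
    space = build_directed_space(sample_model, split.core_reaction_ids)
    rng = np.random.default_rng(seed)
    if space.dim == 0:
        alpha = np.zeros(0)
    else:
        center = space.chebyshev_center()
        alpha = space.hit_and_run(center, 1, rng, burn=400, thin=1)[0]
    d = space.directed(alpha)
    v_true = space.net_fluxes(d)
    exchange_true = space.exchange_fluxes(d)

    # noiseless fragment MDVs
    recipes = {
        fid: resolve_fragment(
            MDVMeasurement(
                fragment_id=fid,
                metabolite_id=met,
                positions=pos,
                values=MDV(fid, _unlabeled(len(pos))),
                sd=np.full(len(pos) + 1, 0.01),
            )
        )
        for fid, met, pos in fragments
    }
    targets = sorted({e for parts in recipes.values() for e in parts})
    network = emu_decompose(split, targets)
    from .labeling import labeling_fluxes

    w = labeling_fluxes(split, v_true, network.directed, exchange_true)
    sim = network.simulate(w, feed)
    mdv_true = {}
    for fid, parts in recipes.items():
        value = np.array([1.0])
        for e in parts:
            value = np.convolve(value, sim[e])
        mdv_true[fid] = value

    exchange_rates = {rid: v_true[rid] for rid in measured_exchange_ids}
    growth = (
        v_true[model.biomass_reaction_id]
        if model.biomass_reaction_id
        else None
    )
    return GroundTruth(
        split=split,
        v_true=v_true,
        exchange_true=exchange_true,
        feed=feed,
        fragments=list(fragments),
        mdv_true=mdv_true,
        exchange_rates=exchange_rates,
        growth_rate=growth,
    )


def _unlabeled(n: int) -> np.ndarray:
    out = np.zeros(n + 1)
    out[0] = 1.0
    return out


def generate_measurements(
    gt: GroundTruth, noise_sd: float = DEFAULT_NOISE_SD, seed: int = 0
) -> MeasurementSet:
    """Perturb the ground truth with the generator's noise model.

    MDV channels get independent additive Gaussian noise (clipped at 0 and
    renormalized); exchange fluxes and growth rate get 5% relative Gaussian
    noise.  ``noise_sd = 0`` reproduces the ground truth exactly.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    mdvs = []
    for fid, met, pos in gt.fragments:
        truth = gt.mdv_true[fid]
        if noise_sd > 0:
            noisy = np.clip(truth + rng.normal(0, noise_sd, len(truth)), 0,
                            None)
            noisy /= noisy.sum()
        else:
            noisy = truth / truth.sum()
        mdvs.append(
            MDVMeasurement(
                fragment_id=fid,
                metabolite_id=met,
                positions=pos,
                values=MDV(fid, noisy),
                sd=np.full(len(truth), max(noise_sd, 1e-6)),
            )
        )
    exchanges = []
    for rid, rate in gt.exchange_rates.items():
        sd = max(EXCHANGE_REL_NOISE * abs(rate), 0.01)
        value = rate + rng.normal(0, sd) if noise_sd > 0 else rate
        exchanges.append(ExchangeMeasurement(rid, value, sd))
    growth = None
    if gt.growth_rate is not None:
        sd = max(EXCHANGE_REL_NOISE * abs(gt.growth_rate), 1e-3)
        value = (
            gt.growth_rate + rng.normal(0, sd) if noise_sd > 0
            else gt.growth_rate
        )
        growth = (value, sd)
    return MeasurementSet(
        mdv_measurements=mdvs,
        exchange_measurements=exchanges,
        growth_rate=growth,
    )


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------


def emit_input_files(
    ms: MeasurementSet,
    split: CoreSplit,
    directory,
    feed: FeedLabeling,
    fit_options: dict | None = None,
    alpha: float = 0.95,
    elva_threshold: float = 0.01,
    min_flux: float = 0.01,
    balance_metabolite: str = "accoa_c",
) -> dict[str, str]:
    """Write the full pipeline input set (SBML, TSVs, feed YAML, config)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "sbml": directory / "model.xml",
        "atom_maps": directory / "atom_maps.tsv",
        "mdv_table": directory / "mdvs.tsv",
        "exchange_table": directory / "exchanges.tsv",
        "feed": directory / "feed.yaml",
        "core_reactions": directory / "core_reactions.txt",
        "config": directory / "config.yaml",
    }
    write_sbml(split.model, paths["sbml"])
    maps = {
        rid: split.model.reactions[rid].atom_map
        for rid in split.core_reaction_ids
    }
    symmetric = [
        m.id for m in split.model.metabolites.values() if m.symmetric
    ]
    write_atom_maps(maps, paths["atom_maps"], symmetric=symmetric)
    write_mdv_table(ms.mdv_measurements, paths["mdv_table"])
    exchanges = list(ms.exchange_measurements)
    write_exchange_table(exchanges, paths["exchange_table"])
    write_feed_yaml(feed, paths["feed"])
    with open(paths["core_reactions"], "w") as fh:
        fh.write("\n".join(sorted(split.core_reaction_ids)) + "\n")

    config = {
        "paths": {
            k: str(paths[k].name)
            for k in ("sbml", "atom_maps", "mdv_table", "exchange_table",
                      "feed", "core_reactions")
        },
        "feed_metabolite": split.feed_metabolite_id,
        "growth_rate": (
            None
            if ms.growth_rate is None
            else {"value": float(ms.growth_rate[0]),
                  "sd": float(ms.growth_rate[1])}
        ),
        "fit": fit_options or {"n_starts": 10, "seed": 0},
        "alpha": alpha,
        "elva_threshold": elva_threshold,
        "min_flux": min_flux,
        "balance_metabolite": balance_metabolite,
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return {k: str(p) for k, p in paths.items()}


# ---------------------------------------------------------------------------
# small validation fixtures (oracle-sized)
# ---------------------------------------------------------------------------


def build_linear_chain(uptake: float = 10.0) -> CoreSplit:
    """Fully determined linear pathway: feed → A → B → C → drain.

    The feed exchange is pinned to ``-uptake``, so every flux is structurally
    fixed; confidence intervals must collapse to points.
    """
    mets = [_met("a_e", 2), _met("a_c", 2), _met("b_c", 2), _met("c_c", 2)]
    R = [
        _rxn("EX_a", {"a_e": -1}, lb=-uptake, ub=-uptake),
        _rxn("U", {"a_e": -1, "a_c": 1},
             _amap("U", [("a_e", "ab")], [("a_c", "ab")]), ub=2 * uptake),
        _rxn("AB", {"a_c": -1, "b_c": 1},
             _amap("AB", [("a_c", "ab")], [("b_c", "ab")]), ub=2 * uptake),
        _rxn("BC", {"b_c": -1, "c_c": 1},
             _amap("BC", [("b_c", "ab")], [("c_c", "ab")]), ub=2 * uptake),
        _rxn("DC", {"c_c": -1}, ub=2 * uptake),
    ]
    model = NetworkModel({m.id: m for m in mets}, {r.id: r for r in R})
    model.check()
    return split_core(model, ["U", "AB", "BC"], "a_e")


def build_parallel_routes(uptake: float = 10.0) -> CoreSplit:
    """Two routes with identical carbon transitions: structurally unidentifiable."""
    mets = [_met("s_e", 2), _met("s_c", 2), _met("x_c", 2)]
    R = [
        _rxn("EX_s", {"s_e": -1}, lb=-uptake, ub=-uptake),
        _rxn("U", {"s_e": -1, "s_c": 1},
             _amap("U", [("s_e", "ab")], [("s_c", "ab")]), ub=2 * uptake),
        _rxn("R1", {"s_c": -1, "x_c": 1},
             _amap("R1", [("s_c", "ab")], [("x_c", "ab")]), ub=2 * uptake),
        _rxn("R2", {"s_c": -1, "x_c": 1},
             _amap("R2", [("s_c", "ab")], [("x_c", "ab")]), ub=2 * uptake),
        _rxn("DX", {"x_c": -1}, ub=2 * uptake),
    ]
    model = NetworkModel({m.id: m for m in mets}, {r.id: r for r in R})
    model.check()
    return split_core(model, ["U", "R1", "R2"], "s_e")


def build_branch_fixture(uptake: float = 10.0) -> CoreSplit:
    """Identifiable branch point: two routes that scramble carbon differently.

    Route R1 preserves the carbon order of the 2-carbon substrate, R2 reverses
    it; cleaving the product and measuring the 1-carbon halves makes the split
    ratio observable (with a [1-13C] feed, M1 of the first half equals the R1
    fraction).
    """
    mets = [_met("s_e", 2), _met("s_c", 2), _met("x_c", 2), _met("p_c", 1),
            _met("q_c", 1)]
    R = [
        _rxn("EX_s", {"s_e": -1}, lb=-uptake, ub=-uptake),
        _rxn("U", {"s_e": -1, "s_c": 1},
             _amap("U", [("s_e", "ab")], [("s_c", "ab")]), ub=2 * uptake),
        _rxn("R1", {"s_c": -1, "x_c": 1},
             _amap("R1", [("s_c", "ab")], [("x_c", "ab")]), ub=2 * uptake),
        _rxn("R2", {"s_c": -1, "x_c": 1},
             _amap("R2", [("s_c", "ab")], [("x_c", "ba")]), ub=2 * uptake),
        _rxn("CLV", {"x_c": -1, "p_c": 1, "q_c": 1},
             _amap("CLV", [("x_c", "ab")], [("p_c", "a"), ("q_c", "b")]),
             ub=2 * uptake),
        _rxn("DP", {"p_c": -1}, ub=2 * uptake),
        _rxn("DQ", {"q_c": -1}, ub=2 * uptake),
    ]
    model = NetworkModel({m.id: m for m in mets}, {r.id: r for r in R})
    model.check()
    return split_core(model, ["U", "R1", "R2", "CLV"], "s_e")


def branch_feed() -> FeedLabeling:
    return FeedLabeling("s_e", [("10", 1.0)])


def build_condensation_fixture(uptake: float = 10.0) -> CoreSplit:
    """Cleavage plus condensation: exercises EMU convolutions end to end."""
    mets = [_met("a_e", 2), _met("a_c", 2), _met("b_c", 1), _met("c_c", 1),
            _met("d_c", 2)]
    R = [
        _rxn("EX_a", {"a_e": -1}, lb=-uptake, ub=-uptake),
        _rxn("U", {"a_e": -1, "a_c": 1},
             _amap("U", [("a_e", "ab")], [("a_c", "ab")]), ub=2 * uptake),
        _rxn("CLV", {"a_c": -1, "b_c": 1, "c_c": 1},
             _amap("CLV", [("a_c", "ab")], [("b_c", "a"), ("c_c", "b")]),
             ub=2 * uptake),
        _rxn("CND", {"b_c": -1, "c_c": -1, "d_c": 1},
             _amap("CND", [("b_c", "a"), ("c_c", "b")], [("d_c", "ba")]),
             ub=2 * uptake),
        _rxn("DD", {"d_c": -1}, ub=2 * uptake),
    ]
    model = NetworkModel({m.id: m for m in mets}, {r.id: r for r in R})
    model.check()
    return split_core(model, ["U", "CLV", "CND"], "a_e")


def build_mini_tca(uptake: float = 2.0) -> CoreSplit:
    """Small cyclic network with symmetric succinate and a reversible step.

    23 total core carbons, within the isotopomer-enumeration budget; covers
    condensation (citrate synthase), double-product decarboxylation, pool
    symmetry, and forward/backward exchange flux.
    """
    mets = [_met("ac_e", 2), _met("accoa_c", 2), _met("oaa_c", 4),
            _met("cit_c", 6), _met("succ_c", 4, symmetric=True),
            _met("mal_c", 4), _met("co2_c", 1)]
    R = [
        _rxn("EX_ac", {"ac_e": -1}, lb=-uptake, ub=-uptake),
        _rxn("ACS", {"ac_e": -1, "accoa_c": 1},
             _amap("ACS", [("ac_e", "ab")], [("accoa_c", "ab")]),
             ub=5 * uptake),
        _rxn("CS", {"accoa_c": -1, "oaa_c": -1, "cit_c": 1},
             _amap("CS", [("oaa_c", "abcd"), ("accoa_c", "ef")],
                   [("cit_c", "dcbfea")]), ub=5 * uptake),
        _rxn("IDH", {"cit_c": -1, "succ_c": 1, "co2_c": 2},
             _amap("IDH", [("cit_c", "abcdef")],
                   [("succ_c", "bcde"), ("co2_c", "a"), ("co2_c", "f")]),
             ub=5 * uptake),
        _rxn("FUM", {"succ_c": -1, "mal_c": 1},
             _amap("FUM", [("succ_c", "abcd")], [("mal_c", "abcd")]),
             lb=-5 * uptake, ub=5 * uptake),
        _rxn("MDH", {"mal_c": -1, "oaa_c": 1},
             _amap("MDH", [("mal_c", "abcd")], [("oaa_c", "abcd")]),
             ub=5 * uptake),
        _rxn("EX_co2", {"co2_c": -1}, ub=20 * uptake),
    ]
    model = NetworkModel({m.id: m for m in mets}, {r.id: r for r in R})
    model.check()
    return split_core(model, ["ACS", "CS", "IDH", "FUM", "MDH"], "ac_e")


def mini_tca_feed() -> FeedLabeling:
    return FeedLabeling("ac_e", [("01", 0.5), ("00", 0.5)])


def build_elva_fixture() -> CoreSplit:
    """Core chain with a 10% unmapped (non-core) influx into the core pool B."""
    mets = [_met("a_e", 2), _met("a_c", 2), _met("b_c", 2), _met("z_c", 2)]
    R = [
        _rxn("EX_a", {"a_e": -1}, lb=-9.0, ub=-9.0),
        _rxn("U", {"a_e": -1, "a_c": 1},
             _amap("U", [("a_e", "ab")], [("a_c", "ab")])),
        _rxn("AB", {"a_c": -1, "b_c": 1},
             _amap("AB", [("a_c", "ab")], [("b_c", "ab")])),
        _rxn("SK_z", {"z_c": 1}, lb=0.0, ub=20.0),
        _rxn("ZB", {"z_c": -1, "b_c": 1}, lb=1.0, ub=1.0),  # non-core influx
        _rxn("DB", {"b_c": -1}),
    ]
    model = NetworkModel({m.id: m for m in mets}, {r.id: r for r in R})
    model.check()
    return split_core(model, ["U", "AB"], "a_e")
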