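"""Stoichiometric network model with carbon-atom maps and a core/non-core split.

The two-scale idea: a genome-scale stoichiometric model constrains all fluxes
through mass balance (S·v = 0) and bounds, while a designated *core* subnetwork
additionally carries carbon-atom transition maps so that isotope labeling can be
simulated for its metabolites.  Core reactions must be atom-mapped; everything
else is tracked by stoichiometry only, and carbon influx from non-core reactions
into core pools is assumed negligible (quantified separately by ELVA).

Identifiers follow BIGG conventions: metabolite ids end in a compartment suffix
(``accoa_c``, ``mal_m``), with compartments cytosol ``c``, mitochondrion ``m``,
peroxisome ``x``, and extracellular ``e``.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

COMPARTMENTS = ("c", "m", "x", "e")

#: default bounds applied when an SBML file carries none
DEFAULT_BOUND = 1000.0


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a model or split violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    """A metabolite in one compartment.

    ``n_carbons`` is the number of (tracer-relevant) carbon atoms; cofactors
    and other species excluded from labeling carry 0.  ``symmetric`` marks
    molecules (succinate, fumarate) whose two orientations are chemically
    indistinguishable, triggering 0.5/0.5 scrambling on consumption.
    """

    id: str
    name: str = ""
    n_carbons: int = 0
    compartment: str = "c"
    symmetric: bool = False

    def __post_init__(self):
        if self.n_carbons < 0:
            raise ValidationError(f"{self.id}: n_carbons must be >= 0")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"{self.id}: unknown compartment {self.compartment!r}"
            )
        suffix = self.id.rsplit("_", 1)[-1]
        if suffix != self.compartment:
            raise ValidationError(
                f"metabolite id {self.id!r} does not end in compartment "
                f"suffix _{self.compartment}"
            )


@dataclass(frozen=True)
class AtomMap:
    """Carbon transitions of one reaction.

    Each slot is a ``(metabolite_id, letters)`` pair, one per stoichiometric
    instance of a carbon-bearing metabolite; the k-th letter names the atom at
    carbon position k.  The multiset of letters must be conserved across sides.
    """

    reaction_id: str
    reactant_slots: tuple[tuple[str, str], ...]
    product_slots: tuple[tuple[str, str], ...]


@dataclass
class Reaction:
    """A (possibly exchange) reaction with flux bounds in mmol/gDW/h.

    Stoichiometric coefficients are signed: negative for substrates, positive
    for products.  Exchange reactions touch a single metabolite and model
    transport across the system boundary.
    """

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    atom_map: AtomMap | None = None

    @property
    def substrates(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1


@dataclass
class NetworkModel:
    """A stoichiometric model: metabolites, reactions, and a biomass reaction."""

    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    biomass_reaction_id: str | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty means valid)."""
        problems = []
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    problems.append(
                        f"reaction {rxn.id} references unknown metabolite {met}"
                    )
            if not rxn.is_exchange:
                if not rxn.substrates or not rxn.products:
                    problems.append(
                        f"reaction {rxn.id} lacks a substrate or product"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                problems.append(f"reaction {rxn.id}: lower bound > upper bound")
            if not rxn.reversible and rxn.lower_bound < 0:
                problems.append(
                    f"reaction {rxn.id}: irreversible but lower bound < 0"
                )
        return problems

    def check(self) -> None:
        problems = self.validate()
        if problems:
            raise ValidationError("; ".join(problems))

    def stoichiometric_matrix(
        self, reaction_ids: list[str] | None = None
    ) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S (one row per metabolite, one column per reaction)."""
        rxn_ids = list(self.reactions) if reaction_ids is None else reaction_ids
        met_ids = sorted(self.metabolites)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met, coeff in self.reactions[rid].stoichiometry.items():
                S[met_index[met], j] = coeff
        return S, met_ids, rxn_ids

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            metabolites=dict(self.metabolites),
            reactions={
                rid: Reaction(
                    id=r.id,
                    stoichiometry=dict(r.stoichiometry),
                    name=r.name,
                    reversible=r.reversible,
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    atom_map=r.atom_map,
                )
                for rid, r in self.reactions.items()
            },
            biomass_reaction_id=self.biomass_reaction_id,
        )


@dataclass
class CoreSplit:
    """A model plus its core reaction set and the labeled feed metabolite."""

    model: NetworkModel
    core_reaction_ids: frozenset[str]
    feed_metabolite_id: str

    def validate(self) -> list[str]:
        problems = []
        model = self.model
        for rid in sorted(self.core_reaction_ids):
            if rid not in model.reactions:
                problems.append(f"core reaction {rid} not in model")
            elif model.reactions[rid].atom_map is None:
                problems.append(f"core reaction {rid} has no atom map")
        for rid, rxn in model.reactions.items():
            if rxn.atom_map is not None and rid not in self.core_reaction_ids:
                problems.append(f"atom-mapped reaction {rid} is not core")
        if self.feed_metabolite_id not in model.metabolites:
            problems.append(f"feed metabolite {self.feed_metabolite_id} missing")
        else:
            touched = any(
                self.feed_metabolite_id in model.reactions[rid].stoichiometry
                for rid in self.core_reaction_ids
                if rid in model.reactions
            )
            if not touched:
                problems.append(
                    f"feed metabolite {self.feed_metabolite_id} does not "
                    "participate in any core reaction"
                )
        return problems

    def check(self) -> None:
        problems = self.validate()
        if problems:
            raise ValidationError("; ".join(problems))


# ---------------------------------------------------------------------------
# atom-map validation
# ---------------------------------------------------------------------------


def _validate_one_atom_map(model: NetworkModel, am: AtomMap) -> list[str]:
    problems: list[str] = []
    rid = am.reaction_id
    if rid not in model.reactions:
        return [f"{rid}: atom map for unknown reaction"]
    rxn = model.reactions[rid]

    for side_name, slots, stoich in (
        ("reactant", am.reactant_slots, rxn.substrates),
        ("product", am.product_slots, rxn.products),
    ):
        seen: Counter = Counter()
        letters: Counter = Counter()
        for met, s in slots:
            seen[met] += 1
            if met not in model.metabolites:
                problems.append(f"{rid}: {side_name} slot names unknown {met}")
                continue
            n_c = model.metabolites[met].n_carbons
            if len(s) != n_c:
                problems.append(
                    f"{rid}: {side_name} slot {met} has {len(s)} letters, "
                    f"metabolite has {n_c} carbons"
                )
            letters.update(s)
        # every carbon-bearing instance must have exactly one slot
        for met, coeff in stoich.items():
            n_c = model.metabolites[met].n_carbons if met in model.metabolites else 0
            if n_c > 0 and seen[met] != round(coeff):
                problems.append(
                    f"{rid}: {side_name} {met} has {seen[met]} slots for "
                    f"stoichiometric coefficient {coeff}"
                )
        dup = [x for x, k in letters.items() if k > 1]
        if dup:
            problems.append(
                f"{rid}: {side_name} letters used more than once: {sorted(dup)}"
            )
    r_letters = Counter()
    for _, s in am.reactant_slots:
        r_letters.update(s)
    p_letters = Counter()
    for _, s in am.product_slots:
        p_letters.update(s)
    if r_letters != p_letters:
        problems.append(
            f"{rid}: carbon not conserved (reactant letters "
            f"{sorted(r_letters.elements())} vs product letters "
            f"{sorted(p_letters.elements())})"
        )
    return problems


def validate_atom_maps(split: CoreSplit) -> list[str]:
    """Per-reaction carbon-conservation and length checks; empty ⇔ valid."""
    report: list[str] = []
    for rid in sorted(split.core_reaction_ids):
        rxn = split.model.reactions.get(rid)
        if rxn is None or rxn.atom_map is None:
            report.append(f"{rid}: core reaction without atom map")
            continue
        report.extend(_validate_one_atom_map(split.model, rxn.atom_map))
    return report


def split_core(
    model: NetworkModel, core_ids, feed: str
) -> CoreSplit:
    """Designate ``core_ids`` as the atom-mapped core with ``feed`` as tracer source.

    Raises :class:`ValidationError` naming offenders if a core reaction lacks an
    atom map, if the set is empty, or if the split invariants fail.
    """
    core_ids = frozenset(core_ids)
    if not core_ids:
        raise ValidationError(
            "empty core set: labeling simulation is impossible without "
            "at least one atom-mapped reaction"
        )
    missing = sorted(r for r in core_ids if r not in model.reactions)
    if missing:
        raise ValidationError(f"core reactions not in model: {missing}")
    unmapped = sorted(
        r for r in core_ids if model.reactions[r].atom_map is None
    )
    if unmapped:
        raise ValidationError(
            f"core reactions lacking atom maps: {unmapped}"
        )
    split = CoreSplit(model=model, core_reaction_ids=core_ids,
                      feed_metabolite_id=feed)
    split.check()
    return split


# ---------------------------------------------------------------------------
# atom-map TSV I/O
# ---------------------------------------------------------------------------
# Format: three tab-separated columns (reaction_id, reactant_slots,
# product_slots); slots are space-separated "metabolite=letters" tokens, with
# a bare "metabolite=" allowed for zero-carbon species.  '#' starts a comment;
# the directive line "#! symmetric: id id ..." lists symmetric metabolites.


def _parse_slots(text: str) -> tuple[tuple[str, str], ...]:
    slots = []
    for token in text.split():
        if "=" not in token:
            raise FormatError(f"bad slot token {token!r} (expected met=letters)")
        met, letters = token.split("=", 1)
        slots.append((met, letters))
    return tuple(slots)


def read_atom_maps(path) -> tuple[dict[str, AtomMap], set[str]]:
    maps: dict[str, AtomMap] = {}
    symmetric: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#!"):
                body = line[2:].strip()
                if body.startswith("symmetric:"):
                    symmetric.update(body.split(":", 1)[1].split())
                continue
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            rid, reac, prod = parts
            if rid in maps:
                raise FormatError(f"{path}:{lineno}: duplicate reaction {rid}")
            maps[rid] = AtomMap(rid, _parse_slots(reac), _parse_slots(prod))
    return maps, symmetric


def write_atom_maps(maps: dict[str, AtomMap], path, symmetric=()) -> None:
    with open(path, "w") as fh:
        fh.write("# reaction_id\treactant_slots\tproduct_slots\n")
        if symmetric:
            fh.write("#! symmetric: " + " ".join(sorted(symmetric)) + "\n")
        for rid in sorted(maps):
            am = maps[rid]
            reac = " ".join(f"{m}={s}" for m, s in am.reactant_slots)
            prod = " ".join(f"{m}={s}" for m, s in am.product_slots)
            fh.write(f"{rid}\t{reac}\t{prod}\n")


def apply_atom_maps(
    model: NetworkModel, maps: dict[str, AtomMap], symmetric=()
) -> NetworkModel:
    """Attach atom maps to reactions and set symmetric flags (returns a copy)."""
    out = model.copy()
    for rid, am in maps.items():
        if rid not in out.reactions:
            raise ValidationError(f"atom map for unknown reaction {rid}")
        out.reactions[rid].atom_map = am
    for mid in symmetric:
        if mid not in out.metabolites:
            raise ValidationError(f"symmetric flag for unknown metabolite {mid}")
        out.metabolites[mid] = replace(out.metabolites[mid], symmetric=True)
    return out


# ---------------------------------------------------------------------------
# SBML I/O (Level 3 + FBC preferred, Level 2 accepted)
# ---------------------------------------------------------------------------

_FORMULA_C = re.compile(r"C(?![a-z])(\d*)")


def n_carbons_from_formula(formula: str | None) -> int | None:
    """Carbon count from a chemical formula, or None if no formula."""
    if not formula:
        return None
    m = _FORMULA_C.search(formula)
    if not m:
        return 0
    return int(m.group(1)) if m.group(1) else 1


def load_sbml(path) -> NetworkModel:
    """Read an SBML model (Level 2 or Level 3/FBC) into a :class:`NetworkModel`.

    Exchange reactions are detected as single-metabolite reactions.  Carbon
    counts come from FBC ``chemicalFormula`` (or a ``FORMULA`` note); species
    without a formula get ``n_carbons = 0`` with a warning, which excludes them
    from labeling but not from stoichiometry.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise FormatError(f"unparseable SBML {path}: " + " | ".join(msgs[:3]))
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"no model element in {path}")

    def _strip(sid: str, prefix: str) -> str:
        # BIGG-style SBML prefixes ("M_", "R_") keep SIds legal for ids that
        # start with a digit; strip them back off on read
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    metabolites: dict[str, Metabolite] = {}
    no_formula: list[str] = []
    for sp in sbml_model.getListOfSpecies():
        sid = _strip(sp.getId(), "M_")
        if sid in metabolites:
            raise ValidationError(f"duplicate species id {sid}")
        formula = None
        fbc_sp = sp.getPlugin("fbc")
        if fbc_sp is not None and fbc_sp.isSetChemicalFormula():
            formula = fbc_sp.getChemicalFormula()
        if formula is None and sp.isSetNotes():
            note = sp.getNotesString()
            m = re.search(r"FORMULA:\s*([A-Za-z0-9]+)", note)
            if m:
                formula = m.group(1)
        n_c = n_carbons_from_formula(formula)
        if n_c is None:
            no_formula.append(sid)
            n_c = 0
        compartment = sp.getCompartment() or sid.rsplit("_", 1)[-1]
        metabolites[sid] = Metabolite(
            id=sid,
            name=sp.getName() or "",
            n_carbons=n_c,
            compartment=compartment,
        )
    if no_formula:
        warnings.warn(
            f"{len(no_formula)} species without formula annotations get "
            f"n_carbons=0 and are excluded from labeling: "
            f"{sorted(no_formula)[:8]}...",
            stacklevel=2,
        )

    def _bound_value(sbml_rxn, which: str, fallback: float) -> float:
        fbc_rxn = sbml_rxn.getPlugin("fbc")
        if fbc_rxn is not None:
            pid = (
                fbc_rxn.getLowerFluxBound()
                if which == "lower"
                else fbc_rxn.getUpperFluxBound()
            )
            if pid:
                par = sbml_model.getParameter(pid)
                if par is not None:
                    return par.getValue()
        kl = sbml_rxn.getKineticLaw()
        if kl is not None:
            name = "LOWER_BOUND" if which == "lower" else "UPPER_BOUND"
            par = kl.getParameter(name)
            if par is not None:
                return par.getValue()
        return fallback

    reactions: dict[str, Reaction] = {}
    for sr in sbml_model.getListOfReactions():
        rid = _strip(sr.getId(), "R_")
        if rid in reactions:
            raise ValidationError(f"duplicate reaction id {rid}")
        stoich: dict[str, float] = {}
        for ref in sr.getListOfReactants():
            met = _strip(ref.getSpecies(), "M_")
            if met not in metabolites:
                raise ValidationError(
                    f"reaction {rid} references missing species {met}"
                )
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for ref in sr.getListOfProducts():
            met = _strip(ref.getSpecies(), "M_")
            if met not in metabolites:
                raise ValidationError(
                    f"reaction {rid} references missing species {met}"
                )
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        reversible = sr.getReversible()
        lb = _bound_value(sr, "lower", -DEFAULT_BOUND if reversible else 0.0)
        ub = _bound_value(sr, "upper", DEFAULT_BOUND)
        reactions[rid] = Reaction(
            id=rid,
            name=sr.getName() or "",
            stoichiometry=stoich,
            reversible=lb < 0,
            lower_bound=lb,
            upper_bound=ub,
        )

    biomass = None
    fbc_model = sbml_model.getPlugin("fbc")
    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            biomass = _strip(obj.getFluxObjective(0).getReaction(), "R_")
    if biomass is None:
        for rid in reactions:
            if "biomass" in rid.lower():
                biomass = rid
                break

    model = NetworkModel(metabolites, reactions, biomass_reaction_id=biomass)
    model.check()
    return model


def write_sbml(model: NetworkModel, path) -> None:
    """Write a Level 3 + FBC SBML file readable by :func:`load_sbml`."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId("model")
    fbc_model = sm.getPlugin("fbc")
    fbc_model.setStrict(True)

    for comp in sorted({m.compartment for m in model.metabolites.values()}):
        c = sm.createCompartment()
        c.setId(comp)
        c.setConstant(True)
        c.setSize(1.0)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(f"M_{met.id}")
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialConcentration(0.0)
        if met.n_carbons > 0:
            sp.getPlugin("fbc").setChemicalFormula(f"C{met.n_carbons}")

    def _param(value: float, pid: str) -> str:
        par = sm.createParameter()
        par.setId(pid)
        par.setValue(value)
        par.setConstant(True)
        return pid

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(f"R_{rxn.id}")
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met, coeff in rxn.substrates.items():
            ref = sr.createReactant()
            ref.setSpecies(f"M_{met}")
            ref.setStoichiometry(coeff)
            ref.setConstant(True)
        for met, coeff in rxn.products.items():
            ref = sr.createProduct()
            ref.setSpecies(f"M_{met}")
            ref.setStoichiometry(coeff)
            ref.setConstant(True)
        fbc_rxn = sr.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(_param(rxn.lower_bound, f"R_{rxn.id}_lb"))
        fbc_rxn.setUpperFluxBound(_param(rxn.upper_bound, f"R_{rxn.id}_ub"))

    if model.biomass_reaction_id:
        obj = fbc_model.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(f"R_{model.biomass_reaction_id}")
        fo.setCoefficient(1.0)
        fbc_model.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")
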