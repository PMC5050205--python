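"""Steady-state isotope labeling simulation on the core network.

Labeling is propagated with the elementary-metabolite-unit (EMU) decomposition:
starting from the measured fragments, the minimal set of carbon-atom subsets
whose mass distributions influence them is traced backward through the atom
maps, and one linear balance system is solved per EMU size, smallest first.
Condensation reactions enter as convolutions of smaller EMUs, so the cascade is
closed and finite.

Conventions and choices
-----------------------
* Reversible core reactions are decomposed into a forward and a backward
  irreversible reaction; the labeling flux vector ``w`` therefore contains only
  non-negative entries, one per directed mapped reaction.
* Symmetric metabolites (succinate, fumarate) are scrambled on consumption:
  every directed reaction consuming one is expanded into orientation variants
  of weight 1/2 each.
* Carbon influx into core pools from non-core (unmapped) reactions is ignored
  by the balances — the two-scale validity assumption that flux does not flow
  back from peripheral metabolism.  ELVA bounds the consequences.

A brute-force positional-isotopomer oracle (:func:`isotopomer_oracle`) solves
the same steady state by fixed-point iteration over all 2**n isotopomer states
and is used to validate the EMU path on small networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .core_network import CoreSplit, ValidationError

logger = logging.getLogger(__name__)

MDV_SUM_TOL = 1e-9
MDV_NEG_TOL = -1e-12


class SingularBalanceError(RuntimeError):
    """A core metabolite has zero influx but nonzero outflux demand."""


class NetworkSizeError(ValueError):
    """Isotopomer enumeration refused: network exceeds the carbon budget."""


# ---------------------------------------------------------------------------
# basic types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class EMU:
    """A subset of one metabolite's carbon atoms (1-based positions)."""

    metabolite_id: str
    positions: tuple[int, ...]

    def __post_init__(self):
        pos = tuple(sorted(self.positions))
        object.__setattr__(self, "positions", pos)
        if not pos:
            raise ValidationError(f"EMU on {self.metabolite_id}: empty positions")
        if len(set(pos)) != len(pos) or pos[0] < 1:
            raise ValidationError(
                f"EMU on {self.metabolite_id}: bad positions {pos}"
            )

    @property
    def size(self) -> int:
        return len(self.positions)

    def __str__(self) -> str:
        return f"{self.metabolite_id}{{{','.join(map(str, self.positions))}}}"


def full_emu(metabolite_id: str, n_carbons: int) -> EMU:
    return EMU(metabolite_id, tuple(range(1, n_carbons + 1)))


@dataclass
class MDV:
    """Mass distribution vector of a fragment: fractions at shifts M0..Mn."""

    fragment: EMU | str
    fractions: np.ndarray

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.validate()

    def validate(self) -> None:
        if np.any(self.fractions < MDV_NEG_TOL):
            raise ValidationError(
                f"MDV {self.fragment}: negative fraction "
                f"{self.fractions.min():.3e}"
            )
        s = self.fractions.sum()
        if abs(s - 1.0) > MDV_SUM_TOL:
            raise ValidationError(
                f"MDV {self.fragment}: fractions sum to {s:.12f}, not 1"
            )

    def __len__(self) -> int:
        return len(self.fractions)


@dataclass
class FeedLabeling:
    """Positional labeling of the feed as a mixture of isotopologues.

    ``components`` is a list of ``(pattern, fraction)`` pairs where pattern is
    a 0/1 string over carbon positions (1 = 13C).  The study design here is a
    glucose feed of 80% [1-13C] plus 20% [U-13C]:
    ``[("100000", 0.8), ("111111", 0.2)]``.
    """

    metabolite_id: str
    components: list[tuple[str, float]]
    purity: float = 1.0  # isotopic enrichment of nominally labeled positions

    def __post_init__(self):
        fracs = np.array([f for _, f in self.components], dtype=float)
        if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > MDV_SUM_TOL:
            raise ValidationError(
                f"feed fractions must be >= 0 and sum to 1, got {fracs}"
            )
        lengths = {len(p) for p, _ in self.components}
        if len(lengths) > 1:
            raise ValidationError("feed patterns differ in length")
        if not 0.0 <= self.purity <= 1.0:
            raise ValidationError("purity must be in [0, 1]")

    @property
    def n_carbons(self) -> int:
        return len(self.components[0][0])


def feed_mdv(feed: FeedLabeling, emu: EMU) -> MDV:
    """MDV of ``emu`` (positions of the feed metabolite) under the feed mixture."""
    if emu.metabolite_id != feed.metabolite_id:
        raise ValidationError(
            f"EMU metabolite {emu.metabolite_id} != feed {feed.metabolite_id}"
        )
    n = feed.n_carbons
    if any(p > n for p in emu.positions):
        raise ValidationError(
            f"EMU positions {emu.positions} out of range for {n}-carbon feed"
        )
    out = np.zeros(emu.size + 1)
    for pattern, frac in feed.components:
        dist = np.array([1.0])
        for p in emu.positions:
            atom = (
                np.array([1.0 - feed.purity, feed.purity])
                if pattern[p - 1] == "1"
                else np.array([1.0, 0.0])
            )
            dist = np.convolve(dist, atom)
        out[: len(dist)] += frac * dist
    return MDV(emu, out)


def convolve(a: MDV | np.ndarray, b: MDV | np.ndarray) -> np.ndarray:
    """Discrete convolution of two MDVs (labeling of a condensation product)."""
    va = a.fractions if isinstance(a, MDV) else np.asarray(a, dtype=float)
    vb = b.fractions if isinstance(b, MDV) else np.asarray(b, dtype=float)
    out = np.convolve(va, vb)
    s = out.sum()
    if abs(s - 1.0) > 1e-12 and s > 0:
        out = out / s
    return out


# ---------------------------------------------------------------------------
# directed mapped reactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DirectedLabelReaction:
    """One direction of an atom-mapped reaction; index into the labeling flux w."""

    reaction_id: str
    direction: int  # +1 forward, -1 backward
    index: int
    substrates: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]

    @property
    def key(self) -> tuple[str, int]:
        return (self.reaction_id, self.direction)


def build_directed_label_reactions(split: CoreSplit) -> list[DirectedLabelReaction]:
    """Directed reaction table for the core; deterministic (sorted by id)."""
    out: list[DirectedLabelReaction] = []
    idx = 0
    for rid in sorted(split.core_reaction_ids):
        rxn = split.model.reactions[rid]
        am = rxn.atom_map
        subs = tuple((m, s) for m, s in am.reactant_slots if s)
        prods = tuple((m, s) for m, s in am.product_slots if s)
        out.append(DirectedLabelReaction(rid, +1, idx, subs, prods))
        idx += 1
        if rxn.lower_bound < 0:  # reversible: add the backward direction
            out.append(DirectedLabelReaction(rid, -1, idx, prods, subs))
            idx += 1
    return out


@dataclass(frozen=True)
class _Variant:
    """A directed reaction after symmetric-substrate scrambling expansion."""

    flux_index: int
    weight: float
    substrates: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]


def _expand_symmetric(
    split: CoreSplit, directed: list[DirectedLabelReaction]
) -> list[_Variant]:
    mets = split.model.metabolites
    variants: list[_Variant] = []
    for dr in directed:
        pool = [(_Variant(dr.index, 1.0, dr.substrates, dr.products))]
        for slot_i, (met, letters) in enumerate(dr.substrates):
            if mets[met].symmetric and len(letters) > 1:
                nxt = []
                for var in pool:
                    subs = list(var.substrates)
                    flipped = subs[slot_i][1][::-1]
                    subs_f = list(subs)
                    subs_f[slot_i] = (met, flipped)
                    nxt.append(
                        _Variant(var.flux_index, var.weight * 0.5,
                                 var.substrates, var.products)
                    )
                    nxt.append(
                        _Variant(var.flux_index, var.weight * 0.5,
                                 tuple(subs_f), var.products)
                    )
                pool = nxt
        variants.extend(pool)
    return variants


# ---------------------------------------------------------------------------
# EMU network compilation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Term:
    """One production channel of an EMU: flux index, weight, precursor EMUs."""

    flux_index: int
    weight: float
    precursors: tuple[EMU, ...]


@dataclass
class EmuNetwork:
    """Backward-traced EMU dependency network, layered by EMU size."""

    split: CoreSplit
    targets: list[EMU]
    directed: list[DirectedLabelReaction]
    emus_by_size: dict[int, list[EMU]] = field(default_factory=dict)
    terms: dict[EMU, list[_Term]] = field(default_factory=dict)
    #: symmetric targets are read out as the average with their mirror EMU
    readout: dict[EMU, tuple[EMU, ...]] = field(default_factory=dict)
    #: mapped consumption channels per metabolite: (flux_index, weight)
    met_consumption: dict[str, list[tuple[int, float]]] = field(
        default_factory=dict
    )

    @property
    def n_fluxes(self) -> int:
        return len(self.directed)

    def flux_keys(self) -> list[tuple[str, int]]:
        return [dr.key for dr in self.directed]

    # -- simulation -------------------------------------------------------

    def _sources(self, feed: FeedLabeling) -> dict[EMU, np.ndarray]:
        src = {}
        for size in sorted(self.emus_by_size):
            for emu in self.emus_by_size[size]:
                if emu.metabolite_id == self.split.feed_metabolite_id:
                    src[emu] = feed_mdv(feed, emu).fractions
        return src

    def simulate(self, w: np.ndarray, feed: FeedLabeling) -> dict[EMU, np.ndarray]:
        """Solve the size-layered EMU balances at labeling fluxes ``w``."""
        values, _ = self._solve(np.asarray(w, dtype=float), feed, jac=False)
        return self._readout(values)

    def simulate_with_jac(
        self, w: np.ndarray, feed: FeedLabeling
    ) -> tuple[dict[EMU, np.ndarray], dict[EMU, np.ndarray]]:
        """MDVs plus their Jacobians d(mdv)/d(w), shape (n_fluxes, size+1)."""
        values, dvalues = self._solve(np.asarray(w, dtype=float), feed, jac=True)
        return self._readout(values), self._readout(dvalues)

    def _readout(self, values: dict[EMU, np.ndarray]) -> dict[EMU, np.ndarray]:
        out = {}
        for tgt in self.targets:
            parts = self.readout[tgt]
            out[tgt] = sum(values[p] for p in parts) / len(parts)
        return out

    def _solve(self, w, feed, jac):
        if np.any(w < -1e-9):
            raise ValidationError("labeling fluxes must be non-negative")
        w = np.clip(w, 0.0, None)
        if w.shape != (self.n_fluxes,):
            raise ValidationError(
                f"flux vector has shape {w.shape}, expected ({self.n_fluxes},)"
            )
        if not np.any(w > 0):
            raise SingularBalanceError("flux-free network: no labeling flux")
        nf = self.n_fluxes
        values: dict[EMU, np.ndarray] = self._sources(feed)
        dvalues: dict[EMU, np.ndarray] = {
            e: np.zeros((nf, len(v))) for e, v in values.items()
        }

        for size in sorted(self.emus_by_size):
            unknowns = [
                e
                for e in self.emus_by_size[size]
                if e.metabolite_id != self.split.feed_metabolite_id
            ]
            if not unknowns:
                continue
            index = {e: i for i, e in enumerate(unknowns)}
            n = len(unknowns)
            A = np.zeros((n, n))
            B = np.zeros((n, size + 1))
            dB = np.zeros((nf, n, size + 1)) if jac else None
            dA_entries: list[tuple[int, int, int, float]] = []

            for emu in unknowns:
                i = index[emu]
                for term in self.terms[emu]:
                    f = w[term.flux_index] * term.weight
                    A[i, i] += f
                    if jac:
                        dA_entries.append((term.flux_index, i, i, term.weight))
                    precs = term.precursors
                    if (
                        len(precs) == 1
                        and precs[0] in index
                    ):
                        j = index[precs[0]]
                        A[i, j] -= f
                        if jac:
                            dA_entries.append(
                                (term.flux_index, i, j, -term.weight)
                            )
                    else:
                        y = np.array([1.0])
                        for p in precs:
                            y = np.convolve(y, values[p])
                        B[i] += f * y
                        if jac:
                            dB[term.flux_index, i] += term.weight * y
                            for k, p in enumerate(precs):
                                others = np.array([1.0])
                                for q, p2 in enumerate(precs):
                                    if q != k:
                                        others = np.convolve(others, values[p2])
                                dB[:, i, :] += f * _conv_rows(
                                    dvalues[p], others
                                )

            # EMUs with (numerically) no influx: harmless if nothing consumes
            # their metabolite at this flux vector — park them at M0 so the
            # solve stays regular; a real outflux demand is a diagnostic error.
            scale = float(np.max(w))
            diag = np.diag(A).copy()
            dead = [i for i in range(n) if diag[i] <= 1e-10 * scale]
            if dead:
                demand = []
                for i in dead:
                    met = unknowns[i].metabolite_id
                    cons = sum(
                        w[k] * wt
                        for k, wt in self.met_consumption.get(met, [])
                    )
                    if cons > 1e-6 * scale:
                        demand.append(met)
                if demand:
                    raise SingularBalanceError(
                        "singular labeling balance: zero influx but nonzero "
                        f"outflux for core metabolite(s) {sorted(set(demand))}"
                    )
                for i in dead:
                    A[i, :] = 0.0
                    A[i, i] = 1.0
                    B[i, :] = 0.0
                    B[i, 0] = 1.0
                    if jac:
                        dB[:, i, :] = 0.0
                dead_set = set(dead)
                dA_entries = [
                    (k, i, j, wt)
                    for (k, i, j, wt) in dA_entries
                    if i not in dead_set
                ] if jac else dA_entries
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                lu = lu_factor(A)
                X = lu_solve(lu, B)
            if not np.isfinite(X).all():
                raise SingularBalanceError(
                    "singular labeling balance: a set of core metabolites "
                    "carries circulating flux with no external influx "
                    f"(size-{size} system)"
                )
            for emu, i in index.items():
                values[emu] = X[i]
            if jac:
                R = dB.copy()
                for k, i, j, wt in dA_entries:
                    # dA[i, j] = ±wt  ⇒  RHS_k[i] -= dA[i, j] * X[j]
                    R[k, i] -= wt * X[j]
                dX = lu_solve(lu, R.transpose(1, 0, 2).reshape(n, -1))
                dX = dX.reshape(n, nf, size + 1)
                for emu, i in index.items():
                    dvalues[emu] = dX[i]
        return values, dvalues


def _conv_rows(D: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve each row of D (n, L2) with kernel (L1,) -> (n, L1+L2-1)."""
    n, L2 = D.shape
    out = np.zeros((n, len(kernel) + L2 - 1))
    for i, k in enumerate(kernel):
        if k != 0.0:
            out[:, i : i + L2] += k * D
    return out


def _core_carbon_metabolites(split: CoreSplit) -> set[str]:
    mets = set()
    for rid in split.core_reaction_ids:
        am = split.model.reactions[rid].atom_map
        for m, s in am.reactant_slots + am.product_slots:
            if s:
                mets.add(m)
    return mets


def emu_decompose(split: CoreSplit, targets: list[EMU]) -> EmuNetwork:
    """Trace the EMUs needed to simulate ``targets`` backward through the core.

    Returns the size-layered EMU network.  Raises if a target sits on a
    metabolite outside the carbon-mapped core.
    """
    core_mets = _core_carbon_metabolites(split)
    mets = split.model.metabolites
    for t in targets:
        if t.metabolite_id not in core_mets:
            raise ValidationError(
                f"target {t} is not on a core carbon-mapped metabolite"
            )
        if t.positions[-1] > mets[t.metabolite_id].n_carbons:
            raise ValidationError(f"target {t}: position out of range")

    directed = build_directed_label_reactions(split)
    variants = _expand_symmetric(split, directed)

    producers: dict[str, list[tuple[_Variant, int]]] = {}
    for var in variants:
        for slot_i, (met, _s) in enumerate(var.products):
            producers.setdefault(met, []).append((var, slot_i))

    net = EmuNetwork(split=split, targets=list(targets), directed=directed)
    for var in variants:
        for met, _s in var.substrates:
            net.met_consumption.setdefault(met, []).append(
                (var.flux_index, var.weight)
            )

    # symmetric targets read out as the mirror average
    queue: list[EMU] = []
    for t in targets:
        parts = [t]
        if mets[t.metabolite_id].symmetric:
            n = mets[t.metabolite_id].n_carbons
            mirror = EMU(t.metabolite_id, tuple(n + 1 - p for p in t.positions))
            if mirror != t:
                parts.append(mirror)
        net.readout[t] = tuple(parts)
        queue.extend(parts)

    seen: set[EMU] = set()
    while queue:
        emu = queue.pop()
        if emu in seen:
            continue
        seen.add(emu)
        if emu.metabolite_id == split.feed_metabolite_id:
            continue
        term_list: list[_Term] = []
        for var, slot_i in producers.get(emu.metabolite_id, []):
            letters = {var.products[slot_i][1][p - 1] for p in emu.positions}
            precs = []
            for met, s in var.substrates:
                pos = tuple(
                    i + 1 for i, ch in enumerate(s) if ch in letters
                )
                if pos:
                    precs.append(EMU(met, pos))
            precs.sort()
            term_list.append(_Term(var.flux_index, var.weight, tuple(precs)))
            queue.extend(precs)
        net.terms[emu] = term_list

    for emu in seen:
        net.emus_by_size.setdefault(emu.size, []).append(emu)
    for size in net.emus_by_size:
        net.emus_by_size[size].sort()
    return net


# ---------------------------------------------------------------------------
# public simulation front ends
# ---------------------------------------------------------------------------


def labeling_fluxes(
    split: CoreSplit,
    v,
    directed: list[DirectedLabelReaction],
    exchange: dict[str, float] | None = None,
) -> np.ndarray:
    """Map net fluxes (dict or aligned array) + exchange fluxes onto ``w``.

    For a reversible core reaction the forward/backward pair is
    ``max(v,0)+x`` / ``max(-v,0)+x`` with exchange flux ``x >= 0``.
    """
    if not isinstance(v, dict):
        rxn_ids = list(split.model.reactions)
        v = dict(zip(rxn_ids, np.asarray(v, dtype=float)))
    exchange = exchange or {}
    w = np.zeros(len(directed))
    for dr in directed:
        net = v[dr.reaction_id]
        x = exchange.get(dr.reaction_id, 0.0)
        if dr.direction > 0:
            w[dr.index] = max(net, 0.0) + x
        else:
            w[dr.index] = max(-net, 0.0) + x
    return w


def simulate_labeling(
    split: CoreSplit,
    v,
    feed: FeedLabeling,
    targets: list[EMU],
    exchange: dict[str, float] | None = None,
    network: EmuNetwork | None = None,
) -> dict[EMU, MDV]:
    """Steady-state MDVs of ``targets`` at net fluxes ``v`` under ``feed``.

    ``v`` is a dict (reaction id → net flux) or an array aligned with the
    model's reaction order; ``exchange`` optionally carries bidirectional
    exchange fluxes for reversible core reactions.
    """
    if network is None:
        network = emu_decompose(split, targets)
    w = labeling_fluxes(split, v, network.directed, exchange)
    raw = network.simulate(w, feed)
    return {t: MDV(t, np.clip(x, 0.0, None) / np.clip(x, 0.0, None).sum())
            for t, x in raw.items()}


# ---------------------------------------------------------------------------
# positional-isotopomer oracle
# ---------------------------------------------------------------------------

_MAX_ORACLE_CARBONS = 24


def _project_isotopomers(dist: np.ndarray, n: int, positions) -> np.ndarray:
    """Marginalize a 2**n isotopomer dist onto a subset of positions."""
    k = len(positions)
    out = np.zeros(1 << k)
    idx = np.arange(1 << n)
    sub = np.zeros(1 << n, dtype=int)
    for b, p in enumerate(positions):
        sub |= ((idx >> (p - 1)) & 1) << b
    np.add.at(out, sub, dist)
    return out


def _mdv_from_isotopomers(dist: np.ndarray, n: int, positions) -> np.ndarray:
    proj = _project_isotopomers(dist, n, positions)
    k = len(positions)
    out = np.zeros(k + 1)
    counts = np.array([bin(i).count("1") for i in range(1 << k)])
    np.add.at(out, counts, proj)
    return out


def _reverse_bits_table(n: int) -> np.ndarray:
    idx = np.arange(1 << n)
    rev = np.zeros(1 << n, dtype=int)
    for b in range(n):
        rev |= ((idx >> b) & 1) << (n - 1 - b)
    return rev


def isotopomer_oracle(
    split: CoreSplit,
    v,
    feed: FeedLabeling,
    targets: list[EMU] | None = None,
    exchange: dict[str, float] | None = None,
    tol: float = 1e-13,
    max_iter: int = 50000,
) -> dict[EMU, MDV]:
    """Exact steady-state MDVs by full positional-isotopomer enumeration.

    Solves the standard isotopomer balance (nonlinear through condensations) by
    Gauss–Seidel fixed-point iteration over all 2**n states of every internal
    core metabolite, then marginalizes the requested fragments.  Limited to
    networks with at most 24 total core carbons.  Deliberately shares no
    machinery with the EMU solver.
    """
    model = split.model
    mets = model.metabolites
    core_mets = _core_carbon_metabolites(split)
    internal = sorted(m for m in core_mets if m != split.feed_metabolite_id)
    total_c = sum(mets[m].n_carbons for m in internal)
    if total_c > _MAX_ORACLE_CARBONS:
        raise NetworkSizeError(
            f"core network has {total_c} carbons; isotopomer enumeration is "
            f"limited to {_MAX_ORACLE_CARBONS}"
        )
    if targets is None:
        targets = [full_emu(m, mets[m].n_carbons) for m in internal]

    # directed flux-carrying mapped reactions, built independently
    if not isinstance(v, dict):
        v = dict(zip(list(model.reactions), np.asarray(v, dtype=float)))
    exchange = exchange or {}
    dir_rxns = []  # (flux, substrates, products) with slots (met, letters)
    for rid in sorted(split.core_reaction_ids):
        rxn = model.reactions[rid]
        am = rxn.atom_map
        subs = tuple((m, s) for m, s in am.reactant_slots if s)
        prods = tuple((m, s) for m, s in am.product_slots if s)
        net = v[rid]
        x = exchange.get(rid, 0.0)
        fwd = max(net, 0.0) + x
        bwd = max(-net, 0.0) + x
        if fwd > 0:
            dir_rxns.append((fwd, subs, prods))
        if bwd > 0 and rxn.lower_bound < 0:
            dir_rxns.append((bwd, prods, subs))
    if not dir_rxns:
        raise SingularBalanceError("flux-free network: no labeling flux")

    # feed distribution over isotopomer states
    nf = mets[split.feed_metabolite_id].n_carbons

    def _feed_dist() -> np.ndarray:
        # bit b of the state corresponds to carbon position b+1
        dist = np.zeros(1 << nf)
        for pattern, frac in feed.components:
            d = np.array([1.0])
            for b, ch in enumerate(pattern):
                p13 = feed.purity if ch == "1" else 0.0
                nd = np.zeros(len(d) * 2)
                nd[: len(d)] += d * (1 - p13)
                for i in range(len(d)):
                    nd[i | (1 << b)] += d[i] * p13
                d = nd
            dist[: len(d)] += frac * d
        return dist

    x_state: dict[str, np.ndarray] = {}
    for m in internal:
        d = np.zeros(1 << mets[m].n_carbons)
        d[0] = 1.0
        x_state[m] = d
    feed_dist = _feed_dist()
    rev_tables = {
        m: _reverse_bits_table(mets[m].n_carbons)
        for m in set(internal) | {split.feed_metabolite_id}
        if mets[m].symmetric
    }

    def _pool(m: str) -> np.ndarray:
        d = feed_dist if m == split.feed_metabolite_id else x_state[m]
        if m in rev_tables:
            d = 0.5 * (d + d[rev_tables[m]])
        return d

    # per product metabolite: production channels
    production: dict[str, list] = {m: [] for m in internal}
    for flux, subs, prods in dir_rxns:
        for pslot_i, (pm, ps) in enumerate(prods):
            if pm not in production:
                continue
            # for each substrate slot: which of its positions land where in pm
            routing = []
            for sm, ss in subs:
                src, dst = [], []
                for i, ch in enumerate(ss):
                    j = ps.find(ch)
                    if j >= 0:
                        src.append(i + 1)
                        dst.append(j)
                if src:
                    routing.append((sm, tuple(src), tuple(dst)))
            production[pm].append((flux, routing))

    # pools with no influx: harmless (parked unlabeled) unless consumed
    scale = max(flux for flux, _, _ in dir_rxns)
    consumption = {m: 0.0 for m in internal}
    for flux, subs, _ in dir_rxns:
        for sm, _s in subs:
            if sm in consumption:
                consumption[sm] += flux
    dead_pools = set()
    for m in internal:
        influx = sum(flux for flux, _ in production[m])
        if influx <= 1e-10 * scale:
            if consumption[m] > 1e-6 * scale:
                raise SingularBalanceError(
                    f"zero influx but nonzero outflux for core metabolite {m}"
                )
            dead_pools.add(m)

    for it in range(max_iter):
        delta = 0.0
        for m in internal:
            if m in dead_pools:
                continue
            n_m = mets[m].n_carbons
            total = 0.0
            acc = np.zeros(1 << n_m)
            for flux, routing in production[m]:
                contrib = np.zeros(1 << n_m)
                contrib[0] = 1.0
                for sm, src, dst in routing:
                    sd = _pool(sm)
                    proj = _project_isotopomers(sd, mets[sm].n_carbons, src)
                    # embed: bit b of proj goes to product bit dst[b]
                    emb = np.zeros(1 << len(src), dtype=int)
                    for b, dbit in enumerate(dst):
                        emb |= ((np.arange(1 << len(src)) >> b) & 1) << dbit
                    new = np.zeros(1 << n_m)
                    idx_c = np.nonzero(contrib)[0]
                    for ii in idx_c:
                        np.add.at(new, ii | emb, contrib[ii] * proj)
                    contrib = new
                acc += flux * contrib
                total += flux
            if total <= 0:
                raise SingularBalanceError(
                    f"no labeling influx into core metabolite {m}"
                )
            newd = acc / total
            if m in rev_tables:
                newd = 0.5 * (newd + newd[rev_tables[m]])
            delta = max(delta, float(np.abs(newd - x_state[m]).max()))
            x_state[m] = newd
        if delta < tol:
            break
    else:
        logger.warning("isotopomer oracle: fixed point not fully converged "
                       "(last delta %.2e)", delta)

    out = {}
    for t in targets:
        m = t.metabolite_id
        if m == split.feed_metabolite_id:
            d = _pool(m)
            n_m = nf
        else:
            d = _pool(m)
            n_m = mets[m].n_carbons
        out[t] = MDV(t, np.clip(_mdv_from_isotopomers(d, n_m, t.positions),
                                0.0, None))
    return out


# ---------------------------------------------------------------------------
# natural-abundance correction
# ---------------------------------------------------------------------------

#: isotopic abundances as mass-shift distributions (M+0, M+1, M+2, ...)
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0),
    "P": (1.0,),
}

_FORMULA_TOKEN = __import__("re").compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    out: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValidationError(f"cannot parse formula {formula!r}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + (
            int(m.group(2)) if m.group(2) else 1
        )
    if pos != len(formula):
        raise ValidationError(f"cannot parse formula {formula!r}")
    return out


def correction_matrix(
    formula: str, size: int, abundances: dict | None = None
) -> np.ndarray:
    """Matrix M with raw = M @ true for natural abundance of non-tracer atoms.

    All ``size`` carbons are tracer positions (the fragments here are whole
    amino acids measured without fragmentation), so the correction covers the
    remaining elements of the formula only.
    """
    if size <= 0:
        raise ValidationError("fragment size must be positive")
    ab = dict(NATURAL_ABUNDANCE)
    if abundances:
        ab.update(abundances)
    counts = parse_formula(formula)
    if counts.get("C", 0) != size:
        raise ValidationError(
            f"formula {formula} has {counts.get('C', 0)} carbons, fragment "
            f"size is {size}"
        )
    base = np.array([1.0])
    for elem, k in counts.items():
        if elem == "C":
            continue
        if elem not in ab:
            raise ValidationError(f"no abundance data for element {elem}")
        dist = np.asarray(ab[elem], dtype=float)
        for _ in range(k):
            base = np.convolve(base, dist)
    M = np.zeros((size + 1, size + 1))
    for j in range(size + 1):
        top = min(size + 1 - j, len(base))
        M[j : j + top, j] = base[:top]
    return M


def add_natural_abundance(
    mdv: MDV, formula: str, abundances: dict | None = None
) -> MDV:
    """Forward-contaminate a tracer-only MDV with natural isotope abundance."""
    M = correction_matrix(formula, len(mdv) - 1, abundances)
    raw = M @ mdv.fractions
    return MDV(mdv.fragment, raw / raw.sum())


def correct_natural_abundance(
    raw: MDV, formula: str, abundances: dict | None = None
) -> MDV:
    """Remove natural-abundance contributions by inverting the correction matrix.

    Small negative fractions produced by the inversion are clipped (and logged)
    before renormalization.
    """
    M = correction_matrix(formula, len(raw) - 1, abundances)
    if np.linalg.cond(M) > 1e8:
        raise ValidationError("ill-conditioned natural-abundance correction")
    x = np.linalg.solve(M, raw.fractions)
    if np.any(x < 0):
        if x.min() < -1e-6:
            logger.info(
                "natural-abundance correction clipped negatives down to %.3e",
                x.min(),
            )
        x = np.clip(x, 0.0, None)
    return MDV(raw.fragment, x / x.sum())
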