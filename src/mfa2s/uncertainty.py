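"""Confidence intervals by 13C flux variability analysis; core-set validation.

A flux value is "compatible with the data" when some flux vector attaining it
fits the labeling and exchange measurements almost as well as the optimum.
13C FVA therefore minimizes and maximizes each net flux subject to steady
state, bounds, and a profile-likelihood SSR ceiling

    SSR(v) ≤ SSR_opt + χ²(alpha, 1)

(the per-flux profile threshold; a global χ²(alpha, dof) ceiling is available
as an option).  Intervals are reported in the study's notation
``best [lo–hi]``.

External labeling variability analysis (ELVA) checks the core-set choice: it
bounds how much the labeling of each measured fragment could move if the
carbon entering core pools through *non-core* (unmapped) reactions carried
arbitrary labeling, at the fitted flux magnitudes.  Positions are scored by a
linear "tainted-carbon" propagation through the atom maps; a fragment's bound
is the (union-bound) sum over its positions, so it is conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core_network import CoreSplit, ValidationError
from .labeling import FeedLabeling
from .measurements import MeasurementSet, resolve_fragment
from .fitting import FitProblem, FluxSolution

logger = logging.getLogger(__name__)


@dataclass
class ConfidenceInterval:
    """Flux range compatible with the data, bracketing the best fit."""

    reaction_id: str
    best_fit: float
    lo: float
    hi: float
    alpha: float = 0.95
    unreliable: bool = False

    def __post_init__(self):
        if self.lo > self.hi:
            self.lo, self.hi = self.hi, self.lo
        # the best fit must sit inside its own interval; widen if the inner
        # optimizations came up short rather than report an incoherent range
        tol = 1e-6
        if self.best_fit < self.lo - tol or self.best_fit > self.hi + tol:
            logger.warning(
                "interval for %s widened to include best fit %.6g "
                "(was [%.6g, %.6g])",
                self.reaction_id, self.best_fit, self.lo, self.hi,
            )
        self.lo = min(self.lo, self.best_fit)
        self.hi = max(self.hi, self.best_fit)

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass
class ElvaFragmentBound:
    fragment_id: str
    min_contribution: float
    max_contribution: float

    def __post_init__(self):
        if not 0.0 <= self.min_contribution <= self.max_contribution <= 1.0:
            raise ValidationError(
                f"{self.fragment_id}: bad ELVA contributions "
                f"[{self.min_contribution}, {self.max_contribution}]"
            )


@dataclass
class ElvaReport:
    threshold: float
    fragments: list[ElvaFragmentBound]

    @property
    def verdict(self) -> str:
        worst = max((f.max_contribution for f in self.fragments), default=0.0)
        return "pass" if worst <= self.threshold else "fail"

    @property
    def worst_fragment(self) -> ElvaFragmentBound | None:
        if not self.fragments:
            return None
        return max(self.fragments, key=lambda f: f.max_contribution)


# ---------------------------------------------------------------------------
# 13C FVA
# ---------------------------------------------------------------------------


def ssr_threshold(
    sol: FluxSolution, alpha: float, mode: str = "profile"
) -> float:
    """SSR ceiling defining "compatible with the data" at confidence alpha."""
    if mode == "profile":
        return sol.ssr + stats.chi2.ppf(alpha, 1)
    if mode == "global":
        return sol.ssr + stats.chi2.ppf(alpha, sol.dof)
    raise ValidationError(f"unknown threshold mode {mode!r}")


def _line_max_step(space, alpha0, u) -> float:
    """Largest t keeping alpha0 + t*u inside the bound polytope."""
    rows = space.free_rows
    A = space.N[rows]
    a = A @ u
    b = A @ alpha0
    lo = (space.lb - space.v_p)[rows]
    hi = (space.ub - space.v_p)[rows]
    t_max = np.inf
    pos = a > 1e-13
    neg = a < -1e-13
    if np.any(pos):
        t_max = min(t_max, float(np.min((hi[pos] - b[pos]) / a[pos])))
    if np.any(neg):
        t_max = min(t_max, float(np.min((lo[neg] - b[neg]) / a[neg])))
    return max(t_max, 0.0)


def _bisect_threshold(problem, alpha0, u, t_max, thr, n_iter=25):
    """Largest t in [0, t_max] with SSR(alpha0 + t*u) <= thr."""
    if t_max <= 0:
        return 0.0
    f = lambda t: problem.ssr(alpha0 + t * u)
    if f(t_max) <= thr:
        return t_max
    lo_t, hi_t = 0.0, t_max
    for _ in range(n_iter):
        mid = 0.5 * (lo_t + hi_t)
        if f(mid) <= thr:
            lo_t = mid
        else:
            hi_t = mid
    return lo_t


def fva13c(
    split: CoreSplit,
    meas: MeasurementSet,
    feed: FeedLabeling,
    sol: FluxSolution,
    alpha: float = 0.95,
    reactions: list[str] | None = None,
    threshold_mode: str = "profile",
    problem: FitProblem | None = None,
    maxiter: int = 100,
) -> list[ConfidenceInterval]:
    """Confidence intervals for net fluxes by 13C flux variability analysis.

    For each requested reaction the net flux is pushed to its extremes subject
    to S·v = 0, bounds, and the SSR ceiling.  Each direction starts from the
    best fit and from a bisection point near the SSR ceiling along the flux
    direction, so flat (unidentifiable) directions reach the polytope boundary
    even when the local solver stalls.  Failed inner optimizations flag the
    interval as unreliable; they never tighten it.
    """
    if not sol.converged:
        raise ValidationError("13C FVA requires a converged fit")
    if sol.alpha is None:
        raise ValidationError("solution carries no coordinates; refit first")
    if problem is None:
        problem = FitProblem(split, meas, feed)
    space = problem.space
    if reactions is None:
        reactions = sorted(split.core_reaction_ids)
    thr = ssr_threshold(sol, alpha, threshold_mode)
    alpha_opt = np.asarray(sol.alpha, dtype=float)
    cons = problem.constraints()

    out: list[ConfidenceInterval] = []
    base_d = space.v_p
    idx = space.column_index()
    for rid in reactions:
        if (rid, +1) not in idx:
            raise ValidationError(f"unknown reaction {rid}")
        c = space.net_gradient(rid)
        base = base_d[idx[(rid, +1)]]
        if (rid, -1) in idx:
            base -= base_d[idx[(rid, -1)]]
        v_best = float(sol.v[rid])
        norm = np.linalg.norm(c)
        if norm < 1e-12:
            out.append(ConfidenceInterval(rid, v_best, v_best, v_best, alpha))
            continue

        ssr_cons = {
            "type": "ineq",
            "fun": lambda a: thr - problem.ssr_grad(a)[0],
            "jac": lambda a: -problem.ssr_grad(a)[1],
        }
        lo_val, hi_val = v_best, v_best
        failed = False
        for sign in (-1.0, +1.0):
            u = sign * c / norm
            t_edge = _line_max_step(space, alpha_opt, u)
            t_ok = _bisect_threshold(problem, alpha_opt, u, t_edge, thr)
            starts = [alpha_opt + t_ok * u]
            if 0 < t_ok < t_edge:
                starts.append(alpha_opt + 0.5 * t_ok * u)
            best_here = v_best + sign * norm * t_ok
            success = t_ok > 0
            for a0 in starts:
                try:
                    res = optimize.minimize(
                        lambda a: sign * -(base + c @ a),
                        a0,
                        jac=lambda a: sign * -c,
                        method="SLSQP",
                        constraints=cons + [ssr_cons],
                        options={"maxiter": maxiter, "ftol": 1e-10},
                    )
                except (np.linalg.LinAlgError, RuntimeError):
                    continue
                cand = res.x
                feasible = (
                    space.bound_violation(cand) <= 1e-6
                    and problem.ssr(cand) <= thr + 1e-6
                )
                if feasible:
                    val = base + float(c @ cand)
                    best_here = (
                        max(best_here, val) if sign > 0 else min(best_here, val)
                    )
                    success = success or res.success
            if not success:
                failed = True
            if sign > 0:
                hi_val = max(hi_val, best_here)
            else:
                lo_val = min(lo_val, best_here)
        out.append(
            ConfidenceInterval(rid, v_best, lo_val, hi_val, alpha,
                               unreliable=failed)
        )
    return out


# ---------------------------------------------------------------------------
# ELVA
# ---------------------------------------------------------------------------


def elva(
    split: CoreSplit,
    sol: FluxSolution,
    meas: MeasurementSet,
    threshold: float = 0.01,
) -> ElvaReport:
    """Bound the influence of non-core carbon influx on measured labeling.

    For every EMU feeding a measured fragment, a fixed point computes the
    worst-case probability τ that a fragment molecule carries at least one
    carbon that entered the core through an unmapped (non-core) reaction,
    at the fitted flux magnitudes: non-core influx into a pool counts as fully
    tainted, the feed as clean, flux-weighted averaging propagates τ through
    mapped reactions, and condensations combine as 1 − Π(1 − τᵢ).  No MDV
    channel of the fragment can move by more than τ whatever labeling the
    non-core carbon carries, so τ bounds the perturbation; the minimum is 0
    (non-core carbon may coincide with the core labeling).
    """
    from .labeling import emu_decompose

    model = split.model

    # EMU dependency network of the measured fragments
    recipes = {m.fragment_id: resolve_fragment(m) for m in meas.mdv_measurements}
    targets = sorted({e for parts in recipes.values() for e in parts})
    if not targets:
        return ElvaReport(threshold=threshold, fragments=[])
    net = emu_decompose(split, targets)
    directed = net.directed
    w = np.zeros(len(directed))
    for dr in directed:
        vnet = sol.v[dr.reaction_id]
        x = sol.exchange_fluxes.get(dr.reaction_id, 0.0)
        w[dr.index] = (max(vnet, 0.0) if dr.direction > 0
                       else max(-vnet, 0.0)) + x

    # non-core production flux into each core pool
    noncore_influx: dict[str, float] = {}
    for rid, rxn in model.reactions.items():
        if rid in split.core_reaction_ids:
            continue
        for m, coeff in rxn.stoichiometry.items():
            noncore_influx[m] = noncore_influx.get(m, 0.0) + max(
                coeff * sol.v[rid], 0.0
            )

    all_emus = [e for lst in net.emus_by_size.values() for e in lst]
    tau = {e: 0.0 for e in all_emus}
    feed_id = split.feed_metabolite_id
    for _ in range(10000):
        delta = 0.0
        for emu in all_emus:
            if emu.metabolite_id == feed_id:
                continue
            influx = noncore_influx.get(emu.metabolite_id, 0.0)
            acc = influx  # tainted fraction 1 on the non-core channel
            for term in net.terms.get(emu, []):
                f = w[term.flux_index] * term.weight
                influx += f
                clean = 1.0
                for p in term.precursors:
                    clean *= 1.0 - (0.0 if p.metabolite_id == feed_id
                                    else tau[p])
                acc += f * (1.0 - clean)
            new = acc / influx if influx > 0 else 0.0
            delta = max(delta, abs(new - tau[emu]))
            tau[emu] = new
        if delta < 1e-13:
            break

    fragments = []
    for m in meas.mdv_measurements:
        clean = 1.0
        for emu in recipes[m.fragment_id]:
            t = 0.0 if emu.metabolite_id == feed_id else tau[emu]
            clean *= 1.0 - t
        fragments.append(
            ElvaFragmentBound(m.fragment_id, 0.0,
                              min(max(1.0 - clean, 0.0), 1.0))
        )
    return ElvaReport(threshold=threshold, fragments=fragments)
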