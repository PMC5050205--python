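"""Two-scale flux estimation.

The estimator searches the genome-scale steady-state flux polytope for the
flux vector whose simulated core labeling and exchange fluxes best match the
measurements, minimizing the weighted sum of squared residuals

    SSR(v) = Σ_channels ((m_sim − m_meas)/σ)² + Σ_exchanges ((v − r)/σ)²

over null-space coordinates α (v = v_p + N·α), so S·v = 0 holds by
construction and only bound constraints remain.  The labeling residuals are
differentiable through the EMU balance systems, and the analytic Jacobian is
passed to a gradient-based local solver (SLSQP) restarted from seeded
hit-and-run samples of the polytope interior — the SSR landscape is nonconvex,
so the multistart is what buys global reliability.

Growth enters as an exchange-like residual on the biomass reaction.  Measured
glucose uptake is soft (a residual) by default; pin the exchange reaction's
bounds to make it hard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core_network import CoreSplit, ValidationError
from .labeling import EMU, EmuNetwork, FeedLabeling, emu_decompose
from .measurements import MDVMeasurement, MeasurementSet, resolve_fragment
from .polytope import DEFAULT_EXCHANGE_CAP, DirectedFluxSpace, build_directed_space

logger = logging.getLogger(__name__)


@dataclass
class FitOptions:
    n_starts: int = 10
    seed: int = 0
    exchange_cap: float = DEFAULT_EXCHANGE_CAP
    ftol: float = 1e-12
    maxiter: int = 300

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValidationError("n_starts must be >= 1")


@dataclass
class FluxSolution:
    """Best-fit net fluxes with bookkeeping for downstream analyses."""

    v: dict[str, float]
    exchange_fluxes: dict[str, float]
    ssr: float
    n_residuals: int
    converged: bool
    alpha: np.ndarray | None = None
    jac_rank: int | None = None
    seed: int | None = None

    @property
    def dof(self) -> int:
        """Residual degrees of freedom (residual count minus fitted rank)."""
        rank = self.jac_rank or 0
        return max(self.n_residuals - rank, 1)

    def to_dict(self) -> dict:
        return {
            "v": {k: float(x) for k, x in self.v.items()},
            "exchange_fluxes": {k: float(x) for k, x in
                                self.exchange_fluxes.items()},
            "ssr": float(self.ssr),
            "n_residuals": int(self.n_residuals),
            "converged": bool(self.converged),
            "alpha": None if self.alpha is None else
                     [float(a) for a in self.alpha],
            "jac_rank": self.jac_rank,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FluxSolution":
        return cls(
            v=doc["v"],
            exchange_fluxes=doc.get("exchange_fluxes", {}),
            ssr=doc["ssr"],
            n_residuals=doc["n_residuals"],
            converged=doc["converged"],
            alpha=None if doc.get("alpha") is None else np.array(doc["alpha"]),
            jac_rank=doc.get("jac_rank"),
            seed=doc.get("seed"),
        )


class FitProblem:
    """Residuals and Jacobians of the two-scale fit in α-coordinates.

    Built once per (split, measurements, feed) combination; reused by the fit,
    the SSR evaluation, and the variability analysis.
    """

    def __init__(
        self,
        split: CoreSplit,
        meas: MeasurementSet,
        feed: FeedLabeling,
        exchange_cap: float = DEFAULT_EXCHANGE_CAP,
    ):
        self.split = split
        self.meas = meas
        self.feed = feed
        self.space: DirectedFluxSpace = build_directed_space(
            split.model, split.core_reaction_ids, exchange_cap
        )

        # resolve measured fragments into precursor EMU recipes
        self.recipes: list[tuple[MDVMeasurement, list[EMU]]] = []
        targets: set[EMU] = set()
        for m in meas.mdv_measurements:
            recipe = resolve_fragment(m)
            size = sum(e.size for e in recipe)
            if size + 1 != len(m.values):
                raise ValidationError(
                    f"{m.fragment_id}: MDV has {len(m.values)} channels but "
                    f"the precursor recipe carries {size} carbons"
                )
            self.recipes.append((m, recipe))
            targets.update(recipe)
        self.network: EmuNetwork | None = None
        if targets:
            self.network = emu_decompose(split, sorted(targets))
            col_idx = self.space.column_index()
            self.label_cols = np.array(
                [col_idx[key] for key in self.network.flux_keys()], dtype=int
            )

        # linear residual rows: exchange fluxes (+ growth on biomass)
        self.linear_rows: list[tuple[str, float, float]] = []
        for em in meas.exchange_measurements:
            if em.reaction_id not in split.model.reactions:
                raise ValidationError(
                    f"measured exchange {em.reaction_id} not in model"
                )
            self.linear_rows.append((em.reaction_id, em.rate, em.sd))
        if meas.growth_rate is not None:
            biomass = split.model.biomass_reaction_id
            if biomass is None:
                raise ValidationError(
                    "growth rate measured but model has no biomass reaction"
                )
            mu, sd = meas.growth_rate
            self.linear_rows.append((biomass, mu, sd))

        self.n_residuals = meas.n_residuals

    # -- residuals ---------------------------------------------------------

    def residuals_directed(
        self, d: np.ndarray, jac: bool = False
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Residual vector (and Jacobian w.r.t. directed fluxes) at d."""
        rows: list[float] = []
        jrows: list[np.ndarray] = []
        n_cols = self.space.n_columns

        if self.network is not None:
            w = np.clip(d[self.label_cols], 0.0, None)
            if jac:
                sim, dsim = self.network.simulate_with_jac(w, self.feed)
            else:
                sim = self.network.simulate(w, self.feed)
                dsim = None
            for m, recipe in self.recipes:
                value = np.array([1.0])
                for e in recipe:
                    value = np.convolve(value, sim[e])
                rows.extend((value - m.values.fractions) / m.sd)
                if jac:
                    dval = np.zeros((len(w), len(value)))
                    for k, e in enumerate(recipe):
                        others = np.array([1.0])
                        for q, e2 in enumerate(recipe):
                            if q != k:
                                others = np.convolve(others, sim[e2])
                        dval += _conv_rows(dsim[e], others)
                    J = np.zeros((len(value), n_cols))
                    J[:, self.label_cols] = dval.T
                    jrows.extend(J / m.sd[:, None])

        idx = self.space.column_index()
        for rid, target, sd in self.linear_rows:
            net = d[idx[(rid, +1)]]
            grad = np.zeros(n_cols)
            grad[idx[(rid, +1)]] = 1.0
            if (rid, -1) in idx:
                net -= d[idx[(rid, -1)]]
                grad[idx[(rid, -1)]] = -1.0
            rows.append((net - target) / sd)
            if jac:
                jrows.append(grad / sd)

        r = np.array(rows)
        J = np.vstack(jrows) if jac else None
        return r, J

    def residuals(self, alpha, jac: bool = False):
        d = self.space.directed(alpha)
        r, Jd = self.residuals_directed(d, jac=jac)
        if jac:
            return r, Jd @ self.space.N
        return r, None

    def ssr(self, alpha) -> float:
        r, _ = self.residuals(alpha)
        return float(r @ r)

    def ssr_grad(self, alpha) -> tuple[float, np.ndarray]:
        from .labeling import SingularBalanceError

        key = np.asarray(alpha, dtype=float).tobytes()
        cached = getattr(self, "_grad_cache", None)
        if cached is not None and cached[0] == key:
            return cached[1]
        try:
            r, J = self.residuals(alpha, jac=True)
            out = float(r @ r), 2.0 * (J.T @ r)
        except (SingularBalanceError, np.linalg.LinAlgError):
            # infeasible excursion of the line search: flat, huge objective
            out = 1e12, np.zeros(self.space.dim)
        self._grad_cache = (key, out)
        return out

    def constraints(self) -> list[dict]:
        """SLSQP inequality constraints: lb ≤ v_p + N·α ≤ ub on free rows."""
        rows = self.space.free_rows
        A = self.space.N[rows]
        lo = (self.space.lb - self.space.v_p)[rows]
        hi = (self.space.ub - self.space.v_p)[rows]
        return [
            {"type": "ineq", "fun": lambda a: A @ a - lo, "jac": lambda a: A},
            {"type": "ineq", "fun": lambda a: hi - A @ a, "jac": lambda a: -A},
        ]

    def jac_rank_at(self, alpha) -> int:
        _, J = self.residuals(alpha, jac=True)
        s = np.linalg.svd(J, compute_uv=False)
        if len(s) == 0:
            return 0
        return int(np.sum(s > max(J.shape) * np.finfo(float).eps * s[0]))


def _conv_rows(D: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    n, L2 = D.shape
    out = np.zeros((n, len(kernel) + L2 - 1))
    for i, k in enumerate(kernel):
        if k != 0.0:
            out[:, i : i + L2] += k * D
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def ssr(
    split: CoreSplit,
    v,
    meas: MeasurementSet,
    feed: FeedLabeling,
    exchange: dict[str, float] | None = None,
    problem: FitProblem | None = None,
) -> float:
    """Weighted sum of squared residuals at net fluxes ``v`` (dict or array)."""
    if problem is None:
        problem = FitProblem(split, meas, feed)
    if not isinstance(v, dict):
        v = dict(zip(list(split.model.reactions), np.asarray(v, dtype=float)))
    d = problem.space.directed_from_net(v, exchange)
    r, _ = problem.residuals_directed(d)
    return float(r @ r)


def fit_fluxes(
    split: CoreSplit,
    meas: MeasurementSet,
    feed: FeedLabeling,
    opts: FitOptions | None = None,
    problem: FitProblem | None = None,
) -> FluxSolution:
    """Multistart local minimization of the SSR over the flux polytope.

    Reproducible for a fixed seed: starting points come from seeded
    hit-and-run sampling around the Chebyshev center.  The returned solution
    is the best SSR seen at any feasible iterate (monotone bookkeeping).
    """
    opts = opts or FitOptions()
    if problem is None:
        problem = FitProblem(split, meas, feed, exchange_cap=opts.exchange_cap)
    space = problem.space

    if space.dim == 0:  # fully determined: nothing to optimize
        d = space.v_p
        alpha0 = np.zeros(0)
        return FluxSolution(
            v=space.net_fluxes(d),
            exchange_fluxes=space.exchange_fluxes(d),
            ssr=problem.ssr(alpha0),
            n_residuals=problem.n_residuals,
            converged=True,
            alpha=alpha0,
            jac_rank=0,
            seed=opts.seed,
        )

    rng = np.random.default_rng(opts.seed)
    center = space.chebyshev_center()
    starts = [center]
    if opts.n_starts > 1:
        starts += space.hit_and_run(center, opts.n_starts - 1, rng)

    best_ssr = np.inf
    best_alpha = None
    any_success = False
    cons = problem.constraints()

    for alpha0 in starts:
        try:
            res = optimize.minimize(
                problem.ssr_grad,
                alpha0,
                jac=True,
                method="SLSQP",
                constraints=cons,
                options={"ftol": opts.ftol, "maxiter": opts.maxiter},
            )
        except (np.linalg.LinAlgError, RuntimeError) as exc:
            logger.warning("fit start failed: %s", exc)
            continue
        for cand in (res.x, alpha0):
            if space.bound_violation(cand) <= 1e-6:
                val = problem.ssr(cand)
                if val < best_ssr:
                    best_ssr, best_alpha = val, np.asarray(cand, dtype=float)
        any_success = any_success or bool(res.success)

    if best_alpha is None:
        raise ValidationError(
            "no feasible iterate found: check bounds and measurements for "
            "conflicts (infeasible constraint system)"
        )

    d = np.clip(space.directed(best_alpha), space.lb, space.ub)
    sol = FluxSolution(
        v=space.net_fluxes(d),
        exchange_fluxes=space.exchange_fluxes(d),
        ssr=best_ssr,
        n_residuals=problem.n_residuals,
        converged=any_success,
        alpha=best_alpha,
        jac_rank=problem.jac_rank_at(best_alpha),
        seed=opts.seed,
    )
    return sol


def ssr_chi2_band(
    n_residuals: int, jac_rank: int, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided χ² acceptance band for the minimized SSR.

    The minimized weighted SSR of a correctly specified model is asymptotically
    χ²-distributed with dof = (number of residuals) − (number of identifiable
    parameter combinations); the latter is the rank of the residual Jacobian
    at the optimum.
    """
    dof = max(n_residuals - jac_rank, 1)
    lo = stats.chi2.ppf((1 - level) / 2, dof)
    hi = stats.chi2.ppf(1 - (1 - level) / 2, dof)
    return float(lo), float(hi)
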