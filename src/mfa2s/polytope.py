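"""Directed flux space: steady-state polytope, null-space coordinates, sampling.

The fit and the variability analysis both work in coordinates α on the null
space of the steady-state constraints: every flux vector is v = v_p + N·α with
S·v_p = 0, so mass balance holds identically and only the bound constraints
lb ≤ v ≤ ub remain.  Reversible *core* (atom-mapped) reactions are split into
non-negative forward/backward columns so the labeling simulation sees only
directed fluxes; the bidirectional exchange flux is then min(fwd, bwd) and the
net flux their difference.  Reactions with pinned bounds (lb = ub) are moved
into the equality system, which keeps the polytope full-dimensional in α.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

from .core_network import NetworkModel, ValidationError

#: default cap on the bidirectional (exchange) flux of reversible core reactions
DEFAULT_EXCHANGE_CAP = 300.0

_PIN_TOL = 1e-12


@dataclass
class DirectedFluxSpace:
    """Null-space parameterization of {v : S·v = 0, lb ≤ v ≤ ub} (directed)."""

    model: NetworkModel
    core_ids: frozenset[str]
    columns: list[tuple[str, int]]  # (reaction_id, +1 fwd / -1 bwd)
    lb: np.ndarray
    ub: np.ndarray
    v_p: np.ndarray  # particular solution of the equality system
    N: np.ndarray  # null-space basis, shape (n_columns, dim)
    free_rows: np.ndarray  # indices of columns with lb < ub (inequalities)

    @property
    def dim(self) -> int:
        return self.N.shape[1]

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def column_index(self) -> dict[tuple[str, int], int]:
        return {key: i for i, key in enumerate(self.columns)}

    # -- conversions ------------------------------------------------------

    def directed(self, alpha: np.ndarray) -> np.ndarray:
        return self.v_p + self.N @ np.asarray(alpha, dtype=float)

    def net_fluxes(self, d: np.ndarray) -> dict[str, float]:
        """Collapse directed fluxes into net flux per reaction."""
        idx = self.column_index()
        out: dict[str, float] = {}
        for rid in self.model.reactions:
            fwd = d[idx[(rid, +1)]]
            bwd = d[idx[(rid, -1)]] if (rid, -1) in idx else 0.0
            out[rid] = fwd - bwd
        return out

    def exchange_fluxes(self, d: np.ndarray) -> dict[str, float]:
        idx = self.column_index()
        out = {}
        for rid, direction in self.columns:
            if direction == -1:
                fwd = d[idx[(rid, +1)]]
                bwd = d[idx[(rid, -1)]]
                out[rid] = float(min(fwd, bwd))
        return out

    def directed_from_net(
        self, v: dict[str, float], exchange: dict[str, float] | None = None
    ) -> np.ndarray:
        exchange = exchange or {}
        idx = self.column_index()
        d = np.zeros(self.n_columns)
        for rid in self.model.reactions:
            net = v[rid]
            if (rid, -1) in idx:
                x = exchange.get(rid, 0.0)
                d[idx[(rid, +1)]] = max(net, 0.0) + x
                d[idx[(rid, -1)]] = max(-net, 0.0) + x
            else:
                d[idx[(rid, +1)]] = net
        return d

    def net_gradient(self, reaction_id: str) -> np.ndarray:
        """d(net flux of reaction)/d(alpha), a constant vector."""
        idx = self.column_index()
        row = self.N[idx[(reaction_id, +1)]].copy()
        if (reaction_id, -1) in idx:
            row = row - self.N[idx[(reaction_id, -1)]]
        return row

    # -- feasibility ------------------------------------------------------

    def bound_violation(self, alpha: np.ndarray) -> float:
        d = self.directed(alpha)
        return float(
            max(np.max(self.lb - d, initial=0.0), np.max(d - self.ub, initial=0.0))
        )

    def chebyshev_center(self) -> np.ndarray:
        """Interior point maximizing the margin to the (free) bound faces."""
        rows = self.free_rows
        A_rows = self.N[rows]
        norms = np.linalg.norm(A_rows, axis=1)
        keep = norms > 1e-12
        A_rows, norms = A_rows[keep], norms[keep]
        lo = (self.lb - self.v_p)[rows][keep]
        hi = (self.ub - self.v_p)[rows][keep]
        k = self.dim
        # variables (alpha, t): maximize t
        A_ub = np.vstack(
            [
                np.hstack([-A_rows, norms[:, None]]),
                np.hstack([A_rows, norms[:, None]]),
            ]
        )
        b_ub = np.concatenate([-lo, hi])
        c = np.zeros(k + 1)
        c[-1] = -1.0
        res = linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=[(None, None)] * k + [(0, None)],
            method="highs",
        )
        if not res.success:
            raise ValidationError(f"infeasible flux polytope: {res.message}")
        if res.x[-1] <= 0:
            raise ValidationError(
                "flux polytope has an empty interior (Chebyshev radius 0)"
            )
        return res.x[:-1]

    def hit_and_run(
        self, x0: np.ndarray, n_samples: int, rng: np.random.Generator,
        burn: int = 200, thin: int = 10,
    ) -> list[np.ndarray]:
        """Seeded hit-and-run sampling of interior points."""
        rows = self.free_rows
        A = self.N[rows]
        lo = (self.lb - self.v_p)[rows]
        hi = (self.ub - self.v_p)[rows]
        x = np.asarray(x0, dtype=float).copy()
        samples: list[np.ndarray] = []
        total = burn + n_samples * thin
        for step in range(total):
            u = rng.normal(size=self.dim)
            u /= np.linalg.norm(u)
            a = A @ u
            b = A @ x
            t_min, t_max = -np.inf, np.inf
            with np.errstate(divide="ignore", invalid="ignore"):
                t_lo = (lo - b) / a
                t_hi = (hi - b) / a
            pos = a > 1e-13
            neg = a < -1e-13
            if np.any(pos):
                t_max = min(t_max, np.min(t_hi[pos]))
                t_min = max(t_min, np.max(t_lo[pos]))
            if np.any(neg):
                t_max = min(t_max, np.min(t_lo[neg]))
                t_min = max(t_min, np.max(t_hi[neg]))
            if not np.isfinite(t_min) or not np.isfinite(t_max) or t_max <= t_min:
                continue
            # stay strictly interior
            span = t_max - t_min
            t = rng.uniform(t_min + 1e-9 * span, t_max - 1e-9 * span)
            x = x + t * u
            if step >= burn and (step - burn) % thin == 0:
                samples.append(x.copy())
        while len(samples) < n_samples:
            samples.append(x.copy())
        return samples


def build_directed_space(
    model: NetworkModel,
    core_ids,
    exchange_cap: float = DEFAULT_EXCHANGE_CAP,
) -> DirectedFluxSpace:
    """Construct the directed flux space for a model and core set."""
    core_ids = frozenset(core_ids)
    columns: list[tuple[str, int]] = []
    lb_list: list[float] = []
    ub_list: list[float] = []
    for rid, rxn in model.reactions.items():
        if rid in core_ids and rxn.lower_bound < 0:
            columns.append((rid, +1))
            lb_list.append(0.0)
            ub_list.append(rxn.upper_bound)
            columns.append((rid, -1))
            lb_list.append(0.0)
            ub_list.append(min(-rxn.lower_bound, exchange_cap))
        else:
            columns.append((rid, +1))
            lb_list.append(rxn.lower_bound)
            ub_list.append(rxn.upper_bound)
    lb = np.array(lb_list)
    ub = np.array(ub_list)

    S, _mets, _rids = model.stoichiometric_matrix()
    n_cols = len(columns)
    S_d = np.zeros((S.shape[0], n_cols))
    rxn_order = {rid: j for j, rid in enumerate(model.reactions)}
    for j, (rid, direction) in enumerate(columns):
        S_d[:, j] = direction * S[:, rxn_order[rid]]

    # pinned columns (lb == ub) become equality constraints
    pinned = np.where(np.abs(ub - lb) <= _PIN_TOL)[0]
    free_rows = np.array(
        [j for j in range(n_cols) if j not in set(pinned.tolist())], dtype=int
    )
    E = S_d
    f = np.zeros(S_d.shape[0])
    if len(pinned):
        rows = np.zeros((len(pinned), n_cols))
        rows[np.arange(len(pinned)), pinned] = 1.0
        E = np.vstack([S_d, rows])
        f = np.concatenate([f, lb[pinned]])

    if np.allclose(f, 0.0):
        v_p = np.zeros(n_cols)
    else:
        v_p, *_ = np.linalg.lstsq(E, f, rcond=None)
        if np.linalg.norm(E @ v_p - f) > 1e-8:
            raise ValidationError(
                "pinned bounds are inconsistent with steady state"
            )
    N = null_space(E)
    if N.size == 0:
        # fully determined system: a zero-dimensional (single point) polytope
        N = np.zeros((n_cols, 0))
        if np.any(v_p < lb - 1e-6) or np.any(v_p > ub + 1e-6):
            raise ValidationError(
                "flux system is fully determined but violates its bounds"
            )
    return DirectedFluxSpace(
        model=model,
        core_ids=core_ids,
        columns=columns,
        lb=lb,
        ub=ub,
        v_p=v_p,
        N=N,
        free_rows=free_rows,
    )
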