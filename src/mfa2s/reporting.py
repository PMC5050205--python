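"""Metabolite balance reports: the sankey tables behind the flux diagrams.

For a chosen metabolite (cytosolic acetyl-CoA by default) every reaction
carrying more than ``min_flux`` of it is listed on its producing or consuming
side with the best-fit magnitude and confidence interval; at steady state the
two sides must balance.  Output is tabular (JSON / Markdown) plus a sankey
node-link structure for external plotting — rendering itself is out of scope.
"""

from __future__ import annotations

import difflib
import json
import re
from dataclasses import dataclass, field

import pandas as pd

from .core_network import NetworkModel, ValidationError
from .fitting import FluxSolution
from .uncertainty import ConfidenceInterval

BALANCE_TOL = 1e-6

EN_DASH = "–"


@dataclass
class BalanceEntry:
    reaction_id: str
    side: str  # "producing" | "consuming"
    best_fit: float  # magnitude toward the stated side, >= 0
    interval: ConfidenceInterval | None = None

    def __post_init__(self):
        if self.side not in ("producing", "consuming"):
            raise ValidationError(f"bad side {self.side!r}")
        if self.best_fit < 0:
            raise ValidationError(
                f"{self.reaction_id}: balance magnitude must be >= 0"
            )


@dataclass
class BalanceReport:
    metabolite_id: str
    entries: list[BalanceEntry] = field(default_factory=list)

    @property
    def total_production(self) -> float:
        return sum(e.best_fit for e in self.entries if e.side == "producing")

    @property
    def total_consumption(self) -> float:
        return sum(e.best_fit for e in self.entries if e.side == "consuming")

    def to_dict(self) -> dict:
        return {
            "metabolite_id": self.metabolite_id,
            "total_production": self.total_production,
            "total_consumption": self.total_consumption,
            "entries": [
                {
                    "reaction_id": e.reaction_id,
                    "side": e.side,
                    "best_fit": e.best_fit,
                    "lo": None if e.interval is None else e.interval.lo,
                    "hi": None if e.interval is None else e.interval.hi,
                }
                for e in self.entries
            ],
        }

    def to_markdown(self, digits: int = 3) -> str:
        lines = [
            f"### Balance of {self.metabolite_id} (mmol/gDW/h)",
            "",
            "| side | reaction | flux [CI] |",
            "|------|----------|-----------|",
        ]
        for e in self.entries:
            ci = (
                format_ci(e.interval, digits)
                if e.interval is not None
                else _sig(e.best_fit, digits)
            )
            lines.append(f"| {e.side} | {e.reaction_id} | {ci} |")
        lines.append(
            f"| | **total** | {_sig(self.total_production, digits)} produced, "
            f"{_sig(self.total_consumption, digits)} consumed |"
        )
        return "\n".join(lines)

    def to_sankey(self) -> dict:
        """Node-link structure: producers → metabolite → consumers."""
        nodes = [self.metabolite_id] + [e.reaction_id for e in self.entries]
        links = []
        for e in self.entries:
            lo = e.interval.lo if e.interval else None
            hi = e.interval.hi if e.interval else None
            if e.side == "producing":
                links.append({"source": e.reaction_id,
                              "target": self.metabolite_id,
                              "value": e.best_fit, "lo": lo, "hi": hi})
            else:
                links.append({"source": self.metabolite_id,
                              "target": e.reaction_id,
                              "value": e.best_fit, "lo": lo, "hi": hi})
        return {"nodes": nodes, "links": links}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def metabolite_balance(
    model: NetworkModel,
    sol: FluxSolution,
    cis: list[ConfidenceInterval],
    metabolite: str,
    min_flux: float = 0.01,
) -> BalanceReport:
    """Production/consumption ledger of one metabolite at the fitted fluxes.

    Reactions with |coefficient × net flux| above ``min_flux`` appear once on
    the side given by the sign; totals must balance for internal metabolites
    (steady state), which is re-checked here and surfaced as an error if the
    flux vector violates it.
    """
    if metabolite not in model.metabolites:
        close = difflib.get_close_matches(
            metabolite, list(model.metabolites), n=5
        )
        hint = f"; did you mean: {', '.join(close)}" if close else ""
        raise ValidationError(f"unknown metabolite {metabolite!r}{hint}")
    ci_map = {ci.reaction_id: ci for ci in cis}
    entries = []
    net_total = 0.0
    excluded = {"producing": 0.0, "consuming": 0.0}
    for rid, rxn in model.reactions.items():
        coeff = rxn.stoichiometry.get(metabolite)
        if coeff is None:
            continue
        rate = coeff * sol.v[rid]
        net_total += rate
        if abs(rate) <= min_flux:
            if rate > 0:
                excluded["producing"] += rate
            else:
                excluded["consuming"] -= rate
            continue
        side = "producing" if rate > 0 else "consuming"
        ci = ci_map.get(rid)
        if ci is not None:
            # orient the interval toward the stated side
            span = sorted((coeff * ci.lo, coeff * ci.hi))
            lo, hi = (span if side == "producing"
                      else (-span[1], -span[0]))
            ci = ConfidenceInterval(rid, abs(rate), max(lo, 0.0), max(hi, 0.0),
                                    ci.alpha, ci.unreliable)
        entries.append(BalanceEntry(rid, side, abs(rate), ci))
    is_boundary = any(
        model.reactions[rid].is_exchange
        and metabolite in model.reactions[rid].stoichiometry
        for rid in model.reactions
    )
    if not is_boundary and abs(net_total) > BALANCE_TOL:
        raise ValidationError(
            f"flux vector violates steady state at {metabolite}: net "
            f"{net_total:.3e} mmol/gDW/h"
        )
    entries.sort(key=lambda e: (-e.best_fit, e.reaction_id))
    # aggregate the sub-threshold remainder so the report itself balances
    if entries:
        for side, total in excluded.items():
            if total > 1e-12:
                entries.append(BalanceEntry("(minor reactions)", side, total))
    return BalanceReport(metabolite_id=metabolite, entries=entries)


# ---------------------------------------------------------------------------
# formatting
# ---------------------------------------------------------------------------


def _sig(x: float, digits: int) -> str:
    """Fixed significant digits with trailing zeros trimmed."""
    if abs(x) < 1e-9:  # numerical zero at any printed precision used here
        return "0"
    # %g trims trailing zeros itself and falls back to scientific notation
    # only where fixed notation would lose the value entirely
    return f"{x:.{digits}g}"


def format_ci(ci: ConfidenceInterval, digits: int = 3) -> str:
    """Render an interval as ``best [lo–hi]`` (en-dash), e.g. ``0.5 [0.3–0.66]``."""
    return (
        f"{_sig(ci.best_fit, digits)} "
        f"[{_sig(ci.lo, digits)}{EN_DASH}{_sig(ci.hi, digits)}]"
    )


_CI_RE = re.compile(
    rf"^\s*(?P<best>[-\d.eE+]+)\s*\[\s*(?P<lo>[-\d.eE+]+)\s*{EN_DASH}"
    rf"\s*(?P<hi>[-\d.eE+]+)\s*\]\s*$"
)


def parse_ci(text: str, reaction_id: str = "", alpha: float = 0.95
             ) -> ConfidenceInterval:
    """Inverse of :func:`format_ci` at the printed precision."""
    m = _CI_RE.match(text)
    if not m:
        raise ValidationError(f"cannot parse interval string {text!r}")
    return ConfidenceInterval(
        reaction_id, float(m["best"]), float(m["lo"]), float(m["hi"]), alpha
    )


def compare_strains(
    reports: dict[str, BalanceReport], digits: int = 3
) -> pd.DataFrame:
    """Wide comparison table: one row per reaction, per-strain (best, lo, hi).

    All reports must describe the same metabolite; reactions absent from a
    strain are left blank (NaN).
    """
    if not reports:
        raise ValidationError("no reports to compare")
    met_ids = {r.metabolite_id for r in reports.values()}
    if len(met_ids) != 1:
        raise ValidationError(
            f"reports describe different metabolites: {sorted(met_ids)}"
        )
    rows: dict[tuple[str, str], dict] = {}
    for strain, report in reports.items():
        for e in report.entries:
            key = (e.side, e.reaction_id)
            row = rows.setdefault(key, {})
            row[(strain, "best")] = e.best_fit
            if e.interval is not None:
                row[(strain, "lo")] = e.interval.lo
                row[(strain, "hi")] = e.interval.hi
    index = pd.MultiIndex.from_tuples(sorted(rows), names=["side", "reaction"])
    columns = pd.MultiIndex.from_product(
        [list(reports), ["best", "lo", "hi"]], names=["strain", "stat"]
    )
    df = pd.DataFrame(index=index, columns=columns, dtype=float)
    for key, row in rows.items():
        for col, val in row.items():
            df.loc[key, col] = val
    return df
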