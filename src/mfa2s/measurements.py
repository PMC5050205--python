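"""Experimental observations consumed by the flux fit.

Three kinds of inputs: mass distribution vectors of intact intracellular amino
acids (LC-MS, measured without fragmentation), exchange fluxes derived from
OD/extracellular-concentration timecourses (or given directly), and the growth
rate.  Amino-acid labeling is tied to central metabolism through curated
precursor recipes: each amino acid's carbon backbone is a convolution of
cytosolic precursor EMUs (all intracellular amino-acid pools are treated as
cytosolic).

Units: fluxes in mmol/gDW/h (uptake negative), growth rate in 1/h, biomass via
the OD600→dry-weight conversion factor 0.835 gDW/L per OD unit.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import stats

from .core_network import FormatError, ValidationError
from .labeling import EMU, MDV, FeedLabeling

#: floor on per-channel MDV standard deviations (mole fraction); prevents a
#: single near-noiseless channel from dominating the weighted SSR
MDV_SD_FLOOR = 0.005

#: rows whose fractions sum within this tolerance of 1 are renormalized;
#: larger deviations are rejected as corrupt
MDV_RENORM_TOL = 0.02

#: OD600 to dry weight, gDW/L per OD unit
OD_TO_GDW = 0.835

#: relative sd assigned to rates from minimal two-point fits
DEFAULT_REL_SD = 0.05

EXCHANGE_SD_FLOOR = 0.01


@dataclass
class MDVMeasurement:
    """Measured MDV of one fragment (a whole amino acid, all carbons)."""

    fragment_id: str
    metabolite_id: str
    positions: tuple[int, ...]
    values: MDV
    sd: np.ndarray

    def __post_init__(self):
        self.sd = np.maximum(np.asarray(self.sd, dtype=float), MDV_SD_FLOOR)
        if len(self.sd) != len(self.values):
            raise ValidationError(
                f"{self.fragment_id}: sd length {len(self.sd)} != "
                f"MDV length {len(self.values)}"
            )


@dataclass
class ExchangeMeasurement:
    """Measured net exchange flux, mmol/gDW/h; uptake is negative."""

    reaction_id: str
    rate: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValidationError(f"{self.reaction_id}: sd must be > 0")


@dataclass
class GrowthTimecourse:
    """OD600 and extracellular concentrations over exponential growth."""

    timepoints: np.ndarray  # h
    od600: np.ndarray
    concentrations: dict[str, np.ndarray]  # mM (or g/L with molar_mass given)
    od_to_gdw: float = OD_TO_GDW

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if len(self.timepoints) < 2:
            raise ValidationError("need at least 2 timepoints")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValidationError("timepoints must be strictly increasing")
        if np.any(self.od600 <= 0):
            raise ValidationError("OD600 must be positive")

    @property
    def biomass(self) -> np.ndarray:
        """gDW/L at each timepoint."""
        return self.od600 * self.od_to_gdw


@dataclass
class MeasurementSet:
    """Everything the fit consumes: MDVs, exchange fluxes, growth rate."""

    mdv_measurements: list[MDVMeasurement] = field(default_factory=list)
    exchange_measurements: list[ExchangeMeasurement] = field(default_factory=list)
    growth_rate: tuple[float, float] | None = None  # (value 1/h, sd)

    def __post_init__(self):
        frags = [m.fragment_id for m in self.mdv_measurements]
        if len(frags) != len(set(frags)):
            raise ValidationError("duplicate fragment ids in measurement set")
        rids = [m.reaction_id for m in self.exchange_measurements]
        if len(rids) != len(set(rids)):
            raise ValidationError("duplicate exchange reaction ids")

    @property
    def n_residuals(self) -> int:
        n = sum(len(m.values) for m in self.mdv_measurements)
        n += len(self.exchange_measurements)
        if self.growth_rate is not None:
            n += 1
        return n


# ---------------------------------------------------------------------------
# exchange fluxes from timecourses
# ---------------------------------------------------------------------------


def exchange_rates_from_timecourse(
    tc: GrowthTimecourse,
    metabolite_to_reaction: dict[str, str],
    molar_mass: dict[str, float] | None = None,
) -> tuple[list[ExchangeMeasurement], tuple[float, float]]:
    """Specific exchange rates and growth rate from an exponential culture.

    The growth rate μ comes from a log-linear fit of OD600 vs time.  For each
    metabolite, the yield Y is the slope of a linear fit of concentration
    against biomass (gDW/L); the specific rate is Y·μ in mmol/gDW/h, negative
    for consumed substrates.  Concentrations in g/L are converted to mM first
    when a molar mass (g/mol) is supplied.  Standard deviations are propagated
    from the fit standard errors; two-point fits carry no residual information
    and fall back to a default relative sd.
    """
    t = tc.timepoints
    fit_mu = stats.linregress(t, np.log(tc.od600))
    mu = fit_mu.slope
    mu_sd = fit_mu.stderr if len(t) > 2 and fit_mu.stderr > 0 else abs(
        mu
    ) * DEFAULT_REL_SD
    biomass = tc.biomass

    out = []
    for met, conc in tc.concentrations.items():
        conc = np.asarray(conc, dtype=float)
        if molar_mass and met in molar_mass:
            conc = conc / molar_mass[met] * 1000.0  # g/L -> mM
        fit = stats.linregress(biomass, conc)
        yield_mmol = fit.slope  # mM per gDW/L == mmol/gDW
        y_sd = fit.stderr if len(t) > 2 and fit.stderr > 0 else abs(
            yield_mmol
        ) * DEFAULT_REL_SD
        rate = yield_mmol * mu
        rel = math.hypot(
            y_sd / yield_mmol if yield_mmol != 0 else 0.0, mu_sd / mu
        )
        sd = max(abs(rate) * rel, EXCHANGE_SD_FLOOR)
        rid = metabolite_to_reaction.get(met, met)
        out.append(ExchangeMeasurement(rid, rate, sd))
    return out, (mu, max(mu_sd, 1e-4))


# ---------------------------------------------------------------------------
# amino-acid precursor recipes
# ---------------------------------------------------------------------------

_RECIPES: dict[str, list[EMU]] | None = None


def _parse_positions(text: str) -> tuple[int, ...]:
    out: list[int] = []
    for chunk in text.split(","):
        chunk = chunk.strip()
        if "-" in chunk:
            a, b = chunk.split("-")
            out.extend(range(int(a), int(b) + 1))
        elif chunk:
            out.append(int(chunk))
    return tuple(out)


def _load_recipes() -> dict[str, list[EMU]]:
    global _RECIPES
    if _RECIPES is None:
        _RECIPES = {}
        src = importlib.resources.files("mfa2s.data").joinpath(
            "aa_precursors.tsv"
        )
        for line in src.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            aa, n_c, recipe = line.split("\t")
            parts = []
            for token in recipe.split():
                met, pos = token.split(":")
                parts.append(EMU(met, _parse_positions(pos)))
            if sum(p.size for p in parts) != int(n_c):
                raise FormatError(
                    f"recipe for {aa} does not add up to {n_c} carbons"
                )
            _RECIPES[aa] = parts
    return _RECIPES


def supported_amino_acids() -> list[str]:
    return sorted(_load_recipes())


def map_aa_to_precursor(amino_acid: str) -> list[EMU]:
    """Precursor EMUs whose convolution gives the amino acid's backbone MDV.

    All pools are cytosolic.  Raises for amino acids outside the measured set.
    """
    recipes = _load_recipes()
    if amino_acid not in recipes:
        raise ValidationError(
            f"unsupported amino acid {amino_acid!r}; supported: "
            f"{', '.join(sorted(recipes))}"
        )
    return list(recipes[amino_acid])


def resolve_fragment(meas: MDVMeasurement) -> list[EMU]:
    """Precursor EMUs for a measurement: amino-acid recipe, else direct EMU."""
    recipes = _load_recipes()
    if meas.fragment_id in recipes:
        return list(recipes[meas.fragment_id])
    return [EMU(meas.metabolite_id, meas.positions)]


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def _format_positions(positions: tuple[int, ...]) -> str:
    return ",".join(map(str, positions))


def read_mdv_table(path) -> list[MDVMeasurement]:
    """Read the MDV TSV (fragment_id, metabolite_id, positions, M0..Mn, sd).

    Rows whose fractions sum within ±0.02 of 1 are renormalized; rows further
    off are rejected with their line number.  Malformed numerics raise with
    the offending location.
    """
    out = []
    rejected = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if parts[:3] != ["fragment_id", "metabolite_id", "positions"]:
                    raise FormatError(f"{path}:{lineno}: unexpected header")
                continue
            frag, met, pos_text = parts[:3]
            cells = [c for c in parts[3:] if c.strip() != ""]
            try:
                numbers = [float(c) for c in cells]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            *fracs, sd = numbers
            fracs = np.array(fracs)
            total = fracs.sum()
            if abs(total - 1.0) > MDV_RENORM_TOL:
                rejected.append((lineno, total))
                continue
            positions = _parse_positions(pos_text)
            if len(fracs) != len(positions) + 1:
                raise FormatError(
                    f"{path}:{lineno}: {len(fracs)} fractions for "
                    f"{len(positions)}-carbon fragment"
                )
            out.append(
                MDVMeasurement(
                    fragment_id=frag,
                    metabolite_id=met,
                    positions=positions,
                    values=MDV(frag, np.clip(fracs, 0, None) / total),
                    sd=np.full(len(fracs), sd),
                )
            )
    if rejected:
        import warnings

        warnings.warn(
            "MDV rows rejected (fraction sum too far from 1): "
            + ", ".join(f"line {ln} (sum {s:.3f})" for ln, s in rejected),
            stacklevel=2,
        )
    return out


def write_mdv_table(measurements: list[MDVMeasurement], path) -> None:
    n_max = max(len(m.values) for m in measurements)
    cols = [f"M{i}" for i in range(n_max)]
    with open(path, "w") as fh:
        fh.write(
            "fragment_id\tmetabolite_id\tpositions\t"
            + "\t".join(cols)
            + "\tsd\n"
        )
        for m in measurements:
            cells = [f"{x:.10f}" for x in m.values.fractions]
            cells += [""] * (n_max - len(cells))
            fh.write(
                f"{m.fragment_id}\t{m.metabolite_id}\t"
                f"{_format_positions(m.positions)}\t"
                + "\t".join(cells)
                + f"\t{float(m.sd[0]):.10f}\n"
            )


def read_exchange_table(path) -> list[ExchangeMeasurement]:
    out = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            try:
                out.append(
                    ExchangeMeasurement(parts[0], float(parts[1]),
                                        float(parts[2]))
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_exchange_table(measurements: list[ExchangeMeasurement], path) -> None:
    with open(path, "w") as fh:
        fh.write("reaction_id\trate\tsd\n")
        for m in measurements:
            fh.write(f"{m.reaction_id}\t{m.rate:.10f}\t{m.sd:.10f}\n")


def read_feed_yaml(path) -> FeedLabeling:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return FeedLabeling(
            metabolite_id=doc["metabolite_id"],
            components=[(c["pattern"], float(c["fraction"]))
                        for c in doc["components"]],
            purity=float(doc.get("purity", 1.0)),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"bad feed spec {path}: {exc}") from None


def write_feed_yaml(feed: FeedLabeling, path) -> None:
    doc = {
        "metabolite_id": feed.metabolite_id,
        "components": [
            {"pattern": p, "fraction": float(f)} for p, f in feed.components
        ],
        "purity": float(feed.purity),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
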