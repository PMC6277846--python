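"""Stoichiometric data model and the core C1 network of *M. alcaliphilum* 20Z.

The model captures methane oxidation to methanol by pMMO, the two
alternative methanol-oxidation routes — the calcium-dependent MxaFI
methanol dehydrogenase and the lanthanide-dependent XoxF enzyme — plus a
cytochrome-linked formaldehyde→formate reaction (``MXALa``) that encodes
the hypothesised dual methanol/formaldehyde activity of XoxF.  Downstream
carbon handling (H4MPT-linked formaldehyde oxidation, formate
dehydrogenase, a lumped RuMP assimilation step) and a lumped electron
transport chain close the redox and energy balances.

Conventions
-----------
* Single compartment; protons are folded into the lumped P/O parameters.
* Exchange reactions are written ``met_e -> met`` with the boundary
  species flagged ``is_exchange_species``; uptake fluxes are therefore
  positive numbers.
* Redox carriers are bookkeeping pairs: ``nadh`` carries 2 H, a reduced
  cytochrome carries 1 H, ``qh2`` carries 2 H, so that non-lumped
  reactions close for H and O as well as carbon.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "EnzymeConfig",
    "BalanceReport",
    "ConfigurationError",
    "ModelValidationError",
    "ReactionParseError",
    "parse_reaction_equation",
    "format_reaction_equation",
    "build_core_model",
    "check_balance",
    "write_model_table",
    "read_model_table",
    "write_sbml_subset",
    "read_sbml_subset",
]

DEFAULT_BOUND = 1000.0


class ReactionParseError(ValueError):
    """Malformed reaction-equation string."""


class ConfigurationError(ValueError):
    """Inconsistent enzyme/route configuration."""


class ModelValidationError(ValueError):
    """Structurally invalid model."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    formula: dict[str, int] = field(default_factory=dict)
    compartment: str = "c"
    is_exchange_species: bool = False
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if any(v < 0 for v in self.formula.values()):
            raise ModelValidationError(f"negative element count in formula of {self.id!r}")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    objective_coefficient: float = 0.0
    is_lumped: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        zeros = [m for m, c in self.stoichiometry.items() if c == 0]
        for m in zeros:
            del self.stoichiometry[m]
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: all coefficients zero")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class StoichiometricModel:
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    #: extra linear rows: (coefficients by reaction id, relation in {"=", "<=", ">="}, rhs)
    extra_constraints: list[tuple[dict[str, float], str, float]] = field(default_factory=list)
    annotations: dict[str, str] = field(default_factory=dict)

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            metabolites=dict(self.metabolites),
            reactions={rid: replace(r, stoichiometry=dict(r.stoichiometry))
                       for rid, r in self.reactions.items()},
            extra_constraints=[(dict(c), rel, rhs) for c, rel, rhs in self.extra_constraints],
            annotations=dict(self.annotations),
        )

    @property
    def objective_reactions(self) -> list[str]:
        return [rid for rid, r in self.reactions.items() if r.objective_coefficient != 0]

    def balanced_species(self) -> list[str]:
        """Metabolite ids that enter the steady-state constraint S·v = 0."""
        return [m for m, met in self.metabolites.items() if not met.is_exchange_species]

    def is_exchange_reaction(self, rid: str) -> bool:
        rxn = self.reactions[rid]
        return any(self.metabolites[m].is_exchange_species for m in rxn.stoichiometry)

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )


# ---------------------------------------------------------------------------
# equation grammar: coef? met_id (" + " coef? met_id)* (" -> " | " <-> ") products
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_COEF_RE = re.compile(r"^\d+(\.\d+)?$")


def _parse_side(side: str, sign: float, text: str) -> dict[str, float]:
    entries: dict[str, float] = {}
    side = side.strip()
    if not side:
        return entries
    for term in side.split(" + "):
        term = term.strip()
        if not term:
            raise ReactionParseError(f"empty term in equation {text!r}")
        parts = term.split()
        if len(parts) == 1:
            coef, met = 1.0, parts[0]
        elif len(parts) == 2:
            if not _COEF_RE.match(parts[0]):
                raise ReactionParseError(f"bad coefficient {parts[0]!r} in {text!r}")
            coef, met = float(parts[0]), parts[1]
        else:
            raise ReactionParseError(f"malformed term {term!r} in {text!r}")
        if not _TOKEN_RE.match(met):
            raise ReactionParseError(f"bad metabolite token {met!r} in {text!r}")
        if coef <= 0:
            raise ReactionParseError(f"non-positive coefficient for {met!r} in {text!r}")
        if met in entries:
            raise ReactionParseError(f"duplicate metabolite {met!r} on one side of {text!r}")
        entries[met] = sign * coef
    return entries


def parse_reaction_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse an equation string into a signed stoichiometry map.

    Returns ``(stoichiometry, reversible)`` with substrates negative and
    products positive.  ``" -> "`` marks irreversible, ``" <-> "``
    reversible reactions; both sides of a reversible arrow must be
    non-empty.
    """
    if " <-> " in text or text.rstrip().endswith("<->"):
        reversible = True
        lhs, _, rhs = text.partition("<->")
    elif " -> " in text or text.rstrip().endswith("->"):
        reversible = False
        lhs, _, rhs = text.partition("->")
    else:
        raise ReactionParseError(f"no reaction arrow in {text!r}")
    subs = _parse_side(lhs, -1.0, text)
    prods = _parse_side(rhs, +1.0, text)
    if reversible and (not subs or not prods):
        raise ReactionParseError(f"empty side with reversible arrow in {text!r}")
    if not subs and not prods:
        raise ReactionParseError(f"both sides empty in {text!r}")
    overlap = set(subs) & set(prods)
    if overlap:
        raise ReactionParseError(
            f"metabolite {sorted(overlap)[0]!r} appears on both sides of {text!r}"
        )
    stoich = dict(subs)
    stoich.update(prods)
    return stoich, reversible


def _fmt_coef(c: float) -> str:
    if c == int(c):
        return str(int(c)) if c != 1 else ""
    return repr(round(c, 10))


def format_reaction_equation(rxn: Reaction) -> str:
    """Inverse of :func:`parse_reaction_equation` (stable metabolite order)."""
    subs = [(m, -c) for m, c in rxn.stoichiometry.items() if c < 0]
    prods = [(m, c) for m, c in rxn.stoichiometry.items() if c > 0]

    def side(entries: list[tuple[str, float]]) -> str:
        parts = []
        for m, c in entries:
            coef = _fmt_coef(c)
            parts.append(f"{coef} {m}".strip())
        return " + ".join(parts)

    arrow = "<->" if rxn.reversible else "->"
    return f"{side(subs)} {arrow} {side(prods)}".strip()


# ---------------------------------------------------------------------------
# default core model
# ---------------------------------------------------------------------------


@dataclass
class EnzymeConfig:
    """Which enzymes are wired in and the lumped energetic parameters.

    ``po_nadh`` / ``po_cyt`` are ATP yields per NADH / per cytochrome pair
    oxidised in the electron transport chain (lumped P/O ratios);
    ``biomass_atp_cost`` (β) and ``biomass_nadh_cost`` (γ) are moles of ATP
    and NADH consumed per pyruvate drawn into biomass; ``maintenance_atp``
    is a non-growth ATP drain (mmol gDCW⁻¹ h⁻¹, lower bound on NGAM).
    """

    mxaFI_active: bool = True
    xoxF_active: bool = False
    mxala_active: bool = False
    formate_reclaim_active: bool = False
    direct_coupling_active: bool = True
    po_nadh: float = 1.5
    po_cyt: float = 1.0
    biomass_atp_cost: float = 2.7
    biomass_nadh_cost: float = 0.3
    maintenance_atp: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("po_nadh", "po_cyt", "biomass_atp_cost",
                     "biomass_nadh_cost", "maintenance_atp"):
            if getattr(self, attr) < 0:
                raise ConfigurationError(f"{attr} must be >= 0")

    @classmethod
    def calcium(cls, **kw) -> "EnzymeConfig":
        """Ca-grown wild-type wiring: MxaFI methanol route only."""
        return cls(mxaFI_active=True, xoxF_active=False, mxala_active=False,
                   formate_reclaim_active=False, **kw)

    @classmethod
    def lanthanum(cls, **kw) -> "EnzymeConfig":
        """La-grown wiring: XoxF route, MXALa branch, H4F formate reclaim."""
        return cls(mxaFI_active=False, xoxF_active=True, mxala_active=True,
                   formate_reclaim_active=True, **kw)


_FORMULAS: dict[str, dict[str, int]] = {
    "ch4": {"C": 1, "H": 4},
    "ch3oh": {"C": 1, "H": 4, "O": 1},
    "hcho": {"C": 1, "H": 2, "O": 1},
    "chooh": {"C": 1, "H": 2, "O": 2},
    "co2": {"C": 1, "O": 2},
    "o2": {"O": 2},
    "h2o": {"H": 2, "O": 1},
    "pyr": {"C": 3, "H": 4, "O": 3},
}

# bookkeeping species: redox carriers hold the H they ferry; energy species empty
_PSEUDO_FORMULAS: dict[str, dict[str, int]] = {
    "q": {}, "qh2": {"H": 2},
    "cytm_ox": {}, "cytm_red": {"H": 1},
    "cytx_ox": {}, "cytx_red": {"H": 1},
    "nad": {}, "nadh": {"H": 2},
    "atp": {}, "adp": {}, "pi": {},
    "biomass": {},
}

_MET_NAMES = {
    "ch4": "methane", "ch3oh": "methanol", "hcho": "formaldehyde",
    "chooh": "formate", "co2": "carbon dioxide", "o2": "oxygen",
    "h2o": "water", "pyr": "pyruvate", "q": "quinone (oxidised)",
    "qh2": "quinol", "cytm_ox": "MxaFI cytochrome pool (ox)",
    "cytm_red": "MxaFI cytochrome pool (red)",
    "cytx_ox": "XoxF cytochrome pool (ox)",
    "cytx_red": "XoxF cytochrome pool (red)",
    "nad": "NAD+", "nadh": "NADH", "atp": "ATP", "adp": "ADP",
    "pi": "phosphate", "biomass": "biomass",
}


def build_core_model(config: EnzymeConfig | None = None) -> StoichiometricModel:
    """Assemble the default core model for the given enzyme configuration.

    Raises :class:`ConfigurationError` if no methanol-oxidation route is
    active (growth on methane would be impossible).
    """
    config = config or EnzymeConfig()
    if not (config.mxaFI_active or config.xoxF_active):
        raise ConfigurationError(
            "no active methanol-oxidation route (need mxaFI_active or xoxF_active)"
        )
    m = StoichiometricModel(annotations={"source": "laswitch core model"})

    for mid, formula in _FORMULAS.items():
        m.add_metabolite(Metabolite(mid, name=_MET_NAMES.get(mid, mid), formula=formula))
    for mid, formula in _PSEUDO_FORMULAS.items():
        m.add_metabolite(Metabolite(
            mid, name=_MET_NAMES.get(mid, mid), formula=formula, is_pseudo=True,
            is_exchange_species=(mid == "biomass"),
        ))
    for mid in ("ch4_e", "o2_e", "co2_e", "h2o_e"):
        m.add_metabolite(Metabolite(
            mid, name=f"{_MET_NAMES.get(mid[:-2], mid)} (extracellular)",
            formula=_FORMULAS.get(mid[:-2], {}), compartment="e",
            is_exchange_species=True,
        ))

    def rxn(rid: str, eq: str | dict[str, float], name: str = "",
            lumped: bool = False, lb: float | None = None,
            ub: float = DEFAULT_BOUND, objective: float = 0.0) -> None:
        if isinstance(eq, dict):
            stoich = {k: v for k, v in eq.items() if v != 0}
            reversible = False
        else:
            stoich, reversible = parse_reaction_equation(eq)
        lower = lb if lb is not None else (-DEFAULT_BOUND if reversible else 0.0)
        m.add_reaction(Reaction(rid, stoich, name=name, lower_bound=lower,
                                upper_bound=ub, objective_coefficient=objective,
                                is_lumped=lumped))

    po_n, po_c = config.po_nadh, config.po_cyt
    beta, gamma = config.biomass_atp_cost, config.biomass_nadh_cost

    rxn("EX_CH4", "ch4_e -> ch4", "methane uptake")
    rxn("EX_O2", "o2_e -> o2", "oxygen uptake")
    rxn("EX_CO2", "co2 -> co2_e", "CO2 export")
    rxn("EX_H2O", "h2o -> h2o_e", "water export")
    rxn("PMMO", "ch4 + o2 + qh2 -> ch3oh + h2o + q",
        "particulate methane monooxygenase")
    if config.mxaFI_active:
        rxn("MXA", "ch3oh + 2 cytm_ox -> hcho + 2 cytm_red",
            "MxaFI methanol dehydrogenase")
    if config.xoxF_active:
        rxn("XOXF", "ch3oh + 2 cytx_ox -> hcho + 2 cytx_red",
            "XoxF methanol dehydrogenase")
    if config.mxala_active:
        rxn("MXALa", "hcho + h2o + 2 cytx_ox -> chooh + 2 cytx_red",
            "XoxF formaldehyde oxidation (cytochrome-linked)")
    if config.maintenance_atp > DEFAULT_BOUND:
        raise ConfigurationError("maintenance_atp exceeds the default flux bound")
    rxn("H4MPT", "hcho + nad -> chooh + nadh",
        "H4MPT-linked formaldehyde oxidation (lumped)", lumped=True)
    rxn("FDH", "chooh + nad -> co2 + nadh", "formate dehydrogenase")
    rxn("RUMP", "3 hcho + adp + pi + nad -> pyr + atp + nadh",
        "RuMP assimilation to pyruvate (lumped)", lumped=True)
    if config.formate_reclaim_active:
        rxn("H4F_RECLAIM", "chooh + atp + nadh -> hcho + adp + pi + nad + h2o",
            "H4folate formate reclaim (lumped)", lumped=True)
    rxn("NDH_Q", "nadh + q -> nad + qh2", "NADH:quinone oxidoreductase")
    rxn("ETC_NADH",
        {"nadh": -1, "o2": -0.5, "adp": -po_n, "pi": -po_n,
         "nad": 1, "h2o": 1, "atp": po_n},
        "NADH respiration (lumped ETC)", lumped=True)
    if config.mxaFI_active:
        rxn("ETC_CYTM",
            {"cytm_red": -2, "o2": -0.5, "adp": -po_c, "pi": -po_c,
             "cytm_ox": 2, "h2o": 1, "atp": po_c},
            "MxaFI-cytochrome respiration", lumped=True)
        if config.direct_coupling_active:
            rxn("CYTM_Q", "2 cytm_red + q -> 2 cytm_ox + qh2",
                "MeDH cytochrome to quinone coupling")
    if config.xoxF_active or config.mxala_active:
        rxn("ETC_CYTX",
            {"cytx_red": -2, "o2": -0.5, "adp": -po_c, "pi": -po_c,
             "cytx_ox": 2, "h2o": 1, "atp": po_c},
            "XoxF-cytochrome respiration", lumped=True)
        if config.direct_coupling_active:
            rxn("CYTX_Q", "2 cytx_red + q -> 2 cytx_ox + qh2",
                "XoxF cytochrome to quinone coupling")
    rxn("BIOMASS",
        {"pyr": -1, "atp": -beta, "nadh": -gamma,
         "biomass": 1, "adp": beta, "pi": beta, "nad": gamma},
        "biomass synthesis (lumped)", lumped=True, objective=1.0)
    rxn("NGAM", "atp -> adp + pi", "non-growth ATP maintenance",
        lb=config.maintenance_atp)

    m.annotations["config"] = repr(config)
    return m


# ---------------------------------------------------------------------------
# element balance
# ---------------------------------------------------------------------------


@dataclass
class BalanceReport:
    imbalances: dict[str, dict[str, float]]
    exempt: list[str]
    passed: bool

    def __bool__(self) -> bool:
        return self.passed


def check_balance(model: StoichiometricModel,
                  elements: tuple[str, ...] = ("C", "O", "H"),
                  tol: float = 1e-9) -> BalanceReport:
    """Element-balance audit of every reaction.

    Carbon must close on all non-exchange reactions, lumped ones included;
    other elements are checked only on non-lumped reactions.  Exchange
    reactions (those touching a boundary species) are exempt entirely.
    """
    for met in model.metabolites.values():
        if not met.formula and not met.is_pseudo:
            raise ModelValidationError(
                f"metabolite {met.id!r} has no formula and is not flagged pseudo"
            )
    imbalances: dict[str, dict[str, float]] = {}
    exempt: list[str] = []
    for rid, rxn in model.reactions.items():
        if model.is_exchange_reaction(rid):
            exempt.append(rid)
            continue
        checked = [e for e in elements if e == "C" or not rxn.is_lumped]
        bad: dict[str, float] = {}
        for elem in checked:
            net = sum(coef * model.metabolites[mid].formula.get(elem, 0)
                      for mid, coef in rxn.stoichiometry.items())
            if abs(net) > tol:
                bad[elem] = net
        if bad:
            imbalances[rid] = bad
        if rxn.is_lumped:
            exempt.append(rid)
    return BalanceReport(imbalances=imbalances, exempt=exempt,
                         passed=not imbalances)


# ---------------------------------------------------------------------------
# reaction-table TSV
# ---------------------------------------------------------------------------

_TABLE_HEADER = "id\tname\tequation\tlb\tub\tobjective"
_MET_HEADER = "id\tformula\tpseudo\texchange\tcompartment\tname"


def _formula_str(formula: dict[str, int]) -> str:
    return "".join(f"{e}{n}" for e, n in sorted(formula.items())) or "-"


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_formula(text: str) -> dict[str, int]:
    if text in ("", "-"):
        return {}
    out: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos or not match.group(0):
            break
        out[match.group(1)] = int(match.group(2) or 1)
        pos = match.end()
    if pos != len(text):
        raise ModelValidationError(f"cannot parse formula {text!r}")
    return out


def write_model_table(model: StoichiometricModel, destination) -> None:
    """Serialise a model to the two-block TSV dialect (reactions, then
    ``# metabolites``)."""
    lines = [_TABLE_HEADER]
    for rid, rxn in model.reactions.items():
        eq = format_reaction_equation(rxn)
        lines.append(f"{rid}\t{rxn.name}\t{eq}\t{rxn.lower_bound:g}\t"
                     f"{rxn.upper_bound:g}\t{rxn.objective_coefficient:g}"
                     + ("\tlumped" if rxn.is_lumped else ""))
    lines.append("# metabolites")
    lines.append(_MET_HEADER)
    for mid, met in model.metabolites.items():
        lines.append(f"{mid}\t{_formula_str(met.formula)}\t{int(met.is_pseudo)}\t"
                     f"{int(met.is_exchange_species)}\t{met.compartment}\t{met.name}")
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w", encoding="utf-8") as fh:
            fh.write(text)


def read_model_table(source) -> StoichiometricModel:
    """Inverse of :func:`write_model_table`."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    lines = text.splitlines()
    try:
        split = lines.index("# metabolites")
    except ValueError:
        raise ModelValidationError("missing '# metabolites' block") from None
    rxn_lines, met_lines = lines[1:split], lines[split + 2:]
    if not lines or lines[0] != _TABLE_HEADER:
        raise ModelValidationError("bad reaction-table header")

    model = StoichiometricModel()
    for row in met_lines:
        if not row.strip():
            continue
        parts = row.split("\t")
        if len(parts) < 6:
            raise ModelValidationError(f"malformed metabolite row: {row!r}")
        mid, formula, pseudo, exch, comp, name = parts[:6]
        model.add_metabolite(Metabolite(
            mid, name=name, formula=_parse_formula(formula), compartment=comp,
            is_pseudo=bool(int(pseudo)), is_exchange_species=bool(int(exch)),
        ))
    for row in rxn_lines:
        if not row.strip():
            continue
        parts = row.split("\t")
        if len(parts) < 6:
            raise ModelValidationError(f"malformed reaction row: {row!r}")
        rid, name, eq, lb, ub, obj = parts[:6]
        lumped = len(parts) > 6 and parts[6] == "lumped"
        stoich, _ = parse_reaction_equation(eq)
        for met_id in stoich:
            if met_id not in model.metabolites:
                raise ModelValidationError(
                    f"row {rid!r}: unknown metabolite {met_id!r}"
                )
        model.add_reaction(Reaction(
            rid, stoich, name=name, lower_bound=float(lb), upper_bound=float(ub),
            objective_coefficient=float(obj), is_lumped=lumped,
        ))
    return model


# ---------------------------------------------------------------------------
# SBML Level 3 + fbc subset
# ---------------------------------------------------------------------------


def write_sbml_subset(model: StoichiometricModel, destination) -> None:
    """Export to SBML Level 3 core + fbc (bounds and objective)."""
    import libsbml

    doc = libsbml.SBMLDocument(libsbml.SBMLNamespaces(3, 1, "fbc", 2))
    doc.setPackageRequired("fbc", False)
    sbml = doc.createModel()
    sbml.setId("laswitch_core")
    fbc = sbml.getPlugin("fbc")
    fbc.setStrict(False)

    comps = {met.compartment for met in model.metabolites.values()}
    for cid in sorted(comps):
        comp = sbml.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for mid, met in model.metabolites.items():
        sp = sbml.createSpecies()
        sp.setId(mid)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(met.is_exchange_species)
        sp.setConstant(False)
        if met.formula or not met.is_pseudo:
            sp.getPlugin("fbc").setChemicalFormula(_formula_str(met.formula).replace("-", ""))
        if met.is_pseudo:
            sp.setSBOTerm("SBO:0000649")  # pseudo/bookkeeping species

    def add_param(pid: str, value: float) -> str:
        par = sbml.createParameter()
        par.setId(pid)
        par.setValue(value)
        par.setConstant(True)
        return pid

    obj = fbc.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fbc.setActiveObjectiveId("obj")

    for i, (rid, rxn) in enumerate(model.reactions.items()):
        rx = sbml.createReaction()
        rx.setId(rid)
        rx.setName(rxn.name)
        rx.setReversible(rxn.reversible)
        rx.setFast(False)
        if rxn.is_lumped:
            rx.setSBOTerm("SBO:0000395")  # lumped/encapsulating process
        for mid, coef in rxn.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(add_param(f"lb_{i}", rxn.lower_bound))
        rfbc.setUpperFluxBound(add_param(f"ub_{i}", rxn.upper_bound))
        if rxn.objective_coefficient:
            fo = obj.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(rxn.objective_coefficient)

    text = libsbml.writeSBMLToString(doc)
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w", encoding="utf-8") as fh:
            fh.write(text)


def read_sbml_subset(source) -> StoichiometricModel:
    """Import an SBML Level 3 core (+fbc) file.

    Only species, reactions, fbc flux bounds and the active objective are
    read; unsupported constructs (rules, events) are ignored with a logged
    warning.  Missing fbc bounds fall back to (−1000, 1000) with a
    warning; a missing objective leaves all objective coefficients zero.
    """
    import libsbml

    if hasattr(source, "read"):
        doc = libsbml.readSBMLFromString(source.read())
    else:
        doc = libsbml.readSBMLFromFile(str(source))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise IOError(
            "unreadable SBML: " + doc.getErrorLog().toString().strip()
        )
    sbml = doc.getModel()
    if sbml is None:
        raise IOError("SBML document contains no model")
    if sbml.getNumRules() or sbml.getNumEvents():
        logger.warning("ignoring %d rules / %d events in SBML import",
                       sbml.getNumRules(), sbml.getNumEvents())

    model = StoichiometricModel(annotations={"sbml_id": sbml.getId() or ""})
    for sp in sbml.getListOfSpecies():
        spf = sp.getPlugin("fbc")
        formula = {}
        if spf is not None and spf.isSetChemicalFormula():
            formula = _parse_formula(spf.getChemicalFormula())
        pseudo = (not formula) or sp.getSBOTermID() == "SBO:0000649"
        model.add_metabolite(Metabolite(
            sp.getId(), name=sp.getName() or "", formula=formula,
            compartment=sp.getCompartment() or "c",
            is_exchange_species=sp.getBoundaryCondition(),
            is_pseudo=pseudo,
        ))

    mfbc = sbml.getPlugin("fbc")
    objective_coefs: dict[str, float] = {}
    if mfbc is not None and mfbc.getActiveObjective() is not None:
        for fo in mfbc.getActiveObjective().getListOfFluxObjectives():
            objective_coefs[fo.getReaction()] = fo.getCoefficient()
    if not objective_coefs:
        warnings.warn("SBML model has no fbc objective; all coefficients zero",
                      stacklevel=2)

    def bound_value(rx, which: str, default: float) -> float:
        rfbc = rx.getPlugin("fbc")
        pid = None
        if rfbc is not None:
            pid = (rfbc.getLowerFluxBound() if which == "lb"
                   else rfbc.getUpperFluxBound()) or None
        if pid is None:
            warnings.warn(f"reaction {rx.getId()!r}: missing fbc {which}, "
                          f"defaulting to {default}", stacklevel=3)
            return default
        par = sbml.getParameter(pid)
        if par is None or math.isnan(par.getValue()):
            warnings.warn(f"reaction {rx.getId()!r}: unresolvable bound {pid!r}",
                          stacklevel=3)
            return default
        return par.getValue()

    for rx in sbml.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rx.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in rx.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        lb = bound_value(rx, "lb", -DEFAULT_BOUND if rx.getReversible() else 0.0)
        ub = bound_value(rx, "ub", DEFAULT_BOUND)
        model.add_reaction(Reaction(
            rx.getId(), stoich, name=rx.getName() or "",
            lower_bound=lb, upper_bound=ub,
            objective_coefficient=objective_coefs.get(rx.getId(), 0.0),
            is_lumped=rx.getSBOTermID() == "SBO:0000395",
        ))
    return model
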