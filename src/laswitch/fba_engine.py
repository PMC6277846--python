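"""Flux balance analysis for the methanol-fate branch model.

Solves max-growth FBA with a fixed methane uptake, optionally constrained
so that a fraction ``phi_formate`` of XoxF-processed methanol is carried
on to formate by the cytochrome-linked MXALa reaction.  A secondary
minimisation of total absolute flux (parsimonious FBA) makes reported
flux vectors reproducible across alternate optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .network_core import (
    ConfigurationError,
    EnzymeConfig,
    StoichiometricModel,
    build_core_model,
)

__all__ = [
    "FluxSolution",
    "ScanRow",
    "CalibrationError",
    "solve_fba",
    "apply_branch_fraction",
    "scan_branch_fractions",
    "calibrate_energetics",
    "flux_variability",
    "best_matching_phi",
    "DEFAULT_CH4_UPTAKE",
]

#: Default methane uptake (mmol gDCW⁻¹ h⁻¹), back-calculated from the
#: wild-type O2 consumption rate and O2:CH4 ratio (13.77 / 1.18).
DEFAULT_CH4_UPTAKE = 13.77 / 1.18

FEASIBILITY_TOL = 1e-9


class CalibrationError(RuntimeError):
    """Bisection target outside the achievable ratio bracket."""


@dataclass
class FluxSolution:
    status: str
    objective_value: float = float("nan")
    fluxes: dict[str, float] = field(default_factory=dict)
    o2_uptake: float = float("nan")
    ch4_uptake: float = float("nan")
    ratio_o2_ch4: float = float("nan")

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class ScanRow:
    scenario: str
    phi_formate: float | None
    o2_rate: float
    ratio: float
    growth: float
    status: str = "optimal"


def _lp_arrays(model: StoichiometricModel):
    rids = list(model.reactions)
    idx = {rid: j for j, rid in enumerate(rids)}
    species = model.balanced_species()
    srow = {mid: i for i, mid in enumerate(species)}
    S = np.zeros((len(species), len(rids)))
    for rid, rxn in model.reactions.items():
        for mid, coef in rxn.stoichiometry.items():
            if mid in srow:
                S[srow[mid], idx[rid]] = coef
    lb = np.array([model.reactions[r].lower_bound for r in rids])
    ub = np.array([model.reactions[r].upper_bound for r in rids])
    A_eq, b_eq = [S], [np.zeros(len(species))]
    A_ub, b_ub = [], []
    for coefs, rel, rhs in model.extra_constraints:
        row = np.zeros(len(rids))
        for rid, c in coefs.items():
            row[idx[rid]] = c
        if rel == "=":
            A_eq.append(row[None, :])
            b_eq.append([rhs])
        elif rel == "<=":
            A_ub.append(row)
            b_ub.append(rhs)
        elif rel == ">=":
            A_ub.append(-row)
            b_ub.append(-rhs)
        else:
            raise ValueError(f"unknown relation {rel!r}")
    A_eq = np.vstack(A_eq)
    b_eq = np.concatenate([np.atleast_1d(b) for b in b_eq])
    A_ub = np.vstack(A_ub) if A_ub else None
    b_ub = np.array(b_ub) if b_ub else None
    return rids, idx, A_eq, b_eq, A_ub, b_ub, lb, ub


def solve_fba(model: StoichiometricModel, ch4_uptake: float | None = None,
              objective: str | None = None,
              parsimonious: bool = True) -> FluxSolution:
    """Maximise the objective reaction at fixed methane uptake.

    ``ch4_uptake`` (mmol gDCW⁻¹ h⁻¹) clamps both bounds of ``EX_CH4``;
    pass ``None`` to leave the model's own bounds in place.  Among
    alternate optima the solution minimising Σ|v| at the fixed optimum is
    returned.  Infeasible/unbounded problems are reported in ``status``,
    not raised.
    """
    work = model.copy()
    if ch4_uptake is not None:
        if ch4_uptake <= 0:
            raise ValueError("ch4_uptake must be > 0")
        if "EX_CH4" not in work.reactions:
            raise ConfigurationError("model has no EX_CH4 reaction")
        work.reactions["EX_CH4"].lower_bound = ch4_uptake
        work.reactions["EX_CH4"].upper_bound = ch4_uptake
    rids, idx, A_eq, b_eq, A_ub, b_ub, lb, ub = _lp_arrays(work)
    n = len(rids)
    c = np.zeros(n)
    if objective is not None:
        if objective not in work.reactions:
            raise ConfigurationError(f"objective reaction {objective!r} not in model")
        c[idx[objective]] = -1.0  # linprog minimises
    else:
        objs = work.objective_reactions
        if not objs:
            raise ConfigurationError("model has no objective reaction")
        for rid in objs:
            c[idx[rid]] = -work.reactions[rid].objective_coefficient

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status == 2:
        return FluxSolution(status="infeasible")
    if res.status == 3:
        return FluxSolution(status="unbounded")
    if res.status != 0:
        return FluxSolution(status=f"solver_error:{res.status}")
    opt = -res.fun
    v = res.x

    if parsimonious:
        # stage 2: min Σ|v| subject to objective fixed at optimum.
        # v = vp - vm with vp, vm >= 0 bounded by the original box.
        c2 = np.ones(2 * n)
        split = lambda A: np.hstack([A, -A]) if A is not None else None
        A_eq2 = np.vstack([split(A_eq),
                           np.concatenate([c * -1, c])[None, :]])
        b_eq2 = np.concatenate([b_eq, [opt]])
        bounds2 = ([(max(0.0, l), max(0.0, u)) for l, u in zip(lb, ub)] +
                   [(max(0.0, -u), max(0.0, -l)) for l, u in zip(lb, ub)])
        res2 = linprog(c2, A_ub=split(A_ub), b_ub=b_ub, A_eq=A_eq2,
                       b_eq=b_eq2, bounds=bounds2, method="highs")
        if res2.status == 0:
            v = res2.x[:n] - res2.x[n:]

    fluxes = {rid: float(v[idx[rid]]) for rid in rids}
    o2 = fluxes.get("EX_O2", float("nan"))
    ch4 = fluxes.get("EX_CH4", float("nan"))
    ratio = o2 / ch4 if ch4 and ch4 > 0 else float("nan")
    return FluxSolution(status="optimal", objective_value=float(opt),
                        fluxes=fluxes, o2_uptake=float(o2),
                        ch4_uptake=float(ch4), ratio_o2_ch4=float(ratio))


def apply_branch_fraction(model: StoichiometricModel,
                          phi_formate: float) -> StoichiometricModel:
    """Return a copy with the constraint v_MXALa = phi_formate · v_XOXF.

    ``phi_formate`` is the fraction of XoxF-oxidised methanol whose
    formaldehyde is carried on to formate by the cytochrome-linked route.
    """
    if not 0.0 <= phi_formate <= 1.0:
        raise ValueError(f"phi_formate must be in [0, 1], got {phi_formate}")
    for rid in ("XOXF", "MXALa"):
        if rid not in model.reactions:
            raise ConfigurationError(
                f"branch constraint needs reaction {rid!r} in the model"
            )
    out = model.copy()
    out.extra_constraints.append(
        ({"MXALa": 1.0, "XOXF": -phi_formate}, "=", 0.0)
    )
    return out


def scan_branch_fractions(model: StoichiometricModel, phis, ch4_uptake: float,
                          include_wt: bool = False,
                          wt_model: StoichiometricModel | None = None
                          ) -> list[ScanRow]:
    """One independent solve per phi at fixed methane uptake.

    Rows come back in input order; infeasible phis are flagged and the
    scan continues.  With ``include_wt`` a wild-type (Ca-configured,
    no-MXALa) row is prepended, solved from ``wt_model`` if given.
    """
    rows: list[ScanRow] = []
    if include_wt:
        base = wt_model if wt_model is not None else build_core_model(
            EnzymeConfig.calcium())
        sol = solve_fba(base, ch4_uptake=ch4_uptake)
        rows.append(ScanRow("WT", None, sol.o2_uptake, sol.ratio_o2_ch4,
                            sol.objective_value, sol.status))
    for phi in phis:
        constrained = apply_branch_fraction(model, phi)
        sol = solve_fba(constrained, ch4_uptake=ch4_uptake)
        rows.append(ScanRow(f"phi={phi:g}", float(phi), sol.o2_uptake,
                            sol.ratio_o2_ch4, sol.objective_value, sol.status))
    return rows


def calibrate_energetics(model_builder, target_ratio: float,
                         beta_range: tuple[float, float] = (0.0, 20.0),
                         ch4_uptake: float = DEFAULT_CH4_UPTAKE,
                         tol: float = 1e-3, max_iter: int = 200) -> float:
    """Bisect the biomass ATP cost β so the solved O₂:CH₄ ratio hits
    ``target_ratio``.

    ``model_builder(beta)`` must return a solvable model.  The ratio is
    checked to be monotone non-decreasing over the bracket; an
    unreachable target raises :class:`CalibrationError` reporting the
    achieved bracket.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    lo, hi = beta_range
    if lo >= hi:
        raise ValueError("empty beta_range")

    def ratio_at(beta: float) -> float:
        sol = solve_fba(model_builder(beta), ch4_uptake=ch4_uptake,
                        parsimonious=False)
        if not sol.optimal:
            raise CalibrationError(f"model infeasible at beta={beta}")
        return sol.ratio_o2_ch4

    r_lo, r_hi = ratio_at(lo), ratio_at(hi)
    if r_hi < r_lo - tol:
        raise CalibrationError(
            f"ratio not monotone non-decreasing over beta_range: "
            f"r({lo})={r_lo:.4f} > r({hi})={r_hi:.4f}"
        )
    if not (r_lo - tol <= target_ratio <= r_hi + tol):
        raise CalibrationError(
            f"target ratio {target_ratio} outside achievable bracket "
            f"[{r_lo:.4f}, {r_hi:.4f}] for beta in [{lo}, {hi}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = ratio_at(mid)
        if abs(r_mid - target_ratio) < tol:
            return mid
        if r_mid < target_ratio:
            lo = mid
        else:
            hi = mid
    r_final = ratio_at(0.5 * (lo + hi))
    if abs(r_final - target_ratio) < tol:
        return 0.5 * (lo + hi)
    raise CalibrationError(
        f"bisection did not converge: best ratio {r_final:.5f} "
        f"vs target {target_ratio}"
    )


def flux_variability(model: StoichiometricModel,
                     fraction_of_optimum: float = 1.0,
                     ch4_uptake: float | None = None
                     ) -> dict[str, tuple[float, float]]:
    """Per-reaction (min, max) flux subject to near-optimal growth."""
    if not 0.0 < fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    base = solve_fba(model, ch4_uptake=ch4_uptake, parsimonious=False)
    if not base.optimal:
        raise RuntimeError(f"base FBA problem is {base.status}")
    work = model.copy()
    if ch4_uptake is not None:
        work.reactions["EX_CH4"].lower_bound = ch4_uptake
        work.reactions["EX_CH4"].upper_bound = ch4_uptake
    objective = work.objective_reactions[0]
    floor = fraction_of_optimum * base.objective_value
    work.extra_constraints.append(({objective: 1.0}, ">=", floor - FEASIBILITY_TOL))
    rids, idx, A_eq, b_eq, A_ub, b_ub, lb, ub = _lp_arrays(work)
    out: dict[str, tuple[float, float]] = {}
    for rid in rids:
        c = np.zeros(len(rids))
        c[idx[rid]] = 1.0
        lohi = []
        for sense in (1.0, -1.0):
            res = linprog(sense * c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq,
                          b_eq=b_eq, bounds=list(zip(lb, ub)), method="highs")
            if res.status != 0:
                raise RuntimeError(f"FVA subproblem for {rid!r} failed ({res.status})")
            lohi.append(sense * res.fun)
        vmin, vmax = min(lohi), max(lohi)
        out[rid] = (float(vmin), float(vmax))
    return out


def best_matching_phi(scan: list[ScanRow], observed_ratio: float) -> float:
    """Phi whose solved ratio is closest to the observed O₂:CH₄ ratio;
    ties break toward the smaller phi.  WT rows (phi None) are ignored."""
    candidates = [r for r in scan if r.phi_formate is not None
                  and r.status == "optimal"]
    if not candidates:
        raise ValueError("scan contains no feasible phi rows")
    dmin = min(abs(r.ratio - observed_ratio) for r in candidates)
    tied = [r for r in candidates
            if abs(r.ratio - observed_ratio) <= dmin + 1e-9]
    return min(r.phi_formate for r in tied)
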