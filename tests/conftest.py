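"""Shared fixtures: core models, one session-wide calibration, toy
networks, and an independent vertex-enumeration LP oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from laswitch.fba_engine import DEFAULT_CH4_UPTAKE, calibrate_energetics
from laswitch.network_core import (
    EnzymeConfig,
    Metabolite,
    Reaction,
    StoichiometricModel,
    build_core_model,
)

TABLE1 = {
    # condition: (dilution rate, biomass g/L, yield g/g, O2:CH4 ratio or None,
    #             q_CH4 printed, q_CH4 sd, productivity printed)
    "ca_optimal": (0.05, 0.64, 1.2, 1.12, 2.59, 0.26, 31.8),
    "ca_limited": (0.05, 0.67, 0.98, None, 3.11, 0.11, 33.7),
    "la_optimal": (0.07, 0.75, 0.64, 1.28, 6.75, 0.09, 53.1),
    "la_limited": (0.06, 0.45, 0.67, None, 5.55, 0.20, 28.7),
}

#: published flux-simulation scan: phi (formate fraction) -> (O2 rate, ratio)
SCAN_TABLE = {
    None: (13.77, 1.18),   # wild type
    0.25: (14.95, 1.28),
    0.5: (16.17, 1.38),
    0.75: (17.39, 1.49),
    1.0: (19.14, 1.64),
}


@pytest.fixture(scope="session")
def ca_model():
    return build_core_model(EnzymeConfig.calcium())


@pytest.fixture(scope="session")
def la_model():
    return build_core_model(EnzymeConfig.lanthanum())


@pytest.fixture(scope="session")
def calibrated_beta():
    """Biomass ATP cost calibrated so the wild type hits ratio 1.18."""
    return calibrate_energetics(
        lambda b: build_core_model(EnzymeConfig.calcium(biomass_atp_cost=b)),
        target_ratio=1.18, ch4_uptake=DEFAULT_CH4_UPTAKE)


@pytest.fixture(scope="session")
def calibrated_models(calibrated_beta):
    wt = build_core_model(EnzymeConfig.calcium(biomass_atp_cost=calibrated_beta))
    la = build_core_model(EnzymeConfig.lanthanum(biomass_atp_cost=calibrated_beta))
    return wt, la


def make_toy_chain() -> StoichiometricModel:
    """EX_A (≤10) → A → B → export; single pathway, optimum 10."""
    m = StoichiometricModel()
    m.add_metabolite(Metabolite("a_e", is_exchange_species=True, is_pseudo=True))
    m.add_metabolite(Metabolite("a", is_pseudo=True))
    m.add_metabolite(Metabolite("b", is_pseudo=True))
    m.add_metabolite(Metabolite("b_e", is_exchange_species=True, is_pseudo=True))
    m.add_reaction(Reaction("EX_A", {"a_e": -1, "a": 1}, upper_bound=10))
    m.add_reaction(Reaction("A2B", {"a": -1, "b": 1}, upper_bound=100))
    m.add_reaction(Reaction("SINK_B", {"b": -1, "b_e": 1}, upper_bound=100,
                            objective_coefficient=1.0))
    return m


def make_parallel_routes() -> StoichiometricModel:
    """Two redundant A→B routes; alternate optima span [0, optimum]."""
    m = make_toy_chain()
    m.add_reaction(Reaction("A2B_ALT", {"a": -1, "b": 1}, upper_bound=100))
    return m


def make_branched_toy() -> StoichiometricModel:
    """A splits into B (worth 1) and C (worth 2), C route capped at 4."""
    m = StoichiometricModel()
    for mid in ("a_e", "b_e", "c_e"):
        m.add_metabolite(Metabolite(mid, is_exchange_species=True, is_pseudo=True))
    for mid in ("a", "b", "c"):
        m.add_metabolite(Metabolite(mid, is_pseudo=True))
    m.add_reaction(Reaction("EX_A", {"a_e": -1, "a": 1}, upper_bound=6))
    m.add_reaction(Reaction("A2B", {"a": -1, "b": 1}, upper_bound=100))
    m.add_reaction(Reaction("A2C", {"a": -1, "c": 1}, upper_bound=4))
    m.add_reaction(Reaction("SINK_B", {"b": -1, "b_e": 1}, upper_bound=100,
                            objective_coefficient=1.0))
    m.add_reaction(Reaction("SINK_C", {"c": -1, "c_e": 1}, upper_bound=100,
                            objective_coefficient=2.0))
    return m


TOY_MODELS = {
    "chain": make_toy_chain,
    "parallel": make_parallel_routes,
    "branched": make_branched_toy,
}


def vertex_enumeration_optimum(model: StoichiometricModel) -> float:
    """Brute-force LP oracle: enumerate polytope vertices of
    {S v = 0, lb ≤ v ≤ ub} and return the best weighted objective.

    Only viable for a handful of reactions; independent of the HiGHS
    solve path used by the implementation.
    """
    rids = list(model.reactions)
    n = len(rids)
    species = model.balanced_species()
    S = np.zeros((len(species), n))
    for j, rid in enumerate(rids):
        for mid, coef in model.reactions[rid].stoichiometry.items():
            if mid in species:
                S[species.index(mid), j] = coef
    lb = np.array([model.reactions[r].lower_bound for r in rids])
    ub = np.array([model.reactions[r].upper_bound for r in rids])
    c = np.array([model.reactions[r].objective_coefficient for r in rids])
    rank = np.linalg.matrix_rank(S) if S.size else 0
    k = n - rank
    best = -np.inf
    for fixed in itertools.combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        for assignment in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.zeros(n)
            for j, val in zip(fixed, assignment):
                v[j] = val
            rhs = -S[:, list(fixed)] @ np.array(assignment) if fixed else np.zeros(len(species))
            if free:
                sol, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
                continue
            best = max(best, float(c @ v))
    return best
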