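"""Six curated substrate scenarios for ethylene production via EFE.

Each scenario is a small carbon-balanced network feeding the lumped EFE
reaction ``akg -> ethylene + 3 co2`` (the succinate-forming side
reaction is deliberately excluded; its stoichiometry is contested).
Scenarios by substrate:

    A  CO2 only (autotrophic, Calvin-Benson-Bassham cycle)
    B  glucose only (heterotrophic, glycolysis)
    C  xylose only (heterotrophic, non-oxidative pentose phosphate)
    D  glucose + xylose (heterotrophic, mixed sugars)
    E  glucose + CO2 (mixotrophic, one-pass Rubisco shunt)
    F  xylose + CO2 (mixotrophic, one-pass Rubisco shunt)

The reaction set uses canonical textbook stoichiometries, lumped to the
metabolites of the scenario diagrams; the maximum carbon yields are
invariant to lumping choices that conserve carbon.  "One-pass" Rubisco
in E/F is enforced structurally: E and F contain no oxidative pentose
phosphate reactions and E contains no FBP aldolase/FBPase, so reduced
3-phosphoglycerate cannot regenerate RuBP on its own and the CO2-fixing
flux cannot iterate as a standalone cycle.  Oxygen does not appear in
the scenario networks (the lumped EFE reaction carries no O2 term);
cofactors (ATP/NADH/NADPH) are annotations, reported as balances but
never constraining flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .efm import FluxMode, UndefinedYieldError, enumerate_efms, mode_yield
from .reaction_model import (
    Network,
    load_metabolites_tsv,
    load_reactions_tsv,
    stoichiometric_matrix,
)

ETHYLENE = "eth_e"
CO2_INTERNAL = "co2"
CO2_EXTERNAL = "co2_e"

#: reaction ids per scenario (single source of truth: data/scenario_reactions.tsv)
SCENARIO_REACTIONS: dict[str, tuple[str, ...]] = {
    "A": (
        "co2_in", "co2_out", "rubisco", "prk", "pgared", "tpi", "fba", "fbpase",
        "tkt1", "tkt2", "sba", "sbpase", "eno", "pyk", "pdh", "ppc", "cs", "icd", "efe",
    ),
    "B": ("glc_upt", "pfk", "gapdh", "eno", "pyk", "pdh", "ppc", "cs", "icd", "efe", "co2_out"),
    "C": (
        "xyl_upt", "tkt1", "tal", "tkt2", "pfk", "gapdh", "eno", "pyk", "pdh",
        "ppc", "cs", "icd", "efe", "co2_out",
    ),
    "D": (
        "glc_upt", "xyl_upt", "tkt1", "tal", "tkt2", "pfk", "gapdh", "eno", "pyk",
        "pdh", "ppc", "cs", "icd", "efe", "co2_out",
    ),
    "E": (
        "glc_upt", "pfk", "gapdh", "eno", "pyk", "pdh", "ppc", "cs", "icd", "efe",
        "tkt1", "tkt2", "tpi", "sba", "sbpase", "pgared", "prk", "rubisco",
        "co2_in", "co2_out",
    ),
    "F": (
        "xyl_upt", "tkt1", "tal", "tkt2", "pfk", "gapdh", "eno", "pyk", "pdh",
        "ppc", "cs", "icd", "efe", "prk", "rubisco", "pgared", "co2_in", "co2_out",
    ),
}

#: organic substrates per scenario; A is scored on net CO2 uptake instead
SCENARIO_SUBSTRATES: dict[str, tuple[str, ...]] = {
    "A": (CO2_EXTERNAL,),
    "B": ("glc_e",),
    "C": ("xyl_e",),
    "D": ("glc_e", "xyl_e"),
    "E": ("glc_e",),
    "F": ("xyl_e",),
}


def build_scenario(scenario_id: str) -> Network:
    """Load one curated scenario network from the shipped TSV tables."""
    sid = scenario_id.upper()
    if sid not in SCENARIO_REACTIONS:
        raise KeyError(f"unknown scenario {scenario_id!r}; expected one of A-F")
    data = resources.files("efeflux.data")
    mets = load_metabolites_tsv(data / "scenario_metabolites.tsv")
    all_rxns = {r.id: r for r in load_reactions_tsv(data / "scenario_reactions.tsv")}
    rxns = [all_rxns[rid] for rid in SCENARIO_REACTIONS[sid]]
    used = set().union(*(r.species() for r in rxns))
    return Network(
        name=f"scenario_{sid}",
        metabolites={m: mets[m] for m in mets if m in used},
        reactions=rxns,
    )


@dataclass(frozen=True)
class ScenarioResult:
    """Per-mole-ethylene summary of the best elementary mode(s).

    ``max_carbon_yield`` is None when the network has no route from the
    scenario substrates to ethylene.  Gross CO2 released/fixed count the
    internal (non-exchange) reactions only, so for the glucose scenario
    they read "5 lost (PDH 1 + ICD 1 + EFE 3), 1 fixed (C4 route)".
    """

    scenario_id: str
    max_carbon_yield: Fraction | None
    best_modes: tuple[FluxMode, ...] = ()
    co2_released_per_ethylene: Fraction | None = None
    co2_fixed_per_ethylene: Fraction | None = None
    atp_balance_per_ethylene: Fraction | None = None
    nadh_balance_per_ethylene: Fraction | None = None
    nadph_balance_per_ethylene: Fraction | None = None

    @property
    def no_route(self) -> bool:
        return self.max_carbon_yield is None


def _is_co2_exchange(rxn) -> bool:
    return CO2_EXTERNAL in rxn.stoich


def co2_gross_flows(mode: FluxMode, net: Network) -> tuple[Fraction, Fraction]:
    """(gross released, gross fixed) moles of CO2 over internal reactions."""
    released = Fraction(0)
    fixed = Fraction(0)
    for rxn, v in zip(net.reactions, mode.fluxes):
        if v == 0 or _is_co2_exchange(rxn):
            continue
        flow = v * rxn.stoich.get(CO2_INTERNAL, Fraction(0))
        if flow > 0:
            released += flow
        else:
            fixed -= flow
    return released, fixed


def cofactor_balance(mode: FluxMode, net: Network) -> dict[str, Fraction]:
    out = {k: Fraction(0) for k in ("atp", "nadh", "nadph")}
    for rxn, v in zip(net.reactions, mode.fluxes):
        for k, c in rxn.cofactors.items():
            out[k] += v * c
    return out


def ethylene_production(mode: FluxMode, net: Network, product_id: str = ETHYLENE) -> Fraction:
    total = Fraction(0)
    for rxn, v in zip(net.reactions, mode.fluxes):
        total += v * rxn.stoich.get(product_id, Fraction(0))
    return total


def scenario_summary(scenario_id: str) -> ScenarioResult:
    """Enumerate the scenario's modes and summarize the best ethylene route.

    Yields follow the module convention: organic-substrate carbon in the
    denominator for B-F, net CO2 uptake for the autotrophic scenario A.
    Values are normalized to the formation of 1 mole of ethylene; on
    yield ties all tied modes are reported and the summary numbers come
    from the lexicographically first.
    """
    sid = scenario_id.upper()
    net = build_scenario(sid)
    substrates = SCENARIO_SUBSTRATES[sid]
    scored: list[tuple[Fraction, FluxMode]] = []
    for mode in enumerate_efms(net):
        if ethylene_production(mode, net) <= 0:
            continue
        try:
            scored.append((mode_yield(mode, net, substrates, ETHYLENE), mode))
        except UndefinedYieldError:
            continue
    if not scored:
        return ScenarioResult(scenario_id=sid, max_carbon_yield=None)
    best_yield = max(y for y, _ in scored)
    best = tuple(m for y, m in scored if y == best_yield)
    top = best[0]
    per_eth = ethylene_production(top, net)
    released, fixed = co2_gross_flows(top, net)
    cof = cofactor_balance(top, net)
    return ScenarioResult(
        scenario_id=sid,
        max_carbon_yield=best_yield,
        best_modes=best,
        co2_released_per_ethylene=released / per_eth,
        co2_fixed_per_ethylene=fixed / per_eth,
        atp_balance_per_ethylene=cof["atp"] / per_eth,
        nadh_balance_per_ethylene=cof["nadh"] / per_eth,
        nadph_balance_per_ethylene=cof["nadph"] / per_eth,
    )


def lp_max_yield(
    net: Network,
    substrate_ids: Sequence[str],
    product_id: str,
    _tol_denominator: int = 10**6,
) -> Fraction | None:
    """Linear-programming cross-check of the maximum carbon yield.

    Maximizes product carbon output subject to steady state and
    irreversibility with total substrate carbon uptake bounded by 1
    carbon-mole.  By the pathway decomposition theorem the optimum is
    attained on an elementary mode, so this must equal the maximum over
    EFM yields; it is used as an independent oracle for the enumerator.
    A network with no route to the product reports Fraction(0); None is
    returned only if the LP itself is infeasible (ill-posed network).

    The solver works in floating point; the result is snapped back to
    the nearest small rational, which is exact for the desk-scale
    networks this package targets.
    """
    S, _, _ = stoichiometric_matrix(net)
    cols: list[tuple[int, int]] = []
    for j, rxn in enumerate(net.reactions):
        cols.append((j, +1))
        if rxn.reversible:
            cols.append((j, -1))
    n = len(cols)

    def species_row(species: str) -> np.ndarray:
        row = np.zeros(n)
        for k, (j, d) in enumerate(cols):
            row[k] = d * float(net.reactions[j].stoich.get(species, 0))
        return row

    A_eq = np.zeros((len(S), n))
    for i, srow in enumerate(S):
        for k, (j, d) in enumerate(cols):
            A_eq[i, k] = d * float(srow[j])
    b_eq = np.zeros(len(S))
    uptake = np.zeros(n)
    for s in substrate_ids:
        uptake -= species_row(s) * net.metabolites[s].carbons

    c = -species_row(product_id) * net.metabolites[product_id].carbons
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=uptake.reshape(1, -1),
        b_ub=np.ones(1),
        bounds=(0, None),
        method="highs",
    )
    if not res.success:
        return None
    return Fraction(-res.fun).limit_denominator(_tol_denominator)
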