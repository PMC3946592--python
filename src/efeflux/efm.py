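"""Exact elementary-flux-mode enumeration for small networks.

An elementary flux mode (EFM) is a steady-state flux vector v (S v = 0
over internal metabolites, v_j >= 0 for irreversible j) whose support is
minimal: no other admissible vector uses a strict subset of its
reactions.  Every admissible steady-state flux is a nonnegative
combination of EFMs, so the EFM set is the complete catalogue of
"minimal pathways" of a network.

The enumerator is the classical tableau (nullspace/double-description)
algorithm: reversible reactions are split into forward/backward columns,
metabolite constraints are imposed one at a time by pairwise combination
of rows with opposite signs, and candidate rays are kept only if no
existing ray's support is contained in theirs.  All arithmetic is exact
(``fractions.Fraction``), so the printed yields of the scenario analyses
are exact rationals, not floating-point approximations.

Intended scale is tens of reactions (the curated substrate scenarios
have 11-24); enumeration aborts if the intermediate tableau exceeds
``max_tableau_rows`` rather than degrade silently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from ._linalg import matvec, nullspace
from .reaction_model import Network, stoichiometric_matrix


class TableauSizeError(RuntimeError):
    """The intermediate tableau grew beyond the configured bound."""


class NotSteadyStateError(ValueError):
    """A vector handed to the elementarity test violates S v = 0."""


class UndefinedYieldError(ZeroDivisionError):
    """Carbon yield is undefined: the mode consumes no listed substrate."""


@dataclass(frozen=True)
class FluxMode:
    """One elementary mode: exact integer fluxes in network reaction order."""

    reaction_ids: tuple[str, ...]
    fluxes: tuple[Fraction, ...]

    @property
    def support(self) -> frozenset[str]:
        return frozenset(r for r, v in zip(self.reaction_ids, self.fluxes) if v != 0)

    def flux(self, rxn_id: str) -> Fraction:
        return self.fluxes[self.reaction_ids.index(rxn_id)]

    def __str__(self) -> str:
        terms = ", ".join(
            f"{r}={v}" for r, v in zip(self.reaction_ids, self.fluxes) if v != 0
        )
        return f"<mode {terms}>"


def _normalize(
    v: Sequence[Fraction], irreversible: Sequence[bool]
) -> tuple[Fraction, ...] | None:
    """Coprime-integer normal form; orientation fixed by irreversibility.

    Returns None for the zero vector.  A mode whose support is entirely
    reversible has a free sign; the convention is that the first support
    entry is positive.
    """
    support = [i for i, x in enumerate(v) if x != 0]
    if not support:
        return None
    denom = math.lcm(*(x.denominator for x in v))
    ints = [x * denom for x in v]
    g = math.gcd(*(int(x) for x in ints))
    ints = [Fraction(int(x) // g) for x in ints]
    if any(irreversible[i] for i in support):
        if any(ints[i] < 0 and irreversible[i] for i in support):
            raise ValueError("sign-infeasible vector cannot be normalized")
    elif ints[support[0]] < 0:
        ints = [-x for x in ints]
    return tuple(ints)


def enumerate_efms(net: Network, max_tableau_rows: int = 10_000) -> list[FluxMode]:
    """All elementary flux modes, deterministically ordered.

    Modes are normalized to coprime integer fluxes and sorted
    lexicographically by support (reaction indices).  A network whose
    modes are all internal cycles (no exchange flux) triggers a warning
    but is returned as-is.
    """
    n_rxn = len(net.reactions)
    if n_rxn == 0:
        return []
    S, _, _ = stoichiometric_matrix(net)
    n_met = len(S)

    # split reversible reactions into forward/backward columns
    cols: list[tuple[int, int]] = []  # (reaction index, direction)
    for j, rxn in enumerate(net.reactions):
        cols.append((j, +1))
        if rxn.reversible:
            cols.append((j, -1))

    # tableau rows: (metabolite part, ray part over split columns)
    rows: list[tuple[list[Fraction], list[Fraction]]] = []
    for k, (j, d) in enumerate(cols):
        m = [S[i][j] * d for i in range(n_met)]
        ray = [Fraction(0)] * len(cols)
        ray[k] = Fraction(1)
        rows.append((m, ray))

    for i in range(n_met):
        zeros = [r for r in rows if r[0][i] == 0]
        pos = [r for r in rows if r[0][i] > 0]
        neg = [r for r in rows if r[0][i] < 0]
        supports = [frozenset(t for t, x in enumerate(r[1]) if x != 0) for r in rows]
        kept: dict[frozenset[int], tuple[list[Fraction], list[Fraction]]] = {}
        for p in pos:
            for n in neg:
                a = p[0][i]
                b = -n[0][i]
                new_ray = [b * x + a * y for x, y in zip(p[1], n[1])]
                supp = frozenset(t for t, x in enumerate(new_ray) if x != 0)
                if supp in kept:
                    continue
                # keep only support-minimal candidates: no other current
                # ray may fit inside the candidate's support
                minimal = True
                for r, s in zip(rows, supports):
                    if r is p or r is n:
                        continue
                    if s <= supp:
                        minimal = False
                        break
                if not minimal:
                    continue
                new_m = [b * x + a * y for x, y in zip(p[0], n[0])]
                g = math.gcd(
                    *(x.numerator for x in new_ray if x != 0)
                ) or 1
                lcm = math.lcm(*(x.denominator for x in new_ray))
                scale = Fraction(lcm, g)
                kept[supp] = ([x * scale for x in new_m], [x * scale for x in new_ray])
        rows = zeros + list(kept.values())
        if len(rows) > max_tableau_rows:
            raise TableauSizeError(
                f"tableau grew to {len(rows)} rows (limit {max_tableau_rows})"
            )

    irreversible = [not r.reversible for r in net.reactions]
    rxn_ids = tuple(r.id for r in net.reactions)
    modes: dict[tuple[Fraction, ...], FluxMode] = {}
    for _, ray in rows:
        v = [Fraction(0)] * n_rxn
        for k, (j, d) in enumerate(cols):
            v[j] += d * ray[k]
        norm = _normalize(v, irreversible)
        if norm is None:  # spurious forward/backward two-cycle
            continue
        modes[norm] = FluxMode(reaction_ids=rxn_ids, fluxes=norm)

    result = sorted(
        modes.values(),
        key=lambda m: tuple(i for i, x in enumerate(m.fluxes) if x != 0),
    )
    if result and not any(_touches_external(m, net) for m in result):
        warnings.warn(
            f"network {net.name!r} has only internal cycles (no exchange flux)",
            stacklevel=2,
        )
    return result


def _touches_external(mode: FluxMode, net: Network) -> bool:
    for rxn, v in zip(net.reactions, mode.fluxes):
        if v != 0 and any(net.metabolites[m].external for m in rxn.species()):
            return True
    return False


def is_elementary(v: Sequence[Fraction], net: Network) -> bool:
    """Rank test: support submatrix of S must have nullspace dimension 1.

    Preconditions (S v = 0, sign feasibility) are enforced; the zero
    vector is not elementary by convention.
    """
    v = [Fraction(x) for x in v]
    if len(v) != len(net.reactions):
        raise ValueError("flux vector length does not match network")
    support = [j for j, x in enumerate(v) if x != 0]
    if not support:
        return False
    S, _, _ = stoichiometric_matrix(net)
    if any(x != 0 for x in matvec(S, v)):
        raise NotSteadyStateError("S v != 0")
    for j in support:
        if not net.reactions[j].reversible and v[j] < 0:
            raise ValueError(f"negative flux through irreversible reaction {net.reactions[j].id!r}")
    sub = [[row[j] for j in support] for row in S]
    return len(nullspace(sub, n_cols=len(support))) == 1


def _net_production(mode: FluxMode, net: Network, species: str) -> Fraction:
    total = Fraction(0)
    for rxn, v in zip(net.reactions, mode.fluxes):
        total += v * rxn.stoich.get(species, Fraction(0))
    return total


def mode_yield(
    mode: FluxMode,
    net: Network,
    substrate_ids: Sequence[str],
    product_id: str,
) -> Fraction:
    """Carbon yield: product carbon formed per substrate carbon consumed.

    The denominator sums net consumption of the listed substrates only,
    weighted by their carbon counts -- so for heterotrophic/mixotrophic
    analyses pass the organic substrates and CO2 exchange stays out of
    the denominator, while an autotrophic analysis passes CO2 itself
    (giving yield on net CO2 uptake).
    """
    denom = Fraction(0)
    for s in substrate_ids:
        consumption = -_net_production(mode, net, s)
        denom += consumption * net.metabolites[s].carbons
    if denom <= 0:
        raise UndefinedYieldError(
            f"mode consumes none of the listed substrates {list(substrate_ids)}"
        )
    produced = _net_production(mode, net, product_id)
    if produced < 0:
        raise ValueError(f"mode consumes the product {product_id!r}")
    return produced * net.metabolites[product_id].carbons / denom
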