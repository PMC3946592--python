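"""Metabolites, reactions, and small stoichiometric networks.

The data model underlying the whole package: species carry explicit carbon
and nitrogen atom counts so that every reaction can be checked for exact
elemental balance, and all stoichiometric coefficients are
``fractions.Fraction`` so that yields such as 1/3 and 1/2 are exact.

Hydrogen/oxygen closure (water, protons) is deliberately not modelled;
only C and N are balanced.  Cofactors (ATP, NADH, NADPH) are reaction
annotations, not network species, so they never constrain steady-state
flux -- negative cofactor balances are meaningful outputs (they must be
supplied from elsewhere, e.g. photosynthetic light reactions).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._linalg import Matrix

COFACTORS = ("atp", "nadh", "nadph")


class ReactionParseError(ValueError):
    """Raised for malformed reaction equation strings."""


class DegenerateReactionError(ValueError):
    """Raised when every species cancels to a net coefficient of zero."""


class UnknownSpeciesError(KeyError):
    """Raised when a reaction references a metabolite not in the registry."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    carbons: int = 0
    nitrogens: int = 0
    external: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 0 or self.nitrogens < 0:
            raise ValueError(f"negative atom count for metabolite {self.id!r}")


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed rational stoichiometry.

    Negative coefficients are consumed species, positive are produced.
    ``cofactors`` maps atp/nadh/nadph to the net amount produced per unit
    flux (negative = consumed).
    """

    id: str
    stoich: Mapping[str, Fraction]
    reversible: bool = False
    cofactors: Mapping[str, Fraction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stoich:
            raise DegenerateReactionError(f"reaction {self.id!r} has empty stoichiometry")
        clean = {m: Fraction(c) for m, c in self.stoich.items() if Fraction(c) != 0}
        if not clean:
            raise DegenerateReactionError(f"reaction {self.id!r} cancels to nothing")
        object.__setattr__(self, "stoich", clean)
        cof = {k: Fraction(v) for k, v in self.cofactors.items() if Fraction(v) != 0}
        unknown = set(cof) - set(COFACTORS)
        if unknown:
            raise ValueError(f"unknown cofactor tags {sorted(unknown)} on {self.id!r}")
        object.__setattr__(self, "cofactors", cof)

    def species(self) -> set[str]:
        return set(self.stoich)


_TERM_RE = re.compile(r"^(?:(\d+(?:/\d+)?)\s+)?([A-Za-z_][A-Za-z0-9_]*)$")
_ARROW_RE = re.compile(r"<->|<=>|->|=")


def parse_reaction(
    equation: str,
    id: str = "r",
    reversible: bool | None = None,
    cofactors: Mapping[str, Fraction] | None = None,
) -> Reaction:
    """Parse ``coef? met (+ coef? met)* (->|<->|=) ...`` into a Reaction.

    ``=`` is accepted as a synonym of ``->`` (figure-legend notation);
    ``<->``/``<=>`` mark reversible reactions unless ``reversible`` is
    given explicitly.  A species appearing on both sides is stored with
    its net coefficient; if everything cancels a
    :class:`DegenerateReactionError` is raised.
    """
    arrows = _ARROW_RE.findall(equation)
    if len(arrows) != 1:
        raise ReactionParseError(f"expected exactly one arrow in {equation!r}")
    arrow = arrows[0]
    lhs_txt, rhs_txt = _ARROW_RE.split(equation)
    if reversible is None:
        reversible = arrow in ("<->", "<=>")
    stoich: dict[str, Fraction] = {}
    for side_txt, sign in ((lhs_txt, -1), (rhs_txt, +1)):
        side_txt = side_txt.strip()
        if not side_txt:
            raise ReactionParseError(f"empty side in {equation!r}")
        for term in side_txt.split("+"):
            term = " ".join(term.split())
            m = _TERM_RE.match(term)
            if not m:
                raise ReactionParseError(f"malformed term {term!r} in {equation!r}")
            coef_txt, met = m.groups()
            coef = Fraction(coef_txt) if coef_txt else Fraction(1)
            if coef <= 0:
                raise ReactionParseError(f"non-positive coefficient in term {term!r}")
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coef
    if all(c == 0 for c in stoich.values()):
        raise DegenerateReactionError(f"reaction {id!r} ({equation!r}) cancels to nothing")
    return Reaction(id=id, stoich=stoich, reversible=reversible, cofactors=dict(cofactors or {}))


def _fmt_coef(c: Fraction) -> str:
    return "" if c == 1 else f"{c} "


def serialize_reaction(r: Reaction) -> str:
    """Canonical equation string: substrates and products sorted by id."""
    lhs = [(m, -c) for m, c in sorted(r.stoich.items()) if c < 0]
    rhs = [(m, c) for m, c in sorted(r.stoich.items()) if c > 0]
    arrow = "<->" if r.reversible else "->"
    fmt = lambda side: " + ".join(f"{_fmt_coef(c)}{m}" for m, c in side)
    return f"{fmt(lhs)} {arrow} {fmt(rhs)}".strip()


@dataclass
class Network:
    name: str
    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ValueError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
            missing = rxn.species() - set(self.metabolites)
            if missing:
                raise UnknownSpeciesError(
                    f"reaction {rxn.id!r} references unregistered species {sorted(missing)}"
                )

    @property
    def internal_metabolites(self) -> list[str]:
        return [m for m in self.metabolites if not self.metabolites[m].external]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)


def element_balance(r: Reaction, net: Network, element: str = "C") -> Fraction:
    """Net element imbalance of a reaction; 0 means balanced.

    ``element`` is ``"C"`` or ``"N"``.  Returns sum(coefficient x atom
    count), which for a balanced reaction is exactly zero.
    """
    attr = {"C": "carbons", "N": "nitrogens"}.get(element.upper())
    if attr is None:
        raise ValueError(f"element must be C or N, got {element!r}")
    total = Fraction(0)
    for met, coef in r.stoich.items():
        if met not in net.metabolites:
            raise UnknownSpeciesError(f"species {met!r} not registered in network {net.name!r}")
        total += coef * getattr(net.metabolites[met], attr)
    return total


def stoichiometric_matrix(net: Network) -> tuple[Matrix, dict[str, int], dict[str, int]]:
    """S with rows = internal metabolites, columns = reactions.

    Returns ``(S, met_index, rxn_index)``; external metabolites have no
    row (they are boundary species freely exchanged with the
    environment).
    """
    mets = net.internal_metabolites
    met_index = {m: i for i, m in enumerate(mets)}
    rxn_index = {r.id: j for j, r in enumerate(net.reactions)}
    S = [[Fraction(0)] * len(net.reactions) for _ in mets]
    for j, rxn in enumerate(net.reactions):
        for met, coef in rxn.stoich.items():
            i = met_index.get(met)
            if i is not None:
                S[i][j] = coef
    return S, met_index, rxn_index


# ---------------------------------------------------------------------------
# TSV I/O


def load_metabolites_tsv(path: str | Path) -> dict[str, Metabolite]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "name", "carbons", "nitrogens", "external"}
    if not required <= set(df.columns):
        raise ValueError(f"metabolite TSV missing columns {sorted(required - set(df.columns))}")
    mets: dict[str, Metabolite] = {}
    for row in df.itertuples(index=False):
        if row.id in mets:
            raise ValueError(f"duplicate metabolite id {row.id!r}")
        mets[row.id] = Metabolite(
            id=row.id,
            name=row.name,
            carbons=int(row.carbons),
            nitrogens=int(row.nitrogens or 0),
            external=str(row.external).strip().lower() in ("1", "true", "yes"),
        )
    return mets


def load_reactions_tsv(path: str | Path) -> list[Reaction]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"id", "equation", "reversible"} <= set(df.columns):
        raise ValueError("reaction TSV needs columns id, equation, reversible")
    out = []
    for row in df.itertuples(index=False):
        cof = {
            k: Fraction(getattr(row, k))
            for k in COFACTORS
            if k in df.columns and getattr(row, k).strip() not in ("", "0")
        }
        out.append(
            parse_reaction(
                row.equation,
                id=row.id,
                reversible=str(row.reversible).strip().lower() in ("1", "true", "yes"),
                cofactors=cof,
            )
        )
    return out


def write_reactions_tsv(reactions: Iterable[Reaction], path: str | Path) -> None:
    rows = []
    for r in reactions:
        rows.append(
            {
                "id": r.id,
                "equation": serialize_reaction(r),
                "reversible": int(r.reversible),
                **{k: str(r.cofactors.get(k, Fraction(0))) for k in COFACTORS},
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_network(metabolites_tsv: str | Path, reactions_tsv: str | Path, name: str = "") -> Network:
    mets = load_metabolites_tsv(metabolites_tsv)
    rxns = load_reactions_tsv(reactions_tsv)
    used = set().union(*(r.species() for r in rxns)) if rxns else set()
    return Network(
        name=name or str(reactions_tsv),
        metabolites={m: mets[m] for m in mets if m in used},
        reactions=rxns,
    )
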