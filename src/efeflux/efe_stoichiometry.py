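"""The dual-circuit EFE reaction scheme.

The ethylene-forming enzyme (EFE) of *Pseudomonas savastanoi* pv.
*phaseolicola* (the "Kudzu" strain enzyme) is a 2-oxoglutarate/Fe(II)
oxygenase proposed to run two catalytic cycles in a fixed ratio:

* main cycle (runs twice):  AKG + O2 -> 2 CO2 + ... per cycle one AKG is
  fully oxidised, ``AKG + O2 -> ethylene + 3 CO2``, with L-arginine bound
  as an activator but not consumed;
* sub-cycle (runs once):  ``AKG + arginine + O2 -> succinate + CO2 +
  guanidine + P5C`` -- the canonical 2OG-oxygenase chemistry, with
  arginine cleaved to guanidine and L-delta1-pyrroline-5-carboxylate.

At the canonical 2:1 main:sub ratio the composite is

    3 AKG + 3 O2 + arginine -> 2 ethylene + succinate + 7 CO2 + guanidine + P5C

i.e. a 3:1 AKG:arginine substrate ratio and a 2:1:1
ethylene:succinate:P5C product ratio.  The per-cycle O2 allocation (one
O2 each) is an assumption: only the total of three O2 per composite is
experimentally constrained.  This scheme is encoded as proposed in the
literature; it is itself still debated and nothing here should be read
as mechanistic proof.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources

from .reaction_model import Network, Reaction, load_metabolites_tsv, parse_reaction

MAIN_EQUATION = "akg + o2 -> ethylene + 3 co2"
SUB_EQUATION = "akg + arginine + o2 -> succinate + co2 + guanidine + p5c"


class MissingSpeciesError(KeyError):
    """A ratio is undefined because the composite lacks a species."""


def _default_main() -> Reaction:
    return parse_reaction(MAIN_EQUATION, id="efe_main")


def _default_sub() -> Reaction:
    return parse_reaction(SUB_EQUATION, id="efe_sub")


def efe_metabolites() -> dict:
    """Registry of the EFE reaction species (with C/N atom counts)."""
    path = resources.files("efeflux.data") / "efe_metabolites.tsv"
    return load_metabolites_tsv(path)


def efe_network(reactions: list[Reaction]) -> Network:
    return Network(name="efe", metabolites=efe_metabolites(), reactions=reactions)


@dataclass(frozen=True)
class DualCircuitSpec:
    main_reaction: Reaction = field(default_factory=_default_main)
    sub_reaction: Reaction = field(default_factory=_default_sub)
    main_per_sub: Fraction = Fraction(2)

    def __post_init__(self) -> None:
        if self.main_per_sub <= 0:
            raise ValueError("main_per_sub must be positive")
        if self.main_reaction.stoich.get("akg") != -1 or self.main_reaction.stoich.get("ethylene") != 1:
            raise ValueError("main cycle must consume exactly 1 AKG and produce exactly 1 ethylene")
        if self.sub_reaction.stoich.get("akg") != -1 or self.sub_reaction.stoich.get("arginine") != -1:
            raise ValueError("sub-cycle must consume exactly 1 AKG and 1 arginine")


def combine_circuits(spec: DualCircuitSpec | None = None, n_sub: Fraction = Fraction(1)) -> Reaction:
    """Composite reaction of ``main_per_sub * n_sub`` main cycles and ``n_sub`` sub-cycles."""
    spec = spec or DualCircuitSpec()
    n_sub = Fraction(n_sub)
    if n_sub <= 0:
        raise ValueError("n_sub must be positive")
    n_main = spec.main_per_sub * n_sub
    stoich: dict[str, Fraction] = {}
    cof: dict[str, Fraction] = {}
    for rxn, mult in ((spec.main_reaction, n_main), (spec.sub_reaction, n_sub)):
        for met, coef in rxn.stoich.items():
            stoich[met] = stoich.get(met, Fraction(0)) + mult * coef
        for k, v in rxn.cofactors.items():
            cof[k] = cof.get(k, Fraction(0)) + mult * v
    return Reaction(id="efe_composite", stoich=stoich, reversible=False, cofactors=cof)


def circuit_ratios(composite: Reaction) -> dict[str, Fraction]:
    """Substrate/product ratios of the composite (absolute coefficients)."""
    out: dict[str, Fraction] = {}
    for key, num, den in (
        ("akg_per_arginine", "akg", "arginine"),
        ("ethylene_per_succinate", "ethylene", "succinate"),
        ("ethylene_per_p5c", "ethylene", "p5c"),
    ):
        for met in (num, den):
            if met not in composite.stoich:
                raise MissingSpeciesError(
                    f"ratio {key!r} undefined: composite lacks species {met!r}"
                )
        out[key] = abs(composite.stoich[num]) / abs(composite.stoich[den])
    return out
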