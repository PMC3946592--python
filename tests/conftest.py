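import sys

from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracle.py importable

from efeflux.reaction_model import Metabolite, Network, parse_reaction


@pytest.fixture
def chain_network() -> Network:
    """A_ext -> B -> C_ext: single pathway, one expected mode."""
    mets = {
        "A": Metabolite("A", external=True, carbons=1),
        "B": Metabolite("B", carbons=1),
        "C": Metabolite("C", external=True, carbons=1),
    }
    rxns = [parse_reaction("A -> B", id="r1"), parse_reaction("B -> C", id="r2")]
    return Network("chain", mets, rxns)


@pytest.fixture
def diamond_network() -> Network:
    """Two parallel routes from A_ext to E_ext: exactly two modes."""
    mets = {m: Metabolite(m, external=m in "AE", carbons=1) for m in "ABCDE"}
    rxns = [
        parse_reaction("A -> B", id="in"),
        parse_reaction("B -> C", id="up"),
        parse_reaction("B -> D", id="down"),
        parse_reaction("C -> E", id="up_out"),
        parse_reaction("D -> E", id="down_out"),
    ]
    return Network("diamond", mets, rxns)
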