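"""Independent brute-force EFM oracle used by the test suite.

Enumerates every support subset, keeps those whose stoichiometric
submatrix has a one-dimensional nullspace spanned by a fully nonzero,
sign-feasible vector.  That is the definition of an elementary mode
unrolled literally, with none of the tableau machinery of the
implementation under test.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

from efeflux._linalg import nullspace
from efeflux.reaction_model import Network, stoichiometric_matrix


def _normal_form(v: list[Fraction], irreversible: list[bool]) -> tuple[Fraction, ...] | None:
    support = [i for i, x in enumerate(v) if x != 0]
    if not support:
        return None
    denom = math.lcm(*(x.denominator for x in v))
    ints = [int(x * denom) for x in v]
    g = math.gcd(*ints)
    ints = [x // g for x in ints]
    feasible_fwd = all(ints[i] > 0 or not irreversible[i] for i in support)
    feasible_bwd = all(ints[i] < 0 or not irreversible[i] for i in support)
    if feasible_fwd:
        pass
    elif feasible_bwd:
        ints = [-x for x in ints]
    else:
        return None
    if not any(irreversible[i] for i in support) and ints[support[0]] < 0:
        ints = [-x for x in ints]
    return tuple(Fraction(x) for x in ints)


def brute_force_efms(net: Network) -> set[tuple[Fraction, ...]]:
    """All EFMs as normalized flux tuples (coprime integers)."""
    S, _, _ = stoichiometric_matrix(net)
    n = len(net.reactions)
    irreversible = [not r.reversible for r in net.reactions]
    found: set[tuple[Fraction, ...]] = set()
    for size in range(1, n + 1):
        for sel in combinations(range(n), size):
            sub = [[row[j] for j in sel] for row in S]
            basis = nullspace(sub, n_cols=size)
            if len(basis) != 1:
                continue
            vec = basis[0]
            if any(x == 0 for x in vec):
                continue  # true support is smaller; found at its own size
            full = [Fraction(0)] * n
            for k, j in enumerate(sel):
                full[j] = vec[k]
            norm = _normal_form(full, irreversible)
            if norm is not None:
                found.add(norm)
    return found
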