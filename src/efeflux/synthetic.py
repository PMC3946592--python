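"""Deterministic synthetic fixtures: networks with known mode sets and
alignments with planted conserved columns and iron triads.

Every generator is driven by an explicit 64-bit linear congruential
generator (Knuth MMIX constants: a = 6364136223846793005,
c = 1442695040888963407, mod 2**64) so that a given seed + config is
byte-identical across platforms and languages; no platform RNG is used.

The generated objects are test harnesses, not biology: network
topologies are layered source->paths->sink graphs or small random
carbon-balanced tangles, and alignments use a uniform substitution model
with no indels.  The alignment background alphabet excludes H, D and E
so that the planted triad is provably the only triad present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .conservation import Alignment
from .reaction_model import Metabolite, Network, Reaction

_LCG_A = 6364136223846793005
_LCG_C = 1442695040888963407
_LCG_MOD = 2**64

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: background alphabet: 20 canonical minus the triad classes {H, D, E}
BACKGROUND_ALPHABET = "".join(c for c in AMINO_ACIDS if c not in "HDE")


class GeneratorError(RuntimeError):
    """Rejection-sampling limit exceeded."""


class LCG:
    """Minimal 64-bit LCG; top 32 bits are used for variates."""

    def __init__(self, seed: int):
        self.state = (seed * 2862933555777941757 + 3037000493) % _LCG_MOD

    def next_u32(self) -> int:
        self.state = (_LCG_A * self.state + _LCG_C) % _LCG_MOD
        return self.state >> 32

    def randint(self, lo: int, hi: int) -> int:
        """Uniform integer in [lo, hi]."""
        return lo + self.next_u32() % (hi - lo + 1)

    def random(self) -> float:
        return self.next_u32() / 2**32

    def choice(self, seq):
        return seq[self.randint(0, len(seq) - 1)]

    def sample(self, seq, k: int) -> list:
        pool = list(seq)
        out = []
        for _ in range(k):
            out.append(pool.pop(self.randint(0, len(pool) - 1)))
        return out


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    # network fixtures
    n_parallel_paths: int = 2
    path_length: int = 2
    shared_intermediate: bool = False
    n_reactions: int = 6
    n_internal: int = 3
    # alignment fixtures
    n_seqs: int = 8
    length: int = 350
    n_conserved: int = 17
    triad_positions: tuple[int, int, int] | None = (189, 191, 268)
    noise: float = 0.2


def _frac(x: int) -> Fraction:
    return Fraction(x)


def gen_network_known_modes(cfg: GeneratorConfig) -> tuple[Network, list[frozenset[str]]]:
    """Source -> k linear paths -> sink network with a known EFM set.

    With disjoint paths the EFMs are exactly the k paths.  With
    ``shared_intermediate`` every path is routed through one common
    middle metabolite, so any front half may pair with any back half:
    k*k expected modes.  The expected supports are returned alongside.
    """
    k, L = cfg.n_parallel_paths, cfg.path_length
    if k < 1 or L < 1:
        raise GeneratorError("need n_parallel_paths >= 1 and path_length >= 1")
    mets: dict[str, Metabolite] = {
        "src": Metabolite("src", external=True, carbons=1),
        "snk": Metabolite("snk", external=True, carbons=1),
    }
    reactions: list[Reaction] = []
    expected: list[frozenset[str]] = []

    def chain(prefix: str, start: str, end: str, length: int) -> list[str]:
        ids = []
        prev = start
        for step in range(length):
            nxt = end if step == length - 1 else f"{prefix}_m{step}"
            if nxt not in mets:
                mets[nxt] = Metabolite(nxt, carbons=1)
            rid = f"{prefix}_r{step}"
            reactions.append(
                Reaction(rid, {prev: _frac(-1), nxt: _frac(1)})
            )
            ids.append(rid)
            prev = nxt
        return ids

    if cfg.shared_intermediate:
        mets["mid"] = Metabolite("mid", carbons=1)
        fronts = [chain(f"f{i}", "src", "mid", max(1, L // 2)) for i in range(k)]
        backs = [chain(f"b{i}", "mid", "snk", max(1, L - L // 2)) for i in range(k)]
        expected = [frozenset(f + b) for f in fronts for b in backs]
    else:
        for i in range(k):
            expected.append(frozenset(chain(f"p{i}", "src", "snk", L)))
    net = Network(name=f"paths_k{k}_L{L}", metabolites=mets, reactions=reactions)
    return net, expected


def gen_random_network(cfg: GeneratorConfig, max_tries: int = 500) -> Network:
    """Random small carbon-balanced network with at least one exchange.

    Metabolite carbon counts are drawn first; each reaction's product
    side is then searched so its carbon total matches the substrate
    side, so every draw balances by construction.  Draws for which no
    balancing product combination exists are rejected and retried.
    """
    rng = LCG(cfg.seed)
    if cfg.n_reactions > 8:
        raise GeneratorError("oracle-tier random networks are capped at 8 reactions")
    for _ in range(max_tries):
        net = _try_random_network(rng, cfg)
        if net is not None:
            return net
    raise GeneratorError(f"no balanced network found in {max_tries} tries (seed {cfg.seed})")


def _try_random_network(rng: LCG, cfg: GeneratorConfig) -> Network | None:
    n_int = max(2, cfg.n_internal)
    mets: dict[str, Metabolite] = {
        "sub_e": Metabolite("sub_e", external=True, carbons=rng.randint(2, 6)),
        "prod_e": Metabolite("prod_e", external=True, carbons=rng.randint(1, 4)),
    }
    for i in range(n_int):
        mets[f"m{i}"] = Metabolite(f"m{i}", carbons=rng.randint(1, 6))
    internal = [f"m{i}" for i in range(n_int)]

    def carbon(m: str) -> int:
        return mets[m].carbons

    reactions: list[Reaction] = []
    # guaranteed exchange backbone: uptake and secretion
    first, last = internal[0], internal[-1]
    r_up = _balance_pair(rng, mets, "sub_e", first)
    r_out = _balance_pair(rng, mets, last, "prod_e")
    if r_up is None or r_out is None:
        return None
    reactions.append(Reaction("upt", r_up))
    reactions.append(Reaction("sec", r_out))
    for ridx in range(cfg.n_reactions - 2):
        subs = rng.sample(internal, rng.randint(1, min(2, n_int)))
        prods_pool = [m for m in internal if m not in subs]
        if not prods_pool:
            return None
        lhs_coefs = {s: rng.randint(1, 2) for s in subs}
        lhs_c = sum(carbon(s) * c for s, c in lhs_coefs.items())
        rhs = _match_carbon(rng, prods_pool, lhs_c, carbon)
        if rhs is None:
            return None
        stoich = {s: Fraction(-c) for s, c in lhs_coefs.items()}
        for p, c in rhs.items():
            stoich[p] = stoich.get(p, Fraction(0)) + c
        if all(v == 0 for v in stoich.values()):
            return None
        reactions.append(
            Reaction(f"r{ridx}", stoich, reversible=rng.random() < 0.3)
        )
    return Network(name=f"rand_{cfg.seed}", metabolites=mets, reactions=reactions)


def _balance_pair(rng: LCG, mets: dict, src: str, dst: str) -> dict | None:
    """src a -> dst b with a*C(src) == b*C(dst), small coefficients."""
    cs, cd = mets[src].carbons, mets[dst].carbons
    for a in range(1, 4):
        for b in range(1, 4):
            if a * cs == b * cd:
                return {src: Fraction(-a), dst: Fraction(b)}
    return None


def _match_carbon(rng: LCG, pool: list[str], target: int, carbon) -> dict | None:
    """1-2 products with small coefficients whose carbons sum to target."""
    options = []
    for p in pool:
        for c in range(1, 4):
            if c * carbon(p) == target:
                options.append({p: Fraction(c)})
    for i, p in enumerate(pool):
        for q in pool[i + 1:]:
            for cp in range(1, 3):
                for cq in range(1, 3):
                    if cp * carbon(p) + cq * carbon(q) == target:
                        options.append({p: Fraction(cp), q: Fraction(cq)})
    return rng.choice(options) if options else None


def gen_alignment(cfg: GeneratorConfig, ref_id: str = "ref") -> Alignment:
    """Alignment with planted conserved columns and (optionally) a triad.

    Conserved columns (including the triad, if requested) are identical
    across rows; every other column is substituted per-row at the noise
    rate and re-rolled until it is not accidentally 100% conserved (for
    noise > 0).  Background residues avoid H/D/E entirely, so the
    planted triad is the only His-x-Asp/Glu...His arrangement present.
    """
    rng = LCG(cfg.seed)
    n, L = cfg.n_seqs, cfg.length
    if n < 1 or L < 1:
        raise GeneratorError("need n_seqs >= 1 and length >= 1")
    planted: dict[int, str] = {}
    if cfg.triad_positions is not None:
        h1, ac, h2 = cfg.triad_positions
        if not (h1 < ac < h2) or ac != h1 + 2 or h2 > L:
            raise GeneratorError(f"inconsistent triad positions {cfg.triad_positions}")
        planted = {h1: "H", ac: rng.choice("DE"), h2: "H"}
    free = [c for c in range(1, L + 1) if c not in planted]
    n_extra = cfg.n_conserved - len(planted)
    if n_extra < 0 or n_extra > len(free):
        raise GeneratorError("n_conserved incompatible with length/triad")
    conserved_cols = dict(planted)
    for col in sorted(rng.sample(free, n_extra)):
        conserved_cols[col] = rng.choice(BACKGROUND_ALPHABET)

    columns: list[str] = []
    for col in range(1, L + 1):
        if col in conserved_cols:
            columns.append(conserved_cols[col] * n)
            continue
        for _ in range(200):
            base = rng.choice(BACKGROUND_ALPHABET)
            rowres = []
            for _ in range(n):
                if cfg.noise > 0 and rng.random() < cfg.noise:
                    rowres.append(rng.choice([c for c in BACKGROUND_ALPHABET if c != base]))
                else:
                    rowres.append(base)
            if cfg.noise == 0 or n == 1 or len(set(rowres)) > 1:
                columns.append("".join(rowres))
                break
        else:
            raise GeneratorError("could not de-conserve a noisy column")

    rows = ["".join(columns[c][i] for c in range(L)) for i in range(n)]
    ids = tuple([ref_id] + [f"seq{i}" for i in range(1, n)])
    return Alignment(ids=ids, rows=tuple(rows))
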