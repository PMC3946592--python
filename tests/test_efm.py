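from fractions import Fraction

import pytest

from efeflux.efm import (
    FluxMode,
    NotSteadyStateError,
    UndefinedYieldError,
    enumerate_efms,
    is_elementary,
    mode_yield,
)
from efeflux.reaction_model import Metabolite, Network, parse_reaction
from efeflux.scenarios import ETHYLENE, build_scenario, scenario_summary
from efeflux.synthetic import GeneratorConfig, gen_network_known_modes, gen_random_network
from oracle import brute_force_efms


class TestEnumerateEfms:
    def test_single_chain_single_mode(self, chain_network):
        modes = enumerate_efms(chain_network)
        assert len(modes) == 1
        assert modes[0].fluxes == (Fraction(1), Fraction(1))

    def test_diamond_has_two_modes(self, diamond_network):
        modes = enumerate_efms(diamond_network)
        assert len(modes) == 2
        assert {m.support for m in modes} == {
            frozenset({"in", "up", "up_out"}),
            frozenset({"in", "down", "down_out"}),
        }

    def test_empty_network(self):
        assert enumerate_efms(Network("empty", {}, [])) == []

    def test_pure_internal_cycle_warns(self):
        mets = {m: Metabolite(m, carbons=1) for m in "ab"}
        net = Network(
            "cycle",
            mets,
            [parse_reaction("a -> b", id="fwd"), parse_reaction("b -> a", id="bwd")],
        )
        with pytest.warns(UserWarning, match="internal cycles"):
            modes = enumerate_efms(net)
        assert len(modes) == 1 and modes[0].support == {"fwd", "bwd"}

    def test_reversible_split_leaves_no_two_cycle(self, chain_network):
        rev = Network(
            "rev",
            chain_network.metabolites,
            [parse_reaction("A <-> B", id="r1"), parse_reaction("B -> C", id="r2")],
        )
        modes = enumerate_efms(rev)
        assert len(modes) == 1  # the forward/backward artefact must not appear

    def test_deterministic_support_ordering(self, diamond_network):
        first = [m.support for m in enumerate_efms(diamond_network)]
        again = [m.support for m in enumerate_efms(diamond_network)]
        assert first == again

    def test_scenario_b_contains_third_yield_mode(self):
        """The glucose network has an EFE-active mode with yield exactly 1/3."""
        net = build_scenario("B")
        modes = [m for m in enumerate_efms(net) if m.flux("efe") > 0]
        assert modes
        assert {mode_yield(m, net, ["glc_e"], ETHYLENE) for m in modes} == {Fraction(1, 3)}

    def test_matches_known_mode_constructions(self):
        for k, L, shared in [(1, 3, False), (3, 2, False), (2, 4, True)]:
            net, expected = gen_network_known_modes(
                GeneratorConfig(n_parallel_paths=k, path_length=L, shared_intermediate=shared)
            )
            assert {m.support for m in enumerate_efms(net)} == set(expected)


class TestOracleEquivalence:
    @pytest.mark.filterwarnings("ignore:network .* has only internal cycles")
    @pytest.mark.parametrize("seed", range(12))
    def test_random_networks_match_brute_force(self, seed):
        """Tableau enumeration equals literal subset-by-subset enumeration."""
        net = gen_random_network(GeneratorConfig(seed=seed, n_reactions=6, n_internal=3))
        ours = {m.fluxes for m in enumerate_efms(net)}
        assert ours == brute_force_efms(net)

    @pytest.mark.filterwarnings("ignore:network .* has only internal cycles")
    def test_no_support_containment(self):
        for seed in range(8):
            net = gen_random_network(GeneratorConfig(seed=seed, n_reactions=7, n_internal=3))
            supports = [m.support for m in enumerate_efms(net)]
            for i, a in enumerate(supports):
                for b in supports[i + 1:]:
                    assert not (a < b or b < a)

    @pytest.mark.filterwarnings("ignore:network .* has only internal cycles")
    def test_conic_combinations_stay_at_steady_state(self):
        from efeflux._linalg import matvec
        from efeflux.reaction_model import stoichiometric_matrix
        from efeflux.synthetic import LCG

        rng = LCG(42)
        for seed in range(5):
            net = gen_random_network(GeneratorConfig(seed=seed))
            modes = enumerate_efms(net)
            if not modes:
                continue
            S, _, _ = stoichiometric_matrix(net)
            weights = [Fraction(rng.randint(0, 5)) for _ in modes]
            combo = [
                sum((w * m.fluxes[j] for w, m in zip(weights, modes)), Fraction(0))
                for j in range(len(net.reactions))
            ]
            assert all(x == 0 for x in matvec(S, combo))


class TestIsElementary:
    def test_each_enumerated_mode_is_elementary(self, diamond_network):
        for m in enumerate_efms(diamond_network):
            assert is_elementary(m.fluxes, diamond_network)

    def test_sum_of_diamond_modes_is_not(self, diamond_network):
        m1, m2 = enumerate_efms(diamond_network)
        total = tuple(a + b for a, b in zip(m1.fluxes, m2.fluxes))
        assert not is_elementary(total, diamond_network)

    def test_zero_vector_not_elementary(self, diamond_network):
        assert not is_elementary([0] * 5, diamond_network)

    def test_non_steady_state_rejected(self, diamond_network):
        with pytest.raises(NotSteadyStateError):
            is_elementary([1, 0, 0, 0, 0], diamond_network)


class TestModeYield:
    def test_zero_product_flux_gives_zero(self, chain_network):
        mode = enumerate_efms(chain_network)[0]
        # score against a product the mode never makes
        net = chain_network
        net.metabolites["D"] = Metabolite("D", external=True, carbons=2)
        assert mode_yield(mode, net, ["A"], "D") == 0

    def test_no_substrate_consumption_is_undefined(self, chain_network):
        mode = enumerate_efms(chain_network)[0]
        with pytest.raises(UndefinedYieldError):
            mode_yield(mode, chain_network, ["C"], "C")

    def test_carbon_conservation_in_every_scenario_mode(self):
        """Carbon in equals carbon out, exactly, for every enumerated mode."""
        for sid in "ABCDEF":
            net = build_scenario(sid)
            for mode in enumerate_efms(net):
                total = Fraction(0)
                for species, met in net.metabolites.items():
                    if not met.external:
                        continue
                    for rxn, v in zip(net.reactions, mode.fluxes):
                        total += v * rxn.stoich.get(species, Fraction(0)) * met.carbons
                assert total == 0

    def test_xylose_yield_equals_glucose_yield(self):
        assert (
            scenario_summary("C").max_carbon_yield
            == scenario_summary("B").max_carbon_yield
        )
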