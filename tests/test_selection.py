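"""Community selection: optimality, enumeration, key species, verdicts."""

import pytest

from comscope import (
    CompoundSet,
    NetworkCollection,
    InfeasibleObjective,
    community_scope,
    enumerate_minimal_communities,
    key_species,
    key_species_from_enumeration,
    minimal_community,
    random_collection,
    verify_community,
)
from conftest import chain_network, exhaustive_communities, roles_from_enumeration


def targets_of(*ids):
    return CompoundSet("targets", frozenset(ids))


def seeds_of(*ids):
    return CompoundSet("seeds", frozenset(ids))


@pytest.fixture
def chain3():
    """G1: A→B, G2: B→C, G3: A→Z — target C needs the G1+G2 relay."""
    return NetworkCollection(
        [
            chain_network("G1", ("A", "B")),
            chain_network("G2", ("B", "C")),
            chain_network("G3", ("A", "Z")),
        ]
    )


class TestMinimalCommunity:
    def test_relay_pair_selected(self, chain3):
        res = minimal_community(chain3, seeds_of("A"), targets_of("C"))
        assert res.min_size == 2
        assert res.community == ("G1", "G2")

    def test_single_sufficient_network(self):
        coll = NetworkCollection([chain_network("solo", ("A", "B"))])
        res = minimal_community(coll, seeds_of("A"), targets_of("B"))
        assert res.min_size == 1 and res.community == ("solo",)

    def test_demo_optimum_is_lexicographically_smallest(self, demo):
        coll, seeds, targets = demo
        res = minimal_community(coll, seeds, targets)
        assert res.min_size == 3
        assert res.community == ("A1", "B1", "Y")

    def test_infeasible_target_dropped_with_warning(self, chain3):
        with pytest.warns(UserWarning, match="dropped"):
            res = minimal_community(
                chain3, seeds_of("A"), targets_of("C", "NOPE")
            )
        assert res.targets_unproducible == {"NOPE"}
        assert res.targets_feasible == {"C"}
        assert res.targets_requested == {"C", "NOPE"}

    def test_all_targets_infeasible_is_an_error(self, chain3):
        with pytest.raises(InfeasibleObjective, match="no producible target"):
            minimal_community(chain3, seeds_of("A"), targets_of("NOPE"))

    def test_solvers_agree_and_are_deterministic(self, demo):
        coll, seeds, targets = demo
        a = minimal_community(coll, seeds, targets, solver="bnb")
        b = minimal_community(coll, seeds, targets, solver="bruteforce")
        c = minimal_community(coll, seeds, targets, solver="bnb")
        assert a == b == c

    def test_mincom_json_contract(self, demo):
        coll, seeds, targets = demo
        d = minimal_community(coll, seeds, targets).to_dict()
        assert d["min_size"] == 3
        assert d["bacteria"] == ["A1", "B1", "Y"]
        assert d["still_unprod"] == []


class TestEnumeration:
    def test_demo_has_exactly_four_optima(self, demo):
        coll, seeds, targets = demo
        enum = enumerate_minimal_communities(coll, seeds, targets)
        assert enum.complete
        assert enum.communities == (
            ("A1", "B1", "Y"),
            ("A1", "B2", "Y"),
            ("A2", "B1", "Y"),
            ("A2", "B2", "Y"),
        )

    def test_cap_truncates_with_flag(self, demo):
        coll, seeds, targets = demo
        with pytest.warns(UserWarning, match="truncated"):
            enum = enumerate_minimal_communities(coll, seeds, targets, cap=2)
        assert len(enum) == 2 and not enum.complete

    def test_relay_chain_unique_optimum(self, chain3):
        enum = enumerate_minimal_communities(chain3, seeds_of("A"), targets_of("C"))
        assert enum.communities == (("G1", "G2"),)

    def test_every_enumerated_community_is_minimal(self, demo):
        coll, seeds, targets = demo
        enum = enumerate_minimal_communities(coll, seeds, targets)
        for members in enum.communities:
            verdict = verify_community(coll, members, seeds, targets)
            assert verdict.feasible and verdict.minimal


class TestKeySpecies:
    def test_demo_roles(self, demo):
        coll, seeds, targets = demo
        ks = key_species(coll, seeds, targets)
        assert ks.key_species == {"Y", "A1", "A2", "B1", "B2"}
        assert ks.essential_symbionts == {"Y"}
        assert ks.alternative_symbionts == {"A1", "A2", "B1", "B2"}

    def test_unique_optimum_means_all_essential(self, chain3):
        ks = key_species(chain3, seeds_of("A"), targets_of("C"))
        assert ks.key_species == ks.essential_symbionts == {"G1", "G2"}
        assert ks.alternative_symbionts == frozenset()

    def test_two_interchangeable_singletons(self):
        coll = NetworkCollection(
            [chain_network("a", ("A", "B")), chain_network("b", ("A", "B"))]
        )
        ks = key_species(coll, seeds_of("A"), targets_of("B"))
        assert ks.key_species == {"a", "b"}
        assert ks.essential_symbionts == frozenset()
        assert ks.alternative_symbionts == {"a", "b"}

    def test_projection_equals_enumeration_route(self, demo):
        coll, seeds, targets = demo
        proj = key_species(coll, seeds, targets, strategy="projection")
        enum = key_species(coll, seeds, targets, strategy="enumeration")
        assert proj == enum


class TestVerifyCommunity:
    def test_optimum_plus_decoy_not_minimal(self, demo):
        coll, seeds, targets = demo
        v = verify_community(coll, ["A1", "B1", "Y", "D1"], seeds, targets)
        assert v.feasible and not v.minimal

    def test_optimum_minus_essential_infeasible(self, demo):
        coll, seeds, targets = demo
        v = verify_community(coll, ["A1", "B1"], seeds, targets)
        assert not v.feasible

    def test_unknown_member_raises(self, demo):
        coll, seeds, targets = demo
        with pytest.raises(KeyError):
            verify_community(coll, ["Y", "ghost"], seeds, targets)


class TestBruteForceEquivalence:
    """Solver vs the powerset oracle on random instances."""

    @pytest.mark.parametrize("rng_seed", range(12))
    def test_random_collections_match_oracle(self, rng_seed):
        n_orgs = 4 + rng_seed % 5
        coll = random_collection(n_orgs, 10, 4, rng_seed=rng_seed)
        seeds = seeds_of("M1", "M2")
        com = community_scope(coll, seeds)
        if not com.produced:
            pytest.skip("degenerate draw: nothing producible")
        # pick the "hardest" targets: producible by the fewest organisms
        targets = targets_of(*sorted(com.produced)[:3])
        oracle = exhaustive_communities(coll, seeds, set(targets.ids))
        assert oracle is not None
        exp_size, exp_comms = oracle
        res = minimal_community(coll, seeds, targets)
        assert res.min_size == exp_size
        assert res.community == exp_comms[0]
        enum = enumerate_minimal_communities(coll, seeds, targets)
        assert list(enum.communities) == exp_comms
        key, ess, alt = roles_from_enumeration(exp_comms)
        ks = key_species(coll, seeds, targets)
        assert ks.key_species == key
        assert ks.essential_symbionts == ess
        assert ks.alternative_symbionts == alt

    def test_size_coherence_on_demo(self, demo):
        coll, seeds, targets = demo
        res = minimal_community(coll, seeds, targets)
        ks = key_species(coll, seeds, targets)
        assert len(ks.essential_symbionts) <= res.min_size <= len(ks.key_species)


def test_key_species_from_truncated_enumeration_still_partitions(demo):
    coll, seeds, targets = demo
    with pytest.warns(UserWarning):
        enum = enumerate_minimal_communities(coll, seeds, targets, cap=3)
    ks = key_species_from_enumeration(enum)
    assert ks.essential_symbionts | ks.alternative_symbionts == ks.key_species
    assert not ks.essential_symbionts & ks.alternative_symbionts
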