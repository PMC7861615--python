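"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own machinery:

* :func:`closure_oracle` computes producibility by repeatedly firing
  any activatable reaction, scanning in an arbitrary (shufflable)
  order, until nothing changes — a direct, quadratic transcription of
  the expansion fixed point;
* :func:`exhaustive_communities` scans the full powerset of the
  collection, using :func:`closure_oracle` on concatenated reaction
  lists, to find every minimum-size feasible community.
"""

from __future__ import annotations

from itertools import chain, combinations

import pytest

from comscope import (
    CompoundSet,
    MetabolicNetwork,
    NetworkCollection,
    Reaction,
    demo_community,
)


def closure_oracle(
    reactions: list[tuple[frozenset[str], frozenset[str]]],
    seeds: set[str],
    order: list[int] | None = None,
) -> tuple[set[str], set[str]]:
    """Naive fire-until-fixpoint closure; returns (reachable, produced)."""
    reached = set(seeds)
    produced: set[str] = set()
    idx = list(range(len(reactions))) if order is None else list(order)
    fired: set[int] = set()
    changed = True
    while changed:
        changed = False
        for i in idx:
            if i in fired:
                continue
            lhs, rhs = reactions[i]
            if lhs <= reached:
                fired.add(i)
                produced |= rhs
                if not rhs <= reached:
                    reached |= rhs
                changed = True
    return reached, produced


def as_pairs(net: MetabolicNetwork) -> list[tuple[frozenset[str], frozenset[str]]]:
    return [(r.reactants, r.products) for r in net]


def exhaustive_communities(
    coll: NetworkCollection, seeds: CompoundSet, targets: set[str]
) -> tuple[int, list[tuple[str, ...]]] | None:
    """All minimum-size communities covering *targets*, by powerset scan."""
    orgs = coll.org_ids
    best: list[tuple[str, ...]] = []
    best_size: int | None = None
    subsets = chain.from_iterable(
        combinations(orgs, k) for k in range(1, len(orgs) + 1)
    )
    for sub in subsets:
        if best_size is not None and len(sub) > best_size:
            break
        pairs = [p for o in sub for p in as_pairs(coll[o])]
        _, produced = closure_oracle(pairs, set(seeds.ids))
        if targets <= produced:
            best_size = len(sub)
            best.append(tuple(sorted(sub)))
    if best_size is None:
        return None
    return best_size, sorted(best)


def roles_from_enumeration(
    communities: list[tuple[str, ...]],
) -> tuple[set[str], set[str], set[str]]:
    sets = [set(c) for c in communities]
    key = set().union(*sets)
    essential = set(sets[0]).intersection(*sets[1:])
    return key, essential, key - essential


def chain_network(org: str, *steps: tuple[str, str]) -> MetabolicNetwork:
    """Helper: one reaction per (substrate, product) pair."""
    return MetabolicNetwork(
        org,
        [
            Reaction(
                id=f"{org}_r{i}",
                reactants=frozenset({a}),
                products=frozenset({b}),
                genes=frozenset({f"{org}_g{i}"}),
            )
            for i, (a, b) in enumerate(steps)
        ],
    )


@pytest.fixture
def chain_toy() -> tuple[NetworkCollection, CompoundSet]:
    """Two-organism cross-feeding chain: G1 does A→B, G2 does B→C."""
    coll = NetworkCollection(
        [chain_network("G1", ("A", "B")), chain_network("G2", ("B", "C"))]
    )
    return coll, CompoundSet("seeds", frozenset({"A"}))


@pytest.fixture(scope="session")
def demo():
    """The packaged eight-organism worked example."""
    return demo_community()


@pytest.fixture
def demo_dir(tmp_path, demo):
    """The worked example written out as SBML files + seeds/targets."""
    from comscope import write_collection, write_compound_set

    coll, seeds, targets = demo
    net_dir = tmp_path / "networks"
    write_collection(coll, net_dir)
    write_compound_set(seeds, tmp_path / "seeds.sbml")
    write_compound_set(targets, tmp_path / "targets.sbml")
    return tmp_path
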