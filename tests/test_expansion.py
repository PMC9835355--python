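import random

import numpy as np
import pytest

from commscope.expansion import diff_scopes, expand, scope_to_frame

from conftest import make_universe
from oracles import naive_expansion_scope


def random_universe(rng: np.random.Generator, n_compounds=25, n_reactions=50):
    compounds = [f"C{i}" for i in range(n_compounds)]
    reactions = []
    for r in range(n_reactions):
        subs = list(rng.choice(compounds, size=int(rng.integers(1, 4)), replace=False))
        prods = list(rng.choice(compounds, size=int(rng.integers(1, 3)), replace=False))
        rev = bool(rng.random() < 0.25)
        reactions.append((f"R{r}", [f"e{r}"], subs, prods, rev))
    uni = make_universe(reactions, extra_compounds=compounds)
    seeds = set(rng.choice(compounds, size=int(rng.integers(1, 6)), replace=False))
    return uni, reactions, seeds


class TestExpand:
    def test_no_reactions_fixed_point_is_seed_set(self):
        uni = make_universe([], extra_compounds=["A", "B"])
        res = expand(uni, None, {"A"})
        assert res.scope == {"A"} and res.fired == frozenset() and res.trace == []

    def test_all_substrates_required(self):
        uni = make_universe([("R1", ["e1"], ["A", "B"], ["C"], False)])
        res = expand(uni, {"e1"}, {"A"})
        assert res.scope == {"A"} and res.fired == frozenset()

    def test_chain_fires_in_two_iterations(self):
        uni = make_universe([("R1", ["e1"], ["A", "B"], ["C"], False),
                             ("R2", ["e2"], ["C"], ["D"], False)])
        res = expand(uni, {"e1", "e2"}, {"A", "B"})
        assert res.scope == {"A", "B", "C", "D"}
        assert res.fired == {"R1", "R2"}
        assert len(res.trace) == 2

    def test_reverse_direction_fires_for_reversible_reactions(self):
        uni = make_universe([("R1", ["e1"], ["A"], ["B"], True)])
        res = expand(uni, {"e1"}, {"B"})
        assert res.scope == {"A", "B"}

    def test_unknown_seeds_dropped_with_warning(self, caplog):
        import logging
        uni = make_universe([("R1", ["e1"], ["A"], ["B"], False)])
        with caplog.at_level(logging.WARNING, logger="commscope.expansion"):
            res = expand(uni, {"e1"}, {"A", "Cxxx"})
        assert res.scope == {"A", "B"}
        assert any("seed" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(10))
    def test_scope_matches_naive_shuffled_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        uni, reactions, seeds = random_universe(rng)
        res = expand(uni, None, seeds)
        raw = [(rid, list(subs), list(prods), rev)
               for rid, _, subs, prods, rev in reactions]
        for shuffle_seed in range(10):
            scope, _ = naive_expansion_scope(raw, set(seeds),
                                             random.Random(shuffle_seed))
            assert scope == set(res.scope)

    def test_fixed_point_invariants(self, default_synth):
        _, universe, truth, _, _ = default_synth
        res = expand(universe, None, truth.treatment_seeds["SM"])
        assert set(truth.treatment_seeds["SM"]) <= res.scope
        for rid in res.fired:
            rxn = universe.reactions[rid]
            assert rxn.substrates <= res.scope or (
                rxn.reversible and rxn.products <= res.scope
            )
        for rid, rxn in universe.reactions.items():
            if rid in res.fired:
                continue
            assert not rxn.substrates <= res.scope
            if rxn.reversible:
                assert not rxn.products <= res.scope


class TestMonotonicityAndIdempotence:
    def test_monotone_in_seeds_and_enzymes(self):
        rng = np.random.default_rng(42)
        uni, _, seeds = random_universe(rng)
        ecs = sorted(uni.all_ecs)
        small, large = set(ecs[:20]), set(ecs)
        s_small = expand(uni, small, seeds).scope
        s_large = expand(uni, large, seeds).scope
        assert s_small <= s_large
        more_seeds = seeds | {"C0", "C1"}
        assert expand(uni, large, seeds).scope <= expand(uni, large, more_seeds).scope

    def test_expansion_is_idempotent_on_its_own_scope(self):
        rng = np.random.default_rng(8)
        uni, _, seeds = random_universe(rng)
        first = expand(uni, None, seeds)
        again = expand(uni, None, first.scope)
        assert again.scope == first.scope


class TestDiffScopes:
    def test_identical_scopes_have_no_unique_compounds(self):
        uni = make_universe([("R1", ["e1"], ["A"], ["B"], False)])
        a = expand(uni, None, {"A"})
        ua, ub, shared = diff_scopes(a, a)
        assert ua == ub == frozenset() and shared == a.scope

    def test_disjoint_seed_only_scopes_share_nothing(self):
        uni = make_universe([], extra_compounds=["A", "B"])
        a, b = expand(uni, None, {"A"}), expand(uni, None, {"B"})
        ua, ub, shared = diff_scopes(a, b)
        assert shared == frozenset() and ua == {"A"} and ub == {"B"}

    def test_private_chain_from_extra_seed(self):
        uni = make_universe([
            ("R1", ["e1"], ["A"], ["B"], False),
            ("R2", ["e2"], ["X"], ["Y"], False),
            ("R3", ["e3"], ["Y"], ["Z"], False),
            ("R4", ["e4"], ["Z"], ["W"], False),
        ])
        a = expand(uni, None, {"A", "X"})
        b = expand(uni, None, {"A"})
        ua, ub, shared = diff_scopes(a, b)
        assert ua == {"X", "Y", "Z", "W"} and len(ua) == 4 and ub == frozenset()
        # the three sets partition the union
        assert (ua | ub | shared) == (a.scope | b.scope)
        assert not (ua & shared) and not (ub & shared)


def test_scope_table_lists_iteration_added(toy_universe):
    res = expand(toy_universe, None, {"A", "B"})
    df = scope_to_frame(res).set_index("compound_id")
    assert df.loc["A", "iteration_added"] == 0
    assert df.loc["C", "iteration_added"] == 1
    assert df.loc["D", "iteration_added"] == 2
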