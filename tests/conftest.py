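import pytest

from commscope.pipeline import run_pipeline
from commscope.synth import SynthSpec, generate_counts, generate_universe
from commscope.universe import Compound, Reaction, ReactionUniverse


def make_universe(reactions, pathways=None, modules=None, extra_compounds=()):
    """Build a universe from (id, ecs, substrates, products, reversible) tuples."""
    rxns = {
        rid: Reaction(
            id=rid,
            ecs=frozenset(ecs),
            substrates=frozenset(subs),
            products=frozenset(prods),
            reversible=rev,
        )
        for rid, ecs, subs, prods, rev in reactions
    }
    cids = set(extra_compounds)
    for r in rxns.values():
        cids |= r.substrates | r.products
    return ReactionUniverse(
        compounds={c: Compound(id=c) for c in sorted(cids)},
        reactions=rxns,
        pathway_map={k: frozenset(v) for k, v in (pathways or {}).items()},
        module_map={k: frozenset(v) for k, v in (modules or {}).items()},
    )


@pytest.fixture
def toy_universe():
    """Two-reaction chain: R1: A+B->C (EC e1), R2: C->D reversible (EC e2)."""
    return make_universe(
        [
            ("R1", ["e1"], ["A", "B"], ["C"], False),
            ("R2", ["e2"], ["C"], ["D"], True),
        ]
    )


@pytest.fixture(scope="session")
def default_synth():
    """The default planted fixture: universe, truth, annotation, design."""
    spec = SynthSpec()
    universe, truth = generate_universe(spec)
    table, design = generate_counts(spec, universe, truth)
    return spec, universe, truth, table, design


@pytest.fixture(scope="session")
def pipeline_result(default_synth):
    _, universe, _, table, design = default_synth
    return run_pipeline(universe, table, design, treatment="SM", control="NTC")
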