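"""Directed metabolite graphs and SCC-based seed (environmental resource) prediction.

A community's enzyme repertoire induces a directed compound graph: every
reaction available to the enzyme set contributes an edge from each of
its substrates to each of its products (both directions for reversible
reactions).  Metabolites that the community cannot synthesize but whose
downstream chemistry it encodes appear as *sources* of this graph —
predicted environmental resources ("seeds").  Formally, after
contracting strongly connected components (Tarjan), the members of
condensation components with no incoming edges are the seed compounds;
each is weighted 1/|component| since only one member of a source cycle
need be externally supplied.

Treatment-specific sub-networks built from differentially abundant
enzymes alone are highly fragmented and therefore over-predict sources;
their raw seed list is intersected with the full meta-network's seeds to
obtain the environment proxy.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import pandas as pd

from .universe import ReactionUniverse

logger = logging.getLogger(__name__)


@dataclass
class SeedSet:
    """Predicted environmental resources with 1/|SCC| confidence weights."""

    treatment: str
    confidence: dict[str, float]  # compound id -> (0, 1]
    component: dict[str, int] = field(default_factory=dict)  # compound -> SCC id
    stage: str = "raw"  # "raw" | "intersected"

    @property
    def seeds(self) -> frozenset[str]:
        return frozenset(self.confidence)

    def filter_confidence(self, min_confidence: float) -> "SeedSet":
        """Drop seeds from large source components (confidence below cutoff)."""
        keep = {c: w for c, w in self.confidence.items() if w >= min_confidence}
        return SeedSet(self.treatment, keep,
                       {c: self.component[c] for c in keep if c in self.component},
                       self.stage)


def build_graph(universe: ReactionUniverse, ecs: Iterable[str] | None = None) -> nx.DiGraph:
    """Directed compound graph of the reactions available to an enzyme set.

    Each available reaction adds an edge substrate -> product for every
    (substrate, product) pair; reversible reactions also add the reverse
    edges.  Edges carry the contributing reaction ids and EC unions; a
    reaction with several qualifying ECs contributes each edge once.
    ``ecs=None`` uses every reaction in the universe.
    """
    query = None if ecs is None else frozenset(ecs)
    g = nx.DiGraph()
    g.graph["enzyme_set_size"] = -1 if query is None else len(query)
    for rxn in universe.reactions.values():
        if query is not None and not (rxn.ecs & query):
            continue
        pairs = [(s, p) for s in rxn.substrates for p in rxn.products]
        if rxn.reversible:
            pairs += [(p, s) for s in rxn.substrates for p in rxn.products]
        for s, p in pairs:
            if g.has_edge(s, p):
                g[s][p]["reactions"].add(rxn.id)
                g[s][p]["ecs"] |= rxn.ecs
            else:
                g.add_edge(s, p, reactions={rxn.id}, ecs=set(rxn.ecs))
    return g


def condensation_seeds(graph: nx.DiGraph, treatment: str = "") -> SeedSet:
    """Seed compounds = members of source SCCs of the condensation DAG.

    A self-loop-only isolated node is its own source component and is
    reported as a seed.  Confidence of each seed is 1/|its component|.
    """
    cond = nx.condensation(graph)
    assert nx.is_directed_acyclic_graph(cond)
    confidence: dict[str, float] = {}
    component: dict[str, int] = {}
    for comp_id in cond.nodes:
        if cond.in_degree(comp_id) == 0:
            members = cond.nodes[comp_id]["members"]
            for cid in members:
                confidence[cid] = 1.0 / len(members)
                component[cid] = comp_id
    return SeedSet(treatment=treatment, confidence=confidence,
                   component=component, stage="raw")


def intersect_seeds(sub: SeedSet, meta: SeedSet) -> SeedSet:
    """Environment proxy: sub-network seeds also predicted on the meta-network.

    Fragmented sub-networks yield artificial source metabolites; keeping
    only seeds present in both lists removes them.  Confidence values are
    taken from the sub-network prediction.
    """
    if sub.stage != "raw" or meta.stage != "raw":
        raise ValueError("intersect_seeds expects two raw-stage seed sets")
    shared = sub.seeds & meta.seeds
    if not shared:
        logger.warning(
            "seed intersection for %r is empty (sub %d, meta %d seeds)",
            sub.treatment, len(sub.seeds), len(meta.seeds),
        )
    return SeedSet(
        treatment=sub.treatment,
        confidence={c: sub.confidence[c] for c in shared},
        component={c: sub.component[c] for c in shared if c in sub.component},
        stage="intersected",
    )


def seeds_to_frame(ss: SeedSet) -> pd.DataFrame:
    rows = [
        {
            "compound_id": cid,
            "confidence": ss.confidence[cid],
            "component_id": ss.component.get(cid, -1),
            "stage": ss.stage,
            "treatment": ss.treatment,
        }
        for cid in sorted(ss.seeds)
    ]
    return pd.DataFrame(
        rows, columns=["compound_id", "confidence", "component_id", "stage", "treatment"]
    )


def read_seed_table(path: str | os.PathLike) -> SeedSet:
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str})
    stage = df["stage"].iloc[0] if len(df) else "raw"
    trt = str(df["treatment"].iloc[0]) if len(df) else ""
    return SeedSet(
        treatment=trt,
        confidence=dict(zip(df["compound_id"], df["confidence"])),
        component=dict(zip(df["compound_id"], df.get("component_id", -1))),
        stage=stage,
    )


def write_graphml(graph: nx.DiGraph, path: str | os.PathLike) -> None:
    """GraphML export (set-valued edge attributes flattened to strings)."""
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    for s, p, data in graph.edges(data=True):
        g.add_edge(
            s, p,
            reactions=";".join(sorted(data.get("reactions", ()))),
            ecs=";".join(sorted(data.get("ecs", ()))),
        )
    nx.write_graphml(g, path)


def write_edgelist(graph: nx.DiGraph, path: str | os.PathLike) -> None:
    rows = [
        {
            "source_compound": s,
            "target_compound": p,
            "reaction_id": ";".join(sorted(data.get("reactions", ()))),
            "ec": ";".join(sorted(data.get("ecs", ()))),
        }
        for s, p, data in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(
        rows, columns=["source_compound", "target_compound", "reaction_id", "ec"]
    ).to_csv(path, sep="\t", index=False)
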