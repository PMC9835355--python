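"""Network expansion: the metabolic scope of a seed set.

The expansion (scope) algorithm simulates community metabolic activity
qualitatively: starting from a set of externally available source
metabolites, it repeatedly scans the reaction bank for reactions whose
substrates are ALL already available, adds their products, and stops at
the fixed point where no further reaction can fire.  The resulting
compound set — the scope — is the least fixed point and is independent
of scan order; reversible reactions are checked independently in each
direction, and nothing is consumed (set semantics, no stoichiometry).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .universe import ReactionUniverse

logger = logging.getLogger(__name__)


@dataclass
class ExpansionResult:
    scope: frozenset[str]
    fired: frozenset[str]
    trace: list[tuple[int, tuple[str, ...], tuple[str, ...]]] = field(default_factory=list)
    seeds: frozenset[str] = frozenset()
    ecs: frozenset[str] | None = None

    def __eq__(self, other: object) -> bool:
        # the trace is diagnostic, not part of result identity
        if not isinstance(other, ExpansionResult):
            return NotImplemented
        return self.scope == other.scope and self.fired == other.fired


def expand(
    universe: ReactionUniverse,
    ecs: Iterable[str] | None,
    seeds: Iterable[str],
) -> ExpansionResult:
    """Least-fixed-point scope of ``seeds`` under the EC-available reactions.

    ``ecs=None`` makes every reaction available.  Seeds not present in
    the universe are dropped with a warning (treatment seed lists may
    reference compounds absent from a restricted bank).  A reaction
    fires once all substrates of one of its directions are in the scope;
    its products then join the scope for the next iteration.
    """
    query = None if ecs is None else frozenset(ecs)
    seeds = frozenset(seeds)
    unknown = seeds - universe.compounds.keys()
    if unknown:
        logger.warning("dropping %d seed(s) not in universe: %s",
                       len(unknown), sorted(unknown)[:5])
    scope = set(seeds - unknown)
    # (reaction id, forward?) direction pairs still eligible to fire
    pending: list[tuple[str, bool]] = []
    for rxn in universe.reactions.values():
        if query is not None and not (rxn.ecs & query):
            continue
        pending.append((rxn.id, True))
        if rxn.reversible:
            pending.append((rxn.id, False))
    fired: set[str] = set()
    trace: list[tuple[int, tuple[str, ...], tuple[str, ...]]] = []
    iteration = 0
    while True:
        iteration += 1
        new_rxns: list[str] = []
        new_cpds: set[str] = set()
        still: list[tuple[str, bool]] = []
        for rid, forward in pending:
            rxn = universe.reactions[rid]
            subs = rxn.substrates if forward else rxn.products
            prods = rxn.products if forward else rxn.substrates
            if subs <= scope:
                new_rxns.append(rid)
                new_cpds |= prods - scope
                fired.add(rid)
            else:
                still.append((rid, forward))
        if not new_rxns:
            break
        added = new_cpds - scope
        scope |= new_cpds
        trace.append((iteration, tuple(sorted(set(new_rxns))), tuple(sorted(added))))
        pending = still
    return ExpansionResult(
        scope=frozenset(scope),
        fired=frozenset(fired),
        trace=trace,
        seeds=frozenset(seeds - unknown),
        ecs=query,
    )


def diff_scopes(
    a: ExpansionResult, b: ExpansionResult
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Partition two scopes into (unique to a, unique to b, shared)."""
    return (
        frozenset(a.scope - b.scope),
        frozenset(b.scope - a.scope),
        frozenset(a.scope & b.scope),
    )


def scope_to_frame(result: ExpansionResult) -> pd.DataFrame:
    """Long-format scope table: compound, iteration added, producing reactions."""
    when: dict[str, int] = {c: 0 for c in result.seeds}
    via: dict[str, str] = {c: "" for c in result.seeds}
    for it, rxns, cpds in result.trace:
        for c in cpds:
            when.setdefault(c, it)
            via.setdefault(c, ";".join(rxns))
    rows = [
        {"compound_id": c, "iteration_added": when[c], "via_reaction": via[c]}
        for c in sorted(result.scope)
    ]
    return pd.DataFrame(rows, columns=["compound_id", "iteration_added", "via_reaction"])
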