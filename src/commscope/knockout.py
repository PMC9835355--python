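"""In-silico taxa knock-outs: scope loss when a group's enzymes are removed.

For each taxonomic group, the enzymes it dominates are deleted from the
community enzyme set and the expansion is recomputed with the same
environmental-resource seeds.  Compounds present in the reference scope
but absent from the truncated scope are the group's taxa-dependent
compounds.  Because feasibility only requires ONE catalysing EC to be
present, a reaction is effectively lost only when every EC it carries in
the enzyme set is dominated by the removed group — redundancy through
alternative catalysts or alternative biosynthetic routes yields an empty
dependent set, which is exactly the robustness the simulation probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .expansion import ExpansionResult, expand
from .universe import ReactionUniverse

COMBINED_GROUP = "__all__"


@dataclass
class KnockoutReport:
    taxon: str
    rank: str
    removed_ecs: frozenset[str]
    reference_scope_size: int
    truncated_scope_size: int
    dependent_compounds: frozenset[str]

    @property
    def reduction_fraction(self) -> float:
        if self.reference_scope_size == 0:
            return 0.0
        return len(self.dependent_compounds) / self.reference_scope_size


def knockout_group(
    universe: ReactionUniverse,
    ecs: Iterable[str],
    seeds: Iterable[str],
    dominated: Mapping[str, set[str]],
    group: str,
    *,
    rank: str = "",
    reference: ExpansionResult | None = None,
) -> KnockoutReport:
    """Remove one group's dominated enzymes and re-expand.

    ``reference`` (the full-enzyme-set expansion) may be passed in to
    avoid recomputation across iterations; it must have been produced
    from the same universe, enzyme set and seeds.
    """
    ecs = frozenset(ecs)
    seeds = frozenset(seeds)
    if reference is None:
        reference = expand(universe, ecs, seeds)
    removed = frozenset(dominated.get(group, set())) & ecs
    truncated = expand(universe, ecs - removed, seeds)
    dependent = reference.scope - truncated.scope
    assert truncated.scope <= reference.scope
    return KnockoutReport(
        taxon=group,
        rank=rank,
        removed_ecs=removed,
        reference_scope_size=len(reference.scope),
        truncated_scope_size=len(truncated.scope),
        dependent_compounds=frozenset(dependent),
    )


def knockout_all(
    universe: ReactionUniverse,
    ecs: Iterable[str],
    seeds: Iterable[str],
    dominated: Mapping[str, set[str]],
    *,
    rank: str = "",
) -> list[KnockoutReport]:
    """One independent knockout per group, plus the combined removal.

    Each per-group report starts from the full enzyme set; the final
    report (taxon ``__all__``) removes the union of every group's
    dominated enzymes at once, so its dependent set is a superset of
    each per-group set.
    """
    ecs = frozenset(ecs)
    seeds = frozenset(seeds)
    reference = expand(universe, ecs, seeds)
    reports = [
        knockout_group(universe, ecs, seeds, dominated, group,
                       rank=rank, reference=reference)
        for group in sorted(dominated)
    ]
    union: set[str] = set()
    for group_ecs in dominated.values():
        union |= set(group_ecs)
    reports.append(
        knockout_group(universe, ecs, seeds, {COMBINED_GROUP: union}, COMBINED_GROUP,
                       rank=rank, reference=reference)
    )
    return reports


def reports_to_frame(reports: list[KnockoutReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "rank": r.rank,
                "n_removed_ecs": len(r.removed_ecs),
                "reference_size": r.reference_scope_size,
                "truncated_size": r.truncated_scope_size,
                "reduction_fraction": r.reduction_fraction,
            }
            for r in reports
        ],
        columns=["taxon", "rank", "n_removed_ecs", "reference_size",
                 "truncated_size", "reduction_fraction"],
    )


def dependents_to_frame(reports: list[KnockoutReport]) -> pd.DataFrame:
    """Long-format taxa-dependent compound table (the removed-metabolite vectors)."""
    rows = [
        {"taxon": r.taxon, "compound_id": c}
        for r in reports
        for c in sorted(r.dependent_compounds)
    ]
    return pd.DataFrame(rows, columns=["taxon", "compound_id"])
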