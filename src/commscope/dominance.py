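"""Simpson-index taxonomic dominance of enzymatic functions.

Each enzyme (EC accession) is treated like an ecological sample whose
"species" are the taxonomic affiliations of its mapped reads.  The
Simpson index in its dominance form, D = sum_i p_i^2, measures how
concentrated those reads are in one taxon: D = 1 for a single-taxon
enzyme, 1/k for an even spread over k taxa.  Within a treatment, an
enzyme is called taxa-dominated when (i) the mean index across the
treatment's replicates exceeds a threshold (default 0.4) and (ii) the
same taxon carries the plurality of reads in every replicate, so the
association is consistent across replicates, not a one-sample artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DOMINANCE_THRESHOLD = 0.4


@dataclass(frozen=True)
class DominanceRecord:
    ec: str
    treatment: str
    rank: str
    mean_simpson: float  # NaN when no replicate had reads for this EC
    dominant_taxon: str | None
    is_dominated: bool


def simpson_index(dist: Mapping[str, float]) -> float:
    """Dominance-form Simpson index sum(p_i^2) of a taxon->count map."""
    total = float(sum(dist.values()))
    if total <= 0:
        raise ValueError("Simpson index undefined for a zero-total distribution")
    return sum((c / total) ** 2 for c in dist.values())


def _argmax_taxon(dist: Mapping[str, float]) -> str:
    # lexicographic tie-break for determinism
    best = max(dist.values())
    winners = sorted(t for t, c in dist.items() if c == best)
    if len(winners) > 1:
        logger.info("dominant-taxon tie between %s; picked %s", winners, winners[0])
    return winners[0]


def call_dominance(
    dists: Sequence[Mapping[str, float]],
    *,
    ec: str,
    treatment: str,
    rank: str,
    threshold: float = DOMINANCE_THRESHOLD,
) -> DominanceRecord:
    """Call treatment-level dominance from per-replicate read distributions.

    Replicates with zero reads for the enzyme are skipped (logged); with
    no scoreable replicate the record carries ``mean_simpson = NaN`` and
    ``is_dominated = False``.  ``dominant_taxon`` is reported only when
    the enzyme is called dominated.
    """
    scoreable = [d for d in dists if sum(d.values()) > 0]
    if len(scoreable) < len(dists):
        logger.info(
            "EC %s (%s): %d/%d replicates had zero reads and were skipped",
            ec, treatment, len(dists) - len(scoreable), len(dists),
        )
    if not scoreable:
        return DominanceRecord(ec, treatment, rank, float("nan"), None, False)
    indices = [simpson_index(d) for d in scoreable]
    mean_d = sum(indices) / len(indices)
    dominants = {_argmax_taxon(d) for d in scoreable}
    dominated = mean_d > threshold and len(dominants) == 1
    return DominanceRecord(
        ec=ec,
        treatment=treatment,
        rank=rank,
        mean_simpson=mean_d,
        dominant_taxon=next(iter(dominants)) if dominated else None,
        is_dominated=dominated,
    )


def compute_dominance(
    dist_df: pd.DataFrame,
    design: pd.DataFrame,
    *,
    rank: str,
    threshold: float = DOMINANCE_THRESHOLD,
    treatments: Sequence[str] | None = None,
) -> list[DominanceRecord]:
    """Score every (EC, treatment) pair from a long (ec, taxon, sample, count) table."""
    for col in ("ec", "taxon", "sample", "count"):
        if col not in dist_df.columns:
            raise ValueError(f"distribution table missing column '{col}'")
    by_treatment = design.groupby("treatment").groups
    if treatments is None:
        treatments = sorted(by_treatment)
    records: list[DominanceRecord] = []
    grouped = dist_df.groupby("ec")
    for ec, sub in grouped:
        per_sample = {
            s: dict(zip(g["taxon"], g["count"]))
            for s, g in sub.groupby("sample")
        }
        for trt in treatments:
            reps = [per_sample.get(s, {}) for s in by_treatment[trt]]
            records.append(
                call_dominance(reps, ec=ec, treatment=trt, rank=rank, threshold=threshold)
            )
    return records


def dominated_enzyme_sets(
    records: Sequence[DominanceRecord], treatment: str
) -> dict[str, set[str]]:
    """Invert dominance calls: taxon -> set of ECs it dominates in a treatment.

    The sets are disjoint by construction since an EC has at most one
    dominant taxon per treatment.
    """
    out: dict[str, set[str]] = {}
    for rec in records:
        if rec.treatment == treatment and rec.is_dominated:
            out.setdefault(rec.dominant_taxon, set()).add(rec.ec)
    return out


def records_to_frame(records: Sequence[DominanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ec": r.ec,
                "treatment": r.treatment,
                "rank": r.rank,
                "mean_simpson": r.mean_simpson,
                "dominant_taxon": r.dominant_taxon or "",
                "is_dominated": r.is_dominated,
            }
            for r in records
        ],
        columns=["ec", "treatment", "rank", "mean_simpson", "dominant_taxon", "is_dominated"],
    )
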