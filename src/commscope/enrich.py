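"""Hypergeometric over-representation of pathways and modules with BH FDR.

Given a selected id set (seed compounds, scope-unique compounds,
taxa-dependent compounds, or DA KOs), each annotation term (pathway or
module) is scored with the upper-tail hypergeometric probability of
drawing at least the observed overlap k from a background of N ids of
which K belong to the term, in n draws:

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

Terms with no overlap are not tested; p-values are Benjamini-Hochberg
adjusted across the tested terms and significance is called on the
adjusted value (default q <= 0.05).  The background set is explicit —
typically all compounds appearing in any scope under comparison, or all
observed KOs — since enrichment is only meaningful relative to it.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

ENRICH_COLUMNS = ["term", "k", "K", "n", "N", "p_value", "q_value", "significant"]


def enrich_terms(
    selected: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided over-representation of every term with overlap k >= 1.

    ``selected`` must be a subset of ``universe``; term member lists are
    intersected with the universe before counting.  Output is sorted by
    (q, p).
    """
    universe = frozenset(universe)
    selected = frozenset(selected)
    if not selected or not universe:
        raise ValueError("selected and universe sets must be non-empty")
    if not selected <= universe:
        raise ValueError(
            f"{len(selected - universe)} selected ids are outside the background universe"
        )
    N, n = len(universe), len(selected)
    rows = []
    for term, members in term_map.items():
        members = frozenset(members) & universe
        k = len(members & selected)
        if k == 0:
            continue
        K = len(members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p_value": p})
    df = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:6])
    if len(df):
        _, q, _, _ = multipletests(df["p_value"], method="fdr_bh")
        df["q_value"] = q
        df["significant"] = df["q_value"] <= alpha
        df = df.sort_values(["q_value", "p_value", "term"], ignore_index=True)
    else:
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def dominance_filtered_terms(
    results: pd.DataFrame,
    entity_counts: Mapping[str, Mapping[str, int]],
    min_entities: int = 6,
    dominance_fraction: float = 0.85,
) -> pd.DataFrame:
    """Keep terms clearly dominated by one treatment.

    ``entity_counts`` gives, per term, how many of its entities came from
    each treatment.  A term survives when it has at least ``min_entities``
    entities in total and at least ``dominance_fraction`` of them from a
    single treatment; that treatment is reported in
    ``dominant_treatment``.
    """
    keep_rows = []
    for _, row in results.iterrows():
        counts = entity_counts.get(row["term"], {})
        total = sum(counts.values())
        if total < min_entities:
            continue
        top_trt = max(sorted(counts), key=lambda t: counts[t])
        if counts[top_trt] / total < dominance_fraction:
            continue
        out = dict(row)
        out["dominant_treatment"] = top_trt
        keep_rows.append(out)
    return pd.DataFrame(keep_rows, columns=list(results.columns) + ["dominant_treatment"])
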