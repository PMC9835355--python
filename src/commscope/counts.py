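"""Count-table construction from gene/contig annotation tables.

Annotated metagenome assemblies arrive as one row per gene: contig of
origin, taxonomic lineage, functional accessions (EC, KO) and mapped-read
counts per sample.  Binning sums those counts under an annotation key —
a taxon at a chosen rank, an EC or a KO — giving the feature x sample
count tables that feed differential abundance and dominance scoring.
Rows lacking the key are pooled under ``unassigned`` so column sums are
conserved; the pool is reported but excluded from downstream testing.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ["phylum", "class", "order", "family", "genus", "species"]
UNASSIGNED = "unassigned"

ANNOTATION_META_COLUMNS = ["gene_id", "contig_id", "taxonomy", "ec", "ko"]


@dataclass
class AnnotationTable:
    """Per-gene annotations with per-sample mapped-read counts.

    ``df`` holds one row per gene with columns ``gene_id``, ``contig_id``,
    ``ec``, ``ko``, one ``tax_<rank>`` column per known rank, and one
    integer column per sample.
    """

    df: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        if self.df["gene_id"].duplicated().any():
            dup = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if (self.df["contig_id"].astype(str) == "").any():
            raise ValueError("empty contig_id")
        counts = self.df[self.samples]
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")


@dataclass
class CountTable:
    """Feature x sample nonnegative integer matrix under one annotation key.

    ``design`` maps each sample to its (treatment, replicate); every
    sample column must appear in the design.
    """

    key_scheme: str
    matrix: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.matrix.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    def samples_of(self, treatment: str) -> list[str]:
        sel = self.design[self.design["treatment"] == treatment].index
        return [s for s in self.matrix.columns if s in set(sel)]

    def drop_unassigned(self) -> "CountTable":
        return CountTable(
            self.key_scheme,
            self.matrix[self.matrix.index != UNASSIGNED],
            self.design,
        )


def parse_lineage(text: object) -> dict[str, str]:
    """Parse a ``rank:name;rank:name`` lineage string (possibly partial)."""
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return {}
    out: dict[str, str] = {}
    for tok in str(text).split(";"):
        if ":" in tok:
            rank, name = tok.split(":", 1)
            out[rank.strip()] = name.strip()
    return out


def format_lineage(lineage: dict[str, str]) -> str:
    return ";".join(f"{r}:{lineage[r]}" for r in RANKS if r in lineage)


def read_annotation_table(path: str | os.PathLike) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig_id": str})
    for col in ANNOTATION_META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    samples = [c for c in df.columns if c not in ANNOTATION_META_COLUMNS]
    lineages = df["taxonomy"].map(parse_lineage)
    for rank in RANKS:
        df[f"tax_{rank}"] = lineages.map(lambda lin: lin.get(rank, ""))
    df = df.drop(columns=["taxonomy"])
    df[samples] = df[samples].fillna(0).astype(int)
    return AnnotationTable(df=df, samples=samples)


def write_annotation_table(table: AnnotationTable, path: str | os.PathLike) -> None:
    df = table.df.copy()
    df["taxonomy"] = df.apply(
        lambda row: format_lineage(
            {r: row[f"tax_{r}"] for r in RANKS if row.get(f"tax_{r}", "")}
        ),
        axis=1,
    )
    cols = ANNOTATION_META_COLUMNS + table.samples
    df[cols].to_csv(path, sep="\t", index=False)


def read_design(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "treatment", "replicate"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return df.set_index("sample")


def assign_contig_taxonomy(table: AnnotationTable, rank: str) -> dict[str, str]:
    """Map each contig to the modal taxon of its genes at ``rank``.

    Gene-level taxonomic calls within a contig occasionally disagree; the
    contig is assigned the most frequent annotation among its genes.
    Ties break to the lexicographically smaller taxon (logged); contigs
    with no gene annotated at this rank map to ``unassigned``.  The
    result is invariant to input row order.
    """
    if rank not in RANKS:
        raise ValueError(f"unsupported rank {rank!r}; expected one of {RANKS}")
    col = f"tax_{rank}"
    out: dict[str, str] = {}
    for contig, sub in table.df.groupby("contig_id", sort=False):
        names = [t for t in sub[col] if t]
        if not names:
            out[contig] = UNASSIGNED
            continue
        tally = Counter(names)
        top = max(tally.values())
        winners = sorted(t for t, c in tally.items() if c == top)
        if len(winners) > 1:
            logger.info(
                "contig %s: taxonomy tie at %s between %s; assigned %s",
                contig, rank, winners, winners[0],
            )
        out[contig] = winners[0]
    return out


def contig_consistency(table: AnnotationTable, rank: str) -> float:
    """Fraction of contigs whose annotated genes all agree at ``rank``."""
    col = f"tax_{rank}"
    consistent = total = 0
    for _, sub in table.df.groupby("contig_id", sort=False):
        names = {t for t in sub[col] if t}
        if not names:
            continue
        total += 1
        consistent += len(names) == 1
    return consistent / total if total else float("nan")


def bin_counts(
    table: AnnotationTable,
    key_scheme: str,
    design: pd.DataFrame,
    *,
    rank: str | None = None,
    use_contig_taxonomy: bool = False,
) -> CountTable:
    """Sum gene counts under an annotation key into a feature x sample table.

    ``key_scheme`` is ``"EC"``, ``"KO"`` or ``"taxon"`` (the latter needs
    ``rank``; with ``use_contig_taxonomy`` genes inherit their contig's
    majority-rule taxon).  Column sums are conserved: genes without the
    key fall into the ``unassigned`` feature.
    """
    if key_scheme in ("EC", "KO"):
        keys = table.df[key_scheme.lower()].fillna("").astype(str)
    elif key_scheme == "taxon":
        if rank is None:
            raise ValueError("key_scheme 'taxon' requires a rank")
        if rank not in RANKS:
            raise ValueError(f"unsupported rank {rank!r}")
        if use_contig_taxonomy:
            contig_tax = assign_contig_taxonomy(table, rank)
            keys = table.df["contig_id"].map(contig_tax)
        else:
            keys = table.df[f"tax_{rank}"]
    else:
        raise ValueError(f"unknown key_scheme {key_scheme!r}")
    keys = keys.where(keys.astype(bool), UNASSIGNED)
    mat = table.df[table.samples].groupby(keys.values).sum()
    mat.index.name = "feature"
    scheme = f"taxon@{rank}" if key_scheme == "taxon" else key_scheme
    return CountTable(key_scheme=scheme, matrix=mat.sort_index(), design=design)


def merge_tables(tables: list[CountTable]) -> CountTable:
    """Merge per-experiment count tables sharing a key scheme.

    Sample sets must be disjoint; the feature set is the union with
    absent cells filled with zeros, so column sums are preserved.
    """
    if not tables:
        raise ValueError("no tables to merge")
    schemes = {t.key_scheme for t in tables}
    if len(schemes) > 1:
        raise ValueError(f"mixed key schemes: {sorted(schemes)}")
    seen: set[str] = set()
    for t in tables:
        dup = seen & set(t.samples)
        if dup:
            raise ValueError(f"duplicate sample ids across tables: {sorted(dup)}")
        seen |= set(t.samples)
    matrix = pd.concat([t.matrix for t in tables], axis=1).fillna(0).astype(int)
    design = pd.concat([t.design for t in tables])
    design = design[~design.index.duplicated()]
    return CountTable(tables[0].key_scheme, matrix.sort_index(), design)


def filter_low_counts(ct: CountTable, min_total: int = 50) -> CountTable:
    """Drop features with fewer than ``min_total`` reads summed over samples."""
    keep = ct.matrix.sum(axis=1) >= min_total
    return CountTable(ct.key_scheme, ct.matrix[keep], ct.design)


def ec_taxon_distribution(table: AnnotationTable, rank: str) -> pd.DataFrame:
    """Long-format (ec, taxon, sample, count) read distribution per enzyme.

    The taxonomic read distribution of each EC is the input to Simpson
    dominance scoring; genes without an EC or without a taxon at this
    rank are excluded.
    """
    if rank not in RANKS:
        raise ValueError(f"unsupported rank {rank!r}")
    df = table.df
    mask = df["ec"].fillna("").astype(bool) & df[f"tax_{rank}"].astype(bool)
    sub = df[mask]
    long = sub.melt(
        id_vars=["ec", f"tax_{rank}"],
        value_vars=table.samples,
        var_name="sample",
        value_name="count",
    ).rename(columns={f"tax_{rank}": "taxon"})
    agg = (
        long.groupby(["ec", "taxon", "sample"], as_index=False)["count"]
        .sum()
        .sort_values(["ec", "taxon", "sample"], ignore_index=True)
    )
    return agg


def write_count_table(ct: CountTable, path: str | os.PathLike) -> None:
    ct.matrix.to_csv(path, sep="\t")


def read_count_table(
    path: str | os.PathLike, design: pd.DataFrame, key_scheme: str = "EC"
) -> CountTable:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    return CountTable(key_scheme, mat.astype(int), design)
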