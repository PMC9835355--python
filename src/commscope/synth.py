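"""Synthetic annotated-metagenome generator with planted ground truth.

Emulates the inputs of the real pipeline — a reaction universe, a
per-gene annotation table with per-sample read counts, and a design
table — at desk scale, with every downstream signal planted and
recorded so each stage can be scored for recovery:

* **Sources.** The universe is a layered DAG: per-treatment planted
  seed compounds form layer 0 and every other compound is the product
  of at least one reaction whose substrates lie in earlier layers, so
  the source SCCs of the full graph are exactly the planted seeds.
  Extra reactions add redundancy (alternative routes) without creating
  new sources.
* **Differential abundance.** Counts are negative-binomial
  (variance = mu + phi * mu^2).  The enzymes consuming a treatment's
  seeds, plus a few extras, get their mean multiplied by a fold change
  in that treatment's samples — the treatment amendment enriches the
  functions that consume its resources, which is what makes the
  intersected seed list recover the planted per-treatment seeds.
* **Dominance.** Reads of each enzyme are split across genera.
  Dominated enzymes give a designated genus a fixed fraction (default
  0.9) in every sample; all other enzymes get an independent
  symmetric-Dirichlet split per sample, so no stable dominant taxon
  emerges across replicates.
* **Knock-outs.** Each genus owns a private linear pathway anchored at a
  treatment seed whose reactions carry that genus's dominated enzymes
  and produce compounds made nowhere else; knocking the genus out must
  lose exactly that chain.  Additional dominated enzymes are attached
  redundantly to core reactions that also keep a non-dominated
  catalyst, probing the alternative-route robustness of the expansion.

Everything is deterministic given the spec's integer seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import AnnotationTable, CountTable, write_annotation_table
from .universe import Compound, Reaction, ReactionUniverse, save_universe

TREATMENT, CONTROL = "SM", "NTC"


@dataclass
class SynthSpec:
    """Generator parameters; the defaults define the standard fixture."""

    seed: int = 17
    # universe
    n_core_compounds: int = 60          # includes the planted seed compounds
    n_seeds_per_treatment: int = 4      # disjoint seed sets per treatment
    n_extra_reactions: int = 25         # redundancy reactions (alternative routes)
    allow_cycles: bool = False
    n_seed_cycles: int = 0              # planted reversible 2-cycles acting as sources
    # community
    n_genera: int = 8
    genera_per_order: int = 2
    n_replicates: int = 5
    # counts
    base_mean: float = 200.0            # NB mean reads per enzyme per sample
    nb_dispersion: float = 0.1
    n_unannotated_genes: int = 10
    genes_per_contig: tuple[int, int] = (2, 3)
    mixed_contig_fraction: float = 0.05
    # differential abundance
    da_fold_change: float = 8.0
    n_da_extra: int = 6                 # extra DA enzymes beyond the seed consumers
    # dominance / knockouts
    chain_length: int = 3               # private-pathway compounds per genus
    n_redundant_dominated: int = 2      # dominated ECs attached to redundant reactions
    dominant_fraction: float = 0.9

    def __post_init__(self) -> None:
        n_seeds = 2 * self.n_seeds_per_treatment
        if self.n_core_compounds <= n_seeds:
            raise ValueError(
                f"n_core_compounds ({self.n_core_compounds}) must exceed the "
                f"{n_seeds} planted seed compounds so every non-seed compound "
                "can be a reaction product"
            )
        if not 0.5 < self.dominant_fraction <= 1.0:
            raise ValueError("dominant_fraction must be in (0.5, 1]")
        for name in ("n_genera", "n_replicates", "chain_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Planted structure, sufficient to score every downstream stage."""

    treatment_seeds: dict[str, list[str]]
    all_seeds: list[str]
    da_ecs: dict[str, list[str]]        # treatment -> enriched ECs
    dominated: dict[str, list[str]]     # genus -> dominated ECs (chain + redundant)
    chains: dict[str, list[str]]        # genus -> private-chain compounds
    chain_ecs: dict[str, list[str]]
    cycle_seeds: list[str] = field(default_factory=list)


def _ec(i: int) -> str:
    return f"{1 + i % 7}.{1 + (i // 7) % 9}.{1 + (i // 63) % 9}.{i + 1}"


def _ko(i: int) -> str:
    return f"K{i + 1:05d}"


def generate_universe(spec: SynthSpec) -> tuple[ReactionUniverse, GroundTruth]:
    """Layered-DAG reaction universe with planted sources and private chains."""
    rng = np.random.default_rng([spec.seed, 1])
    n_seeds = 2 * spec.n_seeds_per_treatment
    core = [f"C{i + 1:05d}" for i in range(spec.n_core_compounds)]
    seeds = core[:n_seeds]
    sm_seeds = seeds[: spec.n_seeds_per_treatment]
    ntc_seeds = seeds[spec.n_seeds_per_treatment:]
    nonseed = core[n_seeds:]

    reactions: dict[str, Reaction] = {}
    ec_counter = 0

    def add_reaction(subs, prods, reversible=False) -> str:
        nonlocal ec_counter
        rid = f"R{len(reactions) + 1:05d}"
        ec = _ec(ec_counter)
        ec_counter += 1
        reactions[rid] = Reaction(
            id=rid, ecs=frozenset([ec]), substrates=frozenset(subs),
            products=frozenset(prods), reversible=reversible,
        )
        return rid

    # one producing reaction per non-seed compound; substrates strictly earlier
    seed_consumer_rids: dict[str, str] = {}
    for i, cpd in enumerate(nonseed):
        earlier = core[: n_seeds + i]
        if i < n_seeds:
            subs = [seeds[i]]  # force one single-substrate consumer per seed
            rid = add_reaction(subs, [cpd])
            seed_consumer_rids[seeds[i]] = rid
        else:
            k = int(rng.integers(1, 3))
            subs = list(rng.choice(earlier, size=min(k, len(earlier)), replace=False))
            add_reaction(subs, [cpd])

    # redundancy reactions: alternative routes to existing non-seed compounds
    for _ in range(spec.n_extra_reactions):
        j = int(rng.integers(n_seeds, spec.n_core_compounds))
        earlier = core[:j]
        k = int(rng.integers(1, 3))
        subs = list(rng.choice(earlier, size=min(k, len(earlier)), replace=False))
        add_reaction(subs, [core[j]])

    # optional planted reversible 2-cycles acting as additional sources
    cycle_seeds: list[str] = []
    compounds_extra: list[str] = []
    for c in range(spec.n_seed_cycles):
        z1 = f"Z{2 * c + 1:03d}"
        z2 = f"Z{2 * c + 2:03d}"
        compounds_extra += [z1, z2]
        cycle_seeds += [z1, z2]
        add_reaction([z1], [z2], reversible=True)
        add_reaction([z1], [nonseed[c % len(nonseed)]])

    # per-genus private chains anchored at treatment seeds
    genera = [f"G{t + 1:02d}" for t in range(spec.n_genera)]
    chains: dict[str, list[str]] = {}
    chain_ecs: dict[str, list[str]] = {}
    for t, genus in enumerate(genera):
        anchor = sm_seeds[t % len(sm_seeds)]
        chain = [f"C{9000 + t * spec.chain_length + i + 1:05d}"
                 for i in range(spec.chain_length)]
        ecs: list[str] = []
        prev = anchor
        for cpd in chain:
            rid = add_reaction([prev], [cpd])
            ecs.extend(reactions[rid].ecs)
            prev = cpd
        chains[genus] = chain
        chain_ecs[genus] = ecs
        compounds_extra += chain

    # redundant dominated ECs: attach a second catalyst to core reactions
    dominated = {g: list(chain_ecs[g]) for g in genera}
    chain_compounds = {c for ch in chains.values() for c in ch}
    # never attach to a chain reaction: the second catalyst would keep the
    # chain alive under its owner's knockout and break planted exactness
    candidate_rids = sorted(
        rid for rid, rxn in reactions.items()
        if rxn.products.isdisjoint(chain_compounds)
    )
    picked = rng.choice(candidate_rids,
                        size=spec.n_genera * spec.n_redundant_dominated,
                        replace=False)
    idx = 0
    for genus in genera:
        for _ in range(spec.n_redundant_dominated):
            rid = str(picked[idx]); idx += 1
            ec = _ec(ec_counter); ec_counter += 1
            old = reactions[rid]
            reactions[rid] = Reaction(old.id, old.ecs | {ec}, old.substrates,
                                      old.products, old.reversible)
            dominated[genus].append(ec)

    all_compounds = core + compounds_extra
    compounds = {c: Compound(id=c) for c in all_compounds}

    # pathways: one per genus chain, plus generic pathways over core compounds
    pathway_map: dict[str, frozenset[str]] = {
        f"PW_{genus}": frozenset(chain) for genus, chain in chains.items()
    }
    n_generic = 4
    assignment = rng.integers(0, n_generic, size=len(core))
    for p in range(n_generic):
        members = frozenset(c for c, a in zip(core, assignment) if a == p)
        if members:
            pathway_map[f"PW{p + 1:03d}"] = members

    # KO per EC, modules of 5 consecutive KOs
    all_ecs = sorted({ec for r in reactions.values() for ec in r.ecs})
    ko_of_ec = {ec: _ko(i) for i, ec in enumerate(all_ecs)}
    module_map: dict[str, frozenset[str]] = {}
    kos = [ko_of_ec[ec] for ec in all_ecs]
    for m in range(0, len(kos), 5):
        module_map[f"M{m // 5 + 1:04d}"] = frozenset(kos[m: m + 5])

    universe = ReactionUniverse(
        compounds=compounds, reactions=reactions,
        pathway_map=pathway_map, module_map=module_map,
    )

    # planted DA: seed-consumer ECs per treatment, plus extras
    consumer_ec = {s: next(iter(reactions[r].ecs)) for s, r in seed_consumer_rids.items()}
    taken = {ec for g in genera for ec in dominated[g]}
    taken |= set(consumer_ec.values())
    # extras must not consume planted seeds: seed-consuming enriched enzymes
    # are exactly the designated consumers, otherwise a seed would surface as
    # a source of the wrong treatment's sub-network
    seed_touching = {
        ec for r in reactions.values() if r.substrates & set(seeds) for ec in r.ecs
    }
    free = [ec for ec in all_ecs if ec not in taken | seed_touching]
    extra = list(rng.choice(free, size=min(spec.n_da_extra, len(free)), replace=False))
    half = len(extra) // 2
    da_ecs = {
        TREATMENT: sorted([consumer_ec[s] for s in sm_seeds] + extra[:half]),
        CONTROL: sorted([consumer_ec[s] for s in ntc_seeds] + extra[half:]),
    }

    truth = GroundTruth(
        treatment_seeds={TREATMENT: sm_seeds, CONTROL: ntc_seeds},
        all_seeds=seeds + cycle_seeds,
        da_ecs=da_ecs,
        dominated={g: sorted(v) for g, v in dominated.items()},
        chains=chains,
        chain_ecs=chain_ecs,
        cycle_seeds=cycle_seeds,
    )
    return universe, truth


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def lineage_of(genus: str, spec: SynthSpec) -> dict[str, str]:
    g = int(genus[1:]) - 1
    order = g // spec.genera_per_order + 1
    phylum = order % 2 + 1
    return {
        "genus": genus,
        "family": f"F{order:02d}",
        "order": f"O{order:02d}",
        "phylum": f"P{phylum:02d}",
    }


def generate_counts(
    spec: SynthSpec, universe: ReactionUniverse, truth: GroundTruth
) -> tuple[AnnotationTable, pd.DataFrame]:
    """Per-gene annotation table + design with planted DA and dominance."""
    rng = np.random.default_rng([spec.seed, 2])
    genera = [f"G{t + 1:02d}" for t in range(spec.n_genera)]
    samples = [f"{trt}_{r + 1}" for trt in (TREATMENT, CONTROL)
               for r in range(spec.n_replicates)]
    design = pd.DataFrame(
        {
            "treatment": [s.rsplit("_", 1)[0] for s in samples],
            "replicate": [s.rsplit("_", 1)[1] for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    all_ecs = sorted({ec for r in universe.reactions.values() for ec in r.ecs})
    ko_of_ec = {ec: _ko(i) for i, ec in enumerate(all_ecs)}
    dominated_by = {ec: g for g, ecs in truth.dominated.items() for ec in ecs}
    da_of = {}
    for trt, ecs in truth.da_ecs.items():
        for ec in ecs:
            da_of[ec] = trt

    k = len(genera)
    gene_rows: list[dict] = []
    for ec in all_ecs:
        counts = np.zeros((k, len(samples)), dtype=int)
        dom = dominated_by.get(ec)
        if dom is not None:
            p_fixed = np.full(k, (1 - spec.dominant_fraction) / (k - 1))
            p_fixed[genera.index(dom)] = spec.dominant_fraction
        for j, s in enumerate(samples):
            trt = design.loc[s, "treatment"]
            mu = spec.base_mean * (spec.da_fold_change if da_of.get(ec) == trt else 1.0)
            total = int(_nb_draw(rng, mu, spec.nb_dispersion))
            p = p_fixed if dom is not None else rng.dirichlet(np.ones(k))
            counts[:, j] = rng.multinomial(total, p)
        for gi, genus in enumerate(genera):
            if counts[gi].sum() == 0:
                continue
            row = {"genus": genus, "ec": ec, "ko": ko_of_ec[ec]}
            row.update({s: int(c) for s, c in zip(samples, counts[gi])})
            gene_rows.append(row)

    # unannotated genes: mapped reads with no functional assignment
    for u in range(spec.n_unannotated_genes):
        genus = genera[int(rng.integers(0, k))]
        row = {"genus": genus, "ec": "", "ko": ""}
        row.update(
            {s: int(_nb_draw(rng, spec.base_mean / 4, spec.nb_dispersion))
             for s in samples}
        )
        gene_rows.append(row)

    # pack genes into contigs genus by genus; a small fraction of contigs
    # carry one gene from a foreign genus (exercises the majority rule)
    df_rows: list[dict] = []
    gene_id = contig_id = 0
    by_genus: dict[str, list[dict]] = {}
    for row in gene_rows:
        by_genus.setdefault(row["genus"], []).append(row)
    lo, hi = spec.genes_per_contig
    for genus in sorted(by_genus):
        pool = by_genus[genus]
        i = 0
        while i < len(pool):
            size = int(rng.integers(lo, hi + 1))
            contig_id += 1
            members = pool[i: i + size]
            i += size
            mixed = (
                len(members) >= 3
                and rng.random() < spec.mixed_contig_fraction
            )
            for m, row in enumerate(members):
                gene_id += 1
                g = row["genus"]
                if mixed and m == len(members) - 1 and row["ec"] not in dominated_by:
                    g = genera[(genera.index(genus) + 1) % k]
                lin = lineage_of(g, spec)
                out = {
                    "gene_id": f"g{gene_id:05d}",
                    "contig_id": f"ctg{contig_id:05d}",
                    "ec": row["ec"],
                    "ko": row["ko"],
                }
                out.update({f"tax_{r}": lin[r] for r in lin})
                out.update({s: row[s] for s in samples})
                df_rows.append(out)

    df = pd.DataFrame(df_rows)
    for rank in ("class", "species"):
        df[f"tax_{rank}"] = ""
    table = AnnotationTable(df=df, samples=samples)
    return table, design


def simulate_count_matrix(
    n_features: int,
    n_a: int,
    n_b: int,
    *,
    base_mean: float = 50.0,
    dispersion: float = 0.1,
    n_da: int = 0,
    fold_change: float = 1.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[CountTable, list[str]]:
    """Plain NB count matrix for calibration/power studies of the DA stage.

    The first ``n_da`` features get ``fold_change`` applied in group A.
    Returns the count table and the list of planted DA feature ids.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    features = [f"f{i + 1:04d}" for i in range(n_features)]
    samples = [f"A_{j + 1}" for j in range(n_a)] + [f"B_{j + 1}" for j in range(n_b)]
    design = pd.DataFrame(
        {
            "treatment": ["A"] * n_a + ["B"] * n_b,
            "replicate": [str(j + 1) for j in range(n_a)]
            + [str(j + 1) for j in range(n_b)],
        },
        index=pd.Index(samples, name="sample"),
    )
    mat = np.empty((n_features, n_a + n_b), dtype=int)
    for i in range(n_features):
        mu_a = base_mean * (fold_change if i < n_da else 1.0)
        mat[i, :n_a] = _nb_draw(rng, mu_a, dispersion, size=n_a)
        mat[i, n_a:] = _nb_draw(rng, base_mean, dispersion, size=n_b)
    matrix = pd.DataFrame(mat, index=pd.Index(features, name="feature"), columns=samples)
    return CountTable("EC", matrix, design), features[:n_da]


def write_all(spec: SynthSpec, outdir: str | os.PathLike) -> None:
    """Generate everything and write the full file bundle.

    Layout: ``universe/`` (reactions/compounds/pathways/modules TSVs),
    ``annotation.tsv``, ``design.tsv``, ``truth/*.tsv`` ground-truth
    label files, and ``spec.json`` recording the generator parameters.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    universe, truth = generate_universe(spec)
    table, design = generate_counts(spec, universe, truth)
    save_universe(universe, outdir / "universe", format="tsv")
    write_annotation_table(table, outdir / "annotation.tsv")
    design.to_csv(outdir / "design.tsv", sep="\t")
    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    pd.DataFrame(
        [{"treatment": t, "compound_id": c}
         for t, cs in truth.treatment_seeds.items() for c in cs]
    ).to_csv(tdir / "seeds.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"treatment": t, "ec": e} for t, es in truth.da_ecs.items() for e in es]
    ).to_csv(tdir / "da_ecs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"genus": g, "ec": e} for g, es in truth.dominated.items() for e in es]
    ).to_csv(tdir / "dominated.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"genus": g, "compound_id": c} for g, cs in truth.chains.items() for c in cs]
    ).to_csv(tdir / "chains.tsv", sep="\t", index=False)
    with open(outdir / "spec.json", "w") as fh:
        json.dump(asdict(spec), fh, indent=1, sort_keys=True)
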