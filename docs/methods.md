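# Methods

This note records the models, numerical choices and design decisions
behind each stage, what the synthetic generator does and does not
emulate, and the known limitations.

## Reaction universe

The reaction bank is purely qualitative: a reaction is a set of EC
labels, a substrate set, a product set and a reversibility flag.  There
is no stoichiometry, mass balance or thermodynamics — every downstream
computation (graph construction, SCC seeds, expansion) is set/graph
based, so coefficients would never be consulted.  Substrates and
products may overlap (catalytic participants).  A reaction is available
to an enzyme set if **any** of its ECs is present: one annotated
catalyst suffices.

Currency metabolites (water, ATP, common cofactors) receive no special
treatment by default; an explicit exclusion list can be supplied at
load, is logged, and removes reactions left without substrates or
products.  Making cofactor handling an explicit option rather than a
built-in list keeps results reproducible across database snapshots.

## Count tables

Contig taxonomy is the modal taxon of the contig's genes at the chosen
rank; ties break to the lexicographically smaller name (logged), which
makes the assignment deterministic and row-order invariant.  Binning
conserves column sums: genes lacking the key are pooled under
`unassigned`, which is reported but excluded from normalization and
testing.  A low-count filter (default: ≥ 50 reads per feature summed
over samples) is available for ordination-style analyses but is *not*
applied before differential abundance, which uses raw counts.  Counts
are integers; fractional multi-mapping weights are unsupported.

## Differential abundance

Counts are modelled as negative binomial with a **common dispersion**
φ, variance `μ + φμ²`.  The stage is deliberately simple:

- **TMM normalization.** Reference sample = library size closest to the
  mean library size; M-values trimmed at 30 %, A-values at 5 %;
  weighted by inverse delta-method variance; factors rescaled to
  geometric mean 1.
- **Dispersion.** Pooled method of moments: regression through the
  origin of the within-group excess variance `s² − m` on `m²` across
  all features.  Pooling across features stabilises the estimate at
  few replicates; per-feature or empirical-Bayes moderated dispersions
  are out of scope.
- **Exact test.** Counts are scaled to a common effective library size
  (pseudo-counts, rounded group sums); conditional on the two-group
  total, the probability of every split is the product of two NB
  masses (sizes `n_g/φ`), and the two-sided p-value sums all splits
  with probability ≤ the observed one.  φ = 0 degenerates to the exact
  binomial split test.
- **FDR.** Benjamini–Hochberg; significance at q ≤ 0.05 by default.
- **Fold changes.** log2 of normalized group means; a pseudo-count of
  0.5 enters the ratio only when a group mean is zero, keeping the
  test itself untouched while reporting finite values.

The test is calibrated by construction rather than tuned: on null NB
simulations the acceptance script measures the empirical type-I error
directly.  Users who prefer a different DA engine can inject a
precomputed (feature, logFC, p, q) table; only the significant sets
propagate downstream.

## Simpson dominance

The **dominance form** `D = Σ pᵢ²` is used (not the diversity form
`1 − Σ pᵢ²`): the threshold `D > 0.4` is a lower bound on
concentration, so the dominance form is the one under which the
inequality reads correctly (a single-taxon enzyme scores 1).  The mean
is taken across the treatment's replicates only, since the calls are
treatment-specific.  Replicates with zero reads for an enzyme are
skipped and logged rather than breaking the consistency condition;
argmax ties break lexicographically.  Each enzyme therefore has at most
one dominant taxon per (treatment, rank), making the taxon → enzymes
inverse map disjoint by construction.

## Seeds and expansion

Seed prediction condenses the directed compound graph (Tarjan SCC via
networkx) and reports **all** members of in-degree-zero components,
weighted 1/|component| — reporting whole components keeps the output
deterministic and complete; a `min_confidence` filter can drop seeds
from large source cycles (default 0: keep everything).  A node with
only a self-loop is its own source component and is reported.
Sub-networks restricted to DA enzymes are fragmented and over-predict
sources, so their raw seeds are intersected with the meta-network
seeds; an empty intersection is a logged warning, not an error.

Expansion is the least fixed point of firing reactions whose substrate
set is contained in the current compound set.  Reversible reactions are
checked independently per direction; set semantics mean nothing is
consumed.  The scope is invariant to scan order, monotone in both seeds
and enzymes, and idempotent — each of these is asserted by oracle-based
tests (naive shuffled full scans, brute-force reachability).  Seeds
absent from the universe are dropped with a warning because treatment
seed lists may reference compounds outside a restricted bank.

## Knock-outs

Per-group knockouts are independent (each starts from the full enzyme
set); one combined run removes the union of all dominated enzymes.
Removal is at the **enzyme** level: a reaction disappears only when all
of its ECs present in the enzyme set are removed, so alternative
catalysts and alternative routes rescue products — the redundancy the
simulation is designed to expose.  Impact is reported as compound
counts (`|dependent| / |reference scope|`); edge counts are available
from the exported graphs but are not a primary statistic.

## Enrichment

Upper-tail hypergeometric per term with k ≥ 1, BH across tested terms,
significance on the adjusted value.  The background set is explicit and
caller-chosen; the pipeline uses the union of the scopes under
comparison for compound enrichment and all observed KOs for module
enrichment.  A reporting filter keeps terms with ≥ 6 entities of which
≥ 85 % come from one treatment, labelling the dominant treatment.

## Synthetic generator

Defaults: 60 core compounds, 4 + 4 disjoint per-treatment seed
compounds, ~100 reactions (one producer per non-seed compound + 25
redundancy reactions), 8 genera in 4 orders / 2 phyla, 2 treatments ×
5 replicates, NB mean 200 reads per enzyme per sample at dispersion
0.1, 8-fold planted DA changes, 90/10 dominated read splits, 3-compound
private chains per genus plus 2 redundantly attached dominated enzymes.
These sizes keep the full chain (and its tests) in the seconds range on
one CPU while leaving every recovery non-trivial.

Construction guarantees, relied on by the recovery tests:

- the universe is a layered DAG whose sources are exactly the planted
  seeds (every non-seed compound has a producer; every seed has a
  single-substrate consumer), so meta-network seed prediction is exact;
- the only seed-consuming enriched enzymes are each treatment's
  designated consumers, so the sub-network ∩ meta-network intersection
  recovers the per-treatment seed sets;
- non-dominated enzymes draw an independent symmetric-Dirichlet taxon
  split *per sample* — modelling functionally redundant enzymes with no
  stable taxonomic association — so replicate-consistent dominance
  arises essentially only where planted;
- chain compounds are produced by chain reactions only, and redundant
  dominated ECs are never attached to chain reactions, so each genus's
  dependent-compound set equals its planted chain exactly.

What the generator does **not** emulate: read-level artifacts (assembly
chimeras, multi-mapping), compositional coupling between features,
genuinely shared seed compounds between treatments, partially annotated
lineages beyond a fixed four-rank hierarchy, and reversible reactions
in the core DAG (reversibility is exercised by hand-built universes in
the unit tests, and optional planted 2-cycles are available via
`n_seed_cycles`).  Passing recovery tests therefore demonstrates the
pipeline's correctness on clean planted structure, not robustness to
annotation noise or compositional artifacts in real metagenomes.

## Numerical/degenerate-input conventions

- All randomness flows through `numpy.random.default_rng` seeded from a
  single integer; generated file bundles are byte-identical per seed.
- Zero-total taxon distributions are an error for `simpson_index`,
  skipped replicates for `call_dominance`, a NaN-flagged record when no
  replicate is scoreable.
- An all-zero sample column is an error in TMM (named in the message).
- Empty enzyme sets give empty graphs; empty universes expand to the
  seed set itself.
- BH q-values come from statsmodels; p-values from scipy distributions.

## Limitations

Scope/seed predictions are qualitative: no fluxes, yields, or exchange
rates, and directionality is only as good as the universe's
reversibility flags.  The DA stage implements a plain common-dispersion
exact test, not a moderated or GLM-based one; for designs with
covariates or paired samples inject an external DA table.  Pathway
enrichment is term-membership only (no topology).
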