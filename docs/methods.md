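# Methods

## Scope and shape

The package is an offline re-implementation of the analysis engine behind a
fast comparative genome browser for prokaryotes: database construction from
annotated assemblies, accelerated homolog search, and the three analyses
layered on hits (gene neighborhoods, taxonomic prevalence, co-occurrence).
Everything external to those analyses — web serving, result caching,
download tooling, and the internals of production search engines — is out of
scope; where the production system delegates alignment to such engines, this
package ships its own reference kernel and exposes the engine workflow only
as an optional adapter contract.

## Alignment kernel and statistics

Pairwise alignment is optimal Smith–Waterman with affine gaps, computed by
Biopython's `PairwiseAligner` (C implementation) under BLOSUM62 with gap
open 11 and gap extend 1 (NCBI convention: a gap of length L costs
11 + L). Raw scores are converted to bits with fixed gapped
Karlin–Altschul constants (λ = 0.267, K = 0.041, the standard values for
this scoring), and E-values use the bit-score closed form
E = m·n·2^(−bits) with m the query length and n the total residue count of
the database's distinct proteins. Every search path (direct, clustered
stage 1, clustered stage 3) uses this one kernel and one n, so scores and
E-values are directly comparable across paths — deliberately unlike
production systems that mix engines with different score scales.

Conventions that downstream thresholds depend on:

* **Identity** is matches / alignment columns *including* gap columns (the
  protein-BLAST convention). This is the denominator for the 30 % ortholog
  gate and the 70 % clustering gate. CD-HIT's identity-over-shorter-sequence
  definition differs subtly; the package applies the one convention
  uniformly.
* **Coverage** of a sequence is the aligned span over its full length.
* **X** scores 0 against everything; sequences are validated to the 20
  standard residues plus X.
* The **score ratio** of a hit is its bit score divided by the query's
  self-alignment bit score; it is ≤ 1 because self-alignment is maximal
  under BLOSUM-type scoring.

Composition-based score adjustment is not implemented; on low-complexity
queries E-values will be more optimistic than a production engine's. The
synthetic generator draws residues uniformly, so tests are not affected by
this omission, and real low-complexity proteins are the main caveat.

The candidate prefilter is an exact shared-k-mer index: a subject is aligned
only if it shares at least `min_shared` distinct k-mers with the query.
Searching uses k = 4 with one shared word — at the ≥ 70 %-identity regime the
expected number of shared words is in the dozens, so recall is effectively
complete (tested ≤ 0.1 % loss) — while clustering prescreens with k = 5 and
two shared words for speed, with `verify_clusters` re-aligning every member
as the correctness backstop. Queries shorter than k fall back to exhaustive
alignment rather than silently returning nothing.

## Database model

Assemblies carry a 7-rank GTDB-style taxonomy and the quality metadata the
gate consumes (CheckM scores, GUNC chimerism, MIMAG flag, selection flags).
Genes are 1-based inclusive stranded intervals (GFF3 convention, used for
all internal arithmetic); contig identifiers are scoped per genome. Protein
records are deduplicated to distinct sequences with content-hash identifiers
(SHA-1 prefix), making deduplication deterministic across runs and input
orders; non-coding rows (tRNA/rRNA/pseudogene) are retained for neighborhood
display but excluded from search. Persistence is a single SQLite file with a
schema-version check; TSV exports exist for interchange. Metadata is
authoritative for quality fields (the package does not recompute CheckM-like
metrics from the annotation).

Search results are expanded to (subject protein, genome) pairs before
ranking, because one distinct sequence may occur in several genomes and all
per-genome analyses (prevalence, co-occurrence, collapsing) need the genome
identity; the hit-list cap of #genomes applies after expansion.

## Quality gate and representative selection

The gate applies, in order: completeness ≥ 90, contamination ≤ 5, not
chimeric, isolate-or-MIMAG-high-quality, has genes, ≥ half protein-coding;
the reported reason names the first failing rule. Selection sorts each genus
(or species) by the preference tuple (RefSeq, type species, species
representative, 2·contamination − completeness ascending, important strains,
largest scaffold descending) and appends the assembly id as a final
lexicographic tiebreak — the stated preference list is not total, and the
tiebreak makes selection a pure function of the metadata, invariant to input
order. Comparisons are exact arithmetic on the given values; no rounding.

## Clustering and clustered search

Greedy incremental clustering processes proteins longest-first (ties by id);
each protein joins the first existing cluster, in creation order, whose
*representative* it matches at ≥ 70 % identity with the alignment covering
≥ 90 % of both sequences, else founds a new cluster. First-fit (not best-fit)
mirrors the greedy behavior of the production clustering tool and is
deterministic. Clustered search then runs in three stages: (1) direct search
against representatives only; (2) expansion of each hit representative to
its full membership, candidates ordered by stage-1 score (members in cluster
order) and truncated at max(#genomes, 200) — when the cap binds this keeps
the strongest families, a choice the workflow leaves open; (3) re-alignment
of the query to every candidate, E-filtering, and ranking exactly as the
direct path.

## Neighborhoods

The view extracts genes overlapping ±10 kb around each anchor (the window is
a package default — configurable — as the production view does not state
one), mirrored so the anchor points right. Visible proteins are grouped by
single-linkage over links with ≥ 50 % coverage of both sequences, links
applied in bit-score order so grouping is input-order independent; the
greedy grouping used in production is unspecified between single-linkage and
representative-based, and single linkage was chosen as the more inclusive
reading. Multi-member groups receive styles from a fixed sequence of 11
colors × 3 hatch states (33 styles, cyclic reuse afterwards), the query
group is white, and singleton groups are neutral gray so they do not consume
styles. Same-species rows whose anchors share a cluster collapse to the
best-scoring member. Gene spacing is start₂ − end₁ − 1 (0 = abutting,
negative = overlap).

Guide trees are neighbor joining (scikit-bio, negative branch lengths
clamped to zero) on distances 1 − fractional identity of pairwise local
alignments restricted to each homolog's query-similar region, then midpoint
rooted; this replaces the external MSA + approximate-ML programs of the
production system to stay dependency-free, at the cost of tree quality on
distant homologs. After rooting, children of every node are ordered by best
descendant bit score, so the best homolog is the first leaf. Homolog
sampling (top / random over all / random over good) is seeded and without
replacement.

## Taxonomic profile

Hits, optionally filtered to potential orthologs or good homologs, are
aggregated at a chosen rank keyed by the full lineage prefix (so label
collisions across higher taxa never merge). A genome counts once regardless
of hit multiplicity; per-taxon max ratio is the best score ratio among its
hits. Taxa present in the database without hits are listed with zero counts
(absence is informative) unless suppressed.

## Co-occurrence

Per genome, the best (lowest-rank) hit of each query gives the score-ratio
pair; a missing side is an absent marker (plotted below zero). *Nearby*
means some homolog gene of each query on one contig and strand with ≤ 5000 bp
(inclusive; overlap = 0) between nearest ends; *fused* means one protein is
the best hit for both queries.

The threshold statistic: a genome is "present" for a query at rank threshold
k iff its best hit has rank ≤ k, with one k shared by both queries. The 2×2
table over **all** database genomes (including genomes hit by neither — the
universe choice is the package's, made explicit so it can be audited) is
scored with the one-sided (enrichment) hypergeometric tail; one-sided
because the statistic exists to detect co-occurrence. Candidate thresholds
are exactly the ranks where either hit list gains a genome — the table is
piecewise constant between them, so scanning candidates equals scanning all
ranks, which tests verify against a literal brute force. Ties take the
smallest k. The minimum P is Bonferroni-multiplied by the number of
candidates (capped at 1). Empty hit lists yield a defined result with
corrected P = 1. The two-threshold optimization of partial phylogenetic
profiling is deliberately not implemented.

## Evaluation harness

Sensitivity of one search path against another is the miss rate by reference
rank: the reference universe is hits with E ≤ 10⁻⁵ and rank ≤ #genomes/2
(hits further down are unlikely to be orthologs), optionally restricted to
potential orthologs or additionally score ratio ≥ 0.3; a reference hit is
missed iff its (query, subject protein) pair is absent from the test
results — scores are never compared. Misses are binned in windows of 50
ranks. Benchmark queries are a seeded uniform sample of database proteins.

## Synthetic data generator

The generator emulates exactly the structure the machinery exploits:

* **Taxonomy**: a balanced hierarchy (phyla × genera × species × genomes per
  species); the order-level benchmark default is 8 genera × 3 species × 8
  genomes = 192 genomes with ~150 families — the redundancy regime clustered
  search targets.
* **Families** evolve root → phylum → genus → species → genome by
  substituting an exact fraction of positions per branch (replacements
  always differ), so identity ground truth is exact and there are no indels
  by default — which also means all family alignments are full-coverage, and
  the coverage-based filters rarely separate subsets on synthetic data.
  Divergence defaults (phylum 0.22, genus 0.16, species 0.05, genome 0.02)
  were chosen once so adjacent taxonomic levels land on opposite sides of
  the field's thresholds: within-species pairs ≈ 96 % identity, within-genus
  ≈ 86 % (above the 70 % clustering gate), cross-genus ≈ 54 % (clearly below
  it, clearly still a homolog), cross-phylum near the detection floor.
* **Layout**: genes are placed on 1–2 contigs with intergenic gaps of
  50–400 bp; operon groups sit adjacently on one strand with 20–200 bp gaps.
* **Implanted pair**: two extra families follow a joint-presence design
  (default 30 genomes with both, 30 with neither); in 90 % of carrier
  genomes the pair is adjacent on one strand (nearby by construction), in
  the rest the two genes are forced onto opposite strands so the proximity
  ground truth is unambiguous. Implant families evolve at 0.3× the
  background rates — functionally coupled genes are conserved, and it keeps
  every carrier's copy detectable so presence/absence matches the implant
  design exactly.
* **Metadata**: quality fields pass the gate by default; a configurable
  disjoint fraction of genomes is made to fail each named rule, recorded in
  the ground truth.

Generation is driven by a single seeded NumPy generator with sorted
iteration everywhere, so output files are byte-identical for a fixed
configuration. What the generator does **not** emulate: indel evolution
(an alignment-defined indel mode is a stress-test option), compositional
bias, codon-level models, rearrangement, HGT, and unbalanced taxonomies —
so passing tests demonstrate the machinery's correctness on clean
phylogenetic signal, not robustness to those real-data complications.

## Problem sizes and numerical choices

The benchmark sizes used by the test suite and the acceptance script — 192
genomes / ~19 k proteins for the clustered-search comparison with 50 random
queries, 60 genomes for co-occurrence instances, 500 null pairs at 200
genomes for type-I error, 20 seeded clustering fixtures, 50 random guide
trees — are the package's desk-scale choices: large enough that the
properties are non-vacuous (the search comparison covers several thousand
reference hits), small enough to run in minutes on one CPU. Determinism
contracts are exact (byte-level); floating-point cross-checks against
independent oracles use relative tolerances of 1e-9..1e-12; the midpoint
property is checked to 1e-9 absolute. Sort orders are always total (score,
then E, then subject id, then genome id) so results never depend on
insertion order.

## Known limitations

* E-values are approximate for biased-composition queries (no compositional
  adjustment) and the Karlin–Altschul constants are fixed rather than
  estimated per scoring variant.
* The clustered search can in principle miss a homolog whose cluster
  representative scores below the E cutoff for the query; measured on the
  redundant benchmark this loss is ≤ 1 % of potential orthologs and usually
  zero.
* Guide trees from pairwise identities are cruder than ML trees on distant
  homologs.
* The external-engine adapter defines and tests the split-align-merge
  contract but no engine is bundled; without one it raises rather than
  silently substituting the internal kernel.
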