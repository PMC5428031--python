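# Methods

This note documents the models, conventions and numerical choices behind
`cazytraits`, and what the synthetic-data tests do and do not demonstrate
about real genome surveys.

## Annotation model

The pipeline consumes HMMER3 `hmmscan` per-domain tables rather than running
the scan itself: proteins are queries, profile HMMs are targets, so the
target-length column is the profile's match-state count and the envelope
columns locate each hit on the protein. Pooled multi-genome tables are
supported through an extended dialect with one extra leading genome-id
column; otherwise the genome id is supplied per file.

A two-stage scan design (a custom database of diagnostic families followed by
a confirmation scan against all of Pfam) is represented by a single parse of
a full-database table plus a **domain registry** that classifies every
family:

* *target-catalytic* — the sixteen accessioned GH/AA families whose
  substrate traits the survey quantifies, plus GH19 (a chitinase family with
  no available profile HMM; it ships accession-less and aggregates to zero
  unless the user configures one);
* *accessory-CBM* — carbohydrate-binding modules (CBM1, CBM10, CBM18, CBM19,
  CBM20, CBM5/12, CBM4/9, CBM-X2), shipped by name with configurable
  accessions;
* *other-catalytic* — catalytic partners observed fused to the targets
  (GH3, GH13, GH25, GH81, GH114); they make a protein multi-activity but
  carry no substrate trait;
* *other* — any family a scan reports that the registry does not know;
  such hits are kept, so unexpected fusion partners surface naturally.

Accession lookup takes priority over names (accessions are stable across
Pfam releases); version suffixes (`PF00150.17`) are stripped; names are
case-sensitive. AA10's dual cellulose/chitin substrate is carried as an
annotation on the LPMO trait, never double-counted.

## Retention filter

A hit is retained iff its **independent per-domain E-value** is ≤ 1e-5
(inclusive — the per-domain statistic, not the full-sequence E-value, because
the decision is made per domain) **and** its profile coverage
`(hmm_to − hmm_from + 1) / profile_length` is **strictly** greater than 0.5.
Coverage is measured on HMM coordinates against the profile length, so a
fragment matching half a model is rejected regardless of score. Both
thresholds are configurable (`--evalue-max`, `--coverage-min`).

Overlapping retained hits on one protein are thinned greedily: candidates are
visited by ascending i-E-value (ties: higher bit score, then lower envelope
start, then family name) and accepted unless their envelope overlaps an
already-accepted domain by more than 50 % of the shorter envelope
(`--max-overlap-frac`). Greedy best-E-value-first tiling is standard practice
for domain annotation; whether the original survey design resolved co-located
hits at all is not specified, so the tolerance is explicit configuration
rather than a fixed rule. The procedure is idempotent and its output is
ordered N→C.

## Architectures and counting conventions

An architecture is the envelope-ordered family list of a protein's retained
domains, encoded with maximal consecutive runs collapsed as `k(NAME)` for
k ≥ 2 and joined by ASCII hyphens (the decoder also accepts en/em dashes,
which printed tables mix in). Non-adjacent repeats are never merged. The
codec is exactly invertible on canonical strings.

Counting rules, chosen once and applied everywhere:

* A protein enters study tables only if it carries ≥ 1 target-catalytic
  domain; accessory or unknown domains never create entries alone.
* All frequency numerators are **domain** counts (`2(GH5)` adds 2), because
  the trait being measured is catalytic capacity; protein-based counts are
  emitted alongside for inventory-style tables.
* Per-family protein attribution: a protein containing family F counts once
  for F, so a GH10–GH11 fusion appears under both families.
* "Percent single-domain" for a family = share of proteins containing the
  family whose total identified-domain count is 1. The alternative
  denominator (domains of the family) is not used; this definition matches
  the protein-centric reading of the published inventory.
* *multi-domain*: ≥ 2 domains of any category; *multi-activity*: ≥ 2
  catalytic domains (target or other-catalytic, so a chitinase–lysozyme
  fusion qualifies); *hetero-activity*: ≥ 2 distinct catalytic families.

Trait frequency is `1000 · domain count / predicted gene count` — domains per
1,000 predicted genes — which decouples repertoire size from genome size.

## Comparative statistics

**Correlations.** Trait-vs-trait correlations are computed on per-genome
frequencies; trait-vs-genome-size on raw counts against the predicted gene
count (both bases are available via a flag — published tables do not state
the basis, so the choice is explicit). Spearman uses tie-corrected ranks;
both coefficients come from SciPy and are cross-checked in the tests against
brute-force rank/moment implementations to 1e-12. Constant variables yield
NA with a warning rather than a spurious coefficient.

**Conservatism.** For each rank from subphylum to species, each taxon with
more than one genome, and each trait: mean, sample standard deviation (n−1
denominator, the R convention), and CoV = sd/mean (NA when the mean is 0).
Frequencies, not raw counts, are the default basis so that genome size does
not masquerade as conservatism. CoV is scale-invariant, which the tests
assert exactly.

**Clustering.** Genome × feature count matrices are built in three spaces:
family, trait, and architecture (full strings, accessory domains included).
Distances default to Bray–Curtis — the conventional community-ecology metric
for non-negative abundance data, matching the vegan-style analysis stack this
workflow comes from — with Euclidean and presence/absence Jaccard
selectable. A pair of all-zero rows has undefined Bray–Curtis distance and is
defined here as 0 (identical emptiness) with a warning. Clustering is
UPGMA (average linkage) on the condensed distance matrix; labels are sorted
before linkage so identical matrices give identical merge heights regardless
of row order; trees are serialized as Newick via scikit-bio.

**Mantel test.** The statistic is the Pearson correlation of lower-triangle
distances; significance is one-sided (greater), permuting one matrix's rows
and columns jointly with a seeded NumPy generator, and
`p = (1 + #{r* ≥ r}) / (permutations + 1)` with 999 permutations by default.
The implementation is in-package so that the permutation scheme and seeding
are fully specified; tests cross-check the statistic against
scikit-bio's Mantel and verify that under independent matrices the test
holds its nominal type-I error (binomial 95 % CI over 200 replicates).

## Synthetic-data generator

The generator emulates the design of a ~200-genome fungal survey. Defaults:
218 genomes; gene counts uniform in 5,000–20,000; planted trait means of
1.5 (cellulase), 0.4 (xylanase), 1.0 (chitinase) and 0.8 (LPMO) domains per
1,000 genes — cellulases around 0.15 % of genes and chitinases around 0.1 %
being the typical observed levels, xylanases sparse, LPMOs intermediate;
trait frequencies conserved at the **genus** rank with 5 % within-clade and
60 % between-clade coefficient of variation (traits are observed to be
conserved at roughly genus/family level, and highly variable across
subphyla); 30 % decoy hits.

Mechanics worth knowing when interpreting tests:

* A balanced ranked taxonomy (branching factors configurable per rank;
  2-2-2-1-2-2-2 by default) is filled contiguously, so multi-genome taxa
  exist at every rank. Each conserved-rank clade draws mean-1 lognormal
  factors for its trait means; genomes multiply in their own within-clade
  factor. Counts are then **planted** as `round(freq · G / 1000)`, so the
  recorded per-genome truth is exact, not sampled — recovery must have zero
  error, and across genomes the mean frequency approaches the configured
  means.
* Architectures are drawn from a grammar: per-trait family weights
  (proportional to the observed dominance of GH5/GH10/GH18/AA9), CBM
  attachment probabilities at either terminus, a multi-activity gate with
  tandem-repeat length options and hetero-fusion partners (GH5+GH6,
  GH10+GH11, GH25 runs before GH18). Envelopes are emitted disjoint and in
  architecture order, with hmm spans drawn at 62–100 % of fixed per-family
  profile lengths (simulator internals, not claims about real Pfam models)
  and i-E-values at 1e-6 or below, so every planted hit passes the filter.
* Decoys fail **exactly one** predicate — E-value decoys draw i-E-value
  > 1e-5 with passing coverage; coverage decoys draw 20–50 % coverage with
  passing E-value — and are recorded in the truth file, half attached to real
  proteins and half on otherwise-empty proteins.

What passing tests therefore show: the filter implements its predicates
exactly; assembly reconstructs architectures from coordinates; counting and
normalisation are correct; the conservatism and Mantel machinery detect
planted structure. What they do not show: robustness to realistic E-value
distributions near the threshold, overlapping ambiguous hits from homologous
profiles, fragmented gene models, or taxonomic misannotation — real surveys
should treat borderline hits and unusual architectures with the same manual
scrutiny as any HMM-based annotation.

## Problem sizes and determinism

Everything is seeded: the generator from `SyntheticConfig.seed`, the Mantel
permutations from an explicit seed, and property tests are derandomised. The
default test suite runs twenty 20-genome end-to-end studies, a 200-replicate
Mantel type-I simulation (n = 20, 199 permutations), and 10,000-case codec
checks; the acceptance script runs the generator at its full 218-genome
default. These sizes keep the whole suite under a minute while leaving the
statistical assertions well-powered; all are the package's own defaults and
can be scaled up freely.

## Known limitations

* GH74 cellulases and AA13 LPMOs have no profile HMM in the registry (none
  is available in Pfam); like GH19 they can be added via a registry override
  once a profile exists.
* CBM accessions are not shipped (the registry carries CBM families by name
  only); for real scans the user must configure the accessions of their Pfam
  release.
* Overlap resolution is not clan-aware: two profiles from the same Pfam clan
  hitting the same region compete only through the envelope-overlap rule.
* The generator does not simulate amino-acid sequences or realistic score
  distributions; it plants coordinates and E-values directly.
* Bray–Curtis on architecture space treats every distinct string as an
  unrelated feature; near-identical architectures (e.g. differing by one
  CBM) share no credit.
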