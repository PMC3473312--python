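# Methods

## Scope and data model

`orthoprof` implements a K-proteome comparative-genomics workflow:
all-vs-all local alignment, reciprocal-best-hit (RBH) orthology,
species-presence classification into the 2^K − 1 organism subsets,
coverage curation, family presence/absence profiling, distance-based
phylogeny with bootstrap, and hypergeometric term enrichment with
process-class overlap accounting. Proteomes are FASTA (one file per
organism, id = first header token); hit tables are BLAST outfmt-6
compatible with three native extras (query coverage, query length,
subject length); all other tables are TSV; trees are Newick.

## Alignment and statistics

The search engine is exact Smith–Waterman with affine gaps rather than a
seeded heuristic: at the scale this package targets (tens to a few
thousand proteins) exactness and determinism are worth more than BLAST's
speed, and external BLASTP tables can be substituted where real proteomes
demand it. The dynamic programming is Biopython's `PairwiseAligner`
(C Gotoh implementation, local mode); a gap of length g costs
open + g·extend. Defaults: BLOSUM62, open 11, extend 1. The ambiguity
residue X is rescored to 0 against everything, so unknown residues are
neutral and can never create signal.

Raw scores are normalized to bits with fixed Karlin–Altschul parameters
λ = 0.267 and K = 0.041 (the standard ungapped-approximation constants for
BLOSUM62/11/1). These are not estimated from the data; E-values are
therefore approximate, which is acceptable because they are used only for
thresholding (default E ≤ 10⁻¹⁰) and for ranking within one target
organism. The search space for a hit is m·n with m the query length and n
the total residue count of the *target organism's* proteome —
per-organism normalization keeps best-hit ranking scale-consistent when
proteome sizes differ by an order of magnitude.

The all-vs-all search computes each unordered pair once (the score is
symmetric) and emits both directed rows when each direction's E-value
clears the cutoff. A k-mer prefilter (skip pairs sharing fewer than 2
distinct exact 4-mers) is on by default; it is purely a speed device and
its equivalence to the exhaustive search on the standard benchmark is
asserted in the test suite.

## Orthology and curation

Best hit per (query, target organism): minimal E-value, ties broken by
higher bit score, then lexicographically smaller subject id — fully
deterministic. A protein's category is its own organism plus the organisms
of its RBH partners; categories therefore always contain the protein's own
organism and partition the database. With paralogs (more than one family
member per organism) RBH recovers at most one partner per organism; the
category — presence, not copy number — is still correct, and this is the
intended behavior.

Coverage curation mirrors a post-hoc manual step applied to pair
categories: within the scoped categories (default: all two-organism
categories; `scope="all"` applies it uniformly), a protein is rejected
when a supporting best-hit alignment spans less than `min_cov` (default
20%) of **the protein's own sequence**. This targets the domain-only
match: a protein that shares merely a small region with its putative
ortholog is not a full-length ortholog. The orientation of the coverage
test (the protein's own span, i.e. query coverage of its own supporting
hit) is a design choice — sources describing such filters rarely state
query vs subject — and is exercised by the generator's planted partial
homologs (below).

## Synthetic proteomes

The generator defines the conditions under which the pipeline is tested.

* **Substitution model.** One ancestral sequence per family; each member
  evolves independently over a branch of length d (expected substitutions
  per site): every site substitutes with probability 1 − e^(−d), the
  replacement uniform over the other 19 residues. The model is chosen for
  its exact closed forms: the one-branch differing fraction is 1 − e^(−d),
  and two members at branch length d each differ in expectation by
  1 − (1−p)² − p²/19 with p = 1 − e^(−d). Both are asserted in tests
  within Monte-Carlo error. There are no indels.
* **Defaults.** Ancestral lengths uniform on 250–350 residues; divergence
  d = 0.15 per branch (≈ 26% pairwise divergence — comfortably detectable
  full-length orthology, far above decoy noise); uniform residue
  frequencies (BLOSUM62 marginals available); one member per organism in
  the standard benchmark; 5 unrelated decoys per organism.
* **Partial homologs.** Since there are no indels, the coverage filter is
  exercised by "fragment" families: one organism's member is planted as a
  full evolved copy embedded in unrelated sequence so the homologous
  region is 15% of the planted protein's length — below the 20% curation
  floor. Its full-length partner aligns over its entire own sequence and
  must survive curation; the partial homolog must not.
* **Standard benchmark.** Four organisms, one family per non-empty
  organism subset (15 families, all categories populated), three extra
  pair-pattern fragment families, 5 decoys/organism: 58 proteins.
* **Annotations.** Planted enriched terms annotate a chosen subset at a
  high rate (power analyses use 0.9 against a 0.05 background over a
  400-protein universe, subset 20; the pipeline demo plants a fully
  penetrant term on the 5-protein pair sample, since at n = 5 a 90%-rate
  term has no power at p < 10⁻⁴).
* **Determinism.** One root seed; child streams are derived per family
  (`[seed, 1, i]`), per organism's decoys (`[seed, 2, j]`), and for
  annotations (`[seed, 3]`), so adding decoys or annotations never
  perturbs family sequences. Identical config reproduces byte-identical
  files.

What the generator does **not** emulate: indels and alignment ambiguity,
domain shuffling, compositional bias, rate heterogeneity across sites,
many-to-many orthology after duplication/loss. Passing tests demonstrate
correctness of the inference machinery under planted truth, not
performance on real proteomes, where divergence, fragmentary gene models
and domain-level homology are all harsher.

## Phylogeny

Distances are observed divergence (p-distance) over the selected alignment
column slice with pairwise gap deletion; the Kimura protein correction
d = −ln(1 − p − p²/5) is optional and errors loudly on saturation
(p ≳ 0.85), naming the offending pair. Neighbor joining is the standard
Saitou–Nei algorithm with the Q-criterion; ties in pair selection are
broken lexicographically by cluster label (a cluster is labelled by its
smallest leaf), so the tree is a deterministic function of the matrix.
Negative intermediate branch lengths are clamped to zero with the deficit
shifted to the sister edge. On additive matrices NJ recovers the
generating topology and branch lengths to 1e-9 (property-tested on random
trees, and cross-checked against scikit-bio's independent implementation).

Bootstrap resamples slice columns with replacement, rebuilds distances and
the tree, and scores each reference bipartition by the fraction of
successful replicates containing it; replicates whose distance computation
fails (saturation) are recorded and excluded from the denominator. The
default flag threshold is 0.70. Newick output writes branch lengths to 12
significant digits and supports as internal labels with shortest
round-trip formatting, so parse(write(t)) reproduces lengths within 1e-9
and supports exactly.

## Enrichment

The hypergeometric upper tail is computed by `scipy.stats.hypergeom.sf`
(log-space internally) and is checked in tests against exhaustive draw
enumeration for every parameter combination with N ≤ 12. Defaults follow
the analysis this package supports: raw p < 10⁻⁴ (no multiple-testing
correction; Benjamini–Hochberg available behind a flag, off by default)
and a retention floor of k ≥ 3 sample proteins, with a strict k > 3
reading available (`strict_min`) because both conventions occur in
practice. Process classes are taken from the term table (three core
classes plus "other"); manual overrides replace — not merge with — the
computed class set, modelling curated reassignment. The overlap report
asserts its own inclusion–exclusion identity (multi-class total =
pair-exclusive counts + triple count) and the partition of the sample into
single-class / multi-class / other / unknown before returning.

## Pipeline

Stages run in a fixed order (simulate/ingest → search → classify → curate
→ profile → tree → enrich → report). The organism-level tree is NJ on
Jaccard profile distances; an alignment-based domain tree with bootstrap
runs when an aligned FASTA and column slice are configured. The enrichment
sample is the largest pair category (the planted pair on the synthetic
path). A manifest records configuration, seed, per-stage row counts and
SHA-256 hashes of every output; reruns with identical config and seed are
byte-identical. The CLI mirrors the library one stage per subcommand; exit
codes are 0 (success), 2 (invalid input), 3 (stage failure).

## Problem sizes

The test suite and acceptance script run the full benchmark (58 proteins,
~1 600 cross-organism pairs), 200 alignment-oracle trials at lengths ≤ 6,
all ~3 200 hypergeometric parameter combinations with N ≤ 12, 100 random
additive matrices of 4–8 leaves, 100 enrichment replicates at 20/400, and
a 100-replicate bootstrap on a six-taxon 500-column alignment — a few
seconds end to end on one CPU. These sizes were chosen as the smallest at
which each property is non-trivially exercised.

## Known limitations

* E-values use fixed ungapped Karlin–Altschul constants; absolute values
  are approximate (thresholding and ranking are what matter here).
* RBH is one-to-one per organism pair: in-paralogs and many-to-many
  ortholog groups are out of scope.
* No indel evolution in the generator, hence no alignment-uncertainty
  stress on the aligner.
* The Kimura correction saturates near p ≈ 0.85; deeper divergences need
  model-based distances this package does not provide.
* Figure-level subfamily "types" within a family are consumed from the
  assignment table, never inferred from sequence.
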