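# Methods notes

This note records the model, the parameters that matter, the numerical
choices, and what the synthetic fixtures do and do not demonstrate.

## The D2S dissimilarity

Each genome view is reduced to a table of k-mer counts X_w (packed 2 bits
per base, so k ≤ 31; windows containing any non-ACGT symbol are skipped
whole, with no expansion of IUPAC ambiguity codes) plus an order-0
background: the empirical A/C/G/T frequencies of the scanned text and the
number of scanned window positions n. With the default strand policy
`both`, the reverse complement of every segment is scanned as an additional
strand — counts, n, and background frequencies all come from the same
doubled text, so the background model always matches the counting process,
and tables are invariant to the arbitrary assembly strand of each isolate.
`forward` is available for comparisons against single-strand oracles.

Counts are centered, X̃_w = X_w − n·p_w with p_w the product of the
genome's own base frequencies over the word's letters, and combined as

    D2S = Σ_w X̃_w Ỹ_w / √(X̃_w² + Ỹ_w²)
    dissimilarity = ½ (1 − D2S / √(A·B)),
    A = Σ_w X̃_w² / √(X̃_w² + Ỹ_w²),   B = Σ_w Ỹ_w² / √(X̃_w² + Ỹ_w²)

Terms with X̃² + Ỹ² = 0 are skipped; the result is clamped to [0, 1]
against floating-point drift. Words are processed in sorted packed order,
so accumulation order — and hence the double-precision result — is
identical across runs for a fixed input.

**Word space.** By default the sum runs over the union of words observed in
either genome. Words observed in neither contribute only
product-of-expectation terms, but those terms carry essentially the whole
background probability mass and are *not* negligible in aggregate: summing
over all 4^k words (`word_space="exhaustive"`, feasible for k ≤ 12) yields
a systematically different — compressed — statistic (unrelated genomes land
near dissimilarity 0.3 rather than 0.5). The two spaces are therefore
distinct estimators, not approximations of one another. The pipeline
standardizes on the observed-union sum, whose behavior anchors the distance
scale below; the exhaustive mode exists so that the optimized path can be
checked to 1e-9 against a brute-force enumeration oracle in the same space.

## Distance and similarity scale

Under the observed-union statistic, identical k-mer contents give
dissimilarity 0 and genomes sharing *no* k-mers give dissimilarity ≈ 0.5:
the centered count vectors of unrelated genomes are essentially
uncorrelated, and at k = 25 expected counts n·p_w ≈ 10⁻¹¹ make every
observed word's centered count ≈ its raw count. This pins down the distance
scale: the default transform is linear,

    d = 20 · dissimilarity,   S = 10 − d,

which places "no shared k-mers" exactly at the d = 10 edge-filter boundary.
Pairs with d > 10 (anti-correlated beyond noise, i.e. sharing nothing) are
dropped from all edge lists, so retained similarities span S ∈ [0, 10],
with S = 9.999 for near-identical genomes (d = 0.001) and S = 0.075 for
nearly disjoint ones (d = 9.925). A logarithmic alternative
d = −ln(1 − dissimilarity) (capped at d_max = 100) is available via
`transform="log"` for workflows that want unbounded growth near
dissimilarity 1, but note that with this statistic realistic genome pairs
never approach dissimilarity 1, which is why it is not the default. The
transform in force is recorded in every edge-list header.

Genomes with identical k-mer contents (distance exactly 0, e.g. re-deposited
assemblies) are collapsed before pairwise comparison; the lexicographically
smallest isolate id represents the group and the kept→dropped map is
reported.

## Genome views

Four views per isolate: `whole` (chromosomes + plasmids verbatim),
`no_rrna`, `rrna_only`, `plasmid_only`. rRNA intervals come from
annotation only (never inferred); overlapping intervals are unioned before
excision; the flanking segments of an excision are kept as separate
sequences and never re-joined, so no artificial junction k-mers can arise —
the `no_rrna` and `rrna_only` views partition the annotated genome's
sequence exactly, which is asserted by tests. rRNA genes on plasmids are
excised like chromosomal ones, and `no_rrna` includes plasmid components by
default (a `chromosomes_only` flag restricts it). Feature strand is ignored
for excision: the interval on the component is what is removed. Internally
all coordinates are 0-based half-open; GFF3's 1-based inclusive convention
is converted at the I/O boundary. Isolates without any annotation cannot
produce rRNA-dependent views and raise `AnnotationMissing`; isolates
without plasmids yield an empty `plasmid_only` view and are dropped from
that network.

## Networks and statistics

Edges with S ≥ t form the I-network (the `strict_threshold` flag switches
to S > t); all deduplicated isolates remain as nodes so singleton counts
are meaningful. Statistics per threshold: c = nodes with ≥ 1 edge,
D = y/(x(x−1)/2) (undefined and an error below 2 nodes), z = largest clique
size (exact branch-and-bound), n = number of maximal cliques on ≥ 3 nodes
(a triangle, with its three edges, is the smallest counted clique).
Maximal cliques are enumerated with Bron–Kerbosch with pivoting; past a
configurable budget (default 5×10⁶ cliques) n is reported as unavailable
("NA" in tables) rather than raising — on very dense graphs the count is
impractical while z remains computable. c, D and z are non-increasing in t
because edge sets are nested; n is not monotone (breaking one large clique
can create several smaller maximal ones).

The P-network aggregates I-network edges by phylum, with Proteobacteria
split into its classes (taken from the `class` column of the taxonomy
table). Cross-phylum edge weights g count connected isolate pairs;
within-phylum counts are node metadata, not self-loops. Connectedness
C_ab = g/(N_a·N_b) is restricted to phyla with ≥ 10 genomes (configurable)
to avoid small-sample artifacts; the matrix diagonal holds the
within-phylum analogue g_aa/(N_a(N_a−1)/2). Networks serialize to
D3-force-layout JSON (`nodes`/`links`, keys sorted) and read back
losslessly.

## Core k-mers and COG enrichment

The core of a taxon group is the intersection of member word sets; K =
|core| / |isolates|. An empty core is a legitimate result for divergent
groups. Core words are annotated through a location index (word →
occurrences with gene features overlapping by ≥ 1 base): per word, the COG
letters of all overlapping CDS features across all member genomes are
collected, each (word, letter) pair counting once — profiles count core
k-mers, not occurrences. A word whose occurrences touch both a CDS and an
rRNA gene counts as protein-coding (any CDS overlap qualifies); words with
no CDS overlap go to an `unannotated` tally. Multi-letter annotations
("EC") are split per character.

Enrichment contrasts each phylum's annotated core words against the pooled
annotated core words of all other phyla, category by category, with a
one-sided (greater) Fisher exact test — the question is enrichment;
two-sided is available. Benjamini–Hochberg correction spans the entire
phylum × category family as one batch, the conservative choice. Categories
R and S (noninformative) are removed before testing; phyla with zero
annotated core words are skipped with a warning.

## The simulator

`simulate()` draws a random root genome, mutates it once per clade at the
between-clade rate to make clade ancestors, and mutates each ancestor once
per isolate at the within-clade rate. Substitutions are i.i.d. per site and
always change the base, so the expected number of surviving ancestral
k-windows is exactly (L−k+1)(1−r)^k and every fixture expectation can be
derived in closed form. Optional structure: a conserved block at a fixed
locus evolving at its own (tiny) rate and annotated as rRNA; plasmids from
a common plasmid ancestor, restricted to configured host clades; lateral
transfers that overwrite a recipient segment with the donor's bytes after
mutation. CDS features are tiled over non-rRNA sequence with COG letters
drawn from a seeded Dirichlet-multinomial over the 23 informative
categories (R/S added occasionally so their exclusion is exercised; Y never
occurs). Everything is reproducible byte-for-byte from the seed.

Default conditions — 3 clades × 10 genomes × 10 kb, within-clade rate
0.001, between-clade 0.08 — were chosen from the closed form so that the
fixture spans the similarity scale end to end at k = 25: within-clade pairs
share ≈ (0.999²)²⁵ ≈ 95% of windows (S ≈ 9.4) while cross-clade pairs share
≈ (0.92²)²⁵ ≈ 1.5% (S ≈ 0.1, just inside the d ≤ 10 filter). Consequently
the I-network is a single component at t = 0 and splits into exactly the
three clades from t = 1 up through t = 9. The `structured` preset adds a
1500-nt conserved block (rate 5×10⁻⁴) and 2000-nt plasmids (rate 0.05,
clade-A hosts only), sized so that at t = 3 the rRNA-only network is
complete, the plasmid network is empty, and excising the block collapses
cross-clade connectedness — the qualitative signal-decomposition ordering
the pipeline is meant to expose.

What the simulator does *not* emulate: indels, rearrangement,
recombination, rate heterogeneity, codon structure, compositional bias, or
realistic genome sizes. Passing tests demonstrate that the implementation
recovers planted structure under the stated substitution model at 10-kb
scale; they do not validate biological conclusions on real genomes, where
signal strength, annotation quality and genome-size heterogeneity differ.
Problem sizes in the test suite (10-kb genomes, 30 isolates, 50 Monte-Carlo
replicates, 200 null-enrichment replicates) are the package's chosen
desk-scale study conditions; all thresholds and expectations above were
fixed from the closed forms before the fixtures were run.

## Numerical and degenerate-input choices

* Fisher p-values come from the exact hypergeometric computation in scipy
  and are validated against a rational-arithmetic summation oracle to
  1e-10; BH comes from statsmodels and is validated against the textbook
  step-up definition.
* If a genome's centered counts are identically zero (A or B = 0 — only
  possible for degenerate inputs that match their background exactly), the
  dissimilarity is defined as 0.5 (no signal either way).
* Sequences shorter than k yield empty count maps, not errors; empty views
  raise `EmptyViewError` so missing-plasmid isolates are dropped explicitly.
* Duplicate thresholds in a sweep are deduplicated with a warning;
  mixed-k or mixed-strand-policy inputs fail hard (`ConfigMismatch`) at
  every stage boundary.
* The null false-positive behavior of the enrichment battery is checked at
  per-phylum totals of 4000 category assignments, where Fisher p-values are
  effectively continuous; with small discrete tables the test is
  conservative (rates below alpha), which is inherent to exact tests.

## Known limitations

* The observed-union D2S is a different estimator from the exhaustive-space
  statistic (see above); results are comparable only within one word-space
  convention.
* The location index is in-memory and suited to desk-scale data, not to
  thousands of complete genomes; the query surface (word → locations,
  genes, COGs) is what matters for core-k-mer annotation.
* Clique counting on dense graphs hits the enumeration budget and reports
  NA by design.
* P-network weights aggregate isolate-pair connections; they are not
  distances between concatenated phylum-level sequences, which would be a
  different (and coarser) construction.
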