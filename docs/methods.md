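# Methods

## Scope and model

`lectinscape` treats a lectin-family survey as a deterministic function
of four inputs: a gene-level genome annotation (GFF3), a protein
domain-hit table, per-protein signal-peptide/transmembrane calls, and a
collinearity file with per-pair Ks values.  Producing those inputs
(BLAST/HMM scans, SignalP, TMHMM, InterProScan, MCScan) is out of
scope; the package consumes their outputs and makes the downstream
bookkeeping — classification, clustering, filtering, attribution —
explicit, configurable and testable.

### Gene order

All neighbourhood reasoning uses **ranks**: within each chromosome,
genes are sorted by start coordinate (ties broken by end, then id) and
numbered 0..n−1.  The number of intervening genes between two genes
with ranks r1 < r2 is r2 − r1 − 1, counted over the *entire*
annotation, not just lectin genes — "ten intervening genes" is a
statement about physical gene neighbourhood.  GFF3 coordinates stay
1-based inclusive.  "Start" means the smaller coordinate; a
strand-aware alternative (`strand_aware_start=True`) is provided
because annotation conventions differ, but the default matches how
gene-position tables are usually exported.  Genes on unmapped
scaffolds keep their family labels and count in totals, but are
excluded from tandem detection and the chromosome map: without a
chromosome they have no neighbourhood.

### Family classification

A family definition is a set of domain accessions plus a reference CRD
length.  Accession sets must be disjoint across families; a violation
is a configuration error, not a tie to break silently.  A gene with
lectin hits from two families is flagged and counted once, under the
family of its best-scoring hit (e-values rank ascending, bit scores
descending, per the config's `score_kind`).  This keeps census tables
additive; a strict mode labels the gene with every matching family for
users who prefer visibility over additivity.  The shipped
`family_definitions.yaml` uses placeholder accessions (`LEC_*`,
`DOM_*`): several CRDs (EUL, Nictaba, CRA) have no public domain-model
identifier and are identified by alignment in practice, so real
analyses must supply their own accession mapping anyway.

Architecture strings are the N→C sequence of tokens: `SP` first when a
signal peptide is predicted, domain tokens in ascending hit-start
order (overlapping hits of the *same* accession merged; overlapping
hits of different accessions both kept), `TM` tokens interleaved at
their amino-acid positions.  A TM segment lying entirely within the
first 30 aa of a protein that also has a signal peptide is suppressed
at read time — hydrophobic signal-peptide cores are a well-known
false-positive mode of TM predictors, and 30 aa comfortably covers
plant signal-peptide lengths.  A domain hit is flagged *truncated*
when its length is strictly below `truncation_fraction` (default 0.75)
× the family reference length; the threshold is configurable because
no sharp biological cutoff exists, only the observation that some
survey families contain clearly sub-length CRDs.

### Tandem duplication

Two genes are tandem-linked iff they share a (primary) family and a
chromosome and have ≤ `max_intervening` (default 10) intervening
genes.  Clusters are maximal transitive chains, so a cluster may span
more than `max_intervening` genes end to end; this is deliberate — a
tandem array grown by repeated local duplication has no reason to fit
inside one window.  The detector is a single linear sweep per
(family, chromosome); tests compare it against an independent
pairwise-link + connected-components oracle, including the boundary
cases at exactly 10 and 11 intervening genes, and verify monotonicity
in `max_intervening`.

### Segmental duplication

A collinear pair is retained iff its Ks is present and ≤ `ks_max`
(default 1.0); *strictly higher* values are excluded because
synonymous sites saturate and the estimate becomes unreliable.  Pairs
without a Ks value are excluded conservatively and counted.  A lectin
gene is segmental when either end of a retained pair is that gene —
collinear blocks pair whole chromosome segments, so the partner gene
need not itself be a lectin.  Genes whose every pair fails the filter
are reported separately (`excluded_gene_count`), mirroring the
bookkeeping a survey needs to explain why genes drop out of the
segmental set.

### Mechanism attribution

tandem ∩ segmental → `both`; differences → `tandem_only` /
`segmental_only`; the complement of the union → `other`.  `other` is a
residual — retrotransposition and mechanisms this pipeline does not
detect are never inferred positively.  The percentage denominator is
the full lectin universe including unplaced genes (they can be
segmental but never tandem).  Percentages are rounded half-up to one
decimal, so the four values sum to 100 ± 0.3; the underlying counts
always sum exactly.

### Maximum parsimony

Fitch small parsimony is computed on bitmask-encoded site patterns
(identical alignment columns collapsed with weights).  Gaps are a 21st
state by default: in domain-level alignments an indel is shared
evidence, not missing data; `gaps_as_missing=True` switches to fully
ambiguous.  The search is branch and bound over stepwise taxon
addition in input order: a partial tree is pruned when its Fitch score
plus a lower bound — one guaranteed change per site for every state
that is the sole possibility of some unadded taxon and cannot occur
among the added ones — exceeds the best complete score (ties are kept,
so all co-optimal topologies are returned, in canonical newick order).
The initial upper bound comes from a caterpillar topology.  The search
is exact and is guarded to ≤ 15 taxa; the intended use is
family-level questions on a handful of domain sequences, and tests
verify exhaustive-enumeration equality for all n ≤ 7 matrices.
Monophyly on an unrooted tree means the taxon subset is one side of
some edge bipartition.

## Synthetic genomes

The generator emulates the statistical structure the pipeline
analyses, at the scale of the soybean survey by default: 20
chromosomes × 500 genes, 53 planted tandem arrays of 2–5 members
spaced 0–10 intervening genes apart, ~170 scattered lectin genes
(family mix proportional to the nine observed family sizes, so total
lectin count lands near 359), 2 unplaced scaffold lectins, and 121
collinear blocks of 3–10 gene pairs, 80% of them anchored to contain
at least one lectin gene.  Domain hits, architectures and SP/TM calls
come from a per-family template catalogue covering the architectures
seen across the families (G-type receptor kinases with S-locus/PAN
domains, hevein–chitinase and hevein–Barwin fusions, triple-jacalin
repeats, F-box fusions, GH5/GH27–ricin B fusions, truncated GNA
domains).  One protein per gene; no isoforms.

Ks is drawn from a two-component lognormal mixture (recent median
~0.15, ancient median ~1.6).  A pair is first assigned its side of the
saturation threshold by a Bernoulli draw with
`fraction_ks_above_threshold` (default 0.16, the order of the excluded
fraction in real soybean data), and the component draw is then
truncated to that side.  The truncation makes the planted
above-threshold count exactly binomial and keeps the mixture's sides
from leaking across the boundary; `theoretical_ks_moments` gives the
resulting truncated-mixture mean/sd in closed form for moment checks.

Planted truth is exact by construction, not by luck: any two
same-family lectin genes belonging to different planted units are kept
at least `max(spacing_max, 10) + 2` ranks apart, so the tandem
detector at its default window recovers precisely the planted arrays —
no accidental links, no merged arrays.  Consequently, on synthetic
data the pipeline's mechanism labels must equal the planted labels
gene for gene, and the tests assert exactly that.

Beyond the spec'd condition fields, the config carries one extra
count, `n_scattered_lectins`, making the non-array lectin budget
explicit (the family-proportion map alone does not determine how many
lectins to scatter).

**What passing synthetic tests does not show:** the generator plants
clean structure.  Real annotations have isoforms, nested and
overlapping genes, fragmented scaffolds, domain hits with fuzzy
boundaries and families whose CRDs resist accession-based detection
(EUL, Nictaba, CRA).  Perfect recovery on synthetic data validates the
bookkeeping — the rules are applied exactly as stated — not the
upstream evidence quality those rules consume.

## Published-table arithmetic

The survey's printed census (nine nonzero families summing to 359
genes) and duplication table (53 clusters, 188 tandem genes across
seven families) ship as in-package fixtures and serve as worked
inputs: feeding the counts through `summarize_families` reproduces
every printed percentage under half-up rounding to one decimal (e.g.
166/359 → 46.2, 3/359 → 0.8), which is how the rounding convention was
fixed.  The printed duplication table's segmental column sums to 188
while the running text reports 166 distinct segmental genes; the
pipeline therefore always reports both the per-family tallies and the
distinct-gene total so such discrepancies stay visible, and no check
is pinned to the inconsistent number.  Genome-scale results (the 359
total itself, per-chromosome shares, the 36.5/36.2/16.2/11.1 split)
depend on a specific assembly plus external scan databases and are not
reproducible from a desk; they are exercised structurally, on
synthetic data and printed-table arithmetic only.

## Numerical and formatting choices

* Rounding is decimal half-up (`round_half_up`), not banker's
  rounding, chosen to reproduce the printed census percentages.
* Localization strings switch to "all except chr N" form when a family
  occupies more than half the chromosome universe (threshold
  configurable); full occupancy prints "all", empty prints "/".
* Collinearity parsing follows the MCScanX dialect: `## Alignment`
  block headers, optional `N-M:` pair indices, Ks as the last numeric
  field; unordered duplicate pairs within a block are dropped keeping
  the first, while the same pair in two blocks is two records (block
  identity matters for block counts).  The dialect is configurable.
* Problem sizes in tests and the acceptance script (chromosomes of
  30–1000 genes, 50–100 oracle trials, parsimony matrices of 4–7 taxa,
  one full-default simulated genome of 10,000 genes) were chosen so
  every oracle comparison is exhaustive or exact at that size while
  the whole suite stays interactive-fast.

## Known limitations

* Family assignment is only as good as the accession config; the
  shipped config is a placeholder vocabulary for synthetic data.
* Tandem detection is rank-based; a physical-distance (bp) variant is
  not implemented.
* The parsimony module is exact-small-scale by design: no heuristic
  search, no bootstrap, no branch lengths.
* SVG renderings of the chromosome map and mechanism bars are not
  produced; the coordinate and summary tables contain everything a
  plotting layer needs.
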