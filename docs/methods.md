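# Methods

This note documents the models, rules and numerical choices behind famkit,
what the synthetic-data generators do and do not emulate, and the design
decisions taken where the underlying analysis conventions are genuinely
open.

## Curation

The redundancy filter operationalizes "keep only the longest of similar
sequences". Records are processed longest-first (ties broken by id); a
record is removed when it matches an already-kept record at global-alignment
identity at or above the threshold (default 0.95). Identity is defined as
identical positions divided by *aligned* (gap-free) columns of a
Needleman–Wunsch global alignment with match = 1, mismatch = 0, linear gap
penalty −1, with a deterministic traceback (diagonal over up over left).
Excluding gap columns from the denominator is deliberate: a sequence that is
a perfect truncation of a longer one — the typical alternative-transcript
artifact this filter exists to remove — scores identity 1.0 rather than
being sheltered by its own missing residues. The scoring scheme itself is
the simplest reproducible way to define which columns are aligned; it is
not meant as a biologically tuned aligner, and the filter is idempotent by
construction. Transcript-evidence screening is supported as an optional
keep-list input rather than re-derived, since it depends on RNA-seq that a
user must supply.

Naming orders placed genes by (chromosome, start coordinate) with
chromosomes sorted numerically (`chr2` before `chr10`), then numbers
unplaced genes last by coordinate; ties on (chromosome, start) fall back to
gene id and are logged. Naming is a bijection onto `prefix001…prefixN` and
invariant to input order.

## Domain conservation and binding rules

Column numbering follows the curated 65-column alignment frame, because
every positional rule in the plant bHLH literature is stated in that frame;
the default region map is basic 1–17, helix 1 18–32, loop 33–47,
helix 2 48–65, and it is configurable. Consensus rates use the
sequence-logo convention: gaps are excluded from the denominator (an
all-gap column gets no category and a warning). A column is `conserved50`
or `conserved90` when its top residue's rate strictly exceeds 0.50 or 0.90;
ties on rate resolve to the alphabetically first residue, which matters
only in degenerate synthetic inputs.

Basic residues are taken as {R, K, H}: the His-9 rule itself treats
histidine as a functional basic-region residue. The classifier tests rules
in a fixed order — non-binder (fewer than six basic residues), then G-box,
then E-box — because a G-box site is a specialized E-box site, so the more
specific call must win. A row satisfying the G-box residues while lacking
Arg-16 is still called `G_BOX` but logged, since the combination falls
outside the usual rule statements. A gap at a rule column simply fails that
rule. The plant-versus-animal comparison takes the reference lineage's
per-column rates as user input and flags columns where the profiled rate
exceeds the reference.

## Phylogeny

Distances are p-distances with pairwise deletion (a Poisson correction
−ln(1−p) is available); a pair with no shared non-gap columns is an error
rather than a guess. Neighbor joining follows Saitou–Nei exactly: at each
step the pair minimizing Q(i,j) = (r−2)d(i,j) − Rᵢ − Rⱼ is joined, with
Q-ties broken toward the lexicographically smallest id pair so runs are
deterministic and input-order independent away from ties. Negative branch
lengths, which NJ can produce on non-additive input, are clamped to zero.
On additive matrices the generating topology and all path lengths are
recovered exactly; this is the main correctness oracle.

Bootstrap resamples alignment columns with replacement, rebuilds the
distance matrix and tree per replicate, and scores each internal edge by
the percentage of replicates containing its leaf bipartition. Supports are
kept in the data regardless of magnitude; the display convention of hiding
supports below 50% is applied only when rendering output. The default of
1000 replicates matches common practice; tests and examples use 50–200
replicates on small alignments, which is sufficient for the properties they
assert.

Subfamily assignment uses labelled anchor leaves (in grape bHLH work,
Arabidopsis members of the 25 named subfamilies). For each query the
smallest edge-induced bipartition side containing the query and at least
one anchor is found; a unanimous anchor label is transferred, a mixed clade
yields `orphan`. Published manual adjustments to subfamily boundaries are
represented by editing the anchor label table, not by code branches, so the
algorithm stays pure.

## Gene structure

Phases are computed on CDS exons only — phase is a codon concept, and UTR
exons would corrupt it. GFF3 `phase` fields are ignored in favour of
recomputation; `validate_gff_phases` cross-checks declared values and
reports conflicts instead of silently trusting either side. First and last
exons are never symmetric, matching the between-two-introns definition.
The summary enforces its own bookkeeping identity
(n_exons = n_introns + n_genes and phase counts summing to the intron
total) as a hard invariant on its outputs; published tallies that violate
the identity are a property of those tallies, not something the summary
tries to reproduce. The symmetry theorem — internal exon symmetric iff its
flanking phases are equal iff its length is divisible by three — is
verified by exhaustive enumeration over all exon-length tuples with at most
5 exons and lengths at most 9 (66 429 tuples).

When a gene carries several mRNAs, the transcript with the longest total
CDS is used, mirroring the keep-the-longest curation; a transcript tie
resolves to the lexicographically smallest transcript id.

## Summaries

An ortholog pair is any cross-species pair of genes co-occurring in one
cluster (so a cluster with a grape genes and b tomato genes contributes
a·b pairs); a paralog pair is any within-species pair (C(n,2) per cluster).
This is the standard reading of pair counts over clustering output;
per-gene best-pair counting is out of scope. The cluster parser enforces
that a gene appears in at most one cluster, which makes the counts
well-defined. Motif universality defaults to carriage by ≥ 90% of family
members (the threshold is configurable, since the convention is usually
stated by example); a motif is subfamily-specific when all its carriers sit
in one subfamily. Duplicate (gene, motif) occurrences are flagged because
conserved protein motifs are expected once per gene.

## Expression screen

The screen encodes "on at and after veraison in black berries, off before
veraison and in white berries" with two RPKM thresholds: on = 5 and
off = 1 by default. The published analyses of this design are qualitative,
so both thresholds are explicit, mandatory parameters everywhere the screen
is exposed; 1 RPKM is the conventional expressed/not-expressed floor and
5 RPKM a conservative "clearly on" level for berry skin RNA-seq. The screen
is threshold-monotone (raising off never removes a candidate, raising on
never adds one), and the expressed-gene count bounds the candidate count
whenever on ≥ expressed-floor; both properties are tested. The heatmap
matrix is log2(RPKM+1) over expressed genes, row-ordered by average-linkage
hierarchical clustering on Euclidean distance — a display convention, not
an inference step.

## Synthetic data

The generators produce the inputs of every stage together with ground
truth computed by logic independent of the module under test: alignment
truth is the planted per-column (residue, rate) map; gene-structure truth
is a cumulative-mod-3 hand oracle over the exon-length tuples; expression
truth is the planted candidate id set; tree truth is the generating
topology with path-length distances. Defaults mirror the study design the
package is built around: 115 members, a 65-column domain, six berry
samples with 6 planted candidates, on/off levels of 20 and 0.2 RPKM
(clearly separated from the 5/1 thresholds so the planted set is
recoverable exactly).

What the generators do not emulate: alignment columns are i.i.d. with a
uniform background over the 19 non-planted residues (no phylogenetic
autocorrelation, no indels, no gap columns); gene models have uniform
random intron lengths and no UTRs; expression noise is uniform scaling
rather than count-based overdispersion. Passing tests therefore show that
the *computations* are correct under known truth, not that real data will
be as cleanly separable; on real alignments the conservation profile and
binding calls inherit whatever ambiguity the alignment has. At planted
rate 0 a column contains no copy of the planted residue at all — the
background explicitly excludes it — so "rate 0" means pure noise, not a
20-residue uniform draw.

## Problem sizes and determinism

Unit and acceptance tests run at the family's own scale (115 members,
65 columns, 8-leaf trees for exact-recovery trials, 20–50 replicate seeds)
and complete in a few seconds; bootstrap examples use a few hundred
replicates on ≤ 8 taxa. All randomness flows through explicit integer
seeds (numpy `default_rng`); every generator and the bootstrap are
byte-reproducible under a fixed seed, and the pipeline manifest echoes the
seed and all parameters so a run can be reproduced from the manifest alone.

## Known limitations

Curation identity uses one fixed alignment scoring scheme; families with
highly divergent termini may warrant a local-alignment notion of identity.
NJ is the only tree method (by design); supports below ~50% on small
alignments are noisy, and the bootstrap rebuilds distances per replicate,
which is quadratic in members per replicate. Subfamily assignment depends
entirely on the anchor table's coverage: a query with no anchored clade in
its part of the tree can only be an orphan. The expression screen has no
replicate-aware statistics because the underlying design has none; it is a
deterministic filter, and its output should be treated as a candidate list
for validation, not a differential-expression result.
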