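# Methods

This note documents the models and procedures implemented in orthosplice,
the parameters that matter, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Local similarity search

The search is a classical seed-and-extend heuristic over a positional
k-mer index.

**Seeding.** Nucleotide subjects are indexed by exact k-mers (default
word size 11); words containing N are skipped. Protein mode indexes exact
3-mers of the subjects and expands each query word into its BLOSUM62
neighbourhood at threshold T = 11, which yields the same seed set as a
neighbourhood index with far less memory.

**Extension.** Each seed is first extended without gaps under an X-drop
rule (default X = 20); a candidate (query, subject) pair survives when its
best ungapped seed score reaches a floor (15 for nucleotide +1/−2, 25 for
BLOSUM62). Surviving pairs are aligned with the exact affine-gap local
(Gotoh) kernel, and further colinear HSPs are extracted by recursing into
the rectangles left of/above and right of/below the best alignment. The
consequence of this design is that *when* the heuristic finds a pair its
score equals the exact Smith–Waterman optimum; heuristic loss can only
come from seeding, which the acceptance checks measure directly (top-hit
agreement with the exact oracle on diverged pairs).

**Scoring and e-values.** Defaults: match +1, mismatch −2, gap cost
`5 + 2·L` for a gap of length L (the first gapped column pays
open + extend); protein mode BLOSUM62 with `11 + 1·L`. E-values use the
ungapped Karlin–Altschul form `E = K·m·n·e^(−λS)` with constants fixed per
scoring scheme (λ = 1.28, K = 0.46 for +1/−2; λ = 0.3176, K = 0.134 for
BLOSUM62) and treated as calibration constants, not recomputed: only the
behaviour of the `E ≤ 1e−10` cutoff matters downstream, and the exact
halving-the-database-halves-E identity is tested. Percent identity divides
identical columns by all alignment columns including gaps; N/X never count
as identical.

**Determinism.** Ties among equal-bit-score hits break by lower e-value,
then longer alignment, then lexicographic subject id, so best-hit maps and
everything downstream are reproducible.

## RBH orthology and the similarity distribution

A pair (a, b) is reported iff b is a's unique best hit and a is b's,
best-by-bit-score under the deterministic tie order (uniqueness is then
guaranteed by construction). The similarity attached to a pair is the
percent identity of the supporting HSP from the a→b direction; the b→a
value agrees within half a percentage point on simulated data, and the
choice is recorded as an assumption (whether a single best HSP or a
combined statistic underlies published "similarity" figures is usually
unstated; single best HSP is used here). Histograms bin at 1% with
similarity 100 folded into [99,100]; the conserved subset is *strictly*
above the threshold (default 93%), by default excluding singleton
fragments, whose similarity reflects only the fragment's local context
rather than the whole gene.

## GO enrichment

One-sided hypergeometric enrichment of a query id set against an annotated
reference superset, AgriGO-style: terms enter the tested family when they
map at least `min_mapping = 4` *query* entries (whether the floor should
apply to query or reference counts is ambiguous in common tool
descriptions; query-side is the default and the reference-side variant is
a flag), p-values are adjusted by Benjamini–Yekutieli — valid under
arbitrary dependence, which matters because GO terms overlap — and
significance is `p_adj ≤ 0.05`. Unannotated reference ids are dropped and
counted. Ontology-ancestor propagation from an OBO file is available but
off by default: flat annotation exports are the common input and requiring
an ontology file would be a gratuitous dependency. The null behaviour
(annotations independent of query membership) is calibrated by simulation
in the acceptance checks; BY is conservative, so the familywise
false-positive rate sits well below the nominal 0.05.

## Transcript-to-model mapping and intron retention

Isotigs are aligned to the genomic sequence of their gene model in both
orientations with the exact local kernel; colinear non-overlapping
alignments come from the same recursive rectangle decomposition as the
search (with an 8-column overlap re-exposed at each split). Every aligned
column is attributed to the feature — exon i or intron j — containing its
genomic position. Two details make the labels crisp:

- *Boundary-spill trimming.* A local alignment occasionally extends a few
  chance matches across a splice junction; terminal runs of ≤ 8 columns
  whose feature differs from the adjacent run are trimmed before columns
  are committed. Genuine feature blocks (exons ≥ 80 nt, introns ≥ 60 nt at
  the defaults) are far longer than the trim window, so real retention is
  never clipped.
- *Column deduplication.* Where overlapping alignments claim the same
  query or genomic position, the higher-scoring alignment wins, column by
  column.

Intron j is called retained when its aligned coverage reaches
`min_coverage = 0.8`. No published threshold exists for
"assigned to introns by position"-style calls, so the value is explicit,
configurable and logged; retention calls are monotone in it by
construction. ORF completeness requires a proper ATG…stop ORF spanning at
least 90% of the mature mRNA's coding length — a quantitative proxy for
"contains the correct ORF". The ORF finder scans both strands, three
frames each, preferring start-to-stop ORFs and falling back to the longest
stop-free stretch when no ATG exists.

## Locus count and chimera inference

For each exon, the exon-overlapping block sequences of all isotigs
(requiring ≥ 50% exon coverage) are clustered by single linkage at
≥ 98% identity; identity is computed as the edit-distance identity of the
shorter sequence aligned *within* the longer (infix alignment), so
truncated blocks of the same variant cluster together. The locus estimate
is the maximum cluster count over exons: 98% separates alleles and
residual noise from paralogs at the few-percent divergence where assembly
confusion actually happens, and is configurable. Cluster labels are
reconciled across exons by co-occurrence with the most discriminating
(anchor) exon; an isotig drawing reconciled labels from two loci across
multi-variant exons is flagged chimeric. The procedure is invariant to
isotig input order. Known limitation: paralogs more similar than the
cluster threshold are indistinguishable from alleles and the locus count
will undercount — transcript data alone cannot resolve that case.

## Nei–Gojobori Ka/Ks

Per codon, the synonymous site count is the fraction of one-step changes
preserving the amino acid (changes to stops are nonsynonymous sites),
summed over positions and averaged between the two sequences; S + N equals
3 × codons exactly. Codon pairs differing at 2–3 positions are scored by
equal-weight averaging over all stop-free orderings of the changes;
pathways through stops are excluded, and a pair whose every pathway hits a
stop is excluded and counted. Columns with gaps, ambiguity codes or stop
codons are excluded. Proportions are Jukes–Cantor corrected,
`d = −(3/4)·ln(1 − (4/3)p)`, undefined (NaN sentinel) at p ≥ 3/4, and
ω = dn/ds is undefined when ds = 0. NG86 + JC was chosen over ML codon
models as the standard, assumption-light estimator for pairwise
transcriptome screens; on simulated data at ω = 0.4 the estimator's mean
over 100 × 500-codon replicates sits within a few hundredths of the truth
(the per-replicate spread is ±0.05–0.07), which is the accuracy class this
package claims — not likelihood-grade inference.

## Presence/absence and concordance

A reference protein is present in a transcript set when the forward
protein-vs-six-frame-translated search finds a transcript at `E ≤ 1e−10`
*and* that transcript's translation points back to the same protein as its
best reverse hit — reciprocity, not a mere forward hit, is required
because a one-way hit to a paralogous family member is exactly the error
mode this guards against (a forward-only switch exists for sensitivity
analysis). All transcripts qualifying reciprocally are counted, so
two-copy (duplicated) genes report n_transcripts ≥ 2. Calls carry an
explicit transcript-evidence-only caveat column: absence from a
transcriptome is never, by itself, evidence of genomic absence — the
scientific weight comes from *concordant* absence across species, which
the 2×2 table quantifies. Stricter e-value thresholds can only move calls
from present to absent, never the reverse.

## Read filter

A read passes iff mean phred ≥ 25, length ≥ 100, zero non-ACGT bases, and
longest homopolymer ≤ 8. Whether "min phred 25"-style criteria mean the
mean or the minimum per-base quality is generally underspecified; mean is
the default and `phred_mode="min"` switches. The first failing rule (in
the fixed order quality, length, ambiguity, homopolymer) is logged per
read; the decision is per-read pure and order-independent.

## Synthetic data: what it emulates and what it does not

The generator is the package's test bed and defines its study conditions.
Gene models are plus-strand, 2–9 exons of 80–300 nt with introns of
60–200 nt; each mature mRNA is 5′UTR + ATG…stop CDS + 3′UTR with ATG-free
UTRs (so the embedded CDS is the unambiguous longest ORF) and introns
carrying an early stop in all three forward frames (so retention reliably
breaks the ORF, as real intron retention almost always does). Species B
derives from species A by per-site substitution at the divergence rate
(default 0.13, giving ~87% ortholog identity), a conserved fifth of genes
at a third of that rate, 10% lineage-specific loss, and 5% duplication
with the extra copy diverging at twice the base rate after copying — the
factor that lets RBH distinguish ortholog from paralog. Mutation is
substitution-only (no indels outside fragmentation), keeping identity
analytically tied to divergence. Fragmentation replaces 15% of species-A
transcripts by one uniform 40–80% substring (≥ 100 nt when the source
allows) — the singleton length rule is a free choice, as real singleton
length distributions are assembler- and chemistry-specific. Codon pairs
evolve by proposal-rejection: synonymous proposals always accepted,
nonsynonymous with probability ω, stop-creating proposals rejected, with
the proposal count calibrated so expected dS ≈ t.

Everything runs from one integer seed with a separate deterministic
stream per operation (hash of seed and operation name), so identical
configurations give byte-identical files across runs and platforms.

What the generator does *not* emulate: sequencing error (no homopolymer
miscalls, no chimeric reads from library artifacts), expression-level
variation, assembler-specific contig graphs, indel evolution, codon-usage
bias, or genuine GO topology (annotations are flat labels with a
housekeeping-style signal planted in the conserved subset). Passing tests
therefore demonstrate correctness of the *analysis* under a clean,
controlled evolutionary model — they bound algorithmic error, not the
full messiness of a real 454 assembly.

## Problem sizes

Default analysis sizes — 100-gene fixtures, 200-pair oracle comparisons,
200-isotig isogroups, 100 × 500-codon Ka/Ks replicates, 1,000-replicate
enrichment nulls — were chosen so every statistical check has comfortable
power while the whole suite and the acceptance script each run in well
under a minute of compute on a single core; all of them scale up by
changing one configuration value.
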