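# Methods

This note records the models, conventions, tunable parameters and known
limitations behind each stage of the pipeline, and what the synthetic
generators do and do not emulate.

## Coordinates and alphabets

All in-memory coordinates are 0-based, half-open, in transcript space on
the forward strand; GFF3 output converts to 1-based inclusive at the I/O
boundary. RNA input (U) is normalized to DNA (T) at ingest. Codons
containing the ambiguity code N are never called as starts, stops or NCCs
and are counted as masked in every statistic.

## Leader scanning

A uORF is an AUG-initiated ORF whose start codon lies upstream of the
annotated main start (mAUG), in any frame, with a minimum of two codons
(start + stop); an ORF whose stop falls downstream of the mAUG is flagged
`overlapping_uORF` rather than dropped, as is an open-ended ORF reaching
the 3′ end. Frames are labelled 1/2/3 with frame 1 anchored at the mAUG.

An NCC candidate is a codon from the configured near-cognate set at a
position p in frame 1, upstream of the scan boundary, with no stop codon
in frame 1 between p and the mAUG (a ribosome initiating there must be
able to read through into the main ORF). The default NCC set is all nine
single-mismatch neighbours of ATG (ATA, ATC, ATT, ACG, AAG, AGG, CTG,
GTG, TTG); the subset actually observed as fungal initiators is contained
in it and filtering is identical either way. The default boundary is the
second uORF's AUG when at least two uORFs exist (the Pezizomycotina
convention, where initiation upstream of uORF2 bypasses its inhibitory
effect), else the single uORF's start, else the mAUG; it is overridable
for architectures where the relevant boundary is uORF1 (some
Basidiomycota). No minimal context quality is imposed on candidates; the
context score is reported, not filtered on.

The maximal N-terminal extension runs from the codon after the 3′-most
in-frame stop upstream of the mAUG (or from the 5′-most in-frame
position) to the mAUG; `reaches_5prime` records the absence of any
in-frame stop in the leader.

## Initiation context

The context window is an 11-mer: positions −6..−1, the codon (+1..+3),
and +4, +5. Frequency matrices add a Jeffreys pseudocount (α = 0.5 per
cell) before normalization so unseen letters keep finite log-odds; N is
excluded per position. The log-odds score sums log₂(f/b) over the seven
non-codon positions −6..−1 and +4 against a background b (uniform 0.25 by
default, optionally estimated from input composition); the codon itself
is judged by the NCC set, not the context, and +5 is carried for display
only. "Optimal" requires the window to match the matrix consensus at both
−3 and +4 (the crucial positions: −3 purine, +4 G in fungal consensus
contexts); exactly one match is "near-optimal", neither is "poor". A
window with N at −3 or +4 gets label "unknown" and is scored over the
remaining positions.

## Codon alignment

Sequences are conceptually translated (internal stops allowed in leader
regions; they translate to `*`, which BLOSUM62's `*` row scores) and each
non-reference peptide is aligned globally against the reference peptide
(star topology; BLOSUM62, gap open −11, extend −1, via Biopython's
PairwiseAligner). Back-translation threads each CDS's codons through its
aligned peptide; columns gapped in the reference are removed, mapping
everything to reference codon coordinates. A pre-computed peptide
alignment can be supplied instead, in which case only back-translation
and reference-mapping are performed. Consensus codons are the per-column
mode over non-gap entries, ties broken reference-first then
lexicographically — deterministic and reference-centric.

Frames 2 and 3 are obtained by shifting the reference codon grid by 1 or
2 nt on the underlying nucleotide alignment and re-chunking; codons
spanning a gap become gap codons. Substitution tallies classify each
non-consensus codon once (codon-level, not per deviant nucleotide):
synonymous, nonsynonymous, or stop (a stop where the consensus is not).

## NG86 dN/dS

Counting (Nei–Gojobori 1986 style) rather than ML codon models: it is
self-contained, desk-scale, and verifiable against a brute-force oracle;
exact reproduction of published ML estimates is not claimed. Site
fractions per codon position exclude stop-creating changes from the
mutational opportunity and renormalize (s_j = syn/(3 − stops)), keeping
S + N = 3 per codon while treating stop-creating changes as neither
class; this matches an evolutionary process in which mutations to stops
are purged instantly. Multi-nucleotide codon differences are averaged
with equal weights over substitution pathways, excluding pathways through
stop codons (all pathways if every one is blocked). Proportions are
Jukes–Cantor corrected; a pair with p ≥ 3/4 is flagged saturated and
excluded (the correction is undefined there). Pairwise estimates are
pooled with weights proportional to compared codons; ω is undefined when
pooled dS = 0. The bootstrap resamples codon columns with replacement
(default B = 100, seeded; replicates with undefined ω are dropped and
counted) and reports the SD and the 0.5/99.5 percentile interval.

## Synonymous-site conservation

Per pair, the neutral synonymous rate is estimated globally from the
whole alignment (or the analysis region); per 5-codon window, o/e
compares observed synonymous differences with the neutral expectation.
Significance uses the one-sided Poisson **mid-p** value
P(X < O) + ½P(X = O): window expectations are of order 10, where the
plain discrete CDF p-value is markedly super-uniform (its largest
probability step exceeds 0.1), so mid-p — the standard discreteness
correction — is used to keep the null distribution close to uniform.
Windows with E = 0 or with more than half of their cells masked by gaps
are flagged and excluded.

A known limitation: the statistic sums over reference-vs-other pairs as
if independent. On real alignments the reference is an extant sequence,
so all pairs share the reference branch and window counts are
overdispersed relative to Poisson — p-values are then anti-conservative
and should be read comparatively, not literally. The synthetic validation
uses the generator's ancestral sequence as the reference, for which the
independence assumption holds exactly.

## Coding likelihood ratio

A simplified star-topology form of the coding-potential LRT: per
non-reference row and gap-free codon site,
log P_cod(c_r → c_s) − log P_noncod(c_r → c_s), where P_noncod treats the
three nucleotides independently with the pair's global divergence p̂
(match 1 − p̂, each mismatch p̂/3) and P_cod multiplies the same
nucleotide term by w = exp(λ·BLOSUM62[aa_r, aa_s]), with substitutions
into stops weighted ε before normalization over all target codons. The
per-site contribution reduces to log w(obs) − log Z(ref, pair). Defaults
λ = 0.3 and ε = 10⁻³ are exposed in configuration; they encode "how much
more probable is a conservative substitution under coding constraint"
and "how strongly are stops excluded", and only the model-comparison
principle — not any published implementation's internals — is reproduced.
Windows are 20 codons, sliding by one; a window with more than half its
cells gapped, or wider than the alignment, is flagged omitted. Identical
rows score exactly 0 in every frame (both models then assign probability
one to the identity event). The statistic is pairwise star-topology, not
tree-aware: shared ancestry inflates magnitudes but not the sign
structure the tests assert.

## Ribosome footprints

Input is transcript-space 5′-end positions (BED6: chrom = transcript id,
start = 5′ end, score = read length); trimming and genome alignment are
out of scope. Reads of 28–31 nt are accepted by default; others are
counted and dropped. The A-site offset is 15 nt (elongating ribosome),
and initiation-peak assignment uses a P-site offset of 12 nt (A site
minus one codon — an initiating ribosome holds the start codon in the P
site); both are configurable. Region ratios use raw A-site-assigned
counts (a per-nucleotide density variant is emitted alongside). Peak
calling is deliberately simple: position x is a peak when
counts[x] ≥ max(min_count, k × median of counts within ±50 nt excluding
x), with k = 5 and min_count = 10; these are invented, exposed
parameters — the published analyses report "larger peaks" without a
formula — and assignment to a candidate start requires exact (1-nt)
agreement of x + 12 with the codon start.

## Synthetic data

`make_transcript` samples a leader position by position under trigram
constraints (no unplanned AUG in any frame, no unplanned in-frame NCC
upstream of the boundary, no forbidden in-frame stop, no premature uORF
termination) with depth-first backtracking, then verifies the result by
re-running the scanners; specifications whose planted features conflict
fail fast with diagnostics. The worked-example spec (`cpc1_like_spec`)
plants the published *cpc-1* architecture — 703-nt leader, two uORFs,
eight NCCs of the published composition, stop-free leader — with
invented coordinates and sequence; it is a labelled synthetic stand-in,
not the real leader.

`evolve_alignment` evolves each species independently from a common root
(star topology; no indels, so the alignment is born reference-mapped).
Per site, a change is proposed with probability mu (default 0.08 per
branch — pairwise nucleotide divergence around 0.1 after selection, a
typical within-subphylum distance for the fungal leaders emulated);
proposals creating stops are rejected; synonymous proposals are accepted
with the block multiplier (1 outside suppression blocks) and
nonsynonymous ones with probability ω times a mean-normalized
conservative-substitution grading exp(λ·(B[a1,a2] − B[a1,a1])) (λ = 0.3,
settable to 0) — real coding evolution favours conservative replacements,
and a generator without this feature produces "coding" data that no
acceptability-weighted model should score as coding. A global scale keeps
all acceptance probabilities ≤ 1 while preserving the nonsyn/syn ratio
exactly, so NG86 recovery of ω is unbiased by construction. The ancestor
is included as the reference row by default (see the overdispersion note
above). Not emulated: indels, tree-shaped phylogenies, codon-usage bias,
transition/transversion bias — so passing tests demonstrate estimator
correctness under the model's own assumptions, not robustness to those
real-data features.

`simulate_footprints` draws A-site positions per region from planted
densities and frame mixes, converts to 5′ ends with the A-site offset,
adds peak reads whose P site sits exactly on the planted codon start, and
adds Poisson background (default 0.05 reads/nt). Read lengths are drawn
from a distribution over 28–31 (uniform by default). Not emulated:
sequencing error, ligation/library bias, rRNA contamination, multimapping.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed (default 1729); fixed
seed + fixed input gives bit-identical output, and the pipeline records a
configuration hash in every report. The validation suite uses 20 species
× 300 codons with 50 replicates per ω for parameter recovery, 300
non-overlapping 5-codon windows (five independent alignments) for null
calibration, and 10,000 reads for footprint recovery — sizes at which the
binomial/Poisson sampling error is comfortably below the asserted
tolerances.
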