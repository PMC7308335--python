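# Methods

This note documents the models, rules and numerical choices behind the two
analysis arms of `repscan`, the assumptions of its synthetic-data generators,
and what passing tests do and do not establish about real data.

## Repertoire profiling

### Read joining

R2 is reverse-complemented and slid ungapped against R1 over every offset.
Candidate overlaps must span at least `join_min_overlap` (default 10 nt) with
a mismatch fraction at most `join_max_mismatch_frac` (default 0.25); among
candidates the lowest mismatch fraction wins, ties broken toward the longest
overlap. At each overlap mismatch the base with the higher Phred quality is
kept, with R1 winning quality ties. Rejection is an ordinary return value,
not an error, so a pipeline can count rejected pairs. The defaults are
deliberately permissive: the amplicon design guarantees a large mate overlap,
and the V/J identity filter downstream removes junk joins.

### V/J classification

Each joined read is compared against a conserved anchor window per segment:
for V, the (up to) 30 nt ending at the last base of the cysteine codon; for
J, the (up to) 30 nt starting at the first base of the phenylalanine codon.
These windows are chosen — rather than the literal segment termini — because
the terminal bases on the junction-facing side are removed by exonucleolytic
truncation and cannot serve as anchors; everything from the anchor codon
away from the junction is invariant in every rearrangement. A segment is
called at ungapped identity ≥ `assign_min_ident` (default 0.9, tolerant of
sub-percent sequencing error) over ≥ `assign_min_len` (default 15) nt. Ties
are broken by higher identity, then longer window, then lexicographically
smallest name, making classification deterministic. The CDR3 is the read
interval from the V anchor through the J anchor codon inclusive.

### Clonotypes, merging, cutoff

A clonotype is a unique (V name, J name, CDR3 nucleotide sequence) triple;
its frequency is reads / total assigned reads. To absorb PCR and sequencing
artifacts, a clonotype is merged into the most abundant clonotype with the
same V, J and CDR3 length at Hamming distance 1 whose read count is at least
`merge_fold_threshold` (default 20) times its own. Rows are processed in
ascending abundance with eligibility recomputed after every merge; the total
read count is conserved exactly. "Differs by 1 bp" is read as one
substitution — indel neighbours are not merged, since a 1-nt indel changes
CDR3 length and hence the clonotype's architecture class. The frequency
cutoff (default 0.001%) then removes rows *strictly below* the threshold —
the conservative reading of a "cutoff" — without renormalising the surviving
frequencies. Merging precedes the cutoff by default (`cutoff_before_merge`
flips the order): merging first lets an abundant clonotype reclaim its error
tail before that tail is discarded.

### Architecture decomposition

The kept V part is the longest CDR3 prefix matching the germline V from its
anchor; the kept J part the longest suffix matching the germline J up to its
anchor codon. The remaining junction is searched for the longest contiguous
exact substring of any germline D; a D is called only at ≥ `min_d_match`
(default 5) nt, below which the whole junction is reported as N1. Ties
(equal best length) prefer D1 over D2 (genomic order), then the leftmost
junction placement, and set a `d_ambiguous` flag. Truncations follow from
germline lengths and match offsets, and the reconstruction identity

    kept V + N1 + kept D + N2 + kept J == CDR3

holds for every decomposed clonotype (asserted over simulated data).
Functionality is defined minimally and testably: CDR3 length divisible by 3
and no TAA/TAG/TGA codon in the frame starting at the V anchor codon. Because
non-templated bases can coincidentally equal the adjacent germline base, the
greedy matches can extend past the generative truth; the decomposition is
still a valid parse (the identity holds) and the closed-loop test counts and
bounds these reinterpretations rather than forbidding them.

### Summary metrics and group comparisons

Richness is the post-cutoff clonotype count. Ratios (functional /
non-functional, D1 / D2) and means are computed over clonotypes, not reads —
repertoire composition, not clonal expansion, is the quantity of interest —
with a `weight_by_reads` switch for the read-weighted alternative. Zero
denominators yield NaN, never an exception. Group differences use two-tailed
Mann-Whitney U tests: exact enumeration of the U null when the pooled size is
≤ 12 with no ties, otherwise the normal approximation with tie and 0.5
continuity corrections; the mode used is reported. Fold changes are ratios of
group medians; when two groups are jointly compared against one, the mean of
the two medians forms the numerator. Raw p-values are reported (matching the
source analyses); a clearly-labelled Benjamini–Hochberg column is emitted for
convenience only.

## Motif scanning and enrichment

### Matrices and similarity

A PWM column holds pseudocounted base frequencies
`f = (count + 0.01) / (n + 0.04)` over the unique seed sequences, with
information weight `c = 2 + Σ_b f(b) log2 f(b)` bits. The similarity of a
window is the weight-normalised score `Σ c·f(observed) / Σ c·max f`, which is
1 for the consensus, in [0, 1] always, monotone toward the consensus
(property-tested), and 0 for windows containing non-ACGT characters or for
all-uniform matrices. The default similarity threshold everywhere is 0.8.

Packaged matrices: two heptamer and two nonamer matrices built from canonical
CACAGTG- / ACAAAAACC-family seed sets of D-3′ and J-5′ RSS elements (the
D-to-J geometry initiates the rearrangement, so these are the relevant
elements), and an 11-column RUNX1 matrix with a strong TGTGG core, a
preferred following T, and weakly informative flanks. All are user-replaceable
through a documented 4×width tab-separated file format (round-trip tested);
the packaged RUNX1 matrix is a synthetic stand-in constructed from the
published core, not a licensed database matrix.

### Scanning and RSS modules

Scanning scores every offset on both strands (minus-strand windows on their
reverse complement, reported in plus coordinates) via a vectorised
lookup-table sum, verified against a brute-force per-window oracle. An RSS
module is a heptamer hit with a same-strand nonamer hit at a spacer of 12±1
or 23±1 bp on the heptamer's 3′ side in module orientation; eight models
(2 heptamer × 2 nonamer matrices × 2 spacer classes) are scanned and
deduplicated per (heptamer start, strand, model), keeping the smallest
spacer.

### Deletion ends, windows, counting

Each deletion contributes two 67-bp end regions: [start−7, start+60) and
[end−60, end+7), carrying the border coordinate (regions running off a
chromosome are clipped and flagged). Heptamer hits are expanded by ±7 nt,
clipped to the region, and merged when overlapping by ≥1 nt (idempotent by
construction); a merged window is the counting unit. A window is
RUNX1-positive iff a RUNX1 hit overlaps a *contributing heptamer hit* (not
merely the flanked window) by ≥4 nt. The background applies identical
thresholds and window rules to the whole provided genome. Backgrounds are
recomputed per run rather than cached to disk: at the synthetic scales this
package targets a full rescan costs ~2 s, so content-hash caching was
dropped as needless complexity.

### Enrichment statistics

With background positive rate p and n foreground units, expected = n·p,
fold = observed/expected, and the analytic Z-score is
`(observed − expected ∓ 0.5) / sqrt(n·p·(1−p))` (0 within the continuity
band). The tail probability is the exact binomial upper tail P(X ≥ observed)
(lower tail when observed < expected), computed by scipy's regularised
incomplete beta — no large-λ underflow. A resampling estimator (seeded
hypergeometric draws of n units from the background; empirical mean/SD and
tail) is provided as the alternative, and agrees with the analytic route
within Z ± 0.3 and a factor-2 tail for expected ≥ 5 (property-tested).
For reproducing published worked numbers quoted as "expected E ± sqrt(E)",
`stats_core.z_score` with the Poisson-limit SD sqrt(E) is the matching
formula; the binomial SD above is used whenever the package computes its own
backgrounds. The two-tailed Fisher test uses the point-probability
(minimum-likelihood) convention — the one that reproduces published
contingency-table p-values — with the tail-doubling method behind a flag.

### Spatial classification

Each RUNX1 hit in a border region is classified, in priority order:
overlapping (≥4 nt) a heptamer inside an RSS module; overlapping any heptamer
hit; carrying a partial heptamer — a GTG or CAC trinucleotide immediately
flanking the hit with a same-strand nonamer at a spacer of 12 or 19–25 nt
measured from that trinucleotide; or none of these. Distance to the border is
unsigned, from the hit's first (plus-strand leftmost) position, with a signed
variant also emitted. Per-category medians are reported.

## Synthetic data: what it emulates, and what it does not

Truncation lengths are geometric (on {0, 1, ...}), N-region lengths Poisson
with i.i.d. uniform bases, clone sizes Zipf (exponent 1.3) truncated at the
clonotype count, sequencing errors i.i.d. substitutions — canonical
single-parameter laws matching the first moments the study design calls for,
chosen because only summary statistics of the real distributions are
published. Reads are 2×150 with a mate overlap guaranteed by the amplicon
design; errors exercise the 1-bp merge rule, while indels, quality decay
along the read, chimeric PCR products and primer bias are *not* modelled.
The packaged germline registry is a toy locus (4 V, the two mouse D
sequences GGGACAGGGGGC / GGGACTGGGGGGGC, 6 J in two clusters); real IMGT
references load through the same registry format. Planted motif instances
use matrix consensus sequences, so planted-truth recovery is guaranteed by
construction of the similarity score and tests the plumbing, not threshold
sensitivity. Consequently, green tests show the rules are implemented
exactly and recover known ground truth under these laws — they do not certify
performance on real repertoires with UMI-free PCR amplification bias or on
repetitive genomic sequence.

The knockout/wildtype cohort presets encode a ~4-fold richness deficit,
functional:non-functional dropping from ~2.9 to ~1, 1.2-fold longer N
regions, a 1.2-fold heavier measured 5′ D truncation and a 2.5-fold measured
D1/D2 shift, at 10 samples per group, ~2000 (wildtype) vs ~500 (knockout)
clonotypes per sample, with log-normal between-sample richness variation
(CV 0.15). Two presets are calibrated on the generator rather than set
naively, because the ≥5 nt D-calling threshold biases measured quantities:
heavier truncation pushes more D remnants below the threshold, trimming the
observable truncation tail (so knockout `d5_trunc_mean` is 2.8, whose
*measured* conditional mean is 1.2× the wildtype's) and dropping the shorter
D1 more often than D2 (so knockout `p_d2` is 0.2, input odds 4.0, whose
measured ratio shift is 2.5×). Real cohorts carry the same bias; calibrating
to the measured effect is what makes the recovery test meaningful.

## Problem sizes and numerical conventions

All intervals are 0-based half-open; 1-based coordinates appear only in
rendered reports. All generators are pure functions of (parameters, seed)
via `numpy.random.default_rng`, and the profiling pipeline is deterministic
for identical input files. The test-suite and the acceptance script run at
desk scale as the package's own choice of problem size: background genomes
of 150 kb with ~125 planted sites, cohorts of 10×2000 / 10×500 clonotypes,
read-level closed loops at 100–200 clonotypes × 2500–4000 pairs, 400-draw
null calibrations and 200-draw power estimates; the complete suite finishes
in well under a minute of CPU. Null calibration and power replicates resample
window counts from the scanned background (the unit at which the Z statistic
operates); one full sequence-level planted deletion cohort is additionally
run end to end per suite.

## Known limitations

- The V/J classifier is a terminal-window identity matcher, not a full
  aligner: it assumes amplicons contain intact anchor-proximal segments, as
  the amplicon design guarantees; it is not suitable for somatically
  hypermutated loci.
- Indel sequencing errors create length-shifted clonotypes the 1-bp merge
  rule will not absorb.
- Single-match similarity scores carry no p-value calibration; significance
  is only defined at the region-set level through the enrichment statistics.
- The packaged RUNX1 matrix approximates the published core motif; users
  reproducing database-matrix results should supply that matrix file.
- D assignment inside the junction is exact-substring based; a D carrying a
  sequencing error in the junction is reported as N sequence.
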