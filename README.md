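# repscan

Quantitative TCRβ repertoire profiling and cryptic-RSS / RUNX1 motif-enrichment
analysis, with synthetic-data generators for fully self-contained testing.

## The scientific problem

During V(D)J recombination the RAG1/2 recombinase excises the DNA between
germline V, D and J segments, guided by recombination signal sequences (RSS):
a conserved heptamer (CACAGTG-like) and nonamer (ACAAAAACC-like) separated by
a 12 or 23 bp spacer. The transcription factor RUNX1 binds a TGTGG-core motif
that overlaps RSS heptamers, and has been proposed to act as a recombinase
cofactor — both for physiological TCRβ rearrangement and for aberrant,
RAG-mediated deletions in *ETV6-RUNX1* acute lymphoblastic leukemia.

`repscan` implements the two computational procedures this hypothesis rests
on, for anyone who wants to profile amplicon-based TCRβ repertoires or score
RUNX1/RSS co-occurrence at genomic breakpoints:

1. **Repertoire profiling** — paired 2×150 reads are joined by
   quality-weighted consensus, classified to V and J segments, clustered into
   clonotypes keyed by (V, J, CDR3), cleaned by a 1-bp / ≥20-fold
   merge rule and a 0.001% frequency cutoff, and decomposed into the full
   junctional architecture: CDR3 (conserved V-cysteine codon through
   J-phenylalanine codon), V/J/D-end truncations, N1/N2 non-templated
   regions (D called only at ≥5 nt), and in-frame/stop-free functionality.
   Per-sample metrics (richness, functional and D1/D2 ratios, CDR3 length,
   truncation and N-length means) are compared between groups with two-tailed
   Mann-Whitney U tests and median-based fold changes.
2. **Motif enrichment** — position weight matrices with the
   information-weighted similarity score
   `sim(w) = Σᵢ cᵢ f_i(wᵢ) / Σᵢ cᵢ max_b f_i(b)` (cᵢ the column information in
   bits), eight composite RSS models (2 heptamer × 2 nonamer matrices ×
   {12±1, 23±1} spacers), 67-bp deletion-end regions, ±7 nt merged heptamer
   windows, the ≥4 nt RUNX1–heptamer overlap rule, and
   fold / continuity-corrected Z-score / exact binomial tail statistics
   against a whole-genome background, plus spatial classification of RUNX1
   hits by distance to the deletion border.

A third arm (`synthetic_data`) generates repertoires with known architecture
(geometric truncations, Poisson N regions, Zipf clone sizes), paired reads
with substitution errors, and background genomes with planted
heptamer/nonamer/RUNX1 instances — every downstream stage is tested against
this recorded ground truth.

## Worked example

```python
import repscan.synthetic_data as sd
import repscan.clonotype_pipeline as cp
import repscan.repertoire_stats as rs
from repscan.io_core import load_germline_registry, read_fastq_pairs, RunConfig

registry = load_germline_registry("builtin")   # toy TCRβ-like locus
params = sd.RepertoireSimParams(n_clonotypes=120, read_depth=3000,
                                error_rate=0.0, seed=42)
truth = sd.simulate_repertoire(params, registry)
sd.reads_from_repertoire(truth, params, registry, "r1.fastq", "r2.fastq")

table = cp.profile_reads(read_fastq_pairs("r1.fastq", "r2.fastq"), registry,
                         RunConfig(clonotype_frequency_cutoff=1e-9))
m = rs.summarize_sample(table, "demo")
print(m.richness, round(m.functional_ratio, 2), round(m.mean_n_len, 2))
```

prints

```
117 0.1 4.75
```

meaning: 117 distinct clonotypes were recovered (the three clonotypes missing
from the 120 simulated drew zero reads at this depth), one functional
clonotype for every ten non-functional ones (no thymic-selection pressure is
simulated by default, so most junctions are out of frame or hit a stop), and
an average of 4.8 non-templated N bases per junction (N1+N2, Poisson mean
2×2.5 before the D-calling conditioning). With `error_rate=0` and no frequency cutoff the
recovered clonotype set equals the simulated truth set exactly — this
closed-loop identity is asserted in the test-suite.

On the enrichment side:

```python
from repscan.stats_core import z_score, poisson_upper_tail
print(round(15 / 7.6, 2), round(z_score(15, 7.6, 7.6 ** 0.5), 2),
      round(poisson_upper_tail(15, 7.6), 3))
```

prints `1.97 2.5 0.011` — a 2-fold excess of RUNX1-positive RSS peaks over
the background expectation of 7.6 ± 2.8 is significant at Z = 2.5, P ≈ 0.01.

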