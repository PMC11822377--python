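# Methods

This note documents the models and procedures implemented in `piclusterkit`,
their assumptions, the parameters that matter, and what the synthetic-data
generators do and do not establish.

## The biological setting

*C. elegans* type I piRNAs (21U-RNAs) are transcribed from >10,000 discrete
loci concentrated in two multi-megabase clusters on chromosome IV. Each
locus has a small promoter: the 8-nt Ruby motif (CTGTTTCA) bound by the
USTC complex, flanked by AT-rich sequence. Mature piRNAs are ~21 nt, begin
with a 5′ U, and derive from slightly longer capped precursors (csRNAs)
whose 5′ ends sit 2 nt upstream of the mature 5′ end. Type II piRNAs arise
at the transcription start sites of other genes. The package's analyses
quantify how depleting an AT-hook transcription factor changes piRNA/csRNA
output, the binding-site distribution of two chromatin factors (one
Ruby-motif-bound, one AT-rich-bound), the proteome labeled in the clusters'
neighborhood, and the mRNA output of genes whose promoters the factor binds.

## Small-RNA assignment

A read is counted for a mature piRNA locus iff all five rules hold:

1. unique (multiplicity 1) and perfect (0 mismatches) alignment,
2. sense orientation relative to the locus,
3. first read base T (the 5′ U),
4. length in [15, 40] nt (both bounds inclusive),
5. 5′ end at the annotated locus 5′ end + offset ∈ {0, +1, +2} in the
   transcription direction.

The csRNA rule instead requires the 5′ end exactly 2 nt upstream; it keeps
unique/perfect/sense/length but deliberately does **not** require a 5′ T,
because the capped precursor 5′ end precedes the U. Whether the original
pipelines imposed 5′ T on csRNAs is not documented; this package's choice is
recorded here as its own.

Strand-aware coordinates are centralized in one helper (plus strand:
5′ = start; minus strand: 5′ = end − 1; all intervals 0-based half-open).
Two same-strand loci with 5′ ends < 3 nt apart would make the mature offset
window ambiguous; this raises an error naming the loci rather than
resolving ties arbitrarily.

RPM normalization divides by the number of reads with at least one
alignment, each counted once (multimappers count once in the denominator,
never in locus counts). Per-class fold changes are raw RPM ratios with no
pseudocount; a zero denominator is reported as a flagged infinity. The
per-locus scatter table drops loci below 0.5 RPM in both conditions and
flags |log₂FC| ≥ 2 inclusively (a locus at exactly 4-fold is flagged).

The bundled aligner is an exact seed-and-verify substring matcher (12-nt
seed index, full-length verification, both strands) standing in for a
`-v 0 -a -m 100`-style short-read aligner at miniature-genome scale: all
perfect placements are reported; reads exceeding `max_hits` placements are
suppressed but still counted as mapped.

## ChIP-seq quantification and annotation

* **Ratio tracks**: (exp + 1)/(ctrl + 1) per 5-bp bin after averaging onto a
  common grid. Tracks are plain bedGraph text; binary formats are avoided so
  fixtures stay byte-reproducible.
* **Chromosome summary**: re-bin the ratio to 1 kb (mean), drop bins < 1.2,
  average surviving bins per chromosome, then average across replicates —
  in that order. Whether the floor should apply to 5-bp bins before
  re-binning is ambiguous in prose descriptions of such pipelines; the
  re-bin-then-floor order used here is a documented choice. A chromosome
  with no surviving bins is reported as NaN, never silently 0.
* **Peak filtering**: score ≥ min_score AND significance ≥ min_significance,
  inclusive. "Significance" is the narrowPeak −log₁₀(q) column by default,
  switchable to −log₁₀(p). Presets: (200, 3) and (500, 3).
* **Cluster membership**: a peak is in-cluster iff start AND end lie inside
  one cluster interval; straddling peaks are outside. Percentages are
  rounded to one decimal.
* **Annotation**: each peak gets exactly one class by priority
  snRNA promoter > snoRNA promoter > ncRNA > protein-coding promoter >
  pseudogene. Promoters are strand-aware upstream windows (500 nt for
  protein-coding, 100 nt for snRNA/snoRNA) clipped at position 0; ncRNA and
  pseudogene matches use gene bodies. Histone genes are a flagged subset of
  protein-coding genes, reported as a sub-label rather than a separate
  priority tier. Peaks overlapping nothing are unassigned.
* **Overlap**: two peaks overlap when the intersection covers ≥ 50% of at
  least one of them (either-side test; a reciprocal variant is a flag).
  Overlap significance uses the upper-tail hypergeometric probability
  P(X ≥ k); the population size N is a required argument because the correct
  universe (annotated loci vs. peaks) depends on the question.
* **Metagene/motif context**: windows are extracted strand-aware (minus
  anchors reversed so columns read 5′→3′); windows leaving a chromosome are
  NaN-padded and ignored in the mean. The motif scan reports exact CTGTTTCA
  matches on both strands within a window around each locus 5′ end plus the
  per-position A/T fraction.

## TurboID enrichment

Spectral counts are scaled so each sample's total equals the mean total
(total-count normalization — the simplest defensible reading of
"normalized spectral counts"; a no-normalization flag exists). Fold change
is (mean_tagged + 0.1)/(mean_control + 0.1); the pseudocount is applied to
both sides (denominator-only is a flag; the published fold changes cannot
disambiguate the convention without the raw table). Significance is a
one-tailed (tagged > control) *equal-variance* Student's t-test — not Welch
— with ≥ 2 replicates per condition required. Degenerate zero-variance rows
get p = 0.5 / 0 / 1 for equal / greater / smaller tagged means, matching the
one-tailed convention at t = 0. The enrichment filter is
mean_tagged ≥ 2 ∧ FC ≥ 8 ∧ p ≤ .05, all inclusive; the count threshold
applies to the tagged-condition mean, not each replicate (a documented
reading). Proteins detected in only one condition are kept with zeros.
Volcano coordinates are (log₂FC, −log₁₀p) with lines at log₂FC = 3 ≡
FC = 8 and p = .05, so the volcano cut and the filter agree by construction.

## mRNA group comparison

Size factors follow the median-of-ratios construction: over genes with
positive counts in every sample, the per-sample median of
count / geometric-mean. No shrinkage or per-gene Wald testing is
reimplemented — the group comparison is a two-tailed equal-variance t-test
on per-gene log₂ fold changes, which is what the bound/unbound analysis
actually uses. Genes with **any** raw count < 1 are excluded (a "sum < 1"
variant is a flag); log₂FC = log₂((mean_depleted + ε)/(mean_control + ε))
with ε = 0.5 on normalized means. Group medians are reported as
2^|median log₂FC| with the orientation labeled.

**Known attenuation.** Median-of-ratios assumes most genes are unchanged.
In the default depletion scenario, 362 of 2000 genes (162 bound at 2-fold +
200 germline at 1.2-fold) are truly reduced, which biases the depleted
samples' size factors low and attenuates recovered medians by ~4–6%
(observed: bound ≈ 1.87 for a true 2.0, germline ≈ 1.13–1.17 for a true
1.2). This is a property of the estimator on this composition — the same
attenuation would affect the real analysis — and is left visible rather
than corrected. The germline set was fixed at 10% of the gene universe when
the count model was designed; much larger changed fractions (≥ 30%) break
the estimator's assumption outright.

## Synthetic data: the stated world

All generators are pure functions of (spec, seed); identical inputs give
byte-identical files. Truth labels are verifiable by independent predicates
on the emitted files — no hidden state.

* **Genome**: 2 chromosomes × 200 kb, GC 0.36 (worm-like). Cluster
  intervals are the chromosome IV piRNA clusters at 1:100 scale
  (47.5–75 kb and 135–175 kb), recorded in the metadata so the in-cluster
  predicate keeps its real-genome structure. 100 type I loci (40 + 60 per
  cluster) each get TTT at transcript positions 0–2 (so every offset
  variant retains a 5′ U) and the Ruby octamer ending 40 nt upstream of the
  5′ end with 20-nt AT-rich flanks (AT ≥ 0.7). The 40-nt motif-to-5′-end
  spacing is a free parameter of this package, not a measured value.
  Chance Ruby occurrences near type I promoters are scrubbed so motif scans
  recover exactly the designated sites. Type II loci sit at protein-coding
  TSSs outside the clusters (a modeling choice; type II structure is only
  loosely characterized). A 20 × 1 kb identical tandem array provides the
  5S rDNA-SL1 locus (SL1 annotated as snRNA, 5S as ncRNA, oppositely
  oriented), so reads from it genuinely multimap. Four histone
  mini-clusters of four flagged protein-coding genes each are dispersed
  outside the clusters.
* **Small-RNA libraries**: 2 × 10⁵ reads; 8,000 type I + 2,000 type II
  piRNA-class reads (5% of the library, so RPM fold changes track count
  ratios), 0.2% per contaminant class, the rest background reads sampled
  away from locus 5′ windows. Class totals are deterministic rounded
  expectations; randomness covers per-locus allocation (lognormal locus
  weights), offsets (0.7/0.2/0.1), lengths (mode 21) and placements. This
  keeps the recovered 29× and 120× depletion factors within a fraction of
  a percent of their configured values at any seed; a fully multinomial
  draw of class totals would leave the 120× recovery with ~12% relative
  noise at this library size — indistinguishable from a failed recovery.
  Each contaminant class violates exactly one assignment rule (its
  *defining* violation): multimappers are reads from four decoy type I loci
  whose 5′ context is copied once elsewhere in the genome (decoys are
  excluded from the regular read pool); antisense reads are
  reverse-complements (their 5′ base and offset are evaluated in the
  antisense frame and not separately controlled); mismatch reads carry one
  internal substitution verified to abolish all perfect placements (so the
  exact aligner drops them, mirroring a `-v 0` policy); off-length reads
  are 14 or 44 nt but otherwise valid.
* **Peak fixtures**: exactly `in_cluster` peaks with both ends inside a
  cluster and the rest placed entirely outside, widths 50–200 bp, summit
  uniform within the peak. Defaults encode 642/710 and 244/735.
* **Spectral counts**: 600 proteins, 54 enriched (tagged mean 15 vs control
  0.5, with 10 of them absent from controls to exercise the pseudocount),
  Poisson replicates (3 per condition) with per-sample depth factors for
  the normalizer to undo. The separate null generator draws both conditions
  from Poisson(100) — near-normal, so t-test p-values are calibrated and
  testable by KS.
* **mRNA counts**: gamma-Poisson with fixed dispersion 0.05, lognormal
  baseline means (log-mean 5, log-sd 1), 2 replicates per condition with
  unequal depths, 2000 genes of which 162 bound (2-fold down) and 200
  germline-flagged (1.2-fold down), disjoint sets so both medians are
  independently recoverable.

What a green test establishes: the *procedures* are correct on data whose
generating process is known exactly. What it does not establish: robustness
to sequencing error, adapter artifacts, unannotated loci, partial
annotation, batch effects, or real-library composition — none of which the
generators emulate (no quality scores, no error model, no FASTQ).

## Numerical and interface conventions

* All boundary comparisons are inclusive (length 15 and 40 pass; score 200
  / significance 3 pass; FC exactly 8 and p exactly .05 pass; a 4-fold
  locus is flagged).
* Seeds: every stage seed derives from one integer as
  `seed*1000 + offset (mod 2³¹)`; scenario summaries are rounded to 6
  decimals and serialized with sorted keys, so reruns are byte-identical.
* Formats: FASTA (60-column wrap), BED6 with `name|class[|histone]`,
  narrowPeak (BED6+4, significance in the q column), 4-column bedGraph,
  TSV with header; writers sort by (chrom, start).
* Exit codes of the CLI: 0 ok, 2 configuration error, 3 data error.

## Limitations

* The aligner is exact-match only; mismatch-tolerant alignment modes are
  out of scope (mismatch handling enters only through the record contract).
* The mRNA stage reimplements only size-factor normalization, not a full
  differential-expression model.
* Exon-junction references, 22G/26G siRNA classes, transposon
  quantification, GO analysis and de-novo motif discovery are out of scope.
* The hypergeometric overlap test leaves the population size N to the
  caller; there is no safe default.
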