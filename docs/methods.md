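# Methods

This note documents the statistical procedures, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Coordinates and gene models

All internal coordinates are 0-based, half-open (BED native); GTF input
(1-based, closed) is converted on read. Duplicate gene ids collapse to
the longest transcript, since all downstream calls are made at gene
level. The promoter is the strand-aware window from 2 kb upstream to
1 kb downstream of the TSS, clipped at the chromosome start; the gene
body is the full transcript interval. Whether the promoter-overlapping
prefix of the transcript belongs to the "body" is not separately
resolved: body coverage is computed over the whole transcript, which
makes body-wide repression override an otherwise active promoter (see
below).

## Histone-state grading

Consensus peaks are the replicate-1 peaks with ≥ 1 bp overlap in
replicate 2. One-way overlap keeps observed coordinates from a single
replicate instead of inventing merged intervals; the peak caller's
scores are carried but never used for grading — the rules are
presence-based.

The classifier evaluates, in order: (1) **bivalent** if both marks
overlap the promoter; (2) **active** if H3K4me3 overlaps the promoter,
H3K27me3 does not, and H3K27me3 body coverage is below the threshold;
(3) **repressed** if H3K27me3 overlaps the promoter without H3K4me3 *or*
body coverage reaches the threshold; (4) **unmarked** if no mark touches
promoter or transcript; (5) anything left (e.g. a mark confined to the
gene body below the repression threshold) is *unmarked* with an
`atypical` flag rather than a fifth state. Body "coverage" is the
union-coverage fraction with default threshold 0.5, configurable; a
fraction is robust to peak fragmentation, and letting rule 3 beat rule 2
keeps the description of a gene whose H3K4me3 promoter signal is similar
in both lineages but whose body fills with H3K27me3 in one of them
internally consistent (such a gene is repressed there, a gain for the
other lineage).

Cross-lineage comparison: a higher state rank is a gain
(basis `state_switch`). Equal ranks fall back to the simplified
differential-enrichment test: pooled per-million rates with pseudocount
0.5 reads scaled to the smaller library, two-sided Fisher exact test of
in-window vs out-of-window pooled counts, BH over all windows of a run,
significance at |log2FC| > 1 and q < 0.05. Two replicates per group
cannot support per-window dispersion estimation, so no dispersion-based
differential-binding model is attempted; the "enrichment > 1" cutoff is
interpreted on the log2 scale. Stronger H3K4me3 or weaker H3K27me3 is a
gain (basis `same_state_signal`), the mirror a loss; conflicting or
absent signals leave the gene `unchanged`. The orchestrated pipeline
applies the rank rule only, because processed peak/signal inputs carry
no per-window read counts; the test is exposed for datasets that have
them.

## Expression

TPM is the standard length-normalised rate rescaled to 1e6 per sample.
Up-sets use log2FC > 1 and FDR < 0.01 on an A-over-B table; externally
produced DE tables can be supplied directly. For synthetic pipelines two
tests are provided on log2(TPM+1): a plain Welch t-test, and a
variance-moderated pooled t (per-gene variance shrunk toward the
run-wide mean with prior weight d₀ = 4, degrees of freedom
d₀ + n_A + n_B − 2). The pipeline default is the moderated test: at the
study design of two replicates per lineage a plain Welch test has
essentially no power at FDR < 0.01, while information sharing across
genes — the same idea used by count-model DE tools — restores it.
qPCR quantification is 2^−ΔCT against a reference gene; replicate groups
are summarised by arithmetic mean + SD, on the 2^−ΔCT scale by default
(the ΔCT scale is exposed as an option, since either choice is
defensible for downstream t-tests).

## Methylation

Probes are retained when detected (p < 0.01) in **all** samples and
free of cross-hybridisation and SNP-overlap flags. β is clamped to
[1e-6, 1−1e-6] before M = log2(β/(1−β)), preserving monotonicity while
avoiding infinities. Per-probe testing uses the same moderated-t scheme
as expression (d₀ = 4, two-sided p from the t distribution with
moderated df, BH across retained probes); probes with zero variance
everywhere give NA and are excluded from the multiplicity count. The
signed z score carries the sign of Δβ = mean β(A) − mean β(B), so
`hypo_a` means lower methylation in cell type A.

DMR calling is a deliberately transparent surrogate for kernel-based
region callers: candidate regions are maximal runs of probes with
q < 0.25 (seed threshold), consecutive gaps ≤ 1000 bp and consistent z
sign; each candidate is scored by the unweighted Stouffer statistic
Σzᵢ/√k, candidates are BH-adjusted, and regions with ≥ 3 probes and
Stouffer FDR < 0.05 are reported. All four knobs are configurable. DMRs
are assigned to every gene whose promoter window they overlap by ≥ 1 bp;
a DMR is an *enhancer DMR* when it contains at least one individually
significant (q < 0.05) enhancer-targeting probe. Probe significance is
q < 0.05 alone; an optional effect-size cutoff on |ΔM| is not applied by
default. Genic-region labels (TSS1500, TSS200, 5'UTR, 1stExon, Body,
ExonBnd, 3'UTR, intergenic) are taken from the probe table, which in
real use comes from the array manifest.

## Motif integration

PWM scanning computes log2-odds against the background at every offset
on both strands (probabilities floored at 1e-3; windows containing N are
skipped); a hit is a window scoring at least 0.8 × the PWM's maximal
attainable score. Enrichment is ZOOPS (a sequence either has ≥ 1 hit or
none) with a hypergeometric upper-tail p-value and BH over motifs — the
simplest defensible stand-in for a known-motif enrichment tool.
Foregrounds are (a) the sequences of hypomethylated enhancer DMRs with
zero H3K27me3 consensus overlap in the focal cell type and (b) the
−2 kb/+1 kb promoters of that cell type's upregulated genes.
Backgrounds: enhancers not overlapping any DMR, count-matched by seeded
sampling (floor of 50), and promoters of expressed (TPM > 0)
non-upregulated genes. A TF is *selected* when enriched (q < 0.05, a
documented choice) in both scans, in an `active` state, and upregulated
in the focal cell type; the motif→TF mapping is an explicit input table
with no name matching, and unresolvable TFs are kept for audit but never
selected.

## The synthetic generator

The generator emulates the *processed* outputs of a two-lineage study —
two cell types, two replicates per assay — with a manifest recording
every planted truth. Defaults: 2,000 non-overlapping stranded genes
(3–15 kb, 2–6 exons) on one 50-Mb chromosome, 300 intergenic enhancers,
≈ 17,000 CpG probes. Histone states are drawn per gene and cell type
(upregulated genes are biased toward `active` in their lineage);
replicate-1 peaks realise the state exactly, replicate 2 adds Gaussian
boundary jitter and optional dropout, and fold-enrichment tracks carry
5–10 inside peaks and ~1 outside. Counts are negative binomial with
log-normal baselines (median ≈ 300) and planted log2FC = 2 in 10 % of
genes; dispersion defaults to 0.02, a realistic value for cultured
donor-matched primary cells. Methylation background sits near β = 0.2
at promoters, 0.7 in gene bodies and 0.45 at enhancers with per-sample
noise SD 0.02; planted DMRs (≥ 3 clustered probes) raise the opposing
lineage's mean by Δβ = 0.3, and small probe fractions carry
cross-hybridisation/SNP/failed-detection flags to exercise the filters.
One informative PWM per lineage (consensus probability 0.85) is planted
with per-base mutation probability 0.1 into 70 % of that lineage's
truth-selected enhancer DMRs and upregulated promoters; nine decoy PWMs
are equally informative but planted nowhere and mapped to
non-differential genes. A configurable fraction of enhancer DMRs is
deliberately covered by an H3K27me3 peak to exercise the
"devoid of H3K27me3" filter.

What it does **not** emulate: read-level data, peak-caller artefacts,
array normalisation (β values are generated post-normalisation, so the
pipeline's omission of SWAN-style steps is by construction), CpG-island
spatial statistics, correlated probe noise, and motif co-occurrence
structure. Passing recovery tests therefore demonstrates the
correctness of the analysis logic under the stated noise model, not
performance on raw real-world data.

## Problem sizes used in tests

The unit suite runs a 150-gene study end to end; recovery and error
control are asserted at the full default scale (2,000 genes × 2 cell
types, ≈ 16,000 retained probes, 143 planted DMRs, 200 planted DE
genes), where the package achieves 100 % state recovery at zero jitter,
≥ 95 % at 200-bp jitter, ≥ 90 % DE and probe-level sensitivity with
BH-controlled false positives, ≥ 90 % DMR recovery with no
opposite-direction calls, and unique recovery of both planted
transcription factors.

## Known limitations

- The differential-enrichment surrogate pools replicates and ignores
  biological variability between them; it is a screening statistic, not
  a calibrated differential-binding test.
- The DMR caller has no kernel smoothing; a planted region interrupted
  by a > 1 kb probe gap or an opposite-sign null probe splits into
  shorter candidates (still called when ≥ 3 probes remain).
- ZOOPS enrichment ignores hit multiplicity and positional bias within
  sequences.
- With the default 0.8 × max score cutoff, a 12-bp planted instance is
  detected with roughly one mismatch of tolerance, so per-region
  detection of planted motifs is ~0.65; enrichment remains decisive at
  realistic foreground sizes but is fragile below ~10 foreground
  regions.
- Minus-strand promoters are the mirror of the plus-strand rule about
  the TSS; unstranded gene models are rejected rather than guessed.
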