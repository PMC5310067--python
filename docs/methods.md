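# Methods

## Scope and model

`methylpanel` analyses targeted bisulfite amplicon sequencing of a small
gene panel. The unit of measurement is one *library* — a (subject, tissue,
replicate) triple — sequenced over every panel amplicon. The analysis
pipeline has five stages: methylation calling from reads, a read-depth
retention rule, group statistics on region means and per-CpG counts,
co-methylation networks, and PLS discriminant classification. A synthetic
cohort generator provides inputs with the statistical structure the
analysis assumes.

## Panel

Coordinates are 1-based inclusive (GRCh38): an amplicon's length is
`end − start + 1`, and every packaged panel row satisfies this identity
against its declared size (the *EDNRA* end coordinate is stored in its
full form, 147,481,216, the only value consistent with the declared
260 bp). CpG sites are numbered 1-based in 5′→3′ order along the amplicon.
The packaged panel totals 194 CpG sites over 14 genes.

Because genome extraction is deliberately out of scope (no download
dependency), the packaged amplicon *sequences* are synthetic: for each
amplicon a random sequence of exactly the declared length is drawn with a
CG-free backbone and exactly the declared number of CG dinucleotides
planted at non-adjacent offsets (`panel._synthetic_sequence`). Everything
downstream depends only on length, CpG layout and non-CpG cytosine
content, which the stand-ins reproduce; analyses of real data should load
the true sequences via `load_panel` (FASTA + TSV sidecar).

## Synthetic cohort

Default design: 24 controls; 48 patients split 23/13/12 into mild /
intermediary / severe lung-disease strata; blood for all 72 subjects, NEC
for all but 9 patients; 4 patients measured in duplicate in both tissues;
one genotyped locus (*GSTM3*) with Hardy–Weinberg 0/1/2 dosages at
minor-allele frequency 0.3.

Per subject s, tissue t, gene g, site j the latent methylation level is

    logit μ = logit(π[g,t]) + site_offset[g,j] + group_offset[g,t,group(s)]
              + dosage[s,g]·slope[g] + Σ_f λ_f·z[s,f]
    p ~ Beta(μc, (1−μ)c)

with z ~ N(0,1) latent factors shared across the (gene, tissue) variables
they load on, optionally restricted to one stratum. Technical replicates
share p exactly — they re-measure the same material, so their disagreement
reflects only read sampling, conversion failure and sequencing error.

Parameter defaults and rationale:

* **Baselines π** — one near-complete gene (*MUC5AC*: 0.95 blood /
  0.83 NEC), one intermediate (*TLR5*: 0.38 / 0.26), the rest < 0.20,
  matching the reported control ranges for this panel.
* **Concentration c = 40** — gives a between-sample logit-scale SD of
  ≈ 0.45–0.55 at low baselines, the order reported for these data.
* **Conversion failure ε = 0.01 per cytosine** — applied independently per
  cytosine (an unmethylated C escapes conversion and reads C with
  probability ε). Only the read-level 0.97 threshold is externally given;
  per-cytosine independence is the simplest mechanism consistent with it,
  and at ε = 0.01 a realistic minority of reads falls below 0.97.
* **Sequencing error 0.002 per base**, uniform substitutions.
* **Depth** — log-uniform on [9, 2704] per (library, amplicon); only the
  range of per-amplicon read counts is known, and the log-uniform choice
  reproduces its heavy spread across three orders of magnitude.
* **Planted effects** — the default truth model hypomethylates *EDNRA* and
  *HMOX1* in patient blood (monotone in severity), hypermethylates *HMOX1*
  in patient NEC non-monotonically (a U-shape over severity, so monotone
  and non-monotone shapes are both exercised), adds a severity trend at
  *GSTM3* in NEC, a −0.5 logit/allele *GSTM3* dosage slope, one CF-only
  NEC co-methylation factor (*TLR5*, *MUC5AC*, *CFTR*, *HMOX1*, λ = 0.6)
  and one inter-tissue *GSTM3* factor (λ = 0.8). Severity is an ordinal
  covariate (controls, mild, intermediary, severe).
* **Reads** are emitted from the converted top strand; about half are
  written as reverse complements (bidirectional sequencing of the PCR
  product). Bottom-strand conversion products are not simulated: amplicon
  primers select one converted strand.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, so stages can be re-run independently and byte-identically.

What the generator does **not** emulate: platform-specific homopolymer
errors, PCR amplification bias, primer artifacts, chimeric reads,
cell-composition heterogeneity within tissues, and any dependence of
conversion efficiency on sequence context. Passing tests therefore
demonstrate correctness of the computational pipeline under the stated
generative model, not robustness to those real-data artifacts.

## Calling

Demultiplexing is exact barcode-prefix matching (after an optional
adaptor skip); barcode and adaptor are trimmed. Amplicon assignment is
ungapped bisulfite-aware matching against every amplicon of the read's
length, in both orientations: a reference cytosine (any context) matches
read C or T, every other base must match exactly; the minimum-mismatch
candidate wins, ties go to the first amplicon in panel order (tie counts
are reported), and a read is unassigned when its best mismatch fraction
exceeds 10%. Ungapped matching is adequate because the amplicons are
short and distinct; indel-containing reads simply fail assignment rather
than being realigned.

The conversion rate of an oriented read is the fraction of non-CpG
reference-cytosine positions read as T. Reads with rate < 0.97 are
discarded; the threshold is inclusive (0.97 retained) since the rule is a
*minimal* conversion rate. Reads with zero informative positions are
retained with a flag — the filter is about conversion evidence, and every
real amplicon contains many non-CpG cytosines, so the case is
pathological.

Calls at CpG positions: C → 1, T → 0, anything else → missing. Per-site
fractions are methylated/total over retained reads; the region mean is the
unweighted mean of site fractions over sites with ≥ 1 call.

## Coverage filter

A region-level measurement with mean p̂ from n retained reads is kept iff
`sqrt(p̂(1−p̂)/n)/p̂ < 0.05` (strict) or `sqrt(p̂(1−p̂)/n) ≤ 0.01`
(inclusive). The binomial SD uses the region read count n, because the
rule is phrased on the mean methylation percentage of a measurement and
its sequencing depth. Degenerate consequences are accepted as printed:
p̂ = 0 or 1 gives SD 0 and automatic retention; zero reads is never
retained. The rule is applied per region-level measurement; a per-site
variant is available through `coverage_filter` directly. Note the rule is
demanding at intermediate methylation: p̂ ≈ 0.2 needs ≥ 1600 reads.

## Statistics

* **Logit transform** with clamping into [ε, 1−ε]; ε defaults to half the
  smallest observable fraction, 1/(2n), which is depth-adaptive and keeps
  the ordering of exact zeros from different depths. Clamping is flagged.
* **Repeatability** — duplicates (x₁,x₂) give the pooled within-pair SD
  sqrt(Σd²/2k) over the k complete pairs, with df = k; pairs broken by a
  missing (filtered) replicate are excluded and counted. A difference-based
  estimator was chosen over a two-way model because only duplicate pairs
  are available.
* **Group comparisons** — Shapiro–Wilk per group and median-centered
  Levene across groups, both at α = 0.05, pick the test: two groups →
  Student (normal, homoscedastic), Welch (normal, heteroscedastic), else
  Wilcoxon rank-sum; more groups → one-way ANOVA or Kruskal–Wallis. The
  diagnostics are stored so every choice is reproducible. Groups with < 3
  values or zero spread are treated as non-normal; fully degenerate data
  (all values equal) returns p = 1. Two-sided throughout; directions are
  descriptive.
* **Per-CpG tests** — Fisher's exact test on 2×2 tables of methylated vs
  unmethylated reads pooled within cases and controls at each site; the
  per-read 0/1 call is the natural counting unit of the calling output,
  and a per-sample dichotomization alternative can be built from the site
  table. Bonferroni families are per tissue (the number of sites actually
  tested in that tissue), mirroring separate blood/NEC reporting; q =
  min(1, m·p). The two-sided p sums hypergeometric point probabilities ≤
  the observed one over the table's support, evaluated in one vectorized
  log-gamma pass (verified against integer-arithmetic enumeration and
  against `scipy.stats.fisher_exact`). Pooling reads across subjects
  ignores between-subject overdispersion, so at high depth these tests are
  powerful but anti-conservative with respect to subject-level inference —
  a property of the design, not a bug in the test.
* **Networks** — Spearman correlations over all unordered pairs of
  (gene, tissue) mean-methylation variables, pairwise-complete with ≥ 5
  pairs, Bonferroni at FWER 10% over the pairs tested; strata (control /
  CF) are analysed separately. Constant variables are skipped and logged.
  For complete data all pairs are computed in one ranked-correlation pass
  with t-approximation p-values, identical per pair to
  `scipy.stats.spearmanr`. Limitation: the t approximation is slightly
  anticonservative in the extreme tail, so the realized null FWER at
  n ≈ 48 is ≈ 11% rather than ≤ 10%.
* **Genotype association** — Spearman correlation of 0/1/2 allele dosage
  with methylation; negative r means methylation decreases per allele
  copy.

## PLS-DA

PLS1 regression (scikit-learn NIPALS backend) of the ±1-coded response on
autoscaled descriptors; 2 components by default (two score axes are
displayed), configurable up to the rank of the centered matrix. A sample
is classified by the sign of its predicted response. The sign-to-class
mapping is configurable because the source description of the mapping is
internally inconsistent with its own coding; the default is
coding-consistent (positive → case). A predicted response of exactly 0 is
assigned to the positive-side class and flagged. Percent correct is
leave-one-out by default (resubstitution optional; both reported by the
pipeline) — the cross-validated figure is the honest one when the choice
is unstated. Missing descriptors are imputed with the class-agnostic
descriptor mean computed inside the training fold (no leakage); a
drop-sample policy is available and dropped samples are counted.

## Pipeline

`RunConfig` carries every threshold (min conversion 0.97, CV 5%, SD 1%,
p 0.05, site FWER 5%, network FWER 10%), PLS options, cohort layout and
seeds; it is serialized verbatim into each run directory. Stages
communicate only through declared TSV/FASTQ/JSON artifacts, the manifest
records seed, input hashes and per-stage counts, and a rerun with the same
config and seed is byte-identical. Filtering counts (reads in, unassigned
barcode/amplicon, failed conversion, measurements failing coverage) are
logged at every step.

## Problem sizes in tests and acceptance

Calibration and error-control experiments use the sizes their properties
demand: 1000 null cohorts for type-I error and family-wise rates, 200
label permutations for the PLS null, 40–60 simulated cohorts for recovery
rates. Read-level checks run a reduced cohort (≈ 10 subjects) at the full
log-uniform depth range; pipeline-level tests use a reduced cohort at a
fixed depth of 1600 reads — the depth at which the coverage filter retains
measurements across the panel's methylation range. Effect-recovery
experiments generate per-site counts binomially from the latent p (the
exact distribution the read simulator induces at zero error), which keeps
them fast without changing the model being tested.

## Known limitations

* Ungapped assignment cannot rescue indel-containing reads.
* Pooled-count Fisher tests are anti-conservative for subject-level
  claims at high depth (see above).
* The Spearman t-approximation slightly exceeds the nominal network FWER.
* The coverage filter's binomial-SD reading retains p̂ = 0/1 measurements
  at any depth ≥ 1 read — the printed rule's degenerate corner.
* With unbalanced classes, null PLS-DA leave-one-out accuracy centers
  above 50% (majority-class pull), ≈ 56% at the 24/48 design.
* Multivariate adjustment for clinical covariates is out of scope.
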