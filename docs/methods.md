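# Methods

This note records the scientific and numerical choices behind the package:
what each stage computes, which parameters matter, what the synthetic
cohort does and does not emulate, and where the design was genuinely open.

## Expression scoring

NRZ scores use the sample standard deviation (ddof=1) of the normal panel.
With a 22-sample panel the unbiased estimator is the conventional choice;
at that size the difference from the population estimator is ~2% of the
score, well below the decision threshold's granularity.

Scores are computed on whatever scale the input matrices declare — by
convention log2(normalized count + 1) — with no internal re-normalization.
Variance stabilization is what makes a Z-score across tissues meaningful;
callers who mix quantification pipelines must normalize upstream.

Degenerate cases:

* **Zero normal-panel variance.**  NRZ is reported as a sign-coded sentinel
  (±1e6) with a `qc_sd_zero` flag rather than dropped: a gene silent across
  every normal tissue but expressed in the tumor is biologically
  informative, and dropping it would hide exactly the genes a board wants
  to see.  The sentinel keeps the column numeric and sorts above any real
  score.
* **ECDF ties.**  The cumulative cancer score counts ties into the
  numerator (`#{values ≤ x}/N`), so the maximum attainable score is exactly
  1 and "top quartile" (> 0.75) has its natural meaning in a 41-tumor
  cohort.

The overexpression flag requires **both** NRZ > 2 and cumulative score
> 0.75.  The two criteria are listed jointly in the trial's selection
procedure without an explicit connective; conjunction is the conservative
reading (every flagged gene passes both), and `flag_mode="or"` is exposed
for the permissive reading.

## Actionable DNA events

DNA rules match on gene + alteration kind, optionally a specific protein
change.  Rule specificity (protein-change match > gene-level match) resolves
conflicts; remaining ties break alphabetically.

A copy-number gain is actionable when a segment overlapping the gene has
log2 ratio ≥ +0.3 or an integer call ≥ 3 **and the segment is focal**
(span ≤ 10 Mb, configurable).  The focality requirement is deliberate: a
whole-arm 2p gain covers ALK but is a chromosome-instability event, common
in this tumor type, and treating it as an ALK-inhibitor indication would
be clinically wrong.  Broad events are reported through the arm-level
caller instead.

Arm-level calls use coverage-weighted mean log2 ratio over segments clipped
to each GRCh37 arm, calling gain/loss at ±0.3 with ≥ 50% arm coverage —
conventional segmental-event defaults, all configurable.  The packaged arm
table pins centromere/length coordinates for chr1–22 and X; a custom table
can be supplied for other builds.

## Mutational signatures

Catalogs are fitted on channel **proportions**, not raw counts, because
catalog size varies by orders of magnitude across patients and the cosine
objective should not.  Exposures come from non-negative least squares and
are renormalized onto the simplex; reconstruction quality is the cosine
distance between the catalog and its reconstruction.  A signature is
"dominant" when its exposure reaches 0.4 — the trial-style readout is
presence/absence of a signature, not its exact weight, and 0.4 cannot be
reached by two signatures simultaneously unless they split nearly all mass.

The packaged signature set is **synthetic**: five deterministic 96-channel
probability vectors occupying the roles of recurrent COSMIC-v2 signatures,
with `sig18` concentrating mass on C>A channels (the reactive-oxygen-species
signature recurrent in neuroblastoma).  Block-structured signatures keep
the NNLS problem well conditioned, which real COSMIC v2 approximately is
for this subset.  Any 96×k column-stochastic matrix can be passed instead.

## Promoter methylation

Per-gene scores are the arithmetic mean beta over QC-passing TSS200 probes
only.  TSS1500/body probes are excluded — promoter-window methylation has
the strongest coupling to expression, and a gene whose promoter probes sit
farther upstream is reported `not_evaluable` rather than scored from the
wrong window.  QC defaults to `detection_p < 0.01` when a detection-p
column exists, otherwise an explicit `qc_pass` column, otherwise all-pass.
Probes annotated to several genes contribute to each (EPIC annotation
convention).  Thresholds are strict as printed: beta > 0.80 hyper,
beta < 0.20 hypo, boundaries neutral.

Concordance between expression and methylation is a Spearman rank
correlation (monotone, not linear, is all the coupling claims) plus the
fraction of overexpression-flagged genes that are hypomethylated.  Constant
inputs yield an explicitly undefined correlation with a reason, while the
fraction is still reported.

## Drug recommendation

DNA priority is absolute: any rule-matched DNA alteration selects its drug
regardless of expression evidence (the expression trail for that drug is
still attached to the report).  Expression scoring ranks drugs by
`(n flagged target genes, max NRZ)`; the count leads because a board reads
convergent evidence across a pathway as stronger than one extreme value.
Exact ties break alphabetically and are flagged `tie_broken` — the trial
resolved ties by human deliberation, and a deterministic stand-in is
required for reproducibility.

Bortezomib and lapatinib ship without expression rules rather than with
invented target lists; they are selectable only through rules the user
adds.  CTBP2 and RAD23 appear in the vorinostat rule as printed in the
trial's evidence tables but are flagged `contextual` in evidence trails,
since they are board-contextual markers rather than canonical direct
HDAC-inhibitor targets ("RAD 23" is taken as the RAD23 family symbol).
Hooks for pluggable scorers (network-based methods, drug-response and
drug-sensitivity signatures) are interface-only: those algorithm families
belong to an upstream proprietary report generator and are not defined
here.

## Synthetic cohort generator

The generator emulates the study conditions a 20-patient HRNB cohort
presents to this pipeline:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 20 | cohort size |
| `n_normal_samples` / tissues | 22 / 14 | normal reference panel (tissue labels round-robin, metadata only) |
| `n_cancer_reference` | 41 | HRNB expression reference cohort |
| MYCN amp / ALK SNV / ALK CN-gain | 0.45 / 0.05 / 0.05 | genomic feature prevalences |
| `overexpression_prob` | per gene | e.g. HDAC2 0.85, MYCN 0.90, LIN28B 1.0, ODC1 0.5, ALK 0.90 |
| `effect_lfc` | 3.0 | log2 shift of an overexpressed tumor gene above its normal mean |
| `ref_shift` | 1.0 | milder shift of prone genes in the cancer reference cohort |
| `gene_sd` | 0.5 | per-gene log-scale noise sd |
| `beta_coupling`, `beta_noise` | 0.45, 0.08 | methylation–expression coupling map and noise |
| `mutations_per_catalog` | 150 | catalog size (sig18-dominant in 75% of patients, dominant weight 0.7) |
| `passenger_mean` | 30 | mean coding passengers per exome (~1 mut/Mb over 30 Mb callable) |
| arm events | gains 1q/2p/7q/17q, losses 1p/3p/11q, each 0.5 | recurrent segmental changes |

Binary features are assigned by **exact quota** — `round(p·n)` patients,
then shuffled — so a 20-patient fixture hits printed prevalences exactly
(9 MYCN-amplified, 17 HDAC2-overexpressed, 15 sig18-dominant, ...);
`iid_features=True` switches to independent Bernoulli draws, and
`strict_quota=True` rejects non-integral quotas.  All randomness flows from
one `numpy` generator seeded by `CohortConfig.seed` (default 12012), and
fixtures round-trip byte-identically.

Expression is lognormal-style on the log2 scale (gene means uniform on
[3, 8], Gaussian noise).  The study never describes its expression
distribution — only the Z and percentile thresholds — so this is a
stand-in chosen for variance stability, not an estimate of the real data.
The cancer reference receives an attenuated shift (`ref_shift`) for
overexpression-prone genes: real HRNB reference cohorts share part of the
tumor's signal, and this keeps the percentile score informative without
saturating it.

Methylation is coupled to expression through
`beta = base − coupling·tanh(z/2) + noise`, with hypermethylated baselines
for SRC/LCK, a slightly hypomethylated baseline for SOX2, and TSS200 probes
(plus one body probe) per gene; BRAF, PDGFRB and HDAC8 get only TSS1500
promoter probes, reproducing the annotation gap that removes such genes
from promoter scoring.  `beta_coupling = 0.45` is the documented floor for
reliable concordance recovery: genes at the flagging boundary (NRZ ≈ 2)
then map to beta ≈ 0.16, safely inside the hypomethylated class, so the
planted negative correlation and the hypomethylated majority among
overexpressed genes are recovered in ≥ 95% of seeded replicates at 200
genes.  Weaker coupling leaves boundary genes straddling beta = 0.2 and
recovery degrades.

What the generator does **not** emulate: raw reads, aligner/caller error
profiles, IDAT-level array artifacts, tumor purity and subclonality, batch
effects, inter-gene correlation structure, or clinical outcomes (response,
toxicity, survival — pass-through annotation only).  Passing tests
therefore demonstrate correctness of the decision procedure on data with
the assumed structure, not robustness to real-data artifacts.

## Pipeline and reporting

Per-patient failures are contained: the failing patient is recorded with
its error and the run continues (`strict=True` re-raises).  Outputs carry
provenance (config hash, seed, package version) and deliberately no
timestamps, so reruns on identical inputs are byte-identical.  Oncoprint
columns are sorted by patient id; summary percentages are rounded to whole
numbers in the table while raw fractions are kept in machine output.
TSV writers use `%.17g` floats and readers `float_precision="round_trip"`,
making fixture round-trips exact.

## Problem sizes

The default test cohort is 20 patients × 170 genes (20 named + 150
background), the concordance property runs 50 single-tumor replicates at
200 genes, and signature recovery uses 20 seeds at 5,000 mutations — sizes
chosen so the full suite exercises every stage end-to-end in a few seconds
while keeping quota arithmetic exact at the printed prevalences.

## Known limitations

* The six-drug rulebook is the trial's; extending it to other panels is
  config-only but the packaged gene-region table covers only the genes the
  default DNA rules need (ALK, MYCN).
* Signature fitting assumes the supplied matrix spans the catalog; no
  de novo extraction.
* The expression thresholds (2, 0.75) are fixed trial constants, exposed
  as module constants rather than per-call parameters.
* `cum_pct` from a 41-tumor cohort has granularity 1/41; percentile
  comparisons finer than that are meaningless.
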