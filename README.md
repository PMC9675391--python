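# tumorboard

A molecular tumor-board decision pipeline for newly diagnosed high-risk
neuroblastoma (HRNB).  Given one tumor's molecular evidence — RNA expression,
somatic small variants, copy-number segments, fusion calls, and promoter
methylation — the package scores the evidence the way a precision-oncology
tumor board does and selects one of six targeted agents (bortezomib,
crizotinib, dasatinib, lapatinib, sorafenib, vorinostat) from a declarative
drug rulebook.

It is written for computational-biology and translational-oncology teams who
need a tested, reproducible implementation of this decision procedure:
patient-level sequencing data from such trials sit behind controlled access,
so a seeded synthetic-cohort generator with ground truth ships as a
first-class module.

## The scoring model

**Expression.**  For gene *g* with tumor value *x_g*, the NRZ score
("normal Z-score") standardizes against a 22-sample / 14-tissue normal
reference panel:

```
NRZ(g) = (x_g − mean_normal(g)) / sd_normal(g)        (sample sd, ddof=1)
```

and the cumulative cancer reference score is the empirical-CDF percentile of
*x_g* within a 41-tumor HRNB reference cohort (ties count as ≤).  A gene is
overexpression evidence when **NRZ > 2 and cumulative score > 0.75** (top
quartile among HRNB tumors).

**DNA.**  Actionable alterations — e.g. an ALK F1174L SNV, a focal ALK
copy-number gain, or an ALK fusion — are matched against the rulebook's DNA
rules and **always take priority** over expression evidence.  Arm-level
segmental changes (1q/2p/7q/17q gains, 1p/3p/11q losses) are called from
coverage-weighted mean log2 ratios per chromosome arm (GRCh37) and reported
in the oncoprint, not as drug evidence.

**Methylation.**  Probe-level beta values are averaged over QC-passing
TSS200 probes per gene; beta > 0.80 is hypermethylated, beta < 0.20
hypomethylated.  A concordance report quantifies the expected negative
relation between promoter beta and NRZ.

**Mutational signatures.**  96-channel trinucleotide catalogs are fitted by
non-negative least squares against a signature matrix (a packaged synthetic
stand-in for COSMIC v2; a real matrix can be supplied), with exposures on
the simplex and cosine reconstruction error reported.

**Selection.**  If a DNA rule fires, its drug is chosen.  Otherwise each
drug scores `(number of overexpression-flagged target genes, max NRZ among
them)` and the highest-scoring drug wins; exact ties break alphabetically
and are flagged.

## Worked example

```python
from tumorboard import (generate_cohort, load_rulebook, score_patient,
                        classify_actionable, recommend, cohort_drug_counts)

cohort = generate_cohort()          # default 20-patient cohort, seed 12012
rulebook = load_rulebook()
recs = []
for p in cohort.profiles:
    scores = score_patient(p.expression, cohort.normal_panel, cohort.cancer_panel)
    events = classify_actionable(p.variants, p.segments, p.fusions, rulebook)
    recs.append(recommend(p.patient_id, scores, events, rulebook))
for drug, (n, frac) in cohort_drug_counts(recs).items():
    print(f"{drug:12s} {n:2d}  ({frac:.0%})")
```

prints

```
crizotinib    3  (15%)
sorafenib     1  (5%)
vorinostat   16  (80%)
```

i.e. on the default synthetic cohort the board's HDAC-inhibitor-heavy
selection pattern emerges: most patients carry several overexpressed HDAC
targets (vorinostat), a few route to ALK inhibition — including the planted
ALK F1174L patient, whose recommendation shows the DNA-priority trail:

```
P008 crizotinib dna
  DNA ALK ALK SNV F1174L
  expression ALK overexpressed (NRZ 5.07)
```

The same flow is available from the shell:

```
tumorboard synth-cohort --out fixtures --seed 12012
tumorboard run --out results_dir
```

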