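# tacfis

Tacrolimus clearance classification in the early post-liver-transplant
period: concentration-to-dose-ratio (CDR) phenotypes, clinical and
genotype-based metabolizer classifications, a two-tier SNP association
screen, weekly regression models, and concordance analysis — all runnable
end to end on synthetic therapeutic-drug-monitoring (TDM) cohorts.

## The problem

After allogeneic liver transplantation, tacrolimus dosing is steered by
daily trough-concentration monitoring. Patients differ sharply in how fast
they eliminate the drug; the standard summary is the CDR,

```
CDR = trough concentration (ng/mL) / weight-adjusted daily dose (mg/kg),
```

with high CDR meaning slow elimination. Because graft (donor) and
recipient-intestine genomes both metabolise the drug, a recipient-only
CYP3A5 rs776746 genotype classification (EM/IM/PM for AA/AG/GG) predicts
the observed clearance phenotype poorly. This package implements, as a
tested reusable pipeline, the chain of analyses that addresses this:

* **pk_features** — natural-log CDR, per-patient weekly medians over
  post-operative days 1–28, and per-center month-1 quartile anchors
  (Q1, Q3).
* **classifiers** — the retrospective **clinical-FIS** rule (more than
  half of the four weekly medians above Q3 → slow eliminator SE, below
  Q1 → fast FE, else IE); **CPIC-EIP** from a single rs776746 genotype;
  **paired-EIP** from donor and recipient jointly (both AA/AG → EM,
  exactly one GG → IM, both GG → PM); and **genetic-EIP**, the paired
  classification refined by two minor-effect loci (recipient SULT1E1
  rs3775770, donor SLC7A8 rs7141505), with the slow/fast refinement
  direction learned from training data.
* **association_screen** — per-week Welch t-tests of log CDR between
  dominant-coded genotype groups, retention rules (p < 0.05 in
  consecutive weeks, MAF > 0.1, LD pruning at r² > 0.5, region
  preference), and training→validation replication, with a complete
  filter audit.
* **regression_models** — weekly OLS of log CDR on donor+recipient
  CYP3A5 indicators, adjusted R², forward selection of minor loci, and
  single-locus fits within paired-EM/PM strata.
* **concordance_outcomes** — 3×3 agreement matrices (FE↔EM, IE↔IM,
  SE↔PM), per-group outcome rates with chi-square tests, and
  Kruskal–Wallis/Dunn comparisons.
* **synthetic_cohort** — a calibrated generator (Hardy–Weinberg
  genotypes with optional LD, genotype-dependent clearance, early
  post-operative CDR decline, feedback dosing toward a 6–8 ng/mL trough
  window, exposure-dependent outcomes) so every stage is testable with
  no patient data.

## Worked example

```python
from tacfis.synthetic import GeneratorConfig, simulate_cohort
from tacfis.io import pk_frame
from tacfis.pipeline import classify_all, labels_by_scheme, stable_dose_by_group
from tacfis.concordance import agreement

cohort = simulate_cohort(GeneratorConfig().scaled(1000), seed=1)
pk = pk_frame(cohort.pk)
labels = labels_by_scheme(classify_all(pk, cohort.genotypes))
fis = labels["clinical-FIS"]
print(stable_dose_by_group(pk, fis))
for scheme in ("CPIC-recipient", "paired-EIP", "genetic-EIP"):
    print(scheme, agreement(fis, labels[scheme], scheme).overall_pct)
```

prints

```
group   n  mean_dose_per_kg  sd_dose_per_kg
   FE 106          0.100346        0.026502
   IE 834          0.050576        0.022042
   SE  60          0.020913        0.006808
CPIC-recipient 39.5
paired-EIP 54.5
genetic-EIP 62.0
```

Fast eliminators need a stable-phase dose near 0.10 mg/kg, five times the
slow eliminators' 0.02 mg/kg, and the agreement with the clinical
classification rises monotonically as the genetic classification
incorporates the donor genome and then the minor-effect loci — the
qualitative behaviour of the real cohorts this generator emulates.

The same chain is scriptable from a shell:

```
tacfis simulate --seed 1 --n 1000 --out-dir run/
tacfis features --pk run/pk.tsv --out-dir run/
tacfis classify --pk run/pk.tsv --genotypes run/genotypes.tsv --out-dir run/
tacfis concord  --labels run/labels.tsv --out-dir run/
```

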