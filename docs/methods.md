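# Methods

## Phenotype definitions

The concentration-to-dose ratio is CDR = trough (ng/mL) / (daily dose (mg)
/ weight (kg)). CDRs are normalised by **natural** logarithm before any
pooling; the convention is pinned by the published weekly medians the
package reproduces in its tests (ln 228 = 5.43, ln 122 = 4.80 to two
decimals). The weekly phenotype is the per-patient median of daily log-CDR
values within post-operative weeks 1–4 (days 7(w−1)+1 … 7w). Medians are
taken on the log scale; since the median commutes with monotone
transforms this equals the log of the median CDR, and is documented only
for clarity. Days without monitoring simply shrink a week's support; a
week with no observation is missing and never counts toward a
classification tally.

Month-1 quartile anchors (Q1, Q3) are computed per center over the pooled
patient-day log-CDR observations of days 1–28. Pooled patient-days rather
than per-patient summaries is a choice — the alternative is defensible —
and the quantile convention is configurable (default: linear interpolation
between order statistics, R type 7). Fewer than four observations refuse
to anchor a center.

## Classification rules

**clinical-FIS.** A patient with more than half of the four weekly
medians (≥ 3; missing weeks count toward neither side) strictly above the
center's Q3 is a slow eliminator (SE); strictly below Q1, fast (FE);
otherwise intermediate (IE). The SE rule is evaluated first; with the
default majority of 3 the two rules cannot both fire, so the order is
fixed only for determinism. The majority threshold stays 3 regardless of
missing weeks: "more than half" is read against the four nominal weeks,
not the observed ones.

**CPIC-EIP.** AA → EM, AG → IM, GG → PM from a single rs776746 genotype
(recipient or donor). The pooled expresser grouping used by the
association analyses (AA/AG vs GG) is exposed separately
(`classify_cpic_pooled`).

**paired-EIP.** Donor and recipient rs776746 jointly: zero, one or two GG
calls give EM, IM, PM.

**genetic-EIP.** Paired-EM patients whose recipient SULT1E1 rs3775770
genotype lies on the slow side move to IM; paired-PM patients whose donor
SLC7A8 rs7141505 genotype lies on the fast side move to IM. Refinement is
one step toward IM only — EM can never become PM — and a missing minor
call or an unlearnable direction leaves the paired label in place. Which
genotype group of each minor locus is "slow" is not something the label
definitions fix, so it is learned from training data
(`infer_minor_direction`): within the refined stratum, the genotype group
with the lower mean week-2–4 log CDR is fast; groups under 5 patients or
exact ties leave the locus unrefined. A config override accepts an
explicit direction map.

## Association screen

Loci are contrasted as dominant-coded two-group splits (minor-allele
carriers vs non-carriers by default; explicit per-locus groupings such as
GG vs CC/CG are accepted). Weekly group differences use Welch's t-test by
default — the pooled-variance Student test is selectable — and two
identical constant groups report t = 0, p = 1 rather than an undefined
ratio.

Training-phase retention applies four rules, each audited per locus:

1. p < 0.05 in at least 2 **consecutive** weeks (the stricter ≥ 3 reading
   is available by config; the rule's phrasing is genuinely ambiguous and
   the choice is surfaced, not buried);
2. MAF > 0.1;
3. LD pruning: within each connected component of the r² > 0.5 graph
   (genotype-dosage Pearson r²) exactly one locus is kept;
4. the survivor of rule 3 is chosen by region rank (exonic/UTR/splicing
   over intronic over intergenic/upstream), then smaller minimum weekly
   p, then lexicographic key — fully deterministic and idempotent.

A training-retained locus replicates if its validation-cohort p is below
0.05 in at least one week (configurable). No multiple-testing correction
is applied by default: the two-tier design substitutes replication for
correction, and the test suite verifies by simulation that replication
lowers the false-discovery proportion against the one-tier screen at
matched settings. Cross-population allele-frequency spread is summarised
as Diff = max − min over the five reference populations.

## Regression models

Weekly models are OLS on complete cases (no imputation), dominant-coded
indicators, with adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) as the
headline summary. The optimal-model search is forward selection on top of
an always-included donor+recipient CYP3A5 base: at each step the candidate
with the smallest coefficient p enters if p < 0.05, and candidates
collinear with the current design are skipped. Forward selection from a
fixed base is the simplest procedure that reproduces the published
"base + added SNPs" model structure. Stratified fits (paired-EM/PM) are
single-predictor OLS and refuse strata under 10 complete cases.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes, not any
particular patient data.

**Genetics.** Donor and recipient genomes are independent (deceased-donor
transplantation). Each locus is drawn in Hardy–Weinberg proportions at
its configured MAF; LD pairs are drawn through two-locus haplotype
frequencies with D = r·√(p_a q_a p_b q_b), with the feasible r² bound
reported when a target is unreachable. The default panel: rs776746
(MAF 0.28, splicing), rs2242480 (0.25, intronic, r² = 0.52 with rs776746,
no effect of its own — it associates only through LD), rs3775770 (0.22),
rs7141505 (0.16).

**Clearance.** Baseline log CDR = μ + Σ genotype effects + center offset
+ patient effect N(0, σ_p). Effects are dominant-coded: CYP3A5
non-expressers (GG) +0.35 per genome; recipient rs3775770 minor-allele
carriers +0.30; donor rs7141505 TT −0.70. Daily log CDR adds an
early-phase trend (rise to +0.95 over days 2–3, linear decline to 0 by
day 11, plateau after) and day noise N(0, σ_d).

**Dosing.** Trough = exp(log CDR) × dose/weight. Dose starts at
0.04 mg/kg and every 2 days, if the last trough fell outside the 6–8
ng/mL window, is multiplied by 7/observed-trough clipped to ±50%, within
0.5–10 mg/day — the dose range seen clinically. The deadband mirrors
routine TDM practice; no controller is specified by the source analyses,
and this is the simplest mechanism producing the observed dose ramp over
weeks 1–2.

**Outcomes.** Binary outcomes (leukocytosis, infection, rejection) are
Bernoulli with logistic probabilities in the week-1 mean trough; ALT and
creatinine are linear plus Gaussian noise. Rejection has a negative slope
(under-exposure risk), the others positive.

**Calibration.** Defaults were fixed once against four clinical anchors:
clinical-FE mean stable-phase (weeks 3–4) dose ≈ 0.101 mg/kg at n = 1000;
donor+recipient CYP3A5 week-1 adjusted R² near the published 13–18% band
(measured 0.16–0.21 across seeds); pooled month-1 log-CDR SD near 0.8;
and a roughly three-fold leukocytosis excess of SE over FE (≈ 7% vs
≈ 24%). One structural finding from the calibration: the shallow
published FE/IE/SE dose ratios (0.101/0.068/0.038 mg/kg) are only
reachable when most CDR dispersion is within-patient day-to-day noise
(σ_d = 0.60) over a comparatively narrow between-patient spread
(σ_p = 0.35); a wide between-patient lognormal makes the fast tail far
too fast. Under that constraint the generator's month-1 quartiles sit
about 0.2 log units above the published (4.43, 5.47) and its IE/SE doses
about 0.015 mg/kg below their published counterparts — the FE-dose anchor
was prioritised, since all three cannot hold simultaneously under a
lognormal clearance model. The within-patient day-to-day CDR variance
itself is a free parameter: no published value constrains it.

**What the generator does not emulate.** Real TDM involves discrete
tablet strengths, dose holds for toxicity, drug–drug interactions
(notably CYP3A4 inhibitors), assay-specific bias between centers beyond a
location shift, time-varying liver regeneration differing by patient, and
relatedness structure in genotypes. Passing tests therefore demonstrate
that the pipeline's logic is correct and well calibrated under the stated
generative assumptions, not that the generator reproduces any real
cohort's joint distribution; in particular the absolute agreement
percentages between clinical-FIS and the EIP schemes are lower here
(≈ 40/55/62% for CPIC/paired/genetic at n = 1000) than the published
real-data values (35.56/58.45/73.2%), while their ordering is robustly
reproduced.

## Numerical choices and degenerate inputs

- Quantile convention configurable; default linear (R type 7).
- Genotype calls canonicalised by allele sort; missing is explicit, with
  a recognised token set ("./.", "NA", "0", …).
- Monomorphic loci are untestable, never an error; zero-variance dosage
  makes r² undefined, treated as not-in-LD.
- HWE chi-square (1 df) is undefined for monomorphic samples (NaN).
- Ties in the minor-allele choice break lexicographically.
- Percentages are reported at 3 significant figures, matching the mixed
  2-dp/1-dp style of the published rates; unrounded values stay available.
- Problem sizes used by the test suite and reproduction script — 1,000
  patients for end-to-end checks, 114/170 for training/validation
  simulations, 200 replicates for power and selection-rate estimates —
  keep Monte-Carlo error comfortably below the asserted tolerances.

## Known limitations

- The refinement direction of genetic-EIP is data-driven; on small
  strata it can remain unset, leaving paired labels unrefined (flagged).
- The screen's t-tests do not adjust for center; multi-center cohorts
  lose power to center offsets (the training tier is single-center, so
  the default screen matches the design it models).
- Forward selection inherits the usual instability of stepwise methods;
  it reproduces the published model structure, not a recommendation.
- Cohen's kappa is deliberately out of scope for agreement; only raw
  percentage agreement is reported.
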