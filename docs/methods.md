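# Methods

`pkpgx` implements a pooled pharmacokinetic–pharmacogenetic analysis of
single-dose crossover bioequivalence trials of valsartan, olmesartan and
hydrochlorothiazide, together with a synthetic-cohort generator that
reproduces the statistical structure such an analysis assumes. This note
describes the models, the defaults and the reasoning behind the choices
that were genuinely open.

## Non-compartmental analysis

Each concentration–time profile is analysed without a structural model:

- **Cmax, tmax** are read directly off the observed curve; ties go to the
  earliest time.
- **AUCt** is the linear trapezoidal rule up to the last quantifiable
  sample at or before 48 h. Linear-up/linear-down and log-linear-down
  variants are deliberately not the default, since only "the trapezoidal
  rule" is specified by the workflow being emulated; the end anchor is the
  last quantifiable sample rather than exactly 48 h.
- **Ke (λz)** is the negated slope of ordinary least squares on ln C vs t
  over a terminal tail of quantifiable points strictly after tmax.
  Commercial NCA tools leave tail selection to the analyst; here the
  default scans all tails of ≥ 3 points and keeps the one with the highest
  adjusted R² (ties to the longest tail), with `fixed_last_3` available as
  an alternative. A non-declining tail makes the profile non-evaluable.
- **AUC∞** = AUCt + Clast/Ke, with the extrapolated percentage flagged
  above 20 %. **t1/2** = ln 2/Ke, reading the conventional −ln 2/slope as a
  sign convention on the fitted slope.
- **Normalisation**: X/D = X/dose; X/DW = X·weight/dose (units
  ng·h·kg/mL·mg for AUC∞/DW).

**BLOQ policy** (not specified by the emulated workflow, so fixed here):
samples below the limit of quantification before the first quantifiable
one — including the mandatory pre-dose sample — are set to 0 and retained;
BLOQ samples embedded between quantifiable ones are excluded; trailing
BLOQ samples are truncated. Profiles with no quantifiable sample are
logged as non-evaluable and excluded listwise downstream.

**Crossover aggregation**: valsartan and hydrochlorothiazide test
formulations were bioequivalent to the reference, so each subject's
parameters are the arithmetic mean over all T and R periods (`mean_TR`);
olmesartan uses reference periods only (`reference_only`). Because every
parameter is averaged arithmetically, the algebraic identity
t1/2 = ln 2/Ke holds per period but not after aggregation; invariant
checks therefore run on per-period results.

## Genotype → phenotype translation

Star alleles are defined by bundled PharmVar-style tables restricted to
the genotyping panel (`src/pkpgx/data/`); the reference allele *1 is the
absence of every defining variant. Unphased diplotype calling enumerates
all allele pairs whose summed defining-variant counts reproduce the
observed counts at every locus. Phasing is unobservable, so when several
pairs are consistent the caller prefers the pair containing the allele
defined by the most variants (the nested-allele rule: SLCO1B1 *1/*15 over
*5/*37) and reports the alternatives as ambiguity diagnostics; counts no
pair can produce, or missing defining calls, yield an explicit
"indeterminate".

Phenotypes follow CPIC-style rules: the CYP2D6 activity score (0 → PM,
0.25–1 → IM, 1.25–2.25 → NM, > 2.25 → UM) with copy-number handling — a
deletion leaves the remaining (higher-activity) allele, each copy beyond
two duplicates the higher-activity allele, copy number 0 scores 0;
SLCO1B1 normal/decreased/poor function (NF/DF/PF) from the count of
decreased-function alleles; two-way function lookups for CYP3A5, CYP3A4
(DPWG-style), CYP2C9, CYP2C19, CYP2B6, CYP2A6 and UGT1A1 (rs887829 as the
*28 surrogate). CYP2C8 assignments are provisional literature-based
fixtures. Which allele a duplication amplifies is unobservable from the
assays emulated here; duplicating the higher-activity allele is a
documented convention.

## Statistical cascade

Continuous outcomes pass a Shapiro–Wilk gate at α = 0.05 on the raw scale,
then — if rejected and all values are positive — on the natural-log scale
(base unspecified in the emulated workflow; natural log chosen);
otherwise the route is nonparametric. Two-group comparisons use a pooled
t-test or Mann–Whitney; k > 2 groups use one-way ANOVA or
Kruskal–Wallis, each with Bonferroni-adjusted pairwise post hocs
(pairwise t-tests or Mann–Whitney; the correction applies within one
post-hoc family only, preserving the exploratory design — no
across-variant correction). The pooled (not Welch) t-test is the default
so that the single-binary-predictor regression β/p reproduce the t-test
exactly; Welch is available by flag. Predictors with univariate p < 0.05
enter an OLS model on the gate-chosen scale; perfectly collinear columns
are dropped with a warning and the model refitted. Paired
pharmacodynamic tests (SBP, DBP, HR, QTc changes at t3h/t6h) are paired
t-tests; a zero-variance nonzero change returns a flagged
machine-floor p rather than raising. Incidence tables use Pearson's χ²
(uncorrected), switching to the two-sided Fisher exact test for 2×2
tables whenever any expected count is below 5 — the classical reading of
"when appropriate". Wider tables are merged to 2×2 by the analysis
grouping rules before exact testing.

## Synthetic cohort

The generator emulates the pooled seven-trial structure: trials 1–4
(valsartan ± hydrochlorothiazide, four periods TTRR, replicate design)
and 5–7 (olmesartan + hydrochlorothiazide, two periods TR), enrolment
6/4/8/8/12/10/16, 64 subjects, 27 women.

- **Demographics**: per-sex truncated normals at the published cohort
  moments (men 24.6 y, 1.78 m, 78.8 kg; women 31.2 y, 1.62 m, 60.6 kg),
  ages truncated to 18–55 and weight/height pairs rejected until BMI lies
  in the eligible 18.5–30 kg/m² window. Truncation lifts the female
  conditional mean weight by ~0.7 kg; tests compare against the truncated
  expectation, not the unconditional moments.
- **Genotypes**: Hardy–Weinberg, independent across loci and genes
  (the partial linkage disequilibrium among the three ABCB1 variants is
  not modelled — no haplotype table is available — but a haplotype
  frequency input can replace the per-locus draw). Transporter SNVs are
  drawn allele-wise from European frequencies; star-allele genes are
  drawn haplotype-wise so the emitted per-locus calls are internally
  consistent, which also yields locus-level HWE marginally. CYP2D6 copy
  number defaults to 2 with a configurable distribution.
- **PK model**: one-compartment, first-order absorption with lag:
  C(t) = (D/V)·ka/(ka−ke)·(e^(−ke(t−tlag)) − e^(−ka(t−tlag))). CL/F and
  V/F scale proportionally with body weight (reference 71 kg), so
  dose/weight correction removes body size exactly, half-life is
  weight-free, and AUC/D is higher in lighter subjects — the behaviour the
  DW-corrected analysis assumes. Between-subject variability is
  log-normal (SD of log: CL 0.25, V 0.20, ka 0.35, matching the published
  exposure CVs of 20–45 %); within-subject between-period variability is
  exposed as a config and defaults to 0, since no such component is
  reported. Proportional log-normal assay error defaults to CV 15 % (no
  assay error model is published).
- **Base parameters** (71-kg adult): valsartan CL/F 5.85 L/h, V/F 50.9 L,
  ka 2.2 h⁻¹, tlag 0.3 h; olmesartan 6.80 / 56.7 / 2.0 / 0.3;
  hydrochlorothiazide 21.1 / 140 / 2.2 / 0.25. These put noise-free NCA
  AUC∞ and Cmax within ±25 % of the published study means (e.g. valsartan
  160 mg AUC∞ ≈ 28,500 vs 27,359 ng·h/mL). A one-compartment model cannot
  simultaneously match AUC∞, Cmax and the published ~9 h terminal
  half-lives: Cmax/AUC∞ = ke·e^(−ke·tmax) is bounded by 1/(e·tmax), so a
  profile with the published exposure ratio forces a faster single
  elimination rate than the shallow terminal phase of the real
  multiphasic curves. Exposure fidelity was prioritised; simulated
  half-lives land near label-scale disposition values (~5–6 h) and tmax
  near the low end of the published ranges. Conclusions about half-life
  *contrasts* (sex, CYP2D6) are unaffected because effects are injected
  multiplicatively.
- **Covariate effects** (multiplicative, all configurable; an effect of
  1.0 for every covariate yields a covariate-free population): ABCB1
  rs1045642 T/T halves valsartan ka (slower absorption, higher tmax);
  SLC22A1 rs34059508 A carriers get 0.76× hydrochlorothiazide CL/F
  (1/0.76 ≈ 1.32× AUC∞/DW, the published group ratio); CYP2D6 PM gets
  0.65× valsartan ke at fixed CL (longer t1/2, exposure unchanged); women
  get 1.35× valsartan CL/F (lower DW-corrected exposure) and 1.12×
  hydrochlorothiazide ke (shorter t1/2, exposure unchanged).
- **Sampling schedule**: "at least 17 samples to 48 h" is fixed as 0, 0.5,
  1, 1.5, 2, 2.5, 3, 3.5, 4, 5, 6, 8, 10, 12, 24, 36, 48 h — dense through
  the 1–5 h absorption window with ≥ 3 terminal points. Assay LLOQs:
  1.01 (hydrochlorothiazide), 2.51 (olmesartan), 20.02 (valsartan) ng/mL;
  the pre-dose sample is below quantification by design.
- **Safety**: each ADR term (headache, dizziness, postural dizziness,
  nausea) is an independent Bernoulli draw with logit = intercept +
  slope·z(log AUC∞); intercepts are set to the published marginal
  incidences (33 %, 4.7 %, 3.1 %, 3.1 %) and the default slope 1 encodes
  the observed higher exposure among subjects with ADRs. SBP/DBP decrease
  and HR increase at t3h/t6h and the +12.5 ms QTc change at t6h are normal
  draws around configured means, with an exposure coefficient on the BP
  changes.
- **Seeding**: every stage draws from
  `default_rng(SeedSequence([master_seed, stage_code, indices…]))`, so any
  stage is independently re-runnable and identical configurations give
  byte-identical outputs.

## What the simulation does and does not establish

The generator reproduces the data *structure* — crossover periods, LLOQ
censoring, HWE genotypes, exposure-linked safety — not real
pharmacology: no multi-compartment disposition, no drug–drug interaction
(the olmesartan tmax shift under the 25 mg hydrochlorothiazide dose is
not mechanistically simulated), no linkage disequilibrium, no amlodipine.
Passing the recovery and calibration studies shows the analysis chain is
unbiased and correctly calibrated under its own assumptions; it says
nothing about whether those assumptions hold in real cohorts.

## Validation studies and problem sizes

`scripts/acceptance.py` (and `tests/test_acceptance.py`) recompute:

1. the three Fisher exact p-values and ADR proportions from the pooled
   study's printed contingency counts;
2. oracle equivalence — trapezoidal AUC vs the analytic one-compartment
   integral on 200-point noise-free grids (< 1 %), and the Fisher test vs
   brute-force hypergeometric enumeration (exhaustive to N = 25 plus 500
   random tables to N = 200);
3. effect-sign recovery over 200 replicates of n = 200 single-period
   cohorts per drug (expected ≥ 95 % per effect), with detection
   fractions also reported at the emulated per-drug sizes (valsartan 26,
   hydrochlorothiazide 58);
4. null calibration — 500 covariate-free replicates at n = 26; each
   cascade test's type-I rate should sit within a 3-SE binomial band of
   5 %;
5. NCA identities (t1/2·Ke = ln 2, AUC∞ ≥ AUCt, normalisation
   round-trips) on the per-period results of one simulated cohort.

Replicate counts and cohort sizes were chosen so each study pins its
quantity well inside its tolerance while the whole battery runs in a few
minutes on one core.

## Known limitations

- Transporter genes (ABCB1, ABCC2, ABCG2, SLC22A1) lack star-allele
  definitions; they are analysed as raw genotypes, as in the emulated
  study.
- Hybrid CYP2D6 structures are not resolved beyond the copy-number
  convention described above.
- The multivariate step inherits the exploratory design: predictor
  selection by univariate p < 0.05 is not a causal adjustment strategy
  and no across-test multiplicity correction is applied.
- Mixed-effects/period modelling and formal bioequivalence (TOST/90 % CI)
  analyses are out of scope.
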