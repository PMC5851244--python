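# Methods

## Scores

**qSOFA** counts three bedside criteria with inclusive boundaries: systolic
blood pressure ≤ 100 mmHg, respiratory rate ≥ 22 breaths/min, and altered
mental status (any AVPU level other than Alert). **qSOFA + lactate** adds
one point when plasma lactate ≥ 2.0 mmol/L; the boundary is inclusive and
the threshold is a configurable parameter (`lactate_threshold`, default
2.0 mmol/L) because some clinical texts phrase hyperlactatemia as a strict
inequality. **SIRS** uses the consensus criteria with strict inequalities
(temperature > 38 or < 36 °C; heart rate > 90/min; respiratory rate
> 20/min or PaCO₂ < 32 mmHg; white cells > 12 or < 4 ×10³/µL); boundary
values do not score, so (36.0 °C, 91/min, 20/min, 4.0) scores exactly one
point, for the heart rate.

**SOFA** sums six organ subscores of 0–4. The cut-point tables ship as
data files (`sepscore/data/sofa_bands.json`, `sirs_criteria.json`) rather
than code so the exact bands used are inspectable and versioned. Two
implementation choices matter:

- *CNS from AVPU.* ED mentation is recorded on the AVPU scale, not the
  Glasgow Coma Scale. The mapping A/V/P/U → 0/1/3/4 comes from the
  conventional AVPU→GCS anchors (15/13/8/3) pushed through the standard
  SOFA CNS bands (15→0, 13–14→1, 10–12→2, 6–9→3, <6→4). V→1 rather than
  V→2 is a judgment call — GCS 13 sits at the top of its band — and the
  mapping is a data-file entry, so a user who prefers the conservative
  variant can change one number.
- *Respiration without ventilation status.* The canonical SOFA table
  requires respiratory support for scores 3–4; ventilation status is not
  part of this package's data schema, so the bands are applied on
  PaO₂/FiO₂ alone (<400→1, <300→2, <200→3, <100→4). This can overscore
  unventilated patients with very low ratios.
- *Missing organ inputs* score 0 and are flagged `imputed_normal` on the
  result — ED records routinely lack FiO₂ — and urine-output renal
  criteria are not implemented (not collectable from flat ED exports).
  The cardiovascular subscore uses the vasopressor dose class when
  present, otherwise mean arterial pressure (< 70 mmHg → 1).

All scoring functions are pure and validated: vitals outside broad
physiologic ranges (e.g. SBP outside 30–300 mmHg) are rejected at
construction, and a missing required input raises an error naming the
field so the I/O layer can route the record to the exclusion list.

When a patient has repeated measurements, the CSV reader reduces per field
before scoring (default `WORST` = most abnormal in the scoring direction:
minimum SBP, maximum RR, temperature farthest from 37 °C, and so on;
`FIRST` is available since severity scores are sometimes computed on
presentation values). Keeping the reduction in the I/O layer keeps the
scoring functions pure.

## Diagnostic accuracy

Severity scores take a handful of integer values, so ties dominate and all
estimators are tie-aware:

- **AUROC** is the tie-corrected Mann–Whitney concordance,
  AUC = (#{S⁺ > S⁻} + ½·#{S⁺ = S⁻}) / (n⁺·n⁻). The point estimate is
  computed from exact integer pair counts, which makes the grouped-table
  closed form and the per-record computation bit-identical — an identity
  the tests assert exactly. For a dichotomous test this reduces to
  (sensitivity + specificity)/2.
- **Variance and paired comparison** use DeLong's placement values with
  0.5 weight on ties, ddof = 1 sample (co)variances, and the usual normal
  reference for the paired z statistic. When the variance of the AUC
  difference is numerically zero the test returns p = 1 for a zero delta
  (identical scores) with an explanatory note. An optional logit-scale CI
  keeps intervals inside (0, 1).
- **Sensitivity/specificity** use the positive-call convention
  score ≥ cutoff (cutoff 2 by default for the 0–3/0–4 scores; the binary
  lactate criterion is positive at 1). Binomial CIs go through statsmodels:
  Wald by default — it reproduces most of the reference report's printed
  intervals after integer rounding — with Wilson and exact Clopper–Pearson
  selectable. The reference report's own CI provenance is model-based and
  not reproducible from the marginals (it prints two different intervals
  for identical 36/50 proportions), so CI bounds are not an acceptance
  surface; point estimates are.
- **Paired sensitivity/specificity comparison** runs McNemar
  marginal-homogeneity tests within the diseased subset (sensitivities)
  and the non-diseased subset (specificities) — exact binomial when
  discordant pairs < 25, chi-square with continuity correction otherwise —
  plus a joint 2-df chi-square summing the squared standardised contrasts
  (the two strata are disjoint patients, so the contrasts are
  independent). Zero discordance yields p = 1 with a flag, not an error.
- **Display rounding** (integer percent, 3-decimal AUC, half-up) is
  applied only at serialization; internal values stay at full precision.

Paired tests require the within-patient joint distribution of the two
scores. Grouped marginal tables do not determine it, so on the embedded
fixture the panel marks every comparison unavailable with that reason
instead of approximating. This is why the reference report's p-values
(AUC comparison, sensitivity/specificity comparison) are not reproduced:
they need the unreleased patient-level data.

## The embedded fixture

`table2_fixture()` loads three grouped score-by-outcome tables committed
as TSV (457 patients, 407 survivors, 50 non-survivors): qSOFA
(223/129/51/4 vs 11/16/20/3 at scores 0–3), qSOFA+lactate
(158/138/68/39/4 vs 5/9/18/15/3 at 0–4), and the binary lactate criterion
(243/164 vs 14/36). These counts alone reproduce the headline results:
AUROCs 0.717 / 0.754 / 0.659, sensitivity/specificity 46%/86% and
72%/73%, lactate 72%/60%, 17% of patients at qSOFA ≥ 2, 27 non-survivors
below the cutoff, 10.9% mortality.

One internal inconsistency of the source tables is worth recording: the
qSOFA and composite multinomials of the non-survivor class jointly imply
37 lactate-positive non-survivors, while the lactate row prints 36
(72.0%). The score multinomials are treated as authoritative where the
two conflict (they are what the headline metrics are computed from).

## Synthetic cohorts

The generator emulates a two-class ED cohort (death prevalence 50/457 by
default) in two modes.

**Score-multinomial mode** (default) draws each patient's qSOFA level from
the per-class published multinomial and the lactate point from the
conditional probabilities P(lactate ≥ 2 | qSOFA = k) obtained by solving
the triangular system that maps the qSOFA multinomial onto the composite
multinomial (`lactate_coupling`). For the survivor class this coupling
lands exactly on the published 164/407 lactate marginal. Score
distributions therefore match the published tables in expectation — the
mode's purpose — and `expected_auroc` gives the implied AUC in closed
form (0.717 for qSOFA, 0.754 for the composite, at the defaults). The
drawn qSOFA level is decomposed into its three criteria by sampling the
indicator combination conditional on the sum, weighted by independent
Bernoulli marginals; because of this conditioning the criterion *indicator*
marginals carry a small systematic bias relative to the configured values
(computed ≤ 0.04), which is why exact marginal recovery is tested in the
copula mode instead.

**Criterion-copula mode** is mechanistic: the four binary criteria arise
by thresholding an equicorrelated latent Gaussian with correlation `rho`
(default 0.4; the criteria's true joint dependence is unpublished, so rho
is an explicit modeling assumption), with per-class thresholds matching
the configured marginals exactly in expectation. A shared latent severity
factor also drives SIRS and SOFA organ measurements through monotone
quantile coupling with class-shifted marginals; the resulting SOFA
distribution (median ≈ 1 in survivors vs ≈ 5–6 in non-survivors) is a
soft calibration target, not an exact one.

Continuous back-fill values are synthetic dressing drawn from documented
truncated normals on the correct side of each criterion threshold (e.g.
SBP ~ N(85, 15) on (40, 100] when hypotensive, N(125, 18) on (100, 250]
otherwise); they carry no outcome information beyond the indicator.
Lactate is drawn from the class log-normal truncated to the correct side
of 2.0 mmol/L. The log-normals are fitted from the published median/IQR
(survivors 1.6 [0.9–2.8], non-survivors 3.3 [1.775–4.875] mmol/L) as
mu = ln median, sigma = (ln q3 − ln q1)/(2·z₀.₇₅). A two-parameter
log-normal has log-symmetric quartiles, so it reproduces the median and
quartile ratio exactly but symmetrises asymmetric quartiles; for the
non-survivor row the fitted quartiles deviate ~12% from the printed ones.
Age is normal per class (62.11 ± 16.19 vs 68.94 ± 15.27 years, truncated
to 18–105).

All randomness flows through one `numpy.random.default_rng(seed)`;
regeneration from (config, seed) is bit-identical, and the seed is echoed
in every cohort artifact.

**What passing tests do and do not show.** The generator reproduces the
published marginal structure and known score distributions; it does not
model measurement timing, repeated measurements, missing-data mechanisms
other than lactate missingness, treatment effects, or any real joint
dependence beyond the single equicorrelation parameter. Passing tests
therefore validate the estimators and pipeline plumbing, not clinical
generalisability of the composite score.

## Validation strategy and problem sizes

Beyond the exact fixture reproductions, the estimators are validated
against independent oracles at sizes chosen to keep the default suite
fast: brute-force pair enumeration (n ≤ 200) for the AUROC; a 5,000-rep
stratified bootstrap for the DeLong standard error (30+30 records, within
10%); a simulated null — identical score laws in both outcome classes, so
both true AUCs are 0.5 while the two scores stay correlated within
patient — for the paired DeLong type-I error (500 seeds at n = 457,
observed rejection ≈ 0.05); 10,000-rep coverage simulation for the Wilson
interval (n = 50, p = 0.7); and scikit-learn's `roc_auc_score` as an
external cross-check on tied data. Generator calibration is checked at
n = 4,000–20,000 against 3-standard-error binomial/Monte-Carlo bands.

## Known limitations

- SOFA respiration bands ignore ventilatory support; renal scoring omits
  urine output; SIRS cannot distinguish a missing component from a normal
  one beyond the flag it returns.
- CI methods are marginal; no exact small-sample AUC intervals.
- The copula's equicorrelation is a convenience; real criterion dependence
  is unlikely to be exchangeable.
- The WLS joint statistic assumes independent sensitivity and specificity
  contrasts (true when the strata are disjoint patients) and is not a full
  GEE treatment of clustered binary outcomes.
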