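# sepscore

Severity scoring and diagnostic-accuracy evaluation for emergency-department
sepsis cohorts, built around the **qSOFA + lactate composite score**.

qSOFA (quick Sequential Organ Failure Assessment) flags one point each for
systolic blood pressure ≤ 100 mmHg, respiratory rate ≥ 22 /min, and altered
mental status. It is specific but insensitive as a mortality screen in
surgical patients with intra-abdominal infection — very few such patients
present with altered mentation. Adding one point for hyperlactatemia
(plasma lactate ≥ 2.0 mmol/L) yields a 0–4 composite that trades a little
specificity for a large sensitivity gain and an AUROC close to the full
SOFA score, while remaining computable at the bedside.

The package is aimed at clinical epidemiologists validating bedside
severity scores against in-hospital mortality. It provides:

- **`sepscore.scores`** — pure scoring functions: qSOFA, the qSOFA+lactate
  composite, SIRS, and full SOFA (0–24, six organ subscores; AVPU mentation
  mapped A/V/P/U → 0/1/3/4 through the conventional GCS anchors). Band
  tables ship as versioned data files.
- **`sepscore.diagnostics`** — the statistical engine for ordinal scores
  with heavy ties: tie-corrected Mann–Whitney AUROC
  `AUC = P(S⁺ > S⁻) + ½·P(S⁺ = S⁻)`, DeLong placement-value variance and
  the paired DeLong test of two AUCs on the same patients, empirical ROC
  curves, sensitivity/specificity at a cutoff (positive call: score ≥ c)
  with Wald/Wilson/Clopper–Pearson CIs, and paired McNemar + joint WLS
  sensitivity/specificity comparison. Grouped score-by-outcome count
  tables are first-class inputs and agree exactly with per-record data.
- **`sepscore.cohort_io`** — cohort CSV reader with worst-value reduction
  and eligibility filtering (missing lactate, uncontrolled source), grouped
  TSV I/O, report writers, and the embedded published grouped counts of a
  457-patient cohort (50 deaths).
- **`sepscore.synthetic`** — a calibrated two-class cohort generator
  (score-multinomial and latent-Gaussian-copula modes) so that every
  pipeline stage, including the paired tests, is exercisable without any
  patient data.
- **`sepscore.pipeline`** + a thin `sepscore` CLI — end-to-end analysis
  producing the full metric panel.

## Worked example

```python
from sepscore import run_analysis, table2_fixture

panel = run_analysis(table2_fixture())
report = panel.to_dict()
for name in ("lactate", "qsofa", "qsofa_lactate"):
    row = report["scores"][name]
    print(f"{name:>14}: sens {row['sensitivity_pct']}%  "
          f"spec {row['specificity_pct']}%  AUROC {row['auroc']:.3f}")
```

prints

```
       lactate: sens 72%  spec 60%  AUROC 0.659
         qsofa: sens 46%  spec 86%  AUROC 0.717
 qsofa_lactate: sens 72%  spec 73%  AUROC 0.754
```

Reading: at the conventional cutoff of 2, plain qSOFA misses more than half
of the non-survivors (46% sensitivity); adding the lactate point lifts
sensitivity to 72% while specificity falls only from 86% to 73%, and the
ranking quality (AUROC) rises from 0.717 to 0.754. The same panel is
available from the shell as `sepscore reproduce`, and
`sepscore simulate | analyze | roc` cover synthetic cohorts, cohort CSVs
and ROC plots. The scripts in `examples/` walk through each capability.

Paired significance tests (DeLong for AUCs, McNemar/WLS for sensitivity
and specificity) require patient-level joint scores; on grouped marginal
tables the panel reports them as unavailable with the reason, and on
patient-level cohorts (real or synthetic) they are computed in full.

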