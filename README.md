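# nodulestrat

Risk stratification of **solid pulmonary nodules** found at baseline
low-dose CT in lung cancer screening: which nodules can be safely ruled
out, which need a 3-month interval scan, and which should be referred for
definitive investigation.

The package is for biostatisticians and screening-programme analysts who
want to evaluate nodule-management protocols (BTS-style volumetric
80/300 mm³ cut-offs, EUPS 100 mm³, diameter-primary 5/8 mm) on
participant-level cohort tables, with the full statistical toolkit such an
evaluation needs.

## What it computes

Each participant is reduced to one **index nodule** — the malignant one if
any, otherwise the largest — and classified against a protocol's
thresholds (rule-out strictly below the cut-off, rule-in at or above it;
diameter fallback cut-offs when volumetric segmentation is unreliable).
On top of the resulting 2×2 tables the package provides:

- **Diagnostic accuracy** — Se = TP/(TP+FN), Sp = TN/(FP+TN), PPV, NPV,
  on the percentage scale with exact (Clopper–Pearson) binomial CIs;
  crude risks; Pearson χ²; exact McNemar for paired sensitivity and
  specificity; univariable logistic odds ratios per unit size.
- **Brock (PanCan) score** — the published logistic malignancy model with
  the non-linear size term
  `lp ∋ −5.3854·((d/10)^(−1/2) − 1.58113883)`, applied (never refitted)
  and gated at 10 % predicted risk for referral.
- **ROC analysis** — empirical curves, AUC = Mann–Whitney statistic,
  DeLong variance/covariance from placement values, paired DeLong test,
  and Youden's J = Se + Sp − 1 cut-point selection.
- **Weighted net benefit** of switching rules,
  `NB = ΔSe + ΔSp·(1/W)·(1−p)/p` (percentage points), with
  participant-level bootstrap CIs and an explicit choice of which
  population's prevalence enters `p`.
- **Synthetic cohorts** — a seeded generator of realistic screening
  cohorts, and an exact reconstruction of a participant-level cohort from
  published cumulative size-threshold counts (shipped for a large UK
  screening baseline round: 11 355 participants, 5 929 with a solid
  nodule, 228 nodule cancers).

## Worked example

```python
from nodulestrat import (
    packaged_counts_spec, reconstruct_fixture, reduce_to_index,
    SizeRule, stratify, diagnostic_summary, crude_risk,
)

cohort = reconstruct_fixture(packaged_counts_spec(), seed=1)
indexed = reduce_to_index(cohort, size_key="volume")

risk = crude_risk(228, 5929)
print(f"crude risk {risk.risk_pct:.2f}% "
      f"(95% CI {risk.ci[0]:.2f} to {risk.ci[1]:.2f})")

counts = stratify(indexed, SizeRule(80.0, "mm3", fallback_diameter_mm=6.0))
d = diagnostic_summary(counts)
print(f"<80 mm3 rule-out: sens {d.sensitivity[0]:.1f}%, "
      f"spec {d.specificity[0]:.1f}%, NPV {d.npv[0]:.1f}%")
```

prints

```
crude risk 3.85% (95% CI 3.37 to 4.37)
<80 mm3 rule-out: sens 86.8%, spec 65.4%, NPV 99.2%
```

i.e. 3.85 % of nodule participants proved malignant; discharging every
nodule under 80 mm³ to the next screening round misses 13.2 % of cancers
at baseline (caught later by surveillance), avoids follow-up in 65.4 % of
benign-nodule participants, and 99.2 % of the discharged participants are
cancer-free.

The same pipeline runs from the shell:

```sh
nodulestrat --seed 1 report --out results/
nodulestrat generate --n 20000 --out cohort.csv
nodulestrat roc cohort.csv --score volume --layout nodule_rows
```

`report` writes `summary.json` (full precision) and `report.txt`
(rendered rule-out/rule-in tables and net-benefit comparisons).

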