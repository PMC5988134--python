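# spectriage

Early health-economic evaluation of a serum-spectroscopy triage test for
suspected brain tumours.

Patients with malignant brain tumours lose more life-years than those with
any other primary cancer, partly because early symptoms (headache,
dizziness) are non-specific and diagnosis is delayed. A rapid blood test
based on infrared spectroscopy of serum — sensitivity 92.8%, specificity
91.5% in case-control data — could triage which patients are fast-tracked
to definitive MRI/CT imaging. `spectriage` implements the decision-analytic
evaluation of that idea for health economists and trial designers: would
adding the test to the diagnostic pathway be cost-effective, and under what
prices, accuracies and prevalences?

## The model

Two one-shot decision trees over a 2-year horizon (healthcare-service
perspective, no discounting) compare *test-then-image* against the current
*imaging-only* pathway in two settings:

* **Primary care** (prevalence 0.5%): test-positives are fast-tracked to
  imaging (delay D1 = 1 week); 50% of test-negatives still proceed to
  imaging at the standard delay (D2 = 4 weeks), the rest avoid the imaging
  work-up entirely.
* **Secondary care** (prevalence 3%): as above, but every test-negative
  still proceeds to imaging.

A cohort of N = 10,000 splits by disease status, then by test result:
TP = N·p·Se, FN = N·p·(1−Se), TN = N·(1−p)·Sp, FP = N·(1−p)·(1−Sp).
Each fast-tracked true positive gains g QALYs (earlier diagnosis, valued
with a utility weight of 0.89) and δ years of monitored survival; each
skipped work-up saves the work-up bundle cost c_avoid. The increments are

```
ΔQALY = TP·g
ΔCost = N·(test price) + TP·δ·(monitoring rate) − (1−q)·(TN+FN)·c_avoid
ICER  = ΔCost / ΔQALY        (dominant when ΔQALY > 0 and ΔCost < 0)
```

where q is the post-negative imaging probability. g, δ and c_avoid derive
from natural-history and resource-use assumptions that survive only through
the published increments, so they are recovered by closed-form calibration
(g ≈ 0.1899 QALY, δ ≈ 0.2140 y, c_avoid ≈ £203.50; see
`docs/methods.md`). On top of the deterministic tree the package provides
one-way and scenario sensitivity analyses, threshold search, probabilistic
sensitivity analysis with cost-effectiveness acceptability curves, and a
patient-level microsimulation used as a Monte-Carlo oracle.

## Worked example

```python
from spectriage import default_parameters, evaluate

params = default_parameters("secondary", "UK", test_cost=50)
result = evaluate(params)
print(f"ΔQALY = {result.delta_qaly:.2f}, ΔCost = {result.delta_cost:,.0f}, "
      f"ICER = {result.display()}")

params = default_parameters("primary", "UK", test_cost=50)
print(evaluate(params).display())
```

prints

```
ΔQALY = 52.86, ΔCost = 527,646, ICER = 9,982
-47,913 (dominates)
```

Read: in secondary care at £50 per test, testing 10,000 patients adds
52.86 QALYs for £527,646 — £9,982 per QALY gained, well below the
£20,000–£30,000 UK threshold. In primary care at £50 the test *dominates*:
it adds QALYs **and** saves £422,116, because avoided work-ups outweigh the
test cost at low prevalence.

The same numbers are available from the shell:

```sh
spectriage run --scenario secondary --country UK --test-cost 50
spectriage table2 --out table2.csv      # all 8 published cells side by side
spectriage owsa --parameter specificity --from 0.7 --to 0.99 --steps 30 --out owsa.csv
spectriage psa --scenario secondary --seed 1 --out ceac.csv
spectriage simulate --n 10000 --seed 7 --out cohort.csv
```

The `examples/` directory holds short narrative scripts — base-case table
reproduction, specificity OWSA with threshold search, PSA/CEAC at both
test prices, and the microsimulation cross-check — each printing the
numbers it computes and what they mean.

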