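# Methods

## Model structure

The evaluation compares two arms on an identical cohort of N patients with
suspected brain tumour over a 2-year horizon from a healthcare-service
perspective, as one-shot decision trees (no Markov cycles: median survival
for high-grade glioma, the dominant malignant tumour here, is about one
year, so a short horizon captures the survival benefit of earlier
diagnosis).

**Comparator (imaging alone).** Every patient receives the imaging work-up
at the standard delay (D2 = 4 weeks). Diseased patients accrue baseline
survival (default one year, the high-grade-glioma median) with
stable-disease monitoring costs; non-diseased patients accrue a fixed
utility-weighted full-horizon QALY stream.

**With-test arm.** Every patient is tested first (test price paid for
all). The cohort splits by disease status at the prevalence, then by test
result via sensitivity/specificity. Test-positives are fast-tracked to
imaging (D1 = 1 week); true positives gain g QALYs and δ years of
monitored survival from the earlier diagnosis. Test-negatives proceed to
imaging at D2 with probability q (1.0 in secondary care, 0.5 in primary
care) and otherwise skip the work-up, avoiding its cost. False negatives
revert to the comparator pathway and carry no extra harm; false positives
are fast-tracked but gain nothing. D3 (8 weeks, late/emergency
presentation) is defined but not routed by default: the emergency
fraction's position in the comparator tree is not quantified in the main
text.

Because non-diseased QALYs and all shared work-up/monitoring terms appear
identically in both arms, the increments reduce to

* ΔQALY = TP·g — proportional to true positives only, hence invariant to
  specificity (the published model states the same behaviour);
* ΔCost = N·τ + TP·δ·r − (1−q)·(TN+FN)·c_avoid, with τ the test price and
  r the annualised monitoring rate (4 × the quarterly cost).

## Calibration of g, δ and c_avoid

The survival-by-delay values S(t|D) and several resource assumptions live
in supplementary material that is not available; under the fixed horizon
they collapse to three constants, each identifiable from the published
base-case table:

| constant | meaning | calibrated on | value (UK) |
|---|---|---|---|
| g | QALY gain per fast-tracked true positive | secondary-care ΔQALY 52.86 | 52.86/278.4 ≈ 0.18987 |
| δ | extra monitored years per true positive | secondary-care £50 ΔCost 527,646 | 27,646/(278.4·464) ≈ 0.21402 y |
| c_avoid | avoided work-up bundle cost | primary-care £50 ΔCost −422,116 (UK) | ≈ £203.50 |

g and δ are properties of the natural-history model and are shared across
countries; c_avoid is money-valued and calibrated per country (USA ≈
$488.50, from the $200 primary-care row — see below). The two published
ΔQALYs are exactly proportional to true-positive counts (8.81 : 52.86 =
46.4 : 278.4), so g calibrated on either setting predicts the other to
2 dp — the package's headline consistency check.

g and δ imply survival gains of 77.9 and 78.2 days respectively. A single
survival-gain parameter priced at the monitoring rate would leave an £87.5
residual in the secondary-care cost increment (within rounding of the
published table); the two constants are kept separate so that every UK
cell reproduces *exactly* at the published rounding. With all three
constants fitted (3 constants, 9 remaining printed numbers), the pipeline
reproduces all four UK (ΔQALY, ΔCost, ICER) cells and both USA $200 rows.

**Work-up bundle.** In the default "calibrated" costing mode the imaging
work-up (scan plus associated clinic/GP visits) is priced at c_avoid for
every imaged patient in both arms — consistent with £203.50 ≈ MRI £164 +
neurology visit £35 + a share of GP time. Since it cancels between arms
except through the skipped mass, this choice affects absolute arm costs
but no increment. An "itemised" mode prices the work-up from the unit-cost
table (CT/MRI mix × scan cost + configured visits) for users exploring
alternative structures.

**USA table anomaly.** The published USA cost increments move by
$1,500,000 between the $100 and $200 rows, where a $100 price change over
10,000 patients can only move them by $1,000,000. Both USA $100-row
increments equal exactly what the model produces at a $50 price,
suggesting the $100 rows were computed at the lower UK-equivalent price.
The package follows N·δ scaling (internally consistent), calibrates USA
c_avoid on the $200 primary-care row, reports the $100 rows as
source-inconsistent in `reproduce_table2`, and excludes USA cost cells
from exact checks. USA primary-care ICERs differ by 1–2 units from the
rounded quotient of their own printed increments (upstream rounding of
ΔQALY to 8.81), so their identity checks carry a ±3-unit tolerance.

## Key parameters

| parameter | default | units | note |
|---|---|---|---|
| sensitivity / specificity | 0.928 / 0.915 | — | SDs 0.011 / 0.019 from repeated classifier evaluation |
| prevalence | 0.005 (primary), 0.03 (secondary) | — | 0.01 packaged as a named primary-care alternative |
| test price τ | £50–£100 / $100–$200 | per test | assumed pre-commercial bounds; a policy variable, never sampled |
| q = P(image after negative) | 0.5 (primary), 1.0 (secondary) | — | expert-opinion conservative estimate |
| utility | 0.89 | — | stable high-grade glioma health state |
| horizon | 730 | days | discount rate 0 by default (exposed) |
| monitoring | 116 (£/quarter), 154 ($/quarter) | | annualised ×4 |
| fast-track premium | 0 | per episode | exposed for exploring false-positive-driven fast-track costs |

Rounding convention for reported values: half-away-from-zero to the
nearest currency unit for ICERs and cost increments, 2 dp for QALY
increments — the convention under which every reproducible published cell
matches. ICERs are reported as signed numbers with a dominance flag
alongside, never replaced by the flag. Probability sums at chance nodes
must be within 1e−9 of 1; violations are errors, never renormalised.

## Sensitivity analyses

OWSA re-runs the full pipeline over a grid of one parameter (sensitivity,
specificity, test price, prevalence, utility, or q). Threshold search
verifies numerical monotonicity of the ICER on a probe grid, then bisects
to 1e−4. Named scenario toggles: a result-discussion consultation for
test-positives (one GP visit in primary care, one neurology visit in
secondary care — magnitudes are not published; these are package choices),
q = 0.75, mean instead of median baseline survival (15 months; affects
only terms that cancel, demonstrating robustness), and 1% primary-care
prevalence.

## Probabilistic sensitivity analysis

The source does not publish its PSA distributions; the package's defaults
follow standard HTA practice and are exposed per parameter: moment-matched
betas for sensitivity, specificity (published SDs), utility (sd 0.05) and
prevalence (cv 0.2); gammas for monitoring cost, c_avoid (cv 0.2) and the
natural-history-derived g (cv 0.3, the most uncertain input). Draw i uses
an independent RNG substream keyed by (seed, i): runs are reproducible
bit-for-bit and order-independent, and comparing test prices under one
seed uses common random numbers, making pointwise CEAC dominance across
prices exact. CEAC levels are therefore qualitative: at £30,000/QALY the
defaults give ≈ 1.0 (primary, £50) and ≈ 0.99 (secondary, £50) versus the
published "near 100%" and "approximately 90%" readings — same decision,
different distributional assumptions.

## Microsimulation

`simulate_cohort` samples integer patients by multinomial allocation over
the built tree's root-to-leaf path probabilities, looking payoffs up from
the terminal nodes, so any disagreement with `rollback` is attributable to
sampling alone; an independently coded flat Bernoulli-chain sampler in the
test suite provides a genuinely independent routing oracle.
`simulate_pair` shares disease-status draws between arms (common random
numbers), removing prevalence noise from incremental estimates. The
generator emulates branch membership and terminal payoffs only — not
within-patient event times, imaging capacity/queueing, or correlated
comorbidity — so agreement demonstrates the tree algebra, not realism of
individual patient trajectories.

Problem sizes used in the shipped checks: 500 random trees (depth ≤ 5)
against exhaustive path enumeration at 1e−12; 20 random parameter sets ×
both arms at N = 100,000 against analytic expectations at 4 standard
errors; PSA determinism and price-dominance checks at 400 draws (the full
pipeline runs in ≈ 0.2 ms, so larger runs are cheap if wanted).

## Limitations

* g, δ and c_avoid are calibrated to the published table, not estimated
  from data; the reproduction is calibration-constrained by construction,
  and its value is the internal-consistency structure it verifies, not
  independent validation.
* No harm pathway for false negatives or false positives beyond cost; no
  metastasis/primary stratification; no treatment-phase costs (absent from
  the published cost table); no currency or inflation adjustment between
  the UK (2015) and USA (2016) price bases.
* CEAC probability levels depend on unpublished distribution choices and
  should be read qualitatively.
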