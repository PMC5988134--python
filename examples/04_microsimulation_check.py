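"""Patient-level microsimulation as a Monte-Carlo oracle.

Simulates 200,000 individual patients through the with-test decision tree
(secondary care, £50) and compares the empirical mean cost and QALYs per
patient with the analytic rollback expectation: they agree within
Monte-Carlo error, confirming the tree algebra.
"""

from spectriage import (build_arm, default_parameters, rollback,
                        simulate_cohort, summarize)

params = default_parameters("secondary", "UK", 50).replace(
    **{"cohort.size": 200_000})
analytic = rollback(build_arm(params, True), params.cohort.size)
cohort = simulate_cohort(params, with_test=True, seed=2026)
emp = summarize(cohort)

print(f"analytic per-patient cost: {analytic.per_patient_cost:10.4f}   "
      f"QALY: {analytic.per_patient_qaly:.6f}")
print(f"simulated per-patient cost: {emp.per_patient_cost:9.4f} "
      f"(SE {emp.se_cost:.4f})   QALY: {emp.per_patient_qaly:.6f} "
      f"(SE {emp.se_qaly:.6f})")
print(f"cost within {abs(emp.per_patient_cost - analytic.per_patient_cost) / emp.se_cost:.2f} SE, "
      f"QALY within {abs(emp.per_patient_qaly - analytic.per_patient_qaly) / emp.se_qaly:.2f} SE")
print("\nroute counts:")
for route, count in sorted(emp.route_counts.items()):
    print(f"  {route:40s} {count:7d}")
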