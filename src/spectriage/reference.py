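"""Published base-case results used as calibration inputs and golden values.

The source evaluation reports incremental QALYs, incremental costs and ICERs
for cohorts of 10,000 patients in four settings (primary/secondary care ×
UK/USA) at the lower and upper bound of the assumed test price. Two of the
model's inputs (the per-true-positive QALY gain and the avoided work-up cost)
were taken from supplementary material that only survives through this table,
so the table doubles as the calibration target: see
:mod:`spectriage.outcomes`.

Notes on internal consistency of the published table
----------------------------------------------------
* The four UK cells are mutually consistent with the tree model and are
  reproduced exactly by the calibrated pipeline.
* The USA cost increments move by $1,500,000 between the $100 and $200 rows,
  whereas a $100 change in test price over 10,000 patients can only move the
  increment by $1,000,000. Both USA $100-row cost increments are exactly what
  the model produces at a $50 test price, suggesting a transcription slip in
  the source. The USA $100 rows are therefore flagged
  ``increment_consistent=False`` and only their ICER-from-increment
  identities are checked (the quotient of the printed increments reproduces
  the printed ICER). USA primary-care ICERs differ by 1-2 currency units
  from the rounded quotient of their printed increments (upstream rounding
  of the printed ΔQALY), hence ``icer_identity_tol=3``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Table2Row:
    """One published base-case cell: scenario × country × test price."""

    scenario: str  # "primary" | "secondary"
    country: str  # "UK" | "USA"
    test_cost: float  # price per test in local currency
    delta_qaly: float  # published incremental QALYs per 10,000 patients
    delta_cost: float  # published incremental cost per 10,000 patients
    icer: float  # published ICER (cost per QALY), signed
    dominates: bool  # published "(dominates)" annotation
    #: the printed quotient ΔCost/ΔQALY reproduces the printed ICER within
    #: this many currency units after half-away-from-zero rounding
    icer_identity_tol: int = 0
    #: False where the printed cost increment is inconsistent with
    #: N×δ test-price scaling (see module docstring)
    increment_consistent: bool = True


TABLE2: tuple[Table2Row, ...] = (
    Table2Row("primary", "UK", 50, 8.81, -422_116, -47_913, True),
    Table2Row("primary", "UK", 100, 8.81, 77_884, 8_840, False),
    Table2Row("secondary", "UK", 50, 52.86, 527_646, 9_982, False),
    Table2Row("secondary", "UK", 100, 52.86, 1_027_646, 19_441, False),
    Table2Row("primary", "USA", 100, 8.81, -1_718_475, -195_058, True,
              icer_identity_tol=3, increment_consistent=False),
    Table2Row("primary", "USA", 200, 8.81, -218_475, -24_798, True,
              icer_identity_tol=3),
    Table2Row("secondary", "USA", 100, 52.86, 536_702, 10_153, False,
              increment_consistent=False),
    Table2Row("secondary", "USA", 200, 52.86, 2_036_702, 38_530, False),
)


def table2_row(scenario: str, country: str, test_cost: float) -> Table2Row:
    """Look up one published cell; raises ``KeyError`` if absent."""
    for row in TABLE2:
        if (row.scenario == scenario and row.country == country
                and row.test_cost == test_cost):
            return row
    raise KeyError(f"no published cell for ({scenario}, {country}, {test_cost})")
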