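"""Blood-pressure aggregation, hypertension labeling rules, and MAP categories.

Implements three parallel labeling rules used to split a cohort into
normotensive and hypertensive groups:

* **systolic** — hypertensive above a systolic cut (default > 130 mmHg),
  normotensive below the 2017-guideline normal limits (< 120 / < 80 mmHg);
  subjects in neither range are excluded from the systolic sub-experiment.
* **diastolic** — hypertensive above a diastolic cut (default > 80 mmHg),
  normotensive below the normal limits.
* **MAP** — mean arterial pressure, MAP = (1/3)·SBP + (2/3)·DBP, categorized
  into six clinical bands (optimal, normal, high normal, hypertension grades
  1–3) and collapsed to a binary label with the optimal band excluded.

All category boundaries are printed to two decimals; MAP values are rounded
to two decimals before comparison, which makes the six-band partition
exhaustive over positive pressures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

NORMOTENSIVE = "normotensive"
HYPERTENSIVE = "hypertensive"
EXCLUDED = "excluded"

MAP_CATEGORIES = (
    "optimal",
    "normal",
    "high_normal",
    "grade1",
    "grade2",
    "grade3",
)


@dataclass(frozen=True)
class BPCategoryRules:
    """Thresholds (mmHg) defining the labeling rules.

    ``map_boundaries`` are the *upper* bounds of the first five MAP bands
    (optimal, normal, high normal, grade 1, grade 2); grade 3 is everything
    above the last bound.  Comparison happens after rounding MAP to 2
    decimals, so band edges printed as e.g. 99.00 / 99.01 leave no gap.
    """

    systolic_hypertensive_cut: float = 130.0  # strict >
    diastolic_hypertensive_cut: float = 80.0  # strict >
    normal_sbp_max: float = 120.0  # strict <
    normal_dbp_max: float = 80.0  # strict <
    map_boundaries: Tuple[float, ...] = (93.32, 99.00, 105.67, 119.00, 132.33)

    def __post_init__(self) -> None:
        b = self.map_boundaries
        if len(b) != 5 or any(b[i] >= b[i + 1] for i in range(4)):
            raise ValueError("map_boundaries must be 5 strictly increasing values")


DEFAULT_RULES = BPCategoryRules()


def resting_bp(readings: Sequence[Tuple[float, float]]) -> Tuple[float, float]:
    """Average four (SBP, DBP) reading pairs into the resting measurement.

    Exactly four pairs are required; each component must be positive.
    """
    readings = list(readings)
    if len(readings) != 4:
        raise ValueError(f"expected exactly 4 BP reading pairs, got {len(readings)}")
    for sbp, dbp in readings:
        if sbp <= 0 or dbp <= 0:
            raise ValueError("BP readings must be positive")
    sbp = sum(r[0] for r in readings) / 4.0
    dbp = sum(r[1] for r in readings) / 4.0
    return sbp, dbp


def compute_map(sbp: float, dbp: float) -> float:
    """Mean arterial pressure, (1/3)·SBP + (2/3)·DBP, rounded to 2 decimals."""
    if sbp < 0 or dbp < 0:
        raise ValueError("pressures must be non-negative")
    return round(sbp / 3.0 + 2.0 * dbp / 3.0, 2)


def label_systolic(sbp: float, dbp: float, rules: BPCategoryRules = DEFAULT_RULES) -> str:
    """Systolic rule: hypertensive iff SBP > cut; normotensive iff both
    components are below the guideline normal limits; otherwise excluded."""
    if sbp > rules.systolic_hypertensive_cut:
        return HYPERTENSIVE
    if sbp < rules.normal_sbp_max and dbp < rules.normal_dbp_max:
        return NORMOTENSIVE
    return EXCLUDED


def label_diastolic(sbp: float, dbp: float, rules: BPCategoryRules = DEFAULT_RULES) -> str:
    """Diastolic rule: hypertensive iff DBP > cut; normotensive iff both
    components are below the guideline normal limits; otherwise excluded."""
    if dbp > rules.diastolic_hypertensive_cut:
        return HYPERTENSIVE
    if sbp < rules.normal_sbp_max and dbp < rules.normal_dbp_max:
        return NORMOTENSIVE
    return EXCLUDED


def map_category(map_value: float, rules: BPCategoryRules = DEFAULT_RULES) -> str:
    """Assign a MAP value (mmHg) to one of the six clinical bands.

    The value is rounded to 2 decimals first, matching the printed precision
    of the band edges, so every positive MAP lands in exactly one band:
    optimal < 93.33 ≤ normal ≤ 99.00 < high normal ≤ 105.67 < grade 1
    ≤ 119.00 < grade 2 ≤ 132.33 < grade 3.
    """
    if map_value <= 0:
        raise ValueError("MAP must be positive")
    m = round(map_value, 2)
    for bound, name in zip(rules.map_boundaries, MAP_CATEGORIES[:-1]):
        if m <= bound:
            return name
    return "grade3"


def collapse(category: str) -> str:
    """Collapse a six-band MAP category to the binary experiment label.

    Normal MAP is one class; high normal and grades 1–3 are the other; the
    optimal band has no counterpart under the systolic/diastolic rules and
    is excluded.
    """
    if category == "optimal":
        return EXCLUDED
    if category == "normal":
        return NORMOTENSIVE
    if category in MAP_CATEGORIES:
        return HYPERTENSIVE
    raise ValueError(f"unknown MAP category: {category!r}")


def label_map(sbp: float, dbp: float, rules: BPCategoryRules = DEFAULT_RULES) -> str:
    """MAP rule label: compute MAP, categorize, collapse to binary."""
    return collapse(map_category(compute_map(sbp, dbp), rules))
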