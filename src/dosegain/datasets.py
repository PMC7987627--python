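"""Published summary statistics of the reference clinical cohort.

A retrospective dual-CT-planning cohort of 116 left-sided breast cancer
patients (ClinicalTrials.gov NCT02237469) is the motivating dataset for this
pipeline.  Its raw DVHs are not public, but the reported gain counts and the
univariable robust-regression estimates are, and they are sufficient inputs
for two of the pipeline's operations: exact binomial confidence intervals
from counts, and prone-better cutoffs from fitted lines.  They are shipped
here as reference data, the way statistics packages ship canonical example
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

#: gain counts (patients in whom prone reduced the penalty, cohort size)
#: overall and in the reported subgroups / alternative priority types
CLINICAL_GAIN_COUNTS: dict[str, tuple[int, int]] = {
    "type1_overall": (72, 116),
    "type1_supine_below_2": (7, 26),
    "type1_supine_at_least_2": (65, 90),
    "heart_priority": (27, 116),
    "lungs_priority": (109, 116),
}


@dataclass(frozen=True)
class ClinicalFit:
    """One reported univariable robust fit of the penalty difference."""

    name: str
    intercept: float
    coefficient: float
    coefficient_sd: float
    unit: str
    cutoff_decimals: int  # precision at which the cutoff is reported


#: reported fits whose printed intercept/coefficient reproduce the reported
#: cutoff at its printed precision (the remaining fits were evidently
#: reported from unrounded estimates and are excluded from exact replay)
CLINICAL_FITS: tuple[ClinicalFit, ...] = (
    ClinicalFit("breast_depth_ratio", 1.244, -0.7950, 0.2493, "ratio", 1),
    ClinicalFit("breast_volume_per_weight", 0.278, -0.0564, 0.0273, "mL/kg", 1),
    ClinicalFit("breast_depth_supine", 0.278, -0.0073, 0.0038, "mm", 0),
    ClinicalFit("weight", 0.474, -0.0087, 0.0046, "kg", 0),
    ClinicalFit("bmi", 0.156, -0.0115, 0.0143, "kg/m2", 0),
    ClinicalFit("height", 3.029, -0.0193, 0.0118, "cm", 0),
    ClinicalFit("lung_volume_right", -0.708, 0.2071, 0.1484, "L", 1),
    ClinicalFit("lung_volume_total", -0.640, 0.0970, 0.0766, "L", 1),
    ClinicalFit("lung_volume_left", -0.537, 0.1641, 0.1542, "L", 1),
    ClinicalFit("age", 0.261, -0.0074, 0.0064, "years", 0),
    ClinicalFit("prone_penalty_score", -2.134, 0.8961, 0.0389, "%dose", 1),
    ClinicalFit("supine_penalty_score", 1.464, -0.7004, 0.1008, "%dose", 1),
)
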