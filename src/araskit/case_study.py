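"""Bundled case study: provisional-restoration options for single-tooth implants.

Seven treatment alternatives assessed qualitatively on eight criteria.
Three criteria (treatment time, laboratory cost, occlusal clearance) are
costs; the rest are benefits.  Each criterion column uses one of the five
built-in ordinal vocabularies.
"""

from __future__ import annotations

from .conversion import (
    CriterionSpec,
    DecisionMatrix,
    Direction,
    RawAssessmentTable,
    convert_table,
)

__all__ = [
    "ALTERNATIVES",
    "CRITERIA",
    "load_case_study",
    "case_study_matrix",
]

ALTERNATIVES: tuple[str, ...] = (
    "Removable partial denture",
    "Vacuum-formed appliances",
    "Bonded extracted tooth or denture",
    "Metal or fiber-reinforced resin-bonded fixed partial denture",
    "Wire-retained resin-bonded fixed partial denture",
    "Acrylic resin provisional fixed partial denture",
    "Implant-supported fixed provisional restoration",
)

# name, direction, conversion rule per criterion.  Patient comfort only ever
# takes {poor, good, excellent} but uses the full rule-1 vocabulary so the
# retained spacing (1/3/5) matches the published scores.
CRITERIA: tuple[CriterionSpec, ...] = (
    CriterionSpec("Esthetic potential", Direction.MAX, rule_id=1),
    CriterionSpec("Patient comfort", Direction.MAX, rule_id=1),
    CriterionSpec("Treatment time", Direction.MIN, rule_id=2),
    CriterionSpec("Laboratory cost", Direction.MIN, rule_id=3),
    CriterionSpec("Occlusal clearance", Direction.MIN, rule_id=4),
    CriterionSpec("Ease of removal", Direction.MAX, rule_id=5),
    CriterionSpec("Durability", Direction.MAX, rule_id=1),
    CriterionSpec("Modifications", Direction.MAX, rule_id=5),
)

_LABELS: tuple[tuple[str, ...], ...] = (
    ("Good", "Poor", "Minimal", "Medium", "Substantial", "Easy", "Fair", "Easy"),
    ("Fair", "Poor", "Minimal", "Low", "None", "Easy", "Fair", "Moderate"),
    ("Poor", "Good", "Moderate", "None", "Minimal", "Moderate", "Poor", "Difficult"),
    ("Good", "Good", "Lengthy", "High", "Moderate", "Difficult", "Good", "Difficult"),
    ("Good", "Good", "Moderate", "Low", "Moderate", "Easy", "Good", "Moderate"),
    ("Very good", "Excellent", "Lengthy", "Low", "Minimal", "Easy", "Fair", "Easy"),
    ("Excellent", "Excellent", "Lengthy", "Medium", "Minimal", "Easy", "Excellent", "Easiest"),
)


def load_case_study() -> RawAssessmentTable:
    """Return the bundled 7-alternative x 8-criterion qualitative table."""
    return RawAssessmentTable(ALTERNATIVES, CRITERIA, _LABELS)


def case_study_matrix() -> DecisionMatrix:
    """Return the bundled case study converted to its numeric decision matrix."""
    return convert_table(load_case_study())
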