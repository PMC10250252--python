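"""Global Segmentation Score (GSS): rubric, assessments, aggregation.

The GSS is a 0–100 point expert rubric for overall segmentation quality,
scored per image by consensus of interventional cardiologists.  The scoring
itself is a human act and is not automated here; this module owns the
schema (a rubric whose criterion points sum to exactly 100, per-image
assessments) and the aggregation the study reports: median and
interquartile range of totals, per-criterion medians, and the bookkeeping
of images whose catheter could not be scored (collimation).

Quantile convention: linear interpolation between order statistics
(numpy's default), used consistently with the statistics module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyInputError, InvalidRubricError

CATHETER_CRITERION_PREFIX = "catheter"


@dataclass(frozen=True)
class GssCriterion:
    id: str
    description: str
    max_points: int


@dataclass
class GssRubric:
    criteria: tuple
    version: str = "v1"

    def max_total(self) -> int:
        return sum(c.max_points for c in self.criteria)

    def criterion(self, cid: str) -> GssCriterion:
        for c in self.criteria:
            if c.id == cid:
                return c
        raise InvalidRubricError(f"no criterion '{cid}'")

    def catheter_criteria(self) -> list[str]:
        return [c.id for c in self.criteria if c.id.startswith(CATHETER_CRITERION_PREFIX)]

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "criteria": [c.__dict__ for c in self.criteria],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GssRubric":
        return validate_rubric(cls(
            criteria=tuple(GssCriterion(**c) for c in d["criteria"]),
            version=d.get("version", "v1"),
        ))


def validate_rubric(rubric: GssRubric) -> GssRubric:
    """Enforce the 100-point total and unique criterion ids."""
    if not rubric.criteria:
        raise InvalidRubricError("rubric has no criteria")
    if any(c.max_points <= 0 for c in rubric.criteria):
        raise InvalidRubricError("criterion max_points must all be > 0")
    total = rubric.max_total()
    if total != 100:
        raise InvalidRubricError(f"criterion points must sum to 100, got {total}")
    ids = [c.id for c in rubric.criteria]
    if len(set(ids)) != len(ids):
        raise InvalidRubricError("duplicate criterion ids")
    return rubric


def default_rubric() -> GssRubric:
    """An illustrative rubric covering the defect categories a segmentation
    review discusses (main-vessel completeness, collateral gaps, catheter
    continuity, artifacts).  The weights are placeholders, NOT a published
    canon; studies should supply their own rubric via configuration."""
    return validate_rubric(GssRubric(
        criteria=(
            GssCriterion("main_vessel_completeness", "Main vessel fully segmented without gaps", 40),
            GssCriterion("collateral_continuity", "Collateral branches present and continuous", 20),
            GssCriterion("catheter_continuity", "Catheter segmented without gaps", 20),
            GssCriterion("artifact_burden", "Freedom from false-positive structures", 20),
        ),
        version="illustrative-v1",
    ))


@dataclass
class GssAssessment:
    """One scored image (single consensus row, not per-rater rows)."""

    case_id: str
    points: dict = field(default_factory=dict)
    rater: str = "consensus"
    catheter_scorable: bool = True

    def validate(self, rubric: GssRubric) -> "GssAssessment":
        for cid, awarded in self.points.items():
            c = rubric.criterion(cid)
            if not 0 <= awarded <= c.max_points:
                raise InvalidRubricError(
                    f"case {self.case_id}: {awarded} points outside [0, {c.max_points}] for '{cid}'"
                )
        return self

    def total(self) -> float:
        return float(sum(self.points.values()))


@dataclass
class GssSummary:
    median: float
    q25: float
    q75: float
    per_criterion_median: dict
    n_scored: int
    n_excluded: int


def summarize(assessments: list[GssAssessment], rubric: GssRubric | None = None) -> GssSummary:
    """Median (IQR) of totals over fully scorable assessments.

    Catheter-unscorable images (collimation) are excluded from totals and
    from catheter criteria, but still contribute to the non-catheter
    per-criterion medians.
    """
    if rubric is not None:
        for a in assessments:
            a.validate(rubric)
    scorable = [a for a in assessments if a.catheter_scorable]
    if not scorable:
        raise EmptyInputError("no scorable assessments")
    totals = np.array([a.total() for a in scorable])
    q25, med, q75 = np.percentile(totals, [25, 50, 75])

    catheter_ids = set(rubric.catheter_criteria()) if rubric is not None else set()
    per_criterion: dict[str, float] = {}
    all_ids = sorted({cid for a in assessments for cid in a.points})
    for cid in all_ids:
        pool = scorable if cid in catheter_ids else assessments
        vals = [a.points[cid] for a in pool if cid in a.points]
        if vals:
            per_criterion[cid] = float(np.median(vals))
    return GssSummary(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        per_criterion_median=per_criterion,
        n_scored=len(scorable),
        n_excluded=len(assessments) - len(scorable),
    )


# ---------------------------------------------------------------------- I/O
def load_assessments(path: str | Path) -> list[GssAssessment]:
    """Read assessments from a JSON list of objects."""
    raw = json.loads(Path(path).read_text())
    return [
        GssAssessment(
            case_id=str(r["case_id"]),
            points={k: float(v) for k, v in r["points"].items()},
            rater=r.get("rater", "consensus"),
            catheter_scorable=bool(r.get("catheter_scorable", True)),
        )
        for r in raw
    ]


def save_assessments(assessments: list[GssAssessment], path: str | Path) -> None:
    rows = [
        {
            "case_id": a.case_id,
            "points": a.points,
            "rater": a.rater,
            "catheter_scorable": a.catheter_scorable,
        }
        for a in assessments
    ]
    Path(path).write_text(json.dumps(rows, indent=2))
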