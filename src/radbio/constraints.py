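"""Normal-tissue dose-constraint evaluation for lung SBRT plans.

The default rule set mirrors the institutional criteria used to vet each
plan: max-point-dose ceilings for cord, heart and esophagus, and
absolute-volume-above-threshold ceilings for heart, esophagus and
bilateral-lung-minus-ITV.  All inequalities are strict — a measured value
exactly at the limit fails.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

from .dvh import DoseVolumeHistogram, absolute_volume_at_dose, summary_metrics

__all__ = ["Constraint", "ConstraintResult", "DEFAULT_CONSTRAINTS", "check_constraints"]


@dataclass(frozen=True)
class Constraint:
    """One dose rule on one structure.

    ``kind`` is ``"max_dose"`` (max point dose strictly below ``limit``,
    in Gy) or ``"volume_above"`` (absolute volume receiving at least
    ``threshold_gy`` strictly below ``limit``, in cc).
    """

    structure: str
    kind: str
    limit: float
    threshold_gy: Optional[float] = None

    def describe(self) -> str:
        if self.kind == "max_dose":
            return f"{self.structure}: max dose < {self.limit} Gy"
        return (
            f"{self.structure}: volume >= {self.threshold_gy} Gy "
            f"< {self.limit} cc"
        )


@dataclass(frozen=True)
class ConstraintResult:
    constraint: Constraint
    verdict: str  # "pass" | "fail" | "not_evaluable"
    measured: Optional[float] = None
    reason: Optional[str] = None

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


DEFAULT_CONSTRAINTS: List[Constraint] = [
    Constraint("cord", "max_dose", 30.0),
    Constraint("heart", "max_dose", 38.0),
    Constraint("esophagus", "max_dose", 35.0),
    Constraint("heart", "volume_above", 15.0, threshold_gy=32.0),
    Constraint("esophagus", "volume_above", 5.0, threshold_gy=19.5),
    Constraint("lung", "volume_above", 1000.0, threshold_gy=13.5),
    Constraint("lung", "volume_above", 1500.0, threshold_gy=12.5),
]


def check_constraints(
    dvhs: Dict[str, DoseVolumeHistogram],
    constraints: Optional[List[Constraint]] = None,
) -> List[ConstraintResult]:
    """Evaluate every rule against the structure DVHs.

    A rule whose structure is missing, or whose absolute-volume check lacks
    ``total_volume_cc``, is reported as ``not_evaluable`` — never silently
    passed.
    """
    results: List[ConstraintResult] = []
    for rule in DEFAULT_CONSTRAINTS if constraints is None else constraints:
        dvh = dvhs.get(rule.structure)
        if dvh is None:
            results.append(
                ConstraintResult(rule, "not_evaluable", reason="structure missing")
            )
            continue
        if rule.kind == "max_dose":
            measured = summary_metrics(dvh)["max_gy"]
        elif rule.kind == "volume_above":
            if dvh.total_volume_cc is None:
                results.append(
                    ConstraintResult(
                        rule, "not_evaluable", reason="total_volume_cc unknown"
                    )
                )
                continue
            measured = absolute_volume_at_dose(dvh, rule.threshold_gy)
        else:  # pragma: no cover - defensive
            raise ValueError(f"unknown constraint kind {rule.kind!r}")
        verdict = "pass" if measured < rule.limit else "fail"
        results.append(ConstraintResult(rule, verdict, measured=measured))
    return results
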