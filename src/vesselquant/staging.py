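"""Rule-based resectability staging from per-vessel involvement degrees.

Resectability of pancreatic ductal adenocarcinoma is determined per vessel:
arterial involvement (celiac trunk, hepatic artery, superior mesenteric
artery) is graded more strictly than venous involvement (superior
mesenteric vein, portal vein).  The bundled default rule table encodes the
Dutch Pancreatic Cancer Group (DPCG) scheme — arterial: 0 degrees is
compatible with a resectable tumor, contact up to 90 degrees is borderline
resectable, beyond 90 degrees locally advanced; venous: up to 90 degrees
resectable, 90-270 borderline, beyond 270 locally advanced — but any rule
table with the same schema can be supplied, so the engine adapts to other
guidelines without retraining anything upstream.

The case stage is the worst (most severe) stage implied by any single
vessel.  Interval boundaries are right-closed, mirroring the degree
binning convention: arterial involvement of exactly 90 degrees is
borderline resectable, not locally advanced.

Occlusion and stenosis qualifiers present in published criteria are not
evaluated — the involvement report carries no such signal — and every
staging decision states this caveat.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .involvement import InvolvementReport
from .volume_io import VESSELS

__all__ = [
    "Stage",
    "RuleSet",
    "StagingDecision",
    "RuleValidationError",
    "load_ruleset",
    "default_ruleset",
    "classify_stage",
    "stage_for_degrees",
    "OCCLUSION_CAVEAT",
]

OCCLUSION_CAVEAT = (
    "Occlusion/stenosis qualifiers are not evaluated; staging reflects "
    "circumferential contact geometry only."
)


class Stage(enum.IntEnum):
    """Resectability stage, ordered by severity."""

    RESECTABLE = 0
    BORDERLINE_RESECTABLE = 1
    LOCALLY_ADVANCED = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Stage":
        try:
            return cls[label.upper()]
        except KeyError:
            raise ValueError(f"unknown stage label: {label!r}") from None


class RuleValidationError(ValueError):
    """The rule table is malformed (gap, overlap or missing class)."""


@dataclass(frozen=True)
class RuleSet:
    """Vessel-class assignment plus per-class degree thresholds.

    ``class_stages`` maps a vessel class to an ordered sequence of
    ``(stage, lower, upper)`` triples; intervals are right-closed, the
    first interval of a class also contains its lower bound, and together
    they must tile [0, 360] in order of non-decreasing severity.
    """

    vessel_classes: Mapping[str, str]
    class_stages: Mapping[str, Sequence[tuple[Stage, float, float]]]

    def __post_init__(self) -> None:
        missing = [v for v in VESSELS if v not in self.vessel_classes]
        if missing:
            raise RuleValidationError(f"vessels without a class: {missing}")
        unknown = sorted(set(self.vessel_classes.values()) - set(self.class_stages))
        if unknown:
            raise RuleValidationError(f"vessel classes without stage rules: {unknown}")
        for cls_name, stages in self.class_stages.items():
            if not stages:
                raise RuleValidationError(f"{cls_name}: empty stage list")
            sevs = [s for s, _, _ in stages]
            if sevs != sorted(sevs):
                raise RuleValidationError(f"{cls_name}: stages not ordered by severity")
            lo0 = stages[0][1]
            if lo0 != 0:
                raise RuleValidationError(f"{cls_name}: rules must start at 0 degrees")
            prev_hi = stages[0][2]
            if prev_hi < lo0:
                raise RuleValidationError(f"{cls_name}: inverted interval")
            for _, lo, hi in stages[1:]:
                if lo != prev_hi:
                    raise RuleValidationError(
                        f"{cls_name}: gap or overlap at {lo} (previous upper {prev_hi})"
                    )
                if hi < lo:
                    raise RuleValidationError(f"{cls_name}: inverted interval at {lo}")
                prev_hi = hi
            if prev_hi != 360:
                raise RuleValidationError(
                    f"{cls_name}: rules must cover [0, 360], last upper is {prev_hi}"
                )


@dataclass(frozen=True)
class StagingDecision:
    """Case stage with the per-vessel trace that produced it."""

    stage: Stage
    vessel_stages: Mapping[str, Stage]
    driving_vessels: tuple[str, ...]
    caveat: str = OCCLUSION_CAVEAT


def _parse_stage_block(name: str, block: Mapping) -> list[tuple[Stage, float, float]]:
    out = []
    for label, interval in block.items():
        if not (isinstance(interval, (list, tuple)) and len(interval) == 2):
            raise RuleValidationError(f"{name}/{label}: expected [lower, upper]")
        out.append((Stage.from_label(label), float(interval[0]), float(interval[1])))
    out.sort(key=lambda t: t[0])  # config key order is not significant
    return out


def load_ruleset(path: str | Path) -> RuleSet:
    """Load and validate a YAML rule table.

    The schema has a ``vessel_classes`` mapping and one ``<class>_stages``
    block per vessel class, each stage an inclusive-upper degree interval.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "vessel_classes" not in data:
        raise RuleValidationError(f"{path}: missing 'vessel_classes'")
    classes = {str(k): str(v) for k, v in data["vessel_classes"].items()}
    class_stages = {}
    for cls_name in sorted(set(classes.values())):
        key = f"{cls_name}_stages"
        if key not in data:
            raise RuleValidationError(f"{path}: missing '{key}' block")
        class_stages[cls_name] = _parse_stage_block(key, data[key])
    return RuleSet(vessel_classes=classes, class_stages=class_stages)


def default_ruleset() -> RuleSet:
    """The bundled DPCG-style default rule table."""
    ref = resources.files("vesselquant.data").joinpath("dpcg_default.yaml")
    with resources.as_file(ref) as path:
        return load_ruleset(path)


def stage_for_degrees(rules: RuleSet, vessel: str, degrees: float) -> Stage:
    """Stage implied by one vessel's involvement degrees."""
    if not 0 <= degrees <= 360:
        raise ValueError(f"degrees must lie in [0, 360], got {degrees}")
    cls_name = rules.vessel_classes[vessel]
    stages = rules.class_stages[cls_name]
    for i, (stage, lo, hi) in enumerate(stages):
        if i == 0 and degrees == lo:
            return stage
        if lo < degrees <= hi:
            return stage
    raise AssertionError("rule table does not cover the input; validation should prevent this")


def classify_stage(report: InvolvementReport, rules: RuleSet | None = None) -> StagingDecision:
    """Map a five-vessel involvement report to a resectability stage.

    Each vessel's maximum degrees is staged under its class rules and the
    case stage is the maximum severity over vessels.  The decision trace
    lists every vessel whose individual stage equals the case stage.
    """
    if rules is None:
        rules = default_ruleset()
    vessel_stages = {
        v: stage_for_degrees(rules, v, report[v].max_degrees) for v in VESSELS
    }
    case_stage = max(vessel_stages.values())
    driving = tuple(v for v in VESSELS if vessel_stages[v] == case_stage)
    return StagingDecision(stage=case_stage, vessel_stages=vessel_stages, driving_vessels=driving)
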