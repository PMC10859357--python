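"""Agreement, per-group summaries and one-way ANOVA for paired assessments.

These are the evaluation computations used when a model's continuous
involvement degrees are compared against a rater's categorical calls:
exact categorical agreement (overall and per stratum), median/IQR of the
model's degrees within each rater group, and a one-way ANOVA across rater
groups.  They operate on any paired model/rater data — clinical reports or
phantom batches alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .involvement import CATEGORIES, InvolvementReport, bin_degree
from .volume_io import VESSELS

__all__ = [
    "PairedAssessments",
    "AgreementResult",
    "AnovaResult",
    "categorical_agreement",
    "summarize_by_rater_group",
    "one_way_anova",
    "read_rater_csv",
    "build_paired",
    "VESSEL_CLASS_STRATIFIER",
]

#: Default stratifier: arteries vs veins.
VESSEL_CLASS_STRATIFIER = {
    "CeTr": "arterial",
    "HA": "arterial",
    "SMA": "arterial",
    "SMV": "venous",
    "PV": "venous",
}

_COLUMNS = ("case_id", "vessel", "model_degrees", "model_category", "rater_category")


@dataclass(frozen=True)
class PairedAssessments:
    """Paired model/rater records, one row per (case, vessel).

    ``records`` is a DataFrame with columns ``case_id``, ``vessel``,
    ``model_degrees``, ``model_category`` and ``rater_category``.  The
    model category must equal ``bin_degree(model_degrees)`` on every row
    and rater categories must come from the five-group vocabulary.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"paired records missing columns: {missing}")
        bad_rater = set(df["rater_category"]) - set(CATEGORIES)
        if bad_rater:
            raise ValueError(f"rater categories outside the five-group vocabulary: {bad_rater}")
        expected = df["model_degrees"].map(bin_degree)
        mismatch = df.loc[expected != df["model_category"]]
        if len(mismatch):
            raise ValueError(
                "model_category inconsistent with bin_degree(model_degrees) "
                f"on {len(mismatch)} record(s), e.g. row {mismatch.index[0]}"
            )
        object.__setattr__(self, "records", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_rows(cls, rows: Sequence[tuple]) -> "PairedAssessments":
        return cls(pd.DataFrame(rows, columns=list(_COLUMNS)))


@dataclass(frozen=True)
class AgreementResult:
    """Exact-match agreement counts, overall and per stratum."""

    n_agree: int
    n_total: int
    per_stratum: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.n_agree / self.n_total


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA outcome."""

    F: float
    p_value: float
    n_groups: int
    n_total: int
    degenerate: bool = False


def categorical_agreement(
    pairs: PairedAssessments,
    stratifier: Mapping[str, str] | Callable[[pd.Series], str] | str | None = None,
) -> AgreementResult:
    """Count records where the model's category matches the rater's.

    ``stratifier`` optionally splits the count: a mapping from vessel name
    to stratum (e.g. :data:`VESSEL_CLASS_STRATIFIER`), a column name of
    ``records``, or a callable applied to each row.
    """
    df = pairs.records
    if len(df) == 0:
        raise ValueError("no paired records")
    match = df["model_category"] == df["rater_category"]
    per_stratum: dict[str, tuple[int, int]] = {}
    if stratifier is not None:
        if isinstance(stratifier, str):
            strata = df[stratifier]
        elif callable(stratifier):
            strata = df.apply(stratifier, axis=1)
        else:
            strata = df["vessel"].map(stratifier)
        for name, idx in match.groupby(strata).groups.items():
            sub = match.loc[idx]
            per_stratum[str(name)] = (int(sub.sum()), int(len(sub)))
    return AgreementResult(
        n_agree=int(match.sum()), n_total=int(len(match)), per_stratum=per_stratum
    )


def summarize_by_rater_group(pairs: PairedAssessments) -> pd.DataFrame:
    """Median and IQR of model degrees within each rater group.

    Returns one row per rater category present in the data, in the
    canonical category order, with columns ``n``, ``median``, ``q1`` and
    ``q3``.  Quartiles use linear interpolation between order statistics.
    Categories absent from the data are omitted (listed in the frame's
    ``attrs['absent_groups']``).
    """
    df = pairs.records
    rows = []
    for cat in CATEGORIES:
        vals = df.loc[df["rater_category"] == cat, "model_degrees"].to_numpy(float)
        if len(vals) == 0:
            continue
        rows.append(
            {
                "rater_category": cat,
                "n": len(vals),
                "median": float(np.median(vals)),
                "q1": float(np.quantile(vals, 0.25)),
                "q3": float(np.quantile(vals, 0.75)),
            }
        )
    out = pd.DataFrame(rows, columns=["rater_category", "n", "median", "q1", "q3"])
    out.attrs["absent_groups"] = [c for c in CATEGORIES if c not in set(out["rater_category"])]
    return out


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA across numeric samples.

    F is the ratio of between-group to within-group mean squares; the
    p-value comes from the F distribution.  With zero within-group
    variance and unequal means the result is degenerate: F is infinite
    and the p-value is reported as 0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    n_total = sum(len(a) for a in arrays)
    if n_total - len(arrays) < 1:
        raise ValueError("at least one group needs two or more observations")
    within_ss = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    means = [a.mean() for a in arrays]
    if within_ss == 0.0 and len(set(np.round(means, 12))) > 1:
        return AnovaResult(
            F=float("inf"), p_value=0.0, n_groups=len(arrays), n_total=n_total, degenerate=True
        )
    with np.errstate(invalid="ignore"):
        F, p = stats.f_oneway(*arrays)
    if not np.isfinite(F):  # all observations identical
        F, p = 0.0, 1.0
    return AnovaResult(F=float(F), p_value=float(p), n_groups=len(arrays), n_total=n_total)


def read_rater_csv(path: str | Path) -> pd.DataFrame:
    """Read rater categories: CSV with case_id, vessel, rater_category."""
    df = pd.read_csv(path, dtype={"case_id": str, "vessel": str, "rater_category": str})
    required = ["case_id", "vessel", "rater_category"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = set(df["rater_category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"{path}: rater categories outside the vocabulary: {bad}")
    bad_vessels = set(df["vessel"]) - set(VESSELS)
    if bad_vessels:
        raise ValueError(f"{path}: unknown vessels: {bad_vessels}")
    return df[required]


def build_paired(
    model_reports: Mapping[str, InvolvementReport], raters: pd.DataFrame
) -> PairedAssessments:
    """Join model reports with rater categories on (case_id, vessel)."""
    rows = []
    for _, rec in raters.iterrows():
        case = str(rec["case_id"])
        if case not in model_reports:
            raise KeyError(f"no model report for case {case!r}")
        vi = model_reports[case][rec["vessel"]]
        rows.append((case, rec["vessel"], vi.max_degrees, vi.category, rec["rater_category"]))
    return PairedAssessments.from_rows(rows)
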