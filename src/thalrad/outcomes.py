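"""PANSS-based outcome labeling and cohort-description statistics.

Treatment response on the Positive and Negative Syndrome Scale (PANSS) is
quantified as a percentage change relative to the 30-point scale floor:

    percent_change = (total_1 - total_0) * 100 / (total_0 - 30)

where total_0 is the baseline and total_1 the discharge total. A patient is
a responder when the total score dropped by at least 30% on this scale
(percent_change <= -30; the boundary counts as response). Cohort summaries
compare groups with Pearson chi-square (no continuity correction) for
categorical rows and Welch's unequal-variance t-test for continuous rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ThalradError

__all__ = [
    "SubjectRecord",
    "OutcomeLabel",
    "panss_percent_change",
    "label_responder",
    "chi_square_2x2",
    "welch_t_from_summary",
    "cohort_summary",
]

PANSS_FLOOR = 30
PANSS_INCLUSION_MIN = 60


@dataclass(frozen=True)
class SubjectRecord:
    """One subject of a two-dataset case-control cohort."""

    subject_id: str
    class_label: str                      # "patient" | "control"
    dataset_id: int                       # 1 | 2
    panss_baseline_total: Optional[int] = None
    panss_discharge_total: Optional[int] = None
    age_years: Optional[float] = None
    education_years: Optional[float] = None
    sex: Optional[str] = None             # "M" | "F"

    def __post_init__(self):
        if self.class_label not in ("patient", "control"):
            raise ConfigurationError(f"bad class_label {self.class_label!r}")
        if self.dataset_id not in (1, 2):
            raise ConfigurationError(f"bad dataset_id {self.dataset_id!r}")
        if self.class_label == "patient":
            if (
                self.panss_baseline_total is not None
                and self.panss_baseline_total < PANSS_INCLUSION_MIN
            ):
                raise ConfigurationError(
                    "patients require a baseline PANSS total >= 60"
                )
        elif self.panss_baseline_total is not None:
            raise ConfigurationError("controls carry no PANSS scores")
        for v in (self.panss_baseline_total, self.panss_discharge_total):
            if v is not None and v < PANSS_FLOOR:
                raise ConfigurationError("PANSS totals cannot fall below 30")

    @property
    def outcome(self) -> Optional["OutcomeLabel"]:
        if (
            self.panss_baseline_total is None
            or self.panss_discharge_total is None
        ):
            return None
        change = panss_percent_change(
            self.panss_baseline_total, self.panss_discharge_total
        )
        return OutcomeLabel(change, label_responder(change))


@dataclass(frozen=True)
class OutcomeLabel:
    percent_change: float
    responder: bool


def panss_percent_change(total0: int, total1: int) -> float:
    """Signed percentage change of the PANSS total relative to the 30 floor.

    Negative values are improvement: (90, 60) -> -50.0.
    """
    if total0 <= PANSS_FLOOR:
        raise ThalradError(
            f"baseline total {total0} must exceed the PANSS floor of 30"
        )
    return (total1 - total0) * 100.0 / (total0 - PANSS_FLOOR)


def label_responder(change: float, threshold_pct: float = 30.0) -> bool:
    """Responder iff the reduction reached ``threshold_pct`` (inclusive)."""
    if not np.isfinite(change):
        raise ThalradError("percent change must be finite")
    return change <= -threshold_pct


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, without continuity correction.

    Rows are groups, columns categories: [[a, b], [c, d]].
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ThalradError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ThalradError("chi-square requires all margins > 0")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from summary statistics.

    Returns (t, Satterthwaite df, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise ThalradError("Welch test needs n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ThalradError("Welch test needs positive SDs")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    se2 = sd1**2 / n1 + sd2**2 / n2
    df = se2**2 / (
        (sd1**2 / n1) ** 2 / (n1 - 1) + (sd2**2 / n2) ** 2 / (n2 - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


def _welch_row(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    if len(x) < 2 or len(y) < 2 or (x.std() == 0 and y.std() == 0):
        return None
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def cohort_summary(records: Iterable[SubjectRecord]) -> dict:
    """Per-group descriptive statistics with between-group p-values.

    Continuous rows report mean +/- SD per group with a Welch p-value;
    categorical rows (sex) report counts with a chi-square p-value. When
    discharge PANSS exists, a responder/non-responder stratum is included.
    p-value entries are omitted when only one group is present.
    """
    recs = list(records)
    if not recs:
        raise ThalradError("empty cohort")
    df = pd.DataFrame(
        {
            "class_label": [r.class_label for r in recs],
            "age_years": [r.age_years for r in recs],
            "education_years": [r.education_years for r in recs],
            "sex": [r.sex for r in recs],
            "panss_baseline": [r.panss_baseline_total for r in recs],
            "panss_discharge": [r.panss_discharge_total for r in recs],
        }
    )
    out: dict = {"groups": {}, "p_values": {}}

    def describe(sub: pd.DataFrame) -> dict:
        d: dict = {"n": int(len(sub))}
        for col in ("age_years", "education_years", "panss_baseline",
                    "panss_discharge"):
            vals = sub[col].dropna().astype(float)
            if len(vals):
                d[col] = {"mean": float(vals.mean()),
                          "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
        sexes = sub["sex"].dropna()
        if len(sexes):
            d["sex"] = {"M": int((sexes == "M").sum()),
                        "F": int((sexes == "F").sum())}
        return d

    def compare(sub1: pd.DataFrame, sub2: pd.DataFrame, prefix: str):
        for col in ("age_years", "education_years", "panss_baseline",
                    "panss_discharge"):
            x = sub1[col].dropna().astype(float).to_numpy()
            y = sub2[col].dropna().astype(float).to_numpy()
            p = _welch_row(x, y)
            if p is not None:
                out["p_values"][f"{prefix}.{col}"] = p
        s1, s2 = sub1["sex"].dropna(), sub2["sex"].dropna()
        if len(s1) and len(s2):
            try:
                _, p = chi_square_2x2(
                    int((s1 == "M").sum()), int((s1 == "F").sum()),
                    int((s2 == "M").sum()), int((s2 == "F").sum()),
                )
                out["p_values"][f"{prefix}.sex"] = p
            except ThalradError:
                pass

    patients = df[df.class_label == "patient"]
    controls = df[df.class_label == "control"]
    if len(patients):
        out["groups"]["patients"] = describe(patients)
    if len(controls):
        out["groups"]["controls"] = describe(controls)
    if len(patients) and len(controls):
        compare(patients, controls, "patients_vs_controls")

    with_outcome = [
        r for r in recs
        if r.class_label == "patient" and r.outcome is not None
    ]
    if with_outcome:
        resp_ids = {r.subject_id for r in with_outcome if r.outcome.responder}
        pat = df.assign(subject_id=[r.subject_id for r in recs])
        pat = pat[pat.subject_id.isin({r.subject_id for r in with_outcome})]
        resp = pat[pat.subject_id.isin(resp_ids)]
        nonresp = pat[~pat.subject_id.isin(resp_ids)]
        out["groups"]["responders"] = describe(resp)
        out["groups"]["non_responders"] = describe(nonresp)
        if len(resp) and len(nonresp):
            compare(resp, nonresp, "responders_vs_non_responders")
    return out
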