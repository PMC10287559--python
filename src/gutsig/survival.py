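"""Ever-I2 classification and time-to-dysplasia Kaplan-Meier analysis.

Patients are flagged ever-I2 when any visit's biopsy was classified I2.
Time runs from colitis diagnosis to the first dysplasia event on the
requested side (right = cecum, ascending colon or hepatic flexure) or to
the last recorded colonoscopy; right- and non-right-sided dysplasia are
independent events, so a patient with only the other side's event is
censored. Follow-up outliers (Tukey 1.5*IQR fences per diagnosis group,
type-7 quartiles) can be removed before estimation, and groups are compared
with a two-sided log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

DAYS_PER_YEAR = 365.25


@dataclass
class KmCurve:
    group: str
    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray


def classify_ever_i2(visits: pd.DataFrame) -> pd.Series:
    """True per patient iff any visit (including post-dysplasia visits) is I2.

    ``visits`` needs columns patient_id and cluster.
    """
    if visits.groupby("patient_id").size().min() < 1:
        raise ValueError("every patient needs at least one visit")
    return visits.groupby("patient_id")["cluster"].apply(lambda c: (c == "I2").any())


def assemble_time_to_event(records: pd.DataFrame, side: str = "right") -> pd.DataFrame:
    """Per-patient (time in years, event flag) table for one dysplasia side.

    ``records`` columns: patient_id, diagnosis, ever_i2,
    colitis_diagnosis_date, event_date, event_side, last_colonoscopy_date
    (dates parseable by pandas). Patients whose event is on the other side
    are censored at the last colonoscopy. Negative times are rejected.
    """
    rec = records.copy()
    for col in ("colitis_diagnosis_date", "event_date", "last_colonoscopy_date"):
        rec[col] = pd.to_datetime(rec[col].replace("", pd.NA))
    rows = []
    for _, r in rec.iterrows():
        has_event = pd.notna(r["event_date"]) and r["event_side"] == side
        end = r["event_date"] if has_event else r["last_colonoscopy_date"]
        time = (end - r["colitis_diagnosis_date"]).days / DAYS_PER_YEAR
        if time < 0:
            raise ValueError(
                f"negative follow-up time for patient {r['patient_id']!r}"
            )
        rows.append((r["patient_id"], r["diagnosis"], bool(r["ever_i2"]), time, has_event))
    return pd.DataFrame(
        rows, columns=["patient_id", "diagnosis", "ever_i2", "time_years", "event"]
    )


def remove_followup_outliers(
    table: pd.DataFrame, multiplier: float = 1.5
) -> pd.DataFrame:
    """Drop records outside Tukey fences on follow-up time, per diagnosis group.

    Quartiles use linear interpolation (type 7); applied once, not iterated.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 records")
    keep = pd.Series(True, index=table.index)
    for _, idx in table.groupby("diagnosis").groups.items():
        t = table.loc[idx, "time_years"]
        q1, q3 = np.percentile(t, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
        keep.loc[idx] = (t >= lo) & (t <= hi)
    return table[keep].copy()


def km_estimate(
    table: pd.DataFrame, group_col: str = "ever_i2"
) -> tuple[dict[str, KmCurve], float | None]:
    """Product-limit curves per group and a two-sided log-rank p.

    With one group empty only the nonempty curve is returned and the
    p-value is None.
    """
    curves: dict[str, KmCurve] = {}
    groups = [g for g, sub in table.groupby(group_col) if len(sub) > 0]
    for g in groups:
        sub = table[table[group_col] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_years"], event_observed=sub["event"])
        times = kmf.survival_function_.index.to_numpy()
        curves[str(g)] = KmCurve(
            group=str(g),
            times=times,
            at_risk=kmf.event_table["at_risk"].to_numpy(),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
            censor_times=sub.loc[~sub["event"].astype(bool), "time_years"].to_numpy(),
        )
    if len(groups) != 2:
        return curves, None
    a = table[table[group_col] == groups[0]]
    b = table[table[group_col] == groups[1]]
    res = logrank_test(
        a["time_years"], b["time_years"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return curves, float(res.p_value)
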