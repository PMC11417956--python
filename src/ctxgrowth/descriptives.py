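"""Per-individual biomarker summaries and day-to-day variability (CV).

The day-to-day coefficient of variation — 100 * SD / mean of repeated
same-time-of-day samples within an individual — is the standard measure of
a biomarker's intra-individual biological variability.  The cohort-level
figure is the unweighted mean of the per-individual CVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SummaryRow", "individual_summary", "cohort_mean_cv",
           "summary_table"]


@dataclass(frozen=True)
class SummaryRow:
    individual_id: str
    n: int
    mean: float
    median: float
    sd: float        # sample (n-1) standard deviation
    se: float        # sd / sqrt(n)
    min: float
    max: float
    cv_percent: float  # 100 * sd / mean


def individual_summary(values, individual_id="") -> SummaryRow:
    """Summarize one individual's (SG-corrected) concentrations."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least two samples per individual")
    sd = float(values.std(ddof=1))
    mean = float(values.mean())
    return SummaryRow(
        individual_id=str(individual_id), n=int(values.size), mean=mean,
        median=float(np.median(values)), sd=sd,
        se=sd / np.sqrt(values.size), min=float(values.min()),
        max=float(values.max()), cv_percent=100.0 * sd / mean)


def cohort_mean_cv(rows) -> float:
    """Unweighted arithmetic mean of per-individual CV percentages."""
    cvs = [r.cv_percent if isinstance(r, SummaryRow) else float(r)
           for r in rows]
    if not cvs:
        raise ValueError("cohort_mean_cv needs at least one summary row")
    return float(np.mean(cvs))


def summary_table(processed: pd.DataFrame, value_col: str = "ctx_sg",
                  id_col: str = "individual_id",
                  min_n: int = 2) -> pd.DataFrame:
    """Per-individual summary rows for all individuals with >= ``min_n``
    samples, as a DataFrame in the standard column order."""
    rows = []
    for iid, g in processed.groupby(id_col, sort=True):
        if len(g) >= min_n:
            rows.append(individual_summary(g[value_col].to_numpy(), iid))
    return pd.DataFrame([r.__dict__ for r in rows])
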