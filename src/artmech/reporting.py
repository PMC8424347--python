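"""Summary tables for cross-validation results.

Per-sample rows (sample, method, R^2, c, k1, k2) are condensed into the
cohort summary: median and standard deviation of R^2 and componentwise
parameter medians -- once over all samples and once excluding samples
with R^2 < -1 (poor predictions whose squared error dwarfs the signal
variance), plus the count the exclusion removes.  Censored entries
(R^2 reported only as "< -1") participate in order statistics as
arbitrarily small values and are always excluded by the threshold rule.

``reference_results`` loads the published per-sample table for the
27-sample human aortic media cohort that ships with the package, so its
printed medians can be recomputed rather than quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["ReportTable", "summarize", "rows_from_cv", "rows_from_standard",
           "reference_results"]

#: Default exclusion threshold for the starred summary rows.
R2_EXCLUDE_BELOW = -1.0


@dataclass
class ReportTable:
    """Per-sample rows plus recomputable cohort summary statistics."""

    rows: pd.DataFrame
    median_r2: float
    sd_r2: float
    median_r2_excl: float
    sd_r2_excl: float
    n_excluded: int
    median_params: tuple
    exclude_below: float = R2_EXCLUDE_BELOW

    def to_frame(self) -> pd.DataFrame:
        """Rows with an appended median row (matching the printed layout)."""
        med = {"sample": "median", "r2": self.median_r2,
               "c": self.median_params[0], "k1": self.median_params[1],
               "k2": self.median_params[2]}
        if "method" in self.rows.columns and self.rows["method"].nunique() == 1:
            med["method"] = self.rows["method"].iloc[0]
        return pd.concat([self.rows, pd.DataFrame([med])], ignore_index=True)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def _censored_fill(df: pd.DataFrame) -> pd.Series:
    """R^2 with censored entries mapped below any finite value, so they
    sort to the bottom of order statistics."""
    r2 = df["r2"].astype(float).copy()
    if "r2_censored" in df.columns:
        r2[df["r2_censored"].astype(bool)] = -np.inf
    return r2


def summarize(rows: pd.DataFrame,
              exclude_below: float = R2_EXCLUDE_BELOW) -> ReportTable:
    """Cohort summary of a per-sample result table.

    ``rows`` needs columns sample, r2 (c, k1, k2 optional; r2_censored
    optional).  Raises on empty input and on a median that would fall
    into the censored range.
    """
    if rows is None or len(rows) == 0:
        raise DomainError("empty result table")
    rows = rows.reset_index(drop=True)
    r2 = _censored_fill(rows)
    med = float(np.median(r2))
    if not np.isfinite(med):
        raise DomainError("median falls among censored entries")
    finite = r2[np.isfinite(r2)]
    sd = float(np.std(finite, ddof=1)) if len(finite) > 1 else 0.0
    keep = r2 >= exclude_below
    if not keep.any():
        raise DomainError("all samples excluded by the R^2 threshold")
    med_x = float(np.median(r2[keep]))
    sd_x = float(np.std(r2[keep], ddof=1)) if keep.sum() > 1 else 0.0
    if {"c", "k1", "k2"}.issubset(rows.columns):
        mp = tuple(float(np.median(rows[k].astype(float))) for k in ("c", "k1", "k2"))
    else:
        mp = (np.nan, np.nan, np.nan)
    return ReportTable(rows=rows, median_r2=med, sd_r2=sd,
                       median_r2_excl=med_x, sd_r2_excl=sd_x,
                       n_excluded=int((~keep).sum()), median_params=mp,
                       exclude_below=exclude_below)


def rows_from_cv(cv, method: str = "hybrid",
                 params: Optional[dict] = None) -> pd.DataFrame:
    """Per-sample rows from a trainer CVResult (optionally with the
    predicted parameters per validation sample)."""
    recs = []
    for f in cv.folds:
        rec = {"sample": f.validation_id, "method": method, "r2": f.r2}
        if params and f.validation_id in params:
            p = params[f.validation_id]
            rec.update(c=p.c, k1=p.k1, k2=p.k2)
        recs.append(rec)
    return pd.DataFrame(recs)


def rows_from_standard(loo) -> pd.DataFrame:
    """Per-sample rows from a fitting.LooStandardResult."""
    recs = []
    for sid in loo.sample_ids:
        if sid not in loo.r2:
            continue
        p = loo.params_used[sid]
        recs.append({"sample": sid, "method": "standard", "r2": loo.r2[sid],
                     "c": p.c, "k1": p.k1, "k2": p.k2})
    return pd.DataFrame(recs)


def reference_results(table: Optional[str] = None,
                      method: Optional[str] = None) -> pd.DataFrame:
    """The packaged published per-sample results (27-sample aortic media
    cohort).  Filter by ``table`` in {"roi", "full"} and ``method`` in
    {"standard", "hybrid"}."""
    with resources.files("artmech.data").joinpath(
            "reference_cohort_results.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    if table is not None:
        df = df[df["table"] == table]
    if method is not None:
        df = df[df["method"] == method]
    return df.reset_index(drop=True)
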