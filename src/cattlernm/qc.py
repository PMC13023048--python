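"""Record filters, class recodings and contemporary-group construction.

The cleaning rules mirror routine beef-herdbook practice: drop animals
with no birth date or with neither trait, set phenotypes beyond mean
+/- 3.5 SD (computed once, per trait, pre-filter) to missing, recode dam
parity into classes 1..7 (7 pools everything above 6), and form
contemporary groups as farm x birth-year x season, keeping only groups
with more than five observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEASONS = ("early_rainy", "late_rainy", "early_dry", "late_dry")

#: calendar month -> birth season (southern-hemisphere rainy season)
_MONTH_SEASON = {
    10: "early_rainy", 11: "early_rainy", 12: "early_rainy",
    1: "late_rainy", 2: "late_rainy", 3: "late_rainy", 4: "late_rainy",
    5: "early_dry", 6: "early_dry", 7: "early_dry",
    8: "late_dry", 9: "late_dry",
}

OUTLIER_SD_UNITS = 3.5
MIN_CG_SIZE = 6  # "more than five observations"


def assign_season(birth_date):
    """Birth season from the calendar month (vectorised over dates)."""
    months = pd.to_datetime(pd.Series(np.atleast_1d(np.asarray(birth_date, dtype=object)))).dt.month
    out = months.map(_MONTH_SEASON).to_numpy()
    return out if out.size > 1 else out[0]


def recode_parity(raw_parity):
    """Pool parities above 6 into class 7; parity must be >= 1."""
    p = np.atleast_1d(np.asarray(raw_parity))
    if np.any(pd.isna(p)) or np.any(p.astype(float) < 1):
        raise ValueError("parity must be a known integer >= 1")
    out = np.minimum(p.astype(int), 7)
    return out if out.size > 1 else int(out[0])


def filter_outliers(values: pd.Series, sd_units: float = OUTLIER_SD_UNITS
                    ) -> tuple[pd.Series, int]:
    """Set values with |x - mean| > sd_units * SD to missing.

    Mean and SD come from the pre-filter non-missing distribution in a
    single pass (no iterative re-trimming); the boundary itself is kept
    (strict inequality).  Returns (filtered series, n removed).
    """
    x = pd.to_numeric(values, errors="coerce")
    obs = x.dropna()
    if len(obs) < 2:
        return x, 0
    mu, sd = float(obs.mean()), float(obs.std(ddof=1))
    if sd == 0.0:
        return x, 0
    bad = (x - mu).abs() > sd_units * sd
    out = x.mask(bad)
    return out, int(bad.sum())


@dataclass
class QCReport:
    """Per-rule exclusion counts plus a record-level log."""

    n_input: int = 0
    n_retained: int = 0
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)
    outliers_set_missing: dict = field(default_factory=dict)
    dropped_groups: pd.DataFrame = field(default_factory=pd.DataFrame)

    def counts(self) -> dict:
        by_reason = (self.exclusions["reason"].value_counts().to_dict()
                     if len(self.exclusions) else {})
        return {"input": self.n_input, "retained": self.n_retained,
                "excluded": by_reason, "outliers": dict(self.outliers_set_missing)}


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records without a birth date or with neither BW nor WW.

    Returns (retained, log) where the log lists (animal, reason) with
    reason in {no_birth_date, no_trait}.
    """
    no_date = records["birth_date"].isna()
    no_trait = records["bw_kg"].isna() & records["ww_kg"].isna()
    reasons = np.where(no_date, "no_birth_date", np.where(no_trait, "no_trait", ""))
    log = pd.DataFrame({"animal": records["animal"], "reason": reasons})
    log = log[log["reason"] != ""].reset_index(drop=True)
    kept = records[~(no_date | no_trait)].reset_index(drop=True)
    return kept, log


def form_contemporary_groups(records: pd.DataFrame, min_size: int = MIN_CG_SIZE
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach cg_id = farm x birth year x season; drop groups with fewer
    than ``min_size`` records (paper rule: retain only > 5 observations).

    Returns (records with cg_id, dropped-group table).
    """
    rec = records.copy()
    bd = pd.to_datetime(rec["birth_date"])
    if "season" not in rec.columns:
        rec["season"] = bd.dt.month.map(_MONTH_SEASON)
    rec["cg_id"] = (rec["farm"].astype(str) + "_" + bd.dt.year.astype(str)
                    + "_" + rec["season"].astype(str))
    sizes = rec["cg_id"].value_counts()
    small = sizes[sizes < min_size]
    dropped = pd.DataFrame({"cg_id": small.index, "n_records": small.to_numpy()})
    rec = rec[~rec["cg_id"].isin(small.index)].reset_index(drop=True)
    return rec, dropped


def run_qc(records: pd.DataFrame, sd_units: float = OUTLIER_SD_UNITS,
           min_cg_size: int = MIN_CG_SIZE) -> tuple[pd.DataFrame, QCReport]:
    """Full QC pipeline: exclusions -> per-trait outlier screen ->
    re-check the no-trait rule -> season/CG formation -> CG-size filter.

    Expects columns animal, birth_date, farm, bw_kg, ww_kg (plus whatever
    else rides along).  Weaning age is set missing wherever WW is missing.
    Idempotent: a second pass changes nothing.
    """
    report = QCReport(n_input=len(records))
    rec, log1 = apply_exclusions(records)

    logs = [log1]
    for trait in ("bw_kg", "ww_kg"):
        rec[trait], n_out = filter_outliers(rec[trait], sd_units)
        report.outliers_set_missing[trait] = n_out

    # records that lost their last trait to the outlier screen
    rec, log2 = apply_exclusions(rec)
    log2 = log2.assign(reason="no_trait_after_outlier")
    logs.append(log2)

    if "weaning_age_d" in rec.columns:
        rec.loc[rec["ww_kg"].isna(), "weaning_age_d"] = np.nan

    if "parity" in rec.columns:
        rec["parity_class"] = recode_parity(rec["parity"].to_numpy())

    rec, dropped = form_contemporary_groups(rec, min_cg_size)
    if len(dropped):
        small = pd.DataFrame({"animal": records.loc[~records["animal"].isin(rec["animal"])
                                                    & ~records["animal"].isin(pd.concat(logs)["animal"]),
                                                    "animal"],
                              "reason": "small_cg"})
        logs.append(small)

    report.exclusions = pd.concat(logs, ignore_index=True) if logs else pd.DataFrame()
    report.dropped_groups = dropped
    report.n_retained = len(rec)
    return rec, report
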