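"""Environmental covariates for prenatal drought and heat stress.

Four environmental conditions (EC) summarise the weather an animal was
exposed to in utero, anchored at its birth date:

* ``sumPrec365`` / ``sumPrec280`` / ``sumPrec90`` — cumulative precipitation
  (mm) over the 365, 280 and 90 days before birth;
* ``meanTHI90`` — mean hourly temperature-humidity index over the 90 days
  before birth.

The window is the half-open interval ``[birth_date - window, birth_date)``:
the birth day itself is excluded.  Raw EC values are rescaled to [-1, 1]
from the observed min/max so that the reaction-norm covariates are the
first-order Legendre pair (1, scaled EC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EC_NAMES = ("sumPrec365", "sumPrec280", "sumPrec90", "meanTHI90")

#: Magnus saturation-vapour-pressure constants (Alduchov & Eskridge).
_MAGNUS_A = 17.625
_MAGNUS_B = 243.04


class DataError(ValueError):
    """Input data violates a documented contract (coverage, finiteness)."""


class DegenerateGradientError(ValueError):
    """All raw EC values identical: the reaction norm is unidentifiable."""


@dataclass(frozen=True)
class ECDefinition:
    """A named environmental covariate: what is aggregated and over how long."""

    name: str
    kind: str  # "precip_sum" | "thi_mean"
    window_days: int

    def __post_init__(self) -> None:
        expected = {
            "sumPrec365": ("precip_sum", 365),
            "sumPrec280": ("precip_sum", 280),
            "sumPrec90": ("precip_sum", 90),
            "meanTHI90": ("thi_mean", 90),
        }
        if self.name not in expected:
            raise ValueError(f"unknown EC name {self.name!r}")
        if (self.kind, self.window_days) != expected[self.name]:
            raise ValueError(
                f"EC {self.name!r} requires kind/window {expected[self.name]}, "
                f"got ({self.kind!r}, {self.window_days})"
            )

    @classmethod
    def from_name(cls, name: str) -> "ECDefinition":
        kind = "thi_mean" if name == "meanTHI90" else "precip_sum"
        window = 90 if name.endswith("90") else int(name[len("sumPrec"):])
        return cls(name, kind, window)


def compute_rh(t_air, t_dew):
    """Relative humidity (%) from air and dewpoint temperature (°C).

    August-Roche-Magnus ratio: ``100 * es(DT) / es(T)`` with
    ``es(x) = exp(17.625 x / (243.04 + x))``.  RH <= 100 iff DT <= T.
    """
    t_air = np.asarray(t_air, dtype=float)
    t_dew = np.asarray(t_dew, dtype=float)
    if not (np.all(np.isfinite(t_air)) and np.all(np.isfinite(t_dew))):
        raise DataError("non-finite temperature or dewpoint")
    if np.any(t_air <= -_MAGNUS_B) or np.any(t_dew <= -_MAGNUS_B):
        raise DataError("temperature at or below Magnus singularity (-243.04 °C)")
    rh = 100.0 * np.exp(
        _MAGNUS_A * t_dew / (_MAGNUS_B + t_dew) - _MAGNUS_A * t_air / (_MAGNUS_B + t_air)
    )
    return rh if rh.ndim else float(rh)


def compute_thi(t_air, rh):
    """Temperature-humidity index from air temperature (°C) and RH (%).

    ``THI = (1.8 T + 32) - (0.55 - 0.0055 RH) * (1.8 T - 26)`` — the NRC
    outdoor-cattle form; RH enters in percent (the 0.0055 coefficient
    cancels the stress adjustment exactly at RH = 100).
    """
    t_air = np.asarray(t_air, dtype=float)
    rh = np.asarray(rh, dtype=float)
    thi = (1.8 * t_air + 32.0) - (0.55 - 0.0055 * rh) * (1.8 * t_air - 26.0)
    return thi if thi.ndim else float(thi)


def cumulative_precip_window(daily: pd.DataFrame, birth_date, window_days: int,
                             *, farm: object = None, animal: object = None) -> float:
    """Sum of daily precipitation (mm) over the window before ``birth_date``.

    ``daily`` needs columns ``date`` (datetime-like) and ``precip_mm``.
    The window is [birth_date - window_days, birth_date); every day in it
    must be present exactly once.
    """
    birth = pd.Timestamp(birth_date).normalize()
    start = birth - pd.Timedelta(days=window_days)
    dates = pd.to_datetime(daily["date"].to_numpy())
    mask = (dates >= start) & (dates < birth)
    n = int(mask.sum())
    if n != window_days or pd.Index(dates[mask]).has_duplicates:
        raise DataError(
            f"daily precipitation does not cover [{start.date()}, {birth.date()}) "
            f"(farm={farm}, animal={animal}: {n} of {window_days} days)"
        )
    return float(np.asarray(daily["precip_mm"])[mask].sum())


def mean_thi_window(hourly: pd.DataFrame, birth_date, window_days: int = 90,
                    *, min_coverage: float = 0.95,
                    farm: object = None, animal: object = None) -> float:
    """Mean hourly THI over the window before ``birth_date``.

    ``hourly`` needs columns ``timestamp``, ``temp_c``, ``dewpoint_c``.
    THI is computed per hour (RH from the Magnus ratio first) and then
    averaged; at least ``min_coverage`` of the expected hours must be
    present.
    """
    birth = pd.Timestamp(birth_date).normalize()
    start = birth - pd.Timedelta(days=window_days)
    ts = pd.to_datetime(hourly["timestamp"].to_numpy())
    mask = (ts >= start) & (ts < birth)
    n = int(mask.sum())
    expected = window_days * 24
    if n < min_coverage * expected:
        raise DataError(
            f"hourly weather covers {n}/{expected} hours of "
            f"[{start}, {birth}) (farm={farm}, animal={animal})"
        )
    t_air = np.asarray(hourly["temp_c"], dtype=float)[mask]
    t_dew = np.asarray(hourly["dewpoint_c"], dtype=float)[mask]
    thi = compute_thi(t_air, compute_rh(t_air, t_dew))
    return float(np.mean(thi))


@dataclass(frozen=True)
class ECScale:
    """Persisted (min, max) of a raw EC so new animals project onto the
    same [-1, 1] gradient."""

    ec_name: str
    minimum: float
    maximum: float

    def scale(self, raw):
        x = np.asarray(raw, dtype=float)
        out = 2.0 * (x - self.minimum) / (self.maximum - self.minimum) - 1.0
        return out if out.ndim else float(out)

    def unscale(self, scaled):
        x = np.asarray(scaled, dtype=float)
        out = self.minimum + (x + 1.0) * (self.maximum - self.minimum) / 2.0
        return out if out.ndim else float(out)


def scale_ec(raw_values, ec_name: str = "") -> tuple[np.ndarray, ECScale]:
    """Rescale raw EC values linearly onto [-1, 1] (min -> -1, max -> +1)."""
    x = np.asarray(raw_values, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise DegenerateGradientError(
            f"all {ec_name or 'EC'} values identical ({lo}): no gradient"
        )
    sc = ECScale(ec_name, lo, hi)
    return sc.scale(x), sc


def legendre_covariates(scaled) -> np.ndarray:
    """First-order Legendre covariate pair phi = (1, scaled EC), row-wise."""
    s = np.atleast_1d(np.asarray(scaled, dtype=float))
    return np.column_stack([np.ones_like(s), s])


def compute_ec_table(animals: pd.DataFrame, daily_by_farm: dict, hourly_by_farm: dict,
                     ec_defs: list[ECDefinition] | None = None) -> pd.DataFrame:
    """Per-animal raw EC values for every requested EC definition.

    ``animals`` needs ``animal``, ``farm``, ``birth_date`` columns; weather
    is a dict farm -> DataFrame in the schemas of :func:`cumulative_precip_window`
    / :func:`mean_thi_window`.  Uses per-farm prefix sums, so cost is
    O(weather + animals).  Returns a tidy frame (animal, ec_name, raw).
    """
    if ec_defs is None:
        ec_defs = [ECDefinition.from_name(n) for n in EC_NAMES]
    rows: dict[str, list] = {"animal": [], "ec_name": [], "raw": []}

    for farm, grp in animals.groupby("farm", sort=False):
        births = pd.to_datetime(grp["birth_date"]).dt.normalize()
        need_precip = any(d.kind == "precip_sum" for d in ec_defs)
        need_thi = any(d.kind == "thi_mean" for d in ec_defs)

        if need_precip:
            daily = daily_by_farm.get(farm)
            if daily is None:
                raise DataError(f"no daily precipitation series for farm {farm}")
            d_dates = pd.to_datetime(daily["date"].to_numpy())
            d0 = d_dates.min()
            day_idx = ((d_dates - d0) // pd.Timedelta(days=1)).astype(np.int64)
            n_days = int(day_idx.max()) + 1
            if len(np.unique(day_idx)) != len(day_idx) or n_days != len(day_idx):
                raise DataError(f"daily series for farm {farm} has gaps or duplicates")
            csum = np.concatenate([[0.0], np.cumsum(np.asarray(daily["precip_mm"], float)[np.argsort(day_idx)])])
            b_idx = ((births - d0) // pd.Timedelta(days=1)).to_numpy(np.int64)

        if need_thi:
            hourly = hourly_by_farm.get(farm)
            if hourly is None:
                raise DataError(f"no hourly weather series for farm {farm}")
            h_ts = pd.to_datetime(hourly["timestamp"].to_numpy())
            h0 = h_ts.min()
            hr_idx = ((h_ts - h0) // pd.Timedelta(hours=1)).astype(np.int64)
            order = np.argsort(hr_idx)
            hr_idx = np.asarray(hr_idx)[order]
            n_hours = int(hr_idx.max()) + 1
            if len(np.unique(hr_idx)) != len(hr_idx) or n_hours != len(hr_idx):
                raise DataError(f"hourly series for farm {farm} has gaps or duplicates")
            t_air = np.asarray(hourly["temp_c"], float)[order]
            t_dew = np.asarray(hourly["dewpoint_c"], float)[order]
            thi = compute_thi(t_air, compute_rh(t_air, t_dew))
            thi_csum = np.concatenate([[0.0], np.cumsum(thi)])
            bh_idx = ((births - h0) // pd.Timedelta(hours=1)).to_numpy(np.int64)

        for ec in ec_defs:
            if ec.kind == "precip_sum":
                lo = b_idx - ec.window_days
                hi = b_idx
                if np.any(lo < 0) or np.any(hi > n_days):
                    bad = grp["animal"].to_numpy()[(lo < 0) | (hi > n_days)][0]
                    raise DataError(
                        f"precipitation for farm {farm} does not cover the "
                        f"{ec.window_days}-day window of animal {bad}"
                    )
                raw = csum[hi] - csum[lo]
            else:
                lo = bh_idx - ec.window_days * 24
                hi = bh_idx
                if np.any(lo < 0) or np.any(hi > n_hours):
                    bad = grp["animal"].to_numpy()[(lo < 0) | (hi > n_hours)][0]
                    raise DataError(
                        f"hourly weather for farm {farm} does not cover the "
                        f"{ec.window_days}-day window of animal {bad}"
                    )
                raw = (thi_csum[hi] - thi_csum[lo]) / (ec.window_days * 24)
            rows["animal"].extend(grp["animal"].tolist())
            rows["ec_name"].extend([ec.name] * len(grp))
            rows["raw"].extend(np.asarray(raw, float).tolist())

    return pd.DataFrame(rows)
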