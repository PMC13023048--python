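"""Compute the four environmental conditions per animal.

Reads the weather and phenotype tables from results/data/, computes
sumPrec365/280/90 and meanTHI90 for every animal, and writes the per-
animal EC table plus the EC correlation matrix.
"""

import sys
from importlib import import_module
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfg = import_module("00_config")

from cattlernm.enviro import ECDefinition, compute_ec_table  # noqa: E402


def main():
    records = pd.read_csv(cfg.DATA / "phenotypes.csv", parse_dates=["birth_date"])
    daily = pd.read_csv(cfg.DATA / "weather_daily.csv", parse_dates=["date"])
    hourly = pd.read_csv(cfg.DATA / "weather_hourly.csv", parse_dates=["timestamp"])
    daily_by_farm = {f: g.drop(columns="farm") for f, g in daily.groupby("farm")}
    hourly_by_farm = {f: g.drop(columns="farm") for f, g in hourly.groupby("farm")}

    ec = compute_ec_table(records, daily_by_farm, hourly_by_farm,
                          [ECDefinition.from_name(n) for n in cfg.EC_NAMES])
    wide = ec.pivot(index="animal", columns="ec_name", values="raw")[list(cfg.EC_NAMES)]
    wide.to_csv(cfg.RESULTS / "ec_values.csv")
    corr = wide.corr().round(3)
    corr.to_csv(cfg.RESULTS / "ec_correlations.csv")
    print("per-animal EC summary:")
    print(wide.describe().loc[["mean", "std", "min", "max"]].round(1).to_string())
    print("\nEC correlation matrix:")
    print(corr.to_string())


if __name__ == "__main__":
    main()
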