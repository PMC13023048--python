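"""Synthetic herdbook, weather and phenotype generation.

The generator emulates the structure of a Southern-African beef
herdbook: a multi-generation pedigree with repeated dams (parities
accumulate over years), widely used AI sires linking farms, farm x
birth-year x season contemporary groups, seasonal rainfall with
drought/wet-year variation, and hot-season heat load.  Phenotypes (birth
weight and weaning weight) are drawn under the bivariate maternal
reaction-norm model itself: per-animal direct+maternal regression
coefficients with pedigree covariance A (x) G8 (built by the recursive
parent-average + Mendelian-sampling decomposition, so no dense A is ever
formed), maternal-permanent-environment effects per dam, contemporary-
group effects, and a 2x2 residual, with weaning weight set missing at a
configurable rate.

Every stochastic draw descends from one integer seed through
``numpy.random.SeedSequence`` spawning (one child stream per stage), so
re-runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import qc
from .enviro import ECDefinition, compute_ec_table, scale_ec
from .pedigree import PedigreeTable, _inbreeding_and_d

#: calving-month weights: concentrated early-rainy but all seasons occur
_MONTH_WEIGHTS = np.array([8, 6, 4, 3, 3, 3, 4, 5, 6, 10, 12, 10], dtype=float)


_WW_SD_SCALE = 3.0  # WW phenotypic SD ~3x the BW SD, herdbook-like


def _scale_ww(g8: np.ndarray, s: float = _WW_SD_SCALE) -> np.ndarray:
    d = np.ones(8)
    d[[2, 3, 6, 7]] = s
    return g8 * np.outer(d, d)


def _default_g8() -> np.ndarray:
    """Moderate-GxE default truth: direct h2 ~ 0.3, maternal ~ 0.1 at the
    gradient midpoint, slope-to-intercept ratios ~ 0.4; BW on a ~25 kg^2
    phenotypic scale and WW scaled to a ~3x larger SD."""
    g8 = build_g8(h2_direct=0.30, h2_maternal=0.10, ratio_direct=0.4,
                  ratio_maternal=0.3, r01_direct=0.2, r01_maternal=0.1,
                  r_traits_direct=0.4, r_traits_maternal=0.3, vp=25.0,
                  prop_mpe=0.08, prop_cg=0.10)[0]
    return _scale_ww(g8)


@dataclass
class SimScenario:
    """Study conditions for one synthetic dataset.

    Counts default to the herdbook proportions the analysis targets
    (~15k records in ~600 contemporary groups on 12 farms); covariance
    defaults give moderate GxE.  All counts are configurable.
    """

    n_founders: int = 1000
    n_generations: int = 4
    n_farms: int = 12
    n_veg_zones: int = 4
    years: tuple = (2000, 2020)
    dams_per_sire: int = 15
    progeny_per_dam: int = 3
    true_g8: np.ndarray = field(default_factory=_default_g8)
    true_pm: np.ndarray = field(default_factory=lambda: np.diag([2.0, 18.0]))
    true_cg: np.ndarray = field(default_factory=lambda: np.diag([2.5, 22.5]))
    true_r: np.ndarray = field(default_factory=lambda: np.array([[13.0, 9.0],
                                                                 [9.0, 117.0]]))
    fixed_effect_values: dict = field(default_factory=lambda: {
        "mu": {"bw": 38.0, "ww": 230.0},
        "sex_birth_class": {"1": 0.0, "2": 2.0, "3": -3.0, "4": -1.5},
        "parity_class": {str(k): v for k, v in
                         zip(range(1, 8), [0.0, 1.0, 1.5, 1.5, 1.2, 0.8, 0.3])},
        "veg_zone": {"1": 0.0, "2": 1.0, "3": -1.0, "4": 0.5, "5": -0.5},
        "weaning_age_slope": 0.9,      # kg/d on WW, around 220 d
        "ec_slope": {"bw": 1.0, "ww": 1.5},  # kg per scaled-EC unit
    })
    ec_definition: str = "sumPrec365"
    missing_ww_rate: float = 0.15
    weaning_age_range: tuple = (180.0, 260.0)
    twin_rate: float = 0.03
    seed: int = 2024
    # weather process
    annual_precip_mm: float = 350.0
    wet_dry_amplitude: float = 0.45    # SD of log annual-total year effect
    farm_precip_spread: float = 0.20
    temp_mean_c: float = 22.0
    temp_seasonal_amp_c: float = 7.0
    temp_diurnal_amp_c: float = 8.0
    temp_noise_sd_c: float = 1.5
    dewpoint_depression_c: float = 10.0
    dewpoint_seasonal_amp_c: float = 5.0
    dewpoint_noise_sd_c: float = 1.5

    def __post_init__(self) -> None:
        for name in ("true_g8", "true_pm", "true_cg", "true_r"):
            m = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, 0.5 * (m + m.T))
            w = np.linalg.eigvalsh(getattr(self, name))
            if w.min() < -1e-8 * max(w.max(), 1.0):
                raise ValueError(f"{name} must be positive semi-definite")
        if not 0.0 <= self.missing_ww_rate <= 1.0:
            raise ValueError("missing_ww_rate must be in [0, 1]")
        if self.n_generations < 1:
            raise ValueError("need at least one generation")
        if self.years[1] - self.years[0] < 2:
            raise ValueError("year range must span at least 2 years")

    def streams(self) -> dict:
        kids = np.random.SeedSequence(self.seed).spawn(7)
        names = ("pedigree", "weather", "genetic", "mpe_cg", "residual",
                 "missing", "weaning")
        return {n: np.random.default_rng(s) for n, s in zip(names, kids)}


@dataclass
class WeatherSeries:
    farm: int
    daily: pd.DataFrame   # date, precip_mm
    hourly: pd.DataFrame  # timestamp, temp_c, dewpoint_c


@dataclass
class SimTruth:
    """Everything needed for parameter- and effect-recovery checks."""

    coefficients: pd.DataFrame   # per animal: u_bw0..v_ww1
    mpe: pd.DataFrame            # per dam: bw, ww
    cg_effects: pd.DataFrame     # per cg_id: bw, ww
    ec_scale: object             # generative ECScale
    scenario: SimScenario


def simulate_pedigree(scenario: SimScenario) -> pd.DataFrame:
    """Multi-generation pedigree with repeated dams and shared AI sires.

    Founders form generation 0; each later generation takes its dams from
    the previous generation's females (each producing
    ``progeny_per_dam`` calves at successive parities) and its sires from
    a global pool of previous-generation males, each serving
    ``dams_per_sire`` dams across farms.
    """
    rng = scenario.streams()["pedigree"]
    y0, y1 = scenario.years
    farm_zone = 1 + (np.arange(scenario.n_farms) % scenario.n_veg_zones)

    rows = []
    counter = [0]

    def new_animal(gen, sire, dam, farm, year, parity, prev_twin=False):
        counter[0] += 1
        aid = f"A{counter[0]:06d}"
        month = rng.choice(12, p=_MONTH_WEIGHTS / _MONTH_WEIGHTS.sum()) + 1
        day = int(rng.integers(1, 29))
        sex = "F" if rng.random() < 0.5 else "M"
        twin = rng.random() < scenario.twin_rate
        rows.append({
            "animal": aid, "sire": sire, "dam": dam,
            "birth_date": pd.Timestamp(int(year), int(month), day),
            "sex": sex, "birth_type": "twin" if twin or prev_twin else "singleton",
            "farm": int(farm), "veg_zone": int(farm_zone[farm]),
            "parity": int(parity), "generation": int(gen),
        })
        return aid, sex

    gen_members: list[list[tuple]] = []
    founders = []
    for _ in range(scenario.n_founders):
        farm = int(rng.integers(scenario.n_farms))
        year = int(y0 + 2 + rng.integers(2))
        aid, sex = new_animal(0, None, None, farm, year, 1 + int(rng.integers(3)))
        founders.append((aid, sex, farm, year))
    gen_members.append(founders)

    span = max(1, (y1 - y0 - 6) // max(scenario.n_generations, 1))
    for g in range(1, scenario.n_generations + 1):
        prev = gen_members[-1]
        females = [m for m in prev if m[1] == "F"]
        males = [m for m in prev if m[1] == "M"]
        if not females or not males:
            raise ValueError("a generation ran out of breeding animals")
        n_sires = max(1, int(np.ceil(len(females) / scenario.dams_per_sire)))
        sire_pool = [(males[i][0], males[i][3]) for i in
                     rng.choice(len(males), size=min(n_sires, len(males)),
                                replace=False)]
        members = []
        for aid_dam, _, farm, dam_year in females:
            sire, sire_year = sire_pool[int(rng.integers(len(sire_pool)))]
            base = max(dam_year + 2, sire_year + 2, y0 + 2 + g * span)
            for parity in range(1, scenario.progeny_per_dam + 1):
                year = base + (parity - 1)
                if year > y1:
                    break
                aid, sex = new_animal(g, sire, aid_dam, farm, year, parity)
                members.append((aid, sex, farm, year))
        gen_members.append(members)

    return pd.DataFrame(rows)


def simulate_weather(scenario: SimScenario) -> dict[int, WeatherSeries]:
    """Seasonal daily rainfall and hourly temperature/dewpoint per farm.

    Rainfall: Bernoulli occurrence x gamma amounts, day-of-year intensity
    peaking in the rainy season, with lognormal year ("drought") and farm
    effects.  Temperature: annual + diurnal sinusoids plus noise;
    dewpoint is the temperature minus a seasonally varying depression,
    clamped at saturation (dewpoint <= temperature).
    """
    rng = scenario.streams()["weather"]
    y0, y1 = scenario.years[0] - 2, scenario.years[1]
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    years = dates.year.to_numpy()
    n_years = y1 - y0 + 1
    # intensity peaks in late January (southern-hemisphere rainy season)
    seasonal = np.clip(np.cos(2.0 * np.pi * (doy - 25) / 365.25), 0.0, None) ** 2
    p_wet = np.clip(0.08 + 0.45 * seasonal, 0.0, 1.0)

    year_fx = np.exp(scenario.wet_dry_amplitude * rng.standard_normal(n_years)
                     - 0.5 * scenario.wet_dry_amplitude ** 2)
    out = {}
    hours = pd.date_range(f"{y0}-01-01", f"{y1}-12-31 23:00", freq="h")
    h_doy = hours.dayofyear.to_numpy()
    h_hr = hours.hour.to_numpy()
    for farm in range(scenario.n_farms):
        farm_fx = np.exp(scenario.farm_precip_spread * rng.standard_normal()
                         - 0.5 * scenario.farm_precip_spread ** 2)
        lam = p_wet * year_fx[years - y0] * farm_fx
        wet = rng.random(len(dates)) < np.clip(lam, 0, 1)
        # expected annual total = mean occurrence * 365.25 * shape * scale
        gshape = 0.8
        gscale = scenario.annual_precip_mm / (p_wet.mean() * 365.25 * gshape)
        amounts = rng.gamma(shape=gshape, scale=gscale, size=len(dates))
        precip = np.where(wet, amounts, 0.0)
        daily = pd.DataFrame({"date": dates, "precip_mm": precip})

        t_air = (scenario.temp_mean_c
                 + scenario.temp_seasonal_amp_c * np.cos(2 * np.pi * (h_doy - 15) / 365.25)
                 + scenario.temp_diurnal_amp_c * np.cos(2 * np.pi * (h_hr - 14) / 24.0))
        if scenario.temp_noise_sd_c > 0:
            t_air = t_air + scenario.temp_noise_sd_c * rng.standard_normal(len(hours))
        dep = (scenario.dewpoint_depression_c
               + scenario.dewpoint_seasonal_amp_c * np.cos(2 * np.pi * (h_doy - 200) / 365.25))
        if scenario.dewpoint_noise_sd_c > 0:
            dep = dep + scenario.dewpoint_noise_sd_c * rng.standard_normal(len(hours))
        t_dew = np.minimum(t_air - dep, t_air)  # clamp at saturation
        hourly = pd.DataFrame({"timestamp": hours, "temp_c": t_air,
                               "dewpoint_c": t_dew})
        out[farm] = WeatherSeries(farm=farm, daily=daily, hourly=hourly)
    return out


def _sample_genetic_coefficients(ped: PedigreeTable, g8: np.ndarray,
                                 rng: np.random.Generator) -> np.ndarray:
    """Draw stacked coefficients with covariance A (x) G8 recursively:
    parent average + Mendelian deviation scaled by d_i = 0.5 - 0.25(F_s+F_d)."""
    _, d = _inbreeding_and_d(ped)
    chol = np.linalg.cholesky(g8 + 1e-10 * np.eye(8) * max(np.trace(g8), 1.0))
    z = rng.standard_normal((len(ped), 8))
    coef = np.zeros((len(ped), 8))
    s, dd = ped.sire, ped.dam
    for i in range(len(ped)):
        pa = np.zeros(8)
        if s[i] >= 0:
            pa += 0.5 * coef[s[i]]
        if dd[i] >= 0:
            pa += 0.5 * coef[dd[i]]
        coef[i] = pa + np.sqrt(d[i]) * (chol @ z[i])
    return coef


def simulate_phenotypes(pedigree_df: pd.DataFrame,
                        weather: dict[int, WeatherSeries],
                        scenario: SimScenario
                        ) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotypes under the bivariate maternal reaction-norm model.

    Returns (records, truth).  Records carry everything QC and the model
    need (ids, dates, classes, EC raw/scaled, BW/WW, weaning age); the
    truth ledger carries the per-animal coefficients, per-dam MPE and
    per-group CG effects plus the generative EC scale.
    """
    streams = scenario.streams()
    # input is generated parent-first, so index-based parents are direct
    idx = {a: i for i, a in enumerate(pedigree_df["animal"])}
    sire_idx = np.array([idx.get(s, -1) if pd.notna(s) else -1
                         for s in pedigree_df["sire"]], dtype=np.int64)
    dam_idx = np.array([idx.get(dm, -1) if pd.notna(dm) else -1
                        for dm in pedigree_df["dam"]], dtype=np.int64)
    ped = PedigreeTable(pedigree_df["animal"].to_numpy(object), sire_idx, dam_idx)

    rec = pedigree_df.copy()
    ec_def = ECDefinition.from_name(scenario.ec_definition)
    daily = {f: w.daily for f, w in weather.items()}
    hourly = {f: w.hourly for f, w in weather.items()}
    ec = compute_ec_table(rec.rename(columns={"animal": "animal"}),
                          daily, hourly, [ec_def])
    ec = ec.set_index("animal")["raw"]
    rec["ec_raw"] = rec["animal"].map(ec)
    scaled, ec_scale = scale_ec(rec["ec_raw"].to_numpy(), scenario.ec_definition)
    rec["ec_scaled"] = scaled

    # class codes
    rec["sex_birth_class"] = (
        (rec["sex"] == "M").astype(int) * 2 + (rec["birth_type"] == "twin").astype(int) + 1
    ).astype(str)
    rec["parity_class"] = np.minimum(rec["parity"].to_numpy(int), 7).astype(str)
    rec["veg_zone"] = rec["veg_zone"].astype(str)

    rec["season"] = [qc._MONTH_SEASON[m] for m in pd.to_datetime(rec["birth_date"]).dt.month]
    rec["cg_id"] = (rec["farm"].astype(str) + "_"
                    + pd.to_datetime(rec["birth_date"]).dt.year.astype(str)
                    + "_" + rec["season"])

    coef = _sample_genetic_coefficients(ped, scenario.true_g8, streams["genetic"])
    order = {a: i for i, a in enumerate(ped.ids)}
    ai = rec["animal"].map(order).to_numpy()
    di = np.array([order.get(dm, -1) if pd.notna(dm) else -1 for dm in rec["dam"]])

    rng_env = streams["mpe_cg"]
    dams = np.array(sorted(pd.unique(rec.loc[rec["dam"].notna(), "dam"])), dtype=object)
    lp = np.linalg.cholesky(scenario.true_pm + 1e-12 * np.eye(2))
    mpe = {dm: lp @ rng_env.standard_normal(2) for dm in dams}
    groups = np.array(sorted(pd.unique(rec["cg_id"])), dtype=object)
    lc = np.linalg.cholesky(scenario.true_cg + 1e-12 * np.eye(2))
    cg_fx = {g: lc @ rng_env.standard_normal(2) for g in groups}

    lr = np.linalg.cholesky(scenario.true_r + 1e-12 * np.eye(2))
    resid = (lr @ streams["residual"].standard_normal((2, len(rec)))).T

    fe = scenario.fixed_effect_values
    phi1 = rec["ec_scaled"].to_numpy()
    aw = streams["weaning"].uniform(*scenario.weaning_age_range, size=len(rec))

    vals = {}
    for t, trait in enumerate(("bw", "ww")):
        u0 = coef[ai, 0 + 2 * t]
        u1 = coef[ai, 1 + 2 * t]
        v = np.zeros(len(rec))
        has_dam = di >= 0
        v[has_dam] = (coef[di[has_dam], 4 + 2 * t]
                      + phi1[has_dam] * coef[di[has_dam], 5 + 2 * t])
        mpe_v = np.array([mpe[dm][t] if pd.notna(dm) else 0.0 for dm in rec["dam"]])
        cg_v = np.array([cg_fx[g][t] for g in rec["cg_id"]])
        y = (fe["mu"][trait]
             + rec["sex_birth_class"].map(fe["sex_birth_class"]).to_numpy(float)
             + rec["parity_class"].map(fe["parity_class"]).to_numpy(float)
             + rec["veg_zone"].map(fe["veg_zone"]).to_numpy(float)
             + fe["ec_slope"][trait] * phi1
             + u0 + u1 * phi1 + v + mpe_v + cg_v + resid[:, t])
        if trait == "ww":
            y = y + fe["weaning_age_slope"] * (aw - 220.0)
        vals[trait] = y

    rec["bw_kg"] = vals["bw"]
    rec["weaning_age_d"] = aw
    miss = streams["missing"].random(len(rec)) < scenario.missing_ww_rate
    rec["ww_kg"] = np.where(miss, np.nan, vals["ww"])
    rec.loc[miss, "weaning_age_d"] = np.nan
    rec["maternal_contribution_missing"] = di < 0

    truth = SimTruth(
        coefficients=pd.DataFrame(
            coef, columns=["u_bw0", "u_bw1", "u_ww0", "u_ww1",
                           "v_bw0", "v_bw1", "v_ww0", "v_ww1"]
        ).assign(animal=ped.ids)[["animal", "u_bw0", "u_bw1", "u_ww0", "u_ww1",
                                  "v_bw0", "v_bw1", "v_ww0", "v_ww1"]],
        mpe=pd.DataFrame({"dam": dams,
                          "bw": [mpe[dm][0] for dm in dams],
                          "ww": [mpe[dm][1] for dm in dams]}),
        cg_effects=pd.DataFrame({"cg_id": groups,
                                 "bw": [cg_fx[g][0] for g in groups],
                                 "ww": [cg_fx[g][1] for g in groups]}),
        ec_scale=ec_scale,
        scenario=scenario,
    )
    return rec, truth


def simulate_dataset(scenario: SimScenario):
    """Pedigree + weather + phenotypes in one call."""
    ped = simulate_pedigree(scenario)
    weather = simulate_weather(scenario)
    records, truth = simulate_phenotypes(ped, weather, scenario)
    return ped, weather, records, truth


def write_outputs(outdir, pedigree_df, weather, records, truth) -> None:
    """Delimited-text exports (missing values as empty fields)."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pedigree_df.to_csv(out / "pedigree.csv", index=False)
    cols = ["animal", "bw_kg", "ww_kg", "weaning_age_d", "ec_raw", "ec_scaled",
            "cg_id", "sex_birth_class", "parity_class", "veg_zone", "dam", "sire",
            "farm", "birth_date", "season"]
    records[cols].to_csv(out / "phenotypes.csv", index=False)
    pd.concat([w.daily.assign(farm=f) for f, w in weather.items()]
              ).to_csv(out / "weather_daily.csv", index=False)
    pd.concat([w.hourly.assign(farm=f) for f, w in weather.items()]
              ).to_csv(out / "weather_hourly.csv", index=False)
    truth.coefficients.to_csv(out / "truth_coefficients.csv", index=False)


def simulate_screen_records(n_records: int = 4000, b2: float = 0.05,
                            n_dams: int = 800, n_cg: int = 150,
                            var_dam: float = 3.0, var_cg: float = 4.0,
                            var_res: float = 16.0, ec_range=(0.0, 600.0),
                            trait: str = "bw", seed: int = 0) -> pd.DataFrame:
    """Records under the univariate screen's own generative model:
    fixed classes + a linear EC effect (slope ``b2`` per raw unit) plus
    random dam and contemporary-group intercepts and residual noise.
    Used for slope-recovery checks of the phenotypic screen."""
    rng = np.random.default_rng(seed)
    rec = pd.DataFrame({
        "animal": [f"S{i}" for i in range(n_records)],
        "dam": [f"D{i}" for i in rng.integers(n_dams, size=n_records)],
        "cg_id": [f"G{i}" for i in rng.integers(n_cg, size=n_records)],
        "sex_birth_class": rng.integers(1, 5, n_records).astype(str),
        "parity_class": rng.integers(1, 8, n_records).astype(str),
        "veg_zone": rng.integers(1, 5, n_records).astype(str),
        "weaning_age_d": rng.uniform(180, 260, n_records),
        "ec_raw": rng.uniform(*ec_range, n_records),
    })
    class_fx = {c: dict(zip(sorted(rec[c].unique()),
                            rng.normal(0, 1.5, rec[c].nunique())))
                for c in ("sex_birth_class", "parity_class", "veg_zone")}
    dam_fx = dict(zip([f"D{i}" for i in range(n_dams)],
                      rng.normal(0, np.sqrt(var_dam), n_dams)))
    cg_fx = dict(zip([f"G{i}" for i in range(n_cg)],
                     rng.normal(0, np.sqrt(var_cg), n_cg)))
    y = (40.0 + b2 * rec["ec_raw"]
         + sum(rec[c].map(class_fx[c]) for c in class_fx)
         + rec["dam"].map(dam_fx) + rec["cg_id"].map(cg_fx)
         + rng.normal(0, np.sqrt(var_res), n_records))
    if trait == "ww":
        y = y + 0.9 * (rec["weaning_age_d"] - 220.0) + 190.0
    rec[f"{trait}_kg"] = y
    other = "ww" if trait == "bw" else "bw"
    rec[f"{other}_kg"] = np.nan
    return rec


def build_g8(h2_direct: float, h2_maternal: float, ratio_direct: float,
             ratio_maternal: float, r01_direct: float, r01_maternal: float,
             r_traits_direct: float, r_traits_maternal: float, vp: float,
             prop_mpe: float, prop_cg: float):
    """Construct (G8, Pm, Cg, R) hitting target heritabilities at the
    gradient midpoint with given slope-to-intercept ratios.

    The direct-maternal cross block is zero, so at t=0 the phenotypic
    variance is vd0 + vm0 + mpe + cg + res = vp exactly.
    """
    vd0 = h2_direct * vp
    vm0 = h2_maternal * vp
    mpe = prop_mpe * vp
    cg = prop_cg * vp
    res = vp - vd0 - vm0 - mpe - cg
    if res <= 0:
        raise ValueError("variance proportions exceed the phenotypic variance")

    def block(v0, ratio, r01):
        v1 = ratio * v0
        c = r01 * np.sqrt(v0 * v1)
        return np.array([[v0, c], [c, v1]])

    g8 = np.zeros((8, 8))
    for k, (v0, ratio, r01) in enumerate(
            [(vd0, ratio_direct, r01_direct), (vd0, ratio_direct, r01_direct),
             (vm0, ratio_maternal, r01_maternal), (vm0, ratio_maternal, r01_maternal)]):
        sl = slice(2 * k, 2 * k + 2)
        g8[sl, sl] = block(v0, ratio, r01)
    # cross-trait within effect: scaled copies of the within-trait block
    g8[0:2, 2:4] = g8[2:4, 0:2] = r_traits_direct * block(vd0, ratio_direct, r01_direct)
    g8[4:6, 6:8] = g8[6:8, 4:6] = r_traits_maternal * block(vm0, ratio_maternal, r01_maternal)
    w = np.linalg.eigvalsh(g8)
    if w.min() < -1e-10:
        raise ValueError("constructed G8 not PSD; lower the cross-trait correlations")
    return g8, mpe * np.eye(2), cg * np.eye(2), res * np.eye(2) + 0.2 * res * (np.ones((2, 2)) - np.eye(2))


#: the ten parameter-recovery scenarios: direct h2 0.1-0.5, maternal
#: h2 0.05-0.2, slope-to-intercept ratios 0.1-2 (battery of study
#: conditions; n is set by the caller via n_founders/n_generations).
BATTERY = [
    dict(h2_direct=hd, h2_maternal=hm, ratio_direct=rd, ratio_maternal=rm)
    for hd, hm, rd, rm in [
        (0.10, 0.05, 0.10, 0.10), (0.15, 0.08, 0.30, 0.20),
        (0.20, 0.10, 0.50, 0.30), (0.25, 0.12, 0.80, 0.40),
        (0.30, 0.15, 1.00, 0.50), (0.35, 0.18, 1.25, 0.60),
        (0.40, 0.20, 1.50, 0.70), (0.45, 0.10, 1.75, 0.40),
        (0.50, 0.15, 2.00, 0.50), (0.30, 0.20, 0.60, 0.80),
    ]
]


def battery_scenario(index: int, n_founders: int, n_generations: int = 3,
                     n_farms: int = 8, seed_base: int = 77000) -> SimScenario:
    """The index-th parameter-recovery scenario at the requested scale."""
    p = BATTERY[index]
    g8, pm, cg, r = build_g8(
        p["h2_direct"], p["h2_maternal"], p["ratio_direct"], p["ratio_maternal"],
        r01_direct=0.2, r01_maternal=0.1, r_traits_direct=0.4,
        r_traits_maternal=0.3, vp=25.0, prop_mpe=0.08, prop_cg=0.10)
    return SimScenario(
        n_founders=n_founders, n_generations=n_generations, n_farms=n_farms,
        true_g8=g8, true_pm=pm, true_cg=cg, true_r=r,
        missing_ww_rate=0.10, seed=seed_base + index)
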