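import numpy as np
import pandas as pd
import pytest

from cattlernm import qc
from cattlernm.design import ModelSpec, build_design, start_values
from cattlernm.pedigree import validate_and_sort
from cattlernm.simulate import SimScenario, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated herd shared across tests (deterministic)."""
    scenario = SimScenario(n_founders=150, n_generations=2, n_farms=4,
                           years=(2000, 2012), seed=20240101 % (2**31))
    pedigree_df, weather, records, truth = simulate_dataset(scenario)
    return {"scenario": scenario, "pedigree_df": pedigree_df,
            "weather": weather, "records": records, "truth": truth}


@pytest.fixture(scope="session")
def small_qc(small_dataset):
    records_qc, report = qc.run_qc(small_dataset["records"])
    return records_qc, report


@pytest.fixture(scope="session")
def small_problem(small_dataset, small_qc):
    """Assembled bivariate RNM problem for the small herd."""
    records_qc, _ = small_qc
    ped = validate_and_sort(
        small_dataset["pedigree_df"][["animal", "sire", "dam", "birth_date"]])
    problem, info = build_design(records_qc, ped,
                                 ModelSpec(ec_name="sumPrec365"),
                                 ec_scale=small_dataset["truth"].ec_scale)
    start = start_values(records_qc).as_engine_dict()
    return {"problem": problem, "info": info, "start": start, "ped": ped,
            "records_qc": records_qc}


def toy_records(n=40, seed=0, with_dam=True):
    """Minimal record table accepted by the screen/design builders."""
    rng = np.random.default_rng(seed)
    rec = pd.DataFrame({
        "animal": [f"X{i}" for i in range(n)],
        "dam": [f"D{i % 8}" if with_dam else None for i in range(n)],
        "cg_id": [f"g{i % 4}" for i in range(n)],
        "sex_birth_class": [str(1 + i % 2) for i in range(n)],
        "parity_class": [str(1 + i % 3) for i in range(n)],
        "veg_zone": [str(1 + (i // 3) % 2) for i in range(n)],
        "weaning_age_d": rng.uniform(180, 260, n),
        "farm": [i % 2 for i in range(n)],
        "ec_raw": rng.uniform(0, 400, n),
    })
    rec["ec_scaled"] = 2 * (rec.ec_raw - rec.ec_raw.min()) / np.ptp(rec.ec_raw) - 1
    rec["bw_kg"] = rng.normal(38, 5, n)
    rec["ww_kg"] = rng.normal(230, 20, n)
    return rec
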