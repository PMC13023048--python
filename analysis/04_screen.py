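"""Phenotypic screen: linear mixed-model regressions of BW and WW on
each raw EC (fixed classes, random dam and contemporary group).

The coefficient is kg per mm of cumulative precipitation or kg per THI
unit; a positive precipitation slope and a negative THI slope indicate
drought and heat-stress penalties on growth.
"""

import sys
from importlib import import_module
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfg = import_module("00_config")

from cattlernm.screen import fit_phenotypic_screen  # noqa: E402


def main():
    records = pd.read_csv(cfg.RESULTS / "records_qc.csv",
                          parse_dates=["birth_date"])
    ec = pd.read_csv(cfg.RESULTS / "ec_values.csv").set_index("animal")
    rows = []
    for ec_name in cfg.EC_NAMES:
        rec = records.copy()
        rec["ec_raw"] = rec["animal"].map(ec[ec_name])
        for trait in ("bw", "ww"):
            res = fit_phenotypic_screen(rec, ec_name, trait)
            rows.append({"ec_name": ec_name, "trait": trait,
                         "estimate_kg_per_unit": res.estimate, "se": res.se,
                         "p_value": res.p_value, "n": res.n_records,
                         "var_dam": res.components["dam"],
                         "var_cg": res.components["cg"],
                         "var_residual": res.components["residual"]})
            print(f"{ec_name:>11} {trait}: b = {res.estimate:+.4f} "
                  f"(se {res.se:.4f}), p = {res.p_value:.2e}, n = {res.n_records}")
    pd.DataFrame(rows).to_csv(cfg.RESULTS / "screen_regressions.csv", index=False)


if __name__ == "__main__":
    main()
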