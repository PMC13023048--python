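"""Fit the bivariate maternal reaction-norm animal model, one fit per EC.

Variance components by accelerated EM-REML on the sparse mixed-model
equations.  Writes, per EC: the 8x8 genetic matrix (direct+maternal x
intercept/slope x BW/WW), the 2x2 MPE/CG/residual matrices, the REML
trace, the EC scaling bounds, and the per-animal BLUP coefficients.
"""

import sys
import time
from importlib import import_module
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfg = import_module("00_config")

from cattlernm.design import (RNM_SCALE_GROUPS, ModelSpec, VarianceComponents,
                              build_design, start_values)  # noqa: E402
from cattlernm.enviro import scale_ec  # noqa: E402
from cattlernm.pedigree import validate_and_sort  # noqa: E402
from cattlernm.reml import EMControls, em_reml_fit  # noqa: E402


def main():
    records = pd.read_csv(cfg.RESULTS / "records_qc.csv",
                          parse_dates=["birth_date"])
    ec = pd.read_csv(cfg.RESULTS / "ec_values.csv").set_index("animal")
    pedf = pd.read_csv(cfg.DATA / "pedigree.csv", parse_dates=["birth_date"])
    ped = validate_and_sort(pedf[["animal", "sire", "dam", "birth_date"]])
    controls = EMControls(max_iter=60, tol=1e-3, loglik_tol=1e-6,
                          backend="sparse", scale_search=RNM_SCALE_GROUPS)
    scales = []
    for ec_name in cfg.EC_NAMES:
        rec = records.copy()
        rec["ec_raw"] = rec["animal"].map(ec[ec_name])
        rec["ec_scaled"], scale = scale_ec(rec["ec_raw"].to_numpy(), ec_name)
        problem, info = build_design(rec, ped, ModelSpec(ec_name=ec_name),
                                     ec_scale=scale)
        t0 = time.time()
        fit = em_reml_fit(problem, start_values(rec).as_engine_dict(), controls)
        vc = VarianceComponents.from_engine_dict(fit.components)
        print(f"{ec_name}: {fit.n_iter} EM iterations, "
              f"{'converged' if fit.converged else 'iteration cap reached'}, "
              f"logL = {fit.loglik:.1f}, {time.time() - t0:.0f}s; "
              f"{info.unknown_dam_records} records without known dam")
        np.savetxt(cfg.RESULTS / f"components_g8_{ec_name}.csv", vc.g8,
                   delimiter=",")
        small = pd.DataFrame({
            "block": ["pm"] * 2 + ["cg"] * 2 + ["residual"] * 2,
            "row": ["bw", "ww"] * 3,
            "bw": np.concatenate([vc.pm[:, 0], vc.cg[:, 0], vc.residual[:, 0]]),
            "ww": np.concatenate([vc.pm[:, 1], vc.cg[:, 1], vc.residual[:, 1]]),
        })
        small.to_csv(cfg.RESULTS / f"components_small_{ec_name}.csv", index=False)
        fit.trace[["iteration", "loglik", "max_rel_change"]].to_csv(
            cfg.RESULTS / f"reml_trace_{ec_name}.csv", index=False)
        coefs = fit.term_solutions["genetic"]
        pd.DataFrame(coefs, columns=["u_bw0", "u_bw1", "u_ww0", "u_ww1",
                                     "v_bw0", "v_bw1", "v_ww0", "v_ww1"]) \
            .assign(animal=info.animal_ids) \
            .to_csv(cfg.RESULTS / f"blup_coefficients_{ec_name}.csv", index=False)
        scales.append({"ec_name": ec_name, "minimum": scale.minimum,
                       "maximum": scale.maximum})
    pd.DataFrame(scales).to_csv(cfg.RESULTS / "ec_scales.csv", index=False)


if __name__ == "__main__":
    main()
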