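"""Gradient-wise genetic parameters from the fitted components.

Per EC: direct/maternal heritabilities along the gradient, genetic
correlations between gradients (the GxE evidence), BW-WW genetic
correlations, and the intercept-slope statistics (r_mu0mu1 and the
slope-to-intercept variance ratio).
"""

import sys
from importlib import import_module
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfg = import_module("00_config")

from cattlernm.design import VarianceComponents  # noqa: E402
from cattlernm.enviro import ECScale  # noqa: E402
from cattlernm.params import (GradientGrid, gradient_parameter_table,
                              intercept_slope_table, rec_matrix)  # noqa: E402


def main():
    scales = pd.read_csv(cfg.RESULTS / "ec_scales.csv").set_index("ec_name")
    param_tables, isl_tables = [], []
    for ec_name in cfg.EC_NAMES:
        g8 = np.loadtxt(cfg.RESULTS / f"components_g8_{ec_name}.csv",
                        delimiter=",")
        small = pd.read_csv(cfg.RESULTS / f"components_small_{ec_name}.csv")
        blocks = {b: g.set_index("row")[["bw", "ww"]].to_numpy()
                  for b, g in small.groupby("block")}
        vc = VarianceComponents(g8=g8, pm=blocks["pm"], cg=blocks["cg"],
                                residual=blocks["residual"])
        scale = ECScale(ec_name, scales.loc[ec_name, "minimum"],
                        scales.loc[ec_name, "maximum"])
        grid = GradientGrid.default(ec_name, scale)
        param_tables.append(gradient_parameter_table(vc, grid))
        isl_tables.append(intercept_slope_table(vc, ec_name))
        for trait in ("bw", "ww"):
            rec_matrix(vc.direct_block(trait), grid).to_csv(
                cfg.RESULTS / f"rec_direct_{trait}_{ec_name}.csv")
            rec_matrix(vc.maternal_block(trait), grid).to_csv(
                cfg.RESULTS / f"rec_maternal_{trait}_{ec_name}.csv")
        t = param_tables[-1]
        for trait in ("bw", "ww"):
            sub = t[t.trait == trait]
            print(f"{ec_name:>11} {trait}: h2_direct "
                  f"{sub.h2_direct.min():.2f}-{sub.h2_direct.max():.2f}, "
                  f"h2_maternal {sub.h2_maternal.min():.2f}-{sub.h2_maternal.max():.2f}")
    params = pd.concat(param_tables, ignore_index=True)
    params.to_csv(cfg.RESULTS / "gradient_parameters.csv", index=False)
    isl = pd.concat(isl_tables, ignore_index=True)
    isl.to_csv(cfg.RESULTS / "intercept_slope.csv", index=False)
    print("\nintercept-slope statistics (direct effects):")
    print(isl[isl.effect == "direct"]
          .pivot(index="ec_name", columns="trait",
                 values=["r_mu0_mu1", "slope_to_intercept_ratio"])
          .round(2).to_string())


if __name__ == "__main__":
    main()
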