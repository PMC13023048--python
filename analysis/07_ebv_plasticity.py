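"""Gradient-specific breeding values, plasticity classes and sire
re-ranking for the elite sires.

EBV(t) = mu0 + mu1 t from the direct BLUP coefficients; plasticity
classes use the population SD of the slope solutions; re-ranking is
summarised by Spearman correlations between the gradient extremes.
"""

import sys
from importlib import import_module
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfg = import_module("00_config")

from cattlernm.ebv import (ebv_trajectories, rerank_analysis,
                           select_elite_sires)  # noqa: E402


def main():
    records = pd.read_csv(cfg.RESULTS / "records_qc.csv")
    frames, rerank_rows, class_rows = [], [], []
    for ec_name in cfg.EC_NAMES:
        blup = pd.read_csv(cfg.RESULTS / f"blup_coefficients_{ec_name}.csv")
        elite, counts = select_elite_sires(records, min_progeny=20)
        for trait, (c0, c1) in (("bw", ("u_bw0", "u_bw1")),
                                ("ww", ("u_ww0", "u_ww1"))):
            coefs = blup.rename(columns={c0: "mu0", c1: "mu1"})[
                ["animal", "mu0", "mu1"]]
            traj = ebv_trajectories(coefs, trait)
            traj.insert(0, "ec_name", ec_name)
            frames.append(traj)
            elite_traj = traj[traj["animal"].isin(elite)]
            fracs = (elite_traj["plasticity_class"]
                     .value_counts(normalize=True))
            class_rows.append({"ec_name": ec_name, "trait": trait,
                               "n_elite": len(elite_traj),
                               **{c: float(fracs.get(c, 0.0)) for c in
                                  ("robust", "plastic", "extremely_plastic")}})
            if len(elite_traj) >= 3:
                rr = rerank_analysis(elite_traj)
                rho = rr["spearman"][(-1.0, 1.0)]
                rerank_rows.append({"ec_name": ec_name, "trait": trait,
                                    "spearman_lo_hi": rho,
                                    "top10_overlap": rr["top_overlap"][(-1.0, 1.0)]})
                print(f"{ec_name:>11} {trait}: {len(elite_traj)} elite sires, "
                      f"rank corr(-1,+1) = {rho:.2f}, "
                      f"robust/plastic/extreme = "
                      f"{class_rows[-1]['robust']:.0%}/"
                      f"{class_rows[-1]['plastic']:.0%}/"
                      f"{class_rows[-1]['extremely_plastic']:.0%}")
    pd.concat(frames, ignore_index=True).to_csv(
        cfg.RESULTS / "ebv_trajectories.csv", index=False)
    pd.DataFrame(rerank_rows).to_csv(cfg.RESULTS / "sire_reranking.csv",
                                     index=False)
    pd.DataFrame(class_rows).to_csv(cfg.RESULTS / "plasticity_classes.csv",
                                    index=False)


if __name__ == "__main__":
    main()
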