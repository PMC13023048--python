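"""Gradient-specific breeding values, plasticity classes and re-ranking.

Each animal's direct genetic merit along the environmental gradient is
the affine trajectory EBV(t) = mu0 + mu1 * t with t the scaled EC.  The
slope magnitude relative to the population SD of all slopes classifies
animals as robust (|mu1| < sd), plastic (sd <= |mu1| < 2 sd) or
extremely plastic (|mu1| >= 2 sd).  Elite sires (>= 20 recorded progeny
by default) are ranked at chosen gradients to quantify re-ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PLASTICITY_CLASSES = ("robust", "plastic", "extremely_plastic")


def ebv_at_gradient(mu0, mu1, t):
    """EBV(t) = mu0 + mu1 * t (vectorised)."""
    return np.asarray(mu0, dtype=float) + np.asarray(mu1, dtype=float) * t


def classify_plasticity(mu1, sigma_mu1: float | None = None) -> np.ndarray:
    """Three-way slope classification with left-closed boundaries at
    sigma and 2 sigma; sigma defaults to the SD of the supplied slopes."""
    mu1 = np.asarray(mu1, dtype=float)
    if sigma_mu1 is None:
        sigma_mu1 = float(np.std(mu1, ddof=1))
    if not sigma_mu1 > 0:
        raise ValueError("sigma_mu1 must be positive (degenerate slope SD)")
    a = np.abs(mu1)
    out = np.where(a >= 2.0 * sigma_mu1, "extremely_plastic",
                   np.where(a >= sigma_mu1, "plastic", "robust"))
    return out


def select_elite_sires(records: pd.DataFrame, min_progeny: int = 20,
                       top_n: int = 20) -> tuple[np.ndarray, pd.DataFrame]:
    """Sires with at least ``min_progeny`` QC-retained progeny records.

    Returns (elite sire ids, progeny-count table sorted descending; the
    head of the table is the top-``top_n`` most-used sires).
    """
    counts = (records.loc[records["sire"].notna(), "sire"]
              .value_counts().rename_axis("sire").reset_index(name="n_progeny"))
    counts = counts.sort_values(["n_progeny", "sire"],
                                ascending=[False, True]).reset_index(drop=True)
    elite = counts.loc[counts["n_progeny"] >= min_progeny, "sire"].to_numpy()
    return elite, counts.head(top_n)


def ebv_trajectories(coefficients: pd.DataFrame, trait: str,
                     gradients=(-1.0, 0.0, 1.0),
                     sigma_mu1: float | None = None) -> pd.DataFrame:
    """EBV table from per-animal (mu0, mu1) BLUP solutions.

    ``coefficients`` needs columns animal, mu0, mu1 (one trait at a time).
    sigma for the plasticity classes defaults to the SD of mu1 over all
    supplied animals (i.e. pass all pedigree animals, subset afterwards).
    """
    out = coefficients[["animal"]].copy()
    out["trait"] = trait
    out["mu0"] = coefficients["mu0"].to_numpy(dtype=float)
    out["mu1"] = coefficients["mu1"].to_numpy(dtype=float)
    for t in gradients:
        out[f"ebv_at_{t:+.2f}"] = ebv_at_gradient(out["mu0"], out["mu1"], t)
    out["plasticity_class"] = classify_plasticity(out["mu1"], sigma_mu1)
    return out


def rerank_analysis(trajectories: pd.DataFrame,
                    gradients=(-1.0, 0.0, 1.0), top_k: int = 10) -> dict:
    """Rank correlations and top-k overlap of EBVs across gradients.

    Ranks are dense descending (best = 1); ties break by animal id.
    Requires at least 3 animals.
    """
    if len(trajectories) < 3:
        raise ValueError("re-ranking needs at least 3 animals")
    tr = trajectories.sort_values("animal").reset_index(drop=True)
    ranks = {}
    for t in gradients:
        ebv = ebv_at_gradient(tr["mu0"], tr["mu1"], t)
        order = np.lexsort((tr["animal"].to_numpy(), -ebv))
        rk = np.empty(len(tr), dtype=int)
        rk[order] = np.arange(1, len(tr) + 1)
        ranks[t] = rk
    rank_table = pd.DataFrame({"animal": tr["animal"], **{
        f"rank_at_{t:+.2f}": ranks[t] for t in gradients}})
    rhos = {}
    overlaps = {}
    k = min(top_k, len(tr))
    for i, a in enumerate(gradients):
        for b in gradients[i + 1:]:
            rho = stats.spearmanr(ranks[a], ranks[b]).statistic
            rhos[(a, b)] = float(rho)
            top_a = set(tr["animal"][ranks[a] <= k])
            top_b = set(tr["animal"][ranks[b] <= k])
            overlaps[(a, b)] = len(top_a & top_b) / k
    return {"ranks": rank_table, "spearman": rhos, "top_overlap": overlaps}
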