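"""Univariate phenotypic screen of EC effects on BW or WW.

A linear mixed model per trait and EC: fixed sex x birth-type, parity
class, vegetation zone, weaning-age covariate (WW only) and a linear
regression on the *raw* EC (so the coefficient is per mm of cumulative
precipitation or per THI unit); random intercepts for dam (no pedigree)
and contemporary group.  Variance components by the same EM-REML engine;
the EC effect is reported with its Wald z test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .reml import EMControls, MMEProblem, RandomTerm, em_reml_fit


@dataclass
class ScreenResult:
    trait: str
    ec_name: str
    estimate: float      # EC regression coefficient, kg per raw EC unit
    se: float
    z_value: float
    p_value: float
    components: dict     # dam, cg, residual variances (kg^2)
    n_records: int
    fixed_table: pd.DataFrame
    converged: bool


def fit_phenotypic_screen(records: pd.DataFrame, ec_name: str, trait: str,
                          controls: EMControls | None = None) -> ScreenResult:
    """Fit the screen for one trait x EC combination.

    ``records`` needs <trait>_kg, ec_raw, dam, cg_id, sex_birth_class,
    parity_class, veg_zone (and weaning_age_d for WW).  Records missing
    the trait are dropped here; dams stay as plain (non-pedigree) random
    intercepts.
    """
    controls = controls or EMControls(tol=1e-5, loglik_tol=1e-7, max_iter=300)
    rec = records[records[f"{trait}_kg"].notna()].reset_index(drop=True)
    n = len(rec)
    y = rec[f"{trait}_kg"].to_numpy(dtype=float)[:, None]

    cols = [np.ones(n)]
    names = ["intercept"]
    for cls in ("sex_birth_class", "parity_class", "veg_zone"):
        values = rec[cls].astype(str).to_numpy()
        for lev in sorted(pd.unique(values))[1:]:
            cols.append((values == lev).astype(float))
            names.append(f"{cls}={lev}")
    if trait == "ww":
        aw = rec["weaning_age_d"].to_numpy(dtype=float)
        cols.append(aw - np.nanmean(aw))
        names.append("weaning_age_centered")
    ec = rec["ec_raw"].to_numpy(dtype=float)
    cols.append(ec - ec.mean())
    names.append("ec")
    x = sparse.csr_matrix(np.column_stack(cols))

    terms = []
    dam_known = rec["dam"].notna().to_numpy()
    dams = np.array(sorted(pd.unique(rec.loc[dam_known, "dam"])), dtype=object)
    dmap = {d: i for i, d in enumerate(dams)}
    kn = np.where(dam_known)[0]
    zd = sparse.csr_matrix(
        (np.ones(len(kn)), (kn, [dmap[d] for d in rec.loc[kn, "dam"]])),
        shape=(n, len(dams)))
    terms.append(RandomTerm("dam", 1, len(dams), [zd]))

    cgs = np.array(sorted(pd.unique(rec["cg_id"])), dtype=object)
    gmap = {g: i for i, g in enumerate(cgs)}
    zg = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), [gmap[g] for g in rec["cg_id"]])),
        shape=(n, len(cgs)))
    terms.append(RandomTerm("cg", 1, len(cgs), [zg]))

    problem = MMEProblem(y, [x], terms)
    vp = float(np.var(y, ddof=1))
    start = {"dam": np.array([[0.15 * vp]]), "cg": np.array([[0.15 * vp]]),
             "residual": np.array([[0.70 * vp]])}
    fit = em_reml_fit(problem, start, controls)

    k = names.index("ec")
    est, se = float(fit.fixed_effects[k]), float(fit.fixed_se[k])
    z = est / se if se > 0 else np.nan
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    table = pd.DataFrame({"term": names, "estimate": fit.fixed_effects,
                          "se": fit.fixed_se})
    comps = {k2: float(v[0, 0]) for k2, v in fit.components.items()}
    return ScreenResult(trait=trait, ec_name=ec_name, estimate=est, se=se,
                        z_value=z, p_value=p, components=comps, n_records=n,
                        fixed_table=table, converged=fit.converged)
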