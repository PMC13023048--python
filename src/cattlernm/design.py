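"""Design structure of the bivariate reaction-norm animal model.

Two traits — birth weight (BW) and weaning weight (WW) — are modelled
jointly.  Each trait's equation carries fixed effects (sex x birth-type
class, parity class, vegetation zone, weaning-age covariate for WW only,
and a fixed regression on the scaled EC), random contemporary-group and
maternal-permanent-environment effects (2x2 covariance across traits),
and direct plus maternal additive-genetic random regressions (intercept
and slope on the scaled EC) tied to the pedigree.  The stacked
direct+maternal coefficient vector per animal is

    [u_bw0, u_bw1, u_ww0, u_ww1, v_bw0, v_bw1, v_ww0, v_ww1]

with prior covariance A (x) G8, so the 8x8 G8 holds the direct 4x4, the
maternal 4x4 and the direct-maternal cross block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .pedigree import PedigreeTable, build_a_inverse
from .reml import MMEProblem, RandomTerm

TRAITS = ("bw", "ww")

#: coordinate groups for the fitter's likelihood scale searches: all
#: genetic slope coordinates, the maternal block, and the MPE/CG blocks
#: (the directions EM moves slowest along in this model)
RNM_SCALE_GROUPS = (("genetic", (1, 3, 5, 7)), ("genetic", (4, 5, 6, 7)),
                    ("mpe", (0, 1)), ("cg", (0, 1)))

# coefficient layout inside the 8-vector
DIRECT_IDX = {"bw": (0, 1), "ww": (2, 3)}
MATERNAL_IDX = {"bw": (4, 5), "ww": (6, 7)}


@dataclass(frozen=True)
class ModelSpec:
    """What enters each trait's equation; one EC per fitted model."""

    ec_name: str
    fixed_classes: tuple = ("sex_birth_class", "parity_class", "veg_zone")
    weaning_age_covariate: bool = True  # WW equation only
    fit_maternal: bool = True


@dataclass
class VarianceComponents:
    """All (co)variance matrices of the bivariate reaction-norm model."""

    g8: np.ndarray        # 8x8 genetic (direct+maternal x intercept/slope x trait)
    pm: np.ndarray        # 2x2 maternal permanent environment across traits
    cg: np.ndarray        # 2x2 contemporary group across traits
    residual: np.ndarray  # 2x2 residual across traits

    def __post_init__(self) -> None:
        for name in ("g8", "pm", "cg", "residual"):
            m = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, 0.5 * (m + m.T))
            w = np.linalg.eigvalsh(getattr(self, name))
            if w.min() < -1e-8 * max(w.max(), 1.0):
                raise ValueError(f"{name} is not positive semi-definite")

    def direct_block(self, trait: str) -> np.ndarray:
        i = DIRECT_IDX[trait]
        return self.g8[np.ix_(i, i)]

    def maternal_block(self, trait: str) -> np.ndarray:
        i = MATERNAL_IDX[trait]
        return self.g8[np.ix_(i, i)]

    def direct_maternal_block(self, trait: str) -> np.ndarray:
        """2x2 cross-covariance of (intercept, slope) direct vs maternal."""
        return self.g8[np.ix_(DIRECT_IDX[trait], MATERNAL_IDX[trait])]

    def direct_cross_trait(self) -> np.ndarray:
        return self.g8[np.ix_(DIRECT_IDX["bw"], DIRECT_IDX["ww"])]

    def maternal_cross_trait(self) -> np.ndarray:
        return self.g8[np.ix_(MATERNAL_IDX["bw"], MATERNAL_IDX["ww"])]

    def as_engine_dict(self) -> dict:
        return {"genetic": self.g8, "mpe": self.pm, "cg": self.cg,
                "residual": self.residual}

    @classmethod
    def from_engine_dict(cls, d: dict) -> "VarianceComponents":
        return cls(g8=d["genetic"], pm=d["mpe"], cg=d["cg"], residual=d["residual"])


@dataclass
class DesignInfo:
    """Bookkeeping produced alongside the MME problem."""

    fixed_names: list
    animal_ids: np.ndarray       # pedigree order = genetic levels
    dam_levels: np.ndarray       # mpe levels
    cg_levels: np.ndarray
    record_animals: np.ndarray
    unknown_dam_records: int
    ec_scale: object = None
    logdet_a: float = 0.0


def _fixed_design(records: pd.DataFrame, spec: ModelSpec) -> tuple[list, list]:
    """Per-trait fixed design blocks in one global column space.

    Reference levels are dropped per trait among the records observed for
    that trait; a class level absent from a trait's observed records
    yields no column for that trait (keeps X full rank).
    """
    n = len(records)
    cols_by_trait = []
    names = []
    blocks = []
    for trait in TRAITS:
        obs = records[f"{trait}_kg"].notna().to_numpy()
        cols = [np.ones(n)]
        tnames = [f"{trait}:intercept"]
        for cls in spec.fixed_classes:
            values = records[cls].astype(str).to_numpy()
            levels = sorted(pd.unique(values[obs]))
            for lev in levels[1:]:
                cols.append((values == lev).astype(float))
                tnames.append(f"{trait}:{cls}={lev}")
        if trait == "ww" and spec.weaning_age_covariate:
            aw = records["weaning_age_d"].to_numpy(dtype=float)
            center = np.nanmean(aw[obs])
            aw = np.where(np.isnan(aw), 0.0, aw - center)
            cols.append(aw)
            tnames.append("ww:weaning_age_centered")
        cols.append(records["ec_scaled"].to_numpy(dtype=float))
        tnames.append(f"{trait}:ec_slope")
        blocks.append(np.column_stack(cols))
        names.extend(tnames)
        cols_by_trait.append(len(tnames))

    p = sum(cols_by_trait)
    x_by_trait = []
    off = 0
    for block, width in zip(blocks, cols_by_trait):
        x = sparse.lil_matrix((n, p))
        x[:, off:off + width] = block
        x_by_trait.append(x.tocsr())
        off += width
    return x_by_trait, names


def build_design(records: pd.DataFrame, ped: PedigreeTable, spec: ModelSpec,
                 ec_scale=None) -> tuple[MMEProblem, DesignInfo]:
    """Assemble the bivariate RNM as an :class:`MMEProblem`.

    ``records`` must be QC-complete with columns animal, dam, cg_id,
    sex_birth_class, parity_class, veg_zone, weaning_age_d, bw_kg, ww_kg
    and ec_scaled (the [-1, 1] covariate of the chosen EC).  Genetic
    coefficients span *all* pedigree animals; records whose dam is
    unknown get a zero maternal row (and no MPE term) and are counted.
    """
    rec = records.reset_index(drop=True)
    n = len(rec)
    y = rec[["bw_kg", "ww_kg"]].to_numpy(dtype=float)
    phi = np.column_stack([np.ones(n), rec["ec_scaled"].to_numpy(dtype=float)])

    x_by_trait, fixed_names = _fixed_design(rec, spec)

    animal_idx = np.array([ped.index[a] for a in rec["animal"]], dtype=np.int64)
    dam_known = rec["dam"].notna().to_numpy() & rec["dam"].isin(ped.index).to_numpy()
    dam_idx = np.array([ped.index[d] if k else -1
                        for d, k in zip(rec["dam"], dam_known)], dtype=np.int64)
    q = len(ped)

    z_by_trait = []
    for trait in TRAITS:
        di = DIRECT_IDX[trait]
        mi = MATERNAL_IDX[trait]
        rows, cols, vals = [], [], []
        for c, scale in zip(di, (np.ones(n), phi[:, 1])):
            rows.append(np.arange(n))
            cols.append(animal_idx * 8 + c)
            vals.append(scale)
        if spec.fit_maternal:
            kn = np.where(dam_idx >= 0)[0]
            for c, scale in zip(mi, (np.ones(n)[kn], phi[kn, 1])):
                rows.append(kn)
                cols.append(dam_idx[kn] * 8 + c)
                vals.append(scale)
        z = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, 8 * q))
        z_by_trait.append(z)

    dam_levels = np.array(sorted(pd.unique(rec.loc[dam_known, "dam"])), dtype=object)
    dam_level_map = {d: k for k, d in enumerate(dam_levels)}
    m_levels = len(dam_levels)
    r_by_trait = []
    for t, trait in enumerate(TRAITS):
        kn = np.where(dam_known)[0]
        cols = np.array([dam_level_map[d] for d in rec.loc[kn, "dam"]], dtype=np.int64)
        z = sparse.csr_matrix((np.ones(len(kn)), (kn, cols * 2 + t)),
                              shape=(n, 2 * m_levels))
        r_by_trait.append(z)

    cg_levels = np.array(sorted(pd.unique(rec["cg_id"])), dtype=object)
    cg_map = {g: k for k, g in enumerate(cg_levels)}
    cg_idx = np.array([cg_map[g] for g in rec["cg_id"]], dtype=np.int64)
    q_by_trait = [
        sparse.csr_matrix((np.ones(n), (np.arange(n), cg_idx * 2 + t)),
                          shape=(n, 2 * len(cg_levels)))
        for t in range(2)
    ]

    a_inv, _, logdet_a = build_a_inverse(ped)

    terms = [
        RandomTerm("cg", 2, len(cg_levels), q_by_trait),
        RandomTerm("mpe", 2, m_levels, r_by_trait),
        RandomTerm("genetic", 8, q, z_by_trait, k_inverse=a_inv, logdet_k=logdet_a),
    ]
    problem = MMEProblem(y, x_by_trait, terms)
    info = DesignInfo(fixed_names=fixed_names, animal_ids=ped.ids,
                      dam_levels=dam_levels, cg_levels=cg_levels,
                      record_animals=rec["animal"].to_numpy(),
                      unknown_dam_records=int((~dam_known).sum()),
                      ec_scale=ec_scale, logdet_a=logdet_a)
    return problem, info


def start_values(records: pd.DataFrame,
                 spec: ModelSpec | None = None) -> VarianceComponents:
    """Deterministic, scale-aware EM starting point.

    The phenotypic variance of each trait is taken *after* adjusting for
    the fixed effects (ordinary least squares on the trait's fixed
    design), then split 10% per genetic intercept term, 5% per genetic
    slope term, 10% each to MPE and CG, and the remaining 50% to the
    residual; all covariances start at zero.  Adjusting first matters
    for WW, whose raw variance is dominated by the weaning-age covariate.
    """
    spec = spec or ModelSpec(ec_name="sumPrec365")
    x_by_trait, _ = _fixed_design(records.reset_index(drop=True), spec)
    vp = []
    for t, trait in enumerate(TRAITS):
        y = records[f"{trait}_kg"].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        x = np.asarray(x_by_trait[t][obs].todense())
        x = x[:, np.abs(x).sum(axis=0) > 0]
        resid = y[obs] - x @ np.linalg.lstsq(x, y[obs], rcond=None)[0]
        vp.append(np.var(resid, ddof=x.shape[1]))
    vp = np.asarray(vp)
    g8 = np.zeros((8, 8))
    for t, trait in enumerate(TRAITS):
        for idx_map in (DIRECT_IDX, MATERNAL_IDX):
            i0, i1 = idx_map[trait]
            g8[i0, i0] = 0.10 * vp[t]
            g8[i1, i1] = 0.05 * vp[t]
    return VarianceComponents(g8=g8, pm=np.diag(0.10 * vp), cg=np.diag(0.10 * vp),
                              residual=np.diag(0.50 * vp))
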