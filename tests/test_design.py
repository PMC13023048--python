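"""Design-matrix assembly for the bivariate reaction-norm model."""

import numpy as np
import pandas as pd
import pytest

from cattlernm.design import (DIRECT_IDX, MATERNAL_IDX, ModelSpec,
                              VarianceComponents, build_design, start_values)
from cattlernm.pedigree import validate_and_sort

from conftest import toy_records


def toy_design(n=24, with_dam=True):
    rec = toy_records(n=n, with_dam=with_dam)
    animals = pd.DataFrame({
        "animal": rec["animal"], "sire": None,
        "dam": rec["dam"] if with_dam else None})
    dams = pd.DataFrame({"animal": rec["dam"].dropna().unique()
                         if with_dam else [], "sire": None, "dam": None})
    ped = validate_and_sort(pd.concat([dams, animals], ignore_index=True))
    problem, info = build_design(rec, ped, ModelSpec(ec_name="sumPrec365"))
    return rec, ped, problem, info


class TestVarianceComponents:
    def test_psd_validated(self):
        with pytest.raises(ValueError):
            VarianceComponents(g8=-np.eye(8), pm=np.eye(2), cg=np.eye(2),
                               residual=np.eye(2))

    def test_block_extraction(self):
        g8 = np.arange(64, dtype=float).reshape(8, 8)
        g8 = g8 + g8.T  # symmetric
        vc = VarianceComponents(g8=g8 + 200 * np.eye(8), pm=np.eye(2),
                                cg=np.eye(2), residual=np.eye(2))
        i = DIRECT_IDX["ww"]
        assert np.allclose(vc.direct_block("ww"),
                           vc.g8[np.ix_(i, i)])
        j = MATERNAL_IDX["bw"]
        assert np.allclose(vc.maternal_block("bw"), vc.g8[np.ix_(j, j)])
        rt = VarianceComponents.from_engine_dict(vc.as_engine_dict())
        assert np.allclose(rt.g8, vc.g8)


class TestBuildDesign:
    def test_z_row_is_one_and_scaled_ec(self):
        rec, ped, problem, info = toy_design()
        genetic = problem.terms[-1]
        assert genetic.label == "genetic"
        row = genetic.z_by_trait[0][5].toarray().ravel()
        a_idx = ped.index[rec.loc[5, "animal"]]
        assert row[a_idx * 8 + 0] == 1.0
        assert row[a_idx * 8 + 1] == pytest.approx(rec.loc[5, "ec_scaled"])
        # maternal entries on the dam's columns at the record's EC
        d_idx = ped.index[rec.loc[5, "dam"]]
        assert row[d_idx * 8 + 4] == 1.0
        assert row[d_idx * 8 + 5] == pytest.approx(rec.loc[5, "ec_scaled"])

    def test_column_counts(self):
        rec, ped, problem, info = toy_design()
        # per trait: intercept + (2-1) sex + (3-1) parity + (2-1) zone
        # + ec slope (+ weaning age for ww)
        p_bw = 1 + 1 + 2 + 1 + 1
        p_ww = p_bw + 1
        assert problem.p_fixed == p_bw + p_ww
        q = len(ped)
        assert problem.terms[-1].n_cols == 8 * q
        assert problem.terms[1].n_cols == 2 * rec["dam"].nunique()
        assert problem.terms[0].n_cols == 2 * rec["cg_id"].nunique()

    def test_unknown_dam_rows_zero_and_counted(self):
        rec, ped, problem, info = toy_design(with_dam=False)
        assert info.unknown_dam_records == len(rec)
        genetic = problem.terms[-1]
        for t in range(2):
            z = genetic.z_by_trait[t]
            # only the two direct entries per row
            assert (np.diff(z.indptr) == 2).all()
        assert problem.terms[1].n_levels == 0 or \
            problem.terms[1].z_by_trait[0].nnz == 0

    def test_reference_level_dropping_keeps_full_rank(self):
        rec, ped, problem, info = toy_design(n=40)
        x = np.vstack([problem.h_by_trait[t][:, :problem.p_fixed].toarray()
                       for t in range(2)])
        obs = ~np.isnan(problem.y)
        rows = np.concatenate([np.where(obs[:, 0])[0],
                               len(rec) + np.where(obs[:, 1])[0]])
        assert np.linalg.matrix_rank(x[rows]) == problem.p_fixed


class TestDesignRoundTrip:
    def test_phenotype_reconstruction_from_truth(self, small_dataset, small_qc):
        """Simulated phenotypes are reproduced exactly from the truth
        ledger through the design matrices."""
        records_qc, _ = small_qc
        truth = small_dataset["truth"]
        sc = small_dataset["scenario"]
        ped = validate_and_sort(
            small_dataset["pedigree_df"][["animal", "sire", "dam", "birth_date"]])
        problem, info = build_design(records_qc, ped, ModelSpec(ec_name="sumPrec365"))

        coef = truth.coefficients.set_index("animal")
        coef = coef.loc[list(info.animal_ids)].to_numpy()
        u_flat = coef.reshape(-1)
        mpe = truth.mpe.set_index("dam")
        mpe_flat = mpe.loc[list(info.dam_levels)].to_numpy().reshape(-1)
        cg = truth.cg_effects.set_index("cg_id")
        cg_flat = cg.loc[list(info.cg_levels)].to_numpy().reshape(-1)

        fe = sc.fixed_effect_values
        rec = records_qc.reset_index(drop=True)
        for t, trait in enumerate(("bw", "ww")):
            obs = ~np.isnan(problem.y[:, t])
            z = problem.terms[-1].z_by_trait[t]
            r_mpe = problem.terms[1].z_by_trait[t]
            q_cg = problem.terms[0].z_by_trait[t]
            random_part = z @ u_flat + r_mpe @ mpe_flat + q_cg @ cg_flat
            fixed_part = (fe["mu"][trait]
                          + rec["sex_birth_class"].map(fe["sex_birth_class"])
                          + rec["parity_class"].astype(str).map(fe["parity_class"])
                          + rec["veg_zone"].astype(str).map(fe["veg_zone"])
                          + fe["ec_slope"][trait] * rec["ec_scaled"]).to_numpy()
            if trait == "ww":
                fixed_part = fixed_part + fe["weaning_age_slope"] * (
                    rec["weaning_age_d"].fillna(0.0).to_numpy() - 220.0)
            resid = problem.y[:, t] - fixed_part - random_part
            # residuals equal the simulated residual draws: bounded by R
            sd = np.sqrt(sc.true_r[t, t])
            assert np.nanmax(np.abs(resid[obs])) < 6 * sd


class TestStartValues:
    def test_adjusted_variance_split(self, small_qc):
        records_qc, _ = small_qc
        vc = start_values(records_qc)
        # WW raw variance is inflated by weaning age; the start must not be
        raw_ww = np.nanvar(records_qc["ww_kg"])
        assert vc.residual[1, 1] < 0.75 * raw_ww
        # documented proportions: intercept 2x slope, residual half
        for t in range(2):
            tr = ("bw", "ww")[t]
            assert vc.direct_block(tr)[0, 0] == pytest.approx(
                2 * vc.direct_block(tr)[1, 1])
        assert np.all(np.linalg.eigvalsh(vc.g8) >= 0)
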