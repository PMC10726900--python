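"""Mixed-model DGE: agreement with a generic mixed-model fitter, null
calibration and power, coding consistency, and the rank metric."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from crmuscle.lmm import (RandomInterceptREML, build_design,
                          correlate_expression_phenotype, fit_gene_lmm,
                          rank_genes, run_dge, significance_summary)
from crmuscle.types import DesignSpec
from conftest import make_meta


def _gaussian_y(meta, beta1=0.0, subject_sd=0.3, resid_sd=0.3, seed=0,
                design=None):
    X, names, inter = build_design(meta, design or DesignSpec())
    beta = np.zeros(X.shape[1])
    beta[names.index(inter[0])] = beta1
    rng = np.random.default_rng(seed)
    codes, idx = np.unique(meta["subject_id"], return_inverse=True)
    u = rng.normal(0, subject_sd, len(codes))
    return X @ beta + u[idx] + rng.normal(0, resid_sd, len(meta))


class TestSolver:
    def test_matches_statsmodels_mixedlm(self):
        meta = make_meta(n_per_arm=12, seed=31)
        for s in range(4):
            y = _gaussian_y(meta, beta1=0.4, seed=s)
            rec = fit_gene_lmm(y, meta)[0]
            df = meta.assign(y=y, cr=(meta.group == "CR").astype(float))
            md = smf.mixedlm("y ~ cr*time_years + age + bmi + C(sex) + C(race) + C(batch)",
                             df, groups=df["subject_id"])
            ref = md.fit(reml=True)
            assert rec["beta"] == pytest.approx(ref.params["cr:time_years"], abs=1e-4)
            assert rec["se"] == pytest.approx(ref.bse["cr:time_years"], rel=0.02)
            assert rec["var_subject"] == pytest.approx(float(ref.cov_re.iloc[0, 0]),
                                                       abs=1e-3)

    def test_single_observation_per_subject_reduces_to_ols(self):
        meta = make_meta(n_per_arm=15, seed=32)
        # one randomly chosen visit per subject: random intercept unidentifiable
        meta = (meta.groupby("subject_id").sample(1, random_state=2)
                .reset_index(drop=True))
        y = _gaussian_y(meta, beta1=0.5, subject_sd=0.0, seed=3)
        rec = fit_gene_lmm(y, meta)[0]
        X, names, inter = build_design(meta, DesignSpec())
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert rec["boundary"]
        assert rec["beta"] == pytest.approx(ols[names.index(inter[0])], abs=1e-6)

    def test_arm_swap_negates_beta(self):
        meta = make_meta(n_per_arm=10, seed=33)
        y = _gaussian_y(meta, beta1=0.7, seed=4)
        b = fit_gene_lmm(y, meta)[0]["beta"]
        swapped = meta.assign(group=meta.group.map({"CR": "AL", "AL": "CR"}))
        b_swap = fit_gene_lmm(y, swapped)[0]["beta"]
        assert b_swap == pytest.approx(-b, abs=1e-8)

    def test_row_order_invariance(self):
        meta = make_meta(n_per_arm=10, seed=34)
        y = _gaussian_y(meta, beta1=0.2, seed=5)
        rec = fit_gene_lmm(y, meta)[0]
        perm = np.random.default_rng(0).permutation(len(meta))
        rec2 = fit_gene_lmm(np.asarray(y)[perm], meta.iloc[perm].reset_index(drop=True))[0]
        assert rec2["beta"] == pytest.approx(rec["beta"], abs=1e-8)
        assert rec2["p"] == pytest.approx(rec["p"], rel=1e-6)

    def test_singular_design_rejected(self):
        meta = make_meta(n_per_arm=6, seed=35)
        meta["race"] = meta["sex"]  # duplicate dummy columns
        with pytest.raises(np.linalg.LinAlgError):
            build_design(meta, DesignSpec())


class TestSweep:
    def test_null_sweep_rejection_and_sign_balance(self):
        meta = make_meta(n_per_arm=20, seed=36)
        rng_genes = 1000
        Y = np.vstack([_gaussian_y(meta, 0.0, seed=s) for s in range(rng_genes)])
        expr = pd.DataFrame(Y, index=[f"g{i:04d}" for i in range(rng_genes)],
                            columns=meta.sample_id)
        dge = run_dge(expr, meta)
        sig = dge[dge.p < 0.05]
        sd = np.sqrt(rng_genes * 0.05 * 0.95)
        assert abs(len(sig) - 50) <= 2 * sd
        assert abs((sig.beta > 0).sum() - len(sig) / 2) <= 2 * np.sqrt(len(sig)) / 2 + 3

    def test_planted_genes_detected(self):
        meta = make_meta(n_per_arm=45, seed=37)
        Y = [_gaussian_y(meta, 1.0, seed=s) for s in range(100)]
        Y += [_gaussian_y(meta, 0.0, seed=1000 + s) for s in range(150)]
        expr = pd.DataFrame(np.vstack(Y), index=[f"g{i:04d}" for i in range(250)],
                            columns=meta.sample_id)
        dge = run_dge(expr, meta)
        detected = (dge.iloc[:100].p < 0.01).sum()
        assert detected >= 90
        summ = significance_summary(dge)
        assert summ.loc[summ.threshold == 0.01, "n_up"].iloc[0] >= 90

    def test_empty_matrix_gives_empty_table(self):
        meta = make_meta(n_per_arm=5, seed=38)
        out = run_dge(pd.DataFrame(columns=meta.sample_id), meta)
        assert out.empty

    def test_linear_and_visit_codings_agree_on_linear_truth(self):
        """With exactly linear trajectories, the continuous-time slope x 2.1
        tracks the 24-month visit contrast."""
        meta = make_meta(n_per_arm=25, seed=39)
        rng = np.random.default_rng(9)
        slopes = rng.normal(0, 0.3, 150)
        Y = np.vstack([_gaussian_y(meta, b, resid_sd=0.2, seed=s)
                       for s, b in enumerate(slopes)])
        expr = pd.DataFrame(Y, index=[f"g{i:04d}" for i in range(150)],
                            columns=meta.sample_id)
        lin = run_dge(expr, meta, DesignSpec(time_coding="linear_years"))
        vis = run_dge(expr, meta, DesignSpec(time_coding="visit_indicators"))
        v24 = vis[vis.contrast == "group_CR:visit_24mo"].set_index("gene_id")
        r = np.corrcoef(lin.set_index("gene_id").beta * 2.1, v24.beta)[0, 1]
        assert r > 0.95


class TestRankMetric:
    def test_arithmetic(self):
        tab = pd.DataFrame({"gene_id": ["up", "down"], "p": [0.01, 0.01],
                            "beta": [1.0, -1.0]})
        r = rank_genes(tab)
        assert r["up"] == pytest.approx(2.0)
        assert r["down"] == pytest.approx(-2.0)

    def test_ties_broken_lexicographically(self):
        tab = pd.DataFrame({"gene_id": ["c", "a", "b"], "p": [1.0, 1.0, 1.0],
                            "beta": [1.0, 1.0, -1.0]})
        r = rank_genes(tab)
        assert list(r.index) == ["a", "b", "c"]
        np.testing.assert_allclose(r.to_numpy(), 0.0)

    def test_matches_bruteforce_sort(self):
        rng = np.random.default_rng(11)
        tab = pd.DataFrame({"gene_id": [f"g{i:02d}" for i in range(20)],
                            "p": rng.uniform(1e-6, 1, 20),
                            "beta": rng.normal(0, 1, 20)})
        r = rank_genes(tab)
        metric = {g: -np.log10(p) * np.sign(b)
                  for g, p, b in zip(tab.gene_id, tab.p, tab.beta)}
        expected = sorted(metric, key=lambda g: (-metric[g], g))
        assert list(r.index) == expected

    def test_missing_p_excluded_with_warning(self):
        tab = pd.DataFrame({"gene_id": ["a", "b"], "p": [0.5, np.nan],
                            "beta": [1.0, 1.0]})
        with pytest.warns(UserWarning):
            r = rank_genes(tab)
        assert list(r.index) == ["a"]


class TestBaselineCorrelation:
    def test_perfect_correlation(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"],
                            columns=list("abcd"))
        ph = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        out = correlate_expression_phenotype(expr, ph)
        assert out.r.iloc[0] == pytest.approx(1.0)

    def test_null_pairs_mostly_uncorrelated(self):
        rng = np.random.default_rng(12)
        expr = pd.DataFrame(rng.normal(0, 1, (100, 90)),
                            index=[f"g{i}" for i in range(100)],
                            columns=[f"s{i}" for i in range(90)])
        ph = pd.Series(rng.normal(0, 1, 90), index=expr.columns)
        out = correlate_expression_phenotype(expr, ph)
        assert (out.r.abs() < 0.3).mean() >= 0.95

    def test_degenerate_inputs(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        with pytest.raises(ValueError, match="zero variance"):
            correlate_expression_phenotype(expr, pd.Series([5.0, 5.0, 5.0],
                                                           index=list("abc")))
        with pytest.raises(ValueError, match="paired"):
            correlate_expression_phenotype(expr[["a", "b"]],
                                           pd.Series([1.0, 2.0], index=list("ab")))
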