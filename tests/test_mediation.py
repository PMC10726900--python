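"""Pathway scores, delta construction, and the beta-attenuation search."""
import numpy as np
import pandas as pd
import pytest

from crmuscle.mediation import (delta_scores, fit_base_model, mediation_search,
                                pathway_scores, percent_mediation)
from crmuscle.simulate import (simulate_pathway_deltas, simulate_phenotypes,
                               _STRENGTH_CHANGE_SD)
from crmuscle.types import PhenotypeTruth
from crmuscle.validation import mediation_noiseless_check


class TestPathwayScores:
    def _expr(self, seed=0, n_genes=5, n_samples=8):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(2, 1, (n_genes, n_samples)),
                            index=[f"g{i}" for i in range(n_genes)],
                            columns=[f"s{i}" for i in range(n_samples)])

    def test_single_gene_score_is_its_zscore(self):
        expr = self._expr()
        s = pathway_scores(expr, {"pw": ["g0"]})["pw"]
        z = (expr.loc["g0"] - expr.loc["g0"].mean()) / expr.loc["g0"].std(ddof=1)
        np.testing.assert_allclose(s, z, atol=1e-12)

    def test_duplicated_gene_equals_single(self):
        expr = self._expr()
        expr.loc["g1"] = 3.0 * expr.loc["g0"] - 1.0  # perfectly correlated
        both = pathway_scores(expr, {"pw": ["g0", "g1"]})["pw"]
        one = pathway_scores(expr, {"pw": ["g0"]})["pw"]
        np.testing.assert_allclose(both, one, atol=1e-12)

    def test_matches_hand_computed_mean(self):
        expr = self._expr(seed=3)
        genes = ["g0", "g2", "g4"]
        s = pathway_scores(expr, {"pw": genes})["pw"]
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=1), axis=0)
        np.testing.assert_allclose(s, z.loc[genes].mean(axis=0), atol=1e-12)

    def test_unmatched_pathway_errors(self):
        with pytest.raises(ValueError, match="no genes"):
            pathway_scores(self._expr(), {"pw": ["nope"]})


class TestDeltaScores:
    def _tidy(self, records):
        rows = []
        for sid, visits in records.items():
            for v, val in visits.items():
                rows.append({"subject_id": sid, "group": "CR", "sex": "F",
                             "visit": v, "x": val})
        return pd.DataFrame(rows)

    def test_24mo_rule_with_fallback(self):
        tidy = self._tidy({"a": {"Ba": 1.0, "12mo": 2.0, "24mo": 4.0},
                           "b": {"Ba": 1.0, "12mo": 2.0},
                           "c": {"Ba": 1.0}})
        out = delta_scores(tidy, ["x"], standardize=False).set_index("subject_id")
        assert out.loc["a", "delta_x"] == 3.0
        assert out.loc["a", "followup_visit"] == "24mo"
        assert out.loc["b", "delta_x"] == 1.0
        assert "c" not in out.index

    def test_standardization(self):
        tidy = self._tidy({f"s{i}": {"Ba": 0.0, "24mo": float(i)} for i in range(6)})
        out = delta_scores(tidy, ["x"])
        assert out["delta_x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["delta_x"].std(ddof=1) == pytest.approx(1.0)


class TestBaseModel:
    def _deltas(self, seed=0, n_cr=28, n_al=16, truth=None):
        subjects = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n_cr + n_al)],
            "group": ["CR"] * n_cr + ["AL"] * n_al,
            "sex": ["F", "M"] * ((n_cr + n_al) // 2)})
        truth = truth or PhenotypeTruth()
        visits = {s: ["Ba", "24mo"] for s in subjects.subject_id}
        pdelta = simulate_pathway_deltas(subjects, ["PW00"], truth, seed=seed)
        ph = simulate_phenotypes(subjects, visits, pdelta, truth, seed=seed + 1)
        ph["peak_torque_60"] = (ph.peak_torque_60_left + ph.peak_torque_60_right) / 2
        return delta_scores(ph, ["leg_lean_mass", "peak_torque_60"],
                            standardize=False)

    def test_recovers_direct_effect_at_study_n(self):
        """Mean CR coefficient over 100 cohorts of 28 CR / 16 AL within
        +/-0.15 of the planted 0.8 change-SD effect."""
        est = []
        for s in range(100):
            d = self._deltas(seed=1000 + 7 * s)
            d["delta_peak_torque_60"] /= _STRENGTH_CHANGE_SD
            est.append(fit_base_model(d, "peak_torque_60")["beta1"])
        assert np.mean(est) == pytest.approx(0.8, abs=0.15)

    def test_group_relabel_negates(self):
        d = self._deltas(seed=5)
        b = fit_base_model(d, "peak_torque_60")["beta1"]
        d2 = d.assign(group=d.group.map({"CR": "AL", "AL": "CR"}))
        assert fit_base_model(d2, "peak_torque_60")["beta1"] == pytest.approx(-b)

    def test_no_arm_difference_gives_null_beta(self):
        truth = PhenotypeTruth(total_cr_effect=0.0, cr_mass_loss=0.0)
        est = [fit_base_model(self._deltas(seed=60 + s, truth=truth),
                              "peak_torque_60")["beta1"] for s in range(40)]
        assert abs(np.mean(est)) < 0.1 * _STRENGTH_CHANGE_SD

    def test_saturated_model_rejected(self):
        d = self._deltas(seed=6).iloc[:4]
        with pytest.raises(ValueError):
            fit_base_model(d, "peak_torque_60")


class TestPercentMediation:
    def test_arithmetic(self):
        assert percent_mediation(1.0, 0.75) == pytest.approx(25.0)
        assert percent_mediation(2.0, 2.0) == 0.0
        assert percent_mediation(-1.0, 0.0) == pytest.approx(100.0)
        assert percent_mediation(1.0, -1.2) == pytest.approx(-20.0)

    def test_zero_base_undefined(self):
        with pytest.raises(ValueError):
            percent_mediation(0.0, 0.5)


class TestSearch:
    def _deltas_with_pathways(self, n_pathways=6, seed=0, fracs=None):
        subjects = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(44)],
            "group": ["CR"] * 28 + ["AL"] * 16,
            "sex": ["F", "M"] * 22})
        pathways = [f"PW{i:02d}" for i in range(n_pathways)]
        truth = PhenotypeTruth(mediated_fractions=fracs or {})
        visits = {s: ["Ba", "24mo"] for s in subjects.subject_id}
        pdelta = simulate_pathway_deltas(subjects, pathways, truth, seed=seed)
        ph = simulate_phenotypes(subjects, visits, pdelta, truth, seed=seed + 1)
        ph["peak_torque_60"] = (ph.peak_torque_60_left + ph.peak_torque_60_right) / 2
        d = delta_scores(ph, ["leg_lean_mass", "peak_torque_60"])
        for p in pathways:
            v = pdelta.loc[d.subject_id, p].to_numpy()
            d[f"delta_{p}"] = (v - v.mean()) / v.std(ddof=1)
        return d, pathways

    def test_k1_fits_every_pathway(self):
        d, pathways = self._deltas_with_pathways(n_pathways=10, seed=2)
        res = mediation_search(d, pathways, "peak_torque_60", k_max=1,
                               threshold=-1e9)
        assert len(res["records"]) == 10

    def test_planted_mediator_flagged_at_k1(self):
        d, pathways = self._deltas_with_pathways(seed=3, fracs={"PW00": 0.5})
        res = mediation_search(d, pathways, "peak_torque_60", k_max=1,
                               threshold=20.0)
        assert "PW00" in set(res["records"].combination)

    def test_orthogonal_pathway_leaves_beta(self):
        d, pathways = self._deltas_with_pathways(n_pathways=1, seed=4)
        y, X = None, None
        from crmuscle.mediation import _design
        y, X = _design(d, "peak_torque_60")
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, len(y))
        basis = np.column_stack([X.to_numpy(), y])
        v -= basis @ np.linalg.lstsq(basis, v, rcond=None)[0]  # orthogonalize
        d["delta_PW00"] = v
        res = mediation_search(d, ["PW00"], "peak_torque_60", k_max=1,
                               threshold=-1e9)
        rec = res["records"].iloc[0]
        assert abs(rec.beta_adj - rec.beta_base) < 1e-6

    def test_collinear_combination_skipped(self):
        d, pathways = self._deltas_with_pathways(n_pathways=2, seed=5)
        d["delta_PW01"] = d["delta_PW00"]
        res = mediation_search(d, pathways, "peak_torque_60", k_max=2,
                               threshold=-1e9)
        assert not (res["records"].k == 2).any()

    def test_per_k_max_consistent_with_records(self):
        d, pathways = self._deltas_with_pathways(seed=6, fracs={"PW00": 0.4})
        res = mediation_search(d, pathways[:4], "peak_torque_60", k_max=3,
                               threshold=-1e9)
        recs = res["records"]
        for k in (1, 2, 3):
            assert res["per_k_max"][k] == pytest.approx(
                recs.loc[recs.k == k, "percent"].max())

    def test_category_distinct_best(self):
        d, pathways = self._deltas_with_pathways(n_pathways=4, seed=7)
        cats = {"PW00": "A", "PW01": "A", "PW02": "B", "PW03": "C"}
        res = mediation_search(d, pathways[:4], "peak_torque_60", k_max=2,
                               threshold=-1e9, categories=cats)
        combo = res["best_distinct"][2]["combination"]
        assert len({cats[p] for p in combo}) == 2

    def test_noiseless_single_mediator_recovers_fraction(self):
        out = mediation_noiseless_check(seed=1, fraction=0.5)
        assert out["percent"] == pytest.approx(out["target"], abs=5.0)


def test_scale_invariance_of_percent():
    """Rescaling a pathway's delta column leaves percent mediation unchanged
    (scores are standardized before fitting anyway)."""
    d = TestSearch()._deltas_with_pathways(n_pathways=1, seed=8,
                                           fracs={"PW00": 0.3})[0]
    r1 = mediation_search(d, ["PW00"], "peak_torque_60", k_max=1, threshold=-1e9)
    d2 = d.assign(delta_PW00=5.0 * d["delta_PW00"])
    r2 = mediation_search(d2, ["PW00"], "peak_torque_60", k_max=1, threshold=-1e9)
    assert r1["records"].percent.iloc[0] == pytest.approx(r2["records"].percent.iloc[0],
                                                          abs=1e-9)
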