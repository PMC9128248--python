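"""Tests for survival-factor discovery, I_gp scoring and Cox analyses."""

import numpy as np
import pandas as pd
import pytest

from pminet.survival import (
    FactorConflictError,
    SurvivalFactor,
    cocnv_patient_groups,
    codm_patient_status,
    cox_multivariate,
    divide_by_score,
    find_cocnv_factors,
    find_codm_factors,
    i_gp,
    logrank,
    nmad,
    score_patients,
    single_cnv_status_table,
    subsample_stability,
)


def factor(pair, better, worse, modality="CoCNV"):
    return SurvivalFactor(pair=pair, modality=modality, better_type=better,
                          worse_type=worse, n_better=30, n_worse=30,
                          statistic=5.0, pvalue=0.01)


class TestPatientGroups:
    def test_all_nc_single_group(self):
        status = pd.Series(["NC"] * 10, index=[f"s{i}" for i in range(10)])
        groups = cocnv_patient_groups(status)
        assert len(groups["NC"]) == 10
        assert all(len(groups[g]) == 0 for g in ("GG", "LL", "GL", "LG"))

    def test_sizes_sum_to_n(self):
        rng = np.random.default_rng(0)
        status = pd.Series(rng.choice(["GG", "LL", "GL", "LG", "NC"], size=100),
                           index=[f"s{i}" for i in range(100)])
        groups = cocnv_patient_groups(status)
        assert sum(len(v) for v in groups.values()) == 100

    def test_planted_split_recovered(self):
        status = pd.Series(["GG"] * 30 + ["LL"] * 30 + ["NC"] * 40,
                           index=[f"s{i}" for i in range(100)])
        groups = cocnv_patient_groups(status)
        assert (len(groups["GG"]), len(groups["LL"]), len(groups["NC"])) == (30, 30, 40)

    def test_unknown_status_rejected(self):
        with pytest.raises(ValueError):
            cocnv_patient_groups(pd.Series(["XX"], index=["s0"]))


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.arange(1.0, 21.0)
        e = np.ones(20, dtype=int)
        stat, p = logrank((t, e), (t.copy(), e.copy()))
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_label_swap_symmetric(self):
        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(10, 30), rng.exponential(20, 30)
        ea, eb = np.ones(30, int), np.ones(30, int)
        sa, _ = logrank((ta, ea), (tb, eb))
        sb, _ = logrank((tb, eb), (ta, ea))
        assert sa == pytest.approx(sb, rel=1e-9)

    def test_no_events_rejected(self):
        t = np.arange(1.0, 11.0)
        z = np.zeros(10, int)
        with pytest.raises(ValueError):
            logrank((t, z), (t, z))

    def test_hazard_ratio_3_detected(self):
        hits = 0
        for s in range(30):
            rng = np.random.default_rng(s)
            ta = rng.exponential(30.0, 100)
            tb = rng.exponential(10.0, 100)
            e = np.ones(100, int)
            _, p = logrank((ta, e), (tb, e))
            hits += p < 0.01
        assert hits >= 27   # >= 90% power at HR 3, n=100/100

    def test_agrees_with_permutation_oracle(self):
        """Log-rank p-values track a label-permutation null within
        Monte-Carlo error on random small cohorts."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = 25
            ta = rng.exponential(rng.uniform(5, 20), n)
            tb = rng.exponential(rng.uniform(5, 20), n)
            ea = (rng.random(n) > 0.2).astype(int)
            eb = (rng.random(n) > 0.2).astype(int)
            stat, p = logrank((ta, ea), (tb, eb))
            times = np.concatenate([ta, tb])
            events = np.concatenate([ea, eb])
            B = 400
            exceed = 0
            for _ in range(B):
                perm = rng.permutation(2 * n)
                t1, t2 = times[perm[:n]], times[perm[n:]]
                e1, e2 = events[perm[:n]], events[perm[n:]]
                if e1.sum() + e2.sum() == 0:
                    continue
                s_perm, _ = logrank((t1, e1), (t2, e2))
                exceed += s_perm >= stat
            p_perm = exceed / B
            se = np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / B)
            assert abs(p - p_perm) < 4 * se + 0.03


class TestFactorDiscovery:
    def planted_cohort(self, seed=0, n=200, gg_rate=0.45, hr_gg=0.5):
        """Cohort where GG halves the hazard (protective) for one pair."""
        rng = np.random.default_rng(seed)
        samples = [f"s{i:03d}" for i in range(n)]
        status = pd.Series(np.where(rng.random(n) < gg_rate, "GG", "NC"),
                           index=samples)
        hz = np.where(status == "GG", 0.01 * hr_gg, 0.01)
        times = rng.exponential(1 / hz)
        clinical = pd.DataFrame({"time": times, "event": 1}, index=samples)
        statuses = {("A", "B"): pd.DataFrame({"status": status, "level_product": 1})}
        return statuses, clinical

    def test_small_groups_never_tested(self):
        statuses, clinical = self.planted_cohort(n=30)
        factors = find_cocnv_factors([("A", "B")], statuses, clinical, min_n=20)
        assert factors == []

    def test_planted_protective_gg_recovered(self):
        statuses, clinical = self.planted_cohort(seed=3)
        factors = find_cocnv_factors([("A", "B")], statuses, clinical)
        assert len(factors) == 1
        f = factors[0]
        assert (f.better_type, f.worse_type) == ("GG", "NC")
        assert f.pvalue < 0.05

    def test_min_n_is_strict(self):
        # 21 GG vs 21 NC: "more than 20" admits exactly-21 groups
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(42)]
        status = pd.Series(["GG"] * 21 + ["NC"] * 21, index=samples)
        clinical = pd.DataFrame({"time": rng.exponential(10, 42), "event": 1},
                                index=samples)
        statuses = {("A", "B"): pd.DataFrame({"status": status, "level_product": 1})}
        # runs one comparison (may or may not be significant); 20-sample
        # groups would run none
        find_cocnv_factors([("A", "B")], statuses, clinical, min_n=20)
        status20 = pd.Series(["GG"] * 20 + ["NC"] * 22, index=samples)
        statuses20 = {("A", "B"): pd.DataFrame({"status": status20, "level_product": 1})}
        assert find_cocnv_factors([("A", "B")], statuses20, clinical,
                                  min_n=20, alpha=1.0) == []

    def test_codm_nmad_filter(self):
        assert nmad([0, 0, 10, 10]) == pytest.approx(1.0)
        with pytest.raises(ZeroDivisionError):
            nmad([0, 0, 0])

    def test_codm_planted_effect_recovered(self):
        rng = np.random.default_rng(5)
        n = 200
        samples = [f"s{i:03d}" for i in range(n)]
        hh = rng.choice([0, 8], size=n)   # NMAD 1.0
        profile = pd.DataFrame({"LL": 1, "HH": hh, "LH": 1, "HL": 1}, index=samples)
        hz = np.where(hh > np.median(hh), 0.005, 0.02)   # HH-high protective
        clinical = pd.DataFrame({"time": rng.exponential(1 / hz), "event": 1},
                                index=samples)
        factors = find_codm_factors([("A", "B")], {("A", "B"): profile}, clinical)
        assert any(f.better_type == "HH-high" and f.worse_type == "HH-low"
                   for f in factors)

    def test_codm_constant_value_skipped(self):
        samples = [f"s{i}" for i in range(50)]
        profile = pd.DataFrame({"LL": 4, "HH": 4, "LH": 4, "HL": 4}, index=samples)
        clinical = pd.DataFrame({"time": np.arange(1.0, 51.0), "event": 1},
                                index=samples)
        assert find_codm_factors([("A", "B")], {("A", "B"): profile}, clinical) == []


class TestIgp:
    def test_single_factor_gg_better_than_nc(self):
        fs = [factor(("G1", "G2"), "GG", "NC")]
        assert i_gp(fs, "GG") == 1
        assert i_gp(fs, "NC") == 0
        assert i_gp(fs, "LL") == 0

    def test_multi_factor_orientation(self):
        fs = [factor(("G3", "G4"), "LL", "NC"),
              factor(("G3", "G4"), "NC", "GG"),
              factor(("G3", "G4"), "LL", "GG"),
              factor(("G3", "G4"), "GL", "GG")]
        assert i_gp(fs, "GG") == -1
        assert i_gp(fs, "LL") == 1
        assert i_gp(fs, "GL") == 1
        assert i_gp(fs, "NC") == 0

    def test_codm_median_group_membership(self):
        fs = [factor(("G1", "G2"), "HH-high", "HH-low", modality="CoDM")]
        assert i_gp(fs, {"HH": "high"}) == 1
        assert i_gp(fs, {"HH": "low"}) == -1

    def test_conflicting_cocnv_orientation_raises(self):
        fs = [factor(("G1", "G2"), "GG", "LL"),
              factor(("G1", "G2"), "LL", "NC")]
        with pytest.raises(FactorConflictError):
            i_gp(fs, "GG")

    def test_output_always_in_range(self):
        fs = [factor(("G1", "G2"), "HH-high", "HH-low", modality="CoDM"),
              factor(("G1", "G2"), "LL-low", "LL-high", modality="CoDM")]
        for status in ({"HH": "high", "LL": "low"}, {"HH": "low", "LL": "high"},
                       {"HH": "high", "LL": "high"}):
            assert i_gp(fs, status) in (-1, 0, 1)


class TestScoring:
    def test_opposite_pairs_cancel(self):
        samples = [f"s{i}" for i in range(9)]
        st1 = pd.DataFrame({"status": ["GG"] * 9, "level_product": 1}, index=samples)
        st2 = pd.DataFrame({"status": ["GG"] * 9, "level_product": 1}, index=samples)
        fs = [factor(("A", "B"), "GG", "NC"), factor(("C", "D"), "NC", "GG")]
        scores = score_patients(fs, cocnv_statuses={("A", "B"): st1, ("C", "D"): st2})
        assert (scores["score"] == 0).all()

    def test_score_bounded_by_pair_count(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(30)]
        statuses = {}
        fs = []
        for pair in [("A", "B"), ("C", "D"), ("E", "F")]:
            statuses[pair] = pd.DataFrame(
                {"status": rng.choice(["GG", "NC", "LL"], 30), "level_product": 1},
                index=samples)
            fs.append(factor(pair, "GG", "LL"))
        scores = score_patients(fs, cocnv_statuses=statuses)
        assert scores["score"].abs().max() <= 3

    def test_no_factors_rejected(self):
        with pytest.raises(ValueError):
            score_patients([], cocnv_statuses={})

    def test_divide_by_score_tertiles(self):
        scores = pd.Series([-1] * 30 + [0] * 30 + [1] * 30,
                           index=[f"s{i}" for i in range(90)])
        groups = divide_by_score(scores)
        assert (groups.value_counts() == 30).all()

    def test_divide_degenerate_scores(self):
        scores = pd.Series([2] * 10, index=[f"s{i}" for i in range(10)])
        groups = divide_by_score(scores)
        assert set(groups) == {"low"}

    def test_planted_beneficial_status_improves_survival(self):
        rng = np.random.default_rng(11)
        n = 300
        samples = [f"s{i:03d}" for i in range(n)]
        status = pd.Series(rng.choice(["GG", "NC"], n), index=samples)
        hz = np.where(status == "GG", 0.005, 0.02)
        clinical = pd.DataFrame({"time": rng.exponential(1 / hz), "event": 1},
                                index=samples)
        statuses = {("A", "B"): pd.DataFrame({"status": status, "level_product": 1})}
        fs = find_cocnv_factors([("A", "B")], statuses, clinical)
        scores = score_patients(fs, cocnv_statuses=statuses)
        joined = clinical.join(scores)
        med_high = joined.loc[joined["score"] > 0, "time"].median()
        med_low = joined.loc[joined["score"] <= 0, "time"].median()
        assert med_high > med_low


class TestCox:
    def test_planted_score_effect_recovered(self):
        rng = np.random.default_rng(0)
        n = 500
        samples = [f"s{i:03d}" for i in range(n)]
        score = rng.integers(-2, 3, n)
        hz = 0.01 * np.exp(np.log(2.0) * score)
        clinical = pd.DataFrame({"time": rng.exponential(1 / hz), "event": 1},
                                index=samples)
        res = cox_multivariate(clinical, pd.Series(score, index=samples, name="score"))
        assert res.loc["score", "coef"] == pytest.approx(np.log(2.0), rel=0.3)

    def test_null_covariate_not_significant(self):
        insignificant = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            n = 300
            samples = [f"s{i:03d}" for i in range(n)]
            clinical = pd.DataFrame({
                "time": rng.exponential(50, n), "event": 1,
                "age": rng.normal(60, 10, n)}, index=samples)
            res = cox_multivariate(clinical, covariates=["age"])
            insignificant += res.loc["age", "p"] > 0.05
        assert insignificant >= 8

    def test_cocnv_and_codm_scores_in_one_model(self):
        rng = np.random.default_rng(3)
        n = 300
        samples = [f"s{i:03d}" for i in range(n)]
        scores = pd.DataFrame({"cocnv_score": rng.integers(-1, 2, n),
                               "codm_score": rng.integers(-1, 2, n)}, index=samples)
        hz = 0.01 * np.exp(0.5 * scores["cocnv_score"] - 0.5 * scores["codm_score"])
        clinical = pd.DataFrame({"time": rng.exponential(1 / hz), "event": 1},
                                index=samples)
        res = cox_multivariate(clinical, scores)
        assert {"cocnv_score", "codm_score"} <= set(res.index)


class TestSubsampleStability:
    def make_clinical(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"s{i:03d}" for i in range(n)]
        age = rng.normal(0, 1, n)
        hz = 0.01 * np.exp(1.0 * age)
        return pd.DataFrame({"time": rng.exponential(1 / hz), "event": 1,
                             "age": age}, index=samples)

    def test_strong_effect_small_p_sd(self):
        clinical = self.make_clinical()
        res = subsample_stability(clinical, covariates=["age"], reps=20, seed=0)
        assert res.loc["age", "p_mean"] < 0.01
        assert res.loc["age", "p_sd"] < 0.01

    def test_seeded_determinism(self):
        clinical = self.make_clinical()
        a = subsample_stability(clinical, covariates=["age"], reps=5, seed=4)
        b = subsample_stability(clinical, covariates=["age"], reps=5, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_single_rep_sd_sentinel(self):
        clinical = self.make_clinical()
        res = subsample_stability(clinical, covariates=["age"], reps=1, seed=1)
        assert np.isnan(res.loc["age", "p_sd"])


def test_single_gene_status_table():
    cnv = pd.DataFrame({"s0": [1, -2, 0]}, index=["A", "B", "C"])
    out = single_cnv_status_table(cnv, ["A", "B", "C"])
    assert out["A"].at["s0", "status"] == "G"
    assert out["B"].at["s0", "status"] == "L"
    assert out["B"].at["s0", "level_product"] == 2
    assert out["C"].at["s0", "status"] == "NC"
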