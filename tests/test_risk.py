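"""Split arithmetic, risk scores, ROC/cutoff, stratification, independence."""

import warnings

import numpy as np
import pandas as pd
import pytest

from irgp.datatypes import (ClinicalTable, PairIndicatorMatrix,
                            SignatureModel, ValidationError)
from irgp.risk import (assign_risk, multivariate_independence, one_year_roc,
                       risk_score, select_cutoff, split_cohort,
                       stratify_and_compare)
from irgp.validation import _null_survival


def _clinical(n, seed=0, **extra):
    rng = np.random.default_rng(seed)
    t, e = _null_survival(n, rng)
    data = {"time": t, "event": e}
    data.update(extra)
    return ClinicalTable(pd.DataFrame(
        data, index=pd.Index([f"S{i}" for i in range(n)], name="sample_id")))


class TestSplit:
    def test_387_samples_split_194_193(self):
        train, test = split_cohort(_clinical(387), 0.5, seed=1)
        assert sorted([len(train), len(test)]) == [193, 194]
        assert len(train) == 194

    def test_ten_samples_split_evenly(self):
        train, test = split_cohort(_clinical(10), 0.5, seed=2)
        assert len(train) == len(test) == 5

    def test_same_seed_identical_partition(self):
        a = split_cohort(_clinical(101), 0.5, seed=9)
        b = split_cohort(_clinical(101), 0.5, seed=9)
        assert a == b

    def test_partition_is_disjoint_and_complete(self):
        train, test = split_cohort(_clinical(57), 0.3, seed=3)
        assert not set(train) & set(test)
        assert len(train) + len(test) == 57

    def test_too_few_samples_errors(self):
        with pytest.raises(ValidationError, match="10"):
            split_cohort(_clinical(9), 0.5, seed=0)


class TestRiskScore:
    def test_all_zero_indicators_score_zero(self, sig17):
        pm = PairIndicatorMatrix(sig17.pairs, ["A", "B"],
                                 np.zeros((17, 2), dtype=int))
        s = risk_score(sig17, pm)
        np.testing.assert_array_equal(s.to_numpy(), 0.0)

    def test_all_one_indicators_sum_printed_coefficients(self, sig17):
        # direct summation of the 17 printed coefficients
        pm = PairIndicatorMatrix(sig17.pairs, ["A"],
                                 np.ones((17, 1), dtype=int))
        s = risk_score(sig17, pm)
        assert s.iloc[0] == pytest.approx(1.115395514, abs=1e-9)

    def test_single_pair_half_weight(self):
        sig = SignatureModel([("X", "Y")], [0.5])
        pm = PairIndicatorMatrix([("X", "Y")], ["A"], [[1]])
        assert risk_score(sig, pm).iloc[0] == 0.5

    def test_missing_pair_errors_by_name(self, sig17):
        pm = PairIndicatorMatrix([("X", "Y")], ["A"], [[1]])
        with pytest.raises(ValidationError, match=r"FAM3D\|FABP3"):
            risk_score(sig17, pm)

    def test_linearity_in_coefficients(self):
        rng = np.random.default_rng(0)
        pairs = [(f"A{k}", f"B{k}") for k in range(4)]
        pm = PairIndicatorMatrix(pairs, [f"S{j}" for j in range(6)],
                                 rng.integers(0, 2, (4, 6)))
        a = rng.normal(size=4)
        b = rng.normal(size=4)
        sa = risk_score(SignatureModel(pairs, a), pm)
        sb = risk_score(SignatureModel(pairs, b), pm)
        sab = risk_score(SignatureModel(pairs, a + b), pm)
        np.testing.assert_allclose(sa + sb, sab, atol=1e-12)


class TestROC:
    def test_perfect_separation_auc_one(self):
        clin = _clinical(40, seed=4)
        e = clin.event.to_numpy()
        t = clin.time.to_numpy()
        pos = (e == 1) & (t <= 365)
        scores = pd.Series(np.where(pos, 10.0, 0.0) +
                           np.arange(40) * 1e-4, index=clin.sample_ids)
        roc = one_year_roc(scores, clin)
        assert roc.auc == 1.0
        cut = select_cutoff(roc)
        assert 0.1 < cut < 10.0  # strictly between the groups

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(11)
        clin = _clinical(1000, seed=11)
        scores = pd.Series(rng.normal(size=1000), index=clin.sample_ids)
        roc = one_year_roc(scores, clin)
        assert roc.auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_brute_force_concordance(self):
        clin = ClinicalTable(pd.DataFrame(
            {"time": [100.0, 200.0, 900.0, 400.0, 800.0, 500.0],
             "event": [1, 1, 0, 1, 1, 0]},
            index=pd.Index(list("ABCDEF"), name="sample_id")))
        scores = pd.Series([3.0, 1.0, 0.5, 2.0, 2.0, 1.5], index=list("ABCDEF"))
        roc = one_year_roc(scores, clin, horizon=365.0)
        # positives: A, B (death <= 365); negatives: C, E (time > 365);
        # D died at 400 -> negative; F censored at 500 -> negative... all
        # with time > horizon are negatives regardless of status
        pos = ["A", "B"]
        neg = ["C", "D", "E", "F"]
        conc = 0.0
        for p in pos:
            for q in neg:
                if scores[p] > scores[q]:
                    conc += 1.0
                elif scores[p] == scores[q]:
                    conc += 0.5
        assert roc.auc == pytest.approx(conc / (len(pos) * len(neg)))
        assert roc.n_excluded == 0

    def test_censored_before_horizon_excluded(self):
        clin = ClinicalTable(pd.DataFrame(
            {"time": [100.0, 200.0, 900.0], "event": [1, 0, 0]},
            index=pd.Index(list("ABC"), name="sample_id")))
        roc = one_year_roc(pd.Series([2.0, 1.0, 0.0], index=list("ABC")), clin)
        assert roc.n_excluded == 1
        assert roc.n_positive == 1 and roc.n_negative == 1

    def test_cutoff_matches_exhaustive_youden_search(self):
        clin = ClinicalTable(pd.DataFrame(
            {"time": [50.0, 120.0, 400.0, 600.0, 90.0, 700.0],
             "event": [1, 1, 0, 1, 1, 0]},
            index=pd.Index(list("ABCDEF"), name="sample_id")))
        scores = pd.Series([2.5, 1.2, 1.4, 0.8, 2.0, 0.6], index=list("ABCDEF"))
        roc = one_year_roc(scores, clin)
        cut = select_cutoff(roc)
        s = scores.to_numpy()
        pos = np.array([True, True, False, False, True, False])
        neg = ~pos

        def j_of(c):
            return (s[pos] > c).mean() + (s[neg] <= c).mean() - 1.0

        candidates = np.concatenate([[s.min() - 1], np.unique(s),
                                     (np.unique(s)[:-1] + np.unique(s)[1:]) / 2])
        assert j_of(cut) == pytest.approx(max(j_of(c) for c in candidates))

    def test_degenerate_all_equal_scores_warns(self):
        clin = _clinical(40, seed=4)
        scores = pd.Series(1.0, index=clin.sample_ids)
        roc = one_year_roc(scores, clin)
        with pytest.warns(UserWarning, match="degenerate"):
            assert select_cutoff(roc) == 1.0


class TestStratify:
    def test_high_risk_group_dies_more_with_signal(self, planted_cohort):
        cfg, em, clinical, truth, _ = planted_cohort
        scores = pd.Series(truth.betas @ truth.indicators.values.astype(float),
                           index=truth.indicators.sample_ids)
        roc = one_year_roc(scores, clinical)
        cut = select_cutoff(roc)
        cmp_ = stratify_and_compare(scores, cut, clinical)
        assert cmp_.death_fraction["high"] > cmp_.death_fraction["low"]
        assert cmp_.p_value < 0.01

    def test_cutoff_below_all_scores_errors(self):
        clin = _clinical(20, seed=5)
        scores = pd.Series(np.linspace(1, 2, 20), index=clin.sample_ids)
        with pytest.raises(ValidationError, match="low"):
            stratify_and_compare(scores, 0.0, clin)

    def test_strict_threshold_assignment(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=list("ABC"))
        ra = assign_risk(scores, 2.0)
        assert ra.high == ["C"]  # score == cutoff goes low
        assert ra.low == ["A", "B"]


class TestIndependence:
    def test_risk_score_dominates_when_only_signal(self, planted_cohort):
        cfg, em, clinical, truth, _ = planted_cohort
        scores = pd.Series(truth.betas @ truth.indicators.values.astype(float),
                           index=truth.indicators.sample_ids)
        res = multivariate_independence(scores, clinical)
        assert res.multivariate.loc["riskScore", "p"] < 0.01
        others = res.multivariate.drop(index="riskScore")
        assert (others["p"] > 0.01).all()

    def test_age_effect_is_detected(self):
        from irgp import SimulationConfig
        from irgp.simulate import (default_planted_pairs,
                                   simulate_expression, simulate_survival)
        base = SimulationConfig(n_tumor=400, n_normal=2, n_genes=10,
                                immune_fraction=1.0, n_de_genes=0,
                                mu_low=6.0, mu_high=6.0, seed=15)
        cfg = SimulationConfig(n_tumor=400, n_normal=2, n_genes=10,
                               immune_fraction=1.0, n_de_genes=0,
                               mu_low=6.0, mu_high=6.0, seed=15,
                               age_effect=0.05,
                               planted_pairs=default_planted_pairs(
                                   base, 1, beta=0.8))
        _, truth = simulate_expression(cfg)
        clin = simulate_survival(cfg, truth)
        scores = pd.Series(truth.betas @ truth.indicators.values.astype(float),
                           index=truth.indicators.sample_ids)
        res = multivariate_independence(scores, clin)
        assert res.multivariate.loc["age", "p"] < 0.05
        assert res.multivariate.loc["age", "coef"] > 0

    def test_constant_risk_score_dropped_with_warning(self, planted_cohort):
        cfg, em, clinical, truth, _ = planted_cohort
        scores = pd.Series(1.0, index=clinical.sample_ids)
        with pytest.warns(UserWarning, match="riskScore"):
            res = multivariate_independence(scores, clinical)
        assert "riskScore" not in res.multivariate.index
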