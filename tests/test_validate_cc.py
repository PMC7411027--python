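"""Case/control validation battery."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sibprs import cohorts
from sibprs.validate_cc import (
    MixtureParams,
    asp_prevalence,
    auc_report,
    estimate_mixture,
    gaussian_mixture_prevalence,
    highrisk_call_rate,
    prevalence_by_threshold,
    sibling_call_rate,
    threshold_sweep,
    trio_call_rate,
)
from sibprs.theory import highrisk_pair_probability
from tests.conftest import make_pedigree, make_scores


def _single_case_pairs(case_scores, ctrl_scores):
    n = len(case_scores)
    ids_case = [f"c{i}" for i in range(n)]
    ids_ctrl = [f"k{i}" for i in range(n)]
    pairs = pd.DataFrame(
        {
            "id_a": ids_case, "id_b": ids_ctrl,
            "family_a": [f"f{i}" for i in range(n)],
            "family_b": [f"g{i}" for i in range(n)],
            "kind": "sibling",
            "case_id": ids_case, "control_id": ids_ctrl,
        }
    )
    scores = make_scores(ids_case + ids_ctrl, list(case_scores) + list(ctrl_scores))
    status = pd.Series([1.0] * n + [0.0] * n, index=ids_case + ids_ctrl)
    return pairs, scores, status


class TestSiblingCallRate:
    def test_all_called_correctly(self):
        pairs, scores, _ = _single_case_pairs([2, 3, 4], [0, 1, 2])
        assert sibling_call_rate(pairs, scores).fraction == 1.0

    def test_enumeration_with_tie_rule(self):
        pairs, scores, _ = _single_case_pairs([1.2, 0.3, 0.9], [0.8, 0.7, 0.9])
        assert sibling_call_rate(pairs, scores).fraction == pytest.approx(0.5)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 10_000
        pairs, scores, _ = _single_case_pairs(rng.normal(size=n), rng.normal(size=n))
        f = sibling_call_rate(pairs, scores)
        assert f.fraction == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / n))

    def test_empty_rejected(self):
        pairs, scores, _ = _single_case_pairs([1], [0])
        with pytest.raises(ValueError):
            sibling_call_rate(pairs.iloc[:0], scores)


class TestHighRisk:
    def test_hand_computation(self):
        # 4 qualifying pairs, 3 correct -> 0.75, Wald sqrt(0.1875/4)
        pairs, scores, _ = _single_case_pairs([2.5, 2.5, 2.5, 0.2, 1.2], [0.5, 0.0, 0.3, 2.5, 0.5])
        z = scores.ensemble_mean()
        sub = cohorts.highrisk_normal_pairs(pairs, z, hi_z=2.0)
        r = highrisk_call_rate(sub)
        assert r.n == 4
        assert r.fraction == pytest.approx(0.75)
        assert r.wald_sd == pytest.approx(np.sqrt(0.1875 / 4), abs=1e-9)

    def test_no_qualifying_pairs_undefined(self):
        pairs, scores, _ = _single_case_pairs([0.5], [0.1])
        sub = cohorts.highrisk_normal_pairs(pairs, scores.ensemble_mean(), hi_z=2.0)
        assert len(sub) == 0
        assert highrisk_call_rate(sub) is None

    def test_monotone_in_threshold_on_mixture(self):
        # informative score: call rate at hi_z=2 should exceed hi_z=1
        rng = np.random.default_rng(1)
        n = 40_000
        case = rng.normal(0.6, 1, n)
        ctrl = rng.normal(0.0, 1, n)
        pairs, scores, _ = _single_case_pairs(case, ctrl)
        z = scores.ensemble_mean()
        r1 = highrisk_call_rate(cohorts.highrisk_normal_pairs(pairs, z, 1.0))
        r2 = highrisk_call_rate(cohorts.highrisk_normal_pairs(pairs, z, 2.0))
        assert r2.fraction > r1.fraction - (r1.combined_err + r2.combined_err)

    def test_random_pair_rate_matches_two_gaussian_oracle(self):
        rng = np.random.default_rng(2)
        n = 60_000
        mu1, mu0 = 0.5, 0.0
        pairs, scores, _ = _single_case_pairs(rng.normal(mu1, 1, n), rng.normal(mu0, 1, n))
        z = scores.ensemble_mean()
        sub = cohorts.highrisk_normal_pairs(pairs, z, 1.5)
        obs = highrisk_call_rate(sub)
        pred = highrisk_pair_probability(mu1, 1.0, mu0, 1.0, 1.5)
        assert obs.fraction == pytest.approx(pred, abs=3 * obs.wald_sd + 0.01)


class TestThresholdSweep:
    def test_nested_counts_and_null_level(self):
        rng = np.random.default_rng(3)
        n = 5000
        pairs, scores, _ = _single_case_pairs(rng.normal(size=n), rng.normal(size=n))
        curve = threshold_sweep(pairs, scores, [1.0, 1.5, 2.0])
        assert (np.diff(curve["n_pairs"]) <= 0).all()
        ok = curve.dropna(subset=["fraction"])
        for _, row in ok.iterrows():
            assert row["fraction"] == pytest.approx(0.5, abs=4 * row["error"] + 0.02)


class TestPrevalence:
    def test_limit_recovers_overall_prevalence(self):
        rng = np.random.default_rng(4)
        z = pd.Series(rng.normal(size=2000))
        status = pd.Series(rng.binomial(1, 0.2, 2000).astype(float), index=z.index)
        curve = prevalence_by_threshold(z, status, [10.0], "below")
        assert curve["fraction"].iloc[0] == pytest.approx(status.mean())

    def test_independent_scores_flat(self):
        rng = np.random.default_rng(5)
        z = pd.Series(rng.normal(size=20_000))
        status = pd.Series(rng.binomial(1, 0.1, 20_000).astype(float), index=z.index)
        curve = prevalence_by_threshold(z, status, [-1.0, 0.0, 1.0], "above")
        for _, row in curve.iterrows():
            assert row["fraction"] == pytest.approx(0.1, abs=4 * row["binomial_sd"])

    def test_mixture_closed_form(self):
        # cases N(0.5,1) K=0.1: above t=1 the affected fraction follows the
        # two-component tail ratio
        rng = np.random.default_rng(6)
        n = 400_000
        n_case = int(0.1 * n)
        z = np.concatenate([rng.normal(0.5, 1, n_case), rng.normal(0, 1, n - n_case)])
        status = np.concatenate([np.ones(n_case), np.zeros(n - n_case)])
        idx = [f"i{i}" for i in range(n)]
        curve = prevalence_by_threshold(pd.Series(z, index=idx), pd.Series(status, index=idx), [1.0], "above")
        expect = 0.1 * stats.norm.sf(0.5) / (0.1 * stats.norm.sf(0.5) + 0.9 * stats.norm.sf(1))
        assert curve["fraction"].iloc[0] == pytest.approx(expect, abs=3 * curve["binomial_sd"].iloc[0])

    def test_gaussian_prediction_symmetric_half(self):
        p = MixtureParams(0.0, 1.0, 100, 0.0, 1.0, 100)
        pred = gaussian_mixture_prevalence(p, [-1, 0, 1], "above")
        assert np.allclose(pred["predicted_fraction"], 0.5)

    def test_gaussian_prediction_limit_is_case_share(self):
        p = MixtureParams(0.3, 1.0, 100, 0.0, 1.0, 900)
        pred = gaussian_mixture_prevalence(p, [-100.0], "above")
        assert pred["predicted_fraction"].iloc[0] == pytest.approx(0.1, abs=1e-9)

    def test_gaussian_prediction_worked_value(self):
        p = MixtureParams(0.3, 1.0, 100, 0.0, 1.0, 900)
        pred = gaussian_mixture_prevalence(p, [1.0], "above")
        assert pred["predicted_fraction"].iloc[0] == pytest.approx(0.145, abs=5e-4)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            MixtureParams(0, 0.0, 10, 0, 1.0, 10)


class TestASPAndAUC:
    def test_asp_baseline_exceeds_population_prevalence(self, small_binary_cohort):
        # family-shared liability makes ASP controls enriched for risk
        c = small_binary_cohort
        sib = c.pedigree.sib_ids()
        gv = c.truth.genetic_values.reindex(sib)
        z = (gv - gv.mean()) / gv.std()
        status = c.phenotypes.values
        curve = asp_prevalence(z, status, c.pedigree, [0.0], "above", with_mixture=False)
        assert curve.attrs["overall_prevalence"] > status.reindex(sib).mean() * 0.9

    def test_auc_report_null_scores(self, small_binary_cohort):
        c = small_binary_cohort
        sib = c.pedigree.sib_ids()
        rng = np.random.default_rng(7)
        scores = make_scores(sib, rng.normal(size=(len(sib), 3)))
        rep = auc_report(scores, c.phenotypes.values, c.pedigree)
        row = rep[rep["cohort"] == "all"].iloc[0]
        assert row["auc"] == pytest.approx(0.5, abs=0.05)

    def test_auc_report_informative_scores_shape(self, small_binary_cohort):
        c = small_binary_cohort
        sib = c.pedigree.sib_ids()
        gv = c.truth.genetic_values.reindex(sib).to_numpy()
        scores = make_scores(sib, np.column_stack([gv, gv]))
        rep = auc_report(scores, c.phenotypes.values, c.pedigree)
        assert set(rep["cohort"]) == {"all", "asp"}
        a_all = rep.loc[rep["cohort"] == "all", "auc"].iloc[0]
        a_asp = rep.loc[rep["cohort"] == "asp", "auc"].iloc[0]
        assert a_all > 0.6
        assert abs(a_all - a_asp) < 0.1  # modest ASP decrease


class TestTrios:
    def _trio_setup(self, z_by_id, status_by_id):
        n_fam = len(z_by_id) // 3
        trios = pd.DataFrame(
            [(f"f{i}a", f"f{i}b", f"f{i}c", f"FAM{i}") for i in range(n_fam)],
            columns=["id_a", "id_b", "id_c", "family_id"],
        )
        ids = list(z_by_id)
        scores = make_scores(ids, [z_by_id[i] for i in ids])
        status = pd.Series({i: status_by_id[i] for i in ids})
        return trios, scores, status

    def test_case_highest_always(self):
        trios, scores, status = self._trio_setup(
            {"f0a": 3.0, "f0b": 1.0, "f0c": 0.0}, {"f0a": 1, "f0b": 0, "f0c": 0}
        )
        assert trio_call_rate(trios, scores, status).fraction == 1.0

    def test_tie_shares_credit(self):
        trios, scores, status = self._trio_setup(
            {"f0a": 2.0, "f0b": 2.0, "f0c": 0.0}, {"f0a": 1, "f0b": 0, "f0c": 0}
        )
        assert trio_call_rate(trios, scores, status).fraction == 0.5

    def test_null_scores_one_third(self):
        rng = np.random.default_rng(8)
        n = 4000
        z_by_id, status_by_id = {}, {}
        for i in range(n):
            vals = rng.normal(size=3)
            for j, tag in enumerate("abc"):
                z_by_id[f"f{i}{tag}"] = vals[j]
                status_by_id[f"f{i}{tag}"] = 1.0 if j == 0 else 0.0
        trios, scores, status = self._trio_setup(z_by_id, status_by_id)
        f = trio_call_rate(trios, scores, status)
        assert f.fraction == pytest.approx(1 / 3, abs=3 * np.sqrt(2 / 9 / n))

    def test_mixture_moment_estimation(self):
        rng = np.random.default_rng(9)
        z = pd.Series(np.concatenate([rng.normal(0.4, 1.2, 5000), rng.normal(0, 1, 5000)]),
                      index=[f"i{i}" for i in range(10_000)])
        status = pd.Series(np.r_[np.ones(5000), np.zeros(5000)], index=z.index)
        p = estimate_mixture(z, status)
        assert p.mu_case == pytest.approx(0.4, abs=0.05)
        assert p.sd_case == pytest.approx(1.2, abs=0.05)
        assert p.n_case == 5000
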