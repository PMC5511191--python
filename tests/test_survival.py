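"""Survival arm: eligibility, LOOCV labels, KM, log-rank, rank-sum."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import prognosig as pg
from prognosig.survival import (
    EligibilityRule,
    check_eligibility,
    cohort_size_effect,
    kaplan_meier,
    logrank_test,
    loocv_nearest_centroid,
)

from conftest import hypergeom_logrank


def _cohort(expr, time, event, genes=None):
    n = len(time)
    ids = [f"s{i}" for i in range(n)]
    genes = genes or [f"g{j}" for j in range(np.asarray(expr).shape[1])]
    return pg.SurvivalCohort(
        pd.DataFrame(expr, index=ids, columns=genes),
        pd.Series(time, index=ids, dtype=float),
        pd.Series(event, index=ids),
    )


class TestEligibility:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.expr = rng.normal(size=(60, 30))
        self.genes = [f"g{j}" for j in range(30)]

    def _make(self, n, death_rate):
        ev = np.zeros(n, dtype=int)
        ev[: int(round(death_rate * n))] = 1
        rng = np.random.default_rng(1)
        return _cohort(rng.normal(size=(n, 30)), rng.uniform(1, 10, n), ev)

    def test_small_cohort_fails_min_samples(self):
        res = check_eligibility(self._make(49, 0.5), self.genes)
        assert not res.passed and res.reasons == ("min_samples",)

    def test_death_rate_boundaries_are_inclusive(self):
        assert check_eligibility(self._make(60, 0.10), self.genes).passed
        assert check_eligibility(self._make(60, 0.90), self.genes).passed
        res = check_eligibility(self._make(100, 0.09), self.genes)
        assert res.reasons == ("death_rate",)

    def test_too_few_signature_genes(self):
        res = check_eligibility(self._make(60, 0.5), self.genes[:24])
        assert res.reasons == ("min_signature_genes",)
        assert check_eligibility(self._make(60, 0.5), self.genes[:25]).passed


class TestLoocvNearestCentroid:
    def test_separable_limit_reproduces_event_status(self):
        rng = np.random.default_rng(2)
        n, g = 80, 20
        ev = (rng.random(n) < 0.5).astype(int)
        expr = rng.normal(size=(n, g))
        expr[ev == 1] += 5.0  # +5 SD shift in every signature gene
        co = _cohort(expr, rng.uniform(1, 5, n), ev)
        risk = loocv_nearest_centroid(co, list(co.gene_ids))
        assert (risk.high_risk_mask.to_numpy() == (ev == 1)).all()

    def test_null_agreement_near_chance(self):
        agree = []
        for s in range(30):
            rng = np.random.default_rng(s)
            n = 100
            ev = (rng.random(n) < 0.5).astype(int)
            co = _cohort(rng.normal(size=(n, 30)), rng.uniform(1, 5, n), ev)
            risk = loocv_nearest_centroid(co, list(co.gene_ids))
            agree.append((risk.high_risk_mask.to_numpy() == (ev == 1)).mean())
        assert np.mean(agree) == pytest.approx(0.5, abs=0.05)

    def test_invariant_to_sample_and_gene_order(self, planted_cohort, signature_genes):
        base = loocv_nearest_centroid(planted_cohort, signature_genes)
        rng = np.random.default_rng(0)
        perm = rng.permutation(planted_cohort.n_samples)
        gperm = rng.permutation(len(planted_cohort.gene_ids))
        shuffled = pg.SurvivalCohort(
            planted_cohort.expression.iloc[perm, gperm],
            planted_cohort.time.iloc[perm],
            planted_cohort.event.iloc[perm],
        )
        out = loocv_nearest_centroid(shuffled, signature_genes)
        pd.testing.assert_series_equal(
            base.labels.sort_index(), out.labels.sort_index()
        )

    def test_unbalanced_remainder_rejected(self):
        rng = np.random.default_rng(3)
        co = _cohort(rng.normal(size=(10, 5)), rng.uniform(1, 5, 10),
                     [1] + [0] * 9)
        with pytest.raises(ValueError, match="unbalanced"):
            loocv_nearest_centroid(co, list(co.gene_ids))

    @pytest.mark.parametrize("metric", ["pearson", "spearman"])
    def test_alternative_metrics_run(self, planted_cohort, signature_genes, metric):
        risk = loocv_nearest_centroid(planted_cohort, signature_genes, metric)
        assert set(risk.labels.unique()) <= {"high_risk", "low_risk"}


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        assert km["survival"].tolist() == [0.75, 0.5, 0.25, 0.0]

    def test_censoring_shrinks_risk_set(self):
        # censor at t=1, death at t=2: risk set at 2 is a single sample
        km = kaplan_meier([1, 2], [0, 1])
        assert km["survival"].tolist() == [0.0]
        assert km["n_at_risk"].tolist() == [1]

    def test_no_events_warns_and_returns_unit_survival(self):
        with pytest.warns(UserWarning, match="no events"):
            km = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert km.empty

    def test_random_no_censoring_matches_ecdf(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(1, 50)
        km = kaplan_meier(t, np.ones(50, dtype=int))
        for _, row in km.iterrows():
            assert row["survival"] == pytest.approx((t > row["time"]).mean())

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 100)
        e = (rng.random(100) < 0.7).astype(int)
        km = kaplan_meier(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        for _, row in km.iterrows():
            ours = row["survival"]
            theirs = float(kmf.survival_function_at_times(row["time"]).iloc[0])
            assert ours == pytest.approx(theirs, abs=1e-12)


class TestLogRank:
    def test_identical_groups_give_null_result(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1] * 8
        lab = ["high_risk"] * 4 + ["low_risk"] * 4
        res = logrank_test(t, e, lab)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-12)

    def test_toy_separated_groups_match_risk_table_oracle(self):
        # group A dies at (1, 2), group B at (3, 4), no censoring
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 1, 1]
        lab = ["high_risk", "high_risk", "low_risk", "low_risk"]
        res = logrank_test(t, e, lab)
        chi2, p, hr = hypergeom_logrank(t, e, np.array([1, 1, 0, 0], bool))
        assert res.chi_square == pytest.approx(chi2, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)
        assert res.hazard_ratio == pytest.approx(hr, abs=1e-12)

    def test_oracle_agreement_random_small_cohorts(self):
        """200 random cohorts (n <= 12) vs the hypergeometric oracle, 10 decimals."""
        rng = np.random.default_rng(6)
        checked = 0
        while checked < 200:
            n = int(rng.integers(4, 13))
            t = np.round(rng.exponential(1, n), 2) + 0.01
            e = (rng.random(n) < 0.8).astype(int)
            grp = rng.random(n) < 0.5
            if e[grp].sum() == 0 or e[~grp].sum() == 0 or grp.all() or not grp.any():
                continue
            lab = np.where(grp, "high_risk", "low_risk")
            res = logrank_test(t, e, lab)
            chi2, p, hr = hypergeom_logrank(t, e, grp)
            assert res.chi_square == pytest.approx(chi2, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)
            if np.isfinite(res.hazard_ratio) and not np.isnan(hr):
                assert res.hazard_ratio == pytest.approx(hr, abs=1e-10)
            checked += 1

    def test_matches_lifelines_chi_square(self, planted_cohort, signature_genes):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        risk = loocv_nearest_centroid(planted_cohort, signature_genes)
        res = logrank_test(planted_cohort.time, planted_cohort.event, risk.labels)
        mask = risk.high_risk_mask.to_numpy()
        ref = lifelines_stats.logrank_test(
            planted_cohort.time[mask], planted_cohort.time[~mask],
            planted_cohort.event[mask], planted_cohort.event[~mask],
        )
        assert res.chi_square == pytest.approx(ref.test_statistic, rel=1e-10)

    def test_one_group_rejected(self):
        with pytest.raises(ValueError, match="two"):
            logrank_test([1, 2], [1, 1], ["high_risk", "high_risk"])

    def test_planted_hazard_ratio_recovered(self, planted_cohort, signature_genes):
        risk = loocv_nearest_centroid(planted_cohort, signature_genes)
        res = logrank_test(planted_cohort.time, planted_cohort.event, risk.labels)
        assert res.p_value < 0.05
        assert 1.8 <= res.hazard_ratio <= 3.5

    def test_median_estimated_hr_monotone_in_planted_hr(self, signature_genes):
        medians = []
        for hr in (1.0, 1.5, 2.0, 3.0):
            ests = []
            for s in range(8):
                co = pg.generate_survival_cohort(pg.CohortSimConfig(
                    n_samples=250, n_genes=120, signature_indices=tuple(range(60)),
                    hazard_ratio=hr, expression_shift=1.0, censor_rate=0.3,
                    seed=1000 + s,
                ))
                risk = loocv_nearest_centroid(co, signature_genes)
                ests.append(logrank_test(co.time, co.event, risk.labels).hazard_ratio)
            medians.append(np.median(ests))
        assert medians == sorted(medians)


class TestCohortSizeEffect:
    def test_identical_samples_give_p_one_region(self):
        data = [(100, 0.01), (200, 0.01), (300, 0.01),
                (100, 0.5), (200, 0.5), (300, 0.5)]
        assert cohort_size_effect(data) > 0.5

    def test_exact_enumeration_value_for_separated_sizes(self):
        # significant sizes (500..800) all above non-significant (50..80):
        # the most extreme of C(8,4)=70 arrangements, two-sided p = 2/70
        data = [(s, 0.01) for s in (500, 600, 700, 800)] + \
               [(s, 0.9) for s in (50, 60, 70, 80)]
        assert cohort_size_effect(data) == pytest.approx(2 / 70)

    def test_rank_invariance_under_constant_shift(self):
        base = [(100, 0.01), (250, 0.01), (80, 0.5), (90, 0.5), (60, 0.5)]
        shifted = [(n + 1000, p) for n, p in base]
        assert cohort_size_effect(base) == pytest.approx(cohort_size_effect(shifted))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="both"):
            cohort_size_effect([(100, 0.01), (200, 0.02)])


class TestSurvivalScreen:
    def test_planted_screen_recovers_membership(self, signature_genes):
        datasets = []
        truth = []
        for i in range(6):
            hr = 2.5 if i % 2 == 0 else 1.0
            truth.append(hr > 1)
            co = pg.generate_survival_cohort(pg.CohortSimConfig(
                n_samples=250, n_genes=120, signature_indices=tuple(range(60)),
                hazard_ratio=hr, expression_shift=1.0 if hr > 1 else 0.0,
                censor_rate=0.3, seed=50 + i,
            ))
            co.name = f"d{i}"
            datasets.append(co)
        screen, summary = pg.run_survival_screen(datasets, signature_genes)
        flags = screen["significant"].tolist()
        sens = np.mean([f for f, t in zip(flags, truth) if t])
        fps = sum(f for f, t in zip(flags, truth) if not t)
        assert sens >= 0.8
        assert fps <= 1
        # summary counts shrink (weakly) as the size threshold rises
        assert summary["n_significant"].is_monotonic_decreasing

    def test_ineligible_datasets_reported_not_raised(self, signature_genes):
        rng = np.random.default_rng(1)
        co = _cohort(rng.normal(size=(30, 120)), rng.uniform(1, 5, 30),
                     (rng.random(30) < 0.5).astype(int),
                     genes=[f"G{i + 1:06d}" for i in range(120)])
        screen, _ = pg.run_survival_screen([co], signature_genes)
        assert not screen.loc[0, "eligible"]
        assert "min_samples" in screen.loc[0, "note"]
        assert np.isnan(screen.loc[0, "p"])
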