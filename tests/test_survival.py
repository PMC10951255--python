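import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import stats

from msihetero.segmentation import compositions, segment_cohort
from msihetero.survival import (
    aic_grid,
    cox_fit,
    cox_score_test,
    heterogeneity_response_fisher,
    km_estimate,
    logrank_test,
    pairwise_subpop_survival,
    presence_matrix,
    response_association,
)
from msihetero.types import ClusterComposition, SurvivalRecord


def make_surv(times, events, prefix="P"):
    return [
        SurvivalRecord(f"{prefix}{i:03d}", float(t), int(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


def sim_cox_data(seed, n=120, beta=(1.0, -0.5), cens_scale=30.0, untied=True):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, len(beta))) < 0.4).astype(float)
    lam = 0.05 * np.exp(X @ np.array(beta))
    T = rng.exponential(1 / lam)
    C = rng.exponential(cens_scale, n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    if untied:
        time = time + rng.random(n) * 1e-9
    return X, time, event


class TestPresenceMatrix:
    def _comps(self, shares_list):
        return [
            ClusterComposition(f"P{i}", np.array(s), 100) for i, s in enumerate(shares_list)
        ]

    def test_strict_threshold(self):
        pm = presence_matrix(self._comps([[0.25, 0.75], [0.24, 0.76]]), 0.24)
        assert pm.matrix[0, 0] == 1
        assert pm.matrix[1, 0] == 0

    def test_multi_assignment(self):
        pm = presence_matrix(self._comps([[0.5, 0.3, 0.2]]), 0.1)
        assert pm.matrix[0].tolist() == [1, 1, 1]

    def test_admissibility_flags(self):
        pm = presence_matrix(self._comps([[0.6, 0.4], [0.7, 0.3]]), 0.5)
        # first column all ones, second all zeros -> both inadmissible
        assert pm.admissible.tolist() == [False, False]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        comps = self._comps([list(rng.dirichlet(np.ones(4))) for _ in range(20)])
        prev = presence_matrix(comps, 0.05).matrix
        for t in (0.1, 0.2, 0.4, 0.8):
            cur = presence_matrix(comps, t).matrix
            assert np.all(cur <= prev)
            prev = cur


class TestCoxFit:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(np.ones(10), times=np.arange(1, 11.0), events=np.ones(10, int))

    def test_aic_formula(self):
        X, time, event = sim_cox_data(0, n=60, beta=(0.8,))
        fit = cox_fit(X, times=time, events=event)
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik, abs=1e-12)

    def test_hr3_recovered(self):
        X, time, event = sim_cox_data(7, n=200, beta=(np.log(3.0),), cens_scale=np.inf)
        fit = cox_fit(X, times=time, events=event)
        assert 2.4 <= fit.hazard_ratios[0] <= 3.75

    def test_matches_lifelines(self):
        X, time, event = sim_cox_data(1)
        fit = cox_fit(X, times=time, events=event)
        df = pd.DataFrame({"T": time, "E": event, "x1": X[:, 0], "x2": X[:, 1]})
        cph = CoxPHFitter()
        cph.fit(df, "T", "E", formula="x1+x2")
        assert np.allclose(fit.beta, cph.params_.values, atol=1e-4)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-5)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-5)

    def test_robust_clustered_matches_lifelines(self):
        X, time, event = sim_cox_data(2, n=100)
        ids = [f"c{i // 2}" for i in range(100)]  # two records per cluster
        fit = cox_fit(X, times=time, events=event, cluster=ids)
        df = pd.DataFrame(
            {"T": time, "E": event, "x1": X[:, 0], "x2": X[:, 1], "id": ids}
        )
        cph = CoxPHFitter()
        cph.fit(df, "T", "E", formula="x1+x2", robust=True, cluster_col="id")
        assert np.allclose(fit.robust_se, cph.standard_errors_.values, rtol=1e-3)

    def test_nested_aic_difference_is_exact(self):
        X, time, event = sim_cox_data(3)
        full = cox_fit(X, times=time, events=event)
        reduced = cox_fit(X[:, :1], times=time, events=event)
        delta = full.aic - reduced.aic
        assert delta == pytest.approx(2 * 1 - 2 * (full.loglik - reduced.loglik), abs=1e-9)

    def test_monotone_likelihood_flagged(self):
        # perfectly separating covariate -> no finite maximiser
        time = np.array([1.0, 2, 3, 10, 11, 12])
        event = np.ones(6, int)
        X = np.array([1.0, 1, 1, 0, 0, 0]).reshape(-1, 1)
        fit = cox_fit(X, times=time, events=event)
        assert not fit.converged

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(
                np.arange(5.0), times=np.arange(1, 6.0), events=np.zeros(5, int)
            )


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.empty  # no drops: S(t) = 1 everywhere

    def test_all_events(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert km["survival"].tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_with_censoring(self):
        # (1+, 2, 3): S(2) = 1/2, S(3) = 0
        km = km_estimate([1.0, 2.0, 3.0], [0, 1, 1])
        assert km["time"].tolist() == [2.0, 3.0]
        assert km["survival"].tolist() == pytest.approx([0.5, 0.0])

    def test_matches_lifelines(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 50).round(0) + 1
        e = (rng.random(50) < 0.7).astype(int)
        km = km_estimate(t, e)
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter()
        kmf.fit(t, e)
        for _, row in km.iterrows():
            assert kmf.predict(row["time"]) == pytest.approx(row["survival"], abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups(self):
        t = np.array([1.0, 2, 3, 4])
        e = np.array([1, 1, 0, 1])
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups(self):
        _, p = logrank_test([1, 2, 3], [1, 1, 1], [10, 20, 30], [1, 1, 1])
        assert p < 0.05

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        ta, tb = rng.exponential(5, 20), rng.exponential(9, 25)
        ea = (rng.random(20) < 0.8).astype(int)
        eb = (rng.random(25) < 0.8).astype(int)
        assert logrank_test(ta, ea, tb, eb) == pytest.approx(logrank_test(tb, eb, ta, ea))

    def test_equals_cox_score_test_untied(self):
        rng = np.random.default_rng(7)
        n = 80
        g = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(10 * (1 + g), n) + rng.random(n) * 1e-9
        e = (rng.random(n) < 0.8).astype(int)
        chi2_lr, p_lr = logrank_test(t[g == 1], e[g == 1], t[g == 0], e[g == 0])
        chi2_sc, p_sc = cox_score_test(g, t, e)
        assert chi2_lr == pytest.approx(chi2_sc, abs=1e-6)
        assert p_lr == pytest.approx(p_sc, abs=1e-9)


@pytest.fixture(scope="module")
def grid_setup(cohort, normalized_cubes):
    segs = segment_cohort(normalized_cubes, range(2, 5), seed=0, n_init=3)
    comps = {k: compositions(segs[k]) for k in segs}
    return comps, cohort.survival


class TestAicGrid:
    def test_deterministic(self, grid_setup):
        comps, surv = grid_setup
        a = aic_grid(comps, surv)
        b = aic_grid(comps, surv)
        pd.testing.assert_frame_equal(a.entries, b.entries)
        assert a.optimum == b.optimum

    def test_scaled_grid_in_unit_interval(self, grid_setup):
        comps, surv = grid_setup
        scaled = aic_grid(comps, surv).scaled()
        ok = scaled["converged"]
        assert scaled.loc[ok, "aic_scaled"].between(0, 1).all()

    def test_optimum_minimises_aic(self, grid_setup):
        comps, surv = grid_setup
        grid = aic_grid(comps, surv)
        ok = grid.entries[grid.entries["converged"]]
        k_star, t_star = grid.optimum
        best = ok.loc[(ok["k"] == k_star) & (ok["threshold"] == t_star), "aic"].iloc[0]
        assert best == ok["aic"].min()


class TestPairwise:
    def test_disjoint_reduces_to_two_group_cox(self):
        rng = np.random.default_rng(8)
        n = 40
        comps = []
        for i in range(n):
            shares = [0.9, 0.1] if i < 20 else [0.1, 0.9]
            comps.append(ClusterComposition(f"P{i:03d}", np.array(shares), 100))
        t = np.concatenate([rng.exponential(5, 20), rng.exponential(15, 20)])
        surv = make_surv(t, np.ones(n))
        pm = presence_matrix(comps, 0.5)
        res = pairwise_subpop_survival(pm, surv)
        row = res[(res["cluster_i"] == 1) & (res["cluster_j"] == 2)].iloc[0]
        grp = np.array([0.0] * 20 + [1.0] * 20)
        ids = [f"P{i:03d}" for i in range(n)]
        fit = cox_fit(grp, times=t, events=np.ones(n, int), cluster=ids)
        assert row["log_hr"] == pytest.approx(fit.beta[0], abs=1e-9)
        assert row["wald_p"] == pytest.approx(fit.wald_p(robust=True)[0], abs=1e-9)

    def test_same_cluster_degenerate(self):
        comps = [
            ClusterComposition(f"P{i}", np.array([0.6, 0.4]), 50) for i in range(6)
        ]
        surv = make_surv(np.arange(1, 7.0), np.ones(6))
        res = pairwise_subpop_survival(presence_matrix(comps, 0.3), surv)
        row = res[(res["cluster_i"] == 1) & (res["cluster_j"] == 1)].iloc[0]
        assert row["wald_p"] == 1.0 and row["status"] == "degenerate"

    def test_planted_hazard_difference_detected(self):
        detected = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 100
            comps = [
                ClusterComposition(
                    f"P{i:03d}", np.array([0.8, 0.2]) if i < 50 else np.array([0.2, 0.8]), 100
                )
                for i in range(n)
            ]
            lam = np.where(np.arange(n) < 50, np.log(2) / 5, np.log(2) / 15)
            t = rng.exponential(1 / lam)
            surv = make_surv(t, np.ones(n))
            res = pairwise_subpop_survival(presence_matrix(comps, 0.5), surv)
            row = res[(res["cluster_i"] == 1) & (res["cluster_j"] == 2)].iloc[0]
            detected += row["wald_p"] < 0.05
        assert detected >= 8

    def test_insufficient_members(self):
        comps = [ClusterComposition("P0", np.array([1.0, 0.0]), 10)] + [
            ClusterComposition(f"P{i}", np.array([0.0, 1.0]), 10) for i in range(1, 8)
        ]
        surv = make_surv(np.arange(1, 9.0), np.ones(8))
        res = pairwise_subpop_survival(presence_matrix(comps, 0.5), surv)
        row = res[(res["cluster_i"] == 1) & (res["cluster_j"] == 2)].iloc[0]
        assert row["status"] == "insufficient"


class TestResponseAssociation:
    def test_perfect_agreement(self):
        pres = np.array([1, 1, 1, 0, 0, 0])
        rho, _ = response_association(pres, pres.copy())
        assert rho == pytest.approx(1.0)

    def test_fisher_hand_table(self):
        # [[3,1],[1,3]]: two-sided p = 34/70
        groups = ["high"] * 4 + ["low"] * 4
        resp = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        _, p, table = heterogeneity_response_fisher(groups, resp)
        assert table.tolist() == [[3, 1], [1, 3]]
        assert p == pytest.approx(34 / 70, abs=1e-12)

    def test_degenerate_presence_rejected(self):
        with pytest.raises(ValueError):
            response_association(np.ones(6, int), np.array([1, 0, 1, 0, 1, 0]))

    def test_unknown_responses_excluded(self):
        pres = np.array([1, 0, 1, 0, 1, 0])
        resp = np.array([1, 0, 1, 0, -1, -1])
        rho, _ = response_association(pres, resp)
        assert rho == pytest.approx(1.0)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(9)
        hits = 0
        reps = 300
        for _ in range(reps):
            pres = (rng.random(40) < 0.5).astype(int)
            resp = (rng.random(40) < 0.5).astype(int)
            if pres.min() == pres.max() or resp.min() == resp.max():
                continue
            _, p = response_association(pres, resp)
            hits += p < 0.05
        assert 0.01 <= hits / reps <= 0.10
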