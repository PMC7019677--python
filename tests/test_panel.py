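"""Logistic risk scores and the greedy AUC-ordered combination path."""
import numpy as np
import pandas as pd
import pytest

import salivadx as sx
from salivadx.panel import rank_by_auc

from conftest import make_expression


def _logistic_data(beta, n, seed, intercept=0.0):
    """Markers ~ lognormal; labels from the logistic model with given betas."""
    rng = np.random.default_rng(seed)
    X = rng.lognormal(0.0, 0.5, size=(n, len(beta)))
    eta = intercept + X @ np.asarray(beta)
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    ids = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    expr = pd.DataFrame(X, columns=[f"g{j}" for j in range(len(beta))], index=ids)
    meta = pd.DataFrame({"group": np.where(y, "case", "control")}, index=ids)
    return sx.ExpressionMatrix(expr, meta)


class TestFitRiskScore:
    def test_uninformative_marker_coefficient_near_zero(self):
        rng = np.random.default_rng(8)
        n = 4000
        ids = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        expr = pd.DataFrame({"g": rng.lognormal(0, 0.4, n)}, index=ids)
        meta = pd.DataFrame({"group": ["control", "case"] * (n // 2)}, index=ids)
        em = sx.ExpressionMatrix(expr, meta)
        m = sx.fit_risk_score(em, ["g"])
        assert abs(m.coefficients["g"]) < 0.1
        assert m.auc == pytest.approx(0.5, abs=0.03)

    def test_single_marker_panel_equals_univariate_auc(self, expr):
        for g in expr.genes:
            m = sx.fit_risk_score(expr, [g])
            direction = "higher" if m.coefficients[g] > 0 else "lower"
            uni = sx.auc(expr.expr[g].to_numpy(), expr.labels, direction)
            assert m.auc == pytest.approx(uni, abs=1e-12)

    def test_parameter_recovery_within_ten_percent(self):
        beta = [1.5, -2.0]
        em = _logistic_data(beta, n=5000, seed=77)
        m = sx.fit_risk_score(em, ["g0", "g1"])
        for b_true, g in zip(beta, ["g0", "g1"]):
            assert m.coefficients[g] == pytest.approx(b_true, rel=0.10)

    def test_constant_marker_rejected(self):
        em = make_expression({"A": [1.0, 1.0, 1.0]}, {"A": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            sx.fit_risk_score(em, ["A"])

    def test_separation_flagged_but_scored(self):
        em = make_expression({"A": [3.0, 4.0, 5.0]}, {"A": [1.0, 1.5, 2.0]})
        m = sx.fit_risk_score(em, ["A"])
        assert m.separation
        assert m.auc == 1.0

    def test_affine_marker_rescaling_leaves_auc_unchanged(self, expr):
        m1 = sx.fit_risk_score(expr, ["SIAE", "NAB2"])
        scaled = sx.ExpressionMatrix(
            expr.expr.assign(SIAE=expr.expr["SIAE"] * 100.0), expr.metadata)
        m2 = sx.fit_risk_score(scaled, ["SIAE", "NAB2"])
        assert m2.auc == pytest.approx(m1.auc, abs=1e-9)


def greedy_oracle(em, direction="lower"):
    """Independent re-implementation of the combination loop: rank markers by
    univariate pairwise-count AUC, then grow the panel one marker at a time,
    refitting an (unpenalised) sklearn logistic model at each step."""
    from sklearn.linear_model import LogisticRegression

    y = em.labels
    uni = []
    for g in em.genes:
        s = em.expr[g].to_numpy()
        case, ctrl = s[y == 1], s[y == 0]
        tot = cor = 0.0
        for c in case:
            for k in ctrl:
                tot += 1
                cor += 0.5 if c == k else float((c < k) == (direction == "lower"))
        # tie rule: larger standardized mean difference first, then gene name
        case_v, ctrl_v = s[y == 1], s[y == 0]
        pooled = np.sqrt(((len(ctrl_v) - 1) * ctrl_v.var(ddof=1)
                          + (len(case_v) - 1) * case_v.var(ddof=1))
                         / (len(s) - 2))
        eff = abs(ctrl_v.mean() - case_v.mean()) / pooled if pooled else 0.0
        uni.append((g, cor / tot, eff))
    order = [g for g, _, _ in sorted(uni, key=lambda t: (-t[1], -t[2], t[0]))]
    path = []
    for k in range(2, len(order) + 1):
        X = em.expr[order[:k]].to_numpy()
        lr = LogisticRegression(penalty=None, max_iter=5000).fit(X, y)
        scores = lr.decision_function(X)
        # pairwise AUC of the risk score, higher = disease
        case, ctrl = scores[y == 1], scores[y == 0]
        tot = cor = 0.0
        for c in case:
            for kk in ctrl:
                tot += 1
                cor += 0.5 if c == kk else float(c > kk)
        path.append((tuple(order[:k]), cor / tot))
    return order, path


class TestGreedyCombine:
    def test_first_panel_is_top_two_by_auc(self):
        rng = np.random.default_rng(3)
        n = 60
        # construct three markers with clearly distinct separation
        ctrl = {"hi": rng.normal(5, 1, n), "mid": rng.normal(2, 1, n),
                "lo": rng.normal(0.8, 1, n)}
        case = {"hi": rng.normal(0, 1, n), "mid": rng.normal(0, 1, n),
                "lo": rng.normal(0, 1, n)}
        em = make_expression({k: np.exp(v / 10) for k, v in ctrl.items()},
                             {k: np.exp(v / 10) for k, v in case.items()})
        panels = sx.greedy_combine(em)
        first_multi = next(p for p in panels if len(p.markers) == 2)
        assert set(first_multi.markers) == {"hi", "mid"}

    def test_two_candidates_minimal_output(self, expr):
        panels = sx.greedy_combine(expr, ["SIAE", "NAB2"])
        sizes = sorted(len(p.markers) for p in panels)
        assert sizes == [1, 1, 2]

    def test_candidate_order_invariance(self, expr):
        a = sx.greedy_combine(expr, ["SIAE", "MAOB", "NAB2"])
        b = sx.greedy_combine(expr, ["NAB2", "SIAE", "MAOB"])
        assert [p.markers for p in a] == [p.markers for p in b]
        for pa, pb in zip(a, b):
            assert pa.auc == pytest.approx(pb.auc, abs=1e-12)

    def test_matches_independent_oracle(self):
        """Full inclusion sequence and per-step AUCs equal the independent
        re-implementation on seeded six-gene cohorts."""
        cfg = sx.default_config()
        for seed in (101, 202):
            em = sx.simulate_cohort(cfg, seed=seed).expression
            order, path = greedy_oracle(em)
            panels = [p for p in sx.greedy_combine(em) if len(p.markers) > 1]
            assert [tuple(p.markers) for p in panels] == [m for m, _ in path]
            for p, (_, a) in zip(panels, path):
                assert p.auc == pytest.approx(a, abs=1e-6)

    def test_rank_table_sorted_descending(self, expr):
        ranked = rank_by_auc(expr)
        assert list(ranked["auc"]) == sorted(ranked["auc"], reverse=True)

    def test_nested_panels_nondecreasing_auc_at_large_n(self):
        """In-sample AUC grows with panel size when data truly follow the
        larger logistic model (checked at n = 10,000)."""
        em = _logistic_data([1.2, -0.8, 0.5], n=10_000, seed=9)
        panels = [p for p in sx.greedy_combine(em, direction="higher")
                  if len(p.markers) > 1]
        aucs = [p.auc for p in panels]
        assert all(b >= a - 1e-9 for a, b in zip(aucs, aucs[1:]))

    def test_frozen_strategy_runs_and_matches_refit_at_step_one(self, expr):
        refit = [p for p in sx.greedy_combine(expr) if len(p.markers) == 2][0]
        frozen = [p for p in sx.greedy_combine(expr, strategy="frozen")
                  if len(p.markers) == 2][0]
        assert frozen.markers == refit.markers
        assert frozen.auc == pytest.approx(refit.auc, abs=1e-9)


class TestEvaluatePanels:
    def test_perfectly_separating_panel(self):
        em = make_expression({"A": [3.0, 4.0, 5.0]}, {"A": [1.0, 1.5, 2.0]})
        m = sx.fit_risk_score(em, ["A"])
        r, = sx.evaluate_panels([m], pd.Series(em.labels, index=em.sample_ids),
                                n_boot=200)
        assert r.auc == 1.0

    def test_evaluation_deterministic(self, expr):
        m = sx.fit_risk_score(expr, ["SIAE", "NAB2"])
        labels = pd.Series(expr.labels, index=expr.sample_ids)
        r1, = sx.evaluate_panels([m], labels, n_boot=300, seed=5)
        r2, = sx.evaluate_panels([m], labels, n_boot=300, seed=5)
        assert (r1.auc, r1.ci_low, r1.ci_high) == (r2.auc, r2.ci_low, r2.ci_high)

    def test_in_sample_auc_approaches_binormal_closed_form(self):
        """Two independent unit-variance markers whose mean-shift vector has
        length d: any linear score has AUC at most Phi(d / sqrt(2)), attained
        by the Fisher direction; at n = 10,000 the fitted panel gets close."""
        from scipy.stats import norm
        d = 1.0
        rng = np.random.default_rng(31)
        n = 10_000
        X0 = rng.normal(d / np.sqrt(2), 1, size=(n, 2))
        X1 = rng.normal(0, 1, size=(n, 2))
        ids = pd.Index([f"s{i}" for i in range(2 * n)], name="sample_id")
        expr = pd.DataFrame(np.vstack([X0, X1]) + 10.0, columns=["a", "b"], index=ids)
        meta = pd.DataFrame({"group": ["control"] * n + ["case"] * n}, index=ids)
        em = sx.ExpressionMatrix(expr, meta)
        m = sx.fit_risk_score(em, ["a", "b"])
        assert m.auc == pytest.approx(norm.cdf(d / np.sqrt(2)), abs=0.02)


def test_cross_validated_auc_below_apparent_on_small_noisy_data():
    em = _logistic_data([0.8], n=80, seed=55)
    apparent = sx.fit_risk_score(em, ["g0"]).auc
    cv = sx.cross_validated_auc(em, ["g0"], seed=1)
    assert 0.0 <= cv <= 1.0
    assert cv <= apparent + 0.05
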