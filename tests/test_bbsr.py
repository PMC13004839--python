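from itertools import combinations

import numpy as np
import pytest

from gremnet.bbsr import (
    BBSRConfig,
    RSS_FLOOR_REL,
    bbsr_gene,
    infer_network,
    preselect_predictors,
    score_subset,
    summarize_tf_degrees,
)
from gremnet.pipeline import edge_recovery_aupr
from gremnet.synthetic import generate_expression
from gremnet.types import ActivityMatrix, ExpressionMatrix, NetworkMatrix


def _activities(vals, tf_ids=None):
    vals = np.asarray(vals, dtype=float)
    tf_ids = tf_ids or [f"TF{i}" for i in range(vals.shape[1])]
    return ActivityMatrix(vals, [f"s{i}" for i in range(vals.shape[0])], tf_ids)


# ---------------------------------------------------------------------------
# independent oracle: explicit normal-equations enumeration on design matrices


def brute_force_bbsr(y, z, candidates, max_k, floor_rel=RSS_FLOOR_REL):
    """Exhaustive enumeration with per-subset design-matrix OLS; returns
    (best subset indices, best bic, model-averaged betas)."""
    y = np.asarray(y, float)
    n = len(y)
    yc = y - y.mean()
    tss = float(yc @ yc)
    floor = max(tss * floor_rel, 1e-300)
    entries = []
    for k in range(0, max_k + 1):
        for sub in combinations(range(len(candidates)), k):
            if sub:
                zc = z[:, list(sub)] - z[:, list(sub)].mean(axis=0)
                beta = np.linalg.lstsq(zc, yc, rcond=None)[0]
                rss = float(((yc - zc @ beta) ** 2).sum())
            else:
                beta = np.zeros(0)
                rss = tss
            bic = n * np.log(max(rss, floor) / n) + k * np.log(n)
            entries.append((sub, rss, bic, beta))
    best = min(
        entries,
        key=lambda e: (e[2], len(e[0]), tuple(sorted(candidates[i] for i in e[0]))),
    )
    bics = np.array([e[2] for e in entries])
    w = np.exp(-0.5 * (bics - bics.min()))
    w /= w.sum()
    beta_bar = np.zeros(len(candidates))
    for wi, (sub, _, _, beta) in zip(w, entries):
        for pos, i in enumerate(sub):
            beta_bar[i] += wi * beta[pos]
    return best[0], best[2], beta_bar


class TestPreselect:
    def test_perfectly_correlated_tf_ranks_first(self):
        rng = np.random.default_rng(0)
        a = _activities(rng.normal(size=(50, 4)))
        y = a.values[:, 2].copy()
        order = preselect_predictors(y, a, set(), BBSRConfig(n_preselect=4))
        assert order[0] == "TF2"

    def test_exact_tie_breaks_lexicographically(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=30)
        # TFb and TFa are identical columns: identical |r|, TFa first
        a = _activities(np.column_stack([col, col]), ["TFb", "TFa"])
        y = col + rng.normal(size=30)
        order = preselect_predictors(y, a, set(), BBSRConfig(n_preselect=2))
        assert order == ["TFa", "TFb"]

    def test_prior_supported_precede_unsupported(self):
        rng = np.random.default_rng(2)
        a = _activities(rng.normal(size=(60, 3)))
        y = a.values[:, 0].copy()  # TF0 has by far the best correlation
        order = preselect_predictors(y, a, {"TF2"}, BBSRConfig(n_preselect=3))
        assert order[0] == "TF2"  # prior block first despite low correlation
        assert order[1] == "TF0"

    def test_self_edge_excluded(self):
        rng = np.random.default_rng(3)
        a = _activities(rng.normal(size=(40, 3)), ["g7", "TF1", "TF2"])
        y = a.values[:, 0].copy()
        order = preselect_predictors(y, a, set(), BBSRConfig(n_preselect=3),
                                     exclude_tf="g7")
        assert "g7" not in order

    def test_zero_variance_response_warns_empty(self):
        a = _activities(np.random.default_rng(4).normal(size=(20, 2)))
        with pytest.warns(UserWarning):
            assert preselect_predictors(np.ones(20), a, set(), BBSRConfig()) == []


class TestScoreSubset:
    def test_exact_fit_recovers_coefficient(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(30, 2))
        y = 2.0 * z[:, 0]
        rss, k, bic, betas = score_subset(y, z, (0,))
        assert rss < 1e-20
        np.testing.assert_allclose(betas, [2.0], atol=1e-10)

    def test_null_model_closed_form(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=50)
        rss, k, bic, betas = score_subset(y, rng.normal(size=(50, 2)), ())
        var_mle = ((y - y.mean()) ** 2).sum() / 50
        assert k == 0
        assert bic == pytest.approx(50 * np.log(var_mle))

    def test_every_subset_matches_normal_equations(self):
        rng = np.random.default_rng(7)
        n, m = 50, 3
        z = rng.normal(size=(n, m))
        y = z @ [1.0, -0.5, 0.0] + rng.normal(size=n)
        yc = y - y.mean()
        for k in range(0, m + 1):
            for sub in combinations(range(m), k):
                rss, _, bic, betas = score_subset(y, z, sub)
                if sub:
                    zc = z[:, list(sub)] - z[:, list(sub)].mean(axis=0)
                    beta_ref = np.linalg.solve(zc.T @ zc, zc.T @ yc)
                    rss_ref = float(((yc - zc @ beta_ref) ** 2).sum())
                    np.testing.assert_allclose(betas, beta_ref, atol=1e-8)
                    assert rss == pytest.approx(rss_ref, abs=1e-8)


class TestBbsrGene:
    def test_noiseless_two_of_five_recovered_with_unit_confidence(self):
        rng = np.random.default_rng(8)
        a = _activities(rng.normal(size=(60, 5)))
        y = 1.5 * a.values[:, 1] - 2.0 * a.values[:, 3]
        res = bbsr_gene(y, a, set(), BBSRConfig(n_preselect=5))
        assert set(res.best_subset) == {"TF1", "TF3"}
        assert res.confidence["TF1"] == pytest.approx(1.0, abs=1e-9)
        assert res.confidence["TF3"] == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_selects_empty_model_usually(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            a = _activities(rng.normal(size=(200, 3)))
            y = rng.normal(size=200)
            res = bbsr_gene(y, a, set(), BBSRConfig(n_preselect=3))
            hits += res.best_subset == ()
        assert hits >= 90

    def test_dominant_model_averaging_collapses_to_ols(self):
        # size-1 enumeration: the true predictor dominates every alternative
        # by a huge BIC margin, so averaging must collapse onto its OLS fit
        rng = np.random.default_rng(9)
        a = _activities(rng.normal(size=(300, 4)))
        y = 3.0 * a.values[:, 0] + rng.normal(size=300, scale=0.05)
        res = bbsr_gene(y, a, set(), BBSRConfig(n_preselect=4, max_subset_size=1))
        assert res.best_subset == ("TF0",)
        _, _, _, beta = score_subset(
            y, a.values, (0,)
        )
        assert res.weights["TF0"] == pytest.approx(float(beta[0]), abs=1e-8)

    def test_matches_brute_force_on_random_instances(self):
        """Implementation agrees with an independent design-matrix
        enumeration on best subset, BIC, and model-averaged coefficients."""
        for s in range(30):
            rng = np.random.default_rng(2000 + s)
            n, m = 50, int(rng.integers(2, 7))
            a = _activities(rng.normal(size=(n, m)))
            k_true = int(rng.integers(0, m + 1))
            beta = np.zeros(m)
            if k_true:
                beta[rng.choice(m, k_true, replace=False)] = rng.normal(size=k_true)
            y = a.values @ beta + rng.normal(size=n)
            cfg = BBSRConfig(n_preselect=m)
            res = bbsr_gene(y, a, set(), cfg)
            # oracle works in the same candidate order
            tf_pos = {tf: i for i, tf in enumerate(a.tf_ids)}
            z = a.values[:, [tf_pos[tf] for tf in res.candidates]]
            sub_ref, bic_ref, bbar_ref = brute_force_bbsr(
                y, z, res.candidates, cfg.max_subset_size
            )
            assert set(res.best_subset) == {res.candidates[i] for i in sub_ref}
            assert res.best_bic == pytest.approx(bic_ref, abs=1e-8)
            got = np.array([res.weights[tf] for tf in res.candidates])
            np.testing.assert_allclose(got, bbar_ref, atol=1e-8)

    def test_confidence_always_in_unit_interval(self):
        for s in range(20):
            rng = np.random.default_rng(3000 + s)
            a = _activities(rng.normal(size=(40, 5)))
            y = a.values @ rng.normal(size=5) + rng.normal(size=40)
            res = bbsr_gene(y, a, {"TF0"}, BBSRConfig(n_preselect=5))
            for c in res.confidence.values():
                assert 0.0 <= c <= 1.0


class TestInferNetwork:
    def test_gene_permutation_permutes_columns_only(self, small_bundle):
        x = generate_expression(small_bundle, "wt")
        a = small_bundle.a_wt
        net, _ = infer_network(x, a, small_bundle.prior_true)
        perm = np.random.default_rng(0).permutation(x.n_genes)
        xp = ExpressionMatrix(
            x.values[:, perm], x.sample_ids, [x.gene_ids[j] for j in perm], x.layer
        )
        netp, _ = infer_network(xp, a, small_bundle.prior_true)
        np.testing.assert_allclose(netp.weights, net.weights[:, perm], atol=1e-12)
        np.testing.assert_allclose(netp.confidence, net.confidence[:, perm], atol=1e-12)

    def test_noiseless_support_recovered_exactly(self, exact_bundle):
        x = generate_expression(exact_bundle, "wt")
        net, _ = infer_network(x, exact_bundle.a_wt, exact_bundle.prior_true)
        assert net.best_model_support() == exact_bundle.w_true.support()

    def test_noise_duplicate_tfs_do_not_inflate_aupr(self, small_bundle):
        x = generate_expression(small_bundle, "wt")
        a = small_bundle.a_wt
        net, _ = infer_network(x, a, small_bundle.prior_true)
        base = edge_recovery_aupr(net, small_bundle.w_true)
        rng = np.random.default_rng(42)
        decoys = rng.normal(size=(a.values.shape[0], 3))
        a_aug = ActivityMatrix(
            np.hstack([a.values, decoys]),
            list(a.sample_ids),
            list(a.tf_ids) + ["ZZdecoy0", "ZZdecoy1", "ZZdecoy2"],
        )
        net_aug, _ = infer_network(x, a_aug, small_bundle.prior_true)
        keep = [net_aug.tf_ids.index(t) for t in small_bundle.tf_ids]
        net_trim = NetworkMatrix(
            net_aug.weights[keep], net_aug.confidence[keep],
            small_bundle.tf_ids, net_aug.gene_ids,
        )
        aug = edge_recovery_aupr(net_trim, small_bundle.w_true)
        assert aug <= base + 0.05


class TestDegreeSummary:
    def test_min_targets_threshold(self):
        conf = np.array([
            [0.9, 0.9, 0.9, 0.9, 0.0],
            [0.9, 0.0, 0.0, 0.0, 0.0],
        ])
        net = NetworkMatrix(conf.copy(), conf, ["TF1", "TF2"],
                            [f"g{j}" for j in range(5)])
        table = summarize_tf_degrees(net, min_conf=0.5, min_targets=4)
        assert table["tf"].tolist() == ["TF1"]
        assert table["n_targets"].tolist() == [4]

    def test_min_targets_one_returns_all_regulating_tfs(self):
        conf = np.array([[0.8, 0.0], [0.0, 0.3]])
        net = NetworkMatrix(conf.copy(), conf, ["TF1", "TF2"], ["g0", "g1"])
        table = summarize_tf_degrees(net, min_conf=0.0, min_targets=1)
        assert table["tf"].tolist() == ["TF1", "TF2"]

    def test_empty_network_empty_table(self):
        net = NetworkMatrix(np.zeros((2, 3)), np.zeros((2, 3)),
                            ["TF1", "TF2"], ["g0", "g1", "g2"])
        assert summarize_tf_degrees(net, 0.0, 1).empty
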