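"""Assay scoring, repeatability, PCA/oblimin, BLUP scores, rank correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from volespace import behavior


def _scan_events(active=True):
    return [(10.0 * (i + 1), "activity_scan", active) for i in range(30)]


class TestScoreTest:
    def test_no_emergence_censored_at_300(self):
        rec = behavior.score_test(_scan_events(False))
        assert rec["latency_body_s"] == 300.0
        assert rec["latency_head_s"] == 300.0
        assert rec["latency_middle_s"] == 300.0

    def test_fully_active_animal(self):
        rec = behavior.score_test(_scan_events(True))
        assert rec["activity_prop"] == 1.0

    def test_scripted_sections_and_crossings(self):
        events = [(5.0, "head_out", None), (9.0, "body_out", None)]
        events += [(10.0 + i, "enter_section", s) for i, s in enumerate([1, 2, 3, 2, 4, 5, 6, 7])]
        events += [(40.0, "enter_middle", None), (80.0, "enter_middle", None)]
        events += [(90.0, "jump", None)] * 3
        events += _scan_events(False)
        rec = behavior.score_test(events)
        assert rec["sections_entered"] == 7
        assert rec["middle_crossings"] == 2
        assert rec["jumps"] == 3
        assert rec["latency_head_s"] == 5.0
        assert rec["latency_middle_s"] == 40.0

    def test_late_events_ignored_with_warning(self):
        events = [(350.0, "jump", None)] + _scan_events(False)
        with pytest.warns(UserWarning):
            rec = behavior.score_test(events)
        assert rec["jumps"] == 0

    def test_wrong_scan_count_rejected(self):
        with pytest.raises(ValueError):
            behavior.score_test(_scan_events()[:-1])


class TestInvertLatencies:
    @pytest.fixture()
    def table(self, rng):
        return pd.DataFrame(
            {"latency_body_s": rng.uniform(1, 300, 40), "middle_crossings": rng.integers(0, 9, 40)}
        )

    def test_rank_reversal(self, table):
        inv = behavior.invert_latencies(table)
        raw_ranks = stats.rankdata(table["latency_body_s"])
        assert np.allclose(stats.rankdata(inv["latency_body_s"]), len(table) + 1 - raw_ranks)
        assert (inv["middle_crossings"] == table["middle_crossings"]).all()

    def test_involution(self, table):
        twice = behavior.invert_latencies(behavior.invert_latencies(table))
        pd.testing.assert_frame_equal(twice, table)

    def test_censored_case_is_minimum(self, table):
        table.loc[0, "latency_body_s"] = 300.0
        inv = behavior.invert_latencies(table)
        assert inv["latency_body_s"].idxmin() == 0

    def test_reflect_mode(self, table):
        ref = behavior.invert_latencies(table, mode="reflect")
        assert np.allclose(ref["latency_body_s"], 300.0 - table["latency_body_s"])


class TestRepeatability:
    def test_zero_within_variance_gives_one(self):
        ids = np.repeat(np.arange(10), 3)
        vals = ids.astype(float) * 2.0
        r = behavior.repeatability(vals, ids, n_boot=0)
        assert r.R > 0.999

    def test_shuffled_labels_near_zero(self, rng):
        ids = np.repeat(np.arange(100), 2)
        vals = rng.normal(size=200)
        r = behavior.repeatability(vals, ids, n_boot=0)
        assert r.R < 0.1

    def test_balanced_matches_anova_icc(self, rng):
        # on balanced designs REML equals the classical one-way ANOVA ICC
        n, k = 40, 2
        ids = np.repeat(np.arange(n), k)
        vals = rng.normal(0, 1, n)[ids // 1][np.argsort(np.argsort(ids))] * 0.0  # placeholder
        a = rng.normal(0, 0.8, n)
        vals = a[ids] + rng.normal(0, 1.0, n * k)
        r = behavior.repeatability(vals, ids, n_boot=0)
        msa = k * np.var([vals[ids == i].mean() for i in range(n)], ddof=1)
        msw = np.mean([np.var(vals[ids == i], ddof=1) for i in range(n)])
        icc_anova = max((msa - msw) / (msa + (k - 1) * msw), 0.0)
        assert abs(r.R - icc_anova) < 1e-3

    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.api as sm

        sizes = rng.integers(2, 5, 30)
        ids = np.concatenate([[i] * s for i, s in enumerate(sizes)])
        a = rng.normal(0, 0.7, 30)
        vals = a[ids] + rng.normal(0, 1.0, len(ids))
        r = behavior.repeatability(vals, ids, n_boot=0)
        fit = sm.MixedLM(vals, np.ones((len(ids), 1)), groups=ids).fit(reml=True)
        R_sm = float(np.asarray(fit.cov_re)[0, 0] / (np.asarray(fit.cov_re)[0, 0] + fit.scale))
        assert abs(r.R - R_sm) < 1e-3

    def test_bootstrap_ci_covers_generating_value(self, rng):
        ids = np.repeat(np.arange(62), 2)
        a = rng.normal(0, np.sqrt(0.453), 62)
        vals = a[ids] + rng.normal(0, np.sqrt(1 - 0.453), 124)
        r = behavior.repeatability(vals, ids, n_boot=200, seed=1)
        assert r.CI_low <= 0.453 <= r.CI_high
        assert r.SE > 0

    def test_single_round_rejected(self):
        with pytest.raises(ValueError):
            behavior.repeatability([1.0, 2.0, 3.0], ["a", "b", "c"], n_boot=0)


class TestSuitability:
    def test_identity_correlation(self, rng):
        X = rng.normal(size=(3000, 4))
        out = behavior.pca_suitability(pd.DataFrame(X))
        assert out["determinant"] > 0.97
        assert out["bartlett_p"] > 0.05

    def test_perfect_correlation_singular(self, rng):
        x = rng.normal(size=200)
        out = behavior.pca_suitability(pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.normal(size=200)}))
        assert out["determinant"] < 1e-10

    def test_kmo_matches_partial_correlation_oracle(self, rng):
        X = rng.normal(size=(150, 6))
        X[:, 1] += 0.8 * X[:, 0]
        X[:, 3] += 0.5 * X[:, 2]
        out = behavior.pca_suitability(pd.DataFrame(X))
        R = np.corrcoef(X, rowvar=False)
        Rinv = np.linalg.inv(R)
        p = 6
        part = np.zeros((p, p))
        for i in range(p):
            for j in range(p):
                part[i, j] = -Rinv[i, j] / np.sqrt(Rinv[i, i] * Rinv[j, j])
        off = ~np.eye(p, dtype=bool)
        kmo = (R[off] ** 2).sum() / ((R[off] ** 2).sum() + (part[off] ** 2).sum())
        assert np.isclose(out["KMO"], kmo)


def _block_data(rng, n=400, r_within=0.8):
    # two independent 3-variable blocks
    f1, f2 = rng.normal(size=(2, n))
    lam = np.sqrt(r_within)
    cols = {}
    for b, f in (("a", f1), ("b", f2)):
        for j in range(3):
            cols[f"{b}{j}"] = lam * f + np.sqrt(1 - lam**2) * rng.normal(size=n)
    return pd.DataFrame(cols)


class TestPCAOblimin:
    def test_block_structure_recovered(self, rng):
        df = _block_data(rng)
        res = behavior.pca_oblimin(df)
        assert res.n_retained == 2
        L = res.loadings.to_numpy()
        # each block loads on its own component after rotation
        for j, block in ((0, slice(0, 3)), (1, slice(3, 6))):
            own = np.abs(L[block, :]).mean(axis=0)
            assert own.max() > 0.8 and own.min() < 0.25

    def test_explained_variance_identity(self, rng):
        df = _block_data(rng)
        res = behavior.pca_oblimin(df)
        assert np.isclose(
            res.explained_variance.sum(), res.eigenvalues[:2].sum() / df.shape[1]
        )

    def test_rotation_preserves_communalities(self, rng):
        df = _block_data(rng)
        res = behavior.pca_oblimin(df)
        # for oblique rotation: communality = diag(P Phi P')
        P = res.loadings.to_numpy()
        comm_rot = np.diag(P @ res.phi @ P.T)
        assert np.allclose(comm_rot, res.communalities.to_numpy(), atol=1e-8)

    def test_variable_order_invariance(self, rng):
        df = _block_data(rng)
        res1 = behavior.pca_oblimin(df)
        shuffled = df[list(df.columns[::-1])]
        res2 = behavior.pca_oblimin(shuffled)
        # same components up to order/sign: compare score correlation structure
        c = np.corrcoef(res1.scores.to_numpy().T, res2.scores.to_numpy().T)[:2, 2:]
        assert np.allclose(np.sort(np.abs(c).max(axis=1)), [1.0, 1.0], atol=1e-6)

    def test_sign_anchors_enforced(self, rng):
        df = _block_data(rng)
        df["a0"] *= -1  # flip one anchor variable
        res = behavior.pca_oblimin(df, sign_anchors={"expl": ["a1", "a2"], "bold": ["b0", "b1"]})
        assert set(res.loadings.columns) == {"expl", "bold"}
        assert res.loadings.loc["a1", "expl"] > 0
        assert res.loadings.loc["b0", "bold"] > 0

    def test_no_component_above_threshold_raises(self, rng):
        X = pd.DataFrame(rng.normal(size=(500, 3)))
        with pytest.raises(ValueError):
            behavior.pca_oblimin(X, eigenvalue_threshold=3.5)


class TestBlupScores:
    def _balanced(self, rng, n=60, k=3, vind=0.5, vres=0.5):
        ids = np.repeat([f"v{i}" for i in range(n)], k)
        a = rng.normal(0, np.sqrt(vind), n)
        y = np.repeat(a, k) + rng.normal(0, np.sqrt(vres), n * k)
        day = np.tile(np.arange(k, dtype=float), n)
        return pd.DataFrame({"PC1": y}), day, ids, a

    def test_full_shrinkage_when_no_between_variance(self, rng):
        scores, day, ids, _ = self._balanced(rng, vind=0.0, vres=1.0)
        out = behavior.blup_scores(scores, day, ids)
        # with no true between-individual variance the conditional modes
        # collapse far toward the population mean relative to raw means
        y = scores["PC1"].to_numpy()
        raw_sd = pd.DataFrame({"y": y, "id": ids}).groupby("id")["y"].mean().std()
        assert out["PC1"].std() < 0.5 * raw_sd
        assert abs(out["PC1"].mean()) < 0.1

    def test_balanced_closed_form_shrinkage(self, rng):
        scores, day, ids, _ = self._balanced(rng, n=80, k=3)
        out = behavior.blup_scores(scores, day, ids)
        # closed form for the balanced one-way design with zero day effect:
        # mode_i = (Vind / (Vind + Vres/k)) * (ybar_i - ybar)
        import statsmodels.api as sm

        fit = sm.MixedLM(
            scores["PC1"].to_numpy(), np.ones((len(ids), 1)), groups=ids
        ).fit(reml=True)
        vind, vres = float(np.asarray(fit.cov_re)[0, 0]), float(fit.scale)
        y = scores["PC1"].to_numpy()
        df = pd.DataFrame({"y": y, "id": ids})
        dev = df.groupby("id")["y"].mean() - y.mean()
        expect = vind / (vind + vres / 3) * dev
        got = out["PC1"].reindex(expect.index)
        assert np.allclose(got, expect, atol=0.02)

    def test_day_shift_invariance(self, rng):
        scores, day, ids, _ = self._balanced(rng)
        a = behavior.blup_scores(scores, day, ids)
        b = behavior.blup_scores(scores, day + 1000.0, ids)
        pd.testing.assert_frame_equal(a, b)

    def test_latent_recovery(self, rng):
        scores, day, ids, a = self._balanced(rng, n=200, k=2, vind=0.45, vres=0.55)
        out = behavior.blup_scores(scores, day, ids)
        truth = pd.Series(a, index=[f"v{i}" for i in range(200)])
        r = np.corrcoef(out["PC1"], truth.reindex(out.index))[0, 1]
        assert r > 0.7

    def test_requires_repeats(self, rng):
        scores = pd.DataFrame({"PC1": rng.normal(size=10)})
        with pytest.raises(ValueError):
            behavior.blup_scores(scores, np.arange(10.0), [f"v{i}" for i in range(10)])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        out = behavior.spearman(x, np.exp(x))
        assert np.isclose(out["rho"], 1.0) and out["S"] == 0.0

    def test_reversal(self):
        x = np.arange(10.0)
        assert np.isclose(behavior.spearman(x, -x)["rho"], -1.0)

    def test_matches_rank_formula_oracle(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20) + 0.5 * x
        out = behavior.spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert np.isclose(out["rho"], ref.statistic)
        assert np.isclose(out["p"], ref.pvalue)
        # no ties here: rho from S by the classical formula
        n = 20
        assert np.isclose(out["rho"], 1 - 6 * out["S"] / (n * (n**2 - 1)))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            behavior.spearman(np.ones(10), np.arange(10.0))
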