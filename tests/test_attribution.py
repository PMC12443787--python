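"""Expected-gradients attributions: closed forms, completeness, rankings."""

import numpy as np
import pytest

from rxseq import attribution as A
from rxseq import model as M
from tests.conftest import FEATURE_NAMES


class LinearModel:
    """f_k(x) = a_k . x over the flattened grid + static — closed-form SHAP."""

    def __init__(self, a_grid, a_static):
        self.a_grid = np.asarray(a_grid)  # (k, T, F)
        self.a_static = np.asarray(a_static)  # (k, 4)

    def input_gradients(self, X, S):
        n = X.shape[0]
        k = self.a_grid.shape[0]
        out = np.einsum("ntf,ktf->nk", X, self.a_grid) + S @ self.a_static.T
        gX = np.broadcast_to(self.a_grid[None], (n,) + self.a_grid.shape).copy()
        gS = np.broadcast_to(self.a_static[None], (n, k, 4)).copy()
        return out, gX, gS


def random_background(rng, n, T=3, F=4):
    return rng.random((n, T, F)), rng.random((n, 4))


class TestExpectedGradients:
    def test_linear_model_closed_form(self):
        """For f(x) = a.x the attribution converges to a_j (x_j - mean bg_j)."""
        rng = np.random.default_rng(0)
        a_grid = rng.normal(size=(2, 3, 4))
        a_static = rng.normal(size=(2, 4))
        lin = LinearModel(a_grid, a_static)
        Xb, Sb = random_background(rng, 300)
        x, s = rng.random((1, 3, 4)), rng.random((1, 4))
        att = A.expected_gradients(lin, x, s, (Xb, Sb), n_samples=4000, seed=1)
        expected = a_grid * (x[0][None] - Xb.mean(axis=0)[None])
        assert np.allclose(att.grid[0], expected, atol=0.02)
        expected_s = a_static * (s[0][None] - Sb.mean(axis=0)[None])
        assert np.allclose(att.static[0], expected_s, atol=0.02)

    def test_zero_weight_feature_gets_zero_attribution(self):
        rng = np.random.default_rng(2)
        a_grid = rng.normal(size=(1, 3, 4))
        a_grid[0, :, 2] = 0.0
        lin = LinearModel(a_grid, np.zeros((1, 4)))
        Xb, Sb = random_background(rng, 50)
        x, s = rng.random((1, 3, 4)), rng.random((1, 4))
        att = A.expected_gradients(lin, x, s, (Xb, Sb), n_samples=200, seed=0)
        assert np.all(att.grid[0, :, :, 2] == 0)

    def test_completeness_within_three_standard_errors(self, planted_run):
        """Aumann-Shapley completeness: total attribution equals the gap
        between the prediction and the mean background prediction, within
        Monte-Carlo error."""
        net = planted_run["net"]
        Xb, Sb = planted_run["X_train"][:60], planted_run["S_train"][:60]
        x, s = planted_run["X_test"][:5], planted_run["S_test"][:5]
        att = A.expected_gradients(net, x, s, (Xb, Sb), n_samples=600, seed=3)
        f_x = M.predict(net, x, s)
        f_bg = M.predict(net, Xb, Sb).mean(axis=0)
        total = att.grid.sum(axis=(2, 3)) + att.static.sum(axis=2)
        gap = np.abs(total - (f_x - f_bg[None, :]))
        # allow a tiny absolute floor where the MC error estimate is ~0
        assert np.all(gap <= 3 * att.total_se + 1e-4)

    def test_empty_background_rejected(self):
        lin = LinearModel(np.zeros((1, 3, 4)), np.zeros((1, 4)))
        with pytest.raises(ValueError):
            A.expected_gradients(
                lin, np.zeros((1, 3, 4)), np.zeros((1, 4)),
                (np.zeros((0, 3, 4)), np.zeros((0, 4))), seed=0,
            )

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(4)
        lin = LinearModel(rng.normal(size=(1, 3, 4)), rng.normal(size=(1, 4)))
        Xb, Sb = random_background(rng, 30)
        x, s = rng.random((2, 3, 4)), rng.random((2, 4))
        a1 = A.expected_gradients(lin, x, s, (Xb, Sb), n_samples=50, seed=9)
        a2 = A.expected_gradients(lin, x, s, (Xb, Sb), n_samples=50, seed=9)
        assert np.array_equal(a1.grid, a2.grid)


def tensor_from(grid, static):
    return A.AttributionTensor(
        grid=np.asarray(grid, dtype=float), static=np.asarray(static, dtype=float),
        n_samples=1, background_size=1,
    )


class TestRelativeConversion:
    def test_signed_percentage_arithmetic(self):
        att = tensor_from(
            np.array([1.0, -1.0, 2.0]).reshape(1, 1, 1, 3), np.zeros((1, 1, 4))
        )
        rel = A.to_relative(att)
        assert np.allclose(rel.grid[0, 0, 0], [25.0, -25.0, 50.0])

    def test_all_zero_attribution_stays_zero(self):
        rel = A.to_relative(tensor_from(np.zeros((1, 1, 2, 3)), np.zeros((1, 1, 4))))
        assert np.all(rel.grid == 0) and np.all(rel.static == 0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        g, s = rng.normal(size=(1, 2, 3, 4)), rng.normal(size=(1, 2, 4))
        r1 = A.to_relative(tensor_from(g, s))
        r2 = A.to_relative(tensor_from(7.3 * g, 7.3 * s))
        assert np.allclose(r1.grid, r2.grid)

    def test_absolute_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(1)
        rel = A.to_relative(
            tensor_from(rng.normal(size=(3, 2, 4, 5)), rng.normal(size=(3, 2, 4)))
        )
        total = np.abs(rel.grid).sum(axis=(2, 3)) + np.abs(rel.static).sum(axis=2)
        assert np.allclose(total, 100.0)

    def test_nonfinite_rejected(self):
        bad = tensor_from(np.full((1, 1, 1, 1), np.nan), np.zeros((1, 1, 4)))
        with pytest.raises(ValueError):
            A.to_relative(bad)


class TestTemporalAggregation:
    def uniform_rel(self, n_months=18):
        grid = np.full((4, 1, n_months, 1), 100.0 / n_months)
        return A.RelativeAttribution(
            grid=grid, static=np.zeros((4, 1, 4)), denominator=np.full((4, 1), 1.0)
        )

    def test_uniform_attribution_cumulative_from_month_ten(self):
        scores, cum = A.monthly_importance(self.uniform_rel(), 0)
        assert cum[9] == pytest.approx(50.0)  # months 10..18 = 9 x 100/18

    def test_concentrated_mass_in_final_month(self):
        grid = np.zeros((2, 1, 18, 1))
        grid[:, :, 17, :] = 100.0
        rel = A.RelativeAttribution(grid=grid, static=np.zeros((2, 1, 4)),
                                    denominator=np.ones((2, 1)))
        scores, cum = A.monthly_importance(rel, 0)
        assert cum[17] == pytest.approx(100.0)
        assert A.months_to_half(scores) == 1

    def test_month_scores_partition_the_grid_total(self):
        rng = np.random.default_rng(3)
        grid = rng.normal(size=(5, 2, 18, 7))
        rel = A.to_relative(tensor_from(grid, rng.normal(size=(5, 2, 4))))
        scores, _ = A.monthly_importance(rel, 1)
        assert scores.sum() == pytest.approx(rel.grid[:, 1].sum(axis=(1, 2)).mean())

    def test_uniform_months_need_ten_to_exceed_half(self):
        scores = np.full(18, 100.0 / 18)
        assert A.months_to_half(scores) == 10  # 9 months reach exactly 50%

    def test_forty_thirty_thirty_tail(self):
        scores = np.zeros(18)
        scores[15], scores[16], scores[17] = 40.0, 30.0, 30.0
        assert A.months_to_half(scores) == 2

    def test_nonpositive_total_undefined(self):
        assert A.months_to_half(np.zeros(18)) is None
        assert A.months_to_half(np.full(18, -1.0)) is None


class TestFeatureRanking:
    def test_planted_single_feature_model_ranks_first(self):
        rng = np.random.default_rng(5)
        a_grid = np.zeros((1, 3, 4))
        a_grid[0, :, 1] = 2.0  # only feature 1 used
        lin = LinearModel(a_grid, np.zeros((1, 4)))
        Xb, Sb = random_background(rng, 100)
        x, s = rng.random((6, 3, 4)), rng.random((6, 4))
        att = A.expected_gradients(lin, x, s, (Xb, Sb), n_samples=300, seed=0)
        ranked = A.feature_importance(A.to_relative(att), 0, list("abcd"))
        assert ranked[0]["feature"] == "b"

    def test_tie_break_is_alphabetical(self):
        grid = np.zeros((2, 1, 2, 2))
        grid[:, :, 0, 0] = 10.0
        grid[:, :, 0, 1] = 10.0
        rel = A.RelativeAttribution(grid=grid, static=np.zeros((2, 1, 4)),
                                    denominator=np.ones((2, 1)))
        ranked = A.feature_importance(rel, 0, ["z_drug", "a_drug"])
        assert [r["feature"] for r in ranked[:2]] == ["a_drug", "z_drug"]

    def test_top_k_excludes_non_medication_features(self):
        ranked = [
            {"feature": f} for f in
            ["hospitalized", "drug_3", "age", "drug_1", "sex", "drug_2"]
        ]
        assert A.top_k(ranked, 2) == ["drug_3", "drug_1"]
        assert A.top_k(ranked, 0) == []
        assert A.top_k(ranked, 99) == ["drug_3", "drug_1", "drug_2"]

    def test_planted_drug_ranks_top_three_for_its_event(self, planted_run):
        """The drug carrying the only planted risk must surface among the
        top-3 ranked features for its event on the test set."""
        net = planted_run["net"]
        rng = np.random.default_rng(0)
        Xtr, Str = planted_run["X_train"], planted_run["S_train"]
        bg = rng.choice(Xtr.shape[0], size=min(80, Xtr.shape[0]), replace=False)
        att = A.expected_gradients(
            net, planted_run["X_test"][:60], planted_run["S_test"][:60],
            (Xtr[bg], Str[bg]), n_samples=80, seed=0,
        )
        ranked = A.feature_importance(A.to_relative(att), 0, FEATURE_NAMES)
        assert "drug_0" in [r["feature"] for r in ranked[:3]]
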