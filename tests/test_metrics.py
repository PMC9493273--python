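import numpy as np
import pandas as pd
import pytest

from soilnorm.metrics import (
    EnvCorrelation,
    env_correlations,
    genotype_overall,
    percentile_grid,
    variance_percentages,
    weighted_mean_correlation,
)

from conftest import make_table


def _pred_frame(rows):
    return pd.DataFrame(rows, columns=["line", "env", "observed", "predicted"])


class TestEnvCorrelations:
    def test_perfect_predictions(self):
        df = _pred_frame(
            [(f"g{i}", "e1", float(i), float(i)) for i in range(10)]
        )
        entries, skipped = env_correlations(df)
        assert not skipped
        (e,) = entries
        assert e.r == pytest.approx(1.0)
        assert e.sampling_variance == pytest.approx(0.0)

    def test_small_environment_excluded(self):
        df = _pred_frame([("g1", "e1", 1.0, 2.0), ("g2", "e1", 2.0, 1.0)])
        entries, skipped = env_correlations(df)
        assert entries == []
        assert skipped[0]["env"] == "e1"

    def test_zero_variance_flagged(self):
        df = _pred_frame([(f"g{i}", "e1", 5.0, float(i)) for i in range(4)])
        entries, skipped = env_correlations(df)
        assert entries == []
        assert "zero variance" in skipped[0]["reason"]

    def test_hand_computed_pearson(self):
        df = _pred_frame(
            [
                ("g1", "e1", 1.0, 2.0),
                ("g2", "e1", 2.0, 1.0),
                ("g3", "e1", 3.0, 4.0),
                ("g4", "e1", 4.0, 3.0),
            ]
        )
        entries, _ = env_correlations(df)
        assert entries[0].r == pytest.approx(0.6)
        assert entries[0].sampling_variance == pytest.approx((1 - 0.36) / 2)


class TestWeightedMeanCorrelation:
    def test_constant_r_returns_constant(self):
        entries = [EnvCorrelation(f"e{n}", 0.4, n) for n in (5, 10, 30)]
        assert weighted_mean_correlation(entries) == pytest.approx(0.4)

    def test_hand_example(self):
        # V = (0.09375, 0.125); weights (10.667, 8) -> 0.2857
        entries = [EnvCorrelation("a", 0.5, 10), EnvCorrelation("b", 0.0, 10)]
        assert weighted_mean_correlation(entries) == pytest.approx(0.2857, abs=1e-4)

    def test_single_environment(self):
        assert weighted_mean_correlation([EnvCorrelation("a", -0.3, 8)]) == pytest.approx(-0.3)

    def test_infinite_weight_entries_excluded(self):
        entries = [EnvCorrelation("a", 1.0, 10), EnvCorrelation("b", 0.2, 10)]
        assert weighted_mean_correlation(entries) == pytest.approx(0.2)
        with pytest.raises(ValueError, match="no environment"):
            weighted_mean_correlation([EnvCorrelation("a", 1.0, 10)])

    def test_bounded_by_entry_range(self):
        rng = np.random.default_rng(0)
        entries = [
            EnvCorrelation(f"e{i}", float(rng.uniform(-0.9, 0.9)), int(rng.integers(4, 40)))
            for i in range(12)
        ]
        rw = weighted_mean_correlation(entries)
        rs = [e.r for e in entries]
        assert min(rs) <= rw <= max(rs)


class TestVariancePercentages:
    def test_uniform_components(self):
        shares = variance_percentages({"E": 2.0, "L": 2.0, "G": 2.0, "R": 2.0})
        assert all(v == pytest.approx(25.0) for v in shares)

    def test_within_drops_environment_term(self):
        shares = variance_percentages(
            {"E": 50.0, "L": 10.0, "G": 15.0, "R": 25.0}, "within"
        )
        assert "E" not in shares
        assert shares["L"] == pytest.approx(20.0)
        assert shares["R"] == pytest.approx(50.0)

    @pytest.mark.parametrize("scope", ["across", "within"])
    def test_sums_to_100(self, scope):
        rng = np.random.default_rng(1)
        comp = {t: float(rng.gamma(2.0)) for t in ("E", "L", "S", "G", "GxE", "GxS", "R")}
        assert variance_percentages(comp, scope).sum() == pytest.approx(100.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            variance_percentages({"E": 0.0, "R": 0.0})
        with pytest.raises(ValueError, match="nonnegative"):
            variance_percentages({"E": -1.0, "R": 1.0})


class TestPercentileGrid:
    def test_perfect_ranking(self):
        x = np.arange(100, dtype=float)
        g = percentile_grid(x, x)
        assert g.top20_success == 1.0
        assert g.bottom20_success == 1.0
        assert g.r2 == pytest.approx(1.0)
        assert g.mse == 0.0
        np.testing.assert_allclose(g.matrix.sum(axis=0), 1.0)

    def test_reversed_ranking_hits_antidiagonal(self):
        x = np.arange(100, dtype=float)
        g = percentile_grid(x[::-1], x)
        assert g.matrix[0, -1] == 1.0  # predicted top land in observed bottom
        assert g.top20_success == 0.0

    def test_pairwise_swap_example(self):
        # oracle-enumerated: the top-20% bins are {9,10} for both vectors
        # and the swapped pairs keep both members inside, so success = 1
        pred = np.arange(1.0, 11.0)
        obs = np.array([2, 1, 4, 3, 6, 5, 8, 7, 10, 9], dtype=float)
        g = percentile_grid(pred, obs)
        assert g.top20_success == pytest.approx(1.0)

    def test_cross_boundary_swap_gives_half(self):
        # swapping rank 9 with rank 8 moves one of the two top-bin
        # predictions out of the observed top bin -> success = 0.5
        pred = np.arange(1.0, 11.0)
        obs = np.array([1, 2, 3, 4, 5, 6, 7, 9, 8, 10], dtype=float)
        g = percentile_grid(pred, obs)
        assert g.top20_success == pytest.approx(0.5)

    def test_columns_sum_to_one_random(self):
        rng = np.random.default_rng(2)
        pred, obs = rng.normal(size=50), rng.normal(size=50)
        g = percentile_grid(pred, obs)
        np.testing.assert_allclose(g.matrix.sum(axis=0), 1.0)
        assert 0.0 <= g.matrix.min() and g.matrix.max() <= 1.0

    def test_rw_attached_when_env_given(self):
        rng = np.random.default_rng(3)
        obs = rng.normal(size=40)
        pred = obs + rng.normal(scale=0.5, size=40)
        env = np.repeat(["e1", "e2"], 20)
        g = percentile_grid(pred, obs, env=env)
        assert g.r_w is not None and -1 <= g.r_w <= 1


class TestGenotypeOverall:
    def test_single_environment_centering_identity(self):
        df = _pred_frame(
            [(f"g{i}", "e1", float(i), float(i) / 2) for i in range(6)]
        )
        out = genotype_overall(df)
        assert out["observed"].sum() == pytest.approx(0.0)
        assert out["predicted"].sum() == pytest.approx(0.0)

    def test_two_env_hand_example(self):
        # env means: e1 obs (10+20)/2=15, e2 obs (30+50)/2=40
        df = _pred_frame(
            [
                ("g1", "e1", 10.0, 12.0),
                ("g2", "e1", 20.0, 18.0),
                ("g1", "e2", 30.0, 35.0),
                ("g2", "e2", 50.0, 45.0),
            ]
        )
        out = genotype_overall(df)
        # g1: ((10-15) + (30-40))/2 = -7.5 ; predicted means (15, 40)
        assert out.loc["g1", "observed"] == pytest.approx(-7.5)
        assert out.loc["g2", "observed"] == pytest.approx(7.5)
        assert out.loc["g1", "predicted"] == pytest.approx(((12 - 15) + (35 - 40)) / 2)

    def test_line_seen_once_keeps_single_centered_value(self):
        df = _pred_frame(
            [
                ("g1", "e1", 10.0, 11.0),
                ("g2", "e1", 20.0, 19.0),
                ("g3", "e1", 30.0, 30.0),
            ]
        )
        out = genotype_overall(df)
        assert out.loc["g3", "observed"] == pytest.approx(30.0 - 20.0)

    def test_table_env_means_override(self):
        table = make_table(
            [
                ("g1", "e1", 2020, "f", "clay", 10.0),
                ("g2", "e1", 2020, "f", "clay", 30.0),
            ]
        )
        df = _pred_frame([("g1", "e1", 10.0, 12.0)])
        out = genotype_overall(df, table)
        assert out.loc["g1", "observed"] == pytest.approx(10.0 - 20.0)
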