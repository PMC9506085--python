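import numpy as np
import pandas as pd
import pytest

from aquacomm import envadapt
from conftest import random_count_table


def make_env(samples, rng):
    return pd.DataFrame(
        rng.normal(size=(len(samples), 3)),
        index=samples,
        columns=["nitrate", "temperature", "pH"],
    )


class TestRda:
    def test_perfect_linear_response_fully_constrained(self):
        samples = [f"s{i}" for i in range(10)]
        x = np.linspace(0, 1, 10)
        table = pd.DataFrame({"sp1": 1 + 2 * x}, index=samples).T
        env = pd.DataFrame({"factor": x}, index=samples)
        res = envadapt.rda_variance(table, env, transform="none", n_permutations=19)
        assert res.constrained_proportion == pytest.approx(1.0)

    def test_orthogonal_factor_explains_nothing(self):
        samples = [f"s{i}" for i in range(8)]
        sp = np.array([1, -1] * 4, dtype=float) + 2
        factor = np.array([1, 1, -1, -1] * 2, dtype=float)  # orthogonal to sp
        table = pd.DataFrame({"sp1": sp}, index=samples).T
        env = pd.DataFrame({"factor": factor}, index=samples)
        res = envadapt.rda_variance(table, env, transform="none", n_permutations=19)
        assert res.constrained_proportion < 1e-10

    def test_single_pair_equals_squared_pearson(self, rng):
        samples = [f"s{i}" for i in range(12)]
        x = rng.normal(size=12)
        y = 0.4 * x + rng.normal(size=12)
        table = pd.DataFrame({"sp1": y + 10}, index=samples).T
        env = pd.DataFrame({"factor": x}, index=samples)
        res = envadapt.rda_variance(table, env, transform="none", n_permutations=19)
        r = np.corrcoef(x, y)[0, 1]
        assert res.constrained_proportion == pytest.approx(r**2, abs=1e-9)

    def test_too_many_factors_rejected(self, rng):
        samples = [f"s{i}" for i in range(4)]
        table = pd.DataFrame(rng.random((3, 4)), columns=samples)
        env = pd.DataFrame(rng.normal(size=(4, 5)), index=samples)
        with pytest.raises(ValueError):
            envadapt.rda_variance(table, env)


class TestCorrelationScreen:
    def test_monotone_pairs_hit_unit_correlation(self):
        samples = [f"s{i}" for i in range(5)]
        table = pd.DataFrame({"up": [1, 2, 3, 4, 5], "down": [5, 4, 3, 2, 1]}, index=samples).T
        env = pd.DataFrame({"factor": [0.1, 0.2, 0.3, 0.4, 0.5]}, index=samples)
        res = envadapt.env_correlation_screen(table, env)
        rho = res.set_index("taxon")["rho"]
        assert rho["up"] == pytest.approx(1.0)
        assert rho["down"] == pytest.approx(-1.0)

    def test_hand_rank_value(self):
        samples = list("abcd")
        table = pd.DataFrame({"t": [1, 2, 3, 4]}, index=samples).T
        env = pd.DataFrame({"f": [2, 1, 4, 3]}, index=samples)
        res = envadapt.env_correlation_screen(table, env)
        assert res["rho"].iloc[0] == pytest.approx(0.6)

    def test_bonferroni_never_increases_significance(self, rng):
        table = random_count_table(rng, n_taxa=10, n_samples=12)
        env = make_env(list(table.columns), rng)
        res = envadapt.env_correlation_screen(table, env)
        raw_sig = (res["p"] < 0.05).sum()
        adj_sig = (res["p_adjusted"] < 0.05).sum()
        assert adj_sig <= raw_sig
        assert (res["p_adjusted"].dropna() >= res["p"].dropna() - 1e-15).all()

    def test_constant_vector_reported_missing(self):
        samples = [f"s{i}" for i in range(6)]
        table = pd.DataFrame({"flat": [3] * 6}, index=samples).T
        env = pd.DataFrame({"f": np.arange(6.0)}, index=samples)
        res = envadapt.env_correlation_screen(table, env)
        assert np.isnan(res["rho"].iloc[0])


def step_table(gradient, change_points, directions, rng, noise=0.0):
    """Taxa with clean step responses along a gradient."""
    rows = {}
    for k, (cp, d) in enumerate(zip(change_points, directions)):
        on = (gradient > cp) if d > 0 else (gradient < cp)
        rows[f"t{k}"] = np.where(on, 5.0 + rng.random(len(gradient)), 0.0) + noise
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(len(gradient))]).T


class TestTitan:
    def test_clean_step_exact_change_point(self):
        gradient = pd.Series(
            [1.0, 2, 3, 4, 5, 6], index=[f"s{i}" for i in range(6)], name="f"
        )
        table = pd.DataFrame(
            {f"s{i}": [0, 0, 0, 5, 5, 5][i] * np.ones(1) for i in range(6)},
            index=["taxon"],
        )
        res = envadapt.titan_change_points(
            table, gradient, n_permutations=50, n_bootstrap=10, seed=0, min_occurrence=3
        )
        row = res.taxa.loc["taxon"]
        assert row["change_point"] == pytest.approx(3.5)
        assert row["direction"] == 1
        assert row["indval"] == pytest.approx(100.0)

    def test_mirrored_response_flips_direction_same_strength(self, rng):
        gradient = pd.Series(
            np.linspace(0, 10, 12), index=[f"s{i}" for i in range(12)], name="f"
        )
        up = step_table(gradient.to_numpy(), [5.0], [1], np.random.default_rng(0))
        down = step_table(gradient.to_numpy(), [5.0], [-1], np.random.default_rng(0))
        both = pd.concat([up, down])
        both.index = ["up", "down"]
        res = envadapt.titan_change_points(
            both, gradient, n_permutations=100, n_bootstrap=10, seed=1
        )
        assert res.taxa.loc["up", "direction"] == 1
        assert res.taxa.loc["down", "direction"] == -1
        assert res.taxa.loc["up", "z"] == pytest.approx(
            res.taxa.loc["down", "z"], rel=0.3
        )

    def test_noise_taxa_rarely_become_indicators(self, rng):
        """Abundance independent of the gradient fails purity/reliability."""
        gradient = pd.Series(
            np.linspace(0, 10, 20), index=[f"s{i}" for i in range(20)], name="f"
        )
        flagged = 0
        n_sim = 40
        for k in range(n_sim):
            local = np.random.default_rng(k)
            table = pd.DataFrame(
                local.integers(0, 6, size=(5, 20)),
                index=[f"t{i}" for i in range(5)],
                columns=gradient.index,
            )
            table = table.loc[(table > 0).sum(axis=1) >= 3]
            res = envadapt.titan_change_points(
                table, gradient, n_permutations=100, n_bootstrap=30, seed=k
            )
            flagged += len(res.indicators)
        assert flagged / (n_sim * 5) < 0.05

    def test_degenerate_factor_rejected(self, rng):
        table = random_count_table(rng, n_taxa=5, n_samples=6)
        factor = pd.Series([1.0, 1, 1, 2, 2, 2], index=table.columns, name="f")
        with pytest.raises(ValueError, match="distinct"):
            envadapt.titan_change_points(table, factor)


class TestBreadth:
    def _titan_result(self, cps, zs):
        taxa = pd.DataFrame(
            {
                "change_point": cps,
                "direction": [1] * len(cps),
                "indval": [80.0] * len(cps),
                "z": zs,
                "p_permutation": [0.01] * len(cps),
                "purity": [1.0] * len(cps),
                "reliability": [1.0] * len(cps),
            },
            index=[f"t{i}" for i in range(len(cps))],
        )
        return envadapt.TitanResult(taxa=taxa, factor="f", n_permutations=1, n_bootstrap=1)

    def test_shared_change_point_zero_span(self):
        res = envadapt.environmental_breadth(self._titan_result([2.0] * 5, [3.0] * 5))
        assert res.span_width == pytest.approx(0.0)

    def test_score_sum_linear_in_z(self):
        a = envadapt.environmental_breadth(self._titan_result([1, 2, 3], [2.0, 3.0, 4.0]))
        b = envadapt.environmental_breadth(self._titan_result([1, 2, 3], [4.0, 6.0, 8.0]))
        assert b.score_sum == pytest.approx(2 * a.score_sum)

    def test_too_few_indicators_warns_missing(self):
        with pytest.warns(UserWarning, match="breadth"):
            res = envadapt.environmental_breadth(self._titan_result([1.0], [2.0]))
        assert np.isnan(res.span_width)

    def test_wider_planted_dispersion_gives_wider_span(self, rng):
        """Indicator change points drawn from a 2x wider distribution give a
        wider 5-95 percentile span in nearly every replicate."""
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            local = np.random.default_rng(seed)
            narrow = 5.0 + local.uniform(-1, 1, 12)
            wide = 5.0 + local.uniform(-2, 2, 12)
            a = envadapt.environmental_breadth(
                self._titan_result(narrow, np.ones(12) * 3)
            )
            b = envadapt.environmental_breadth(
                self._titan_result(wide, np.ones(12) * 3)
            )
            wins += b.span_width > a.span_width
        assert wins >= int(0.95 * n_seeds)
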