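"""ANOVA, Duncan's multiple range test, contrasts, correlations, importance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from soilfq.errors import DomainError
from soilfq.stats import (
    anova_oneway,
    correlation_matrix,
    duncan_lsr,
    duncan_mrt,
    percent_contrast,
    star_code,
    variable_importance,
)


def brute_force_anova(groups):
    """Independent oracle: direct sums of squares over the raw values."""
    all_vals = np.concatenate([np.asarray(g, float) for g in groups])
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    return (ssb / (len(groups) - 1)) / (ssw / (len(all_vals) - len(groups)))


class TestAnova:
    def test_identical_groups_f_zero(self):
        res = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert res.F == pytest.approx(0.0)

    def test_separated_groups_tiny_p(self):
        res = anova_oneway([[0, 1e-4, -1e-4], [10, 10.0001, 9.9999]])
        assert res.p < 1e-6

    def test_hand_worked_example(self):
        """Groups (1,2,3),(4,5,6),(8,9,10): SSB=74, SSW=6, df=(2,6) -> F=37."""
        res = anova_oneway([(1, 2, 3), (4, 5, 6), (8, 9, 10)])
        assert res.F == pytest.approx(37.0, abs=1e-10)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.mse == pytest.approx(1.0)

    def test_group_size_domain(self):
        with pytest.raises(DomainError):
            anova_oneway([[1.0], [2.0, 3.0]])

    def test_matches_brute_force_and_scipy_on_random_inputs(self, rng):
        for _ in range(50):
            k = rng.integers(2, 6)
            groups = [rng.normal(rng.uniform(-3, 3), 1.0, size=rng.integers(2, 9))
                      for _ in range(k)]
            res = anova_oneway(groups)
            assert res.F == pytest.approx(brute_force_anova(groups), abs=1e-10)
            scipy_res = sstats.f_oneway(*groups)
            assert res.F == pytest.approx(scipy_res.statistic, rel=1e-10)
            assert res.p == pytest.approx(scipy_res.pvalue, rel=1e-8)


def duncan_share_oracle(groups, alpha=0.05):
    """Exhaustive pairwise-range oracle: for ordered means, walk all spans
    widest-first applying the containment rule, and report which ordered
    pairs are NOT separated."""
    names = list(groups)
    res = anova_oneway([groups[n] for n in names])
    ns = np.array([len(groups[n]) for n in names], float)
    n_h = len(ns) / np.sum(1.0 / ns)
    order = sorted(names, key=lambda n: -np.mean(groups[n]))
    means = [np.mean(groups[n]) for n in order]
    k = len(order)
    nonsig = set()
    for span in range(k, 1, -1):
        for i in range(k - span + 1):
            j = i + span - 1
            lsr = duncan_lsr(span, res.df_within, res.mse, n_h, alpha)
            contained_in_nonsig = any(
                (a, b) in nonsig for a in range(0, i + 1) for b in range(j, k)
                if (a, b) != (i, j) and b - a > j - i
            )
            if means[i] - means[j] < lsr or contained_in_nonsig:
                nonsig.add((i, j))
    share = {}
    for i in range(k):
        for j in range(i + 1, k):
            covered = any(a <= i and j <= b for (a, b) in nonsig)
            share[(order[i], order[j])] = covered
    return share


def letters_share(frame):
    share = {}
    letters = dict(zip(frame.group, frame.letters))
    names = list(frame.group)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            share[(names[i], names[j])] = bool(
                set(letters[names[i]]) & set(letters[names[j]]))
    return share


class TestDuncan:
    def test_identical_groups_share_one_letter(self):
        out = duncan_mrt({"A": [5, 5.1, 4.9], "B": [5, 5.1, 4.9], "C": [5, 5.1, 4.9]})
        assert set(out.letters) == {"a"}

    def test_well_separated_groups_get_distinct_letters(self):
        out = duncan_mrt({
            "hi": [100, 100.01, 99.99],
            "mid": [50, 50.01, 49.99],
            "lo": [0, 0.01, -0.01],
        })
        assert list(out.letters) == ["a", "b", "c"]
        assert list(out.group) == ["hi", "mid", "lo"]

    def test_letters_match_pairwise_range_oracle(self, rng):
        """Letter sharing must reproduce the exhaustive span-by-span oracle
        on random three-group toys, including marginal separations."""
        for trial in range(60):
            spread = rng.uniform(0.0, 3.0)
            groups = {
                name: list(rng.normal(mu * spread, 1.0, size=4))
                for name, mu in (("g1", 0.0), ("g2", 0.8), ("g3", 1.6))
            }
            got = letters_share(duncan_mrt(groups))
            want = duncan_share_oracle(groups)
            assert got == want, f"trial {trial}: {got} != {want}"

    def test_order_consistency(self, rng):
        """If two groups share a letter, any group with an intermediate mean
        shares it too."""
        for _ in range(40):
            groups = {f"g{i}": list(rng.normal(rng.uniform(0, 3), 1.0, size=3))
                      for i in range(4)}
            out = duncan_mrt(groups)
            means = dict(zip(out.group, out["mean"]))
            letters = dict(zip(out.group, out.letters))
            names = list(out.group)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    common = set(letters[names[i]]) & set(letters[names[j]])
                    for mid in names[i + 1:j]:
                        assert common <= set(letters[mid])

    def test_null_separation_rate_is_stable(self):
        """Under equal means (k=3, n=3), the fraction of simulations that
        declare any separation is a fixed procedural property; assert its
        Monte-Carlo value stays in a band established by this implementation."""
        rng = np.random.default_rng(99)
        flagged = 0
        runs = 400
        for _ in range(runs):
            groups = {f"g{i}": list(rng.normal(0.0, 1.0, size=3)) for i in range(3)}
            out = duncan_mrt(groups)
            flagged += len(set("".join(out.letters))) > 1
        rate = flagged / runs
        assert 0.02 < rate < 0.20

    def test_fewer_than_two_groups(self):
        with pytest.raises(DomainError):
            duncan_mrt({"only": [1, 2, 3]})


class TestPercentContrast:
    @pytest.mark.parametrize("ref,cmp_,expected", [
        (2985, 3483, 16.7),
        (3028, 3483, 15.0),
        (20.0, 22.0, 10.0),
        (5.0, 5.0, 0.0),
    ])
    def test_reported_contrasts(self, ref, cmp_, expected):
        assert percent_contrast(ref, cmp_) == expected

    def test_half_up_rounding(self):
        assert percent_contrast(1000, 1001.5) == 0.2  # 0.15 rounds up

    def test_nonpositive_reference(self):
        with pytest.raises(DomainError):
            percent_contrast(0, 5)

    @given(st.floats(min_value=100, max_value=1000),
           st.floats(min_value=100, max_value=1000))
    @settings(max_examples=200, derandomize=True)
    def test_reciprocal_relation(self, a, b):
        p1 = percent_contrast(a, b)
        p2 = percent_contrast(b, a)
        # (1 + p1/100)(1 + p2/100) = 1 up to the two half-up rounding steps
        # (each <= 0.05 percentage points, amplified by the ratio <= 10)
        assert (1 + p1 / 100) * (1 + p2 / 100) == pytest.approx(1.0, abs=0.011)


class TestCorrelation:
    def test_perfect_positive(self):
        x = np.arange(6, dtype=float)
        res = correlation_matrix(pd.DataFrame({"x": x, "y": 2 * x}))
        assert res.r.loc["x", "y"] == pytest.approx(1.0)
        assert res.stars.loc["x", "y"] == "***"

    def test_perfect_negative(self):
        x = np.arange(5, dtype=float)
        res = correlation_matrix(pd.DataFrame({"x": x, "y": -x}))
        assert res.r.loc["x", "y"] == pytest.approx(-1.0)

    def test_diagonal_is_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        res = correlation_matrix(df)
        np.testing.assert_allclose(np.diag(res.r), 1.0)

    def test_constant_variable_flagged(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=8), "b": np.ones(8)})
        res = correlation_matrix(df)
        assert res.constant_variables == ["b"]
        assert np.isnan(res.r.loc["a", "b"])

    def test_null_correlation_rarely_large(self):
        """n=10 independent normals: |r| < 0.64 (the p=0.05 threshold is
        ~0.632) in >= 95% of seeds."""
        ok = 0
        for seed in range(200):
            g = np.random.default_rng(seed)
            res = correlation_matrix(pd.DataFrame({
                "x": g.normal(size=10), "y": g.normal(size=10)}))
            ok += abs(res.r.loc["x", "y"]) < 0.64
        assert ok / 200 >= 0.95

    def test_star_thresholds(self):
        assert [star_code(p) for p in (0.0005, 0.005, 0.04, 0.2)] == \
            ["***", "**", "*", ""]


class TestVariableImportance:
    def test_planted_signal_ranked_first(self):
        """Response dominated by predictor A: A must top the ranking in
        >= 95% of seeds, and a pure-noise predictor must sit at the bottom
        in >= 90%."""
        top, bottom = 0, 0
        n_seeds = 100
        for seed in range(n_seeds):
            g = np.random.default_rng(seed)
            X = pd.DataFrame(g.normal(size=(60, 5)), columns=list("ABCDE"))
            y = 2.0 * X["A"] + 1.0 * X["B"] + 0.8 * X["C"] + 0.8 * X["D"] \
                + g.normal(scale=0.5, size=60)
            res = variable_importance(X, y, seed=seed, n_estimators=120, n_repeats=10)
            top += res.importances.feature.iloc[0] == "A"
            bottom += res.importances.feature.iloc[-1] == "E"
        assert top / n_seeds >= 0.95
        assert bottom / n_seeds >= 0.90

    def test_too_few_observations(self, rng):
        X = pd.DataFrame(rng.normal(size=(9, 2)), columns=["a", "b"])
        with pytest.raises(DomainError, match=">= 10"):
            variable_importance(X, rng.normal(size=9))

    def test_constant_response(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        with pytest.raises(DomainError, match="constant"):
            variable_importance(X, np.ones(12))
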