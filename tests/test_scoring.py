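"""Z-score standardization, composite-score invariances and ranking."""

import numpy as np
import pandas as pd
import pytest

from soilfq.errors import DomainError, ValidationError
from soilfq.scoring import (
    ConstantInputWarning,
    composite_score,
    quadratic_fit,
    rank_treatments,
    zscore,
)


def _obs(values_by_treatment, indicators=("BD", "SWC", "MWD", "SOCs"),
         n_layers=2, n_reps=3):
    """Build a tidy observation frame where each treatment's indicator values
    are offset by a treatment-specific constant."""
    rows = []
    rng = np.random.default_rng(5)
    base = {ind: rng.uniform(1, 10, size=(n_layers, n_reps)) for ind in indicators}
    for t, offset in values_by_treatment.items():
        for layer in range(n_layers):
            for rep in range(n_reps):
                row = {"layer": f"L{layer}", "treatment": t, "replicate": rep + 1}
                for ind in indicators:
                    row[ind] = base[ind][layer, rep] + offset
                rows.append(row)
    return pd.DataFrame(rows)


class TestZscore:
    def test_unit_spacing(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1])

    def test_constant_input_warns_and_zeroes(self):
        with pytest.warns(ConstantInputWarning):
            z = zscore([4.0, 4.0, 4.0])
        np.testing.assert_array_equal(z, 0.0)

    def test_too_few_values(self):
        with pytest.raises(DomainError):
            zscore([1.0])

    def test_population_mode(self):
        z = zscore([1, 2, 3], sd_mode="population")
        assert z.std(ddof=0) == pytest.approx(1.0)

    def test_mean_zero_unit_sd_property(self, rng):
        for _ in range(1000):
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 10), size=rng.integers(3, 30))
            z = zscore(x)
            assert abs(z.mean()) < 1e-9
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestCompositeScore:
    def test_identical_treatments_give_zero_totals(self):
        obs = _obs({"FNT": 0.0, "FST": 0.0, "FPT": 0.0})
        # make treatments truly identical replicate-by-replicate
        tab = composite_score(obs)
        # replicate noise differs within layer, but treatment means coincide
        summary = tab.treatment_summary()
        per_layer = summary[summary.layer != "overall"]
        means = per_layer.groupby("layer")["mean"].sum()
        np.testing.assert_allclose(means, 0.0, atol=1e-9)

    def test_per_layer_z_sums_to_zero(self):
        obs = _obs({"FNT": 1.0, "FST": 0.0, "FPT": -1.0})
        tab = composite_score(obs)
        sums = tab.scores.groupby(["layer", "indicator"])["z"].sum()
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)

    def test_affine_invariance_of_single_indicator(self):
        obs = _obs({"FNT": 1.0, "FST": 0.0, "FPT": -1.0})
        tab1 = composite_score(obs)
        shifted = obs.copy()
        shifted["SWC"] = 3.7 * shifted["SWC"] + 11.0
        tab2 = composite_score(shifted)
        pd.testing.assert_frame_equal(tab1.totals, tab2.totals, atol=1e-9)

    def test_uniform_bd_shift_leaves_totals_unchanged(self):
        obs = _obs({"FNT": 1.0, "FST": 0.0, "FPT": -1.0})
        tab1 = composite_score(obs)
        shifted = obs.copy()
        shifted["BD"] = shifted["BD"] + 0.5
        tab2 = composite_score(shifted)
        pd.testing.assert_frame_equal(tab1.totals, tab2.totals, atol=1e-9)

    def test_raising_one_treatments_bd_lowers_its_total(self):
        obs = _obs({"FNT": 0.0, "FST": 0.0, "FPT": 0.0})
        tab1 = composite_score(obs)
        worse = obs.copy()
        worse.loc[worse.treatment == "FNT", "BD"] += 2.0
        tab2 = composite_score(worse)
        t1 = tab1.totals[tab1.totals.treatment == "FNT"]["total_z"].mean()
        t2 = tab2.totals[tab2.totals.treatment == "FNT"]["total_z"].mean()
        assert t2 < t1

    def test_missing_indicator_named(self):
        obs = _obs({"FNT": 0.0, "FST": 0.0}).drop(columns=["MWD"])
        with pytest.raises(ValidationError, match="MWD"):
            composite_score(obs)

    def test_means_pooling_mode(self):
        obs = _obs({"FNT": 1.0, "FST": 0.0, "FPT": -1.0})
        tab = composite_score(obs, pool="means")
        assert set(tab.totals.groupby(["layer", "treatment"]).size()) == {1}


class TestRanking:
    def test_orders_by_mean_total(self):
        obs = _obs({"FNT": 2.0, "FST": 0.0, "FPT": -2.0})
        rk = rank_treatments(composite_score(obs))
        assert list(rk.table.treatment) == ["FNT", "FST", "FPT"]
        assert not rk.tied

    def test_exact_tie_alphabetical_and_flagged(self):
        obs = _obs({"B_trt": 0.0, "A_trt": 0.0})
        # symmetric construction: both treatments identical -> exact tie
        rk = rank_treatments(composite_score(obs))
        assert list(rk.table.treatment) == ["A_trt", "B_trt"]
        assert rk.tied

    def test_single_treatment(self):
        obs = _obs({"FNT": 0.0}, n_reps=3)
        rk = rank_treatments(composite_score(obs))
        assert list(rk.table.treatment) == ["FNT"]


class TestQuadraticFit:
    def test_exact_coefficient_recovery(self):
        z = np.array([-2.0, -1.0, 0.0, 1.0, 2.0, 3.0])
        y = -2.0 * z**2 + 1.0 * z + 5.0
        fit = quadratic_fit(z, y)
        assert fit.a == pytest.approx(-2.0, abs=1e-9)
        assert fit.b == pytest.approx(1.0, abs=1e-9)
        assert fit.c == pytest.approx(5.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.opens_downward

    def test_collinear_points_not_downward(self):
        z = np.array([0.0, 1.0, 2.0, 3.0])
        fit = quadratic_fit(z, 2 * z + 1)
        assert fit.a == pytest.approx(0.0, abs=1e-9)
        assert not fit.opens_downward

    def test_too_few_distinct_scores(self):
        with pytest.raises(DomainError):
            quadratic_fit([1.0, 1.0, 2.0], [1.0, 1.0, 2.0])
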