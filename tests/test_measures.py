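"""Potency read-outs: median, AUC, RI, 4PL/IC50 and MINE statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combinet.measures import (
    DoseResponseSeries,
    InvalidSeriesError,
    auc,
    compare_measures,
    compute_measures,
    fit_4pl,
    four_pl,
    ic50,
    median_viability,
    measures_table,
    mine_statistics,
    relative_inhibition,
    series_from_long,
)

from conftest import HALF_LOG_DOSES, make_series


class TestMedianViability:
    @pytest.mark.parametrize(
        "responses, expected",
        [
            ([0.2, 0.5, 0.9], 0.5),
            ([0.2, 0.4, 0.6, 1.0], 0.5),
            ([1.0, 1.0, 1.0], 1.0),
        ],
    )
    def test_order_statistic(self, responses, expected):
        assert median_viability(make_series(responses)) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1.2), min_size=2, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_and_bounded(self, responses):
        s = make_series(responses)
        m = median_viability(s)
        assert min(responses) <= m <= max(responses)
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(responses))
        assert median_viability(make_series(shuffled)) == pytest.approx(m)

    def test_series_invariants(self):
        with pytest.raises(InvalidSeriesError):
            make_series([0.5])  # single dose
        with pytest.raises(InvalidSeriesError):
            make_series([0.5, 0.6], doses=[10.0, 10.0])  # non-increasing
        with pytest.raises(InvalidSeriesError):
            make_series([0.5, 0.6], doses=[-1.0, 10.0])  # non-positive dose


class TestFourPL:
    def test_recovers_exact_model(self):
        y = four_pl(HALF_LOG_DOSES, 1.0, 0.0, 100.0, 1.0)
        fit = fit_4pl(make_series(y, doses=HALF_LOG_DOSES))
        assert fit.converged and not fit.degenerate
        assert fit.ec50 == pytest.approx(100.0, rel=0.01)
        for got, want in [(fit.upper, 1.0), (fit.lower, 0.0), (fit.slope, 1.0)]:
            assert got == pytest.approx(want, rel=1e-3, abs=1e-3)

    @pytest.mark.parametrize("upper,lower,ec50,slope", [
        (1.0, 0.0, 100.0, 1.0),
        (1.1, 0.2, 316.0, 2.0),
        (0.9, 0.1, 50.0, 0.7),
    ])
    def test_parameter_recovery_noiseless(self, upper, lower, ec50, slope):
        y = four_pl(HALF_LOG_DOSES, upper, lower, ec50, slope)
        fit = fit_4pl(make_series(y, doses=HALF_LOG_DOSES))
        assert fit.upper == pytest.approx(upper, rel=1e-3)
        assert fit.lower == pytest.approx(lower, rel=1e-3, abs=1e-3)
        assert fit.ec50 == pytest.approx(ec50, rel=1e-3)
        assert fit.slope == pytest.approx(slope, rel=1e-3)

    def test_constant_series_degenerate(self):
        fit = fit_4pl(make_series([1.0] * 5))
        assert fit.degenerate and not fit.inhibitory
        assert np.isnan(ic50(fit, "relative"))

    def test_stimulation_flagged(self):
        y = four_pl(HALF_LOG_DOSES, 1.0, 0.0, 100.0, 1.0)[::-1]  # increasing
        fit = fit_4pl(make_series(y, doses=HALF_LOG_DOSES))
        assert not fit.inhibitory
        assert fit.slope < 0

    def test_few_doses_fixed_slope(self):
        y = four_pl(np.array([10.0, 100.0, 1000.0]), 1.0, 0.0, 100.0, 1.0)
        fit = fit_4pl(make_series(y, doses=[10.0, 100.0, 1000.0]))
        assert fit.slope == pytest.approx(1.0)


class TestIC50:
    def fit(self, upper=1.0, lower=0.0, ec50=100.0, slope=1.0):
        y = four_pl(HALF_LOG_DOSES, upper, lower, ec50, slope)
        return fit_4pl(make_series(y, doses=HALF_LOG_DOSES))

    def test_relative_is_ec50(self):
        assert ic50(self.fit(), "relative") == pytest.approx(100.0, rel=0.01)

    def test_absolute_on_symmetric_curve(self):
        # solve 4PL = 0.5 analytically: upper=1, lower=0 → d = ec50
        assert ic50(self.fit(), "absolute") == pytest.approx(100.0, rel=0.01)

    def test_absolute_undefined_above_half(self):
        assert np.isnan(ic50(self.fit(lower=0.6), "absolute"))

    def test_absolute_asymmetric_closed_form(self):
        f = self.fit(upper=1.0, lower=0.2, ec50=100.0, slope=2.0)
        # (d/ec50)^2 = (1-0.5)/(0.5-0.2) → d = 100·(5/3)^(1/2)
        assert ic50(f, "absolute") == pytest.approx(100.0 * (5 / 3) ** 0.5, rel=0.01)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            ic50(self.fit(), "banana")


class TestAUCandRI:
    def test_constant_viability_normalised(self):
        assert auc(make_series([1.0] * 5)) == pytest.approx(1.0)
        assert auc(make_series([0.0] * 5)) == pytest.approx(0.0)

    def test_hand_trapezoid(self):
        # viability 1.0 over first half of log range, 0.0 over second half
        doses = [1.0, 10.0, 100.0, 1000.0, 10000.0]
        resp = [1.0, 1.0, 1.0, 0.0, 0.0]
        # trapezoids on log10 axis: 1·1 + 1·1 + 0.5·1 + 0 = 2.5, span 4
        assert auc(make_series(resp, doses=doses)) == pytest.approx(2.5 / 4)

    @pytest.mark.parametrize("resp, expected", [
        ([0.0] * 4, 100.0),
        ([1.0] * 4, 0.0),
        ([1.2] * 4, -20.0),
    ])
    def test_relative_inhibition_examples(self, resp, expected):
        assert relative_inhibition(make_series(resp)) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1.2), min_size=2, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_ri_auc_identity(self, resp):
        s = make_series(resp)
        assert relative_inhibition(s) + 100.0 * auc(s) == pytest.approx(100.0)

    def test_on_fit_matches_raw_for_exact_4pl(self):
        y = four_pl(HALF_LOG_DOSES, 1.0, 0.0, 100.0, 1.0)
        s = make_series(y, doses=HALF_LOG_DOSES)
        assert auc(s, on_fit=True) == pytest.approx(auc(s), abs=0.02)


def _exhaustive_mic_oracle(x, y, max_k=3):
    """Max normalised MI over ALL cut placements for grids up to max_k bins."""
    from itertools import combinations

    import numpy as np

    n = len(x)
    best = 0.0
    ox, oy = np.argsort(x), np.argsort(y)

    def partitions(order, k):
        for cuts in combinations(range(1, n), k - 1):
            lab = np.zeros(n, dtype=int)
            prev = 0
            for b, c in enumerate(list(cuts) + [n]):
                lab[order[prev:c]] = b
                prev = c
            yield lab

    for a in range(2, max_k + 1):
        for b in range(2, max_k + 1):
            for lx in partitions(ox, a):
                for ly in partitions(oy, b):
                    joint = np.zeros((a, b))
                    np.add.at(joint, (lx, ly), 1.0)
                    joint /= n
                    px, py = joint.sum(1), joint.sum(0)
                    nz = joint > 0
                    mi = np.sum(joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz]))
                    best = max(best, mi / np.log2(min(a, b)))
    return best


class TestMineStatistics:
    def test_perfect_relation(self):
        x = np.arange(100, dtype=float)
        mic, mas, mev = mine_statistics(x, x)
        assert mic == pytest.approx(1.0, abs=0.05)

    def test_independent_uniform_low(self):
        rng = np.random.default_rng(42)
        mic, _, _ = mine_statistics(rng.random(200), rng.random(200))
        assert mic < 0.4

    def test_parabola_vs_small_grid_oracle(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(-1, 1, 24))
        y = x**2
        mic, mas, mev = mine_statistics(x, y)
        oracle = _exhaustive_mic_oracle(x, y, max_k=3)
        # the equal-frequency approximation cannot exceed the exhaustive optimum
        assert mic <= oracle + 0.05
        assert mas > 0
        assert mev <= mic

    def test_constant_vector_zero(self):
        assert mine_statistics(np.ones(20), np.arange(20.0)) == (0.0, 0.0, 0.0)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_mev_le_mic_fuzz(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        y = rng.normal(size=40) + (seed % 3) * x
        mic, mas, mev = mine_statistics(x, y)
        assert 0.0 <= mev <= mic <= 1.0
        assert 0.0 <= mas <= 1.0


class TestCompareMeasures:
    def test_identical_columns_perfect_association(self):
        rng = np.random.default_rng(1)
        v = rng.random(60)
        table = pd.DataFrame({"median_viability": v, "auc": v})
        cmp = compare_measures(table, measures=("median_viability", "auc"))
        assert cmp.pearson.loc["median_viability", "auc"] == pytest.approx(1.0)
        assert cmp.mic.loc["median_viability", "auc"] == pytest.approx(1.0, abs=0.05)

    def test_too_few_rows(self):
        table = pd.DataFrame({"median_viability": [0.1, 0.2], "auc": [0.1, 0.2]})
        with pytest.raises(ValueError):
            compare_measures(table, measures=("median_viability", "auc"))

    def test_synthetic_cohort_median_tracks_auc(self, small_cohort):
        responses, _ = small_cohort
        series = series_from_long(responses)
        table = measures_table(series, with_fit=True)
        cmp = compare_measures(table)
        r_median_auc = cmp.pearson.loc["median_viability", "auc"]
        r_icrel_auc = cmp.pearson.loc["ic50_rel", "auc"]
        assert r_median_auc > r_icrel_auc
        assert r_median_auc > 0.9


def test_replicates_aggregated_by_mean():
    df = pd.DataFrame({
        "drug_id": ["A"] * 4,
        "sample_id": ["S"] * 4,
        "dose_nM": [10.0, 10.0, 100.0, 100.0],
        "response": [0.8, 1.0, 0.2, 0.4],
    })
    (s,) = series_from_long(df)
    assert s.responses == pytest.approx([0.9, 0.3])
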