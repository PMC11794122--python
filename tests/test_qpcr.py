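"""Standard-curve simulation, fitting, inversion, LOD and efficiency."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qdacsim.qpcr import (
    REFERENCE_CURVE,
    QPCRWell,
    StandardCurve,
    amplification_efficiency,
    estimate_lod,
    fit_standard_curve,
    invert_ct,
    read_plate,
    simulate_ct,
    write_plate,
)


class TestSimulateCt:
    def test_published_curve_at_one_log_dilution(self):
        well = simulate_ct(1.0, REFERENCE_CURVE, noise_sd=0.0)
        assert well.ct == pytest.approx(12.203, abs=1e-12)

    def test_intercept_at_undiluted(self):
        assert simulate_ct(0.0, REFERENCE_CURVE, noise_sd=0.0).ct == pytest.approx(8.144)

    def test_zero_template_is_undetermined(self):
        well = simulate_ct(math.inf, REFERENCE_CURVE, noise_sd=0.0)
        assert not well.determined

    def test_max_cycle_censoring(self):
        # x = 8 → Ct 40.6 on the published curve, beyond a 40-cycle run
        well = simulate_ct(8.0, REFERENCE_CURVE, noise_sd=0.0, max_cycles=40.0)
        assert not well.determined
        assert simulate_ct(8.0, REFERENCE_CURVE, noise_sd=0.0, max_cycles=45.0).determined


class TestFitStandardCurve:
    def test_noiseless_round_trip_recovers_published_parameters(self):
        pts = [(x, 4.059 * x + 8.144) for x in [0.0, 1.0, 2.0, 3.0, 4.0]]
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(4.059, abs=1e-9)
        assert curve.intercept == pytest.approx(8.144, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolate_exactly(self):
        curve = fit_standard_curve([(0.0, 10.0), (2.0, 16.0)])
        assert curve.slope == pytest.approx(3.0)
        assert curve.intercept == pytest.approx(10.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_undetermined_wells_excluded(self):
        pts = [(0.0, 8.144), (1.0, 12.203), (2.0, 16.262), (9.0, None)]
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(4.059, abs=1e-9)

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_standard_curve([(1.0, 12.0)])
        with pytest.raises(ValueError, match="distinct"):
            fit_standard_curve([(1.0, 12.0), (1.0, 12.1), (1.0, 11.9)])

    def test_ols_is_unbiased_under_replicate_noise(self):
        """Mean recovered slope over 200 noisy plates within 2% of truth."""
        rng = np.random.default_rng(2024)
        slopes = []
        for _ in range(200):
            wells = [
                simulate_ct(x, REFERENCE_CURVE, noise_sd=0.2, seed=rng, well_id=f"{x}{r}")
                for x in [0.0, 1.0, 2.0, 3.0, 4.0]
                for r in range(3)
            ]
            slopes.append(fit_standard_curve(wells).slope)
        assert np.mean(slopes) == pytest.approx(4.059, rel=0.02)

    def test_fit_invariant_to_ordering_and_duplication(self, rng):
        pts = [(x, 4.059 * x + 8.144 + e) for x, e in
               zip([0.0, 1.0, 2.0, 3.0], rng.normal(0, 0.2, 4))]
        base = fit_standard_curve(pts)
        shuffled = fit_standard_curve(list(reversed(pts)))
        doubled = fit_standard_curve(pts + pts)
        for other in (shuffled, doubled):
            assert other.slope == pytest.approx(base.slope, abs=1e-12)
            assert other.intercept == pytest.approx(base.intercept, abs=1e-12)


class TestInvertCt:
    def test_intercept_maps_to_zero(self):
        assert invert_ct(8.144, REFERENCE_CURVE) == pytest.approx(0.0, abs=1e-12)

    def test_printed_equation_inversion(self):
        assert invert_ct(12.203, REFERENCE_CURVE) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(min_value=-2.0, max_value=8.0, allow_nan=False))
    def test_simulate_invert_round_trip(self, x):
        well = simulate_ct(x, REFERENCE_CURVE, noise_sd=0.0, max_cycles=1e9)
        assert invert_ct(well.ct, REFERENCE_CURVE) == pytest.approx(x, abs=1e-12)

    def test_undetermined_rejected(self):
        with pytest.raises(ValueError, match="undetermined"):
            invert_ct(None, REFERENCE_CURVE)


def _wells(cts):
    return [QPCRWell(f"w{i}", "t", ct) for i, ct in enumerate(cts)]


class TestEstimateLod:
    def test_most_dilute_fully_detected_level(self):
        """Dilution series detected down to 100 pM; 10 pM and 1 pM drop out."""
        levels = {
            10.0: _wells([20.0, 20.1, 19.9]),   # 10 nM
            1.0: _wells([24.0, 24.2, 23.8]),
            0.1: _wells([27.0, 26.9, 27.1]),    # 100 pM
            0.01: _wells([29.7, None, 29.6]),   # 10 pM: one dropout
            0.001: _wells([None, None, None]),
        }
        assert estimate_lod(levels) == pytest.approx(0.1)

    def test_all_detected_returns_most_dilute_tested(self):
        levels = {10.0: _wells([20.0]), 1.0: _wells([24.0]), 0.1: _wells([27.0])}
        assert estimate_lod(levels) == pytest.approx(0.1)

    def test_all_undetermined_returns_none(self):
        assert estimate_lod({1.0: _wells([None, None])}) is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_lod({})

    def test_dilution_exponent_keying(self):
        levels = {0.0: _wells([8.1]), 1.0: _wells([12.2]), 2.0: _wells([None])}
        assert estimate_lod(levels, descending_concentration=False) == pytest.approx(1.0)

    def test_noise_never_helps_in_expectation(self):
        """Mean LOD (dilution exponent) over 500 paired plates: 0.5-cycle
        noise never reaches deeper dilution than the noiseless run."""
        xs = [5.0, 6.0, 7.0, 7.8, 8.2]

        def mean_lod(noise_sd, rng):
            lods = []
            for _ in range(500):
                levels = {
                    x: [simulate_ct(x, REFERENCE_CURVE, noise_sd=noise_sd, seed=rng,
                                    well_id=f"{x}{r}") for r in range(3)]
                    for x in xs
                }
                lod = estimate_lod(levels, descending_concentration=False)
                lods.append(lod if lod is not None else min(xs) - 1)
            return np.mean(lods)

        clean = mean_lod(0.0, np.random.default_rng(1))
        noisy = mean_lod(0.5, np.random.default_rng(2))
        assert noisy <= clean + 0.01

    def test_stricter_censoring_never_more_dilute(self):
        """With shared noise draws, lowering max_cycles can only lose levels."""
        xs = [5.0, 6.0, 7.0, 7.8]
        for seed in range(50):
            lods = {}
            for max_cycles in (40.0, 36.0):
                rng = np.random.default_rng(seed)
                levels = {
                    x: [simulate_ct(x, REFERENCE_CURVE, noise_sd=0.5, max_cycles=max_cycles,
                                    seed=rng, well_id=f"{x}{r}") for r in range(3)]
                    for x in xs
                }
                lod = estimate_lod(levels, descending_concentration=False)
                lods[max_cycles] = lod if lod is not None else min(xs) - 1
            assert lods[36.0] <= lods[40.0]


class TestAmplificationEfficiency:
    def test_perfect_doubling_slope(self):
        curve = StandardCurve(slope=math.log2(10), intercept=8.0)
        assert amplification_efficiency(curve) == pytest.approx(1.0, abs=1e-12)

    def test_published_curve_is_sub_ideal(self):
        assert amplification_efficiency(REFERENCE_CURVE) == pytest.approx(0.764, abs=1e-3)

    def test_monotone_decreasing_in_slope(self):
        slopes = np.linspace(3.0, 6.0, 30)
        effs = [amplification_efficiency(StandardCurve(slope=s, intercept=8.0)) for s in slopes]
        assert all(b < a for a, b in zip(effs, effs[1:]))


class TestPersistence:
    def test_plate_csv_round_trip(self, tmp_path):
        wells = [
            QPCRWell("A1", "sample", 21.5, 1.0),
            QPCRWell("A2", "sample", None, 5.0),
            QPCRWell("B1", "standard", 8.144, 0.0),
        ]
        path = tmp_path / "plate.csv"
        write_plate(wells, path)
        assert read_plate(path) == wells

    def test_curve_json_round_trip(self, tmp_path):
        curve = StandardCurve(slope=4.059, intercept=8.144, r_squared=0.998, x_range=(0.0, 4.0))
        path = tmp_path / "curve.json"
        curve.to_json(path)
        assert StandardCurve.from_json(path) == curve
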