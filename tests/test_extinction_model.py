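"""Sighting-rate extinction estimator: closed forms, resampling, invariants."""

import dataclasses
import math

import numpy as np
import pytest

from bonechron import (
    EstimatorConfig,
    InsufficientDataError,
    OccurrenceRecord,
    Source,
    UndefinedRateError,
    estimate_extinction,
    point_estimate_single,
    point_estimate_weighted,
)
from bonechron.extinction_model import _resample_estimates


def _series(ages, sigma=0.0, region="r", source=Source.FOSSIL):
    return [
        OccurrenceRecord(f"{region}_{i:03d}", region, source, float(a), float(sigma))
        for i, a in enumerate(ages)
    ]


class TestPointEstimates:
    def test_three_sighting_closed_form(self):
        # lambda = 2/200 = 0.01; offset = ln(0.05)/ln(0.99); estimate younger
        # than the last sighting by that offset
        est = point_estimate_single([1000.0, 900.0, 800.0], 0, 0.05)
        offset = math.log(0.05) / math.log(0.99)
        assert offset == pytest.approx(298.07, abs=0.01)
        assert est == pytest.approx(800.0 - offset, rel=1e-12)

    def test_saturated_record_returns_youngest(self):
        # yearly sightings: rate 1/yr, persistence already below alpha
        ages = list(range(1010, 999, -1))
        assert point_estimate_single(ages, 0, 0.05) == 1000.0

    def test_alpha_near_one_limit_returns_youngest(self):
        est = point_estimate_single([1000.0, 900.0, 800.0], 0, 1 - 1e-12)
        assert est == pytest.approx(800.0, abs=1e-6)

    def test_reference_equal_to_youngest_is_undefined(self):
        with pytest.raises(UndefinedRateError):
            point_estimate_single([1000.0, 800.0, 800.0], 2, 0.05)

    def test_evenly_spaced_record_gives_common_value(self):
        # equal spacing -> every reference implies the same rate, so the
        # weighted combination equals the common single-reference estimate
        ages = [1400.0, 1300.0, 1200.0, 1100.0, 1000.0]
        single = point_estimate_single(ages, 0, 0.05)
        assert point_estimate_weighted(ages, 0.05) == pytest.approx(single, rel=1e-12)

    def test_weighted_matches_brute_force_loop(self):
        rng = np.random.default_rng(11)
        ages = sorted(rng.uniform(5000, 20000, size=5), reverse=True)
        got = point_estimate_weighted(ages, 0.05)
        num = den = 0.0
        for i in range(len(ages) - 1):
            w = 1.0 / (ages[i] - ages[-1])
            num += w * point_estimate_single(ages, i, 0.05)
            den += w
        assert got == pytest.approx(num / den, rel=1e-12)
        assert min(
            point_estimate_single(ages, i, 0.05) for i in range(4)
        ) <= got <= max(point_estimate_single(ages, i, 0.05) for i in range(4))

    def test_min_sightings_boundary(self):
        assert point_estimate_weighted([3.0, 2.0, 1.0], 0.05, min_sightings=3)
        with pytest.raises(InsufficientDataError):
            point_estimate_weighted([2.0, 1.0], 0.05, min_sightings=3)

    def test_duplicate_ages_rejected(self):
        with pytest.raises(UndefinedRateError):
            point_estimate_weighted([1000.0, 900.0, 900.0, 800.0], 0.05)


class TestResampledEstimate:
    def test_zero_dating_error_collapses_interval(self):
        ages = [14000.0, 12500.0, 11800.0, 11000.0]
        est = estimate_extinction(_series(ages), EstimatorConfig(n_resamples=200, seed=5))
        deterministic = point_estimate_weighted(sorted(ages, reverse=True), 0.05)
        assert est.median == est.ci_lower == est.ci_upper == deterministic
        assert est.mean == pytest.approx(deterministic, rel=1e-12)

    def test_duplicate_ages_with_zero_error_resolved_by_jitter(self):
        ages = [14000.0, 12500.0, 12500.0, 11000.0]
        est = estimate_extinction(_series(ages), EstimatorConfig(n_resamples=50, seed=5))
        assert math.isfinite(est.median)
        assert est.median < 11000.0

    def test_bit_identical_under_fixed_seed(self, occurrence_records):
        fossils = [r for r in occurrence_records if r.source is Source.FOSSIL]
        cfg = EstimatorConfig(n_resamples=500, seed=123)
        assert estimate_extinction(fossils, cfg) == estimate_extinction(fossils, cfg)

    def test_different_seeds_differ(self, occurrence_records):
        fossils = [r for r in occurrence_records if r.source is Source.FOSSIL]
        a = estimate_extinction(fossils, EstimatorConfig(n_resamples=500, seed=1))
        b = estimate_extinction(fossils, EstimatorConfig(n_resamples=500, seed=2))
        assert a.median != b.median

    def test_estimate_never_older_than_resample_youngest(self):
        # extinction cannot precede the last sighting within any resample
        ages = np.array([15000.0, 13000.0, 12000.0, 11500.0, 11000.0])
        sigmas = np.full(5, 150.0)
        cfg = EstimatorConfig(n_resamples=300, seed=9)
        ests = _resample_estimates(ages, sigmas, np.arange(5) * 1e-6, cfg)
        rng = np.random.default_rng(cfg.seed)
        draws = ages[None, :] + sigmas[None, :] * rng.standard_normal((300, 5))
        assert np.all(ests <= draws.min(axis=1) + 1e-9)

    def test_denser_records_estimate_closer_to_last_sighting(self):
        # same span, doubled density -> doubled rate -> smaller offset
        sparse = estimate_extinction(
            _series(np.arange(11000, 16001, 100)[::-1]),
            EstimatorConfig(n_resamples=50, seed=3),
        )
        dense = estimate_extinction(
            _series(np.arange(11000, 16001, 50)[::-1]),
            EstimatorConfig(n_resamples=50, seed=3),
        )
        assert 11000 - dense.median < 11000 - sparse.median

    def test_interval_can_reach_past_present(self):
        # a sparse record ending near the present: the younger bound goes
        # negative ("includes the modern day") and is not clamped
        est = estimate_extinction(
            _series([1400.0, 1150.0, 900.0], sigma=300.0, source=Source.EDNA),
            EstimatorConfig(n_resamples=2000, seed=21),
        )
        assert est.ci_upper < 0 < est.ci_lower

    def test_ordering_invariant_on_bp_axis(self, occurrence_records):
        fossils = [r for r in occurrence_records if r.source is Source.FOSSIL]
        est = estimate_extinction(fossils, EstimatorConfig(n_resamples=400, seed=2))
        assert est.ci_lower >= est.median >= est.ci_upper

    def test_mixed_region_or_source_rejected(self, occurrence_records):
        with pytest.raises(ValueError):
            estimate_extinction(occurrence_records, EstimatorConfig(n_resamples=10))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EstimatorConfig(alpha=0.0)
        with pytest.raises(ValueError):
            EstimatorConfig(n_resamples=0)

    def test_row_order_does_not_change_result(self, occurrence_records):
        fossils = [r for r in occurrence_records if r.source is Source.FOSSIL]
        cfg = EstimatorConfig(n_resamples=300, seed=8)
        assert estimate_extinction(fossils, cfg) == estimate_extinction(
            fossils[::-1], cfg
        )
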