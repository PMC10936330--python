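"""Baseline profile, dB change, stun classification and the per-animal chain."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stuneeg.assess import (
    AssessmentConfig,
    BaselineProfile,
    DBChangeSeries,
    assess_animal,
    classify_stun,
    db_change,
)
from stuneeg.spectral import BandPowerSeries
from stuneeg.synth import BandSpectrumParams, generate_baseline_trace

from conftest import make_animal


def make_series(band_powers: dict, total=None, clean=None, starts=None):
    names = tuple(band_powers)
    arr = np.column_stack([np.asarray(band_powers[n], dtype=float) for n in names])
    n = arr.shape[0]
    total = np.asarray(total) if total is not None else arr.sum(axis=1)
    return BandPowerSeries(
        starts=np.asarray(starts) if starts is not None else 0.75 * np.arange(n),
        band_names=names, powers=arr, total=total,
        clean=np.asarray(clean) if clean is not None else np.ones(n, bool),
    )


class TestDBChange:
    def test_printed_formula_values(self):
        assert db_change(5.0, 5.0) == 0.0
        assert db_change(50.0, 5.0) == pytest.approx(100.0)
        assert db_change(10.0, 5.0) == pytest.approx(30.103, abs=1e-3)

    def test_conventional_scale(self):
        assert db_change(10.0, 5.0, scale=10.0) == pytest.approx(3.0103, abs=1e-4)

    def test_zero_value_maps_to_minus_inf(self):
        assert db_change(0.0, 5.0) == -np.inf

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            db_change(1.0, 0.0)

    @given(v=st.floats(1e-6, 1e6), b=st.floats(1e-6, 1e6), c=st.floats(1e-3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_and_antisymmetry(self, v, b, c):
        assert db_change(c * v, c * b) == pytest.approx(db_change(v, b), abs=1e-6)
        assert db_change(v, b) == pytest.approx(-db_change(b, v), abs=1e-9)

    @given(v1=st.floats(1e-6, 1e6), v2=st.floats(1e-6, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_value(self, v1, v2):
        if v1 < v2:
            assert db_change(v1, 1.0) < db_change(v2, 1.0)


class TestBaselineProfile:
    def test_constant_powers_give_those_medians(self):
        s = make_series({"delta": [2.0] * 5, "theta": [3.0] * 5})
        b = BaselineProfile.from_series(s)
        assert b.band_medians == {"delta": 2.0, "theta": 3.0}
        assert b.low_median == 5.0

    def test_median_is_middle_order_statistic(self):
        s = make_series({"delta": [1.0, 5.0, 2.0], "theta": [1, 1, 1]})
        assert BaselineProfile.from_series(s).band_medians["delta"] == 2.0

    def test_unclean_epochs_excluded(self):
        s = make_series({"delta": [1.0, 1.0, 100.0], "theta": [1, 1, 1]},
                        clean=[True, True, False])
        assert BaselineProfile.from_series(s).band_medians["delta"] == 1.0

    def test_zero_median_is_error(self):
        s = make_series({"delta": [0.0, 0.0, 0.0], "theta": [1, 1, 1]})
        with pytest.raises(ValueError, match="zero baseline"):
            BaselineProfile.from_series(s)

    def test_no_clean_epochs_is_error(self):
        s = make_series({"delta": [1.0], "theta": [1.0]}, clean=[False])
        with pytest.raises(ValueError, match="clean"):
            BaselineProfile.from_series(s)


def _db_series(low_db, total_db=None, starts=None, clean=None):
    """Build a DBChangeSeries directly from pooled-low dB values."""
    n = len(low_db)
    starts = np.asarray(starts if starts is not None else 0.75 * np.arange(n), float)
    low = np.asarray(low_db, float)
    total = np.asarray(total_db if total_db is not None else low, float)
    return DBChangeSeries(
        starts=starts, band_names=("delta", "theta"),
        db=np.column_stack([low, low]), db_low=low, db_total=total,
        clean=np.asarray(clean) if clean is not None else np.ones(n, bool),
        epoch_length=1.0,
    )


class TestClassifyStun:
    def test_all_zero_db_not_sustained(self):
        a = classify_stun(_db_series(np.zeros(40)))
        assert not a.sustained
        assert a.sustained_duration == 0.0
        assert a.suppression is None

    def test_run_not_reaching_25s_is_not_sustained(self):
        starts = 0.75 * np.arange(40) + 5.0
        low = np.where((starts >= 5) & (starts <= 20), 50.0, 0.0)
        a = classify_stun(_db_series(low, starts=starts))
        assert not a.sustained

    def test_run_straddling_25s_is_sustained(self):
        starts = 0.75 * np.arange(60) + 8.0
        low = np.where((starts >= 10) & (starts <= 35), 50.0, 0.0)
        a = classify_stun(_db_series(low, starts=starts))
        assert a.sustained
        assert a.sustained_duration > 20.0

    def test_isolated_late_excursion_not_sustained(self):
        starts = 0.75 * np.arange(60) + 8.0
        low = np.where(np.abs(starts - 40.0) < 1.0, 50.0, 0.0)
        a = classify_stun(_db_series(low, starts=starts))
        assert not a.sustained

    def test_monotone_in_threshold(self):
        starts = 0.75 * np.arange(60) + 8.0
        rng = np.random.default_rng(3)
        low = rng.uniform(0, 60, size=60)
        flags = [classify_stun(_db_series(low, starts=starts), threshold=th).sustained
                 for th in (10.0, 30.0, 50.0, 80.0)]
        # once false at a lower threshold, never true at a higher one
        for a, b in zip(flags, flags[1:]):
            assert a or not b

    def test_suppression_interval_detected(self):
        starts = 0.75 * np.arange(60) + 8.0
        total = np.where(starts > 40, -60.0, 0.0)
        a = classify_stun(_db_series(np.zeros(60), total_db=total, starts=starts))
        assert a.suppression is not None
        assert a.suppression[0] == pytest.approx(40.25, abs=0.8)

    def test_minus_inf_epochs_do_not_break_runs(self):
        starts = 0.75 * np.arange(60) + 8.0
        low = np.where((starts >= 10) & (starts <= 35), 50.0, 0.0)
        low[20] = -np.inf
        a = classify_stun(_db_series(low, starts=starts))
        assert a.sustained

    def test_empty_usable_series_is_error(self):
        with pytest.raises(ValueError, match="usable"):
            classify_stun(_db_series([0.0, 0.0], clean=[False, False]))


def test_analytic_gain_sixteen_example():
    """Amplitude gain 4 on a lone delta component: power x16, so the
    measured dB change at the nadir approaches 100*log10(16) = 120.4."""
    from stuneeg.spectral import compute_band_powers, make_epochs
    from stuneeg.synth import StunResponseParams, generate_poststun_trace

    p = BandSpectrumParams(very_low=0, delta=5.0, theta=0, alpha=0, beta=0,
                           noise=0.0)
    resp = StunResponseParams(latency_s=2.0, artifact_duration_s=6.0,
                              gains={"delta": 4.0}, nadir_s=20.0,
                              sustained_until_s=35.0, quality="good",
                              artifact_multiplier=0.0)
    pre = generate_baseline_trace(p, 30.0, seed=3)
    post = generate_poststun_trace(p, resp, 60.0, seed=4)
    gpre = make_epochs(pre)
    spre = compute_band_powers(pre, gpre)
    gpost = make_epochs(post)
    spost = compute_band_powers(post, gpost)
    baseline = float(np.median(spre.band("delta")))
    i = int(np.argmin(np.abs(gpost.starts + 0.5 - resp.nadir_s)))
    measured = db_change(float(spost.band("delta")[i]), baseline)
    assert measured == pytest.approx(100 * np.log10(16.0), abs=5.0)


class TestAssessAnimal:
    def test_good_stun_flag_nadir_and_t1_delta_rise(self, fast_params):
        pre, post, resp = make_animal(fast_params, "good", seed=21)
        res = assess_animal(pre, post)
        assert res.assessment.sustained
        assert abs(res.assessment.nadir_time - resp.nadir_s) <= 1.5
        assert res.periods["T1"].rms["delta"] > res.periods["T0"].rms["delta"]

    def test_failed_stun_not_flagged(self, fast_params):
        pre, post, _ = make_animal(fast_params, "failed", seed=22)
        assert not assess_animal(pre, post).assessment.sustained

    def test_immobilized_not_flagged_but_beta_rises(self, fast_params):
        pre, post, _ = make_animal(fast_params, "immobilized", seed=23)
        res = assess_animal(pre, post)
        assert not res.assessment.sustained
        assert res.periods["T1"].rms["beta"] > res.periods["T0"].rms["beta"]

    def test_pre_as_both_phases_near_zero_db(self, fast_params):
        worst = 0.0
        for seed in range(10):
            pre = generate_baseline_trace(fast_params, 40.0, seed=300 + seed)
            post = generate_baseline_trace(fast_params, 40.0, seed=400 + seed)
            res = assess_animal(pre, post)
            d = res.db_series
            worst = max(worst, float(np.max(np.abs(d.db_total[d.usable]))))
            assert not res.assessment.sustained
        assert worst < 10.0

    def test_error_annotated_with_animal_id(self, fast_params):
        pre = generate_baseline_trace(fast_params, 40.0, seed=1)
        pre = pre.with_samples(pre.samples, animal_id="X9")
        short = pre.with_samples(pre.samples[: int(3 * fast_params.fs)])
        with pytest.raises(ValueError):
            assess_animal(pre, short)

    def test_conventional_db_scale_config(self, fast_params):
        pre, post, _ = make_animal(fast_params, "good", seed=25)
        cfg = AssessmentConfig(db_scale=10.0, threshold=3.0)
        res = assess_animal(pre, post, cfg)
        assert res.assessment.sustained
        assert res.db_series.scale == 10.0
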