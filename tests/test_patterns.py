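"""Envelope, burst-detection, classification and onset-feature tests."""

import numpy as np
import pytest

from qeegrecovery.patterns import (BURST_SUPPRESSION, CONTINUOUS, ISOELECTRIC,
                                   EnvelopeTrace, PatternInterval,
                                   PatternTimeline, classify_timeline,
                                   compute_envelope, compute_otob_ttnt,
                                   detect_bursts)


def _trace(combined, window_s=0.5, hop_s=0.25):
    combined = np.asarray(combined, dtype=float)
    return EnvelopeTrace(values=combined[None, :], combined=combined,
                         window_s=window_s, hop_s=hop_s)


# ---------------------------------------------------------------- envelope

def test_envelope_of_sinusoid_is_its_amplitude():
    fs = 1000.0
    t = np.arange(int(10 * fs)) / fs
    x = 20.0 * np.sin(2 * np.pi * 10 * t)
    env = compute_envelope(np.vstack([x, x]), fs)
    np.testing.assert_allclose(env.combined, 20.0, rtol=0.01)
    assert env.n_windows == int((len(t) - 500) / 250) + 1


def test_envelope_of_zero_signal_is_zero():
    env = compute_envelope(np.zeros((2, 2000)), 1000.0)
    np.testing.assert_array_equal(env.combined, 0.0)


def test_envelope_combines_channels_by_minimum():
    fs = 1000.0
    t = np.arange(int(5 * fs)) / fs
    big = 20.0 * np.sin(2 * np.pi * 10 * t)
    small = 4.0 * np.sin(2 * np.pi * 10 * t)
    env = compute_envelope(np.vstack([big, small]), fs)
    np.testing.assert_allclose(env.combined, 4.0, rtol=0.02)


def test_envelope_rejects_too_short_signal():
    with pytest.raises(ValueError):
        compute_envelope(np.zeros((2, 10)), 1000.0)


# ------------------------------------------------------------------ bursts

def test_no_bursts_on_flat_trace():
    assert detect_bursts(_trace(np.zeros(500))) == []


def test_square_wave_bursts_counted_and_timed():
    """20 cycles of 2 s bursts / 1 s suppression: run-length enumeration of
    the planted square wave gives 20 bursts totalling 40 s."""
    fs = 1000.0
    t = np.arange(int(60 * fs)) / fs
    x = np.where((t - 0.13) % 3.0 < 2.0, 20.0 * np.sin(2 * np.pi * 10 * t),
                 2.0 * np.sin(2 * np.pi * 7 * t))
    env = compute_envelope(np.vstack([x, x]), fs)
    events = detect_bursts(env)
    assert len(events) == 20
    total = sum(e.duration_s for e in events)
    assert abs(total - 40.0) < 1.5
    durs = [e.duration_s for e in events]
    assert all(abs(d - 2.0) < 0.35 for d in durs)


def test_constant_high_amplitude_is_one_full_burst():
    fs = 500.0
    t = np.arange(int(60 * fs)) / fs
    x = 20.0 * np.sin(2 * np.pi * 10 * t)
    env = compute_envelope(np.vstack([x, x]), fs)
    events = detect_bursts(env)
    assert len(events) == 1
    assert events[0].start_s == 0.0
    assert abs(events[0].duration_s - 60.0) < 1e-9


def test_sub_minimum_suppressions_do_not_split_bursts():
    # 0.3 s quiet dips are below the 0.5 s minimum inter-burst suppression,
    # so the activity reads as one burst
    fs = 1000.0
    t = np.arange(int(60 * fs)) / fs
    x = 20.0 * np.sin(2 * np.pi * 10 * t)
    for k in (15.0, 30.0, 45.0):
        x[int(k * fs):int((k + 0.3) * fs)] = 0.0
    env = compute_envelope(np.vstack([x, x]), fs)
    events = detect_bursts(env)
    assert len(events) == 1
    assert abs(events[0].duration_s - 60.0) < 1e-9


# ----------------------------------------------------------- classification

def test_quiet_trace_is_isoelectric():
    tl = classify_timeline(_trace(np.full(481, 3.0)))  # 120 s at 3 uV
    assert [iv.label for iv in tl.intervals] == [ISOELECTRIC]


def test_burst_gap_alternation_is_burst_suppression():
    reps = np.tile(np.r_[np.full(8, 20.0), np.full(4, 2.0)], 40)
    tl = classify_timeline(_trace(reps))
    assert [iv.label for iv in tl.intervals] == [BURST_SUPPRESSION]


def test_sustained_floor_above_5_is_continuous():
    rng = np.random.default_rng(0)
    env = rng.uniform(6.0, 25.0, size=481)
    tl = classify_timeline(_trace(env))
    assert [iv.label for iv in tl.intervals] == [CONTINUOUS]


def test_classification_is_threshold_based_not_scale_free():
    env = np.full(481, 4.0)
    assert [iv.label for iv in classify_timeline(_trace(env)).intervals] == \
        [ISOELECTRIC]
    assert [iv.label for iv in
            classify_timeline(_trace(3.0 * env)).intervals] == [CONTINUOUS]


def test_timeline_partitions_duration():
    rng = np.random.default_rng(1)
    parts = [np.full(480, 3.0),
             np.tile(np.r_[np.full(8, 20.0), np.full(4, 2.0)], 60),
             rng.uniform(6.5, 25.0, size=720)]
    env = np.concatenate(parts)
    tl = classify_timeline(_trace(env))
    tl.validate()
    assert tl.intervals[0].start_min == 0.0
    assert np.isclose(tl.duration_min, _trace(env).duration_s / 60.0)
    labels = [iv.label for iv in tl.intervals]
    assert labels == [ISOELECTRIC, BURST_SUPPRESSION, CONTINUOUS]


# ------------------------------------------------------------- onset times

def _tl(*spans):
    return PatternTimeline([PatternInterval(lab, s, e) for lab, s, e in spans])


def test_onset_features_standard_sequence():
    tl = _tl((ISOELECTRIC, 0, 20), (BURST_SUPPRESSION, 20, 170),
             (CONTINUOUS, 170, 240))
    got = compute_otob_ttnt(tl, 240.0)
    assert got == {"otob_min": 20, "ttnt_min": 170, "ttnt_censored": False}


def test_onset_features_censored_when_never_continuous():
    tl = _tl((ISOELECTRIC, 0, 30), (BURST_SUPPRESSION, 30, 240))
    got = compute_otob_ttnt(tl, 240.0)
    assert got["ttnt_min"] == 240.0 and got["ttnt_censored"]
    assert got["otob_min"] == 30


def test_onset_features_fallthrough_to_continuous():
    tl = _tl((ISOELECTRIC, 0, 100), (CONTINUOUS, 100, 240))
    got = compute_otob_ttnt(tl, 240.0)
    assert got["otob_min"] == 100 == got["ttnt_min"]
    assert not got["ttnt_censored"]


def test_empty_timeline_is_an_error():
    with pytest.raises(ValueError):
        compute_otob_ttnt(PatternTimeline([]), 240.0)


def test_invalid_timeline_rejected():
    with pytest.raises(ValueError):
        _tl((ISOELECTRIC, 0, 20), (BURST_SUPPRESSION, 25, 240)).validate()


# ----------------------------------------------- planted-truth recovery

def test_detected_onsets_recover_planted_truth(cohort_detection):
    """On the full synthetic cohort, detected OTOB lies within 0.5 min of the
    planted value and detected TTNT within 2 min (censored animals compared
    at the censoring horizon) for at least 95% of animals."""
    df = cohort_detection
    otob_err = (df.otob_min - df.planted_otob_min).abs()
    ttnt_true = df.planted_ttnt_min.clip(upper=240.0)
    ttnt_err = (df.ttnt_min - ttnt_true).abs()
    assert (otob_err <= 0.5).mean() >= 0.95
    assert (ttnt_err <= 2.0).mean() >= 0.95
    assert df.ttnt_censored.equals(df.planted_ttnt_min > 240.0)
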