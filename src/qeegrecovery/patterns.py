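"""EEG recovery-pattern analysis.

Operationalizes the visual annotation rules for early post-resuscitation EEG:
an amplitude envelope (half peak-to-peak in 0.5-s windows, both channels
combined by their minimum so "above threshold in both channels" becomes one
comparison), burst/suppression event detection around the 10 uV threshold,
rolling-window classification into the three recovery patterns
(isoelectric, burst suppression, continuous background), and extraction of
the two onset features:

OTOB  - onset time of burst: minutes from ROSC to the first burst-suppression
        pattern (or to the first continuous pattern when burst suppression is
        never seen);
TTNT  - time to normal trace: minutes from ROSC to the first continuous
        pattern, right-censored at the recording duration when the trace
        never becomes continuous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import Segment
from .synthgen import Recording

__all__ = [
    "EnvelopeTrace",
    "BurstEvent",
    "PatternInterval",
    "PatternTimeline",
    "compute_envelope",
    "artifact_mask",
    "detect_bursts",
    "classify_timeline",
    "compute_otob_ttnt",
    "ISOELECTRIC",
    "BURST_SUPPRESSION",
    "CONTINUOUS",
]

ISOELECTRIC = "isoelectric"
BURST_SUPPRESSION = "burst_suppression"
CONTINUOUS = "continuous"

#: Amplitude thresholds (uV) from the annotation rules.
BURST_THRESHOLD_UV = 10.0
QUIET_THRESHOLD_UV = 5.0


@dataclass
class EnvelopeTrace:
    """Half peak-to-peak amplitude per short window, per channel.

    ``combined`` is the per-window minimum across channels.  Sample ``i``
    summarizes the signal span ``[i * hop_s, i * hop_s + window_s)``.
    """

    values: np.ndarray          # (n_channels, n_windows)
    combined: np.ndarray        # (n_windows,)
    window_s: float
    hop_s: float

    @property
    def n_windows(self) -> int:
        return self.combined.shape[-1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.hop_s

    @property
    def duration_s(self) -> float:
        return (self.n_windows - 1) * self.hop_s + self.window_s


@dataclass(frozen=True)
class BurstEvent:
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PatternInterval:
    label: str
    start_min: float
    end_min: float


@dataclass
class PatternTimeline:
    """Ordered labeled intervals partitioning ``[0, duration]`` minutes."""

    intervals: list[PatternInterval] = field(default_factory=list)

    def validate(self) -> None:
        if not self.intervals:
            return
        prev = self.intervals[0]
        if prev.start_min != 0.0:
            raise ValueError("timeline must start at 0")
        for iv in self.intervals[1:]:
            if not np.isclose(iv.start_min, prev.end_min):
                raise ValueError("timeline intervals must be contiguous")
            if iv.label == prev.label:
                raise ValueError("adjacent intervals must differ in label")
            prev = iv

    def first(self, label: str) -> PatternInterval | None:
        for iv in self.intervals:
            if iv.label == label:
                return iv
        return None

    @property
    def duration_min(self) -> float:
        return self.intervals[-1].end_min if self.intervals else 0.0


def compute_envelope(source, fs: float | None = None,
                     window_s: float = 0.5,
                     hop_s: float = 0.25) -> EnvelopeTrace:
    """Half peak-to-peak envelope of a recording, segment, or raw array.

    Window/hop are rounded to whole samples; the stored ``hop_s`` reflects
    the realized hop so event timing stays exact at any sample rate.
    """
    if isinstance(source, Recording):
        data, fs = source.data, source.fs
    elif isinstance(source, Segment):
        data, fs = source.data, source.fs
    else:
        data = np.atleast_2d(np.asarray(source, dtype=float))
        if fs is None:
            raise ValueError("fs required when passing a raw array")
    w = max(2, int(round(window_s * fs)))
    h = max(1, int(round(hop_s * fs)))
    if data.shape[1] < w:
        raise ValueError("signal shorter than one envelope window")
    view = sliding_window_view(data, w, axis=1)[:, ::h, :]
    values = 0.5 * (view.max(axis=2) - view.min(axis=2))
    return EnvelopeTrace(values=values,
                         combined=values.min(axis=0),
                         window_s=w / fs, hop_s=h / fs)


def artifact_mask(env: EnvelopeTrace,
                  cap_uv: float = 300.0,
                  guard_s: float = 3.0) -> np.ndarray:
    """True where the combined envelope is non-physiological (beyond
    ``cap_uv``), dilated by ``guard_s`` to cover filter ringing around
    high-amplitude transients."""
    bad = env.combined > cap_uv
    if bad.any() and guard_s > 0:
        n_guard = int(round(guard_s / env.hop_s))
        kernel = np.ones(2 * n_guard + 1)
        bad = np.convolve(bad.astype(float), kernel, mode="same") > 0
    return bad


def detect_bursts(env: EnvelopeTrace,
                  threshold_uv: float = BURST_THRESHOLD_UV,
                  min_burst_s: float = 0.1,
                  min_gap_s: float = 0.5,
                  valid_mask: np.ndarray | None = None) -> list[BurstEvent]:
    """Burst events: maximal runs of combined envelope above ``threshold_uv``.

    Suppression gaps shorter than ``min_gap_s`` (the minimum inter-burst
    suppression of the annotation rule) are merged into the surrounding
    burst; events shorter than ``min_burst_s`` are dropped.

    Event boundaries correct for the widening introduced by the peak-to-peak
    windowing: a run of ``k`` supra-threshold envelope samples is estimated
    to span ``k * hop - window`` seconds centred on the run (runs touching
    the trace edges extend to the edge), which makes measured burst time an
    unbiased estimate of true time above threshold.

    ``valid_mask`` (True = usable) excludes artifact-contaminated envelope
    samples from triggering bursts.
    """
    above = env.combined > threshold_uv
    if valid_mask is not None:
        above = above & valid_mask
    if not above.any():
        return []
    h, w = env.hop_s, env.window_s
    edges = np.flatnonzero(np.diff(np.concatenate(
        ([False], above, [False])).astype(int)))
    starts, ends = edges[::2], edges[1::2] - 1  # inclusive sample indices
    events: list[BurstEvent] = []
    for i0, i1 in zip(starts, ends):
        start = i0 * h + w - h / 2
        end = i1 * h + h / 2
        if i0 == 0:
            start = 0.0
        if i1 == env.n_windows - 1:
            end = env.duration_s
        if end - start < h / 2:  # sub-window blip: keep a half-hop event
            c = 0.5 * (i0 + i1) * h + w / 2
            start, end = c - h / 4, c + h / 4
        events.append(BurstEvent(start, end))
    # merge short suppression gaps
    merged = [events[0]]
    for ev in events[1:]:
        if ev.start_s - merged[-1].end_s < min_gap_s:
            merged[-1] = BurstEvent(merged[-1].start_s, ev.end_s)
        else:
            merged.append(ev)
    return [ev for ev in merged if ev.duration_s >= min_burst_s]


def _has_quiet_run(quiet: np.ndarray, n_run: int) -> bool:
    if n_run <= 0:
        return quiet.any()
    if not quiet.any():
        return False
    edges = np.flatnonzero(np.diff(np.concatenate(
        ([False], quiet, [False])).astype(int)))
    return bool(np.max(edges[1::2] - edges[::2]) >= n_run)


def classify_timeline(env: EnvelopeTrace,
                      window_s: float = 60.0,
                      hop_s: float = 10.0,
                      quiet_run_s: float = 30.0,
                      refine: bool = True) -> PatternTimeline:
    """Classify rolling 60-s windows (hop 10 s) and merge into a timeline.

    Per window of the combined envelope:

    * continuous        - max > 10 uV with an essentially unbroken floor
                          above 5 uV (at most ~1% of envelope samples below,
                          so that even smeared sub-second suppressions keep a
                          window in the burst-suppression class);
    * isoelectric       - no sample above 10 uV and some run below 5 uV
                          lasting at least 30 s;
    * burst suppression - at least one burst (sample above 10 uV);
    * fallback          - intermediate amplitude with no bursts: isoelectric
                          if the window median is below 5 uV, else burst
                          suppression.

    With ``refine=True`` (default) the two onset boundaries that define the
    features are sharpened past the 10-s window grid: a burst-suppression
    interval that follows an isoelectric one starts at its first detected
    burst, and the first continuous interval starts where the envelope last
    rose above 5 uV for good.
    """
    if env.duration_s < window_s:
        raise ValueError("envelope shorter than one classification window")
    n_env_per_win = max(1, int(round((window_s - env.window_s) / env.hop_s)))
    n_quiet = int(round(quiet_run_s / env.hop_s))
    bad = artifact_mask(env)
    starts_s = np.arange(0.0, env.duration_s - window_s + 1e-9, hop_s)
    labels: list[str | None] = []
    for w0 in starts_s:
        i0 = int(round(w0 / env.hop_s))
        seg = env.combined[i0:i0 + n_env_per_win]
        m = bad[i0:i0 + n_env_per_win]
        if seg.size == 0:
            break
        valid = seg[~m]
        if valid.size < 0.5 * seg.size:
            labels.append(None)       # artifact-dominated: inherit neighbour
            continue
        mx = valid.max()
        quiet = (seg < QUIET_THRESHOLD_UV) | m  # artifact is not activity
        # continuous demands an unbroken >5 uV floor; tolerate only isolated
        # sub-floor envelope samples (smeared short suppressions must count)
        n_quiet_valid = int((valid < QUIET_THRESHOLD_UV).sum())
        if mx > BURST_THRESHOLD_UV and \
                n_quiet_valid <= max(2, int(0.01 * valid.size)):
            labels.append(CONTINUOUS)
        elif mx <= BURST_THRESHOLD_UV and _has_quiet_run(quiet, n_quiet):
            labels.append(ISOELECTRIC)
        elif mx > BURST_THRESHOLD_UV:
            labels.append(BURST_SUPPRESSION)
        else:
            labels.append(ISOELECTRIC if np.median(valid) < QUIET_THRESHOLD_UV
                          else BURST_SUPPRESSION)
    # artifact-dominated windows inherit the previous (else next) label
    for k in range(len(labels)):
        if labels[k] is None:
            labels[k] = labels[k - 1] if k > 0 else next(
                (lab for lab in labels if lab is not None), None)
    if not labels or labels[0] is None:
        warnings.warn("no classifiable windows (all-artifact input)",
                      stacklevel=2)
        return PatternTimeline([])

    total_min = env.duration_s / 60.0
    # merge runs of identical window labels; interval start = window start
    bounds = [0.0]
    run_labels = [labels[0]]
    for k in range(1, len(labels)):
        if labels[k] != run_labels[-1]:
            bounds.append(starts_s[k] / 60.0)
            run_labels.append(labels[k])
    bounds.append(total_min)

    if refine:
        bursts = detect_bursts(env, valid_mask=~bad)
        for j in range(1, len(run_labels)):
            prev_lab, lab = run_labels[j - 1], run_labels[j]
            coarse_s = bounds[j] * 60.0
            lo_s = bounds[j - 1] * 60.0
            hi_s = min(bounds[j + 1] * 60.0, coarse_s + window_s)
            if lab == BURST_SUPPRESSION and prev_lab == ISOELECTRIC:
                for bv in bursts:
                    if bv.end_s > coarse_s - hop_s:
                        bounds[j] = np.clip(bv.start_s, lo_s + 1e-6,
                                            hi_s) / 60.0
                        break
            elif lab == CONTINUOUS and prev_lab != CONTINUOUS and \
                    run_labels.index(CONTINUOUS) == j:
                i_lo = int(max(0, (coarse_s - window_s - 5.0) // env.hop_s))
                i_hi = int(min(env.n_windows,
                               (coarse_s + hop_s) // env.hop_s))
                win = env.combined[i_lo:i_hi]
                quiet = np.flatnonzero(win < QUIET_THRESHOLD_UV)
                if quiet.size:
                    t_ref = (i_lo + quiet[-1] + 1) * env.hop_s
                    bounds[j] = np.clip(t_ref, lo_s + 1e-6, hi_s) / 60.0

    intervals = [PatternInterval(lab, s, e) for lab, s, e
                 in zip(run_labels, bounds[:-1], bounds[1:]) if e > s]
    # re-merge in case refinement collapsed an interval
    cleaned: list[PatternInterval] = []
    for iv in intervals:
        if cleaned and cleaned[-1].label == iv.label:
            cleaned[-1] = PatternInterval(iv.label, cleaned[-1].start_min,
                                          iv.end_min)
        else:
            cleaned.append(iv)
    tl = PatternTimeline(cleaned)
    tl.validate()
    return tl


def compute_otob_ttnt(timeline: PatternTimeline,
                      duration_min: float | None = None) -> dict:
    """Onset features from a classified timeline.

    Returns ``{"otob_min", "ttnt_min", "ttnt_censored"}``.  OTOB falls back
    to the first continuous interval when no burst-suppression interval
    precedes it; TTNT is censored at ``duration_min`` when the trace never
    becomes continuous.
    """
    if not timeline.intervals:
        raise ValueError("empty timeline")
    if duration_min is None:
        duration_min = timeline.duration_min
    first_bs = timeline.first(BURST_SUPPRESSION)
    first_cont = timeline.first(CONTINUOUS)
    if first_cont is not None and (first_bs is None or
                                   first_cont.start_min < first_bs.start_min):
        otob = first_cont.start_min
    elif first_bs is not None:
        otob = first_bs.start_min
    else:
        otob = duration_min  # never left the isoelectric pattern
    if first_cont is not None and first_cont.start_min <= duration_min:
        return {"otob_min": min(otob, duration_min),
                "ttnt_min": first_cont.start_min,
                "ttnt_censored": False}
    return {"otob_min": min(otob, duration_min),
            "ttnt_min": duration_min,
            "ttnt_censored": True}


def timeline_to_frame(timeline: PatternTimeline, animal_id: str):
    """BED-like table: animal_id, start_s, end_s, label."""
    import pandas as pd

    return pd.DataFrame({
        "animal_id": animal_id,
        "start_s": [iv.start_min * 60.0 for iv in timeline.intervals],
        "end_s": [iv.end_min * 60.0 for iv in timeline.intervals],
        "label": [iv.label for iv in timeline.intervals],
    })
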