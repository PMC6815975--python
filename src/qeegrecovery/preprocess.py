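"""Filtering and scheduled segment extraction.

Raw recordings are band-pass filtered 0.3-100 Hz (zero phase) with a 50 Hz
notch, then one-minute analysis segments are taken at 5 min post-ROSC and
every 30 min thereafter.  Segments containing high-amplitude artifacts may
slide up to +/-60 s to find an artifact-free minute before being flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthgen import Recording

__all__ = [
    "FilterParams",
    "Segment",
    "filter_recording",
    "extract_segments",
    "detect_artifact",
    "DEFAULT_SCHEDULE_MIN",
]

DEFAULT_SCHEDULE_MIN = (5.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0,
                        240.0)


@dataclass(frozen=True)
class FilterParams:
    """Band-pass + notch specification.

    Realized as a 4th-order Butterworth band-pass applied forward-backward
    (zero phase) followed by a second-order IIR notch of quality 30.
    """

    bandpass_lo: float = 0.3
    bandpass_hi: float = 100.0
    notch_freq: float = 50.0
    filter_order: int = 4
    notch_quality: float = 30.0

    def validate(self, fs: float) -> None:
        if not 0 < self.bandpass_lo < self.bandpass_hi:
            raise ValueError("require 0 < bandpass_lo < bandpass_hi")
        if self.bandpass_hi >= fs / 2:
            raise ValueError(
                f"bandpass_hi={self.bandpass_hi} must be below Nyquist "
                f"({fs / 2})")
        if self.notch_freq >= fs / 2:
            raise ValueError("notch_freq must be below Nyquist")


@dataclass
class Segment:
    """One scheduled one-minute analysis window.

    ``timepoint_min`` is minutes post-ROSC (the *scheduled* time; if the
    window slid to dodge an artifact, ``slide_offset_s`` records the shift).
    A negative timepoint marks the pre-arrest baseline minute.
    """

    timepoint_min: float
    data: np.ndarray            # (2, 60 * fs)
    fs: float
    artifact_flag: bool = False
    slide_offset_s: float = 0.0

    @property
    def is_baseline(self) -> bool:
        return self.timepoint_min < 0

    @property
    def label(self) -> str:
        return "baseline" if self.is_baseline else f"{self.timepoint_min:g}"


def filter_recording(rec: Recording, params: FilterParams | None = None
                     ) -> Recording:
    """Zero-phase band-pass then notch, per channel; removes DC offset."""
    params = params or FilterParams()
    params.validate(rec.fs)
    sos = signal.butter(params.filter_order,
                        [params.bandpass_lo, params.bandpass_hi],
                        btype="bandpass", fs=rec.fs, output="sos")
    b_n, a_n = signal.iirnotch(params.notch_freq, params.notch_quality,
                               fs=rec.fs)
    out = np.empty_like(rec.data)
    for ch in range(rec.data.shape[0]):
        x = signal.sosfiltfilt(sos, rec.data[ch])
        out[ch] = signal.filtfilt(b_n, a_n, x)
    return Recording(data=out, fs=rec.fs, animal_id=rec.animal_id,
                     t0_post_rosc_min=rec.t0_post_rosc_min)


def detect_artifact(seg_or_data, fs: float | None = None,
                    amp_threshold: float = 1000.0,
                    flatline_s: float = 1.0) -> bool:
    """Artifact screen: any sample beyond +/-1000 uV, or a channel exactly
    constant for at least one second (clipping / lead-off proxy)."""
    if isinstance(seg_or_data, Segment):
        data, fs = seg_or_data.data, seg_or_data.fs
    else:
        data = np.atleast_2d(np.asarray(seg_or_data, dtype=float))
        if fs is None:
            raise ValueError("fs required when passing a raw array")
    if np.any(np.abs(data) > amp_threshold):
        return True
    run_len = int(round(flatline_s * fs))
    for ch in data:
        if len(ch) < run_len + 1:
            continue
        same = np.diff(ch) == 0.0
        # longest run of identical consecutive samples
        if same.any():
            edges = np.flatnonzero(np.diff(np.concatenate(
                ([False], same, [False])).astype(int)))
            if len(edges) and np.max(edges[1::2] - edges[::2]) >= run_len:
                return True
    return False


def extract_segments(rec: Recording,
                     schedule_min=DEFAULT_SCHEDULE_MIN,
                     segment_s: float = 60.0,
                     max_slide_s: float = 60.0,
                     slide_step_s: float = 10.0) -> list[Segment]:
    """Cut the scheduled one-minute windows ``[t, t + 60 s]`` from a filtered
    recording.

    Windows overlapping an artifact slide in +/-``slide_step_s`` increments
    (nearest shift first) up to ``max_slide_s``; if no clean position exists
    the segment is returned flagged at its scheduled position.  Schedule
    points beyond the end of the recording are skipped (a recording shorter
    than the first point yields an empty list with a warning).
    """
    n_seg = int(round(segment_s * rec.fs))
    offsets = [0.0]
    k = 1
    while k * slide_step_s <= max_slide_s:
        offsets.extend([k * slide_step_s, -k * slide_step_s])
        k += 1
    segments: list[Segment] = []
    t_start_min = rec.t0_post_rosc_min
    for tp in schedule_min:
        placed = False
        for off in offsets:
            i0 = int(round(((tp - t_start_min) * 60.0 + off) * rec.fs))
            if i0 < 0 or i0 + n_seg > rec.n_samples:
                continue
            window = rec.data[:, i0:i0 + n_seg]
            if not detect_artifact(window, rec.fs):
                segments.append(Segment(tp, window.copy(), rec.fs,
                                        artifact_flag=False,
                                        slide_offset_s=off))
                placed = True
                break
        if not placed:
            i0 = int(round((tp - t_start_min) * 60.0 * rec.fs))
            if i0 < 0 or i0 + n_seg > rec.n_samples:
                continue  # schedule point beyond recording
            window = rec.data[:, i0:i0 + n_seg]
            segments.append(Segment(tp, window.copy(), rec.fs,
                                    artifact_flag=True))
    if not segments:
        warnings.warn("recording shorter than the first schedule point; "
                      "no segments extracted", stacklevel=2)
    return segments


def baseline_segment(rec: Recording, segment_s: float = 60.0
                     ) -> Segment | None:
    """Designated baseline minute from a pre-arrest recording
    (``t0_post_rosc_min < 0``)."""
    n_seg = int(round(segment_s * rec.fs))
    if rec.n_samples < n_seg:
        return None
    window = rec.data[:, :n_seg]
    return Segment(-1.0, window.copy(), rec.fs,
                   artifact_flag=detect_artifact(window, rec.fs))
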