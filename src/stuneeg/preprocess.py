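"""Cleaning chain: edge trimming, band-pass filtering, artifact detection.

The analysis chain trims two seconds from each end of a recording (edge
artefacts from applying/removing the electrode wand), applies a
zero-phase 0-30 Hz band-pass, and replaces the original manual,
video-referenced artifact rejection with an automatic amplitude
criterion expressed in multiples of the robust trace scale (median
absolute deviation).  Manual annotations, when present, are honoured and
unioned with the automatic detections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import Annotation, EEGRecording


@dataclass(frozen=True)
class ArtifactCriteria:
    """Amplitude-based artifact detection parameters.

    threshold_mads : detection threshold as a multiple of the scaled MAD
        of the trace (robust standard deviation).
    min_duration : shortest annotation emitted (s); shorter supra-threshold
        runs are widened to this duration.
    merge_gap : supra-threshold runs closer than this (s) are merged.
    """

    threshold_mads: float = 6.0
    min_duration: float = 0.1
    merge_gap: float = 0.25

    def __post_init__(self) -> None:
        for name in ("threshold_mads", "min_duration", "merge_gap"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def trim_edges(rec: EEGRecording, margin: float = 2.0) -> EEGRecording:
    """Remove *margin* seconds from both ends of the recording.

    The time origin shifts forward by *margin*; annotations are clipped to
    the new span and dropped if they fall entirely outside it.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if margin == 0:
        return rec.copy()
    if not rec.duration > 2 * margin:
        raise ValueError(
            f"record of {rec.duration:.3f} s too short to trim {margin} s from each end"
        )
    k = int(round(margin * rec.fs))
    samples = rec.samples[k : rec.n_samples - k]
    new_t0 = rec.t0 + margin
    new_end = new_t0 + samples.size / rec.fs
    clipped = []
    for a in rec.annotations:
        s, e = max(a.start, new_t0), min(a.end, new_end)
        if e > s:
            clipped.append(Annotation(s, e, a.label, a.text))
    return rec.with_samples(samples, t0=new_t0, annotations=clipped)


def bandpass(rec: EEGRecording, low: float = 0.0, high: float = 30.0,
             order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass (forward-backward filtering).

    ``low = 0`` degenerates to a pure low-pass, matching the 0-30 Hz
    analysis filter.  Unity passband gain; epoch timing is preserved by
    the zero-phase realisation.
    """
    nyq = rec.fs / 2
    if not (0 <= low < high <= nyq):
        raise ValueError(f"band edges ({low}, {high}) must satisfy 0 <= low < high <= {nyq}")
    if low == 0 and high >= nyq:
        return rec.copy()
    if low == 0:
        sos = signal.butter(order, high, btype="lowpass", fs=rec.fs, output="sos")
    elif high >= nyq:
        sos = signal.butter(order, low, btype="highpass", fs=rec.fs, output="sos")
    else:
        sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return rec.with_samples(filtered, annotations=list(rec.annotations))


def detect_artifacts(rec: EEGRecording, criteria: ArtifactCriteria | None = None) -> list[Annotation]:
    """Detect high-amplitude artifacts; returns detections unioned with
    any pre-existing manual artifact annotations.

    A sample is supra-threshold when ``|x - median|`` exceeds
    ``threshold_mads`` times the scaled MAD.  Runs are merged across gaps
    shorter than ``merge_gap`` and widened to at least ``min_duration``.
    Detection is invariant to signal polarity by construction.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    criteria = criteria or ArtifactCriteria()
    x = rec.samples
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    robust_sigma = 1.4826 * mad
    detected: list[Annotation] = []
    if robust_sigma > 0:
        mask = np.abs(x - med) > criteria.threshold_mads * robust_sigma
        runs = _mask_runs(mask)
        fs = rec.fs
        intervals = [(rec.t0 + s / fs, rec.t0 + e / fs) for s, e in runs]
        intervals = _merge_intervals(intervals, criteria.merge_gap)
        end_time = rec.t0 + rec.duration
        for s, e in intervals:
            if e - s < criteria.min_duration:
                c = 0.5 * (s + e)
                s = c - criteria.min_duration / 2
                e = c + criteria.min_duration / 2
            s, e = max(s, rec.t0), min(e, end_time)
            if e > s:
                detected.append(Annotation(s, e, "artifact", "auto"))
    combined = _merge_annotations(list(rec.artifact_annotations()) + detected)
    return combined


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/end (exclusive) sample indices of True runs in *mask*."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def _merge_intervals(intervals: list[tuple[float, float]], gap: float) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s - out[-1][1] < gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _merge_annotations(anns: list[Annotation]) -> list[Annotation]:
    """Union overlapping artifact annotations (texts joined)."""
    if not anns:
        return []
    anns = sorted(anns, key=lambda a: a.start)
    out = [anns[0]]
    for a in anns[1:]:
        last = out[-1]
        if a.start <= last.end:
            out[-1] = Annotation(last.start, max(last.end, a.end), "artifact",
                                 last.text if last.text == a.text else f"{last.text}+{a.text}")
        else:
            out.append(a)
    return out
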