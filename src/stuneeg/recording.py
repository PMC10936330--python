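"""In-memory containers for single-channel EEG recordings.

Time convention: all times are in seconds.  Post-stun recordings use the
moment of stun application as the time origin, so ``t0`` is the
stun-to-recording latency and "25 s post stun" is directly addressable.
Pre-stun recordings use origin 0 at the start of the record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

PHASES = ("pre-stun", "post-stun")
TREATMENTS = ("P1-50", "P1-400", "P2-50", "P2-400")

ANNOTATION_LABELS = ("artifact", "event", "note")


@dataclass(frozen=True)
class Annotation:
    """A labelled time interval ``[start, end)`` on a recording (seconds)."""

    start: float
    end: float
    label: str = "artifact"
    text: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"annotation start {self.start} must be < end {self.end}")
        if self.label not in ANNOTATION_LABELS:
            raise ValueError(f"annotation label {self.label!r} not in {ANNOTATION_LABELS}")

    def overlaps(self, start: float, end: float) -> bool:
        return self.start < end and start < self.end


@dataclass
class EEGRecording:
    """A uniformly sampled single-channel EEG trace with metadata.

    Parameters
    ----------
    samples : voltage samples in microvolts.
    fs : sampling rate in Hz.
    phase : "pre-stun" or "post-stun".
    t0 : time of the first sample (s); stun application defines 0 for
        post-stun records.
    animal_id, treatment : cohort metadata; treatment "unknown" when absent.
    annotations : labelled intervals, all within the record span.
    """

    samples: np.ndarray
    fs: float
    phase: str = "pre-stun"
    t0: float = 0.0
    animal_id: str | None = None
    treatment: str = "unknown"
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if self.samples.size < 1:
            raise ValueError("recording must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.phase not in PHASES:
            raise ValueError(f"phase {self.phase!r} not in {PHASES}")
        if self.treatment != "unknown" and self.treatment not in TREATMENTS:
            raise ValueError(f"treatment {self.treatment!r} not in {TREATMENTS}")
        end = self.t0 + self.duration
        tol = 1.0 / self.fs  # one sample; absorbs serialisation rounding
        for ann in self.annotations:
            if ann.start < self.t0 - tol or ann.end > end + tol:
                raise ValueError(
                    f"annotation [{ann.start}, {ann.end}] outside record span "
                    f"[{self.t0}, {end}]"
                )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times (s), starting at ``t0``."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def artifact_annotations(self) -> list[Annotation]:
        return [a for a in self.annotations if a.label == "artifact"]

    def with_samples(self, samples: np.ndarray, **changes) -> "EEGRecording":
        """Copy of this recording with new samples (and optional metadata changes)."""
        out = replace(self, **changes)
        out.samples = np.asarray(samples, dtype=np.float64)
        out.__post_init__()
        return out

    def copy(self) -> "EEGRecording":
        return self.with_samples(self.samples.copy(), annotations=list(self.annotations))
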