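"""Seeded synthetic EEG traces and cohorts with ground-truth labels.

The signal model is a sum of band-limited oscillators plus a 1/f
background.  Each band's carrier is a small set of coherent sinusoids at
seed-randomised frequencies placed well inside the band (so the 1-s Hann
analysis window, whose main lobe spans roughly +-2 Hz, cannot leak their
power across a band edge) with random phases, normalised to unit RMS.
Coherent carriers make the short-time band power nearly deterministic,
which is what lets the generator control the per-band power trajectories
the analysis pipeline measures; see docs/methods.md for the rationale
and for what this deliberately does not emulate about real EEG.

A post-stun trace modulates each band's amplitude with a piecewise
envelope: unity during the initial movement-artifact window, a linear
rise to the configured gain at the nadir, a fast relaxation onto a
sustained plateau, and (after the sustained-change window) a decay
toward a suppression floor.  Good stuns raise delta/theta (high
amplitude, low frequency activity, nadir between 10 and 22 s post-stun)
and end in suppression; electro-immobilisation shifts power toward beta
with no low-frequency rise; failed stuns are statistically
indistinguishable from baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

from .recording import TREATMENTS, Annotation, EEGRecording

QUALITIES = ("good", "immobilized", "failed")

#: Guard-banded carrier placement range per band (Hz): tones stay >= ~1.5 Hz
#: from any out-of-band spectral bin so 1-s Hann leakage stays inside the band.
SYNTH_RANGES: dict[str, tuple[float, float]] = {
    "very_low": (0.02, 0.08),
    "delta": (2.0, 2.5),
    "theta": (5.5, 6.5),
    "alpha": (9.5, 10.5),
    "beta": (13.5, 27.9),
}

#: Number of carrier tones per band; multi-tone bands space tones > 3 Hz apart
#: so their beat terms average out within a 1-s epoch.
_N_TONES = {"very_low": 1, "delta": 1, "theta": 1, "alpha": 1, "beta": 5}

#: Fraction of the very-low amplitude carried by a constant (DC) component;
#: emulates slow electrode drift around a non-zero offset.
_VL_DC_FRACTION = 0.98


@dataclass(frozen=True)
class BandSpectrumParams:
    """Per-band RMS amplitude targets (microvolts) and sampling rate.

    Defaults produce an alpha-dominant baseline spectrum with a moderate
    very-low (< 0.1 Hz) drift component and a small 1/f background.
    """

    very_low: float = 4.0
    delta: float = 3.0
    theta: float = 3.0
    alpha: float = 8.0
    beta: float = 3.0
    noise: float = 1.0
    fs: float = 1024.0

    def __post_init__(self) -> None:
        for name in ("very_low", "delta", "theta", "alpha", "beta", "noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"amplitude {name} must be >= 0")
        if not self.fs >= 60.0:
            raise ValueError(
                f"sampling rate {self.fs} Hz must be >= 60 Hz (2 x highest band edge)"
            )

    @property
    def band_amplitudes(self) -> dict[str, float]:
        return {name: getattr(self, name)
                for name in ("very_low", "delta", "theta", "alpha", "beta")}

    @property
    def total_rms(self) -> float:
        return math.sqrt(sum(a ** 2 for a in self.band_amplitudes.values())
                         + self.noise ** 2)


@dataclass(frozen=True)
class StunResponseParams:
    """Timing and per-band gain parameters of one post-stun response.

    Gains are dimensionless amplitude multipliers on the baseline band
    amplitudes (a gain g multiplies band power by g**2).  Times are
    seconds post-stun.  ``suppression_depth`` is the late-phase power
    floor as a fraction of baseline power (1.0 = no suppression), reached
    after ``sustained_until_s``.
    """

    latency_s: float = 2.0
    artifact_duration_s: float = 8.0
    gains: dict[str, float] = field(default_factory=dict)
    nadir_s: float = 16.0
    sustained_until_s: float = 35.0
    sustain_frac: float = 0.35
    tau_peak_s: float = 4.0
    tau_release_s: float = 4.0
    suppression_depth: float = 1.0
    artifact_multiplier: float = 10.0
    quality: str = "failed"

    def __post_init__(self) -> None:
        if self.quality not in QUALITIES:
            raise ValueError(f"quality {self.quality!r} not in {QUALITIES}")
        if self.latency_s < 0 or self.artifact_duration_s < 0:
            raise ValueError("latency and artifact duration must be >= 0")
        if any(g <= 0 for g in self.gains.values()):
            raise ValueError("band gains must be > 0")
        if not 0 < self.suppression_depth <= 1.0:
            raise ValueError("suppression depth must be in (0, 1]")
        if self.nadir_s <= self.latency_s + self.artifact_duration_s:
            raise ValueError(
                f"nadir at {self.nadir_s} s precedes artifact end at "
                f"{self.latency_s + self.artifact_duration_s} s"
            )
        if self.sustained_until_s < self.nadir_s:
            raise ValueError("sustained-change window must extend past the nadir")

    @property
    def usable_from_s(self) -> float:
        return self.latency_s + self.artifact_duration_s

    def gain(self, band: str) -> float:
        return self.gains.get(band, 1.0)


GOOD_GAINS = {"delta": 6.0, "theta": 4.0}
IMMOBILIZED_GAINS = {"beta": 3.0}


def sample_response(rng: np.random.Generator, quality: str) -> StunResponseParams:
    """Draw response timing for one animal of the given ground-truth quality.

    Latency uniform on [1, 3] s; usable signal begins uniformly on
    [7, 20] s post-stun (latency plus movement-artifact window); the
    nadir falls on [10, 22] s, at least 2 s after the artifact ends.
    """
    latency = rng.uniform(1.0, 3.0)
    usable = rng.uniform(7.0, 20.0)
    nadir = rng.uniform(max(10.0, usable + 2.0), 22.0)
    common = dict(
        latency_s=latency,
        artifact_duration_s=usable - latency,
        nadir_s=nadir,
        sustained_until_s=35.0,
        quality=quality,
    )
    if quality == "good":
        return StunResponseParams(gains=dict(GOOD_GAINS), suppression_depth=0.35,
                                  **common)
    if quality == "immobilized":
        return StunResponseParams(gains=dict(IMMOBILIZED_GAINS), **common)
    return StunResponseParams(gains={}, **common)


# ---------------------------------------------------------------------------
# trace synthesis


def _carrier(rng: np.random.Generator, t: np.ndarray, lo: float, hi: float,
             n_tones: int) -> np.ndarray:
    """Unit-RMS carrier of *n_tones* coherent sinusoids in [lo, hi].

    Tones are jittered around evenly spaced centres; with the placement
    ranges above, multi-tone carriers keep pairwise spacings > 3 Hz.
    """
    if n_tones == 1:
        freqs = np.array([rng.uniform(lo, hi)])
    else:
        edges = np.linspace(lo, hi, n_tones + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        jitter = (edges[1] - edges[0]) * 0.1
        freqs = centers + rng.uniform(-jitter, jitter, size=n_tones)
    phases = rng.uniform(0, 2 * np.pi, size=n_tones)
    x = np.zeros_like(t)
    for f, ph in zip(freqs, phases):
        x += np.sin(2 * np.pi * f * t + ph)
    rms = float(np.sqrt(np.mean(x ** 2)))
    return x / rms if rms > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS 1/f background over [1.5 Hz, min(45, 0.45 fs)].

    The low cut keeps sub-epoch-resolution (< 1 Hz) stochastic content out
    of the background: a 1-s analysis window cannot average it, and slow
    drift is modelled separately by the coherent very-low component.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    hi = min(45.0, 0.45 * fs)
    mask = (freqs >= 1.5) & (freqs <= hi)
    amp = np.zeros(freqs.size)
    amp[mask] = 1.0 / np.sqrt(freqs[mask])
    coeffs = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(coeffs, n=n)
    rms = float(np.sqrt(np.mean(x ** 2)))
    return x / rms if rms > 0 else x


def _acquisition_lowpass(x: np.ndarray, fs: float) -> np.ndarray:
    """Emulate the recording chain's 50 Hz acquisition low-pass."""
    cutoff = min(50.0, 0.45 * fs)
    sos = sp_signal.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    return sp_signal.sosfiltfilt(sos, x)


def _band_components(rng: np.random.Generator, t: np.ndarray,
                     params: BandSpectrumParams) -> dict[str, np.ndarray]:
    """Unit-RMS carrier per band (drawn in fixed order for determinism)."""
    out: dict[str, np.ndarray] = {}
    for name in ("very_low", "delta", "theta", "alpha", "beta"):
        lo, hi = SYNTH_RANGES[name]
        carrier = _carrier(rng, t, lo, hi, _N_TONES[name])
        if name == "very_low":
            c0 = _VL_DC_FRACTION
            carrier = c0 + math.sqrt(1.0 - c0 ** 2) * carrier
        out[name] = carrier
    return out


def generate_baseline_trace(params: BandSpectrumParams, duration: float,
                            seed: int, phase: str = "pre-stun",
                            t0: float = 0.0) -> EEGRecording:
    """Generate a stationary (baseline-like) EEG trace.

    Deterministic for a fixed seed; scaling every amplitude parameter by
    c scales the trace by exactly c.
    """
    if not duration >= 10.0:
        raise ValueError(f"duration {duration} s too short; need >= 10 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * params.fs))
    t = t0 + np.arange(n) / params.fs
    components = _band_components(rng, t, params)
    x = np.zeros(n)
    for name, amp in params.band_amplitudes.items():
        x += amp * components[name]
    x += params.noise * _pink_noise(rng, n, params.fs)
    if np.any(x):
        x = _acquisition_lowpass(x, params.fs)
    return EEGRecording(samples=x, fs=params.fs, phase=phase, t0=t0)


def _envelope(t: np.ndarray, gain: float, resp: StunResponseParams) -> np.ndarray:
    """Amplitude multiplier trajectory for one band (t in s post-stun)."""
    t_u, t_n = resp.usable_from_s, resp.nadir_s
    t_s = resp.sustained_until_s
    sustained = 1.0 + (gain - 1.0) * resp.sustain_frac
    floor = math.sqrt(resp.suppression_depth)
    m = np.ones_like(t)
    rise = (t > t_u) & (t <= t_n)
    m[rise] = 1.0 + (gain - 1.0) * (t[rise] - t_u) / (t_n - t_u)
    relax = (t > t_n) & (t <= t_s)
    m[relax] = sustained + (gain - sustained) * np.exp(-(t[relax] - t_n) / resp.tau_peak_s)
    late = t > t_s
    m_ts = sustained + (gain - sustained) * math.exp(-(t_s - t_n) / resp.tau_peak_s)
    m[late] = floor + (m_ts - floor) * np.exp(-(t[late] - t_s) / resp.tau_release_s)
    return m


def _movement_artifact(rng: np.random.Generator, t: np.ndarray, start: float,
                       end: float, amplitude: float) -> np.ndarray:
    """High-amplitude low-frequency transient bursts in [start, end]."""
    x = np.zeros_like(t)
    cursor = start
    while cursor < end:
        dur = rng.uniform(0.3, 1.0)
        freq = rng.uniform(0.8, 2.5)
        amp = amplitude * rng.uniform(0.7, 1.3)
        phase = rng.uniform(0, 2 * np.pi)
        b0, b1 = cursor, min(cursor + dur, end)
        mask = (t >= b0) & (t < b1)
        if mask.any():
            tt = t[mask]
            taper = np.sin(np.pi * (tt - b0) / dur) ** 2
            x[mask] += amp * taper * np.sin(2 * np.pi * freq * tt + phase)
        cursor = b1 + rng.uniform(0.05, 0.3)
    return x


def generate_poststun_trace(base: BandSpectrumParams, resp: StunResponseParams,
                            duration: float = 60.0, seed: int = 0) -> EEGRecording:
    """Generate a post-stun trace of *duration* seconds starting at the
    stun-to-recording latency (time origin = stun application).

    The initial movement-artifact window is annotated as artifact.
    """
    if resp.nadir_s >= resp.latency_s + duration:
        raise ValueError(
            f"nadir at {resp.nadir_s} s falls outside the recording "
            f"[{resp.latency_s}, {resp.latency_s + duration}] s"
        )
    if duration <= resp.artifact_duration_s:
        raise ValueError("recording shorter than the movement-artifact window")
    rng = np.random.default_rng(seed)
    n = int(round(duration * base.fs))
    t0 = resp.latency_s
    t = t0 + np.arange(n) / base.fs
    components = _band_components(rng, t, base)
    x = np.zeros(n)
    for name, amp in base.band_amplitudes.items():
        x += amp * components[name] * _envelope(t, resp.gain(name), resp)
    x += base.noise * _pink_noise(rng, n, base.fs) * _envelope(t, 1.0, resp)
    art_end = t0 + resp.artifact_duration_s
    annotations = []
    if resp.artifact_duration_s > 0:
        x += _movement_artifact(rng, t, t0, art_end,
                                resp.artifact_multiplier * base.total_rms)
        annotations.append(Annotation(t0, art_end, "artifact", "movement"))
    if np.any(x):
        x = _acquisition_lowpass(x, base.fs)
    return EEGRecording(samples=x, fs=base.fs, phase="post-stun", t0=t0,
                        annotations=annotations)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortDesign:
    """Study design for a synthetic cohort.

    ``good_prob`` is the per-treatment probability that an animal is a
    good stun; non-good animals are split between electro-immobilisation
    and failure by ``immobilized_fraction``.  ``label_allocation`` is
    ``"bernoulli"`` (independent draws; the default) or ``"quota"``
    (exactly ``round(p * n)`` good animals per group, randomly placed),
    the latter reproducing the study's fixed composition.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"P1-50": 31, "P1-400": 29, "P2-50": 29, "P2-400": 30}
    )
    good_prob: dict[str, float] = field(
        default_factory=lambda: {"P1-50": 0.94, "P1-400": 0.90,
                                 "P2-50": 0.90, "P2-400": 0.73}
    )
    immobilized_fraction: float = 0.5
    master_seed: int = 0
    pre_duration_range: tuple[float, float] = (30.0, 60.0)
    post_duration: float = 60.0
    base_params: BandSpectrumParams = field(default_factory=BandSpectrumParams)
    label_allocation: str = "bernoulli"

    def __post_init__(self) -> None:
        for tx, n in self.group_sizes.items():
            if tx not in TREATMENTS:
                raise ValueError(f"unknown treatment {tx!r}")
            if n < 1:
                raise ValueError(f"group size for {tx} must be >= 1")
        for tx, p in self.good_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"good-stun probability for {tx} must be in [0, 1]")
        if self.label_allocation not in ("bernoulli", "quota"):
            raise ValueError("label_allocation must be 'bernoulli' or 'quota'")
        lo, hi = self.pre_duration_range
        if not 10 <= lo <= hi:
            raise ValueError("pre-stun duration range must be within [10, inf)")


@dataclass
class CohortAnimal:
    """One synthetic animal: both traces plus the generating ground truth."""

    animal_id: str
    treatment: str
    pre: EEGRecording
    post: EEGRecording
    quality: str
    response: StunResponseParams
    seed: int


def _draw_labels(rng: np.random.Generator, design: CohortDesign,
                 treatment: str) -> list[str]:
    n = design.group_sizes[treatment]
    p = design.good_prob.get(treatment, 1.0)
    if design.label_allocation == "quota":
        n_good = int(round(p * n))
        labels = ["good"] * n_good
        for _ in range(n - n_good):
            labels.append("immobilized" if rng.random() < design.immobilized_fraction
                          else "failed")
        order = rng.permutation(n)
        return [labels[i] for i in order]
    labels = []
    for _ in range(n):
        if rng.random() < p:
            labels.append("good")
        else:
            labels.append("immobilized" if rng.random() < design.immobilized_fraction
                          else "failed")
    return labels


def generate_cohort(design: CohortDesign | None = None,
                    master_seed: int | None = None) -> list[CohortAnimal]:
    """Generate a full cohort; identical design and seed give a
    bit-identical cohort."""
    design = design or CohortDesign()
    if master_seed is not None:
        design = replace(design, master_seed=master_seed)
    ss = np.random.SeedSequence(design.master_seed)
    label_seed, *children = ss.spawn(1 + sum(design.group_sizes.values()))
    label_rng = np.random.default_rng(label_seed)
    animals: list[CohortAnimal] = []
    child_iter = iter(children)
    for treatment in design.group_sizes:
        labels = _draw_labels(label_rng, design, treatment)
        for i, quality in enumerate(labels):
            child = next(child_iter)
            pre_seed, post_seed, aux_seed = (
                int(s) for s in child.generate_state(3) & 0x7FFFFFFF
            )
            rng = np.random.default_rng(aux_seed)
            pre_duration = rng.uniform(*design.pre_duration_range)
            resp = sample_response(rng, quality)
            pre = generate_baseline_trace(design.base_params, pre_duration, pre_seed)
            post = generate_poststun_trace(design.base_params, resp,
                                           design.post_duration, post_seed)
            animal_id = f"{treatment}-{i + 1:02d}"
            pre = pre.with_samples(pre.samples, animal_id=animal_id, treatment=treatment)
            post = post.with_samples(post.samples, animal_id=animal_id,
                                     treatment=treatment,
                                     annotations=list(post.annotations))
            animals.append(CohortAnimal(animal_id, treatment, pre, post, quality,
                                        resp, aux_seed))
    return animals
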