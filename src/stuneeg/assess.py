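"""Per-animal stun assessment: baseline normalisation, decibel change,
sustained-change classification, nadir and suppression timing.

Power is normalised per animal: the median power over clean pre-stun
epochs (per band, pooled low-frequency delta+theta, and total) is the
baseline, and every post-stun epoch is expressed as a decibel change

    dBchange = 100 * log10(value / baseline)

using the 100x convention (a power doubling is +30.103 units); a config
switch selects the conventional 10x scale.  A stun is classified "good"
(sustained change) when the pooled delta+theta dB change stays at or
above the threshold for a contiguous run of usable epochs extending
beyond 25 s post-stun.  The nadir is the epoch with the greatest
absolute total-power dB change; a suppression interval is the maximal
run with total dB change at or below minus the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bands import DEFAULT_BANDS, LOW_FREQ_BANDS, BandDefinition
from .preprocess import ArtifactCriteria, bandpass, detect_artifacts, trim_edges
from .recording import EEGRecording
from .spectral import (
    DEFAULT_NFFT,
    BandPowerSeries,
    EpochGrid,
    PeriodSummary,
    compute_band_powers,
    make_epochs,
    period_summary,
)

logger = logging.getLogger(__name__)


@dataclass
class AssessmentConfig:
    """Every tunable of the per-animal analysis chain, with its default."""

    trim_margin: float = 2.0
    bp_low: float = 0.0
    bp_high: float = 30.0
    epoch_length: float = 1.0
    overlap: float = 0.25
    nfft: int = DEFAULT_NFFT
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    artifact_criteria: ArtifactCriteria = field(default_factory=ArtifactCriteria)
    db_scale: float = 100.0          # printed convention; 10.0 for conventional dB
    threshold: float = 30.0          # sustained-change threshold (active dB unit)
    min_duration: float = 25.0       # run must extend beyond this (s post-stun)
    epochs_per_period: int = 10
    t1_end: float = 25.0
    t2_window: tuple[float, float] = (26.0, 50.0)

    @property
    def stride(self) -> float:
        return self.epoch_length * (1.0 - self.overlap)


@dataclass
class BaselineProfile:
    """Median clean pre-stun power per band, pooled low band and total."""

    band_medians: dict[str, float]
    low_median: float
    total_median: float

    @classmethod
    def from_series(cls, series: BandPowerSeries) -> "BaselineProfile":
        clean = series.clean
        if not clean.any():
            raise ValueError("no clean pre-stun epochs; baseline undefined")
        band_medians = {
            name: float(np.median(series.band(name)[clean]))
            for name in series.band_names
        }
        low = float(np.median(series.pooled(LOW_FREQ_BANDS)[clean]))
        total = float(np.median(series.total[clean]))
        zeros = [k for k, v in band_medians.items() if not v > 0]
        if zeros or not total > 0 or not low > 0:
            raise ValueError(
                f"zero baseline median in band(s) {zeros or ['total']}; "
                "widen the bands or record a longer baseline"
            )
        return cls(band_medians=band_medians, low_median=low, total_median=total)


def db_change(value, baseline, scale: float = 100.0):
    """Decibel change from baseline: ``scale * log10(value / baseline)``.

    Zero values map to ``-inf`` (flagged downstream, excluded from
    summaries).  Scale-invariant: ``db_change(c*v, c*b) == db_change(v, b)``.
    """
    baseline = np.asarray(baseline, dtype=np.float64)
    if np.any(baseline <= 0):
        raise ValueError("baseline must be strictly positive")
    value = np.asarray(value, dtype=np.float64)
    if np.any(value < 0):
        raise ValueError("power values must be non-negative")
    with np.errstate(divide="ignore"):
        out = scale * np.log10(value / baseline)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class DBChangeSeries:
    """Per-epoch dB change from baseline (per band, pooled low, total)."""

    starts: np.ndarray
    band_names: tuple[str, ...]
    db: np.ndarray                  # shape (n_epochs, n_bands)
    db_low: np.ndarray              # pooled delta+theta
    db_total: np.ndarray
    clean: np.ndarray
    epoch_length: float
    scale: float = 100.0

    @classmethod
    def from_series(cls, series: BandPowerSeries, baseline: BaselineProfile,
                    epoch_length: float, scale: float = 100.0) -> "DBChangeSeries":
        db = np.column_stack([
            db_change(series.band(name), baseline.band_medians[name], scale)
            for name in series.band_names
        ])
        return cls(
            starts=series.starts.copy(),
            band_names=series.band_names,
            db=db,
            db_low=db_change(series.pooled(LOW_FREQ_BANDS), baseline.low_median, scale),
            db_total=db_change(series.total, baseline.total_median, scale),
            clean=series.clean.copy(),
            epoch_length=epoch_length,
            scale=scale,
        )

    def band(self, name: str) -> np.ndarray:
        return self.db[:, self.band_names.index(name)]

    @property
    def usable(self) -> np.ndarray:
        """Clean epochs with finite pooled-low and total dB."""
        return self.clean & np.isfinite(self.db_low) & np.isfinite(self.db_total)


@dataclass
class StunAssessment:
    """Per-animal verdict."""

    sustained: bool                      # the "good stun" flag
    sustained_duration: float            # longest above-threshold run (s)
    nadir_time: float | None             # epoch centre (s post-stun)
    nadir_db: float | None               # signed total dB at the nadir
    suppression: tuple[float, float] | None
    first_usable_time: float | None
    threshold: float
    min_duration: float
    n_usable: int


def _runs(indices: np.ndarray) -> list[np.ndarray]:
    """Split an index array into runs consecutive in the usable subsequence."""
    if indices.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) != 1) + 1
    return np.split(indices, breaks)


def classify_stun(dbs: DBChangeSeries, threshold: float = 30.0,
                  min_duration: float = 25.0) -> StunAssessment:
    """Classify one post-stun dB series.

    The sustained flag requires a contiguous above-threshold run that is
    present at ``min_duration`` seconds post-stun and continues past it
    (an isolated late excursion does not count as a sustained change).
    Excluded (unclean or ``-inf``) epochs do not break runs: runs are
    contiguous in the subsequence of usable epochs.
    """
    usable = np.flatnonzero(dbs.usable)
    if usable.size == 0:
        raise ValueError("no usable post-stun epochs")
    n_excluded_inf = int(np.sum(dbs.clean & ~np.isfinite(dbs.db_low)))
    if n_excluded_inf:
        logger.info("%d zero-power epochs excluded from run-length logic", n_excluded_inf)

    ends = dbs.starts + dbs.epoch_length
    above_pos = usable[dbs.db_low[usable] >= threshold]
    sustained = False
    sustained_duration = 0.0
    for run in _runs(above_pos):
        dur = float(ends[run[-1]] - dbs.starts[run[0]])
        sustained_duration = max(sustained_duration, dur)
        # the change must be present at the mark and continue past it
        if dbs.starts[run[0]] < min_duration and ends[run[-1]] > min_duration:
            sustained = True

    i_nadir = usable[np.argmax(np.abs(dbs.db_total[usable]))]
    nadir_time = float(dbs.starts[i_nadir] + dbs.epoch_length / 2)
    nadir_db = float(dbs.db_total[i_nadir])

    supp_pos = usable[dbs.db_total[usable] <= -threshold]
    suppression = None
    best = 0.0
    for run in _runs(supp_pos):
        dur = float(ends[run[-1]] - dbs.starts[run[0]])
        if dur > best:
            best = dur
            suppression = (float(dbs.starts[run[0]]), float(ends[run[-1]]))

    return StunAssessment(
        sustained=sustained,
        sustained_duration=sustained_duration,
        nadir_time=nadir_time,
        nadir_db=nadir_db,
        suppression=suppression,
        first_usable_time=float(dbs.starts[usable[0]]),
        threshold=threshold,
        min_duration=min_duration,
        n_usable=int(usable.size),
    )


@dataclass
class AnimalAssessment:
    """All per-animal intermediates: period summaries, dB series, verdict."""

    animal_id: str | None
    treatment: str
    periods: dict[str, PeriodSummary]
    db_series: DBChangeSeries
    db_periods: dict[str, dict[str, float]]   # mean finite dB per band, T1/T2
    baseline: BaselineProfile
    assessment: StunAssessment
    pre_series: BandPowerSeries
    post_series: BandPowerSeries
    pre_grid: EpochGrid
    post_grid: EpochGrid


def _prepare(rec: EEGRecording, config: AssessmentConfig) -> EEGRecording:
    out = trim_edges(rec, config.trim_margin)
    out = bandpass(out, config.bp_low, config.bp_high)
    out.annotations = detect_artifacts(out, config.artifact_criteria)
    return out


def _mean_finite_db(dbs: DBChangeSeries, idx: np.ndarray) -> dict[str, float]:
    out = {}
    for name in dbs.band_names:
        v = dbs.band(name)[idx]
        v = v[np.isfinite(v)]
        out[name] = float(v.mean()) if v.size else float("nan")
    v = dbs.db_total[idx]
    v = v[np.isfinite(v)]
    out["total"] = float(v.mean()) if v.size else float("nan")
    return out


def assess_animal(pre: EEGRecording, post: EEGRecording,
                  config: AssessmentConfig | None = None) -> AnimalAssessment:
    """Run the full per-animal chain: preprocess, spectral, baseline
    normalisation, classification, and T0/T1/T2 summaries."""
    config = config or AssessmentConfig()
    animal = pre.animal_id or post.animal_id
    try:
        pre_c = _prepare(pre, config)
        post_c = _prepare(post, config)

        pre_grid = make_epochs(pre_c, config.epoch_length, config.overlap)
        post_grid = make_epochs(post_c, config.epoch_length, config.overlap)
        pre_series = compute_band_powers(pre_c, pre_grid, config.bands, config.nfft)
        post_series = compute_band_powers(post_c, post_grid, config.bands, config.nfft)

        baseline = BaselineProfile.from_series(pre_series)
        dbs = DBChangeSeries.from_series(post_series, baseline,
                                         config.epoch_length, config.db_scale)
        assessment = classify_stun(dbs, config.threshold, config.min_duration)

        n = config.epochs_per_period
        t0_window = (pre_grid.starts[0], pre_grid.starts[-1] + config.epoch_length)
        periods = {
            "T0": period_summary(pre_grid, pre_series, "T0", t0_window, n=n),
            "T1": period_summary(post_grid, post_series, "T1",
                                 (assessment.first_usable_time, config.t1_end),
                                 n=n, allow_fewer=True),
            "T2": period_summary(post_grid, post_series, "T2", config.t2_window,
                                 n=n, allow_fewer=True),
        }
        db_periods = {
            label: _mean_finite_db(dbs, periods[label].indices) for label in ("T1", "T2")
        }
        return AnimalAssessment(
            animal_id=animal,
            treatment=post.treatment if post.treatment != "unknown" else pre.treatment,
            periods=periods,
            db_series=dbs,
            db_periods=db_periods,
            baseline=baseline,
            assessment=assessment,
            pre_series=pre_series,
            post_series=post_series,
            pre_grid=pre_grid,
            post_grid=post_grid,
        )
    except Exception as exc:
        if hasattr(exc, "add_note"):
            exc.add_note(f"while assessing animal {animal!r}")
        raise
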