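"""Epoching, Hann-windowed FFT band powers, and period summaries.

The cleaned signal is cut into 1-s epochs with 25% overlap (0.75 s
stride).  Each epoch is Hann-windowed and transformed with a 1024-point
FFT (epochs shorter than 1024 samples are zero-padded), yielding a
one-sided power spectrum scaled so the bin powers sum to the mean square
of the epoch (window power compensation).  Band powers are sums of bins
whose centre frequency falls in the half-open band ``[lo, hi)``; at the
default 1 Hz resolution the very-low band (< 0.1 Hz) therefore maps to
the 0 Hz bin and delta to the 1-3 Hz bins.

For each analysis period (T0 pre-stun baseline, T1 up to 25 s post-stun,
T2 26-50 s post-stun) ten serial epochs with minimal interference are
selected; the period summary reports the RMS of the band-limited signal
(square root of mean band power) and percentage power per band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy.signal import windows

from .bands import DEFAULT_BANDS, TOTAL_RANGE, BandDefinition
from .recording import EEGRecording

logger = logging.getLogger(__name__)

DEFAULT_NFFT = 1024


@dataclass
class EpochGrid:
    """Epoch tiling of one recording: absolute start times and clean flags."""

    starts: np.ndarray          # absolute epoch start times (s)
    length: float               # epoch length (s)
    overlap: float              # overlap fraction
    clean: np.ndarray           # False iff epoch intersects an artifact annotation

    @property
    def stride(self) -> float:
        return self.length * (1.0 - self.overlap)

    @property
    def n_epochs(self) -> int:
        return int(self.starts.size)


@dataclass
class BandPowerSeries:
    """Per-epoch band powers (microvolt^2) plus total [0, 30) Hz power."""

    starts: np.ndarray                      # epoch start times (s)
    band_names: tuple[str, ...]
    powers: np.ndarray                      # shape (n_epochs, n_bands)
    total: np.ndarray                       # total power in TOTAL_RANGE per epoch
    clean: np.ndarray = field(default=None)  # copied from the grid

    def __post_init__(self) -> None:
        if self.clean is None:
            self.clean = np.ones(self.starts.size, dtype=bool)
        if np.any(self.powers < 0) or np.any(self.total < 0):
            raise ValueError("band powers must be non-negative")

    def band(self, name: str) -> np.ndarray:
        return self.powers[:, self.band_names.index(name)]

    def pooled(self, names: tuple[str, ...]) -> np.ndarray:
        idx = [self.band_names.index(n) for n in names]
        return self.powers[:, idx].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.powers, columns=list(self.band_names))
        df.insert(0, "start", self.starts)
        df["total"] = self.total
        df["clean"] = self.clean
        return df


@dataclass
class PeriodSummary:
    """Band RMS and percentage power over the epochs selected for one period."""

    label: str                       # T0 | T1 | T2
    indices: np.ndarray              # selected epoch indices into the series
    rms: dict[str, float]            # per-band RMS (microvolts)
    pct: dict[str, float]            # per-band percentage of total power
    mean_power: dict[str, float]     # per-band mean power over selected epochs
    n_requested: int = 10


def make_epochs(rec: EEGRecording, length: float = 1.0, overlap: float = 0.25) -> EpochGrid:
    """Tile the record with epochs of *length* seconds at ``length*(1-overlap)``
    stride; the trailing partial epoch is discarded."""
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap fraction must be in [0, 1), got {overlap}")
    if rec.duration + 1e-9 < length:
        raise ValueError(
            f"record of {rec.duration:.3f} s shorter than one {length} s epoch"
        )
    stride = length * (1.0 - overlap)
    n = int(np.floor((rec.duration - length) / stride + 1e-9)) + 1
    starts = rec.t0 + stride * np.arange(n)
    clean = np.ones(n, dtype=bool)
    for a in rec.artifact_annotations():
        clean &= ~((starts < a.end) & (a.start < starts + length))
    return EpochGrid(starts=starts, length=length, overlap=overlap, clean=clean)


def epoch_spectrum(x: np.ndarray, fs: float, nfft: int = DEFAULT_NFFT
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann-windowed power spectrum of a single epoch.

    Returns ``(freqs, power)`` with power scaled so that
    ``power.sum() ~= mean(x**2)`` (window power compensation: the
    squared-window sum divides the raw periodogram).  Epochs shorter than
    *nfft* samples are zero-padded; longer epochs are an error.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n == 0:
        raise ValueError("empty epoch")
    if n > nfft:
        raise ValueError(f"epoch of {n} samples exceeds FFT size {nfft}")
    w = windows.hann(n, sym=False)
    xw = x * w
    X = sp_fft.rfft(xw, n=nfft)
    denom = nfft * np.sum(w ** 2)
    power = (np.abs(X) ** 2) / denom
    power[1:] *= 2.0
    if nfft % 2 == 0:
        power[-1] /= 2.0
    freqs = sp_fft.rfftfreq(nfft, d=1.0 / fs)
    return freqs, power


def band_power(freqs: np.ndarray, power: np.ndarray, band: BandDefinition) -> float:
    """Sum of bin powers whose centre frequency lies in ``[band.lo, band.hi)``."""
    mask = (freqs >= band.lo) & (freqs < band.hi)
    return float(power[mask].sum())


def compute_band_powers(rec: EEGRecording, grid: EpochGrid,
                        bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                        nfft: int = DEFAULT_NFFT) -> BandPowerSeries:
    """Band powers and total [0, 30) Hz power for every epoch of *grid*."""
    nper = int(round(grid.length * rec.fs))
    lo, hi = TOTAL_RANGE
    n_epochs = grid.n_epochs
    powers = np.zeros((n_epochs, len(bands)))
    total = np.zeros(n_epochs)
    for i, start in enumerate(grid.starts):
        k = int(round((start - rec.t0) * rec.fs))
        seg = rec.samples[k : k + nper]
        freqs, p = epoch_spectrum(seg, rec.fs, nfft=nfft)
        for j, band in enumerate(bands):
            powers[i, j] = band_power(freqs, p, band)
        total[i] = float(p[(freqs >= lo) & (freqs < hi)].sum())
    return BandPowerSeries(
        starts=grid.starts.copy(),
        band_names=tuple(b.name for b in bands),
        powers=powers,
        total=total,
        clean=grid.clean.copy(),
    )


def select_serial_epochs(grid: EpochGrid, series: BandPowerSeries,
                         window: tuple[float, float], n: int = 10,
                         allow_fewer: bool = False) -> np.ndarray:
    """Indices of the *n* consecutive epochs inside *window* that minimise
    (unclean count, total-power variance, start time), lexicographically.

    An epoch is inside the window when it lies entirely within
    ``[window[0], window[1]]``.  With fewer than *n* candidate epochs the
    call fails unless *allow_fewer*, in which case all candidates are
    returned and a warning is logged.
    """
    w0, w1 = window
    tol = 1e-9
    candidates = np.flatnonzero(
        (grid.starts >= w0 - tol) & (grid.starts + grid.length <= w1 + tol)
    )
    if candidates.size < n:
        if allow_fewer and candidates.size >= 1:
            logger.warning(
                "window [%s, %s]: only %d epochs available (%d requested); using all",
                w0, w1, candidates.size, n,
            )
            return candidates
        raise ValueError(
            f"window [{w0}, {w1}] holds {candidates.size} epochs; {n} required"
        )
    best = None
    best_key = None
    for i in range(candidates.size - n + 1):
        run = candidates[i : i + n]
        unclean = int((~series.clean[run]).sum())
        var = float(np.var(series.total[run]))
        key = (unclean, var, float(grid.starts[run[0]]))
        if best_key is None or key < best_key:
            best_key, best = key, run
    return best


def period_summary(grid: EpochGrid, series: BandPowerSeries, label: str,
                   window: tuple[float, float], n: int = 10,
                   allow_fewer: bool = True) -> PeriodSummary:
    """Summary (band RMS and percentage power) over the epochs selected for
    one analysis period."""
    idx = select_serial_epochs(grid, series, window, n=n, allow_fewer=allow_fewer)
    mean_power = {
        name: float(series.band(name)[idx].mean()) for name in series.band_names
    }
    rms = {name: float(np.sqrt(p)) for name, p in mean_power.items()}
    band_sums = {name: float(series.band(name)[idx].sum()) for name in series.band_names}
    total_sum = float(series.total[idx].sum())
    if total_sum > 0:
        pct = {name: 100.0 * s / total_sum for name, s in band_sums.items()}
    else:
        pct = {name: float("nan") for name in series.band_names}
    return PeriodSummary(label=label, indices=np.asarray(idx), rms=rms, pct=pct,
                         mean_power=mean_power, n_requested=n)
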