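"""Empirical spectral features: PSD, intrinsic timescale, peak model.

The PSD path converts regional time series into dB spectra on the
analysis grid. The timescale is the lag at which the mean (over
regions) autocorrelation of band-passed signals decays to ``1/e``. The
peak parameterization decomposes a single dB spectrum into an aperiodic
power-law plus Gaussian peaks, with a two-peak summary (lowest two
center frequencies; the second duplicates the first when only one peak
exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import curve_fit

__all__ = [
    "RegionalPSD",
    "PeakSet",
    "TimescaleResult",
    "compute_psd_db",
    "acf_timescale",
    "parameterize_spectrum",
    "load_timeseries",
    "save_timeseries",
]


@dataclass(frozen=True)
class RegionalPSD:
    """Regions x frequencies power spectrum in dB (``20 log10`` amplitude)."""

    frequencies: np.ndarray
    psd_db: np.ndarray
    subject_id: str = ""
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        psd = np.atleast_2d(np.asarray(self.psd_db, dtype=float))
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(psd)):
            raise ValueError("non-finite PSD values")
        if psd.shape[1] != freqs.size:
            raise ValueError(
                f"psd_db has {psd.shape[1]} columns but grid has {freqs.size} points"
            )
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "psd_db", psd)

    @property
    def n_regions(self) -> int:
        return self.psd_db.shape[0]

    def save_csv(self, path: str | Path) -> None:
        idx = self.labels if self.labels else [f"r{i}" for i in range(self.n_regions)]
        pd.DataFrame(self.psd_db, index=idx, columns=self.frequencies).to_csv(path)

    @classmethod
    def load_csv(cls, path: str | Path, subject_id: str = "") -> "RegionalPSD":
        df = pd.read_csv(path, index_col=0)
        return cls(
            np.array([float(c) for c in df.columns]),
            df.to_numpy(float),
            subject_id=subject_id,
            labels=tuple(str(i) for i in df.index),
        )

    def save_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("frequencies", data=self.frequencies)
            fh.create_dataset("psd_db", data=self.psd_db)
            fh.attrs["subject_id"] = self.subject_id

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "RegionalPSD":
        with h5py.File(path, "r") as fh:
            return cls(
                fh["frequencies"][()],
                fh["psd_db"][()],
                subject_id=str(fh.attrs.get("subject_id", "")),
            )


@dataclass(frozen=True)
class TimescaleResult:
    """Intrinsic timescale from the mean autocorrelation function."""

    tau_acf: float  # ms
    acf: np.ndarray  # mean ACF, acf[0] == 1
    lags_ms: np.ndarray


@dataclass(frozen=True)
class PeakSet:
    """Aperiodic + periodic decomposition of one dB spectrum.

    ``aperiodic_offset`` and ``aperiodic_exponent`` parameterize
    ``log10 P(f) = offset - exponent * log10(f)`` (so a 1/f^2 power
    spectrum has exponent 2). Peaks are ``(center_freq Hz, power dB,
    bandwidth Hz)`` sorted by ascending center frequency; bandwidth is
    twice the Gaussian standard deviation.
    """

    aperiodic_offset: float
    aperiodic_exponent: float
    peaks: tuple[tuple[float, float, float], ...] = field(default=())

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def has_peaks(self) -> bool:
        return self.n_peaks > 0

    @property
    def first_cf(self) -> float:
        if not self.peaks:
            raise ValueError("no peaks found: center frequencies undefined")
        return self.peaks[0][0]

    @property
    def second_cf(self) -> float:
        """Second-lowest center frequency; duplicates the first if only one peak."""
        if not self.peaks:
            raise ValueError("no peaks found: center frequencies undefined")
        if len(self.peaks) == 1:
            return self.peaks[0][0]
        return self.peaks[1][0]


def load_timeseries(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read regional time series from HDF5 (datasets data/fs/labels) or CSV."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as fh:
            data = fh["data"][()]
            fs = float(fh["fs"][()])
            labels = [
                x.decode() if isinstance(x, bytes) else str(x) for x in fh["labels"][()]
            ]
        return data, fs, labels
    raise ValueError("CSV time series carry no sampling rate; use HDF5")


def save_timeseries(
    path: str | Path, data: np.ndarray, fs: float, labels: list[str]
) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=data)
        fh.create_dataset("fs", data=float(fs))
        fh.create_dataset("labels", data=np.array([s.encode() for s in labels]))


def compute_psd_db(
    timeseries: np.ndarray,
    fs: float,
    grid: np.ndarray,
    segment_seconds: float = 2.0,
) -> RegionalPSD:
    """Windowed-segment-averaged amplitude spectrum in dB on a grid.

    Welch segments (Hann window, 50% overlap, ``segment_seconds`` long)
    give the power density; the dB spectrum is ``20 log10`` of the
    amplitude, linearly interpolated onto ``grid``.
    """
    ts = np.atleast_2d(np.asarray(timeseries, dtype=float))
    grid = np.asarray(grid, dtype=float)
    if np.any(~np.isfinite(ts)):
        raise ValueError("NaN or infinite samples in time series")
    if fs <= 2.0 * grid.max():
        raise ValueError(f"sampling rate {fs} too low for grid up to {grid.max()} Hz")
    if ts.shape[1] < fs:
        raise ValueError("need at least 1 s of data")
    nperseg = min(int(round(segment_seconds * fs)), ts.shape[1])
    freqs, pxx = signal.welch(
        ts, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=1
    )
    amp_db = 20.0 * np.log10(np.sqrt(pxx) + 1e-300)
    out = np.vstack([np.interp(grid, freqs, row) for row in amp_db])
    return RegionalPSD(grid, out)


def _mean_acf(ts: np.ndarray, max_lag: int) -> np.ndarray:
    """Mean over regions of per-region normalized autocorrelation."""
    ts = ts - ts.mean(axis=1, keepdims=True)
    n = ts.shape[1]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(ts, n=nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, : max_lag + 1]
    ac /= ac[:, :1]
    return ac.mean(axis=0)


def acf_timescale(
    timeseries: np.ndarray,
    fs: float,
    band: tuple[float, float] | None = (1.0, 35.0),
    max_lag_seconds: float = 1.0,
) -> TimescaleResult:
    """Intrinsic timescale: lag (ms) where the mean ACF crosses ``1/e``.

    Each region is band-pass filtered (zero-phase Butterworth; ``band=None``
    skips filtering), autocorrelations are averaged across regions
    *first*, then the crossing is located with linear interpolation
    between the bracketing lags.
    """
    ts = np.atleast_2d(np.asarray(timeseries, dtype=float))
    if ts.shape[1] < 10 * fs:
        raise ValueError("need at least 10 s of data for timescale estimation")
    if band is not None:
        lo, hi = band
        if not (0 < lo < hi < fs / 2):
            raise ValueError(f"band {band} outside (0, {fs / 2})")
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        ts = signal.sosfiltfilt(sos, ts, axis=1)
    max_lag = int(round(max_lag_seconds * fs))
    acf = _mean_acf(ts, max_lag)
    lags_ms = np.arange(max_lag + 1) / fs * 1e3
    thr = np.exp(-1.0)
    below = np.nonzero(acf < thr)[0]
    if below.size == 0:
        raise ValueError(
            f"mean ACF never drops below 1/e within {max_lag_seconds} s"
        )
    i = int(below[0])
    if i == 0:
        raise ValueError("ACF below 1/e at zero lag: degenerate input")
    frac = (acf[i - 1] - thr) / (acf[i - 1] - acf[i])
    tau_ms = lags_ms[i - 1] + frac * (lags_ms[i] - lags_ms[i - 1])
    return TimescaleResult(float(tau_ms), acf, lags_ms)


def _gaussians(logf_hz: np.ndarray, *flat_params: float) -> np.ndarray:
    out = np.zeros_like(logf_hz)
    for j in range(0, len(flat_params), 3):
        cf, amp, sd = flat_params[j : j + 3]
        out += amp * np.exp(-((logf_hz - cf) ** 2) / (2.0 * sd**2))
    return out


def _fit_aperiodic(
    logf: np.ndarray, lp: np.ndarray, robust: bool
) -> tuple[float, float]:
    """Fit ``lp = offset - exponent * logf``; robust mode ignores peak bumps."""
    coef = np.polyfit(logf, lp, 1)
    if robust:
        resid = lp - np.polyval(coef, logf)
        # peaks sit above the aperiodic trend: keep the lower envelope
        mask = resid <= np.percentile(resid, 40.0)
        if mask.sum() >= 3:
            coef = np.polyfit(logf[mask], lp[mask], 1)
    return float(coef[1]), float(-coef[0])  # offset, exponent


def parameterize_spectrum(
    psd_db: np.ndarray,
    freqs: np.ndarray,
    max_peaks: int = 6,
    min_bandwidth: float = 2.0,
    max_bandwidth: float = 12.0,
    peak_threshold_sd: float = 2.0,
) -> PeakSet:
    """Decompose a single dB spectrum into aperiodic + Gaussian peaks.

    Works on ``log10 P = psd_db / 10`` versus ``log10 f``: a robust
    linear fit gives the aperiodic component; Gaussian peaks (in linear
    frequency) are extracted iteratively from the flattened spectrum
    while their amplitude exceeds ``peak_threshold_sd`` standard
    deviations of the flattened residual, then all peaks are refit
    jointly and the aperiodic component is refit on the peak-subtracted
    spectrum. Bandwidth (2 x Gaussian sd) is clamped to
    ``[min_bandwidth, max_bandwidth]``.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd_db = np.asarray(psd_db, dtype=float).ravel()
    if freqs.size < 10:
        raise ValueError("need at least 10 grid points")
    if freqs.size != psd_db.size:
        raise ValueError("frequency grid and spectrum length mismatch")
    lp = psd_db / 10.0  # log10 power
    logf = np.log10(freqs)

    offset, exponent = _fit_aperiodic(logf, lp, robust=True)
    flat = lp - (offset - exponent * logf)

    guesses: list[float] = []
    work = flat.copy()
    min_sd, max_sd = min_bandwidth / 2.0, max_bandwidth / 2.0
    for _ in range(max_peaks):
        i = int(np.argmax(work))
        amp = work[i]
        # relative threshold plus an absolute floor (0.2 dB) against
        # numeric ripple on noiseless smooth spectra
        if amp < max(peak_threshold_sd * np.std(work), 0.02):
            break
        # half-height width from the shorter side, robust to overlapping peaks
        half = amp / 2.0
        left = i
        while left > 0 and work[left] > half:
            left -= 1
        right = i
        while right < work.size - 1 and work[right] > half:
            right += 1
        side = min(freqs[i] - freqs[left], freqs[right] - freqs[i])
        fwhm = max(2.0 * side, 1e-3)
        sd = float(np.clip(fwhm / 2.355, min_sd, max_sd))
        guesses += [freqs[i], amp, sd]
        work = work - _gaussians(freqs, freqs[i], amp, sd)

    n_pk = len(guesses) // 3
    if n_pk == 0:
        return PeakSet(float(offset), float(exponent), ())

    lo_b, hi_b = [], []
    for j in range(n_pk):
        lo_b += [freqs[0], 0.0, min_sd]
        hi_b += [freqs[-1], np.inf, max_sd]
    try:
        popt, _ = curve_fit(
            _gaussians, freqs, flat, p0=guesses, bounds=(lo_b, hi_b), maxfev=5000
        )
    except RuntimeError:
        popt = np.asarray(guesses)

    # refit aperiodic on the peak-subtracted spectrum, then peaks once more
    peaks_only = _gaussians(freqs, *popt)
    offset, exponent = _fit_aperiodic(logf, lp - peaks_only, robust=False)
    flat = lp - (offset - exponent * logf)
    try:
        popt, _ = curve_fit(
            _gaussians, freqs, flat, p0=popt, bounds=(lo_b, hi_b), maxfev=5000
        )
    except RuntimeError:
        pass

    triples = sorted(
        (float(popt[3 * j]), 10.0 * float(popt[3 * j + 1]), 2.0 * float(popt[3 * j + 2]))
        for j in range(n_pk)
    )
    return PeakSet(float(offset), float(exponent), tuple(triples))
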