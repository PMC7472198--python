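"""Narrowband and broadband derivatives of recordings.

Band-limited voltage traces come from zero-phase second-order
Butterworth bandpass filters; spectra from fourth-order (4-cycle) Morlet
wavelets at 50 log-spaced frequencies between 2 and 100 Hz; broadband
power is the mean height of a robust line fit to the log-log spectrum,
a correlate of population firing rate. Every time-resolved output is
returned as a Recording so it can feed the correlation model and the
reconstruction machinery unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import signal

from .io import Recording, SessionData

#: Canonical frequency bands (Hz).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma_low": (30.0, 60.0),
    "gamma_high": (60.0, 100.0),
}


@dataclass(frozen=True)
class BandSpec:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"band {self.name}: need 0 < low < high")

    @classmethod
    def named(cls, name: str) -> "BandSpec":
        if name not in BANDS:
            raise KeyError(f"unknown band {name!r}; choose from {sorted(BANDS)}")
        lo, hi = BANDS[name]
        return cls(name, lo, hi)


@dataclass(frozen=True)
class PowerSpectrumConfig:
    """Wavelet spectrum grid: ``n_freqs`` log-spaced points on [f_min, f_max]."""

    n_freqs: int = 50
    f_min: float = 2.0
    f_max: float = 100.0
    wavelet_order: int = 4  # number of cycles of the Morlet wavelet

    def frequencies(self) -> np.ndarray:
        return np.logspace(np.log10(self.f_min), np.log10(self.f_max), self.n_freqs)

    def min_timepoints(self, samplerate: float) -> int:
        # the longest wavelet spans +/- 5 temporal SDs at the lowest frequency
        sigma_t = self.wavelet_order / (2.0 * np.pi * self.f_min)
        return int(np.ceil(10.0 * sigma_t * samplerate)) + 1


def bandpass(rec: Recording, band: BandSpec, order: int = 2) -> Recording:
    """Zero-phase Butterworth bandpass of every session."""
    nyq = rec.samplerate / 2.0
    if band.high_hz >= nyq:
        raise ValueError(
            f"band {band.name} upper edge {band.high_hz} Hz is at/above Nyquist {nyq} Hz"
        )
    sos = signal.butter(order, [band.low_hz, band.high_hz], btype="bandpass",
                        fs=rec.samplerate, output="sos")
    sessions = [SessionData(signal.sosfiltfilt(sos, s.voltages, axis=0),
                            s.samplerate, s.session_id) for s in rec.sessions]
    return rec.with_sessions(sessions)


def _tfr_power(voltages: np.ndarray, fs: float, cfg: PowerSpectrumConfig) -> np.ndarray:
    """Time-resolved Morlet power, shape (n_electrodes, n_freqs, T)."""
    from mne.time_frequency import tfr_array_morlet

    data = voltages.T[np.newaxis]  # (1, n_ch, T)
    return tfr_array_morlet(
        data, sfreq=fs, freqs=cfg.frequencies(), n_cycles=cfg.wavelet_order,
        output="power", zero_mean=True, verbose="error",
    )[0]


def _check_length(rec: Recording, cfg: PowerSpectrumConfig) -> None:
    need = cfg.min_timepoints(rec.samplerate)
    for ses in rec.sessions:
        if ses.n_timepoints < need:
            raise ValueError(
                f"session {ses.session_id}: {ses.n_timepoints} timepoints is too short "
                f"for a {cfg.f_min} Hz wavelet (need at least {need})"
            )


def wavelet_power(rec: Recording,
                  cfg: PowerSpectrumConfig = PowerSpectrumConfig()
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged log wavelet power per electrode.

    Returns ``(frequencies, log_power)`` with ``log_power`` of shape
    (n_electrodes, n_freqs), averaged over time and (duration-weighted)
    over sessions; natural-log units.
    """
    _check_length(rec, cfg)
    if rec.samplerate <= 2.0 * cfg.f_max:
        raise ValueError(f"samplerate {rec.samplerate} Hz cannot resolve {cfg.f_max} Hz")
    total = np.zeros((rec.n_electrodes, cfg.n_freqs))
    total_t = 0
    for ses in rec.sessions:
        p = _tfr_power(ses.voltages, ses.samplerate, cfg)  # (n_ch, n_freqs, T)
        total += p.sum(axis=2)
        total_t += ses.n_timepoints
    return cfg.frequencies(), np.log(total / total_t)


def _robust_line(log_f: np.ndarray, log_p: np.ndarray) -> tuple[float, float]:
    """Bisquare IRLS fit of log power on log frequency -> (intercept, slope)."""
    if np.ptp(log_p) < 1e-12:
        return float(log_p.mean()), 0.0
    exog = sm.add_constant(log_f)
    fit = sm.RLM(log_p, exog, M=sm.robust.norms.TukeyBiweight()).fit(
        maxiter=50, tol=1e-8)
    return float(fit.params[0]), float(fit.params[1])


def broadband_power(
    rec: Recording,
    cfg: PowerSpectrumConfig = PowerSpectrumConfig(),
    window: int | None = None,
    robust: bool = True,
) -> Recording:
    """Time-resolved broadband power per electrode.

    The session's time-resolved wavelet spectrum is averaged within
    non-overlapping windows (default one second); in each window a robust
    line is fitted to log power versus log frequency and the broadband
    value is the mean height of that line over the frequency grid. The
    output Recording has one sample per window. ``robust=False`` switches
    to ordinary least squares (for comparison only).
    """
    _check_length(rec, cfg)
    if window is None:
        window = int(round(rec.samplerate))
    if window < 1:
        raise ValueError("window must be >= 1 timepoint")
    log_f = np.log(cfg.frequencies())
    mean_log_f = log_f.mean()
    sessions = []
    for ses in rec.sessions:
        p = _tfr_power(ses.voltages, ses.samplerate, cfg)  # (n_ch, n_freqs, T)
        n_win = ses.n_timepoints // window
        if n_win < 2:
            raise ValueError(
                f"session {ses.session_id}: fewer than 2 windows of {window} timepoints"
            )
        bb = np.empty((n_win, rec.n_electrodes))
        for w in range(n_win):
            seg = np.log(p[:, :, w * window:(w + 1) * window].mean(axis=2))
            for e in range(rec.n_electrodes):
                if robust:
                    a, b = _robust_line(log_f, seg[e])
                else:
                    b, a = np.polyfit(log_f, seg[e], 1)
                bb[w, e] = a + b * mean_log_f  # mean height over the grid
        sessions.append(SessionData(bb, rec.samplerate / window, ses.session_id))
    return rec.with_sessions(sessions)


def hilbert_band_power(rec: Recording, band: BandSpec) -> Recording:
    """Band-limited instantaneous power: bandpass, analytic amplitude squared."""
    filtered = bandpass(rec, band)
    sessions = []
    for ses in filtered.sessions:
        analytic = signal.hilbert(ses.voltages, axis=0)
        sessions.append(SessionData(np.abs(analytic) ** 2, ses.samplerate, ses.session_id))
    return rec.with_sessions(sessions)
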