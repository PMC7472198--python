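"""Signal cleaning for intracranial recordings.

The pipeline is: zero-phase Butterworth notch at 60 Hz, downsampling to
a common 250 Hz rate, exclusion of putatively epileptiform electrodes by
excess kurtosis (threshold 10, maximum over sessions), exclusion of
patients left with fewer than two clean electrodes, and per-session
z-scoring. Every step is a pure function returning new Recording
objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import kurtosis as _kurtosis

from .io import Recording, SessionData


@dataclass(frozen=True)
class PreprocessConfig:
    """Cleaning parameters.

    notch_hz / notch_halfwidth_hz / notch_order : line-noise band-stop
        (60 +/- 0.5 Hz, 4th-order Butterworth, applied forward-backward).
    target_rate_hz : common samplerate after downsampling (250 Hz).
    kurtosis_threshold : electrodes whose maximum excess kurtosis across
        sessions reaches this value are dropped (10).
    min_electrodes : patients with fewer surviving electrodes are dropped (2).
    extra_notch_hz : optional additional band-stop centers (e.g. harmonics);
        empty by default.
    """

    notch_hz: float = 60.0
    notch_halfwidth_hz: float = 0.5
    notch_order: int = 4
    target_rate_hz: float = 250.0
    kurtosis_threshold: float = 10.0
    min_electrodes: int = 2
    extra_notch_hz: tuple = ()

    def __post_init__(self) -> None:
        for name in ("notch_hz", "notch_halfwidth_hz", "notch_order",
                     "target_rate_hz", "kurtosis_threshold", "min_electrodes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _apply_notch(voltages: np.ndarray, fs: float, center: float,
                 halfwidth: float, order: int) -> np.ndarray:
    sos = signal.butter(order, [center - halfwidth, center + halfwidth],
                        btype="bandstop", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, voltages, axis=0)


def notch_filter(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> Recording:
    """Remove line noise with a zero-phase Butterworth band-stop.

    Forward-backward application avoids the phase distortion that would
    corrupt cross-electrode correlations. Requires the samplerate to
    exceed twice the upper stop edge.
    """
    centers = (cfg.notch_hz,) + tuple(cfg.extra_notch_hz)
    for c in centers:
        if rec.samplerate <= 2.0 * (c + cfg.notch_halfwidth_hz):
            raise ValueError(
                f"samplerate {rec.samplerate} Hz too low to notch at {c} Hz"
            )
    sessions = []
    for ses in rec.sessions:
        v = ses.voltages
        for c in centers:
            v = _apply_notch(v, ses.samplerate, c, cfg.notch_halfwidth_hz, cfg.notch_order)
        sessions.append(SessionData(v, ses.samplerate, ses.session_id))
    return rec.with_sessions(sessions)


def resample_to(rec: Recording, target_rate: float) -> Recording:
    """Downsample every session to ``target_rate`` with anti-aliasing.

    Rational rate ratios use polyphase filtering; irrational ones fall
    back to Fourier-domain resampling. Upsampling is out of scope.
    """
    current = rec.samplerate
    if target_rate > current:
        raise ValueError(f"upsampling {current} -> {target_rate} Hz is not supported")
    if target_rate == current:
        return rec.with_sessions([SessionData(s.voltages.copy(), s.samplerate, s.session_id)
                                  for s in rec.sessions])
    frac = Fraction(target_rate / current).limit_denominator(10_000)
    rational = abs(float(frac) - target_rate / current) < 1e-12
    sessions = []
    for ses in rec.sessions:
        if rational:
            v = signal.resample_poly(ses.voltages, frac.numerator, frac.denominator, axis=0)
        else:
            n_out = int(round(ses.n_timepoints * target_rate / current))
            v = signal.resample(ses.voltages, n_out, axis=0)
        sessions.append(SessionData(v, target_rate, ses.session_id))
    return rec.with_sessions(sessions)


def max_session_kurtosis(rec: Recording) -> np.ndarray:
    """Per electrode, the maximum excess kurtosis over sessions.

    Fisher (excess) kurtosis by the moment formula m4/m2^2 - 3, so a
    Gaussian electrode scores ~0.
    """
    ks = np.stack([_kurtosis(s.voltages, axis=0, fisher=True, bias=True)
                   for s in rec.sessions])
    return ks.max(axis=0)


def kurtosis_exclude(
    recs: list[Recording], cfg: PreprocessConfig = PreprocessConfig()
) -> tuple[list[Recording], pd.DataFrame]:
    """Drop spiky electrodes, then patients left with too few electrodes.

    Returns the surviving recordings and a report with one row per
    electrode of every input patient: ``patient_id, electrode_id,
    max_kurtosis, excluded, excluded_reason``.
    """
    survivors = []
    rows = []
    for rec in recs:
        mk = max_session_kurtosis(rec)
        keep = mk < cfg.kurtosis_threshold
        patient_dropped = int(keep.sum()) < cfg.min_electrodes
        for i, eid in enumerate(rec.electrode_ids):
            if not keep[i]:
                reason = "kurtosis"
            elif patient_dropped:
                reason = "patient_too_few_electrodes"
            else:
                reason = ""
            rows.append({
                "patient_id": rec.patient_id,
                "electrode_id": eid,
                "max_kurtosis": float(mk[i]),
                "excluded": bool(not keep[i] or patient_dropped),
                "excluded_reason": reason,
            })
        if not patient_dropped:
            survivors.append(rec.subset_electrodes(keep) if not keep.all() else rec)
    return survivors, pd.DataFrame(rows)


def zscore_sessions(rec: Recording) -> Recording:
    """Z-score each electrode within each session (mean 0, sample SD 1)."""
    sessions = []
    for ses in rec.sessions:
        sd = ses.voltages.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [rec.electrode_ids[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(
                f"patient {rec.patient_id}, session {ses.session_id}: zero-variance "
                f"electrode(s) {bad} — exclude them before z-scoring"
            )
        v = (ses.voltages - ses.voltages.mean(axis=0)) / sd
        sessions.append(SessionData(v, ses.samplerate, ses.session_id))
    return rec.with_sessions(sessions)


@dataclass
class PreprocessResult:
    recordings: list[Recording]
    exclusions: pd.DataFrame
    config: PreprocessConfig = field(default_factory=PreprocessConfig)


def preprocess(recs: list[Recording],
               cfg: PreprocessConfig = PreprocessConfig()) -> PreprocessResult:
    """Full cleaning pipeline: notch -> resample -> kurtosis-exclude -> z-score."""
    staged = [resample_to(notch_filter(r, cfg), min(cfg.target_rate_hz, r.samplerate))
              for r in recs]
    kept, report = kurtosis_exclude(staged, cfg)
    return PreprocessResult([zscore_sessions(r) for r in kept], report, cfg)
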