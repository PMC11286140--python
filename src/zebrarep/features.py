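"""Acoustic feature extraction for zebra vocalizations.

Twelve features are measured per call: four fundamental-frequency (F0)
statistics (mean, max, min, range — defined only for the tonal squeal and
quagga quagga), three spectral energy quartiles (Q25/Q50/Q75), the peak
frequency, the duration, and three amplitude metrics (cumulative amplitude
variation per second, amplitude-modulation rate, amplitude-modulation
extent). The eight non-F0 features form the subset used for repertoire
analysis, where non-tonal calls must be comparable with tonal ones.

Calls are first high-pass filtered with a per-type cutoff — 30 Hz for
snorts and soft snorts, 500 Hz for squeals, 600 Hz for quagga quagga
(above the average minimum F0 of the tonal types) — using a zero-phase
forward-backward 4th-order Butterworth filter so envelope metrics are not
phase-distorted.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from zebrarep.synth import CallRecord, Waveform, read_wav

HIGH_PASS_CUTOFF_HZ = {
    "snort": 30.0,
    "soft_snort": 30.0,
    "squeal": 500.0,
    "quagga_quagga": 600.0,
}

# F0 search ranges (Hz) for the tonal call types.
F0_SEARCH_RANGE_HZ = {
    "squeal": (400.0, 4000.0),
    "quagga_quagga": (400.0, 3000.0),
}

F0_FIELDS = ("mean_f0", "max_f0", "min_f0", "range_f0")
REPERTOIRE_FIELDS = ("q25", "q50", "q75", "peak_frequency", "duration",
                     "amplitude_variation", "am_rate", "am_extent")
ALL_FIELDS = F0_FIELDS + REPERTOIRE_FIELDS
# Input to correlation-based screening (KMO): range_f0 is the exact
# difference max_f0 - min_f0, which makes the correlation matrix singular,
# so the redundant column is left out of factor-analytic steps.
INDIVIDUALITY_FIELDS = tuple(f for f in ALL_FIELDS if f != "range_f0")


@dataclass
class FeatureVector:
    """The twelve per-call acoustic features; missing values are NaN.

    Frequencies in Hz, duration in s, amplitude_variation in dB/s,
    am_rate in s^-1, am_extent in dB.
    """

    call_id: str
    mean_f0: float = np.nan
    max_f0: float = np.nan
    min_f0: float = np.nan
    range_f0: float = np.nan
    q25: float = np.nan
    q50: float = np.nan
    q75: float = np.nan
    peak_frequency: float = np.nan
    duration: float = np.nan
    amplitude_variation: float = np.nan
    am_rate: float = np.nan
    am_extent: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


def high_pass(wave: Waveform, call_type: str, order: int = 4) -> Waveform:
    """Zero-phase Butterworth high-pass with the per-type cutoff."""
    if len(wave.samples) == 0:
        raise ValueError("empty waveform")
    cutoff = HIGH_PASS_CUTOFF_HZ[call_type]
    nyq = wave.rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff, btype="highpass", fs=wave.rate, output="sos")
    return Waveform(samples=signal.sosfiltfilt(sos, wave.samples), rate=wave.rate)


def f0_contour(wave: Waveform, fmin: float, fmax: float,
               frame_s: float = 0.040, hop_s: float = 0.010,
               voicing_threshold: float = 0.45
               ) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise autocorrelation F0 track.

    Returns ``(f0_hz, voiced)`` where unvoiced frames (normalized
    autocorrelation peak below `voicing_threshold`) have NaN F0. The
    contour has ``ceil(duration / hop)`` frames; trailing partial frames
    are zero-padded.
    """
    if not 0 < fmin < fmax < wave.rate / 2:
        raise ValueError("need 0 < fmin < fmax < Nyquist")
    x = wave.samples
    rate = wave.rate
    frame_n = int(round(frame_s * rate))
    hop_n = int(round(hop_s * rate))
    n_frames = max(1, int(np.ceil(len(x) / hop_n)))
    lag_min = max(2, int(np.floor(rate / fmax)))
    lag_max = int(np.ceil(rate / fmin))
    window = np.hanning(frame_n)

    f0 = np.full(n_frames, np.nan)
    voiced = np.zeros(n_frames, dtype=bool)
    for i in range(n_frames):
        start = i * hop_n
        frame = x[start:start + frame_n]
        if len(frame) < frame_n:
            frame = np.pad(frame, (0, frame_n - len(frame)))
        frame = (frame - frame.mean()) * window
        e0 = np.dot(frame, frame)
        if e0 <= 0:
            continue
        ac = signal.correlate(frame, frame, mode="full")[frame_n - 1:]
        ac = ac / ac[0]
        hi = min(lag_max + 1, frame_n - 1)
        if hi <= lag_min:
            continue
        seg = ac[lag_min:hi]
        strength = float(np.max(seg))
        if strength < voicing_threshold:
            continue
        # Subharmonic guard: vibrato/AM can lift the 2T autocorrelation peak
        # marginally above the T peak; take the smallest-lag local maximum
        # within 90% of the best peak.
        peaks, _ = signal.find_peaks(seg)
        candidates = peaks[seg[peaks] >= 0.9 * strength]
        k = (int(candidates[0]) if len(candidates) else int(np.argmax(seg))) + lag_min
        # parabolic interpolation around the autocorrelation peak
        if 0 < k < len(ac) - 1:
            denom = ac[k - 1] - 2 * ac[k] + ac[k + 1]
            delta = 0.5 * (ac[k - 1] - ac[k + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        f0[i] = rate / (k + delta)
        voiced[i] = True
    return f0, voiced


def spectral_summary(wave: Waveform) -> tuple[float, float, float, float]:
    """Energy quartiles and peak frequency from the whole-call spectrum.

    A single rectangular-window DFT of the entire call; the quartile q_p is
    the smallest frequency bin where cumulative spectral energy reaches
    p of the total.
    """
    x = wave.samples
    if len(x) == 0:
        raise ValueError("empty waveform")
    power = np.abs(np.fft.rfft(x)) ** 2
    total = power.sum()
    if total <= 0:
        raise ValueError("zero-energy signal")
    freqs = np.fft.rfftfreq(len(x), d=1.0 / wave.rate)
    cum = np.cumsum(power) / total
    q25 = freqs[np.searchsorted(cum, 0.25)]
    q50 = freqs[np.searchsorted(cum, 0.50)]
    q75 = freqs[np.searchsorted(cum, 0.75)]
    peak = freqs[int(np.argmax(power))]
    return float(q25), float(q50), float(q75), float(peak)


def intensity_contour(wave: Waveform, frame_s: float = 0.010,
                      hop_s: float = 0.005) -> tuple[np.ndarray, float]:
    """Frame RMS intensity in dB (re full scale). Returns (contour, hop_s)."""
    x = wave.samples
    frame_n = max(1, int(round(frame_s * wave.rate)))
    hop_n = max(1, int(round(hop_s * wave.rate)))
    n_frames = max(1, 1 + (len(x) - frame_n) // hop_n) if len(x) >= frame_n else 1
    out = np.empty(n_frames)
    for i in range(n_frames):
        frame = x[i * hop_n:i * hop_n + frame_n]
        rms = np.sqrt(np.mean(frame**2)) if len(frame) else 0.0
        out[i] = 20 * np.log10(max(rms, 1e-10))
    return out, hop_n / wave.rate


def amplitude_metrics(wave: Waveform, frame_s: float = 0.010,
                      hop_s: float = 0.005, prominence_db: float = 3.0
                      ) -> tuple[float, float, float]:
    """Amplitude variation (dB/s), AM rate (s^-1) and AM extent (dB).

    The intensity contour is the frame-RMS level in dB. Amplitude
    variation is the cumulative absolute dB change divided by the call
    duration. AM cycles are prominent envelope maxima (prominence >=
    `prominence_db`); the rate is their count over the duration and the
    extent is the mean peak-to-trough excursion of those cycles. A call
    with no qualifying cycle has am_rate 0 and am_extent NaN.
    """
    duration = wave.duration_s
    if duration <= 0:
        raise ValueError("empty waveform")
    contour, _hop = intensity_contour(wave, frame_s, hop_s)
    if len(contour) < 3:
        raise ValueError("call too short for an intensity contour")
    amplitude_variation = float(np.sum(np.abs(np.diff(contour))) / duration)
    peaks, props = signal.find_peaks(contour, prominence=prominence_db)
    if len(peaks) == 0:
        return amplitude_variation, 0.0, np.nan
    am_rate = len(peaks) / duration
    am_extent = float(np.mean(props["prominences"]))
    return amplitude_variation, float(am_rate), am_extent


def extract_features(record: CallRecord, wave: Waveform) -> FeatureVector:
    """Extract the full feature vector for one call.

    `wave` must already be trimmed to [onset, offset]. The per-type
    high-pass filter is applied first; the F0 fields stay NaN for the
    non-tonal snort and soft snort.
    """
    filtered = high_pass(wave, record.call_type)
    fv = FeatureVector(call_id=record.call_id)
    fv.duration = record.offset_s - record.onset_s

    q25, q50, q75, peak = spectral_summary(filtered)
    fv.q25, fv.q50, fv.q75, fv.peak_frequency = q25, q50, q75, peak

    fv.amplitude_variation, fv.am_rate, fv.am_extent = amplitude_metrics(filtered)

    if record.call_type in F0_SEARCH_RANGE_HZ:
        fmin, fmax = F0_SEARCH_RANGE_HZ[record.call_type]
        fmax = min(fmax, wave.rate / 2 * 0.95)
        track, voiced = f0_contour(filtered, fmin, fmax)
        if voiced.any():
            v = track[voiced]
            fv.mean_f0 = float(np.mean(v))
            fv.max_f0 = float(np.max(v))
            fv.min_f0 = float(np.min(v))
            fv.range_f0 = fv.max_f0 - fv.min_f0
    return fv


def extract_feature_table(records: list[CallRecord],
                          audio_root: str | Path | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract features for a batch of calls, reading audio from disk.

    Returns ``(feature_table, failures)``; a call whose extraction raises
    is recorded in `failures` with the reason rather than aborting the
    batch. The feature table carries the call labels alongside the twelve
    features so downstream stages need no extra joins.
    """
    rows, failures = [], []
    for rec in records:
        path = Path(rec.file)
        if audio_root is not None and not path.is_absolute():
            path = Path(audio_root) / path
        try:
            wave = read_wav(path)
            i0 = int(round(rec.onset_s * wave.rate))
            i1 = int(round(rec.offset_s * wave.rate))
            clip = Waveform(samples=wave.samples[i0:i1] if i1 > i0 else wave.samples,
                            rate=wave.rate)
            fv = extract_features(rec, clip)
            row = fv.as_dict()
            row.update(call_type=rec.call_type, individual_id=rec.individual_id,
                       sex=rec.sex, location=rec.location)
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 — batch robustness by contract
            failures.append(dict(call_id=rec.call_id, reason=str(exc)))
    table = pd.DataFrame(rows)
    return table, pd.DataFrame(failures, columns=["call_id", "reason"])
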