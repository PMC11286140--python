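"""Mel-spectrogram preparation for spectrogram-based repertoire analysis.

Calls are converted to log-power mel-spectrograms (STFT magnitude through a
triangular mel filterbank, in dB relative to the call maximum with a fixed
floor), zero-power-padded to the longest call in the set, and time-shifted
so every call's energy onset sits at frame 0. The spectrogram distance is
Euclidean, minimized over a window of integer time shifts, which makes the
comparison tolerant to residual onset misalignment.

"Zero" padding is zero power, i.e. the dB floor (default -80 dB re max) —
literal zeros on a dB scale would inject mid-level energy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from zebrarep.synth import Waveform

MAX_CALL_DURATION_S = 1.25
DB_FLOOR = -80.0


@dataclass(frozen=True)
class MelParams:
    n_mels: int = 128
    window: int = 512
    hop: int = 256
    fmin: float = 30.0
    fmax: float | None = None  # None -> Nyquist


@dataclass
class MelSpectrogram:
    """A log-power mel-spectrogram (dB) with its preparation metadata."""

    matrix: np.ndarray  # n_mels x n_frames
    params: MelParams
    original_frames: int
    call_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(rate: int, n_fft: int, n_mels: int, fmin: float,
                   fmax: float) -> np.ndarray:
    """Triangular mel filterbank: (n_mels, n_fft//2 + 1)."""
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = np.asarray(mel_to_hz(mel_pts))
    bins = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mels, len(bins)))
    for m in range(n_mels):
        lo, center, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (bins - lo) / max(center - lo, 1e-12)
        down = (hi - bins) / max(hi - center, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mel_spectrogram(wave: Waveform, params: MelParams = MelParams(),
                    call_id: str = "",
                    max_duration_s: float = MAX_CALL_DURATION_S) -> MelSpectrogram:
    """Log-power mel-spectrogram of one call.

    Calls longer than `max_duration_s` are rejected (the repertoire rule);
    the number of frames is ``ceil(n_samples / hop) + 1``.
    """
    if wave.duration_s > max_duration_s + 1e-9:
        raise ValueError(
            f"call {call_id or '<unnamed>'} longer than {max_duration_s} s "
            f"({wave.duration_s:.3f} s): excluded from spectrogram analysis")
    fmax = params.fmax if params.fmax is not None else wave.rate / 2.0
    _, _, Z = signal.stft(wave.samples, fs=wave.rate, nperseg=params.window,
                          noverlap=params.window - params.hop, padded=True,
                          boundary="zeros")
    power = np.abs(Z) ** 2
    fb = mel_filterbank(wave.rate, params.window, params.n_mels, params.fmin, fmax)
    mel_power = fb @ power
    ref = mel_power.max()
    if ref <= 0:
        db = np.full_like(mel_power, DB_FLOOR)
    else:
        db = 10.0 * np.log10(np.maximum(mel_power / ref, 10.0 ** (DB_FLOOR / 10.0)))
    return MelSpectrogram(matrix=db, params=replace(params, fmax=fmax),
                          original_frames=db.shape[1], call_id=call_id)


def _onset_frame(matrix: np.ndarray, threshold_db_above_floor: float = 10.0) -> int:
    """First frame whose maximum exceeds the floor by the threshold."""
    floor = matrix.min()
    above = np.where(matrix.max(axis=0) > floor + threshold_db_above_floor)[0]
    return int(above[0]) if len(above) else 0


def pad_and_align(specs: list[MelSpectrogram],
                  onset_threshold_db: float = 10.0) -> list[MelSpectrogram]:
    """Pad all spectrograms to the longest length and align energy onsets.

    Padding is at the dB floor (zero power). Each call's content is shifted
    left so its energy onset (first frame exceeding the floor by
    `onset_threshold_db`) sits at frame 0.
    """
    if not specs:
        raise ValueError("empty spectrogram list")
    target = max(s.n_frames for s in specs)
    out = []
    for s in specs:
        onset = _onset_frame(s.matrix, onset_threshold_db)
        shifted = s.matrix[:, onset:]
        padded = np.full((s.matrix.shape[0], target), DB_FLOOR)
        padded[:, : shifted.shape[1]] = shifted
        out.append(MelSpectrogram(matrix=padded, params=s.params,
                                  original_frames=s.original_frames - onset,
                                  call_id=s.call_id))
    return out


def _shift_matrix(m: np.ndarray, s: int, fill: float) -> np.ndarray:
    """Shift columns right by s (left for negative), filling vacated frames."""
    out = np.full_like(m, fill)
    if s >= 0:
        if s < m.shape[1]:
            out[:, s:] = m[:, : m.shape[1] - s]
    else:
        if -s < m.shape[1]:
            out[:, :s] = m[:, -s:]
    return out


def timeshift_distance(a: MelSpectrogram | np.ndarray,
                       b: MelSpectrogram | np.ndarray,
                       max_shift: int | None = None,
                       fill: float = DB_FLOOR) -> float:
    """Euclidean spectrogram distance minimized over integer time shifts.

    The distance is ``min over s in [-max_shift, max_shift]`` of the
    Frobenius norm of ``a - shift(b, s)`` with vacated frames set to the
    dB floor. `max_shift` defaults to 25% of the frame count.
    """
    A = a.matrix if isinstance(a, MelSpectrogram) else np.asarray(a)
    B = b.matrix if isinstance(b, MelSpectrogram) else np.asarray(b)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if max_shift is None:
        max_shift = max(1, A.shape[1] // 4)
    best = np.inf
    for s in range(-max_shift, max_shift + 1):
        d = np.linalg.norm(A - _shift_matrix(B, s, fill))
        if d < best:
            best = d
    return float(best)


def pairwise_timeshift_distances(specs: list[MelSpectrogram] | np.ndarray,
                                 max_shift: int | None = None,
                                 fill: float = DB_FLOOR,
                                 block: int = 64,
                                 symmetrize: str | None = None) -> np.ndarray:
    """Full pairwise time-shift distance matrix, FFT-accelerated.

    Entry (i, j) equals ``timeshift_distance(specs[i], specs[j])`` (tested
    against that definition); all shifted inner products are computed at
    once via cross-correlation along the time axis:

    ``d2(s) = ||A'||^2 + ||shift(B', s)||^2 - 2 <A', shift(B', s)>``

    where ``X' = X - fill`` turns the fill value into zeros, so shifting
    with fill is shifting with zeros. The directed distance is symmetric
    only up to which call's frames get truncated by the shift; pass
    ``symmetrize="min"`` to take the elementwise minimum of the two
    directions (required by embedding methods).
    """
    if isinstance(specs, np.ndarray):
        mats = specs
    else:
        mats = np.stack([s.matrix for s in specs])
    n, n_mels, n_frames = mats.shape
    if max_shift is None:
        max_shift = max(1, n_frames // 4)
    X = mats - fill  # fill -> 0
    # column norms and cumulative sums for the frames shifted out of view
    col_sq = np.sum(X**2, axis=1)                      # (n, n_frames)
    tot_sq = col_sq.sum(axis=1)                        # (n,)
    head = np.concatenate([np.zeros((n, 1)), np.cumsum(col_sq, axis=1)], axis=1)
    tail = tot_sq[:, None] - head                      # tail[i, k] = sum of last frames from k

    nfft = int(2 ** np.ceil(np.log2(2 * n_frames)))
    F = np.fft.rfft(X, n=nfft, axis=2)                 # (n, n_mels, nf)

    D = np.zeros((n, n, 2 * max_shift + 1))
    shifts = np.arange(-max_shift, max_shift + 1)
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        # cross-correlation of block rows with all rows, summed over mel bands
        cc = np.fft.irfft(
            np.einsum("imf,jmf->ijf", F[i0:i1], np.conj(F)), n=nfft, axis=2)
        # <A_i, shift(B_j, s)> = sum_t A_i[t] B_j[t - s] = corr at lag s
        lag_idx = np.where(shifts >= 0, shifts, nfft + shifts)
        inner = cc[:, :, lag_idx]                      # (bi, n, n_shifts)
        # ||shift(B_j, s)||^2: shifting right by s drops the last s frames,
        # left by |s| drops the first |s| frames
        norm_b = np.empty((n, len(shifts)))
        for k, s in enumerate(shifts):
            if s >= 0:
                norm_b[:, k] = head[:, n_frames - s]
            else:
                norm_b[:, k] = tail[:, -s]
        d2 = tot_sq[i0:i1, None, None] + norm_b[None, :, :] - 2 * inner
        D[i0:i1] = d2
    D = np.sqrt(np.maximum(D.min(axis=2), 0.0))
    np.fill_diagonal(D, 0.0)
    if symmetrize == "min":
        D = np.minimum(D, D.T)
    elif symmetrize is not None:
        raise ValueError(f"unknown symmetrize mode {symmetrize!r}")
    return D


def save_spectrogram_set(specs: list[MelSpectrogram], npz_path: str | Path,
                         index_csv: str | Path | None = None) -> None:
    """Persist a prepared (uniform-shape) spectrogram set as an .npz archive
    plus a CSV index (call_id, original_frames)."""
    mats = np.stack([s.matrix for s in specs])
    np.savez_compressed(npz_path, matrices=mats,
                        original_frames=np.array([s.original_frames for s in specs]),
                        call_ids=np.array([s.call_id for s in specs]))
    if index_csv is not None:
        pd.DataFrame({
            "call_id": [s.call_id for s in specs],
            "original_frames": [s.original_frames for s in specs],
        }).to_csv(index_csv, index=False)


def load_spectrogram_set(npz_path: str | Path,
                         params: MelParams = MelParams()) -> list[MelSpectrogram]:
    data = np.load(npz_path, allow_pickle=False)
    return [MelSpectrogram(matrix=m, params=params, original_frames=int(of),
                           call_id=str(cid))
            for m, of, cid in zip(data["matrices"], data["original_frames"],
                                  data["call_ids"])]
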