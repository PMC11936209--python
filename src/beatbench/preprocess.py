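"""Record preprocessing: QRS detection, segmentation, resampling, normalization.

The detector follows the Pan-Tompkins pipeline: band-pass (5-15 Hz),
five-point derivative, squaring, 150 ms moving-window integration, then
adaptive dual thresholds with a 200 ms refractory period and RR-based
search-back.  The band-pass stage is applied zero-phase (forward-backward),
which removes the classic filter group delay so detected integration peaks
can be mapped back to R apexes with a single local-maximum search.

Segmentation cuts a fixed window around each R index (default 140 samples
before and after, the symmetric split of a 280-sample beat at 360 Hz);
beats whose window leaves the record are dropped, not padded.  Resampling
to the working length of 256 uses the band-limited Fourier method.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .core import Beat, BeatSet, RawRecord

__all__ = [
    "detect_r_peaks",
    "segment_beats",
    "resample_beat",
    "resample_beatset",
    "normalize_beats",
]

log = logging.getLogger(__name__)

REFRACTORY_S = 0.2
INTEGRATION_WINDOW_S = 0.15
BANDPASS_HZ = (5.0, 15.0)


def detect_r_peaks(record: RawRecord) -> list[int]:
    """Detect R-peak sample indices with the Pan-Tompkins method.

    Returns strictly increasing indices separated by at least 0.2 s.
    A flat (zero-variance) signal yields an empty list with a warning;
    a signal shorter than 2 s raises.
    """
    x = record.signal
    fs = record.sampling_rate
    min_len = int(2 * fs)
    if x.size < min_len:
        raise ValueError(
            f"signal too short for QRS detection: {x.size} samples, need >= {min_len} (2 s at {fs:g} Hz)"
        )
    if np.ptp(x) == 0:
        log.warning("flat signal: no QRS complexes detectable")
        return []

    nyq = fs / 2.0
    b, a = sps.butter(2, [BANDPASS_HZ[0] / nyq, BANDPASS_HZ[1] / nyq], btype="band")
    filtered = sps.filtfilt(b, a, x)
    deriv = np.convolve(filtered, np.array([1, 2, 0, -2, -1]) * (fs / 8.0), mode="same")
    squared = deriv**2
    win = max(int(round(INTEGRATION_WINDOW_S * fs)), 1)
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return []

    # adaptive dual thresholds (signal / noise running estimates)
    init = mwi[: int(2 * fs)]
    spki = 0.25 * float(init.max())
    npki = 0.5 * float(init.mean())
    qrs: list[int] = []
    rr_history: list[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    i = 0
    while i < cand.size:
        p = cand[i]
        peak = mwi[p]
        if peak > threshold():
            qrs.append(int(p))
            spki = 0.125 * peak + 0.875 * spki
            if len(qrs) >= 2:
                rr_history.append(qrs[-1] - qrs[-2])
                rr_history[:] = rr_history[-8:]
        else:
            # search-back: if the expected RR was overrun, retry the gap at half threshold
            if qrs and rr_history:
                rr_avg = float(np.mean(rr_history))
                if p - qrs[-1] > 1.66 * rr_avg and peak > 0.5 * threshold():
                    qrs.append(int(p))
                    spki = 0.25 * peak + 0.75 * spki
                else:
                    npki = 0.125 * peak + 0.875 * npki
            else:
                npki = 0.125 * peak + 0.875 * npki
        i += 1

    # map integration peaks back to the R apex: local max of the band-passed
    # signal inside the integration window around each detection
    half = win
    r_peaks = []
    for p in qrs:
        lo, hi = max(p - half, 0), min(p + half // 2 + 1, x.size)
        r_peaks.append(int(lo + np.argmax(filtered[lo:hi])))
    r_peaks = sorted(set(r_peaks))

    # enforce the refractory period after apex refinement
    out: list[int] = []
    for p in r_peaks:
        if out and p - out[-1] < refractory:
            if filtered[p] > filtered[out[-1]]:
                out[-1] = p
        else:
            out.append(p)
    return out


def segment_beats(
    record: RawRecord,
    r_peaks: "list[int] | np.ndarray",
    window: tuple[int, int] = (140, 140),
) -> BeatSet:
    """Cut one fixed half-open window ``[p - pre, p + post)`` per R peak.

    Peaks whose window leaves the record are dropped (counted in a log
    message).  Beats inherit the label of the annotation nearest their
    peak (within 50 ms) when the record carries annotations.
    """
    pre, post = window
    if pre < 0 or post < 0 or pre + post <= 0:
        raise ValueError("window sizes must be non-negative and sum to a positive length")
    n = record.signal.size
    if pre + post > n:
        raise ValueError(f"window length {pre + post} exceeds signal length {n}")
    peaks = sorted(int(p) for p in np.asarray(r_peaks, dtype=int))
    ann_idx = np.array([i for i, _ in record.annotations], dtype=int)
    ann_lab = [lab for _, lab in record.annotations]
    tol = int(round(0.05 * record.sampling_rate))
    beats: list[Beat] = []
    dropped = 0
    for p in peaks:
        start, end = p - pre, p + post
        if start < 0 or end > n:
            dropped += 1
            continue
        label = None
        if ann_idx.size:
            k = int(np.argmin(np.abs(ann_idx - p)))
            if abs(int(ann_idx[k]) - p) <= tol:
                label = ann_lab[k]
        beats.append(Beat(record.signal[start:end].copy(), label))
    if dropped:
        log.info("segment_beats: dropped %d edge peak(s) whose window left the record", dropped)
    return BeatSet(beats)


def resample_beat(beat: Beat, target_len: int = 256, method: str = "fourier") -> Beat:
    """Resample one beat to ``target_len`` samples.

    ``method='fourier'`` is the band-limited FFT method; ``'polyphase'``
    uses polyphase filtering instead.  A same-length request returns the
    beat unchanged.
    """
    x = beat.samples
    if x.size < 2 or target_len < 2:
        raise ValueError("resampling needs input and target lengths >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("beat contains non-finite samples")
    if target_len == x.size:
        return Beat(x.copy(), beat.label)
    if method == "fourier":
        y = sps.resample(x, target_len)
    elif method == "polyphase":
        from math import gcd

        g = gcd(target_len, x.size)
        y = sps.resample_poly(x, target_len // g, x.size // g)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return Beat(np.asarray(y, dtype=float), beat.label)


def resample_beatset(beats: BeatSet, target_len: int = 256, method: str = "fourier") -> BeatSet:
    beats.require_nonempty("resample_beatset")
    return BeatSet([resample_beat(b, target_len, method) for b in beats])


def normalize_beats(beats: BeatSet, mode: str = "per_beat_minmax") -> BeatSet:
    """Min-max normalize a beat set into [-1, 1].

    ``per_beat_minmax`` maps each beat's own range onto [-1, 1] (the
    default: matches the generators' terminal tanh and makes beats
    scale-free); ``global_minmax`` applies one affine map computed over
    the whole set, preserving relative amplitudes between beats.
    """
    beats.require_nonempty("normalize_beats")
    data = beats.data
    if mode == "per_beat_minmax":
        lo = data.min(axis=1, keepdims=True)
        hi = data.max(axis=1, keepdims=True)
        flat = np.nonzero((hi - lo).ravel() == 0)[0]
        if flat.size:
            raise ValueError(f"constant beat at index {int(flat[0])} cannot be per-beat normalized")
        out = 2.0 * (data - lo) / (hi - lo) - 1.0
    elif mode == "global_minmax":
        lo, hi = data.min(), data.max()
        if hi - lo == 0:
            raise ValueError("constant beat set cannot be normalized")
        out = 2.0 * (data - lo) / (hi - lo) - 1.0
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return BeatSet(out, list(beats.labels) if beats.labels else None)
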