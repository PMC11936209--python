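"""Synthetic single-lead ECG fixtures.

Beats are modelled as a sum of five Gaussian waves (P, Q, R, S, T) on a
fixed-length grid — the landmark structure of a normal cardiac cycle
without the full dynamical-system morphology models.  Each draw jitters
the wave amplitudes and centers, adds white noise, and min-max normalizes
to [-1, 1] (the range every generator's terminal tanh produces).  The
same wave model, laid out at jittered RR intervals with baseline wander,
yields continuous records with known R-peak ground truth for testing QRS
detection and segmentation.

Everything here is a pure function of ``(params, n, seed)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import Beat, BeatSet, RawRecord
from .seeding import substream_seed

__all__ = [
    "MorphologyParams",
    "PRESETS",
    "get_preset",
    "synth_beat",
    "synth_beatset",
    "synth_record",
    "synth_two_class",
]

WAVES = ("P", "Q", "R", "S", "T")


@dataclass
class MorphologyParams:
    """Gaussian-wave-sum beat morphology.

    Amplitudes are in normalized units, centers and widths are fractions
    of the beat length.  ``amp_jitter_rel`` is the per-draw multiplicative
    amplitude jitter (s.d. as a fraction of each wave's nominal amplitude);
    ``center_jitter_sd`` is the additive center jitter (s.d. as a fraction
    of the beat length); ``noise_sd`` is additive white Gaussian noise in
    normalized units, applied before normalization.
    """

    amplitudes: dict[str, float]
    centers: dict[str, float]
    widths: dict[str, float]
    amp_jitter_rel: float = 0.05
    center_jitter_sd: float = 0.008
    noise_sd: float = 0.02
    beat_len: int = 256
    label: str = "N"

    def __post_init__(self) -> None:
        for name in WAVES:
            if name not in self.amplitudes or name not in self.centers or name not in self.widths:
                raise ValueError(f"missing wave {name!r} in morphology parameters")
        mus = [self.centers[w] for w in WAVES]
        if not all(0 < a < b < 1 or a < b for a, b in zip(mus, mus[1:])) or mus[0] <= 0 or mus[-1] >= 1:
            raise ValueError("wave centers must satisfy 0 < mu_P < mu_Q < mu_R < mu_S < mu_T < 1")
        if any(self.widths[w] <= 0 for w in WAVES):
            raise ValueError("wave widths must be positive")
        r = self.amplitudes["R"]
        if not (r > 0 and abs(r) >= max(abs(a) for a in self.amplitudes.values())):
            raise ValueError("R must be the dominant positive wave")
        if self.noise_sd < 0 or self.amp_jitter_rel < 0 or self.center_jitter_sd < 0:
            raise ValueError("jitter/noise levels must be non-negative")
        if self.beat_len < 2:
            raise ValueError("beat_len must be >= 2")

    def replace(self, **kw) -> "MorphologyParams":
        d = asdict(self)
        d.update(kw)
        return MorphologyParams(**d)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MorphologyParams":
        return cls(**json.loads(text))


def _normal_v1() -> MorphologyParams:
    return MorphologyParams(
        amplitudes={"P": 0.15, "Q": -0.12, "R": 1.0, "S": -0.22, "T": 0.30},
        centers={"P": 0.18, "Q": 0.42, "R": 0.50, "S": 0.58, "T": 0.78},
        widths={"P": 0.035, "Q": 0.012, "R": 0.016, "S": 0.012, "T": 0.055},
        label="N",
    )


def _lbbb_v1() -> MorphologyParams:
    # wide-QRS second class with the lead-I left-bundle-branch-block
    # signature: broadened R, deepened and widened S, discordant
    # (inverted) T — well separated from normal_v1 under DTW
    p = _normal_v1()
    amps = dict(p.amplitudes)
    widths = dict(p.widths)
    widths["R"] = p.widths["R"] * 3.0
    widths["S"] = 0.03
    amps["S"] = -0.5
    amps["T"] = -0.3
    return p.replace(amplitudes=amps, widths=widths, label="L")


PRESETS = {"normal_v1": _normal_v1, "lbbb_v1": _lbbb_v1}


def get_preset(name: str) -> MorphologyParams:
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def _wave_sum(length: int, amps: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    j = np.arange(length) / length
    out = np.zeros(length)
    for a, mu, sig in zip(amps, centers, widths):
        out += a * np.exp(-((j - mu) ** 2) / (2.0 * sig**2))
    return out


def _draw_beat(params: MorphologyParams, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    amps = np.array([params.amplitudes[w] for w in WAVES])
    centers = np.array([params.centers[w] for w in WAVES])
    widths = np.array([params.widths[w] for w in WAVES])
    amps = amps * (1.0 + params.amp_jitter_rel * rng.standard_normal(len(WAVES)))
    centers = centers + params.center_jitter_sd * rng.standard_normal(len(WAVES))
    clean = _wave_sum(params.beat_len, amps, centers, widths)
    noisy = clean + params.noise_sd * rng.standard_normal(params.beat_len)
    return noisy, float(centers[WAVES.index("R")])


def synth_beat(params: MorphologyParams, rng_seed: int) -> Beat:
    """Draw one beat, min-max normalized to [-1, 1].

    A degenerate all-zero-amplitude draw cannot be normalized; it is
    returned flat with a warning instead.
    """
    rng = np.random.default_rng(int(rng_seed))
    samples, _ = _draw_beat(params, rng)
    lo, hi = samples.min(), samples.max()
    if hi - lo <= 0:
        warnings.warn("degenerate constant beat; returned un-normalized", stacklevel=2)
        return Beat(samples, label=params.label)
    samples = 2.0 * (samples - lo) / (hi - lo) - 1.0
    return Beat(samples, label=params.label)


def synth_beatset(params: MorphologyParams, n: int, seed: int) -> BeatSet:
    """Draw ``n`` independent beats from one seeded stream.

    Per-beat seeds are derived from the master seed by a counter-based
    scheme, so beat ``i`` is reproducible regardless of draw order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    beats = [synth_beat(params, substream_seed(seed, "synth_beat", i)) for i in range(n)]
    return BeatSet(beats)


def synth_record(
    params: MorphologyParams,
    n_beats: int,
    fs: float,
    rr_mean_s: float,
    rr_jitter_sd_s: float = 0.0,
    seed: int = 0,
    noise_sd: float | None = None,
    baseline_amp: float = 0.05,
    baseline_freq_hz: float = 0.33,
) -> RawRecord:
    """Continuous multi-beat record with ground-truth R positions.

    Beats are rendered over a 280-sample-at-360-Hz-equivalent window
    (~0.78 s, the classic segmentation window) at jittered RR intervals;
    a low-frequency sinusoidal baseline wander and white noise are added.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    beat_dur_s = 280.0 / 360.0
    support_s = beat_dur_s * (
        (params.centers["T"] + 3 * params.widths["T"]) - (params.centers["P"] - 3 * params.widths["P"])
    )
    if rr_mean_s - 3.0 * rr_jitter_sd_s < support_s:
        raise ValueError(
            f"RR interval {rr_mean_s:.3f}s (minus 3 sd jitter) is shorter than the "
            f"beat support {support_s:.3f}s; beats would overlap"
        )
    rng = np.random.default_rng(substream_seed(seed, "synth_record"))
    win = int(round(beat_dur_s * fs))
    rr = rr_mean_s + rr_jitter_sd_s * rng.standard_normal(n_beats)
    r_times = np.cumsum(np.concatenate([[rr_mean_s], rr[:-1]]))
    total = int(np.ceil(r_times[-1] * fs + win))
    signal = np.zeros(total)
    peaks = []
    for t_r in r_times:
        amps = np.array([params.amplitudes[w] for w in WAVES])
        centers = np.array([params.centers[w] for w in WAVES])
        widths = np.array([params.widths[w] for w in WAVES])
        amps = amps * (1.0 + params.amp_jitter_rel * rng.standard_normal(len(WAVES)))
        shape = _wave_sum(win, amps, centers, widths)
        # place the window so its mu_R fraction lands on the true R sample
        r_idx = int(round(t_r * fs))
        start = r_idx - int(round(params.centers["R"] * win))
        lo, hi = max(start, 0), min(start + win, total)
        signal[lo:hi] += shape[lo - start : hi - start]
        peaks.append(int(np.argmax(signal[max(r_idx - 3, 0) : r_idx + 4]) + max(r_idx - 3, 0)))
    t = np.arange(total) / fs
    sd = params.noise_sd if noise_sd is None else noise_sd
    signal = signal + baseline_amp * np.sin(2 * np.pi * baseline_freq_hz * t)
    signal = signal + sd * rng.standard_normal(total)
    peaks_arr = np.asarray(peaks, dtype=int)
    return RawRecord(
        signal=signal,
        sampling_rate=fs,
        true_r_peaks=peaks_arr,
        annotations=[(int(p), params.label) for p in peaks_arr],
    )


def synth_two_class(
    params_a: MorphologyParams,
    params_b: MorphologyParams,
    n_a: int,
    n_b: int,
    seed: int,
) -> BeatSet:
    """Labeled two-class set (class tags from each params' ``label``),
    shuffled deterministically by ``seed``."""
    if n_a < 0 or n_b < 0:
        raise ValueError("class counts must be non-negative")
    if n_a + n_b == 0:
        raise ValueError("at least one class count must be positive")
    parts = []
    labels = []
    if n_a:
        sa = synth_beatset(params_a, n_a, substream_seed(seed, "class_a"))
        parts.append(sa.data)
        labels += [params_a.label] * n_a
    if n_b:
        sb = synth_beatset(params_b, n_b, substream_seed(seed, "class_b"))
        parts.append(sb.data)
        labels += [params_b.label] * n_b
    data = np.concatenate(parts, axis=0)
    order = np.random.default_rng(substream_seed(seed, "shuffle")).permutation(len(labels))
    return BeatSet(data[order], [labels[i] for i in order])
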