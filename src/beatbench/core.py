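"""Core containers for segmented cardiac cycles.

A *beat* is one segmented cardiac cycle stored as a fixed-length amplitude
vector (dimensionless after normalization).  A *beat set* is an ordered
collection of equal-length beats — it holds both the real set ``V`` and any
generated set ``G``.  A *raw record* is a continuous single-lead voltage
trace with a known sampling rate, optionally carrying ground-truth R-peak
positions (synthetic fixtures) and beat annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Beat", "BeatSet", "RawRecord"]


@dataclass
class Beat:
    """One segmented cardiac cycle.

    Parameters
    ----------
    samples
        Amplitude vector of length ``L`` (float, finite).
    label
        Optional class tag, e.g. ``"N"`` (normal sinus) or ``"L"``
        (left-bundle-branch-block-like morphology).
    """

    samples: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("a beat must be a non-empty 1-D sample vector")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("beat contains non-finite samples")

    def __len__(self) -> int:
        return int(self.samples.size)


class BeatSet:
    """Ordered collection of equal-length beats.

    Internally a 2-D float array of shape ``(count, beat_len)`` plus an
    optional per-beat label list; this is the container every other module
    operates on.
    """

    def __init__(self, beats: "list[Beat] | np.ndarray", labels: list[str] | None = None):
        if isinstance(beats, np.ndarray):
            data = np.asarray(beats, dtype=float)
            if data.ndim != 2:
                raise ValueError("array form must be 2-D (count, beat_len)")
            self.data = data
            self.labels = list(labels) if labels is not None else None
        else:
            if len(beats) == 0:
                self.data = np.empty((0, 0))
                self.labels = None
            else:
                lengths = {len(b) for b in beats}
                if len(lengths) != 1:
                    raise ValueError(f"beats have mixed lengths {sorted(lengths)}")
                self.data = np.stack([b.samples for b in beats])
                got = [b.label for b in beats]
                if labels is not None:
                    self.labels = list(labels)
                elif any(l is not None for l in got):
                    self.labels = [l if l is not None else "" for l in got]
                else:
                    self.labels = None
        if self.labels is not None and len(self.labels) != len(self.data):
            raise ValueError("labels length does not match beat count")

    # -- basic protocol ----------------------------------------------------
    @property
    def count(self) -> int:
        return int(self.data.shape[0])

    @property
    def beat_len(self) -> int:
        return int(self.data.shape[1]) if self.count else 0

    def __len__(self) -> int:
        return self.count

    def __getitem__(self, i: int) -> Beat:
        return Beat(self.data[i].copy(), self.labels[i] if self.labels else None)

    def __iter__(self):
        for i in range(self.count):
            yield self[i]

    def subset(self, idx) -> "BeatSet":
        idx = np.asarray(idx, dtype=int)
        labels = [self.labels[i] for i in idx] if self.labels else None
        return BeatSet(self.data[idx].copy(), labels)

    def require_nonempty(self, op: str) -> None:
        if self.count == 0:
            raise ValueError(f"{op} requires a non-empty beat set")

    def __repr__(self) -> str:  # pragma: no cover
        return f"BeatSet(count={self.count}, beat_len={self.beat_len})"


@dataclass
class RawRecord:
    """Continuous single-lead record.

    ``signal`` is in millivolt (or normalized) units at ``sampling_rate`` Hz.
    ``true_r_peaks`` carries ground-truth R indices for synthetic fixtures;
    ``annotations`` is a list of ``(sample_index, beat_label)`` pairs.
    """

    signal: np.ndarray
    sampling_rate: float
    true_r_peaks: np.ndarray | None = None
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1:
            raise ValueError("signal must be 1-D")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.true_r_peaks is not None:
            self.true_r_peaks = np.asarray(self.true_r_peaks, dtype=int)
        for idx, _ in self.annotations:
            if not 0 <= idx < self.signal.size:
                raise ValueError(f"annotation index {idx} outside signal")

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.sampling_rate
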