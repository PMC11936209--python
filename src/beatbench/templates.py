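"""Class templates: the statistically-averaged beat and selected exemplars.

A template is one distinguished beat that stands for a whole class.  The
statistically-averaged beat (SAB) is the per-time-step mean over the set;
because beats are not time-registered before averaging, the SAB can look
smeared, but it is the best statistical summary of the class and is used
as-is.  The expert-eye choice of a "most fit" exemplar is operationalized
deterministically as the DTW-medoid of a seeded subsample; a seeded random
draw and an explicit index are also available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import Beat, BeatSet
from .distances import pairwise_distances
from .seeding import substream_seed

__all__ = ["Template", "sab_template", "select_template"]

MEDOID_SUBSAMPLE = 100


@dataclass
class Template:
    beat: Beat
    provenance: str  # "SAB" | "random" | "medoid" | "explicit_index"
    source_size: int
    source_index: int | None = None

    @property
    def samples(self) -> np.ndarray:
        return self.beat.samples

    def save(self, path: "str | Path") -> None:
        """Write the template beat as CSV plus a provenance sidecar JSON."""
        path = Path(path)
        np.savetxt(path, self.beat.samples[None, :], delimiter=",", fmt="%.9g")
        meta = {
            "provenance": self.provenance,
            "source_size": self.source_size,
            "source_index": self.source_index,
            "label": self.beat.label,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: "str | Path") -> "Template":
        path = Path(path)
        samples = np.atleast_2d(np.loadtxt(path, delimiter=","))[0]
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            Beat(samples, meta.get("label")),
            meta["provenance"],
            int(meta["source_size"]),
            meta.get("source_index"),
        )


def sab_template(beats: BeatSet) -> Template:
    """Statistically-averaged beat: component j is the mean of component j
    over all beats in the set."""
    beats.require_nonempty("sab_template")
    mean = beats.data.mean(axis=0)
    label = beats.labels[0] if beats.labels and len(set(beats.labels)) == 1 else None
    return Template(Beat(mean, label), "SAB", beats.count)


def select_template(
    beats: BeatSet,
    mode: str = "medoid",
    seed_or_index: int = 0,
    df: str = "dtw",
) -> Template:
    """Pick one exemplar beat as the class template.

    ``random`` draws uniformly with the given seed; ``medoid`` returns the
    beat minimizing the summed ``df`` distance to a seeded subsample of up
    to 100 beats (ties broken by lowest index) — the deterministic proxy
    for expert visual selection; ``explicit_index`` returns that beat.
    """
    beats.require_nonempty("select_template")
    if mode == "explicit_index":
        idx = int(seed_or_index)
        if not 0 <= idx < beats.count:
            raise IndexError(f"template index {idx} out of range for set of {beats.count}")
    elif mode == "random":
        rng = np.random.default_rng(substream_seed(seed_or_index, "template_random"))
        idx = int(rng.integers(beats.count))
    elif mode == "medoid":
        rng = np.random.default_rng(substream_seed(seed_or_index, "template_medoid"))
        k = min(MEDOID_SUBSAMPLE, beats.count)
        ref = np.sort(rng.choice(beats.count, size=k, replace=False))
        dist = pairwise_distances(beats.data, beats.data[ref], metric=df)
        sums = dist.sum(axis=1)
        idx = int(np.argmin(sums))  # argmin returns the lowest index on ties
    else:
        raise ValueError(f"unknown template mode {mode!r}")
    return Template(beats[idx], mode if mode != "explicit_index" else "explicit_index", beats.count, idx)
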