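"""Template-based evaluation of generated beat sets.

Four scores per distance function ``DF``:

* ``s1`` (cross-set mean) — the mean of ``DF(v, g)`` over all pairs
  between (sub)samples of the real and generated sets; with full portions
  it is the deterministic double mean.
* ``s2`` (mean distance to template) — mean ``DF(g, t)`` over generated
  beats.
* ``s3`` (best beat) — the minimum ``DF(g, t)`` and the index attaining
  it (ties broken by lowest index).
* ``eta`` (threshold) — either the arithmetic mean ``(s2 + s3) / 2`` or a
  factor ``a * s3``; a generated beat is *acceptable* when its distance
  to the template is <= eta.
* ``s4`` (productivity rate) — the percentage of acceptable beats.

``compare_models`` assembles the per-model-per-distance score table and
flags the best model per column (minimum for s1-s3, maximum for s4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BeatSet
from .distances import METRICS, get_metric, pairwise_distances
from .seeding import rng_for
from .templates import Template

__all__ = [
    "EvalConfig",
    "ModelScores",
    "method1_score",
    "method2_score",
    "method3_best",
    "compute_threshold",
    "method4_productivity",
    "score_model",
    "compare_models",
]


@dataclass
class EvalConfig:
    portion_real: int = 300
    portion_generated: int = 300
    seed: int = 0
    threshold_mode: str = "mean_of_min_and_avg"  # or "factor"
    factor_a: float = 2.0
    distances: tuple[str, ...] = ("dtw", "frechet", "euclidean")

    def __post_init__(self) -> None:
        if self.portion_real < 1 or self.portion_generated < 1:
            raise ValueError("portion sizes must be >= 1")
        if self.threshold_mode not in ("mean_of_min_and_avg", "factor"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")
        if self.factor_a <= 0:
            raise ValueError("factor a must be positive")
        unknown = set(self.distances) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown distance ids {sorted(unknown)}")


@dataclass
class ModelScores:
    """s1-s4 plus threshold and accepted count, per distance function."""

    model_id: str
    per_distance: dict[str, dict[str, float]] = field(default_factory=dict)

    def table_row(self) -> dict[str, float]:
        row: dict[str, float] = {"model": self.model_id}
        for df, sc in self.per_distance.items():
            for key in ("s1", "s2", "s3", "eta", "s4"):
                row[f"{key}_{df}"] = sc[key]
        return row


def _subsample(n_total: int, n_take: int, rng: np.random.Generator) -> np.ndarray:
    if n_take > n_total:
        raise ValueError(f"portion {n_take} exceeds set size {n_total}")
    if n_take == n_total:
        return np.arange(n_total)
    return np.sort(rng.choice(n_total, size=n_take, replace=False))


def method1_score(
    real: BeatSet, generated: BeatSet, df: str = "dtw", config: EvalConfig | None = None
) -> float:
    """Cross-set mean distance over seeded uniform subsamples (Method 1)."""
    cfg = config or EvalConfig(portion_real=real.count, portion_generated=generated.count)
    real.require_nonempty("method1_score")
    generated.require_nonempty("method1_score")
    rng = rng_for(cfg.seed, "method1_portions")
    iv = _subsample(real.count, cfg.portion_real, rng)
    ig = _subsample(generated.count, cfg.portion_generated, rng)
    mat = pairwise_distances(real.data[iv], generated.data[ig], df)
    return float(mat.mean())


def method2_score(generated: BeatSet, t: Template, df: str = "dtw") -> float:
    """Mean distance from each generated beat to the template (Method 2)."""
    generated.require_nonempty("method2_score")
    dist = pairwise_distances(generated.data, t.samples[None, :], df)
    return float(dist.mean())


def method3_best(generated: BeatSet, t: Template, df: str = "dtw") -> tuple[int, float]:
    """Best generated beat: lowest distance to the template (Method 3)."""
    generated.require_nonempty("method3_best")
    dist = pairwise_distances(generated.data, t.samples[None, :], df).ravel()
    idx = int(np.argmin(dist))  # argmin -> lowest index on ties
    return idx, float(dist[idx])


def compute_threshold(
    s2: float, s3: float, mode: str = "mean_of_min_and_avg", a: float = 2.0
) -> float:
    """Acceptance threshold: mean of best and average distance, or a * s3."""
    if mode == "mean_of_min_and_avg":
        if s3 < 0 or s2 < s3:
            raise ValueError(f"need s2 >= s3 >= 0, got s2={s2}, s3={s3}")
        return (s2 + s3) / 2.0
    if mode == "factor":
        if a <= 0:
            raise ValueError("factor a must be positive")
        return a * s3
    raise ValueError(f"unknown threshold mode {mode!r}")


def method4_productivity(
    generated: BeatSet, t: Template, df: str = "dtw", eta: float = 0.0
) -> tuple[np.ndarray, float]:
    """Acceptable beats (distance <= eta, inclusive) and the productivity
    rate in percent (Method 4)."""
    generated.require_nonempty("method4_productivity")
    if eta < 0:
        raise ValueError("threshold must be non-negative")
    dist = pairwise_distances(generated.data, t.samples[None, :], df).ravel()
    accepted = np.nonzero(dist <= eta)[0]
    return accepted, 100.0 * accepted.size / generated.count


def score_model(
    real: BeatSet,
    generated: BeatSet,
    t: Template,
    config: EvalConfig,
    model_id: str = "model",
) -> ModelScores:
    """All four scores for one generated set, per distance function."""
    scores = ModelScores(model_id)
    for df in config.distances:
        cfg = EvalConfig(
            portion_real=min(config.portion_real, real.count),
            portion_generated=min(config.portion_generated, generated.count),
            seed=config.seed,
            threshold_mode=config.threshold_mode,
            factor_a=config.factor_a,
            distances=config.distances,
        )
        s1 = method1_score(real, generated, df, cfg)
        s2 = method2_score(generated, t, df)
        best_idx, s3 = method3_best(generated, t, df)
        eta = compute_threshold(s2, s3, config.threshold_mode, config.factor_a)
        accepted, s4 = method4_productivity(generated, t, df, eta)
        scores.per_distance[df] = {
            "s1": s1,
            "s2": s2,
            "s3": s3,
            "best_index": float(best_idx),
            "eta": eta,
            "accepted_count": float(accepted.size),
            "s4": s4,
        }
    return scores


def export_gallery(
    model_runs: dict[str, BeatSet],
    out_dir,
    n_per_model: int = 25,
    seed: int = 0,
    plot: bool = True,
) -> list:
    """Export per-model beat galleries for expert visual review.

    Subjective inspection has no computed score; this writes a seeded
    subsample of each model's beats as CSV (and, when matplotlib is
    available and ``plot`` is set, a grid figure) so a human can judge
    morphology.  Returns the paths written.
    """
    from pathlib import Path

    from .io import save_beats_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for model_id, beats in model_runs.items():
        beats.require_nonempty("export_gallery")
        rng = rng_for(seed, f"gallery_{model_id}")
        k = min(n_per_model, beats.count)
        idx = np.sort(rng.choice(beats.count, size=k, replace=False))
        sub = beats.subset(idx)
        csv_path = out / f"gallery_{model_id}.csv"
        save_beats_csv(sub, csv_path)
        written.append(csv_path)
        if plot:
            try:
                import matplotlib

                matplotlib.use("Agg")
                import matplotlib.pyplot as plt
            except ImportError:
                continue
            cols = 5
            rows = int(np.ceil(k / cols))
            fig, axes = plt.subplots(rows, cols, figsize=(2.2 * cols, 1.6 * rows), squeeze=False)
            for ax, i in zip(axes.ravel(), range(k)):
                ax.plot(sub.data[i], lw=0.8)
                ax.set_xticks([])
                ax.set_yticks([])
                ax.set_title(str(idx[i]), fontsize=6)
            for ax in axes.ravel()[k:]:
                ax.axis("off")
            fig.suptitle(model_id)
            png_path = out / f"gallery_{model_id}.png"
            fig.savefig(png_path, dpi=100)
            plt.close(fig)
            written.append(png_path)
    return written


def compare_models(
    model_runs: dict[str, BeatSet],
    real: BeatSet,
    t: Template,
    config: EvalConfig,
) -> pd.DataFrame:
    """Score table across models with per-column best flags.

    Columns are ``<score>_<distance>``; the companion ``best_<score>_<distance>``
    booleans mark the winning model (min for s1-s3, max for s4).
    """
    if not model_runs:
        raise ValueError("compare_models needs at least one model run")
    lengths = {g.beat_len for g in model_runs.values()} | {real.beat_len}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent beat lengths across runs: {sorted(lengths)}")
    rows = [
        score_model(real, g, t, config, model_id).table_row()
        for model_id, g in model_runs.items()
    ]
    table = pd.DataFrame(rows).set_index("model")
    for df in config.distances:
        for key in ("s1", "s2", "s3"):
            col = f"{key}_{df}"
            table[f"best_{col}"] = table[col] == table[col].min()
        col = f"s4_{df}"
        table[f"best_{col}"] = table[col] == table[col].max()
    table.attrs["template_provenance"] = t.provenance
    table.attrs["seed"] = config.seed
    return table
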