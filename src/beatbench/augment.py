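"""Augmentation-efficacy experiment.

A 1-D residual convolutional classifier is trained from scratch on three
training sets built from the same two-class beat pools — (i) balanced
real, (ii) imbalanced (minority class subsampled), (iii) the imbalanced
set re-balanced by adding synthetic minority beats — and evaluated on one
shared held-out test set.  The point of comparison is the minority-class
recall: it collapses under (ii) and is restored under (iii).

The classifier stacks residual blocks of two kernel-3 convolutions with
an identity shortcut (``F(x) + x``).  The full 34-layer configuration is
available; the default preset is scaled down (10 conv layers, narrow
channels) so the experiment runs in seconds on a CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from . import nn
from .core import BeatSet
from .seeding import rng_for, substream_seed

__all__ = [
    "ClassifierConfig",
    "ClassificationReport",
    "ScenarioSizes",
    "ResNet1D",
    "make_experiment_datasets",
    "train_and_evaluate",
    "efficacy_report",
]


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

@dataclass
class ClassifierConfig:
    preset: str = "scaled"  # "scaled" (10 conv layers) or "resnet34"
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    n_classes: int = 2

    @property
    def blocks(self) -> tuple[int, ...]:
        return (2, 2) if self.preset == "scaled" else (3, 4, 6, 3)

    @property
    def channels(self) -> tuple[int, ...]:
        return (8, 16) if self.preset == "scaled" else (64, 128, 256, 512)


class _ResidualBlock(nn.Module):
    """Two kernel-3 convolutions with an identity shortcut: out = relu(F(x) + x)."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        self.conv1 = nn.Conv1d(in_ch, out_ch, 3, rng, stride=stride, pad=1)
        self.bn1 = nn.BatchNorm1d(out_ch, rng)
        self.conv2 = nn.Conv1d(out_ch, out_ch, 3, rng, stride=1, pad=1)
        self.bn2 = nn.BatchNorm1d(out_ch, rng)
        self.shortcut: nn.Module | None = None
        self.shortcut_bn: nn.Module | None = None
        if stride != 1 or in_ch != out_ch:
            self.shortcut = nn.Conv1d(in_ch, out_ch, 1, rng, stride=stride, pad=0)
            self.shortcut_bn = nn.BatchNorm1d(out_ch, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        identity = x if self.shortcut is None else self.shortcut_bn(self.shortcut(x))
        return (out + identity).relu()


class ResNet1D(nn.Module):
    def __init__(self, config: ClassifierConfig, seed: int):
        rng = rng_for(seed, "classifier_init")
        ch = config.channels
        self.stem = nn.Conv1d(1, ch[0], 7, rng, stride=2, pad=3)
        self.stem_bn = nn.BatchNorm1d(ch[0], rng)
        self.blocks: list[nn.Module] = []
        in_ch = ch[0]
        for stage, (n_blocks, out_ch) in enumerate(zip(config.blocks, ch)):
            for b in range(n_blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                self.blocks.append(_ResidualBlock(in_ch, out_ch, stride, rng))
                in_ch = out_ch
        self.pool = nn.GlobalAvgPool1d()
        self.head = nn.Linear(in_ch, config.n_classes, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        out = self.stem_bn(self.stem(x)).relu()
        for block in self.blocks:
            out = block(out)
        return self.head(self.pool(out))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    classes: list[str]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    accuracy: float
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    confusion: list[list[int]]  # rows = true class, order = self.classes
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_predictions(cls, y_true: list[str], y_pred: list[str]) -> "ClassificationReport":
        classes = sorted(set(y_true))
        prec, rec, f1, sup = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, zero_division=0
        )
        mp, mr, mf, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, average="macro", zero_division=0
        )
        wp, wr, wf, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, average="weighted", zero_division=0
        )
        cm = confusion_matrix(y_true, y_pred, labels=classes)
        return cls(
            classes=classes,
            precision={c: float(p) for c, p in zip(classes, prec)},
            recall={c: float(r) for c, r in zip(classes, rec)},
            f1={c: float(v) for c, v in zip(classes, f1)},
            support={c: int(s) for c, s in zip(classes, sup)},
            accuracy=float(np.mean(np.asarray(y_true) == np.asarray(y_pred))),
            macro_avg={"precision": float(mp), "recall": float(mr), "f1": float(mf)},
            weighted_avg={"precision": float(wp), "recall": float(wr), "f1": float(wf)},
            confusion=cm.tolist(),
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ClassificationReport":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# experiment datasets
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSizes:
    """Per-scenario (minority, majority) training counts plus the shared
    test split.  Defaults mirror the two-class benchmark sizes."""

    balanced: tuple[int, int] = (6457, 6455)
    imbalanced: tuple[int, int] = (500, 6460)
    augmented: tuple[int, int] = (6454, 6458)
    test: tuple[int, int] = (1609, 1607)

    @classmethod
    def scaled(cls) -> "ScenarioSizes":
        return cls(balanced=(500, 500), imbalanced=(50, 500), augmented=(500, 500), test=(150, 150))


def _single_class(pool: BeatSet, what: str) -> str:
    if pool.labels is None or len(set(pool.labels)) != 1:
        raise ValueError(f"{what} must be a single-class labeled pool")
    return pool.labels[0]


def make_experiment_datasets(
    pool_minority: BeatSet,
    pool_majority: BeatSet,
    synth_minority: BeatSet,
    sizes: ScenarioSizes,
    seed: int,
) -> dict[str, BeatSet]:
    """Build the three training scenarios and the shared test set.

    The test split is drawn first and is disjoint from every training
    set; the augmented scenario reuses the imbalanced scenario's real
    beats and tops the minority class up with synthetic beats.
    """
    lab_min = _single_class(pool_minority, "minority pool")
    lab_maj = _single_class(pool_majority, "majority pool")
    if lab_min == lab_maj:
        raise ValueError("pools must carry two distinct class labels")

    need_min = max(sizes.balanced[0], sizes.imbalanced[0]) + sizes.test[0]
    need_maj = max(sizes.balanced[1], sizes.imbalanced[1], sizes.augmented[1]) + sizes.test[1]
    if pool_minority.count < need_min:
        raise ValueError(f"minority pool too small: {pool_minority.count} < {need_min} needed")
    if pool_majority.count < need_maj:
        raise ValueError(f"majority pool too small: {pool_majority.count} < {need_maj} needed")
    n_synth = sizes.augmented[0] - sizes.imbalanced[0]
    if n_synth < 0:
        raise ValueError("augmented minority size must be >= the imbalanced minority size")
    if synth_minority.count < n_synth:
        raise ValueError(f"synthetic pool too small: {synth_minority.count} < {n_synth} needed")

    rng = rng_for(seed, "experiment_split")
    perm_min = rng.permutation(pool_minority.count)
    perm_maj = rng.permutation(pool_majority.count)
    test_min, rest_min = perm_min[: sizes.test[0]], perm_min[sizes.test[0] :]
    test_maj, rest_maj = perm_maj[: sizes.test[1]], perm_maj[sizes.test[1] :]

    def stack(min_data: np.ndarray, maj_data: np.ndarray, shuffle_tag: str) -> BeatSet:
        data = np.concatenate([min_data, maj_data], axis=0)
        labels = [lab_min] * len(min_data) + [lab_maj] * len(maj_data)
        order = rng_for(seed, shuffle_tag).permutation(len(labels))
        return BeatSet(data[order], [labels[i] for i in order])

    test = stack(pool_minority.data[test_min], pool_majority.data[test_maj], "test_shuffle")
    balanced = stack(
        pool_minority.data[rest_min[: sizes.balanced[0]]],
        pool_majority.data[rest_maj[: sizes.balanced[1]]],
        "balanced_shuffle",
    )
    imb_min = pool_minority.data[rest_min[: sizes.imbalanced[0]]]
    imb_maj = pool_majority.data[rest_maj[: sizes.imbalanced[1]]]
    imbalanced = stack(imb_min, imb_maj, "imbalanced_shuffle")
    aug_min = np.concatenate([imb_min, synth_minority.data[:n_synth]], axis=0)
    augmented = stack(aug_min, pool_majority.data[rest_maj[: sizes.augmented[1]]], "augmented_shuffle")
    return {"balanced": balanced, "imbalanced": imbalanced, "augmented": augmented, "test": test}


# ---------------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------------

def _predict(model: ResNet1D, data: np.ndarray, batch: int = 256) -> np.ndarray:
    model.eval()
    preds = []
    for i in range(0, len(data), batch):
        x = nn.Tensor(data[i : i + batch][:, None, :])
        preds.append(np.argmax(model(x).data, axis=1))
    return np.concatenate(preds)


def train_and_evaluate(
    train: BeatSet,
    test: BeatSet,
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> ClassificationReport:
    """Train the residual classifier on ``train`` and report on ``test``."""
    cfg = config or ClassifierConfig()
    if train.labels is None or test.labels is None:
        raise ValueError("both sets must be labeled")
    classes = sorted(set(test.labels))
    if len(classes) < 2:
        raise ValueError("test set must contain both classes")
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y_train = np.array([class_to_idx.get(l, -1) for l in train.labels])
    if np.any(y_train < 0):
        raise ValueError("training set contains labels absent from the test set")

    model = ResNet1D(ClassifierConfig(**{**asdict(cfg), "n_classes": len(classes)}), seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate, beta1=0.9, beta2=0.999)
    shuffle_rng = rng_for(seed, "classifier_shuffle")
    model.train()
    for _ in range(cfg.epochs):
        order = shuffle_rng.permutation(train.count)
        for i in range(0, train.count - cfg.batch_size + 1, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            x = nn.Tensor(train.data[idx][:, None, :])
            loss = nn.cross_entropy_logits(model(x), y_train[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            if not np.isfinite(loss.item()):
                raise RuntimeError("non-finite classifier loss; training aborted")
    pred_idx = _predict(model, test.data)
    y_pred = [classes[i] for i in pred_idx]
    report = ClassificationReport.from_predictions(list(test.labels), y_pred)
    report.extra = {"seed": seed, "preset": cfg.preset, "epochs": cfg.epochs}
    return report


def efficacy_report(
    reports: dict[str, ClassificationReport], minority_label: str
) -> dict:
    """Side-by-side comparison of the three scenarios.

    Flags whether the minority-class recall ordering
    ``imbalanced < augmented`` holds — the signature of successful
    synthetic augmentation.
    """
    required = {"balanced", "imbalanced", "augmented"}
    missing = required - set(reports)
    if missing:
        raise ValueError(f"missing scenario report(s): {sorted(missing)}")
    rows = {}
    for name in ("balanced", "imbalanced", "augmented"):
        r = reports[name]
        rows[name] = {
            "accuracy": r.accuracy,
            "precision": dict(r.precision),
            "recall": dict(r.recall),
            "f1": dict(r.f1),
            "confusion": [list(row) for row in r.confusion],
        }
    rec_imb = reports["imbalanced"].recall[minority_label]
    rec_aug = reports["augmented"].recall[minority_label]
    return {
        "minority_label": minority_label,
        "scenarios": rows,
        "minority_recall_imbalanced": rec_imb,
        "minority_recall_augmented": rec_aug,
        "augmentation_restores_recall": bool(rec_aug > rec_imb),
    }
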