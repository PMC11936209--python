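"""Seeded adversarial training with per-epoch sampling and convergence tracking.

One call to :func:`train` runs the full alternating-update loop for any of
the five model kinds and returns a :class:`TrainingTrace` holding, per
epoch: the mean generator and discriminator losses, ``samples_per_epoch``
freshly generated beats, and their mean DTW / Fréchet / Euclidean distance
to a reference template.  With the defaults (30 epochs, 10 samples per
epoch) the trace's pooled samples form the 300-beat generated portion used
by the cross-set evaluation method.

Update rules per kind:

* classic / dcdc / bilstm_dc — discriminator minimizes binary cross-entropy
  with real beats labelled 1 and generated beats 0; the generator
  minimizes BCE of its samples against label 1 (non-saturating form).
* wgan — critic minimizes ``mean(D(fake)) - mean(D(real))`` with weights
  clipped to ±clip_value after every step; the generator minimizes
  ``-mean(D(fake))`` once every ``critic_steps`` critic updates.
* vaegan — encoder/decoder minimize ``lambda_rec * L1(decoded, real) +
  lambda_kl * KL(q(z|x) || N(0,1)) + lambda_adv * BCE(D(z_enc), 1)`` with
  the reparameterized code ``z = mu + eps * exp(logvar / 2)``; the
  discriminator distinguishes prior draws (label 1) from encoded codes
  (label 0) on the bottleneck.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .core import BeatSet
from .distances import pairwise_distances
from .models import GanModel
from .seeding import rng_for, substream_seed
from .templates import Template

__all__ = ["TrainConfig", "EpochRecord", "TrainingTrace", "train"]


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 9
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    samples_per_epoch: int = 10
    seed: int = 0
    # wgan extras
    clip_value: float = 0.01
    critic_steps: int = 5
    # vaegan extras
    lambda_rec: float = 10.0
    lambda_adv: float = 1.0
    lambda_kl: float = 1.0

    def __post_init__(self) -> None:
        for name in ("epochs", "batch_size", "learning_rate", "samples_per_epoch",
                     "clip_value", "critic_steps", "lambda_rec", "lambda_adv", "lambda_kl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EpochRecord:
    epoch: int
    g_loss: float
    d_loss: float
    samples: np.ndarray  # (samples_per_epoch, 256)
    mean_dtw: float
    mean_frechet: float
    mean_euclidean: float


@dataclass
class TrainingTrace:
    kind: str
    config: TrainConfig
    epochs: list[EpochRecord] = field(default_factory=list)

    def sampled_pool(self) -> BeatSet:
        """All per-epoch samples pooled (epochs * samples_per_epoch beats)."""
        return BeatSet(np.concatenate([e.samples for e in self.epochs], axis=0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": [e.epoch for e in self.epochs],
                "g_loss": [e.g_loss for e in self.epochs],
                "d_loss": [e.d_loss for e in self.epochs],
                "mean_dtw": [e.mean_dtw for e in self.epochs],
                "mean_frechet": [e.mean_frechet for e in self.epochs],
                "mean_euclid": [e.mean_euclidean for e in self.epochs],
            }
        )

    def save_csv(self, path: "str | Path") -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.9g")


def _check_finite(value: float, what: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite {what} ({value}) at epoch {epoch}; training aborted")


def _template_distances(samples: np.ndarray, template: Template) -> tuple[float, float, float]:
    t = template.samples[None, :]
    return (
        float(pairwise_distances(samples, t, "dtw").mean()),
        float(pairwise_distances(samples, t, "frechet").mean()),
        float(pairwise_distances(samples, t, "euclidean").mean()),
    )


def train(model: GanModel, real: BeatSet, config: TrainConfig, template: Template) -> TrainingTrace:
    """Train ``model`` on the real beat set; pure function of its seeds."""
    real.require_nonempty("train")
    if real.beat_len != model.spec.output_len:
        raise ValueError(
            f"real beats have length {real.beat_len}, model expects {model.spec.output_len}"
        )
    if template.beat.samples.size != model.spec.output_len:
        raise ValueError("template length does not match model output length")
    if real.count < config.batch_size:
        raise ValueError(f"need at least one full batch ({config.batch_size} beats)")

    cfg = config
    opt_kw = dict(lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2)
    g_opt = nn.Adam(model.generator_parameters(), **opt_kw)
    d_opt = nn.Adam(model.discriminator.parameters(), **opt_kw)
    shuffle_rng = rng_for(cfg.seed, "train_shuffle")
    latent_rng = rng_for(cfg.seed, "train_latent")
    model.train()

    trace = TrainingTrace(kind=model.kind, config=cfg)
    n_batches = real.count // cfg.batch_size
    critic_counter = 0

    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(real.count)
        g_losses: list[float] = []
        d_losses: list[float] = []
        for b in range(n_batches):
            batch = real.data[order[b * cfg.batch_size : (b + 1) * cfg.batch_size]]
            x_real = nn.Tensor(batch)

            if model.kind == "vaegan":
                mu, logvar = model.encode(x_real)
                eps = latent_rng.standard_normal(mu.shape)
                z_enc = mu + nn.Tensor(eps) * (logvar * 0.5).exp()

                # discriminator on the code: prior draws vs encoded codes
                z_prior = nn.Tensor(latent_rng.standard_normal(mu.shape))
                d_loss = nn.bce_loss(model.discriminator(z_prior), 1.0) + nn.bce_loss(
                    model.discriminator(z_enc.detach()), 0.0
                )
                d_opt.zero_grad()
                d_loss.backward()
                d_opt.step()

                # encoder/decoder: reconstruction + KL + adversarial code matching
                decoded = model.generator(z_enc)
                g_loss = (
                    cfg.lambda_rec * nn.l1_loss(decoded, batch)
                    + cfg.lambda_kl * nn.kl_gaussian(mu, logvar)
                    + cfg.lambda_adv * nn.bce_loss(model.discriminator(z_enc), 1.0)
                )
                g_opt.zero_grad()
                d_opt.zero_grad()  # discard adversarial grads on D's own weights
                g_loss.backward()
                g_opt.step()
                g_losses.append(g_loss.item())
                d_losses.append(d_loss.item())

            elif model.kind == "wgan":
                z = model.sample_latent(cfg.batch_size, latent_rng)
                fake = model.generate_raw(z)
                crit_loss = model.discriminate(nn.Tensor(fake.data)).mean() - model.discriminate(
                    x_real
                ).mean()
                d_opt.zero_grad()
                crit_loss.backward()
                d_opt.step()
                nn.clip_parameters(model.discriminator.parameters(), cfg.clip_value)
                d_losses.append(crit_loss.item())
                critic_counter += 1
                if critic_counter % cfg.critic_steps == 0 or b == n_batches - 1:
                    z = model.sample_latent(cfg.batch_size, latent_rng)
                    fake = model.generate_raw(z)
                    g_loss = -model.discriminate(fake).mean()
                    g_opt.zero_grad()
                    d_opt.zero_grad()
                    g_loss.backward()
                    g_opt.step()
                    g_losses.append(g_loss.item())

            else:  # classic / dcdc / bilstm_dc: BCE minimax
                z = model.sample_latent(cfg.batch_size, latent_rng)
                fake = model.generate_raw(z)
                d_loss = nn.bce_loss(model.discriminate(x_real), 1.0) + nn.bce_loss(
                    model.discriminate(nn.Tensor(fake.data)), 0.0
                )
                d_opt.zero_grad()
                d_loss.backward()
                d_opt.step()

                z = model.sample_latent(cfg.batch_size, latent_rng)
                fake = model.generate_raw(z)
                g_loss = nn.bce_loss(model.discriminate(fake), 1.0)
                g_opt.zero_grad()
                d_opt.zero_grad()
                g_loss.backward()
                g_opt.step()
                g_losses.append(g_loss.item())
                d_losses.append(d_loss.item())

        g_mean = float(np.mean(g_losses)) if g_losses else float("nan")
        d_mean = float(np.mean(d_losses))
        _check_finite(g_mean, "generator loss", epoch)
        _check_finite(d_mean, "discriminator loss", epoch)

        # per-epoch sampling and convergence tracking
        model.eval()
        sample_rng = rng_for(cfg.seed, "epoch_samples", epoch)
        if model.kind == "vaegan":
            z = sample_rng.standard_normal((cfg.samples_per_epoch, model.spec.bottleneck))
            samples = model.generator(nn.Tensor(z)).data.copy()
        else:
            z = model.sample_latent(cfg.samples_per_epoch, sample_rng)
            samples = model.generate_raw(z).data.copy()
        model.train()
        d_dtw, d_fre, d_euc = _template_distances(samples, template)
        trace.epochs.append(
            EpochRecord(epoch, g_mean, d_mean, samples, d_dtw, d_fre, d_euc)
        )
    model.eval()
    return trace
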