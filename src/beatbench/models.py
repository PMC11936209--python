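"""The five generative models for single cardiac cycles.

Every generator maps a standard-normal latent vector to a length-256 beat
through a terminal tanh (hence beats live in [-1, 1]); discriminators end
in a sigmoid except the Wasserstein critic, which outputs an unbounded
score.  The five kinds, tagged 01-05 in reports:

* ``classic``    — fully connected generator and discriminator.
* ``dcdc``       — deep-convolutional generator (transposed convs from a
                   length-1, 100-channel seed) and convolutional critic,
                   with a final FC + tanh readout.
* ``bilstm_dc``  — 2-layer bidirectional LSTM generator (hidden 1000, the
                   latent fed as a single time step) with a convolutional
                   discriminator.
* ``vaegan``     — a VAE (10-d bottleneck, reparameterized) whose latent
                   code is additionally matched to the prior by an
                   adversarial discriminator on the 10-d code.
* ``wgan``       — deep-convolutional Wasserstein GAN with weight
                   clipping.

Convolutions use kernel 4 / stride 2 / padding 1 unless a different
stride is needed to reach length 256; flatten dimensions ahead of final
FC layers are computed from the actual architecture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .core import BeatSet
from .seeding import rng_for

__all__ = ["ModelSpec", "GanModel", "build_model", "generate_beats", "MODEL_KINDS", "MODEL_CODES"]

MODEL_KINDS = ("classic", "dcdc", "bilstm_dc", "vaegan", "wgan")
MODEL_CODES = {"classic": "01", "dcdc": "02", "bilstm_dc": "03", "vaegan": "04", "wgan": "05"}


@dataclass
class ModelSpec:
    kind: str
    latent_dim: int = 100
    output_len: int = 256
    hidden_lstm: int = 1000
    bottleneck: int = 10  # vaegan only

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")
        if self.kind == "vaegan":
            # the VAE bottleneck is the generative latent for this model
            self.latent_dim = self.bottleneck


def _dc_discriminator(rng: np.random.Generator, sigmoid: bool) -> nn.Module:
    """Conv(1->64->128->256->512) k4/s2/p1 + Conv(512,1) + FC(flat,1)."""
    layers: list[nn.Module] = [
        nn.Conv1d(1, 64, 4, rng, stride=2, pad=1), nn.LeakyReLU(0.2),
        nn.Conv1d(64, 128, 4, rng, stride=2, pad=1), nn.BatchNorm1d(128, rng), nn.LeakyReLU(0.2),
        nn.Conv1d(128, 256, 4, rng, stride=2, pad=1), nn.BatchNorm1d(256, rng), nn.LeakyReLU(0.2),
        nn.Conv1d(256, 512, 4, rng, stride=2, pad=1), nn.BatchNorm1d(512, rng), nn.LeakyReLU(0.2),
        nn.Conv1d(512, 1, 4, rng, stride=2, pad=1),
        nn.Flatten(),
        nn.Linear(8, 1, rng),  # 256 -> 128 -> 64 -> 32 -> 16 -> 8 positions
    ]
    if sigmoid:
        layers.append(nn.Sigmoid())
    return nn.Sequential(*layers)


class GanModel:
    """A built model instance: generator (+ encoder for vaegan) and critic."""

    def __init__(self, spec: ModelSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = rng_for(seed, "model_init")
        k = spec.kind
        if k == "classic":
            self.generator = nn.Sequential(
                nn.Linear(100, 128, rng), nn.LeakyReLU(0.2),
                nn.Linear(128, 256, rng), nn.BatchNorm1d(256, rng), nn.LeakyReLU(0.2),
                nn.Linear(256, 512, rng), nn.BatchNorm1d(512, rng), nn.LeakyReLU(0.2),
                nn.Linear(512, 1024, rng), nn.BatchNorm1d(1024, rng), nn.LeakyReLU(0.2),
                nn.Linear(1024, 256, rng), nn.Tanh(),
            )
            self.discriminator = nn.Sequential(
                nn.Linear(256, 512, rng), nn.LeakyReLU(0.2),
                nn.Linear(512, 256, rng), nn.LeakyReLU(0.2),
                nn.Linear(256, 1, rng), nn.Sigmoid(),
            )
        elif k == "dcdc":
            self.generator = nn.Sequential(
                nn.ConvTranspose1d(100, 512, 4, rng, stride=2, pad=1), nn.BatchNorm1d(512, rng), nn.LeakyReLU(0.2),
                nn.ConvTranspose1d(512, 256, 4, rng, stride=2, pad=1), nn.BatchNorm1d(256, rng), nn.LeakyReLU(0.2),
                nn.ConvTranspose1d(256, 128, 4, rng, stride=2, pad=1), nn.BatchNorm1d(128, rng), nn.LeakyReLU(0.2),
                nn.ConvTranspose1d(128, 64, 4, rng, stride=2, pad=1), nn.BatchNorm1d(64, rng), nn.LeakyReLU(0.2),
                nn.ConvTranspose1d(64, 1, 4, rng, stride=2, pad=1), nn.BatchNorm1d(1, rng), nn.LeakyReLU(0.2),
                nn.Flatten(),  # 1 channel x 32 positions
                nn.Linear(32, 256, rng), nn.Tanh(),
            )
            self.discriminator = _dc_discriminator(rng, sigmoid=True)
        elif k == "bilstm_dc":
            self.generator = nn.Sequential(
                nn.BiLSTM(100, spec.hidden_lstm, 2, rng),
                nn.Linear(2 * spec.hidden_lstm, 256, rng), nn.Tanh(),
            )
            self.discriminator = _dc_discriminator(rng, sigmoid=True)
        elif k == "vaegan":
            b = spec.bottleneck
            self.encoder_trunk = nn.Sequential(
                nn.Linear(256, 512, rng), nn.LeakyReLU(0.2),
                nn.Linear(512, 512, rng), nn.BatchNorm1d(512, rng), nn.LeakyReLU(0.2),
            )
            self.enc_mu = nn.Linear(512, b, rng)
            self.enc_logvar = nn.Linear(512, b, rng)
            self.generator = nn.Sequential(  # the decoder doubles as generator
                nn.Linear(b, 512, rng), nn.LeakyReLU(0.2),
                nn.Linear(512, 512, rng), nn.BatchNorm1d(512, rng), nn.LeakyReLU(0.2),
                nn.Linear(512, 256, rng), nn.Tanh(),
            )
            self.discriminator = nn.Sequential(  # adversary on the 10-d code
                nn.Linear(b, 512, rng), nn.LeakyReLU(0.2),
                nn.Linear(512, 256, rng), nn.LeakyReLU(0.2),
                nn.Linear(256, 1, rng), nn.Sigmoid(),
            )
        elif k == "wgan":
            self.generator = nn.Sequential(
                nn.ConvTranspose1d(100, 2048, 4, rng, stride=4, pad=0), nn.BatchNorm1d(2048, rng), nn.ReLU(),
                nn.ConvTranspose1d(2048, 1024, 4, rng, stride=4, pad=0), nn.BatchNorm1d(1024, rng), nn.ReLU(),
                nn.ConvTranspose1d(1024, 512, 4, rng, stride=2, pad=1), nn.BatchNorm1d(512, rng), nn.ReLU(),
                nn.ConvTranspose1d(512, 256, 4, rng, stride=2, pad=1), nn.BatchNorm1d(256, rng), nn.ReLU(),
                nn.ConvTranspose1d(256, 128, 4, rng, stride=2, pad=1), nn.BatchNorm1d(128, rng), nn.ReLU(),
                nn.ConvTranspose1d(128, 64, 4, rng, stride=2, pad=1), nn.BatchNorm1d(64, rng), nn.ReLU(),
                nn.Conv1d(64, 1, 3, rng, stride=1, pad=1), nn.Tanh(),
            )
            self.discriminator = nn.Sequential(  # critic: no terminal sigmoid
                nn.Conv1d(1, 64, 4, rng, stride=2, pad=1), nn.LeakyReLU(0.2),
                nn.Conv1d(64, 128, 4, rng, stride=2, pad=1), nn.BatchNorm1d(128, rng), nn.LeakyReLU(0.2),
                nn.Conv1d(128, 256, 4, rng, stride=2, pad=1), nn.BatchNorm1d(256, rng), nn.LeakyReLU(0.2),
                nn.Conv1d(256, 512, 4, rng, stride=2, pad=1), nn.BatchNorm1d(512, rng), nn.LeakyReLU(0.2),
                nn.Conv1d(512, 1024, 4, rng, stride=2, pad=1), nn.BatchNorm1d(1024, rng), nn.LeakyReLU(0.2),
                nn.Conv1d(1024, 2048, 4, rng, stride=2, pad=1), nn.BatchNorm1d(2048, rng), nn.LeakyReLU(0.2),
                nn.Conv1d(2048, 1, 4, rng, stride=1, pad=0),
                nn.Flatten(),
            )

    # -- forward plumbing --------------------------------------------------
    @property
    def kind(self) -> str:
        return self.spec.kind

    @property
    def latent_dim(self) -> int:
        return self.spec.latent_dim

    def sample_latent(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal((n, self.latent_dim))

    def generate_raw(self, z: np.ndarray) -> nn.Tensor:
        """Latent batch (n, latent_dim) -> beat batch tensor (n, 256)."""
        zt = nn.Tensor(np.asarray(z, dtype=float))
        if self.kind in ("dcdc", "wgan"):
            zt = zt.reshape(zt.shape[0], self.latent_dim, 1)
        out = self.generator(zt)
        if out.data.ndim == 3:  # (n, 1, 256) conv output
            out = out.reshape(out.shape[0], out.shape[2])
        return out

    def discriminate(self, beats: nn.Tensor) -> nn.Tensor:
        """Beat batch (n, 256) -> discriminator/critic output (n, 1)."""
        x = beats
        if self.kind in ("dcdc", "bilstm_dc", "wgan"):
            x = x.reshape(x.shape[0], 1, x.shape[1])
        return self.discriminator(x)

    def encode(self, beats: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        if self.kind != "vaegan":
            raise ValueError("encode() is only defined for the vaegan model")
        h = self.encoder_trunk(beats)
        return self.enc_mu(h), self.enc_logvar(h)

    # -- module bookkeeping ------------------------------------------------
    def _submodules(self) -> list[nn.Module]:
        mods = [self.generator, self.discriminator]
        if self.kind == "vaegan":
            mods += [self.encoder_trunk, self.enc_mu, self.enc_logvar]
        return mods

    def generator_parameters(self) -> list[nn.Tensor]:
        params = self.generator.parameters()
        if self.kind == "vaegan":
            params = self.encoder_trunk.parameters() + self.enc_mu.parameters() + self.enc_logvar.parameters() + params
        return params

    def n_parameters(self) -> int:
        return sum(m.n_parameters() for m in self._submodules())

    def train(self, flag: bool = True) -> "GanModel":
        for m in self._submodules():
            m.train(flag)
        return self

    def eval(self) -> "GanModel":
        return self.train(False)

    # -- checkpoints -------------------------------------------------------
    def save(self, path: "str | Path", extra: dict | None = None) -> None:
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for mi, m in enumerate(self._submodules()):
            for ai, arr in enumerate(m.state_arrays()):
                arrays[f"m{mi}_a{ai}"] = arr
        np.savez_compressed(path, **arrays)
        manifest = {"kind": self.kind, "latent_dim": self.latent_dim, "seed": self.seed}
        manifest.update(extra or {})
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: "str | Path") -> "GanModel":
        path = Path(path)
        manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        model = cls(ModelSpec(kind=manifest["kind"]), manifest["seed"])
        with np.load(path, allow_pickle=False) as z:
            for mi, m in enumerate(model._submodules()):
                arrs = []
                ai = 0
                while f"m{mi}_a{ai}" in z:
                    arrs.append(z[f"m{mi}_a{ai}"])
                    ai += 1
                m.load_state_arrays(arrs)
        return model


def build_model(spec: "ModelSpec | str", seed: int) -> GanModel:
    """Build a model of the given kind with seeded N(0, 0.02) parameters."""
    if isinstance(spec, str):
        spec = ModelSpec(kind=spec)
    return GanModel(spec, seed)


def generate_beats(model: GanModel, n: int, seed: int) -> BeatSet:
    """Sample ``n`` beats from the (trained or untrained) generator."""
    if n < 1:
        raise ValueError("n must be >= 1")
    model.eval()
    rng = rng_for(seed, "latent")
    z = model.sample_latent(n, rng)
    out = model.generate_raw(z)
    return BeatSet(np.asarray(out.data, dtype=float).copy())
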