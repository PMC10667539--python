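"""Convolutional variational autoencoder for topography-map augmentation.

The encoder compresses a 104x104 grayscale map through three stride-2
convolutions (64-32-16 filters) and a 128-unit dense layer into the two
parameters (mu, sigma) of the Gaussian posterior q(z|x); the latent variable
is scalar by default ("two output parameters which are mean and standard
deviation").  The decoder mirrors the chain: a 2704-unit dense layer
reshaped to 13x13x16, three stride-2 transposed convolutions (16-32-64
filters) and a sigmoid 1-channel output conv back to 104x104x1.

Training minimizes the negative evidence lower bound

    loss = E_q(z|x)[-log p(x|z)] + KL(q(z|x) || N(0, 1)),

with a per-pixel Bernoulli reconstruction likelihood (MSE available via
``recon_loss="mse"``) and the closed-form Gaussian KL

    KL = -1/2 (1 + ln sigma^2 - mu^2 - sigma^2).

Sampling uses the reparameterization z = mu + sigma * eps, eps ~ N(0, 1).
New images are generated either from an even (mu, sigma) grid over the
latent space or by resampling the posteriors of encoded originals
(class-conditional augmentation that inherits the source label).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.special import xlogy

from . import nn

__all__ = [
    "VaeConfig", "LatentPosterior", "LatentSample", "LossBreakdown",
    "LabeledImage", "GeneratedImage", "Vae", "ArchitectureMismatch",
    "build_vae", "reparameterize", "kl_divergence", "reconstruction_loss",
    "vae_total_loss", "train_vae", "encode_latents", "latent_grid_decode",
    "synthesize_to_target",
]


class ArchitectureMismatch(ValueError):
    """Encoder flatten width does not match the decoder's first dense width."""


@dataclasses.dataclass(frozen=True)
class VaeConfig:
    input_shape: tuple[int, int, int] = (104, 104, 1)
    enc_filters: tuple[int, int, int] = (64, 32, 16)
    enc_dense: int = 128
    latent_dim: int = 1
    dec_dense: int = 2704
    dec_filters: tuple[int, int, int] = (16, 32, 64)
    kernel: int = 3
    stride: int = 2
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 32
    optimizer: str = "rmsprop"
    recon_loss: str = "bernoulli"
    aug_flip: bool = True
    aug_rotation_frac: float = 0.10  # fraction of a full turn, i.e. +/- 36 deg
    augment: bool = True

    def flatten_shape(self) -> tuple[int, int, int]:
        h, w, _ = self.input_shape
        for _ in self.enc_filters:
            h, w = -(-h // self.stride), -(-w // self.stride)
        return (h, w, self.enc_filters[-1])


@dataclasses.dataclass(frozen=True)
class LatentPosterior:
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclasses.dataclass(frozen=True)
class LatentSample:
    z: float
    eps: float


@dataclasses.dataclass(frozen=True)
class LossBreakdown:
    total: float
    recon: float
    kl: float
    epoch: int = 0

    def __post_init__(self) -> None:
        if self.kl < -1e-9:
            raise ValueError("kl must be >= 0")
        if abs(self.total - (self.recon + self.kl)) > 1e-6 * max(1.0, abs(self.total)):
            raise ValueError("total must equal recon + kl")


@dataclasses.dataclass
class LabeledImage:
    """A model-ready image with its class label and provenance."""

    image: np.ndarray  # H x W x C float32
    label: str
    origin: str = "original"  # "original" | "synthesized"
    source_id: int | None = None


@dataclasses.dataclass
class GeneratedImage:
    """Decoder output from an explicit latent location."""

    image: np.ndarray  # (104, 104, 1) float32 in [0, 1]
    mu: float
    sigma: float
    z: float
    origin: str = "synthesized"


class Vae:
    """Encoder/decoder pair plus the custom two-head training step."""

    def __init__(self, config: VaeConfig, seed: int = 0):
        self.config = config
        fh, fw, fc = config.flatten_shape()
        flat = fh * fw * fc
        if flat != config.dec_dense:
            raise ArchitectureMismatch(
                f"encoder flatten width {flat} != decoder dense width {config.dec_dense}")
        rng = np.random.default_rng(seed)
        c_in = config.input_shape[2]
        enc: list[nn.Layer] = []
        prev = c_in
        for i, f in enumerate(config.enc_filters):
            enc += [nn.Conv2D(prev, f, k=config.kernel, stride=config.stride,
                              rng=rng, name=f"enc_conv{i + 1}"), nn.ReLU()]
            prev = f
        enc += [nn.Flatten(), nn.Dense(flat, config.enc_dense, rng=rng, name="enc_dense"),
                nn.ReLU()]
        self.encoder = nn.Sequential(enc, input_shape=config.input_shape)
        self.mu_head = nn.Dense(config.enc_dense, config.latent_dim, rng=rng, name="mu")
        self.logsig_head = nn.Dense(config.enc_dense, config.latent_dim, rng=rng, name="log_sigma")

        dec: list[nn.Layer] = [
            nn.Dense(config.latent_dim, config.dec_dense, rng=rng, name="dec_dense"),
            nn.ReLU(), nn.Reshape((fh, fw, fc))]
        prev = fc
        for i, f in enumerate(config.dec_filters):
            dec += [nn.ConvTranspose2D(prev, f, k=config.kernel, stride=config.stride,
                                       rng=rng, name=f"dec_convT{i + 1}"), nn.ReLU()]
            prev = f
        # pointwise sigmoid projection closing the 64-channel tensor to the
        # 1-channel input shape (the stated chain fixes every other shape)
        dec += [nn.Conv2D(prev, config.input_shape[2], k=1, stride=1,
                          rng=rng, name="dec_out"), nn.Sigmoid()]
        self.decoder = nn.Sequential(dec, input_shape=(config.latent_dim,))

    # --- summaries ---------------------------------------------------------
    def summary(self) -> dict:
        enc = self.encoder.summary()
        head_shape = (self.config.latent_dim,)
        enc.append({"layer": "mu_head", "output_shape": head_shape,
                    "n_params": int(self.mu_head.w.size + self.mu_head.b.size)})
        enc.append({"layer": "log_sigma_head", "output_shape": head_shape,
                    "n_params": int(self.logsig_head.w.size + self.logsig_head.b.size)})
        return {"encoder": enc, "decoder": self.decoder.summary(),
                "flatten_width": int(np.prod(self.config.flatten_shape())),
                "latent_params": 2 * self.config.latent_dim}

    # --- inference ---------------------------------------------------------
    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior parameters (mu, sigma) for a batch (N, H, W, 1)."""
        h = self.encoder.forward(x.astype(np.float32))
        mu = self.mu_head.forward(h)
        sigma = np.exp(self.logsig_head.forward(h))
        return mu, sigma

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float32))
        return self.decoder.forward(z)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        mu, _ = self.encode(x)
        return self.decode(mu)

    def all_params(self):
        return (self.encoder.params() + self.mu_head.params()
                + self.logsig_head.params() + self.decoder.params())

    # --- serialization -----------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        state = {f"enc_{k}": v for k, v in self.encoder.state_dict().items()}
        state |= {f"dec_{k}": v for k, v in self.decoder.state_dict().items()}
        state |= {f"mu_{j}": p for j, (p, _) in enumerate(self.mu_head.params())}
        state |= {f"ls_{j}": p for j, (p, _) in enumerate(self.logsig_head.params())}
        np.savez(prefix.with_suffix(".npz"), **state)
        manifest = dataclasses.asdict(self.config)
        prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "Vae":
        prefix = Path(prefix)
        manifest = json.loads(prefix.with_suffix(".json").read_text())
        for key in ("input_shape", "enc_filters", "dec_filters"):
            manifest[key] = tuple(manifest[key])
        vae = cls(VaeConfig(**manifest))
        with np.load(prefix.with_suffix(".npz")) as data:
            for k, p in vae.encoder.state_dict().items():
                p[...] = data[f"enc_{k}"]
            for k, p in vae.decoder.state_dict().items():
                p[...] = data[f"dec_{k}"]
            for j, (p, _) in enumerate(vae.mu_head.params()):
                p[...] = data[f"mu_{j}"]
            for j, (p, _) in enumerate(vae.logsig_head.params()):
                p[...] = data[f"ls_{j}"]
        return vae


def build_vae(config: VaeConfig | None = None, seed: int = 0) -> Vae:
    """Construct the VAE; raises :class:`ArchitectureMismatch` if the shape
    chain does not close (encoder flatten width != decoder dense width)."""
    return Vae(config or VaeConfig(), seed=seed)


# --- the three loss primitives -------------------------------------------

def reparameterize(post: LatentPosterior, eps: float) -> LatentSample:
    """z = mu + sigma * eps."""
    return LatentSample(z=post.mu + post.sigma * eps, eps=eps)


def kl_divergence(post: LatentPosterior) -> float:
    """KL(N(mu, sigma^2) || N(0, 1)) = -1/2 (1 + ln sigma^2 - mu^2 - sigma^2)."""
    s2 = post.sigma ** 2
    return float(-0.5 * (1.0 + math.log(s2) - post.mu ** 2 - s2))


def reconstruction_loss(x: np.ndarray, y: np.ndarray, kind: str = "bernoulli") -> float:
    """Per-pixel reconstruction negative log-likelihood, summed over pixels.

    ``bernoulli``: -sum(x ln y + (1-x) ln(1-y)); zero iff y = x with binary x.
    ``mse``: sum((x - y)^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    if kind == "bernoulli":
        return float(-(xlogy(x, y) + xlogy(1.0 - x, 1.0 - y)).sum())
    if kind == "mse":
        return float(((x - y) ** 2).sum())
    raise ValueError(f"unknown reconstruction loss {kind!r}")


def vae_total_loss(x: np.ndarray, y: np.ndarray, post: LatentPosterior,
                   kind: str = "bernoulli", epoch: int = 0) -> LossBreakdown:
    recon = reconstruction_loss(x, y, kind)
    kl = kl_divergence(post)
    return LossBreakdown(total=recon + kl, recon=recon, kl=kl, epoch=epoch)


# --- training -------------------------------------------------------------

def _augment_batch(xb: np.ndarray, cfg: VaeConfig, rng: np.random.Generator) -> np.ndarray:
    out = xb.copy()
    for i in range(out.shape[0]):
        if cfg.aug_flip and rng.random() < 0.5:
            out[i] = out[i, :, ::-1]
        if cfg.aug_rotation_frac > 0:
            deg = rng.uniform(-1, 1) * cfg.aug_rotation_frac * 360.0
            out[i, ..., 0] = ndimage.rotate(out[i, ..., 0], deg, reshape=False,
                                            order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0)


def _as_array(dataset) -> np.ndarray:
    imgs = []
    for item in dataset:
        img = getattr(item, "values", None)
        if img is None:
            img = getattr(item, "image", item)
        img = np.asarray(img, dtype=np.float32)
        if img.ndim == 2:
            img = img[..., None]
        imgs.append(img)
    return np.stack(imgs)


def train_vae(dataset, config: VaeConfig | None = None, seed: int = 0,
              vae: Vae | None = None) -> tuple[Vae, list[LossBreakdown]]:
    """Train the VAE; returns the model and a per-epoch loss history.

    ``dataset`` is a sequence of GrayMaps / LabeledImages / arrays of the
    configured input shape.  Per-batch augmentation applies a random
    horizontal flip and a rotation of up to ``aug_rotation_frac`` of a full
    turn.  Reported losses are batch means of (recon + KL), averaged over
    the epoch.  Deterministic given (dataset, config, seed).
    """
    config = config or VaeConfig()
    x = _as_array(dataset)
    if x.shape[0] == 0:
        raise ValueError("dataset must be nonempty")
    rng = np.random.default_rng(seed)
    if vae is None:
        vae = Vae(config, seed=int(rng.integers(2 ** 31)))
    opt = nn.make_optimizer(config.optimizer, vae.all_params(), config.learning_rate)
    n = x.shape[0]
    history: list[LossBreakdown] = []
    eps_clip = 1e-6
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        tot = rec = kld = 0.0
        nb = 0
        for start in range(0, n, config.batch_size):
            xb = x[order[start:start + config.batch_size]]
            if config.augment:
                xb = _augment_batch(xb, config, rng)
            b = xb.shape[0]
            h = vae.encoder.forward(xb, training=True, rng=rng)
            mu = vae.mu_head.forward(h)
            logsig = vae.logsig_head.forward(h)
            sigma = np.exp(np.clip(logsig, -10, 10))
            eps = rng.standard_normal(mu.shape).astype(np.float32)
            z = mu + sigma * eps
            y = vae.decoder.forward(z, training=True, rng=rng)
            yc = np.clip(y, eps_clip, 1.0 - eps_clip)

            if config.recon_loss == "bernoulli":
                recon_b = float(-(xlogy(xb, yc) + xlogy(1.0 - xb, 1.0 - yc)).sum()) / b
                dy = (yc - xb) / (yc * (1.0 - yc)) / b
            else:
                recon_b = float(((xb - y) ** 2).sum()) / b
                dy = 2.0 * (y - xb) / b
            kl_b = float(-0.5 * (1.0 + 2.0 * logsig - mu ** 2 - sigma ** 2).sum()) / b

            dz = vae.decoder.backward(dy.astype(np.float32))
            dmu = dz + mu / b
            dlogsig = dz * eps * sigma + (sigma ** 2 - 1.0) / b
            dh = (vae.mu_head.backward(dmu.astype(np.float32))
                  + vae.logsig_head.backward(dlogsig.astype(np.float32)))
            vae.encoder.backward(dh)
            opt.step()

            tot += recon_b + kl_b
            rec += recon_b
            kld += kl_b
            nb += 1
        history.append(LossBreakdown(total=tot / nb, recon=rec / nb,
                                     kl=max(kld / nb, 0.0), epoch=epoch + 1))
    return vae, history


# --- latent-space utilities ----------------------------------------------

def encode_latents(dataset, labels: Sequence[str], vae: Vae,
                   scatter_path: str | Path | None = None,
                   csv_path: str | Path | None = None,
                   batch_size: int = 64) -> list[tuple[float, float, str]]:
    """Posterior (mu, sigma, label) per input, order-preserving.

    Optionally writes a mu-vs-sigma scatter colored by label (the standard
    latent-clustering diagnostic) and a CSV of the posteriors.
    """
    x = _as_array(dataset)
    mus, sigmas = [], []
    for start in range(0, x.shape[0], batch_size):
        mu, sigma = vae.encode(x[start:start + batch_size])
        mus.append(mu[:, 0])
        sigmas.append(sigma[:, 0])
    mu = np.concatenate(mus) if mus else np.empty(0)
    sigma = np.concatenate(sigmas) if sigmas else np.empty(0)
    out = [(float(m), float(s), str(l)) for m, s, l in zip(mu, sigma, labels)]
    if csv_path is not None:
        import pandas as pd

        pd.DataFrame(out, columns=["mu", "sigma", "label"]).to_csv(csv_path, index=False)
    if scatter_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for lab in sorted(set(labels)):
            sel = [i for i, l in enumerate(labels) if l == lab]
            ax.scatter(mu[sel], sigma[sel], s=8, alpha=0.6, label=lab)
        ax.set_xlabel("posterior mean $\\mu$")
        ax.set_ylabel("posterior SD $\\sigma$")
        ax.legend()
        fig.tight_layout()
        fig.savefig(scatter_path, dpi=120)
        plt.close(fig)
    return out


def latent_grid_decode(mu_range: tuple[float, float], sigma_range: tuple[float, float],
                       n_mu: int, n_sigma: int, vae: Vae, eps_seed: int = 0,
                       batch_size: int = 64) -> list[GeneratedImage]:
    """Decode an evenly spaced (mu, sigma) grid; one eps draw per cell.

    The default study-scale grid is 30 x 30 = 900 images over mu in [-3, 3],
    sigma in [0.1, 2.0].
    """
    if n_mu < 1 or n_sigma < 1:
        raise ValueError("grid counts must be >= 1")
    if sigma_range[0] <= 0 or sigma_range[1] <= 0:
        raise ValueError("sigma range must be positive")
    mus = np.linspace(mu_range[0], mu_range[1], n_mu)
    sigmas = np.linspace(sigma_range[0], sigma_range[1], n_sigma)
    rng = np.random.default_rng(eps_seed)
    cells = [(m, s) for m in mus for s in sigmas]
    eps = rng.standard_normal(len(cells))
    zs = np.array([m + s * e for (m, s), e in zip(cells, eps)], dtype=np.float32)
    out: list[GeneratedImage] = []
    for start in range(0, len(zs), batch_size):
        batch = zs[start:start + batch_size, None]
        imgs = vae.decode(batch)
        for j in range(imgs.shape[0]):
            m, s = cells[start + j]
            out.append(GeneratedImage(image=imgs[j], mu=float(m), sigma=float(s),
                                      z=float(zs[start + j])))
    return out


def synthesize_to_target(originals: Sequence[LabeledImage], vae: Vae,
                         per_class_target: int, seed: int = 0,
                         batch_size: int = 64) -> list[LabeledImage]:
    """Expand a labelled cohort to ``per_class_target`` images per class.

    For each class, source originals are drawn at random (with replacement),
    z is sampled from their encoded posteriors and decoded, and the output
    inherits the source label with ``origin="synthesized"``.  All originals
    are retained unchanged.
    """
    rng = np.random.default_rng(seed)
    labels = sorted({r.label for r in originals})
    out = list(originals)
    for lab in labels:
        members = [r for r in originals if r.label == lab]
        need = per_class_target - len(members)
        if need < 0:
            raise ValueError(
                f"class {lab!r} already has {len(members)} > target {per_class_target}")
        if need == 0:
            continue
        x = _as_array(members)
        mus = np.empty((len(members), vae.config.latent_dim), dtype=np.float32)
        sigmas = np.empty_like(mus)
        for start in range(0, len(members), batch_size):
            mu, sigma = vae.encode(x[start:start + batch_size])
            mus[start:start + batch_size] = mu
            sigmas[start:start + batch_size] = sigma
        src = rng.integers(0, len(members), size=need)
        z = mus[src] + sigmas[src] * rng.standard_normal((need, vae.config.latent_dim)).astype(np.float32)
        for start in range(0, need, batch_size):
            imgs = vae.decode(z[start:start + batch_size])
            for j in range(imgs.shape[0]):
                out.append(LabeledImage(image=imgs[j], label=lab,
                                        origin="synthesized",
                                        source_id=int(src[start + j])))
    return out
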