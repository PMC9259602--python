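"""Variational-autoencoder latent features of imaging frames.

Each preprocessed imaging frame (non-ROI pixels zeroed, downscaled, scaled
to [0, 1]) is embedded into two latent features by a convolutional VAE:
encoder = two 3x3 stride-2 convolutions (32 then 64 filters) + a 16-unit
dense layer + a 2-D Gaussian latent (two means, two log-variances);
decoder mirrors the encoder with transposed convolutions.  Training
minimizes per-sample reconstruction sum-of-squares plus the KL divergence
of the latent posterior from a standard normal, with RMSProp in batches
of 128 frames.

The per-condition distribution radius — the mean Euclidean distance of a
condition's frames to their centroid in the latent plane — summarizes how
consistently the circuit responds; it is reported relative to session S1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _nn

__all__ = [
    "VaeConfig",
    "ConvVAE",
    "LatentEmbedding",
    "preprocess_frames",
    "select_interaction_frames",
    "train_vae",
    "embed",
    "radius",
    "relative_radius",
]


@dataclass
class VaeConfig:
    """Architecture and training settings (latent dimension is fixed at 2)."""

    input_size: tuple[int, int] = (64, 64)
    conv_filters: tuple[int, int] = (32, 64)
    dense_units: int = 16
    latent_dim: int = 2
    batch_size: int = 128
    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if self.latent_dim != 2:
            raise ValueError("latent dimension is fixed at 2")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        h, w = self.input_size
        if h % 4 or w % 4:
            raise ValueError(
                f"input size {self.input_size} must be divisible by 4 "
                "(two stride-2 layers)"
            )


@dataclass
class LatentEmbedding:
    """Per-frame 2-D posterior means with optional condition labels."""

    coords: np.ndarray  # (frames, 2)
    conditions: np.ndarray | None = None  # per-frame label

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (frames, 2)")
        if self.conditions is not None:
            self.conditions = np.asarray(self.conditions)
            if len(self.conditions) != len(self.coords):
                raise ValueError("conditions length must match coords")

    def subset(self, condition) -> np.ndarray:
        if self.conditions is None:
            raise ValueError("embedding carries no condition labels")
        return self.coords[self.conditions == condition]


# ---------------------------------------------------------------------------
# frame preprocessing


def _block_mean(frames: np.ndarray, factor_h: int, factor_w: int) -> np.ndarray:
    n, H, W = frames.shape
    return frames.reshape(n, H // factor_h, factor_h, W // factor_w, factor_w).mean(
        axis=(2, 4)
    )


def preprocess_frames(
    frames: np.ndarray,
    footprint_masks: np.ndarray | None,
    target_size: tuple[int, int] = (64, 64),
) -> np.ndarray:
    """Zero non-ROI pixels, block-mean downscale, min-max scale to [0, 1].

    ``footprint_masks`` is an (n_rois, H, W) boolean stack (or None to keep
    all pixels); the union of the masks defines the ROI pixels kept.  The
    source size must be an integer multiple of ``target_size``.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be (n, height, width)")
    n, H, W = frames.shape
    if footprint_masks is not None:
        union = np.asarray(footprint_masks).astype(bool).any(axis=0)
        if not union.any():
            raise ValueError("empty footprint union: no ROI pixels to keep")
        frames = frames * union[None, :, :]
    th, tw = target_size
    if H % th or W % tw:
        raise ValueError(f"source size {(H, W)} not a multiple of target {target_size}")
    if (H, W) != (th, tw):
        frames = _block_mean(frames, H // th, W // tw)
    lo, hi = frames.min(), frames.max()
    if hi > lo:
        frames = (frames - lo) / (hi - lo)
    else:
        frames = np.zeros_like(frames)
    return frames


def select_interaction_frames(
    n_frames: int, bouts, stimulus: str, first_n: int | None = None
) -> np.ndarray:
    """Frame indices during one stimulus's bouts, optionally capped per episode.

    With ``first_n`` set, at most the first ``first_n`` frames of each
    episode are used (the familiarity control: equalizes exposure between
    long and short interactions).
    """
    chunks = []
    for b in bouts:
        if b.stimulus != stimulus:
            continue
        end = min(b.end, n_frames)
        idx = np.arange(b.start, end)
        if first_n is not None:
            idx = idx[:first_n]
        chunks.append(idx)
    if not chunks:
        warnings.warn(f"no interaction frames for stimulus {stimulus!r}")
        return np.empty(0, dtype=int)
    return np.concatenate(chunks)


# ---------------------------------------------------------------------------
# model


class ConvVAE:
    """Convolutional VAE over single-channel frames (see module docstring)."""

    def __init__(self, config: VaeConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        h, w = config.input_size
        f1, f2 = config.conv_filters
        self.hq, self.wq = h // 4, w // 4
        flat = f2 * self.hq * self.wq

        self.enc_conv1 = _nn.Conv2D(1, f1, rng)
        self.enc_relu1 = _nn.ReLU()
        self.enc_conv2 = _nn.Conv2D(f1, f2, rng)
        self.enc_relu2 = _nn.ReLU()
        self.enc_dense = _nn.Dense(flat, config.dense_units, rng)
        self.enc_relu3 = _nn.ReLU()
        self.fc_mu = _nn.Dense(config.dense_units, 2, rng)
        self.fc_logvar = _nn.Dense(config.dense_units, 2, rng)

        self.dec_dense1 = _nn.Dense(2, config.dense_units, rng)
        self.dec_relu1 = _nn.ReLU()
        self.dec_dense2 = _nn.Dense(config.dense_units, flat, rng)
        self.dec_relu2 = _nn.ReLU()
        self.dec_convt1 = _nn.ConvTranspose2D(f2, f1, rng)
        self.dec_relu3 = _nn.ReLU()
        self.dec_convt2 = _nn.ConvTranspose2D(f1, 1, rng)
        self.dec_sigmoid = _nn.Sigmoid()

        self.layers = [
            self.enc_conv1, self.enc_conv2, self.enc_dense,
            self.fc_mu, self.fc_logvar,
            self.dec_dense1, self.dec_dense2, self.dec_convt1, self.dec_convt2,
        ]
        self.trained = False
        self._eps_rng = np.random.default_rng(config.seed + 1)

    # -- passes ------------------------------------------------------------

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = self.enc_relu1.forward(self.enc_conv1.forward(x))
        h = self.enc_relu2.forward(self.enc_conv2.forward(h))
        self._enc_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.enc_relu3.forward(self.enc_dense.forward(h))
        return self.fc_mu.forward(h), self.fc_logvar.forward(h)

    def decode(self, z: np.ndarray) -> np.ndarray:
        f2 = self.config.conv_filters[1]
        h = self.dec_relu1.forward(self.dec_dense1.forward(z))
        h = self.dec_relu2.forward(self.dec_dense2.forward(h))
        h = h.reshape(z.shape[0], f2, self.hq, self.wq)
        h = self.dec_relu3.forward(self.dec_convt1.forward(h))
        return self.dec_sigmoid.forward(self.dec_convt2.forward(h))

    def _backward(self, x, recon, mu, logvar, eps) -> None:
        n = x.shape[0]
        drecon = 2.0 * (recon - x) / n
        dh = self.dec_sigmoid.backward(drecon)
        dh = self.dec_convt2.backward(dh)
        dh = self.dec_convt1.backward(self.dec_relu3.backward(dh))
        dh = dh.reshape(n, -1)
        dh = self.dec_dense2.backward(self.dec_relu2.backward(dh))
        dz = self.dec_dense1.backward(self.dec_relu1.backward(dh))

        dmu = dz + mu / n
        dlogvar = dz * eps * 0.5 * np.exp(0.5 * logvar) + 0.5 * (np.exp(logvar) - 1.0) / n

        dh = self.fc_mu.backward(dmu) + self.fc_logvar.backward(dlogvar)
        dh = self.enc_dense.backward(self.enc_relu3.backward(dh))
        dh = dh.reshape(self._enc_shape)
        dh = self.enc_conv2.backward(self.enc_relu2.backward(dh))
        self.enc_conv1.backward(self.enc_relu1.backward(dh))

    @staticmethod
    def _loss(x, recon, mu, logvar) -> tuple[float, float]:
        n = x.shape[0]
        recon_loss = float(np.sum((recon - x) ** 2) / n)
        kl = float(
            -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar)) / n
        )
        return recon_loss, kl

    # -- API ---------------------------------------------------------------

    def fit(self, frames: np.ndarray, epochs: int | None = None) -> list[dict]:
        """Train on (n, H, W) frames in [0, 1]; returns per-epoch loss history."""
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3:
            raise ValueError("frames must be (n, height, width)")
        if frames.shape[1:] != tuple(self.config.input_size):
            raise ValueError(
                f"frame size {frames.shape[1:]} != configured {self.config.input_size}"
            )
        n = frames.shape[0]
        if n < 1:
            raise ValueError("need at least one frame")
        epochs = self.config.epochs if epochs is None else epochs
        x_all = frames.astype(np.float32)[:, None, :, :]
        opt = _nn.RMSProp(self.layers, lr=self.config.learning_rate)
        shuffle_rng = np.random.default_rng(self.config.seed + 2)
        bs = min(self.config.batch_size, n)
        history: list[dict] = []
        for epoch in range(epochs):
            order = shuffle_rng.permutation(n)
            tot_r = tot_k = 0.0
            n_batches = 0
            for lo in range(0, n, bs):
                x = x_all[order[lo : lo + bs]]
                mu, logvar = self.encode(x)
                logvar = np.clip(logvar, -10.0, 10.0)
                eps = self._eps_rng.standard_normal(mu.shape).astype(np.float32)
                z = mu + np.exp(0.5 * logvar) * eps
                recon = self.decode(z)
                r, k = self._loss(x, recon, mu, logvar)
                self._backward(x, recon, mu, logvar, eps)
                opt.step()
                tot_r += r
                tot_k += k
                n_batches += 1
            history.append(
                {
                    "epoch": epoch,
                    "recon": tot_r / n_batches,
                    "kl": tot_k / n_batches,
                    "total": (tot_r + tot_k) / n_batches,
                }
            )
        self.trained = True
        self.loss_history = history
        return history

    def transform(self, frames: np.ndarray) -> np.ndarray:
        """Posterior-mean 2-D coordinates of each frame (deterministic)."""
        if not self.trained:
            raise RuntimeError("model is not trained")
        frames = np.asarray(frames, dtype=float)
        coords = []
        for lo in range(0, frames.shape[0], self.config.batch_size):
            mu, _ = self.encode(
                frames[lo : lo + self.config.batch_size, None, :, :].astype(np.float32)
            )
            coords.append(mu)
        return np.concatenate(coords, axis=0)

    def reconstruct(self, frames: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("model is not trained")
        mu, _ = self.encode(np.asarray(frames, dtype=np.float32)[:, None, :, :])
        return self.decode(mu)[:, 0]


def train_vae(frames: np.ndarray, config: VaeConfig | None = None,
              epochs: int | None = None) -> tuple[ConvVAE, list[dict]]:
    """Build and train a :class:`ConvVAE`; returns (model, loss history)."""
    config = config or VaeConfig()
    model = ConvVAE(config)
    history = model.fit(frames, epochs=epochs)
    return model, history


def embed(
    frames: np.ndarray, model: ConvVAE, conditions: np.ndarray | None = None
) -> LatentEmbedding:
    """Embed frames as 2-D posterior means, carrying condition labels."""
    return LatentEmbedding(model.transform(frames), conditions)


def radius(coords: np.ndarray) -> float:
    """Mean Euclidean distance of points to their centroid in the 2-D plane."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        warnings.warn("radius undefined for an empty condition")
        return float("nan")
    coords = coords.reshape(-1, 2)
    centroid = coords.mean(axis=0)
    return float(np.linalg.norm(coords - centroid, axis=1).mean())


def relative_radius(
    coords_by_session: dict[str, np.ndarray], reference: str = "S1"
) -> dict[str, float]:
    """Radius per session divided by the reference session's radius."""
    if reference not in coords_by_session:
        raise ValueError(f"reference session {reference!r} missing")
    radii = {s: radius(c) for s, c in coords_by_session.items()}
    ref = radii[reference]
    if not np.isfinite(ref) or ref == 0:
        warnings.warn("reference radius is zero or undefined")
        return {s: float("nan") for s in radii}
    return {s: r / ref for s, r in radii.items()}
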