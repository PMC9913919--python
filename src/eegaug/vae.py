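"""Conditional convolutional variational autoencoder for EEG epoch synthesis.

The generative augmentation model: an encoder of two strided temporal
convolutions compresses a standardized multichannel epoch (with the
diagnostic label appended as one-hot constant channels) into the mean and
log-variance of a Gaussian latent; the reparameterization trick samples
the latent; a symmetric decoder (dense -> two upsample+convolution
stages) reconstructs the epoch. Sampling the standard-normal prior and
decoding under a requested label yields artificial epochs for
minority-class augmentation.

Implemented directly in NumPy (im2col convolutions, manual
backpropagation, Adam) so training is deterministic for a fixed seed and
has no framework dependency. Sizing defaults are desk-scale: a few
hundred epochs train in seconds on one CPU core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import LABEL_ORDER, Diagnosis, EpochSet

__all__ = [
    "VAEConfig",
    "VAEModel",
    "reparameterize",
    "vae_loss",
    "train_vae",
    "sample_vae",
]


# ---------------------------------------------------------------------------
# Layers (forward caches what backward needs; grads accumulate in .grads)

class _Conv1d:
    """1-D convolution along time: weight (c_out, c_in*k), 'same' padding."""

    def __init__(self, rng, c_in, c_out, k, stride):
        self.k, self.stride, self.c_in, self.c_out = k, stride, c_in, c_out
        self.W = rng.standard_normal((c_out, c_in * k)) * np.sqrt(2.0 / (c_in * k))
        self.b = np.zeros(c_out)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        n, c, t = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, self.k, axis=2)[:, :, :: self.stride, :]
        self._cols = win.transpose(0, 1, 3, 2).reshape(n, c * self.k, -1)
        self._t_in = t
        return np.matmul(self.W, self._cols) + self.b[:, None]

    def backward(self, dy):
        n = dy.shape[0]
        t_out = dy.shape[2]
        self.gW = np.matmul(dy, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.gb = dy.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T, dy)  # (n, c_in*k, t_out)
        dcols = dcols.reshape(n, self.c_in, self.k, t_out)
        p = self.k // 2
        dxp = np.zeros((n, self.c_in, self._t_in + 2 * p))
        for j in range(self.k):
            dxp[:, :, j : j + self.stride * (t_out - 1) + 1 : self.stride] \
                += dcols[:, :, j, :]
        return dxp[:, :, p : p + self._t_in]

    @property
    def grads(self):
        return [self.gW, self.gb]


class _Dense:
    def __init__(self, rng, d_in, d_out):
        self.W = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.b = np.zeros(d_out)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.gW = self._x.T @ dy
        self.gb = dy.sum(axis=0)
        return dy @ self.W.T

    @property
    def grads(self):
        return [self.gW, self.gb]


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _Upsample:
    """Nearest-neighbour temporal upsampling by an integer factor."""

    params: list = []
    grads: list = []

    def __init__(self, factor):
        self.factor = factor

    def forward(self, x):
        return np.repeat(x, self.factor, axis=2)

    def backward(self, dy):
        n, c, t = dy.shape
        return dy.reshape(n, c, t // self.factor, self.factor).sum(axis=3)


def _out_len(t, stride):
    # 'same' padding with kernel 3: ceil(t / stride)
    return (t - 1) // stride + 1


# ---------------------------------------------------------------------------
# Public closed-form pieces

def reparameterize(mu, logvar, eps_noise):
    """z = mu + exp(logvar/2) * eps_noise (elementwise)."""
    mu, logvar, eps_noise = (np.asarray(a, dtype=np.float64)
                             for a in (mu, logvar, eps_noise))
    if not (mu.shape == logvar.shape == eps_noise.shape):
        raise ValueError("mu, logvar and eps_noise must have identical shapes")
    return mu + np.exp(logvar / 2.0) * eps_noise


def vae_loss(x, x_hat, mu, logvar, beta=1.0):
    """(total, recon, kl).

    recon is the mean squared error between x and x_hat; kl is
    -1/2 * sum_dims(1 + logvar - mu^2 - exp(logvar)), averaged over the
    batch when mu is 2-D; total = recon + beta * kl.
    """
    x, x_hat = np.asarray(x, dtype=np.float64), np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError("x and x_hat shapes differ")
    mu, logvar = np.asarray(mu, dtype=np.float64), np.asarray(logvar, dtype=np.float64)
    if mu.shape != logvar.shape:
        raise ValueError("mu and logvar shapes differ")
    recon = float(np.mean((x - x_hat) ** 2))
    kl_per = -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar), axis=-1)
    kl = float(np.mean(kl_per)) if kl_per.ndim else float(kl_per)
    return recon + beta * kl, recon, kl


# ---------------------------------------------------------------------------
# Configuration and model

@dataclass(frozen=True)
class VAEConfig:
    """Architecture and optimization settings.

    ``conv_channels`` are the two encoder convolution widths (the decoder
    mirrors them); ``conv_strides`` the temporal downsampling per stage.
    ``kl_weight`` balances the KL term against the per-element mean
    reconstruction error; with ~2e4 elements per epoch the ELBO-consistent
    weight is of order 1/n_elements, hence the small default.
    """

    latent_dim: int = 16
    conv_channels: tuple = (16, 32)
    kernel: int = 3
    conv_strides: tuple = (4, 4)
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    kl_weight: float = 2.5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.latent_dim, self.kernel, self.epochs, self.batch_size) < 1:
            raise ValueError("latent_dim, kernel, epochs, batch_size must be >= 1")
        if len(self.conv_channels) != 2 or min(self.conv_channels) < 1:
            raise ValueError("conv_channels must be two positive integers")
        if self.learning_rate <= 0 or self.kl_weight <= 0:
            raise ValueError("learning_rate and kl_weight must be positive")


class VAEModel:
    """Trained conditional encoder/decoder with loss history.

    Input conditioning: one one-hot channel per diagnostic class (HC, MCI,
    AD order), constant over time, appended to the standardized epoch.
    """

    def __init__(self, cfg: VAEConfig, n_channels: int, n_samples: int,
                 fs_hz: float, duration_s: float, channel_names: tuple):
        self.cfg = cfg
        self.n_channels = n_channels
        self.n_samples = n_samples
        self.fs_hz = fs_hz
        self.duration_s = duration_s
        self.channel_names = tuple(channel_names)
        self.n_classes = len(LABEL_ORDER)
        self.loss_history: list = []  # (epoch, total, recon, kl)
        self.trained = False
        self.norm_mean = np.zeros((n_channels, 1))
        self.norm_std = np.ones((n_channels, 1))
        # class-conditional per-channel std of the *standardized* training
        # data, used to variance-calibrate generated samples
        self.class_std = np.ones((self.n_classes, n_channels))

        c1, c2 = cfg.conv_channels
        s1, s2 = cfg.conv_strides
        k = cfg.kernel
        self._t1 = _out_len(n_samples, s1)
        self._t2 = _out_len(self._t1, s2)
        rng = np.random.default_rng(cfg.seed)
        cin = n_channels + self.n_classes
        self.enc = [_Conv1d(rng, cin, c1, k, s1), _ReLU(),
                    _Conv1d(rng, c1, c2, k, s2), _ReLU()]
        flat = c2 * self._t2
        self.head_mu = _Dense(rng, flat, cfg.latent_dim)
        self.head_logvar = _Dense(rng, flat, cfg.latent_dim)
        self.dec_dense = _Dense(rng, cfg.latent_dim + self.n_classes, flat)
        self.dec = [_ReLU(), _Upsample(s2), _Conv1d(rng, c2, c1, k, 1), _ReLU(),
                    _Upsample(s1), _Conv1d(rng, c1, n_channels, k, 1)]
        self._c2 = c2

    # -- plumbing -----------------------------------------------------------
    def _layers(self):
        return self.enc + [self.head_mu, self.head_logvar, self.dec_dense] + self.dec

    def parameters(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def gradients(self):
        out = []
        for layer in self._layers():
            out.extend(layer.grads)
        return out

    def one_hot(self, labels) -> np.ndarray:
        if isinstance(labels, np.ndarray):
            labels = labels.tolist()
        elif not isinstance(labels, (list, tuple)):
            labels = [labels]
        labels = [Diagnosis.coerce(l) for l in labels]
        oh = np.zeros((len(labels), self.n_classes))
        for i, lab in enumerate(labels):
            oh[i, LABEL_ORDER.index(lab)] = 1.0
        return oh

    # -- forward passes -----------------------------------------------------
    def encode(self, x_std: np.ndarray, onehot: np.ndarray):
        """x_std: standardized epochs (n, C, T); returns (mu, logvar)."""
        cond = np.broadcast_to(onehot[:, :, None],
                               (x_std.shape[0], self.n_classes, x_std.shape[2]))
        h = np.concatenate([x_std, cond], axis=1)
        for layer in self.enc:
            h = layer.forward(h)
        hf = h.reshape(h.shape[0], -1)
        self._enc_hshape = h.shape
        return self.head_mu.forward(hf), self.head_logvar.forward(hf)

    def decode(self, z: np.ndarray, onehot: np.ndarray) -> np.ndarray:
        g = self.dec_dense.forward(np.concatenate([z, onehot], axis=1))
        h = g.reshape(z.shape[0], self._c2, self._t2)
        for layer in self.dec:
            h = layer.forward(h)
        self._dec_t = h.shape[2]
        return h[:, :, : self.n_samples]

    def _decode_backward(self, dxhat: np.ndarray) -> np.ndarray:
        if self._dec_t > self.n_samples:
            dxhat = np.pad(dxhat,
                           ((0, 0), (0, 0), (0, self._dec_t - self.n_samples)))
        dh = dxhat
        for layer in reversed(self.dec):
            dh = layer.backward(dh)
        dg = dh.reshape(dh.shape[0], -1)
        dzin = self.dec_dense.backward(dg)
        return dzin[:, : self.cfg.latent_dim]

    def _encode_backward(self, dmu: np.ndarray, dlogvar: np.ndarray) -> None:
        dhf = self.head_mu.backward(dmu) + self.head_logvar.backward(dlogvar)
        dh = dhf.reshape(self._enc_hshape)
        for layer in reversed(self.enc):
            dh = layer.backward(dh)

    # -- data scaling -------------------------------------------------------
    def standardize(self, epochs: np.ndarray) -> np.ndarray:
        return (epochs - self.norm_mean) / self.norm_std

    def destandardize(self, epochs_std: np.ndarray) -> np.ndarray:
        return epochs_std * self.norm_std + self.norm_mean

    # -- persistence (warm-start hook) --------------------------------------
    def save_params(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        arrays["norm_mean"] = self.norm_mean
        arrays["norm_std"] = self.norm_std
        meta = dict(n_channels=self.n_channels, n_samples=self.n_samples,
                    latent_dim=self.cfg.latent_dim,
                    conv_channels=list(self.cfg.conv_channels))
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    def load_params(self, path) -> None:
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            if (meta["n_channels"], meta["n_samples"]) != (self.n_channels,
                                                           self.n_samples):
                raise ValueError("saved parameters do not match model geometry")
            for i, p in enumerate(self.parameters()):
                saved = data[f"p{i}"]
                if saved.shape != p.shape:
                    raise ValueError("saved parameter shape mismatch")
                p[...] = saved
            self.norm_mean = data["norm_mean"]
            self.norm_std = data["norm_std"]


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.params, self.lr, self.b1, self.b2, self.eps = params, lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Training and sampling

def train_vae(eps: EpochSet, cfg: VAEConfig = VAEConfig(),
              warm_start=None) -> VAEModel:
    """Train the conditional VAE on an EpochSet (all classes, label-conditioned).

    Epochs are standardized per channel with training-set statistics before
    training; generated samples are de-standardized back to microvolts.
    ``warm_start`` optionally names a parameter file saved by
    :meth:`VAEModel.save_params` to initialize the weights from.
    Deterministic for fixed data, config and seed.
    """
    if len(eps) == 0:
        raise ValueError("cannot train a VAE on an empty EpochSet")
    model = VAEModel(cfg, eps.n_channels, eps.n_samples, eps.fs_hz,
                     eps.duration_s, eps.channel_names)
    x = eps.epochs
    model.norm_mean = x.mean(axis=(0, 2))[:, None]
    std = x.std(axis=(0, 2))[:, None]
    std[std < 1e-8] = 1e-8
    model.norm_std = std
    if warm_start is not None:
        model.load_params(warm_start)
    x_std = model.standardize(x)
    onehot_all = model.one_hot(eps.labels)
    for ci, lab in enumerate(LABEL_ORDER):
        mask = eps.labels == lab
        if mask.any():
            model.class_std[ci] = x_std[mask].std(axis=(0, 2))

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7A3]))
    opt = _Adam(model.parameters(), cfg.learning_rate)
    n = len(eps)
    numel = model.n_channels * model.n_samples
    beta = cfg.kl_weight
    for ep_i in range(cfg.epochs):
        order = rng.permutation(n)
        tot_sum = rec_sum = kl_sum = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, oh = x_std[idx], onehot_all[idx]
            nb = len(idx)

            mu, logvar = model.encode(xb, oh)
            noise = rng.standard_normal(mu.shape)
            z = reparameterize(mu, logvar, noise)
            xhat = model.decode(z, oh)
            total, recon, kl = vae_loss(xb, xhat, mu, logvar, beta)

            dxhat = 2.0 * (xhat - xb) / (nb * numel)
            dz = model._decode_backward(dxhat)
            dmu = dz + beta * mu / nb
            dlogvar = (dz * noise * 0.5 * np.exp(logvar / 2.0)
                       - beta * 0.5 * (1.0 - np.exp(logvar)) / nb)
            model._encode_backward(dmu, dlogvar)
            opt.step(model.gradients())

            tot_sum += total * nb
            rec_sum += recon * nb
            kl_sum += kl * nb
        model.loss_history.append(
            (ep_i, tot_sum / n, rec_sum / n, kl_sum / n))
    model.trained = True
    return model


def sample_vae(model: VAEModel, label, n: int, seed: int = 0,
               calibrate_variance: bool = True) -> EpochSet:
    """Draw n latent vectors from the prior and decode under ``label``.

    MSE-trained decoders systematically under-disperse, so by default each
    generated channel is rescaled to the class-conditional per-channel
    variance observed on the (standardized) training data, making the
    artificial epochs amplitude-realistic before de-standardization back
    to microvolts. Returns an EpochSet with the model's epoch geometry.
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    if n < 0:
        raise ValueError("n must be >= 0")
    label = Diagnosis.coerce(label)
    if n == 0:
        epochs = np.empty((0, model.n_channels, model.n_samples))
    else:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, model.cfg.latent_dim))
        oh = np.repeat(model.one_hot([label]), n, axis=0)
        xs = model.decode(z, oh)
        if calibrate_variance:
            target = model.class_std[LABEL_ORDER.index(label)]  # (C,)
            got = xs.std(axis=(0, 2))
            got[got < 1e-8] = 1e-8
            xs = xs * (target / got)[None, :, None]
        epochs = model.destandardize(xs)
    return EpochSet(
        epochs=epochs, fs_hz=model.fs_hz, duration_s=model.duration_s,
        labels=np.asarray([label] * n, dtype=object),
        subject_ids=np.asarray([f"VAE_{label.value}_{i:04d}" for i in range(n)],
                               dtype=object),
        channel_names=model.channel_names)
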