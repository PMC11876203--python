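"""The vector-quantized autoencoder with an inner one-class (SVDD) encoder.

Data flow (full mode):

    x --Encoder1--> z_e --Encoder2--> z --Decoder2--> z_d
      --quantize--> z_q --Decoder1--> xhat

Encoder 1 compresses the image to a latent map of side input_size/4 with D
channels.  Encoder 2 flattens that map into a single latent vector z whose
distance to a hypersphere center is the one-class term; Decoder 2 expands z
back to a map z_d of the same size as z_e.  Quantization replaces each
channel vector of z_d with its nearest codebook entry (straight-through
gradients), and Decoder 1 reconstructs the image.

In *bypass* mode — used for the first training stage, where only the outer
autoencoder and the codebook learn — z_e feeds quantization directly and
z_d is identically z_e.

A plain convolutional VAE with the same reconstruction loss terms is
provided as the comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .autograd import Tensor, no_grad
from .errors import ConfigurationError, DimensionError
from .nn import (Conv2d, ConvTranspose2d, Linear, Module, Parameter,
                 ResidualBlock)

__all__ = [
    "ArchitectureConfig", "Codebook", "LatentBundle", "VqSvddModel",
    "BaselineVae", "nearest_codebook_indices", "quantize",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Shapes and widths of the network.

    Defaults are the full-scale settings (256x256 input, 64x64x128 latent
    map, 128x128 codebook); :meth:`tiny` gives the reduced benchmark
    configuration used for CPU-scale experiments on 64x64 phantoms.
    """

    input_size: int = 256
    latent_map_channels: int = 128     # D
    codebook_size: int = 128           # K
    svdd_latent_dim: int = 1024        # size of z(x)
    enc1_hidden: int = 64
    enc2_hidden: int = 64
    n_res_blocks: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 16 != 0:
            raise ConfigurationError("input_size must be divisible by 16 "
                                     "(two stride-2 stages per encoder)")
        if self.codebook_size < 2:
            raise ConfigurationError("codebook_size must be >= 2")
        h = self.latent_map_side
        if self.svdd_latent_dim >= h * h * self.latent_map_channels:
            raise ConfigurationError(
                "svdd_latent_dim must be smaller than the latent map")

    @property
    def latent_map_side(self) -> int:
        return self.input_size // 4

    @classmethod
    def tiny(cls, input_size: int = 64, seed: int = 0) -> "ArchitectureConfig":
        return cls(input_size=input_size, latent_map_channels=16,
                   codebook_size=32, svdd_latent_dim=256,
                   enc1_hidden=16, enc2_hidden=32, n_res_blocks=2, seed=seed)


class Codebook(Module):
    """K learnable D-dimensional embedding vectors with nearest lookup."""

    def __init__(self, n_entries: int, dim: int, rng: np.random.Generator):
        self.n_entries, self.dim = n_entries, dim
        lim = 1.0 / n_entries
        self.vectors = Parameter(rng.uniform(-lim, lim, (n_entries, dim)))


def nearest_codebook_indices(z: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Argmin_j ||z[..., :] - e_j||_2 per channel vector; ties -> smallest j.

    z has shape (..., D); returns integer indices of shape z.shape[:-1].
    """
    e = codebook.vectors.data
    if z.shape[-1] != e.shape[1]:
        raise DimensionError(
            f"channel dim {z.shape[-1]} does not match codebook dim {e.shape[1]}")
    flat = z.reshape(-1, e.shape[1])
    # ||z - e||^2 = ||z||^2 - 2 z.e + ||e||^2 ; argmin unaffected by ||z||^2
    d = -2.0 * flat @ e.T + (e**2).sum(axis=1)
    return np.argmin(d, axis=1).reshape(z.shape[:-1])


def quantize(z_d: np.ndarray, codebook: Codebook) -> tuple[np.ndarray, np.ndarray]:
    """Replace each channel vector by its nearest codebook entry.

    Accepts (H, W, D) or (N, H, W, D); returns (z_q, indices).
    """
    idx = nearest_codebook_indices(z_d, codebook)
    return codebook.vectors.data[idx], idx


@dataclass
class LatentBundle:
    """All intermediate representations of one forward pass.

    Latent maps are stored channels-last, (N, H, W, D); images (N, 1, H, W).
    ``e_sel`` is the differentiable gather of the selected codebook rows, so
    loss terms can route gradients to the codebook; ``z_q`` carries
    straight-through gradients to ``z_d``.
    """

    z_e: Tensor
    z: Optional[Tensor]
    z_d: Tensor
    z_q: Tensor
    e_sel: Tensor
    indices: np.ndarray
    xhat: Tensor
    bypass: bool


class _Encoder1(Module):
    def __init__(self, cfg: ArchitectureConfig, rng):
        w, d = cfg.enc1_hidden, cfg.latent_map_channels
        self.down1 = Conv2d(1, w, 4, 2, 1, rng)
        self.down2 = Conv2d(w, d, 4, 2, 1, rng)
        self.res = [ResidualBlock(d, rng) for _ in range(cfg.n_res_blocks)]

    def __call__(self, x: Tensor) -> Tensor:
        h = self.down2(self.down1(x).leaky_relu()).leaky_relu()
        for block in self.res:
            h = block(h)
        return h


class _Encoder2(Module):
    """Compresses the latent map to the SVDD latent vector z(x).

    No normalization layers and no output activation: the one-class latent
    space must stay unbounded, otherwise the hypersphere can shrink
    trivially through saturation.
    """

    def __init__(self, cfg: ArchitectureConfig, rng):
        d, w = cfg.latent_map_channels, cfg.enc2_hidden
        self.down1 = Conv2d(d, w, 4, 2, 1, rng)
        self.down2 = Conv2d(w, w, 4, 2, 1, rng)
        side = cfg.latent_map_side // 4
        self.flat_dim = w * side * side
        self.proj = Linear(self.flat_dim, cfg.svdd_latent_dim, rng)

    def __call__(self, z_e_nchw: Tensor) -> Tensor:
        h = self.down2(self.down1(z_e_nchw).leaky_relu()).leaky_relu()
        return self.proj(h.reshape(h.shape[0], self.flat_dim))


class _Decoder2(Module):
    def __init__(self, cfg: ArchitectureConfig, rng):
        d, w = cfg.latent_map_channels, cfg.enc2_hidden
        self.side = cfg.latent_map_side // 4
        self.w = w
        self.proj = Linear(cfg.svdd_latent_dim, w * self.side * self.side, rng)
        self.up1 = ConvTranspose2d(w, w, 4, 2, 1, rng)
        self.up2 = ConvTranspose2d(w, d, 4, 2, 1, rng)

    def __call__(self, z: Tensor) -> Tensor:
        h = self.proj(z).leaky_relu()
        h = h.reshape(h.shape[0], self.w, self.side, self.side)
        return self.up2(self.up1(h).leaky_relu())   # linear output: z_e space


class _Decoder1(Module):
    def __init__(self, cfg: ArchitectureConfig, rng):
        w, d = cfg.enc1_hidden, cfg.latent_map_channels
        self.res = [ResidualBlock(d, rng) for _ in range(cfg.n_res_blocks)]
        self.up1 = ConvTranspose2d(d, w, 4, 2, 1, rng)
        self.up2 = ConvTranspose2d(w, 1, 4, 2, 1, rng)

    def __call__(self, z_q: Tensor) -> Tensor:
        h = z_q
        for block in self.res:
            h = block(h)
        return self.up2(self.up1(h).leaky_relu()).sigmoid()


def _to_channels_last(t: Tensor) -> Tensor:
    return _transpose(t, (0, 2, 3, 1))


def _transpose(t: Tensor, axes: tuple[int, ...]) -> Tensor:
    inv = tuple(int(i) for i in np.argsort(axes))

    def bw(g):
        if t.requires_grad:
            t._accumulate(g.transpose(inv))

    return Tensor._make(t.data.transpose(axes), (t,), bw)


class VqSvddModel(Module):
    """The full network; ``forward`` returns a :class:`LatentBundle`."""

    def __init__(self, cfg: ArchitectureConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder1 = _Encoder1(cfg, rng)
        self.encoder2 = _Encoder2(cfg, rng)
        self.decoder2 = _Decoder2(cfg, rng)
        self.decoder1 = _Decoder1(cfg, rng)
        self.codebook = Codebook(cfg.codebook_size, cfg.latent_map_channels, rng)

    # parameter groups for the staged training
    def outer_parameters(self):
        yield from self.encoder1.parameters()
        yield from self.decoder1.parameters()
        yield from self.codebook.parameters()

    def forward(self, x: Tensor, bypass: bool = False) -> LatentBundle:
        if x.data.ndim != 4 or x.shape[1] != 1:
            raise DimensionError("expected input of shape (N, 1, H, W)")
        if x.shape[2] != self.cfg.input_size or x.shape[3] != self.cfg.input_size:
            raise DimensionError(
                f"expected {self.cfg.input_size}x{self.cfg.input_size} input, "
                f"got {x.shape[2]}x{x.shape[3]}")
        z_e_map = self.encoder1(x)                      # (N, D, H, W)
        z_e = _to_channels_last(z_e_map)                # (N, H, W, D)
        if bypass:
            z, z_d, z_d_map = None, z_e, z_e_map
        else:
            z = self.encoder2(z_e_map)                  # (N, dim)
            z_d_map = self.decoder2(z)                  # (N, D, H, W)
            z_d = _to_channels_last(z_d_map)
        indices = nearest_codebook_indices(z_d.data, self.codebook)
        e_sel = self.codebook.vectors.gather_rows(indices)   # (N, H, W, D)
        z_q = z_d + (e_sel.detach() - z_d.detach())          # straight-through
        z_q_map = _transpose(z_q, (0, 3, 1, 2))
        xhat = self.decoder1(z_q_map)
        return LatentBundle(z_e=z_e, z=z, z_d=z_d, z_q=z_q, e_sel=e_sel,
                            indices=indices, xhat=xhat, bypass=bypass)

    def encode_latent(self, x: np.ndarray) -> np.ndarray:
        """z(x) for a (N, H, W) or (H, W) stack, evaluation mode."""
        arr = np.asarray(x, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        with no_grad():
            return self.encoder2(self.encoder1(Tensor(arr[:, None]))).data

    def reconstruct(self, x: np.ndarray, bypass: bool = False) -> np.ndarray:
        """Reconstructions for a (N, H, W) or (H, W) stack, evaluation mode."""
        arr = np.asarray(x, dtype=np.float64)
        squeeze = arr.ndim == 2
        if squeeze:
            arr = arr[None]
        with no_grad():
            out = self.forward(Tensor(arr[:, None]), bypass=bypass).xhat.data
        out = out[:, 0]
        return out[0] if squeeze else out


class BaselineVae(Module):
    """Plain convolutional VAE baseline with a diagonal-Gaussian latent."""

    def __init__(self, cfg: ArchitectureConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed + 1)
        w = cfg.enc1_hidden
        w2 = cfg.enc2_hidden
        self.down1 = Conv2d(1, w, 4, 2, 1, rng)
        self.down2 = Conv2d(w, w, 4, 2, 1, rng)
        self.down3 = Conv2d(w, w2, 4, 2, 1, rng)
        side = cfg.input_size // 8
        self.flat_dim = w2 * side * side
        self.side, self.w2 = side, w2
        self.to_mu = Linear(self.flat_dim, cfg.svdd_latent_dim, rng)
        self.to_logvar = Linear(self.flat_dim, cfg.svdd_latent_dim, rng)
        self.proj = Linear(cfg.svdd_latent_dim, self.flat_dim, rng)
        self.up1 = ConvTranspose2d(w2, w, 4, 2, 1, rng)
        self.up2 = ConvTranspose2d(w, w, 4, 2, 1, rng)
        self.up3 = ConvTranspose2d(w, 1, 4, 2, 1, rng)

    def forward(self, x: Tensor, sample: bool = False,
                rng: np.random.Generator | None = None
                ) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (xhat, mu, logvar); sampling only when ``sample=True``."""
        h = self.down3(self.down2(self.down1(x).leaky_relu()).leaky_relu()).leaky_relu()
        h = h.reshape(h.shape[0], self.flat_dim)
        mu, logvar = self.to_mu(h), self.to_logvar(h)
        if sample:
            if rng is None:
                raise ConfigurationError("sampling requires a Generator")
            eps = Tensor(rng.standard_normal(mu.shape))
            z = mu + (logvar * 0.5).exp() * eps
        else:
            z = mu
        g = self.proj(z).leaky_relu().reshape(x.shape[0], self.w2, self.side,
                                              self.side)
        xhat = self.up3(self.up2(self.up1(g).leaky_relu()).leaky_relu()).sigmoid()
        return xhat, mu, logvar

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        arr = np.asarray(x, dtype=np.float64)
        squeeze = arr.ndim == 2
        if squeeze:
            arr = arr[None]
        with no_grad():
            out = self.forward(Tensor(arr[:, None]), sample=False)[0].data
        out = out[:, 0]
        return out[0] if squeeze else out


def kl_to_standard_normal(mu: Tensor, logvar: Tensor) -> Tensor:
    """KL( N(mu, diag(exp(logvar))) || N(0, I) ), mean over the batch."""
    per_element = 0.5 * (mu * mu + logvar.exp() - logvar - 1.0)
    return per_element.sum() * (1.0 / mu.shape[0])


def save_checkpoint(model: Module, path: str | Path,
                    extra: dict | None = None) -> None:
    """Single-file .npz checkpoint with the config embedded."""
    import json

    arrays = model.state_arrays()
    meta = {"class": type(model).__name__,
            "config": getattr(model, "cfg").__dict__}
    if extra:
        meta.update(extra)
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[Module, dict]:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = ArchitectureConfig(**meta["config"])
        cls = {"VqSvddModel": VqSvddModel, "BaselineVae": BaselineVae}[meta["class"]]
        model = cls(cfg)
        model.load_state_arrays({k: data[k] for k in data.files
                                 if k != "__meta__"})
    return model, meta
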