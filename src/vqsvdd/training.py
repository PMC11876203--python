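"""Three-stage training of the quantized autoencoder with the one-class term.

Stage 1 trains only the outer autoencoder (Encoder 1, Decoder 1) and the
codebook, with the inner pair bypassed.  Stage 2 adds Encoder 2 / Decoder 2
and a latent-consistency term but no one-class term; the hypersphere center
is then initialized as the mean inner latent over the training slices.
Stage 3 trains the whole network with the one-class distance added, and the
center is recomputed every epoch from that epoch's latents.

Loss terms (per batch, each a mean over images of per-image sums):

    recon_l2     = ||x - xhat||_2^2
    msssim_term  = 1 - MS-SSIM(x, xhat)
    codebook     = ||sg[z_d] - e||_2^2      (updates the codebook only)
    commit       = lambda * ||z_d - sg[e]||_2^2   (updates the encoder only)
    consistency  = ||z_e - z_d||_2^2        (stages 2-3)
    svdd         = ||z - c||_2^2            (stage 3)

sg is the stop-gradient operator; in stage 1 z_d is identically z_e.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .autograd import Tensor
from .errors import ConfigurationError, StateError
from .metrics import MsSsimParams, ms_ssim_tensor
from .model import (ArchitectureConfig, BaselineVae, LatentBundle,
                    VqSvddModel, kl_to_standard_normal)
from .nn import Adam
from .phantom import ExamVolume

__all__ = [
    "TrainConfig", "HypersphereState", "LossBreakdown", "TrainResult",
    "loss_step1", "loss_step2", "loss_step3",
    "initialize_center", "update_center", "train", "train_baseline_vae",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow full-scale practice."""

    batch_size: int = 64
    learning_rate: float = 1e-4
    max_epochs: int = 200              # per stage
    lambda_commit: float = 0.25
    seed: int = 0
    # optional per-stage override of learning_rate, (stage1, stage2, stage3)
    stage_learning_rates: tuple[float, float, float] | None = None
    msssim: MsSsimParams = field(default_factory=MsSsimParams)

    def __post_init__(self):
        if self.lambda_commit <= 0:
            raise ConfigurationError("lambda_commit must be > 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")

    def lr_for_stage(self, stage: int) -> float:
        if self.stage_learning_rates is not None:
            return self.stage_learning_rates[stage - 1]
        return self.learning_rate


@dataclass
class HypersphereState:
    """Center of the one-class hypersphere plus epoch bookkeeping."""

    center: np.ndarray | None = None
    n_updates: int = 0

    @property
    def initialized(self) -> bool:
        return self.center is not None


@dataclass(frozen=True)
class LossBreakdown:
    """Scalar loss terms; inactive terms are None; total is the exact sum."""

    recon_l2: float
    msssim_term: float
    codebook_term: float
    commit_term: float                  # already lambda-weighted
    consistency_term: float | None = None
    svdd_term: float | None = None

    @property
    def total(self) -> float:
        return sum(v for v in (self.recon_l2, self.msssim_term,
                               self.codebook_term, self.commit_term,
                               self.consistency_term, self.svdd_term)
                   if v is not None)


def _sq_norm_per_image(t: Tensor) -> Tensor:
    """Mean over the batch of the per-image summed square."""
    n = t.shape[0]
    return (t * t).sum() * (1.0 / n)


def _common_terms(x: Tensor, bundle: LatentBundle, lam: float,
                  msssim: MsSsimParams) -> dict[str, Tensor]:
    recon = _sq_norm_per_image(x - bundle.xhat)
    ms = ms_ssim_tensor(x, bundle.xhat, msssim).mean()
    codebook = _sq_norm_per_image(bundle.z_d.detach() - bundle.e_sel)
    commit = _sq_norm_per_image(bundle.z_d - bundle.e_sel.detach()) * lam
    return {"recon_l2": recon, "msssim_term": 1.0 - ms,
            "codebook_term": codebook, "commit_term": commit}


def loss_step1(x: Tensor, bundle: LatentBundle,
               lam: float = 0.25,
               msssim: MsSsimParams = MsSsimParams()
               ) -> tuple[Tensor, LossBreakdown]:
    """Stage-1 loss (outer autoencoder + codebook, bypass mode)."""
    if not bundle.bypass:
        raise ConfigurationError("stage-1 loss expects a bypass-mode bundle")
    t = _common_terms(x, bundle, lam, msssim)
    total = t["recon_l2"] + t["msssim_term"] + t["codebook_term"] + t["commit_term"]
    return total, LossBreakdown(*(v.item() for v in t.values()))


def loss_step2(x: Tensor, bundle: LatentBundle,
               lam: float = 0.25,
               msssim: MsSsimParams = MsSsimParams()
               ) -> tuple[Tensor, LossBreakdown]:
    """Stage-2 loss: stage-1 terms on z_d plus latent consistency."""
    if bundle.bypass:
        raise ConfigurationError("stage-2 loss expects a full forward pass")
    t = _common_terms(x, bundle, lam, msssim)
    consistency = _sq_norm_per_image(bundle.z_e - bundle.z_d)
    total = (t["recon_l2"] + t["msssim_term"] + t["codebook_term"]
             + t["commit_term"] + consistency)
    return total, LossBreakdown(*(v.item() for v in t.values()),
                                consistency_term=consistency.item())


def loss_step3(x: Tensor, bundle: LatentBundle, sphere: HypersphereState,
               lam: float = 0.25,
               msssim: MsSsimParams = MsSsimParams()
               ) -> tuple[Tensor, LossBreakdown]:
    """Stage-3 loss: stage-2 terms plus the one-class distance ||z - c||^2.

    The center is data, not a trainable weight: it enters as a constant.
    """
    if not sphere.initialized:
        raise StateError("hypersphere center is not initialized")
    if bundle.z is None:
        raise ConfigurationError("stage-3 loss expects a full forward pass")
    t = _common_terms(x, bundle, lam, msssim)
    consistency = _sq_norm_per_image(bundle.z_e - bundle.z_d)
    svdd = _sq_norm_per_image(bundle.z - Tensor(sphere.center))
    total = (t["recon_l2"] + t["msssim_term"] + t["codebook_term"]
             + t["commit_term"] + consistency + svdd)
    return total, LossBreakdown(*(v.item() for v in t.values()),
                                consistency_term=consistency.item(),
                                svdd_term=svdd.item())


def _training_slices(volumes: Sequence[ExamVolume]) -> np.ndarray:
    for v in volumes:
        if v.label != "normal":
            raise ConfigurationError(
                f"abnormal case {v.case_id} in a one-class training set")
    return np.concatenate([v.slices for v in volumes], axis=0)


def initialize_center(model: VqSvddModel,
                      volumes: Sequence[ExamVolume],
                      batch_size: int = 64) -> HypersphereState:
    """Center = mean inner latent z(x) over all training slices."""
    slices = _training_slices(volumes)
    if slices.shape[0] == 0:
        raise ConfigurationError("empty training set")
    total = np.zeros(model.cfg.svdd_latent_dim)
    for i in range(0, slices.shape[0], batch_size):
        total += model.encode_latent(slices[i:i + batch_size]).sum(axis=0)
    return HypersphereState(center=total / slices.shape[0], n_updates=0)


def update_center(sphere: HypersphereState,
                  epoch_latents: np.ndarray) -> HypersphereState:
    """Replace the center by the mean of this epoch's latents."""
    if epoch_latents.size == 0:
        warnings.warn("no latents collected this epoch; center unchanged",
                      stacklevel=2)
        return HypersphereState(center=sphere.center,
                                n_updates=sphere.n_updates)
    return HypersphereState(center=epoch_latents.mean(axis=0),
                            n_updates=sphere.n_updates + 1)


@dataclass
class TrainResult:
    model: VqSvddModel
    sphere: HypersphereState
    history: list[dict]

    def history_for(self, stage: int) -> list[dict]:
        return [h for h in self.history if h["stage"] == stage]


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train(volumes: Sequence[ExamVolume], arch: ArchitectureConfig,
          cfg: TrainConfig,
          validation_volumes: Sequence[ExamVolume] = ()) -> TrainResult:
    """Run the full three-stage protocol on normal volumes only.

    Each stage gets a fresh Adam state; stages 2 and 3 start from the
    weights the previous stage left behind.  The per-epoch history records
    the mean loss terms and, in stage 3, one center update per epoch.
    """
    slices = _training_slices(volumes)
    model = VqSvddModel(arch)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    msp = cfg.msssim

    def run_stage(stage: int, params: Iterable, sphere: HypersphereState | None):
        opt = Adam(params, lr=cfg.lr_for_stage(stage))
        for epoch in range(cfg.max_epochs):
            terms_acc: dict[str, float] = {}
            nb = 0
            epoch_latents: list[np.ndarray] = []
            for idx in _batches(slices.shape[0], cfg.batch_size, rng):
                x = Tensor(slices[idx][:, None])
                bundle = model.forward(x, bypass=(stage == 1))
                if stage == 1:
                    total, bd = loss_step1(x, bundle, cfg.lambda_commit, msp)
                elif stage == 2:
                    total, bd = loss_step2(x, bundle, cfg.lambda_commit, msp)
                else:
                    total, bd = loss_step3(x, bundle, sphere,
                                           cfg.lambda_commit, msp)
                    epoch_latents.append(bundle.z.data.copy())
                opt.zero_grad()
                total.backward()
                opt.step()
                nb += 1
                for k, v in vars(bd).items():
                    if v is not None:
                        terms_acc[k] = terms_acc.get(k, 0.0) + v
            row = {"stage": stage, "epoch": epoch,
                   **{k: v / nb for k, v in terms_acc.items()}}
            row["total"] = sum(v / nb for v in terms_acc.values())
            if stage == 3:
                sphere = update_center(sphere, np.concatenate(epoch_latents)
                                       if epoch_latents else np.empty((0, 0)))
                row["center_updates"] = sphere.n_updates
            if validation_volumes:
                row["val_recon"] = _validation_recon(model, validation_volumes,
                                                     stage, cfg)
            history.append(row)
        return sphere

    run_stage(1, model.outer_parameters(), None)
    run_stage(2, model.parameters(), None)
    sphere = (initialize_center(model, volumes, cfg.batch_size)
              if cfg.max_epochs > 0 else HypersphereState())
    if cfg.max_epochs > 0:
        sphere = run_stage(3, model.parameters(), sphere)
    return TrainResult(model=model, sphere=sphere, history=history)


def _validation_recon(model: VqSvddModel, volumes: Sequence[ExamVolume],
                      stage: int, cfg: TrainConfig) -> float:
    err, count = 0.0, 0
    for v in volumes:
        xhat = model.reconstruct(v.slices, bypass=(stage == 1))
        err += float(((v.slices - xhat) ** 2).sum())
        count += v.n_slices
    return err / max(count, 1)


def train_baseline_vae(volumes: Sequence[ExamVolume], arch: ArchitectureConfig,
                       cfg: TrainConfig) -> BaselineVae:
    """Train the plain-VAE comparator: L2 + (1 - MS-SSIM) + KL, one stage."""
    slices = _training_slices(volumes)
    model = BaselineVae(arch)
    rng = np.random.default_rng(cfg.seed + 7)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    for _ in range(cfg.max_epochs):
        for idx in _batches(slices.shape[0], cfg.batch_size, rng):
            x = Tensor(slices[idx][:, None])
            xhat, mu, logvar = model.forward(x, sample=True, rng=rng)
            recon = _sq_norm_per_image(x - xhat)
            ms = ms_ssim_tensor(x, xhat, cfg.msssim).mean()
            total = recon + (1.0 - ms) + kl_to_standard_normal(mu, logvar)
            opt.zero_grad()
            total.backward()
            opt.step()
    return model
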