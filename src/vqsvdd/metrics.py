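"""Structural-similarity metrics: single-scale SSIM components, MS-SSIM and
the reconstruction-fidelity record (RMSE / PSNR / SSIM).

All statistics are windowed: means, variances and the covariance are taken
over a sliding window (Gaussian 11x11, sigma 1.5 by default), the component
maps are then averaged over all valid window positions.  The stabilization
constants default to delta1=1e-4, delta2=9e-4, delta3=4.5e-4, i.e. the
standard SSIM constants for images on a [0, 1] dynamic range.

The multi-scale index is

    MS-SSIM(x, y) = L_M^alpha * prod_{j=0..M} C_j^beta * S_j^gamma

where scale j is obtained by j successive 2x2 average-pool halvings and the
luminance term L is evaluated at the coarsest scale only.  Two structure
terms are available: ``standard`` is the covariance-normalized form
S = (sigma_xy + d3) / (sigma_x sigma_y + d3); ``literal`` divides by
(sigma_x + sigma_y + d3) instead, a printed variant kept for comparison.

Everything is implemented on autodiff tensors, so the same code path that
evaluates the metric also provides gradients when MS-SSIM appears inside a
training loss.  The public functions accept plain numpy arrays and return
floats.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Literal, NamedTuple

import numpy as np

from .autograd import Tensor, no_grad
from .errors import ConfigurationError, DimensionError

__all__ = [
    "MsSsimParams", "SsimComponents", "FidelityRecord",
    "ssim_components", "ms_ssim", "fidelity",
    "ms_ssim_tensor", "ssim_tensor",
]


@dataclass(frozen=True)
class MsSsimParams:
    """Parameters of the (multi-scale) structural-similarity index."""

    delta1: float = 1e-4
    delta2: float = 9e-4
    delta3: float = 4.5e-4
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    M: int = 5
    window: Literal["gaussian", "uniform"] = "gaussian"
    window_size: int = 11
    window_sigma: float = 1.5
    structure_form: Literal["standard", "literal"] = "standard"

    def __post_init__(self):
        if min(self.delta1, self.delta2, self.delta3) <= 0:
            raise ConfigurationError("stabilization constants must be > 0")
        if self.M < 0:
            raise ConfigurationError("M must be >= 0")
        if self.window_size % 2 == 0 or self.window_size < 1:
            raise ConfigurationError("window size must be odd and positive")


def _window_kernel(params: MsSsimParams) -> np.ndarray:
    """1-D window profile; the 2-D window is its separable outer product."""
    k = params.window_size
    if params.window == "uniform":
        return np.full(k, 1.0 / k)
    ax = np.arange(k) - (k - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * params.window_sigma**2))
    return g / g.sum()


def _filter(x: Tensor, kernel1d: np.ndarray) -> Tensor:
    """Valid-mode separable window filter on (N, C, H, W) tensors.

    The window is symmetric, so the adjoint of the valid-mode correlation
    is the same correlation applied to the zero-padded gradient.
    """
    from scipy.ndimage import correlate1d

    r = len(kernel1d) // 2

    data = correlate1d(x.data, kernel1d, axis=2, mode="constant")
    data = correlate1d(data, kernel1d, axis=3, mode="constant")
    data = data[:, :, r:x.shape[2] - r, r:x.shape[3] - r]

    def bw(g):
        if not x.requires_grad:
            return
        padded = np.zeros_like(x.data)
        padded[:, :, r:x.shape[2] - r, r:x.shape[3] - r] = g
        dx = correlate1d(padded, kernel1d, axis=2, mode="constant")
        dx = correlate1d(dx, kernel1d, axis=3, mode="constant")
        x._accumulate(dx)

    return Tensor._make(np.ascontiguousarray(data), (x,), bw)


def _component_maps(x: Tensor, y: Tensor, kernel: np.ndarray,
                    params: MsSsimParams):
    mx = _filter(x, kernel)
    my = _filter(y, kernel)
    vx = (_filter(x * x, kernel) - mx * mx).relu()
    vy = (_filter(y * y, kernel) - my * my).relu()
    cxy = _filter(x * y, kernel) - mx * my
    sx = vx.sqrt()
    sy = vy.sqrt()
    d1, d2, d3 = params.delta1, params.delta2, params.delta3
    lum = (2.0 * mx * my + d1) / (mx * mx + my * my + d1)
    con = (2.0 * sx * sy + d2) / (vx + vy + d2)
    if params.structure_form == "standard":
        struct = (cxy + d3) / (sx * sy + d3)
    else:
        struct = (2.0 * cxy + d3) / (sx + sy + d3)
    return lum, con, struct


def _check_pair(x: Tensor, y: Tensor) -> None:
    if x.shape != y.shape:
        raise DimensionError(f"image shapes differ: {x.shape} vs {y.shape}")


class SsimComponents(NamedTuple):
    luminance: np.ndarray | float
    contrast: np.ndarray | float
    structure: np.ndarray | float


def _as_batch(img: np.ndarray) -> Tensor:
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2:
        raise DimensionError("expected a 2-D grayscale image")
    return Tensor(a[None, None])


def ssim_components(x: np.ndarray, xhat: np.ndarray,
                    params: MsSsimParams = MsSsimParams()) -> SsimComponents:
    """Windowed-average luminance, contrast and structure terms."""
    tx, ty = _as_batch(x), _as_batch(xhat)
    _check_pair(tx, ty)
    if min(tx.shape[2:]) < params.window_size:
        raise DimensionError("image smaller than the comparison window")
    with no_grad():
        lum, con, struct = _component_maps(tx, ty, _window_kernel(params), params)
        return SsimComponents(float(lum.mean().item()),
                              float(con.mean().item()),
                              float(struct.mean().item()))


def effective_scales(side: int, params: MsSsimParams) -> int:
    """Largest usable M: the coarsest scale must still fit one window."""
    m = params.M
    while m > 0 and (side >> m) < params.window_size:
        m -= 1
    if (side >> m) < params.window_size:
        raise DimensionError(
            f"image side {side} below window size {params.window_size}")
    return m


def ms_ssim_tensor(x: Tensor, y: Tensor,
                   params: MsSsimParams = MsSsimParams()) -> Tensor:
    """Differentiable MS-SSIM on (N, 1, H, W) batches; returns (N,) tensor."""
    _check_pair(x, y)
    side = min(x.shape[2], x.shape[3])
    m = effective_scales(side, params)
    if m < params.M:
        warnings.warn(
            f"MS-SSIM scales reduced from M={params.M} to M={m} for "
            f"{x.shape[2]}x{x.shape[3]} input", stacklevel=2)
        params = replace(params, M=m)
    kernel = _window_kernel(params)
    result: Tensor | None = None
    for j in range(params.M + 1):
        lum, con, struct = _component_maps(x, y, kernel, params)
        # scalar C_j and S_j are the windowed averages; the index is the
        # product of the averaged components across scales
        cs = (con.mean(axis=(1, 2, 3)) ** params.beta
              * struct.mean(axis=(1, 2, 3)) ** params.gamma)
        result = cs if result is None else result * cs
        if j == params.M:
            result = result * lum.mean(axis=(1, 2, 3)) ** params.alpha
        else:
            x = x.avg_pool2d()
            y = y.avg_pool2d()
    assert result is not None
    return result


def ms_ssim(x: np.ndarray, xhat: np.ndarray,
            params: MsSsimParams = MsSsimParams()) -> float:
    """Multi-scale structural similarity of two 2-D images in [0, 1]."""
    with no_grad():
        return float(ms_ssim_tensor(_as_batch(x), _as_batch(xhat), params)
                     .data[0])


def ssim_tensor(x: Tensor, y: Tensor,
                params: MsSsimParams = MsSsimParams()) -> Tensor:
    """Single-scale SSIM (mean of L*C*S maps) on (N, 1, H, W) batches."""
    _check_pair(x, y)
    lum, con, struct = _component_maps(x, y, _window_kernel(params), params)
    return (lum * con * struct).mean(axis=(1, 2, 3))


@dataclass(frozen=True)
class FidelityRecord:
    rmse: float
    psnr: float
    ssim: float


def fidelity(x: np.ndarray, xhat: np.ndarray,
             params: MsSsimParams = MsSsimParams()) -> FidelityRecord:
    """Reconstruction fidelity for images on a [0, 1] dynamic range.

    rmse is the root of the mean squared pixel difference, psnr is
    20*log10(1/rmse) in dB (+inf for identical images), ssim the
    single-scale structural similarity.
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(xhat, dtype=np.float64)
    if xa.shape != ya.shape:
        raise DimensionError(f"image shapes differ: {xa.shape} vs {ya.shape}")
    rmse = float(np.sqrt(np.mean((xa - ya) ** 2)))
    psnr = math.inf if rmse == 0.0 else 20.0 * math.log10(1.0 / rmse)
    with no_grad():
        ssim = float(ssim_tensor(_as_batch(xa), _as_batch(ya), params).data[0])
    return FidelityRecord(rmse=rmse, psnr=psnr, ssim=ssim)
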