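"""Anomaly scoring, ROC / Youden analysis and cross-validation reporting.

A slice's anomaly score is

    S(x) = ||x - xhat||_2^2 + ||z(x) - c||_2^2

i.e. squared reconstruction error plus squared distance of the inner latent
from the hypersphere center (unit weights; a weight on the one-class term
is exposed for experimentation).  An examinee's representative score is the
maximum over their slices; the classification threshold maximizes the
Youden index J = sensitivity + specificity - 1 over the representative
scores, with "abnormal" the positive class and strict ``score > threshold``
calling a case abnormal.  Note the threshold is fit on the same scores it
classifies (in-sample threshold), matching the screening-evaluation design
this package follows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as skmetrics

from .errors import ConfigurationError, DimensionError
from .metrics import FidelityRecord, MsSsimParams, fidelity
from .model import BaselineVae, VqSvddModel
from .phantom import ExamVolume
from .training import HypersphereState

__all__ = [
    "SliceScore", "FoldMetrics", "EvalReport",
    "anomaly_score", "score_volume", "representative_score",
    "roc_auc", "youden_threshold", "fidelity_comparison",
    "evaluate_fold", "evaluate_cv", "paired_t",
]


@dataclass(frozen=True)
class SliceScore:
    case_id: str
    slice_index: int
    recon_term: float
    svdd_term: float

    @property
    def total(self) -> float:
        return self.recon_term + self.svdd_term


def anomaly_score(x: np.ndarray, xhat: np.ndarray, z: np.ndarray,
                  c: np.ndarray, case_id: str = "", slice_index: int = 0,
                  svdd_weight: float = 1.0) -> SliceScore:
    """S(x) for one slice; shapes of (x, xhat) and (z, c) must match."""
    x, xhat = np.asarray(x, float), np.asarray(xhat, float)
    z, c = np.asarray(z, float).ravel(), np.asarray(c, float).ravel()
    if x.shape != xhat.shape:
        raise DimensionError(f"image shapes differ: {x.shape} vs {xhat.shape}")
    if z.shape != c.shape:
        raise DimensionError(f"latent shapes differ: {z.shape} vs {c.shape}")
    return SliceScore(case_id=case_id, slice_index=slice_index,
                      recon_term=float(((x - xhat) ** 2).sum()),
                      svdd_term=float(svdd_weight * ((z - c) ** 2).sum()))


def score_volume(model: VqSvddModel, sphere: HypersphereState,
                 volume: ExamVolume, svdd_weight: float = 1.0,
                 batch_size: int = 64) -> list[SliceScore]:
    """Slice scores for one examinee, evaluation mode."""
    scores: list[SliceScore] = []
    for i in range(0, volume.n_slices, batch_size):
        batch = volume.slices[i:i + batch_size]
        xhat = model.reconstruct(batch)
        z = model.encode_latent(batch)
        for j in range(batch.shape[0]):
            scores.append(anomaly_score(batch[j], xhat[j], z[j], sphere.center,
                                        case_id=volume.case_id,
                                        slice_index=i + j,
                                        svdd_weight=svdd_weight))
    return scores


def representative_score(scores: Sequence[SliceScore]) -> float:
    """The examinee-level score: maximum slice score."""
    if not scores:
        raise ConfigurationError("no slice scores for this examinee")
    return max(s.total for s in scores)


def _check_two_class(labels: np.ndarray) -> None:
    if labels.all() or (~labels).all():
        raise ConfigurationError("ROC analysis needs both classes present")


def roc_auc(scores: Sequence[float], labels: Sequence[bool]
            ) -> tuple[float, np.ndarray]:
    """AUC (trapezoidal / Mann-Whitney with half-credit ties) and ROC points.

    Returns (auc, curve) with curve rows (fpr, tpr).
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    _check_two_class(y)
    fpr, tpr, _ = skmetrics.roc_curve(y.astype(int), s)
    return float(skmetrics.auc(fpr, tpr)), np.column_stack([fpr, tpr])


def youden_threshold(scores: Sequence[float], labels: Sequence[bool]
                     ) -> tuple[float, float, float, float]:
    """(threshold, sensitivity, specificity, accuracy) maximizing J.

    Candidates are midpoints between consecutive distinct sorted scores
    plus one candidate below the minimum and one above the maximum; a case
    is called abnormal when score > threshold.  Ties in J are broken toward
    higher specificity (then the higher threshold).
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    _check_two_class(y)
    distinct = np.unique(s)
    candidates = [distinct[0] - 1.0]
    candidates += list((distinct[:-1] + distinct[1:]) / 2.0)
    candidates.append(distinct[-1] + 1.0)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    best = None
    for thr in candidates:
        pred = s > thr
        sens = float((pred & y).sum() / n_pos)
        spec = float((~pred & ~y).sum() / n_neg)
        j = sens + spec - 1.0
        key = (j, spec, thr)
        if best is None or key > best[0]:
            acc = float((pred == y).mean())
            best = (key, thr, sens, spec, acc)
    return best[1], best[2], best[3], best[4]


@dataclass(frozen=True)
class FidelitySummary:
    n_slices: int
    rmse_mean: float
    rmse_sd: float
    psnr_mean: float
    psnr_sd: float
    ssim_mean: float
    ssim_sd: float

    @staticmethod
    def from_records(records: Sequence[FidelityRecord]) -> "FidelitySummary":
        if not records:
            return FidelitySummary(0, *(float("nan"),) * 6)
        rmse = np.array([r.rmse for r in records])
        psnr = np.array([r.psnr for r in records])
        ssim = np.array([r.ssim for r in records])
        finite = psnr[np.isfinite(psnr)]
        # identical reconstructions yield +inf PSNR; summarize finite values
        psnr_mean = float(finite.mean()) if finite.size else float("inf")
        psnr_sd = float(finite.std()) if finite.size else 0.0
        return FidelitySummary(
            len(records),
            float(rmse.mean()), float(rmse.std()),
            psnr_mean, psnr_sd,
            float(ssim.mean()), float(ssim.std()))


def fidelity_comparison(volumes: Sequence[ExamVolume], reconstruct,
                        msssim: MsSsimParams = MsSsimParams()
                        ) -> dict[str, FidelitySummary]:
    """Per-slice fidelity pooled into normal vs abnormal groups.

    The normal group holds every slice of normal cases; the abnormal group
    holds only the flagged (lesion-bearing) slices of abnormal cases.
    ``reconstruct`` maps a (S, H, W) stack to its reconstructions.
    """
    import warnings as _w

    normal: list[FidelityRecord] = []
    abnormal: list[FidelityRecord] = []
    for v in volumes:
        xhat = reconstruct(v.slices)
        for s in range(v.n_slices):
            rec = fidelity(v.slices[s], xhat[s], msssim)
            if v.label == "normal":
                normal.append(rec)
            elif v.anomaly_slice_flags[s]:
                abnormal.append(rec)
    if any(v.label == "abnormal" for v in volumes) and not abnormal:
        _w.warn("abnormal volumes present but no flagged slices; "
                "abnormal fidelity group is empty", stacklevel=2)
    return {"normal": FidelitySummary.from_records(normal),
            "abnormal": FidelitySummary.from_records(abnormal)}


@dataclass(frozen=True)
class FoldMetrics:
    """Screening metrics of one cross-validation fold."""

    fold_id: int
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    fidelity: dict = field(default_factory=dict)

    def as_vector(self) -> dict[str, float]:
        return {"auc": self.auc, "accuracy": self.accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity}


def evaluate_fold(model: VqSvddModel, sphere: HypersphereState,
                  test_volumes: Sequence[ExamVolume], fold_id: int = 0,
                  svdd_weight: float = 1.0,
                  msssim: MsSsimParams = MsSsimParams()) -> FoldMetrics:
    """Representative-score screening metrics on one fold's test cases."""
    reps, labels = [], []
    for v in test_volumes:
        reps.append(representative_score(
            score_volume(model, sphere, v, svdd_weight)))
        labels.append(v.label == "abnormal")
    auc, _ = roc_auc(reps, labels)
    thr, sens, spec, acc = youden_threshold(reps, labels)
    fid = fidelity_comparison(test_volumes, model.reconstruct, msssim)
    return FoldMetrics(fold_id=fold_id, auc=auc, accuracy=acc,
                       sensitivity=sens, specificity=spec, threshold=thr,
                       fidelity={k: vars(s) for k, s in fid.items()})


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test; returns (t, p) with df = n - 1.

    All-zero differences give (0.0, 1.0) rather than an undefined statistic.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise DimensionError("paired samples must have equal length")
    if np.allclose(a - b, 0.0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass(frozen=True)
class EvalReport:
    """Cross-validation aggregate: per-fold metrics, means +/- SD, p-values."""

    proposed: tuple[FoldMetrics, ...]
    comparator: tuple[FoldMetrics, ...] | None
    summary: dict
    p_values: dict

    def to_dict(self) -> dict:
        return {
            "threshold_convention": "in-sample Youden threshold",
            "proposed": [vars(m) for m in self.proposed],
            "comparator": ([vars(m) for m in self.comparator]
                           if self.comparator else None),
            "summary": self.summary,
            "p_values": self.p_values,
        }


def evaluate_cv(proposed: Sequence[FoldMetrics],
                comparator: Sequence[FoldMetrics] | None = None) -> EvalReport:
    """Aggregate fold metrics and compare models with paired t-tests."""
    if comparator is not None and len(comparator) != len(proposed):
        raise ConfigurationError("fold count mismatch between models")
    names = ("auc", "accuracy", "sensitivity", "specificity")
    summary: dict = {}
    for label, group in (("proposed", proposed), ("comparator", comparator)):
        if group is None:
            continue
        summary[label] = {}
        for name in names:
            vals = np.array([m.as_vector()[name] for m in group])
            summary[label][name] = {"mean": float(vals.mean()),
                                    "sd": float(vals.std(ddof=1))
                                    if len(vals) > 1 else 0.0}
    p_values: dict = {}
    if comparator is not None:
        for name in names:
            a = [m.as_vector()[name] for m in proposed]
            b = [m.as_vector()[name] for m in comparator]
            t, p = paired_t(a, b)
            p_values[name] = {"t": t, "p": p, "df": len(proposed) - 1}
    return EvalReport(proposed=tuple(proposed),
                      comparator=tuple(comparator) if comparator else None,
                      summary=summary, p_values=p_values)
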