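"""Reconstruction quality metrics: SSIM, NRMSE, PSNR and dataset summaries.

SSIM uses the conventional windowed definition (11x11 Gaussian window,
sigma 1.5, stabilizers (0.01 L)^2 and (0.03 L)^2) with a fixed dynamic
range L = 70, the permittivity design span 80 - 10, so scores are
comparable across cases. NRMSE is RMSE over the reference's value range;
PSNR is 20 log10(range / RMSE) in dB, capped at 100 dB for identical
images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

#: permittivity design span (80 - 10), the default SSIM dynamic range
DEFAULT_DATA_RANGE = 70.0

PSNR_CAP_DB = 100.0


class MetricInputError(ValueError):
    pass


def _check_pair(image: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(image, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise MetricInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def ssim(
    image: np.ndarray, reference: np.ndarray, data_range: float = DEFAULT_DATA_RANGE
) -> float:
    """Mean structural similarity over Gaussian-weighted 11x11 windows."""
    a, b = _check_pair(image, reference)
    return float(
        structural_similarity(
            a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03,
        )
    )


def nrmse(image: np.ndarray, reference: np.ndarray) -> float:
    """RMSE normalized by the reference's value range (max - min)."""
    a, b = _check_pair(image, reference)
    span = float(b.max() - b.min())
    if span <= 0:
        raise MetricInputError("constant reference: NRMSE undefined")
    return float(np.sqrt(np.mean((a - b) ** 2)) / span)


def psnr(
    image: np.ndarray, reference: np.ndarray, cap_db: float = PSNR_CAP_DB
) -> float:
    """Peak signal-to-noise ratio, 20 log10(range / RMSE), in dB."""
    a, b = _check_pair(image, reference)
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    span = float(b.max() - b.min())
    if rmse == 0.0:
        return cap_db
    return min(float(20 * np.log10(span / rmse)), cap_db)


@dataclass(frozen=True)
class EvalRecord:
    case_id: str
    ssim: float
    nrmse: float
    psnr: float


@dataclass(frozen=True)
class EvalSummary:
    """Mean/std and acceptable-value proportions per metric."""

    n_cases: int
    ssim_mean: float
    ssim_std: float
    ssim_above_09: float
    nrmse_mean: float
    nrmse_std: float
    nrmse_below_02: float
    psnr_mean: float
    psnr_std: float
    psnr_above_30: float


def evaluate_case(
    case_id: str, prediction: np.ndarray, reference: np.ndarray
) -> EvalRecord:
    return EvalRecord(
        case_id=case_id,
        ssim=ssim(prediction, reference),
        nrmse=nrmse(prediction, reference),
        psnr=psnr(prediction, reference),
    )


def summarize(records: list[EvalRecord]) -> EvalSummary:
    """Dataset summary: means, sample std (ddof=1), threshold proportions.

    Thresholds follow the accepted-quality baselines: SSIM > 0.9,
    NRMSE < 0.2, PSNR > 30 dB.
    """
    if not records:
        raise MetricInputError("summarize needs at least one record")
    s = np.array([r.ssim for r in records])
    e = np.array([r.nrmse for r in records])
    p = np.array([r.psnr for r in records])
    std = lambda v: float(v.std(ddof=1)) if len(v) > 1 else 0.0
    return EvalSummary(
        n_cases=len(records),
        ssim_mean=float(s.mean()), ssim_std=std(s), ssim_above_09=float((s > 0.9).mean()),
        nrmse_mean=float(e.mean()), nrmse_std=std(e), nrmse_below_02=float((e < 0.2).mean()),
        psnr_mean=float(p.mean()), psnr_std=std(p), psnr_above_30=float((p > 30.0).mean()),
    )


def records_to_csv(records: list[EvalRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("case_id,ssim,nrmse,psnr\n")
        for r in records:
            fh.write(f"{r.case_id},{r.ssim:.6f},{r.nrmse:.6f},{r.psnr:.4f}\n")


def summary_to_csv(summary: EvalSummary, path) -> None:
    """Table-style summary CSV: metric, mean, proportion acceptable, std."""
    rows = [
        ("SSIM", summary.ssim_mean, summary.ssim_above_09, summary.ssim_std),
        ("NRMSE", summary.nrmse_mean, summary.nrmse_below_02, summary.nrmse_std),
        ("PSNR_dB", summary.psnr_mean, summary.psnr_above_30, summary.psnr_std),
    ]
    with open(path, "w") as fh:
        fh.write("metric,mean,proportion_acceptable,std\n")
        for name, mean, prop, std in rows:
            fh.write(f"{name},{mean:.6f},{prop:.4f},{std:.6f}\n")
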