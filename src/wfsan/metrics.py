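"""Image-quality metrics for 8-bit grayscale images: PSNR and SSIM.

PSNR is the closed form 10·log10(255²/MSE) in decibels; identical
images return the +inf sentinel (MSE = 0 limit) rather than an
arbitrary cap.  SSIM is the windowed structural-similarity index with
the field-standard parameters: 11×11 Gaussian-weighted windows
(σ = 1.5), c1 = (0.01·255)², c2 = (0.03·255)², averaged over the
image.  The per-window statistic can be negative for anticorrelated
patches, so the value lies in [−1, 1]; no clamping is applied.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["mse", "psnr", "ssim", "metrics_report"]

MAX_I = 255.0


def _check_pair(reference: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(reference, dtype=np.float64)
    tst = np.asarray(test, dtype=np.float64)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    if ref.ndim != 2:
        raise ValueError("metrics are defined for 2-D grayscale images")
    return ref, tst


def mse(reference: np.ndarray, test: np.ndarray) -> float:
    ref, tst = _check_pair(reference, test)
    return float(np.mean((ref - tst) ** 2))


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB on the 8-bit scale.

    Returns ``float('inf')`` for identical images.
    """
    err = mse(reference, test)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(MAX_I**2 / err))


def ssim(reference: np.ndarray, test: np.ndarray) -> float:
    """Mean structural similarity over 11×11 Gaussian windows (σ=1.5)."""
    ref, tst = _check_pair(reference, test)
    return float(
        structural_similarity(
            ref,
            tst,
            data_range=MAX_I,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
        )
    )


def metrics_report(reference: np.ndarray, test: np.ndarray) -> dict[str, float]:
    """MSE, PSNR and SSIM of a reference/test pair as a dict."""
    return {
        "mse": mse(reference, test),
        "psnr": psnr(reference, test),
        "ssim": ssim(reference, test),
    }
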