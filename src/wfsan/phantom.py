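"""Synthetic chest-phantom grayscale images and training datasets.

The generator emulates the statistical signature of a chest radiograph
that the wavelet-separation approach relies on: strong low-frequency
anatomy (smooth background gradient, bright mediastinal column, two
dark elliptical lung fields) plus sparse edges (soft lung borders and
periodic curved rib bands), with optional Gaussian noise.  Under the
undecimated Haar transform such images put nearly all coefficient
energy in the approximate band while the detail bands stay
near-zero-mean and sparse — which is what exercises both network
paths the way real radiographs would.

It does not attempt anatomical realism: no pathology, no scatter or
beam-hardening physics, no inter-patient variability beyond the seeded
geometry jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .training import PatchPair, TrainConfig, extract_patches

__all__ = ["PhantomParams", "make_phantom", "make_dataset"]


@dataclass
class PhantomParams:
    """Geometry and texture parameters of the synthetic phantom.

    All lengths are fractions of the image side so phantoms scale with
    ``size``.  ``seed`` fixes every random element (geometry jitter,
    vessel trees and noise).
    """

    size: int = 256
    n_rib_bands: int = 6
    rib_contrast: float = 35.0
    rib_sharpness: float = 4.0  # sinusoid gain before clipping; higher = crisper bands
    lung_axes: tuple[float, float] = (0.17, 0.30)  # semi-axes, fraction of size
    lung_centers: tuple[tuple[float, float], tuple[float, float]] = (
        (0.30, 0.48),
        (0.70, 0.48),
    )
    background_level: float = 190.0
    gradient_slope: float = 35.0
    lung_depth: float = 95.0
    edge_softness: float = 0.8  # px, sigmoid width of lung borders
    n_vessels: int = 20  # vessel branches per lung (lung markings)
    vessel_contrast: float = 20.0
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("size must be >= 64")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


# cross-section of a vessel stroke: ~1.5 px wide bright ridge
_VESSEL_STAMP = np.array([[0.05, 0.2, 0.05], [0.2, 1.0, 0.2], [0.05, 0.2, 0.05]])


def make_phantom(params: PhantomParams) -> np.ndarray:
    """Render one 8-bit grayscale chest phantom (uint8, size×size)."""
    p = params
    n = p.size
    rng = np.random.default_rng(p.seed)
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    u, v = xx / n, yy / n  # unit coordinates

    # smooth bright background with a gentle diagonal gradient and vignette
    img = p.background_level + p.gradient_slope * (0.6 * (1.0 - v) + 0.4 * u - 0.5)
    img -= 28.0 * ((u - 0.5) ** 2 + (v - 0.5) ** 2)

    # bright mediastinal column between the lungs
    img += 30.0 * np.exp(-(((u - 0.5) / 0.09) ** 2)) * np.exp(-(((v - 0.45) / 0.45) ** 2))

    # two dark elliptical lung fields with crisp sigmoid borders
    ax, ay = p.lung_axes
    lung_mask = np.zeros_like(img)
    centers = []
    for (cx, cy) in p.lung_centers:
        cx_j = cx + rng.normal(0.0, 0.008)
        cy_j = cy + rng.normal(0.0, 0.008)
        centers.append((cx_j, cy_j))
        r = np.sqrt(((u - cx_j) / ax) ** 2 + ((v - cy_j) / ay) ** 2)
        # signed distance from the ellipse boundary, approx. in pixels
        d = (r - 1.0) * min(ax, ay) * n
        lung_mask = np.maximum(lung_mask, 1.0 / (1.0 + np.exp(d / p.edge_softness)))
    img -= p.lung_depth * lung_mask

    # periodic curved rib bands with crisp edges, visible inside the lungs
    if p.n_rib_bands > 0 and p.rib_contrast > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        curve = v + 0.15 * (u - 0.5) ** 2
        bands = np.sin(2.0 * np.pi * p.n_rib_bands * curve + phase)
        ridges = np.clip(bands * p.rib_sharpness, -1.0, 1.0)
        img += p.rib_contrast * 0.5 * ridges * lung_mask

    # sparse vessel trees (lung markings): tapering curvilinear bright
    # strokes walked outward from each hilum
    if p.n_vessels > 0 and p.vessel_contrast > 0:
        vessels = np.zeros_like(img)
        for (cx, cy) in centers:
            for _ in range(p.n_vessels):
                x0 = (cx + rng.normal(0.0, 0.02)) * n
                y0 = (cy + rng.normal(0.0, 0.05)) * n
                ang = rng.uniform(0.0, 2.0 * np.pi)
                curvature = rng.normal(0.0, 0.06)
                steps = int(rng.uniform(0.08, 0.22) * n * 2)
                for t in range(steps):
                    ang += 0.5 * curvature
                    x0 += 0.5 * np.cos(ang)
                    y0 += 0.5 * np.sin(ang)
                    ix, iy = int(round(x0)), int(round(y0))
                    if 1 <= ix < n - 1 and 1 <= iy < n - 1:
                        taper = max(0.3, 1.0 - t / steps)
                        vessels[iy - 1 : iy + 2, ix - 1 : ix + 2] += taper * _VESSEL_STAMP
        img += p.vessel_contrast * np.clip(vessels, 0.0, 1.6) * lung_mask

    if p.noise_sigma > 0:
        img += rng.normal(0.0, p.noise_sigma, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_dataset(
    n_images: int,
    params: PhantomParams | None = None,
    scale: int = 2,
    patch_size: int = 48,
    patch_stride: int = 24,
    seed: int = 0,
) -> list[PatchPair]:
    """Phantoms → aligned LR/HR patch pairs, shuffled under ``seed``.

    Each image gets its own derived seed so disjoint base seeds give
    disjoint pixel content.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    base = params or PhantomParams()
    cfg = TrainConfig(
        patch_size=patch_size, patch_stride=patch_stride, scale=scale, seed=seed
    )
    rng = np.random.default_rng(seed)
    pairs: list[PatchPair] = []
    for i in range(n_images):
        p = PhantomParams(
            **{**base.__dict__, "seed": int(rng.integers(0, 2**31 - 1))}
        )
        pairs.extend(extract_patches(make_phantom(p), cfg))
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]
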