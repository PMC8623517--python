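"""1-level 2D stationary (undecimated) Haar wavelet transform.

The transform maps an H×W image to four coefficient planes of the same
size: A (approximate, low/low), H (horizontal detail), V (vertical
detail) and D (diagonal detail).  With the Haar 2-tap filters
(1/√2, 1/√2) and (1/√2, −1/√2) applied separably and without
decimation, every output entry is a signed half-sum of the 2×2 pixel
window anchored at that position (periodic wrap at the borders)::

    A[i,j] = (a + b + c + d) / 2
    H[i,j] = (a + b - c - d) / 2      a = I[i, j]    b = I[i, j+1]
    V[i,j] = (a - b + c - d) / 2      c = I[i+1, j]  d = I[i+1, j+1]
    D[i,j] = (a - b - c + d) / 2

Boundary handling is periodic (circular) throughout; this is the unique
convention under which the 2×2 worked example holds at all four
positions and the detail planes sum to exactly zero.  The inverse
averages the four redundant per-window reconstructions, which makes it
an exact inverse for consistent coefficient sets and the standard
least-squares read-back for predicted (inconsistent) ones.

Consequences used elsewhere in the package: for pixels in [lo, hi],
A ∈ [2·lo, 2·hi] and |H|, |V|, |D| ≤ hi − lo; mean(A) = 2·mean(I);
mean(H) = mean(V) = mean(D) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaveletBands",
    "swt2_level1",
    "iswt2_level1",
    "split_bands",
    "merge_bands",
    "subband_stats",
]

# Haar analysis filters, applied per axis without decimation.  The
# separable 2D low/low kernel entries then sum to 2, which reproduces
# the 1/2 prefactor of the window algebra above.
HAAR_LOWPASS = np.array([1.0, 1.0]) / np.sqrt(2.0)
HAAR_HIGHPASS = np.array([1.0, -1.0]) / np.sqrt(2.0)


@dataclass
class WaveletBands:
    """The four same-sized coefficient planes of a 1-level undecimated
    Haar transform.  ``level`` is always 1."""

    A: np.ndarray
    H: np.ndarray
    V: np.ndarray
    D: np.ndarray
    level: int = 1

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        self.H = np.asarray(self.H, dtype=np.float64)
        self.V = np.asarray(self.V, dtype=np.float64)
        self.D = np.asarray(self.D, dtype=np.float64)
        shapes = {p.shape for p in (self.A, self.H, self.V, self.D)}
        if len(shapes) != 1:
            raise ValueError(f"band planes must share one shape, got {shapes}")
        if self.A.ndim != 2:
            raise ValueError("band planes must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape


def _validate_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"image must be at least 2x2, got {arr.shape}")
    return arr


def swt2_level1(image: np.ndarray) -> WaveletBands:
    """Decompose an image into its four undecimated Haar sub-bands.

    Parameters
    ----------
    image : (H, W) array_like
        Grayscale image, at least 2×2.  Any real dtype.

    Returns
    -------
    WaveletBands
        Planes A, H, V, D, each of the input's shape.
    """
    x = _validate_image(image)
    right = np.roll(x, -1, axis=1)        # b: pixel to the right (wraps)
    down = np.roll(x, -1, axis=0)         # c: pixel below (wraps)
    diag = np.roll(down, -1, axis=1)      # d: diagonal neighbour
    a_plane = 0.5 * (x + right + down + diag)
    h_plane = 0.5 * (x + right - down - diag)
    v_plane = 0.5 * (x - right + down - diag)
    d_plane = 0.5 * (x - right - down + diag)
    return WaveletBands(a_plane, h_plane, v_plane, d_plane)


def iswt2_level1(bands: WaveletBands) -> np.ndarray:
    """Reconstruct the image from 1-level undecimated Haar sub-bands.

    Each pixel appears in four overlapping analysis windows; each window
    determines it exactly, and the four estimates are averaged.  For
    coefficients produced by :func:`swt2_level1` the result equals the
    original image to floating tolerance.
    """
    if not isinstance(bands, WaveletBands):
        bands = WaveletBands(*bands)
    A, H, V, D = bands.A, bands.H, bands.V, bands.D
    # window anchored at (i, j): pixel is the 'a' corner
    est_a = A + H + V + D
    # anchored at (i, j-1): pixel is 'b'
    est_b = np.roll(A + H - V - D, 1, axis=1)
    # anchored at (i-1, j): pixel is 'c'
    est_c = np.roll(A - H + V - D, 1, axis=0)
    # anchored at (i-1, j-1): pixel is 'd'
    est_d = np.roll(np.roll(A - H - V + D, 1, axis=0), 1, axis=1)
    return (est_a + est_b + est_c + est_d) / 8.0


def split_bands(bands: WaveletBands) -> tuple[np.ndarray, np.ndarray]:
    """Separate bands into the approximate plane and an (H, V, D) stack.

    Returns ``(approx, details)`` where ``approx`` has shape (1, H, W)
    and ``details`` has shape (3, H, W) with fixed channel order
    H, V, D.
    """
    approx = bands.A[None, :, :]
    details = np.stack([bands.H, bands.V, bands.D], axis=0)
    return approx, details


def merge_bands(approx_plane: np.ndarray, detail_stack: np.ndarray) -> WaveletBands:
    """Inverse of :func:`split_bands`: rebuild a :class:`WaveletBands`."""
    approx = np.asarray(approx_plane, dtype=np.float64)
    details = np.asarray(detail_stack, dtype=np.float64)
    if approx.ndim == 3:
        if approx.shape[0] != 1:
            raise ValueError(f"approx plane must have 1 channel, got {approx.shape[0]}")
        approx = approx[0]
    if details.ndim != 3 or details.shape[0] != 3:
        raise ValueError(f"detail stack must be (3, H, W), got {details.shape}")
    if details.shape[1:] != approx.shape:
        raise ValueError(
            f"spatial shape mismatch: approx {approx.shape} vs details {details.shape[1:]}"
        )
    return WaveletBands(approx, details[0], details[1], details[2])


def subband_stats(bands: WaveletBands) -> dict[str, dict[str, float]]:
    """Per-band sample statistics {min, max, mean, std} (population std)."""
    out: dict[str, dict[str, float]] = {}
    for name in ("A", "H", "V", "D"):
        plane = getattr(bands, name)
        out[name] = {
            "min": float(plane.min()),
            "max": float(plane.max()),
            "mean": float(plane.mean()),
            "std": float(plane.std()),
        }
    return out
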