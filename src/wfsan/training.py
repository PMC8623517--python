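"""Training: wavelet-domain L2 loss, patching, schedule, optimization.

The model is trained to predict the four HR stationary-wavelet
coefficient planes from the LR ones.  The loss is the batch-mean
squared coefficient error

    L = 1/(2N) Σ_n ( ||HCA_n − pred_A_n||² + ||HCD_n − pred_D_n||² )

optimized with Adam under global-norm gradient clipping.  The learning
rate follows a cosine decay schedule: at epochs that are multiples of
``decay_epoch`` the rate is cut ×0.1, otherwise it is set to the
absolute cosine expression (1−α)·½(1+cos(π·epoch/decay_epoch))+α.
That expression lives on a [α, 1] scale, so the optimizer applies it as
a multiplier on ``initial_lr`` — the run then actually starts near the
configured initial rate.

Training pairs are HR crops on a regular grid (the HR patch size and
stride are configurable; 48 with 50% overlap by default) with LR sides
produced by bicubic downsampling — the standard degradation protocol
for single-image super-resolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from PIL import Image

from .network import WFSAN, NetworkConfig, reconstruct_bands
from .nn import Adam, clip_by_global_norm
from .metrics import psnr
from .swt import split_bands, swt2_level1

__all__ = [
    "TrainConfig",
    "PatchPair",
    "ScheduleState",
    "cosine_decay_lr",
    "schedule_trace",
    "wavelet_l2_loss",
    "extract_patches",
    "bicubic_resize",
    "train_model",
    "evaluate_model",
    "evaluate_bicubic",
]


@dataclass
class TrainConfig:
    """Optimization and patching hyperparameters.

    ``patch_size`` is the HR crop side; the LR side is
    ``patch_size / scale``.  ``decay_epoch`` defaults to 100; 30 is the
    alternative step used for short schedules.
    """

    batch_size: int = 128
    patch_size: int = 48
    patch_stride: int = 24
    initial_lr: float = 1e-3
    alpha: float = 1e-4
    decay_epoch: int = 100
    max_epochs: int = 100
    grad_clip_norm: float = 1e-3
    scale: int = 2
    seed: int = 0
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.patch_size < 8:
            raise ValueError("patch_size must be >= 8")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.decay_epoch <= 0:
            raise ValueError("decay_epoch must be positive")
        for name in ("initial_lr", "alpha", "grad_clip_norm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.patch_size % self.scale != 0:
            raise ValueError("patch_size must be divisible by scale")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PatchPair:
    """An aligned LR/HR training pair (HR side = scale × LR side)."""

    lr: np.ndarray
    hr: np.ndarray


@dataclass
class ScheduleState:
    epoch: int = 0
    lr: float = 1.0


def cosine_decay_lr(state: ScheduleState, config: TrainConfig) -> float:
    """Advance the schedule by one epoch and return the new rate value.

    Steps the recurrence: at epochs divisible by ``decay_epoch`` the
    current value is multiplied by 0.1; at every other epoch the value
    is *set* (not scaled) to (1−α)·½(1+cos(π·epoch/decay_epoch))+α.
    """
    if config.decay_epoch <= 0:
        raise ValueError("decay_epoch must be positive")
    state.epoch += 1
    e = state.epoch
    if e % config.decay_epoch == 0:
        state.lr = state.lr * 0.1
    else:
        state.lr = (1.0 - config.alpha) * 0.5 * (
            1.0 + math.cos(math.pi * e / config.decay_epoch)
        ) + config.alpha
    return state.lr


def schedule_trace(config: TrainConfig, n_epochs: int, start: float | None = None) -> list[float]:
    """Rate values for epochs 1..n_epochs of the cosine-decay recurrence."""
    state = ScheduleState(epoch=0, lr=config.initial_lr if start is None else start)
    return [cosine_decay_lr(state, config) for _ in range(n_epochs)]


def wavelet_l2_loss(
    pred_hca: np.ndarray,
    pred_hcd: np.ndarray,
    true_hca: np.ndarray,
    true_hcd: np.ndarray,
    batch_n: int | None = None,
) -> float:
    """Mean squared coefficient error, 1/(2N)·Σ(‖ΔA‖² + ‖ΔD‖²)."""
    pred_hca, pred_hcd = np.asarray(pred_hca), np.asarray(pred_hcd)
    true_hca, true_hcd = np.asarray(true_hca), np.asarray(true_hcd)
    if pred_hca.shape != true_hca.shape or pred_hcd.shape != true_hcd.shape:
        raise ValueError("prediction/target shape mismatch")
    n = batch_n if batch_n is not None else (pred_hca.shape[0] if pred_hca.ndim == 4 else 1)
    if n < 1:
        raise ValueError("batch_n must be >= 1")
    da = pred_hca.astype(np.float64) - true_hca.astype(np.float64)
    dd = pred_hcd.astype(np.float64) - true_hcd.astype(np.float64)
    return float((np.sum(da * da) + np.sum(dd * dd)) / (2.0 * n))


def _loss_grads(pred_a, pred_d, true_a, true_d):
    n = pred_a.shape[0]
    dfa = (pred_a - true_a) / n
    dfd = (pred_d - true_d) / n
    return dfa.astype(np.float32), dfd.astype(np.float32)


def bicubic_resize(image: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bicubic resampling to (H, W) on the 8-bit scale (PIL backend)."""
    img = Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L")
    h, w = out_shape
    return np.asarray(img.resize((w, h), Image.BICUBIC), dtype=np.float64)


def extract_patches(hr_image: np.ndarray, config: TrainConfig) -> list[PatchPair]:
    """Aligned LR/HR pairs from a regular crop grid over an HR image.

    HR crops of side ``patch_size`` are taken every ``patch_stride``
    pixels; each LR patch is the bicubic 1/scale downsample of its HR
    crop.  An image smaller than one patch yields an empty list with a
    warning.
    """
    hr = np.asarray(hr_image)
    if hr.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    ps, st, s = config.patch_size, config.patch_stride, config.scale
    h, w = hr.shape
    if h < ps or w < ps:
        warnings.warn(f"image {hr.shape} smaller than patch size {ps}; no patches")
        return []
    lr_side = ps // s
    pairs = []
    for i in range(0, h - ps + 1, st):
        for j in range(0, w - ps + 1, st):
            crop = hr[i : i + ps, j : j + ps]
            lr = bicubic_resize(crop, (lr_side, lr_side))
            pairs.append(PatchPair(lr=lr, hr=crop.astype(np.float64)))
    return pairs


def _bands_tensor(images: list[np.ndarray], norm: float) -> tuple[np.ndarray, np.ndarray]:
    """Stack normalized (A) and (H,V,D) sub-band tensors of a patch list."""
    a_list, d_list = [], []
    for img in images:
        approx, details = split_bands(swt2_level1(np.asarray(img, dtype=np.float64) / norm))
        a_list.append(approx)
        d_list.append(details)
    return (
        np.stack(a_list).astype(np.float32),
        np.stack(d_list).astype(np.float32),
    )


def _residual_tensor(
    lr_images: list[np.ndarray], scale: int, norm: float
) -> tuple[np.ndarray, np.ndarray]:
    from .network import residual_base_from_image

    a_list, d_list = [], []
    for img in lr_images:
        ba, bd = residual_base_from_image(np.clip(np.rint(img), 0, 255), scale, norm)
        a_list.append(ba)
        d_list.append(bd)
    return np.stack(a_list).astype(np.float32), np.stack(d_list).astype(np.float32)


def evaluate_model(model: WFSAN, pairs: list[PatchPair], psnr_cap: float = 100.0) -> float:
    """Mean PSNR of the model's reconstructions on a list of pairs.

    Identical reconstructions (infinite PSNR) are capped at
    ``psnr_cap`` dB so the mean stays finite.
    """
    if not pairs:
        raise ValueError("empty evaluation set")
    norm = model.config.normalization
    lca, lcd = _bands_tensor([p.lr for p in pairs], norm)
    rbase = None
    if model.config.residual:
        rbase = _residual_tensor([p.lr for p in pairs], model.config.scale, norm)
    fa, fd = model.forward(lca, lcd, residual_base=rbase)
    vals = []
    for i, p in enumerate(pairs):
        rec = np.clip(reconstruct_bands(fa[i], fd[i], norm), 0.0, 255.0)
        vals.append(min(psnr(p.hr, rec), psnr_cap))
    return float(np.mean(vals))


def evaluate_bicubic(pairs: list[PatchPair], scale: int, psnr_cap: float = 100.0) -> float:
    """Mean PSNR of plain bicubic upscaling on the same pairs (baseline)."""
    if not pairs:
        raise ValueError("empty evaluation set")
    vals = []
    for p in pairs:
        up = bicubic_resize(np.clip(np.rint(p.lr), 0, 255), p.hr.shape)
        vals.append(min(psnr(p.hr, up), psnr_cap))
    return float(np.mean(vals))


def train_model(
    dataset: list[PatchPair],
    net_config: NetworkConfig,
    train_config: TrainConfig,
    verbose: bool = False,
) -> tuple[WFSAN, list[dict]]:
    """Fit a WFSAN to a patch dataset.

    Shuffles the dataset under the run seed, holds out the last
    ``val_fraction`` as a validation split, precomputes the sub-band
    tensors of both sides, and runs Adam over the wavelet L2 loss with
    the cosine-decay schedule and global-norm clipping.  Returns the
    trained model and a per-epoch log of
    ``{"epoch", "lr", "train_loss", "epoch_loss", "val_psnr"}``, where
    ``train_loss`` is the running mean over the epoch's batches and
    ``epoch_loss`` is the loss at epoch end on a fixed training subset
    (the cleaner monitor of optimization progress).

    Raises ``RuntimeError`` if the loss diverges to NaN/inf.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    cfg = train_config
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(dataset))
    dataset = [dataset[i] for i in order]
    n_val = max(1, int(round(cfg.val_fraction * len(dataset)))) if cfg.val_fraction > 0 else 0
    train_pairs = dataset[: len(dataset) - n_val] if n_val else dataset
    val_pairs = dataset[len(dataset) - n_val :] if n_val else []
    if not train_pairs:
        raise ValueError("no training pairs left after validation split")

    norm = net_config.normalization
    lca, lcd = _bands_tensor([p.lr for p in train_pairs], norm)
    hca, hcd = _bands_tensor([p.hr for p in train_pairs], norm)
    base_a = base_d = None
    if net_config.residual:
        base_a, base_d = _residual_tensor(
            [p.lr for p in train_pairs], net_config.scale, norm
        )

    model = WFSAN(net_config, seed=cfg.seed)
    params = model.params()
    opt = Adam(params, lr=cfg.initial_lr)
    sched = ScheduleState(epoch=0, lr=1.0)  # multiplier on initial_lr

    # fixed probe subset for the end-of-epoch loss: immune to the
    # shuffle noise that an intra-epoch running mean carries
    n = len(train_pairs)
    n_probe = min(256, n)
    probe_base = (
        (base_a[:n_probe], base_d[:n_probe]) if base_a is not None else None
    )
    # precompute the validation tensors once
    if val_pairs:
        vlca, vlcd = _bands_tensor([p.lr for p in val_pairs], norm)
        vbase = None
        if net_config.residual:
            vbase = _residual_tensor([p.lr for p in val_pairs], net_config.scale, norm)

    def _val_psnr() -> float:
        fa, fd = model.forward(vlca, vlcd, residual_base=vbase)
        vals = []
        for i, p in enumerate(val_pairs):
            rec = np.clip(reconstruct_bands(fa[i], fd[i], norm), 0.0, 255.0)
            vals.append(min(psnr(p.hr, rec), 100.0))
        return float(np.mean(vals))

    log: list[dict] = []
    for epoch in range(1, cfg.max_epochs + 1):
        mult = cosine_decay_lr(sched, cfg)
        opt.lr = cfg.initial_lr * mult
        idx = rng.permutation(n)
        total_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            sel = idx[start : start + cfg.batch_size]
            rbase = (base_a[sel], base_d[sel]) if base_a is not None else None
            pa, pd = model.forward(lca[sel], lcd[sel], residual_base=rbase)
            loss = wavelet_l2_loss(pa, pd, hca[sel], hcd[sel])
            if not np.isfinite(loss):
                raise RuntimeError(f"loss diverged at epoch {epoch} (loss={loss})")
            dfa, dfd = _loss_grads(pa, pd, hca[sel], hcd[sel])
            opt.zero_grad()
            model.backward(dfa, dfd)
            clip_by_global_norm(params, cfg.grad_clip_norm)
            opt.step()
            total_loss += loss
            n_batches += 1
        pa, pd = model.forward(lca[:n_probe], lcd[:n_probe], residual_base=probe_base)
        entry = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": total_loss / n_batches,
            "epoch_loss": wavelet_l2_loss(pa, pd, hca[:n_probe], hcd[:n_probe]),
            "val_psnr": _val_psnr() if val_pairs else float("nan"),
        }
        log.append(entry)
        if verbose:
            print(
                f"epoch {entry['epoch']:4d}  lr {entry['lr']:.3e}  "
                f"loss {entry['train_loss']:.6f}  epoch_loss {entry['epoch_loss']:.6f}  "
                f"val_psnr {entry['val_psnr']:.2f}"
            )
    return model, log
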