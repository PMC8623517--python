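"""Image and checkpoint I/O.

Images are 8-bit single-channel PNG/TIFF; multi-channel inputs are
rejected unless conversion is requested, 16-bit TIFFs are rescaled to
8-bit with a warning.  Checkpoints are numpy ``.npz`` archives holding
every weight tensor plus the JSON-encoded network configuration and
training metadata, so a loaded model reproduces the saved one's forward
outputs exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .network import WFSAN, NetworkConfig

__all__ = ["read_grayscale", "write_grayscale", "save_checkpoint", "load_checkpoint"]


def read_grayscale(path: str | Path, to_gray: bool = False) -> np.ndarray:
    """Read a PNG/TIFF as an 8-bit single-channel image (uint8 array).

    Multi-channel images raise unless ``to_gray`` is set (ITU-R 601
    luminance).  16-bit inputs are rescaled to 8-bit with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = iio.imread(path)
    if arr.ndim == 3:
        if not to_gray:
            raise ValueError(
                f"{path.name} has {arr.shape[-1]} channels; pass to_gray=True "
                "(CLI: --to-gray) to convert to single-channel grayscale"
            )
        rgb = arr[..., :3].astype(np.float64)
        arr = rgb @ np.array([0.299, 0.587, 0.114])
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    if arr.dtype == np.uint16:
        warnings.warn(f"{path.name}: 16-bit image rescaled to 8-bit")
        arr = np.rint(arr.astype(np.float64) / 257.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr.astype(np.float64)), 0, 255).astype(np.uint8)
    return arr


def write_grayscale(path: str | Path, image: np.ndarray) -> None:
    """Write an 8-bit grayscale image (values clipped to [0, 255])."""
    arr = np.clip(np.rint(np.asarray(image, dtype=np.float64)), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def save_checkpoint(path: str | Path, model: WFSAN, meta: dict | None = None) -> None:
    """Save model weights with the embedded network config and metadata."""
    payload = {f"weight/{name}": value for name, value in model.state_dict().items()}
    payload["config_json"] = np.array(json.dumps(model.config.to_dict()))
    payload["meta_json"] = np.array(json.dumps(meta or {}))
    np.savez(Path(path), **payload)


def load_checkpoint(path: str | Path) -> tuple[WFSAN, dict]:
    """Load a checkpoint: rebuilds the model from its embedded config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with np.load(path, allow_pickle=False) as data:
        config = NetworkConfig.from_dict(json.loads(str(data["config_json"])))
        meta = json.loads(str(data["meta_json"]))
        state = {
            key[len("weight/") :]: data[key]
            for key in data.files
            if key.startswith("weight/")
        }
    model = WFSAN(config)
    model.load_state_dict(state)
    return model, meta
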