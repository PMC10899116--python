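"""File formats: indexed-PNG label masks with JSON sidecars, RGB images,
and network checkpoints.

Label masks travel as palette PNGs (class ids 0-6 as palette indices) next
to a ``<name>.json`` sidecar holding the microns-per-pixel and the class
codebook; checkpoints are ``.npz`` weight archives with a JSON sidecar of
the architecture configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .config import CLASS_NAMES, NetworkConfig
from .mask import LabelMask, SlideRaster
from .model import Network, build_network

__all__ = [
    "save_mask", "load_mask", "load_image", "save_image",
    "save_checkpoint", "load_checkpoint", "MASK_PALETTE",
]

#: display palette for the 7 classes (background, then the six patterns)
MASK_PALETTE = {
    0: (255, 255, 255),
    1: (255, 214, 0),      # lepidic
    2: (255, 140, 0),      # papillary
    3: (46, 139, 87),      # acinar
    4: (30, 144, 255),     # cribriform
    5: (148, 0, 211),      # micropapillary
    6: (178, 34, 34),      # solid
}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_mask(path, mask: LabelMask, extra: dict | None = None) -> None:
    """Write an indexed PNG plus a JSON sidecar with mpp and class names."""
    path = Path(path)
    img = Image.fromarray(mask.labels.astype(np.uint8), mode="P")
    palette = []
    for c in range(256):
        palette.extend(MASK_PALETTE.get(c, (0, 0, 0)))
    img.putpalette(palette)
    img.save(path)
    meta = {"mpp": mask.mpp, "class_names": {str(k): v for k, v in CLASS_NAMES.items()}}
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_mask(path, mpp: float | None = None) -> LabelMask:
    """Read an indexed PNG mask; mpp comes from the sidecar unless given."""
    path = Path(path)
    labels = np.asarray(Image.open(path).convert("P"), dtype=np.uint8)
    if mpp is None:
        sc = _sidecar(path)
        if not sc.exists():
            raise ValueError(f"no mpp given and no sidecar at {sc}")
        mpp = json.loads(sc.read_text())["mpp"]
    return LabelMask(labels, mpp)


def load_image(path, mpp: float | None = None) -> SlideRaster:
    """Read an RGB PNG/TIFF slide or tile."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
    return SlideRaster(pixels, mpp)


def save_image(path, pixels: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        Image.fromarray(pixels).save(path)


def save_checkpoint(path, network: Network) -> None:
    """Serialize weights (+BN running stats) to .npz with a config sidecar."""
    path = Path(path)
    arrays = {f"param/{k}": p.data for k, p in network.named_parameters()}
    arrays.update({f"buffer/{k}": b for k, b in network.named_buffers()})
    np.savez(path, **arrays)
    _sidecar(path).write_text(json.dumps(network.config.to_dict(), indent=2))


def load_checkpoint(path) -> Network:
    path = Path(path)
    config = NetworkConfig.from_dict(json.loads(_sidecar(path).read_text()))
    network = build_network(config)
    with np.load(path if path.suffix == ".npz" else f"{path}.npz") as data:
        params = dict(network.named_parameters())
        buffers = dict(network.named_buffers())
        for key in data.files:
            kind, name = key.split("/", 1)
            if kind == "param":
                params[name].data = data[key]
            else:
                buffers[name][...] = data[key]
    return network
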