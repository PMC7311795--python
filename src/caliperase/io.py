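"""Serialization: 8-bit grayscale PNGs, ground-truth JSON, model checkpoints."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from caliperase import vib
from caliperase.phantom import Nodule, PhantomDataset, from_uint8, to_uint8


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0,1] float image as 8-bit grayscale PNG (round(255*i))."""
    iio.imwrite(Path(path), to_uint8(image), extension=".png")


def load_image(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return from_uint8(arr)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255), extension=".png")


def load_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def save_dataset(dataset: PhantomDataset, out_dir: str | Path) -> None:
    """Write one PNG per item plus a deterministic ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, item in enumerate(dataset.items):
        save_image(out / f"{item.split}_{i:04d}.png", item.image)
    (out / "ground_truth.json").write_text(dataset.ground_truth_json())


def load_ground_truth(path: str | Path) -> list[dict]:
    payload = json.loads(Path(path).read_text())
    return payload["items"]


def nodules_from_item(item: dict) -> list[Nodule]:
    return [Nodule.from_dict(d) for d in item["nodules"]]


def save_classifier(path: str | Path, model: vib.VIBModel) -> None:
    """Checkpoint a classifier as a compressed npz (arrays + config header)."""
    meta = {"K": model.K, "beta": model.beta, "input_side": model.input_side,
            "hidden": list(model.hidden), "use_vib": model.use_vib,
            "arch": model.arch, "conv_channels": list(model.conv_channels)}
    np.savez_compressed(Path(path), __meta__=json.dumps(meta, sort_keys=True),
                        **model.params)


def load_classifier(path: str | Path) -> vib.VIBModel:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        params = {k: data[k] for k in data.files if k != "__meta__"}
    return vib.VIBModel(params=params, K=meta["K"], beta=meta["beta"],
                        input_side=meta["input_side"], hidden=tuple(meta["hidden"]),
                        use_vib=meta["use_vib"], arch=meta["arch"],
                        conv_channels=tuple(meta["conv_channels"]))
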