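"""Readers and writers for scenes, patch manifests, matrices, and checkpoints.

Images travel as PNG (8- or 16-bit grayscale), tabular artifacts as CSV,
metadata as JSON sidecars, and network checkpoints as NumPy ``.npz``
archives carrying the estimator configuration alongside the weights.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .distance import DistanceMatrix
from .patches import PatchDataset, SourceImage, normalize_image
from .synthetic import SyntheticScene

__all__ = [
    "write_png", "read_png", "write_scene", "load_source_image",
    "write_patch_manifest", "write_patch_bundle", "read_patch_bundle",
    "write_distance_csv", "read_distance_csv", "write_attribute_matrix",
    "read_attribute_matrix", "save_estimator", "load_estimator",
]


def write_png(array: np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Write a [0, 1] float array (or binary mask) as grayscale PNG."""
    array = np.asarray(array)
    if bit_depth == 8:
        img = Image.fromarray(np.round(np.clip(array, 0, 1) * 255).astype(np.uint8), mode="L")
    elif bit_depth == 16:
        data = np.round(np.clip(array, 0, 1) * 65535).astype(np.uint16)
        img = Image.new("I;16", (data.shape[1], data.shape[0]))
        img.frombytes(data.tobytes())
    else:
        raise ValueError("bit_depth must be 8 or 16")
    img.save(path)


def read_png(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG as raw integer values (8- or 16-bit)."""
    with Image.open(path) as img:
        return np.asarray(img.convert("I"))


def write_scene(scene: SyntheticScene, out_dir: str | Path, name: str) -> None:
    """PNG image (+ mask when present) plus a JSON sidecar per scene."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_png(scene.image, out / f"{name}.png")
    sidecar = {"seed": scene.seed, "category_names": list(scene.category_names),
               "has_mask": scene.mask is not None}
    if scene.mask is not None:
        write_png(scene.mask.astype(float), out / f"{name}_mask.png")
    (out / f"{name}.json").write_text(json.dumps(sidecar, indent=1))


def load_source_image(path: str | Path, mask_path: str | Path | None = None,
                      is_negative: bool = False, **source_kwargs) -> SourceImage:
    raw = read_png(path)
    mask = None
    if mask_path is not None:
        mask = (read_png(mask_path) > 0).astype(np.uint8)
    return normalize_image(raw, is_negative=is_negative, mask=mask,
                           image_id=str(Path(path).stem), **source_kwargs)


def write_patch_manifest(ds: PatchDataset, path: str | Path) -> None:
    rows = [{"image_id": p.origin[0], "x": p.origin[1], "y": p.origin[2],
             "category": ds.category_names[p.category_index], "split": ds.split,
             "avg_brightness": p.avg_brightness, "mask_fraction": p.mask_fraction}
            for p in ds.patches]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_patch_bundle(ds: PatchDataset, path: str | Path) -> None:
    """Patch arrays + labels for one split in a single ``.npz`` archive."""
    X, y = ds.arrays()
    meta = {"category_names": list(ds.category_names), "split": ds.split,
            "origins": [list(p.origin) for p in ds.patches]}
    np.savez_compressed(path, X=X, y=y, meta=json.dumps(meta))


def read_patch_bundle(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    with np.load(path, allow_pickle=False) as data:
        return data["X"], data["y"], json.loads(str(data["meta"]))


def write_distance_csv(d: DistanceMatrix, path: str | Path) -> None:
    names = list(d.category_names) or [f"category_{i}" for i in range(d.n_categories)]
    pd.DataFrame(d.values, index=names, columns=names).to_csv(path)
    Path(str(path) + ".json").write_text(json.dumps({"provenance": d.provenance}, indent=1))


def read_distance_csv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    prov = ""
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        prov = json.loads(sidecar.read_text()).get("provenance", "")
    return DistanceMatrix(values=df.to_numpy(dtype=float),
                          category_names=tuple(df.columns), provenance=prov)


def write_attribute_matrix(A: np.ndarray, path: str | Path,
                           category_names: list[str] | None = None,
                           metadata: dict | None = None) -> None:
    A = np.asarray(A)
    names = category_names or [f"category_{i}" for i in range(A.shape[0])]
    cols = [f"attribute_{m}" for m in range(A.shape[1])]
    pd.DataFrame(A, index=names, columns=cols).to_csv(path)
    if metadata is not None:
        Path(str(path) + ".json").write_text(json.dumps(metadata, indent=1))


def read_attribute_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.index)


def save_estimator(est, path: str | Path, extra: dict | None = None) -> None:
    """Serialize a fitted network estimator: params JSON + weight arrays."""
    meta = {"class": type(est).__name__, "params": est.get_params(),
            "n_categories": int(len(est.classes_)), "extra": extra or {}}
    if hasattr(est, "attribute_matrix_") and est.attribute_matrix_ is not None:
        meta["n_attributes"] = int(est.attribute_matrix_.shape[1])
    state = est.net_.state_dict()
    np.savez_compressed(path, meta=json.dumps(meta, default=list),
                        **{f"w{i}": arr for i, arr in enumerate(state)})


def load_estimator(path: str | Path):
    from .mac import MacNet, MaterialAttributeClassifier
    from .similarity import SiameseNet, SiameseSimilarityModel

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        state = [data[f"w{i}"] for i in range(sum(1 for k in data.files if k.startswith("w")))]
    rng = np.random.default_rng(0)
    k = meta["n_categories"]
    params = meta["params"]
    if meta["class"] == "SiameseSimilarityModel":
        est = SiameseSimilarityModel(**params)
        est.classes_ = np.arange(k)
        est.net_ = SiameseNet(params["backbone"], rng, params["head_width"])
    elif meta["class"] == "MaterialAttributeClassifier":
        est = MaterialAttributeClassifier(**{key: (tuple(v) if key == "head_widths" else v)
                                             for key, v in params.items()})
        est.classes_ = np.arange(k)
        m = meta.get("n_attributes", 2)
        widths = tuple(reversed(est.head_widths)) if est.swap_head else tuple(est.head_widths)
        est.net_ = MacNet(k, m, est.backbone, rng, widths, est.aux_hidden)
        est.attribute_matrix_ = None
    else:
        raise ValueError(f"unknown estimator class {meta['class']!r}")
    est.net_.load_state_dict(state)
    return est
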