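"""Readers and writers: TSV with metadata headers, images, configs, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import PipelineConfig

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_image",
    "read_image",
    "load_config",
    "save_config",
    "sha256_file",
    "write_manifest",
]


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a TSV with an optional '#key=value' metadata header block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"#{key}={json.dumps(value) if not isinstance(value, str) else value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a TSV written by :func:`write_tsv`; returns (table, metadata)."""
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].rstrip("\n").partition("=")
            try:
                meta[key] = json.loads(value)
            except json.JSONDecodeError:
                meta[key] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        try:
            df = pd.read_csv(fh, sep="\t")
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed TSV {path}: {exc}") from exc
    return df, meta


def write_image(image: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, image)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PipelineConfig.model_validate(data or {})


def save_config(config: PipelineConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
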