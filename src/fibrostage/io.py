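"""File formats: images (TIFF/PNG), feature tables (CSV), manifests (JSON).

Feature tables are plain CSV for auditability — one row per image, columns
``image_id, stage, f001..f130`` — with a single ``#``-prefixed provenance
header line (package version, seed, config hash).  Round-trips preserve
values to full float precision (repr-level, < 1e-12 relative).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .morphology import MORPH_FEATURE_NAMES
from .texture import TEXTURE_FEATURE_NAMES

__all__ = [
    "read_image",
    "write_image",
    "feature_columns",
    "feature_manifest",
    "write_feature_table",
    "read_feature_table",
]

ALL_FEATURE_NAMES = MORPH_FEATURE_NAMES + TEXTURE_FEATURE_NAMES


def read_image(path: str | Path):
    """Read a TIFF/PNG image as an :class:`SHGImage`, bit depth preserved."""
    from .synthetic import SHGImage

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        px = tifffile.imread(path)
    elif suffix == ".png":
        px = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r} for {path} "
                         "(expected TIFF or PNG)")
    if px.ndim == 3:  # collapse an accidental RGB to gray by averaging
        px = px.mean(axis=2)
    bit_depth = 16 if px.dtype == np.uint16 else 8
    return SHGImage(pixels=px, bit_depth=bit_depth)


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(pixels))
    elif suffix == ".png":
        iio.imwrite(path, np.asarray(pixels).astype(np.uint8))
    else:
        raise ValueError(f"unsupported image format {suffix!r}")


def feature_columns(n_features: int = 130) -> list[str]:
    return [f"f{i:03d}" for i in range(1, n_features + 1)]


def feature_manifest(n_features: int = 130) -> dict:
    """Map each CSV column to its descriptive feature name and index."""
    names = ALL_FEATURE_NAMES[:n_features]
    return {f"f{i + 1:03d}": {"index": i + 1, "name": name,
                              "block": "morphological" if i < 21
                              else "textural"}
            for i, name in enumerate(names)}


def _provenance(seed: int | None, config: dict | None) -> str:
    h = "none"
    if config is not None:
        h = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
    return f"# fibrostage v{__version__} seed={seed} config={h}"


def write_feature_table(df: pd.DataFrame, path: str | Path,
                        seed: int | None = None,
                        config: dict | None = None) -> None:
    """Write a feature table CSV with a provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance(seed, config) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table, validating the schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path, comment="#")
    for col in ("image_id", "stage"):
        if col not in df.columns:
            raise ValueError(f"feature table {path} is missing the "
                             f"required column {col!r}")
    fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    if df[fcols].isna().any().any():
        raise ValueError(f"feature table {path} contains missing values")
    return df
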