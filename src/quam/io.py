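"""Standard-format I/O: TIFF images, CSV cell tables, YAML configs, manifests.

Cell tables are plain CSV with one row per accepted cell. Documented columns:

=======================  =====================================================
column                   meaning
=======================  =====================================================
cell_id                  object label within its field
field_id                 view-field index
condition                treatment / dose / time / culture label
culture_id               (optional) biological replicate id
area_um2                 mask area in μm²
equivalent_diameter_um   2 sqrt(area/pi)
exposure_s               exposure used for this field
raw_<channel>            background-subtracted integrated intensity
intensity_<channel>      raw / area_um2 / exposure_s (/ camera gain)
=======================  =====================================================

The schema version is recorded in every manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

CELL_TABLE_SCHEMA = "quam-cells-v1"


def write_field_tiff(path, images: dict[str, np.ndarray]) -> None:
    """Write one field as a multi-page TIFF, one page per channel (sorted keys
    preserved in insertion order; channel names stored in the page description)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with tifffile.TiffWriter(path) as tif:
        for name, img in images.items():
            tif.write(np.asarray(img), description=name)


def read_field_tiff(path) -> dict[str, np.ndarray]:
    """Read a multi-page TIFF written by :func:`write_field_tiff`."""
    out: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            name = page.description or f"channel{i}"
            out[name] = page.asarray()
    return out


def write_cells(path, cells: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cells.to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(out_dir, *, seeds: dict, parameters: dict,
                   files: list[str | Path]) -> Path:
    """Record seeds, parameters and output checksums for a pipeline run."""
    import quam

    out_dir = Path(out_dir)
    manifest = {
        "schema": CELL_TABLE_SCHEMA,
        "package_version": quam.__version__,
        "seeds": seeds,
        "parameters": parameters,
        "files": {str(Path(f).relative_to(out_dir)): sha256_file(f)
                  for f in files},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
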