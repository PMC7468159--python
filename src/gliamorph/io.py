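"""Standard-format I/O: calibrated 16-bit TIFF fields, CSV/JSON tables,
checksummed output manifests.

Calibration travels with the image: the pixel size (and channel label) is
embedded as JSON in the TIFF ImageDescription tag and must be recoverable --
reading a field with no calibration available is an error, never a silent
fall-back to pixel units.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import FieldImage

__all__ = [
    "write_field_tiff",
    "read_field_tiff",
    "write_csv_with_provenance",
    "read_csv_with_provenance",
    "write_manifest",
    "sha256_of",
]


def write_field_tiff(path: str | Path, image: FieldImage) -> None:
    """Write a field as single-channel 16-bit TIFF with embedded calibration."""
    data = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    description = json.dumps(
        {"pixel_size_um": image.pixel_size, "channel": image.channel})
    tifffile.imwrite(path, data, description=description)


def read_field_tiff(path: str | Path, pixel_size_um: float | None = None,
                    ) -> FieldImage:
    """Read a TIFF field; calibration comes from the embedded description or
    the explicit ``pixel_size_um`` override, never implicitly."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(np.float64)
        desc = tif.pages[0].description or ""
    channel = "unknown"
    embedded = None
    try:
        meta = json.loads(desc)
        embedded = meta.get("pixel_size_um")
        channel = meta.get("channel", channel)
    except (json.JSONDecodeError, AttributeError):
        pass
    ps = pixel_size_um if pixel_size_um is not None else embedded
    if ps is None:
        raise ValueError(
            f"{path}: no pixel-size calibration embedded in the TIFF and none "
            "supplied; refusing to fall back to pixel units")
    return FieldImage(data, float(ps), channel)


def write_csv_with_provenance(path: str | Path, frame: pd.DataFrame,
                              config_hash: str) -> None:
    """Write a CSV with a leading provenance comment carrying the config hash."""
    with open(path, "w") as fh:
        fh.write(f"# gliamorph config_hash={config_hash}\n")
        frame.to_csv(fh, index=False)


def read_csv_with_provenance(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir: str | Path, files: list[str | Path],
                   config_hash: str) -> Path:
    """Checksum manifest of every produced file, for byte-identity audits."""
    out_dir = Path(out_dir)
    manifest = {
        "config_hash": config_hash,
        "files": {Path(f).name: sha256_of(f) for f in sorted(map(str, files))},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
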