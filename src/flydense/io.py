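"""CSV and YAML round-tripping for every pipeline boundary."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .geometry import BottleGeometry, CameraModel


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_calibration(
    path: str | Path,
    bottle: BottleGeometry,
    cameras: tuple[CameraModel, CameraModel],
) -> Path:
    """Write the rig calibration (bottle box + both pinhole cameras) as YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "bottle": bottle.to_dict(),
        "cameras": [c.to_dict() for c in cameras],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_calibration(path: str | Path) -> tuple[BottleGeometry, list[CameraModel]]:
    doc = yaml.safe_load(Path(path).read_text())
    bottle = BottleGeometry.from_dict(doc["bottle"])
    cams = [CameraModel.from_dict(d) for d in doc["cameras"]]
    return bottle, cams


def save_config(path: str | Path, config: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
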