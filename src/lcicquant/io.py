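"""Reading and writing of the pipeline's on-disk formats.

Multi-channel sections are stored as multi-page TIFFs (one page per channel,
channel name in the page description); label and ROI masks as 16-/8-bit
TIFFs; ROI outlines as GeoJSON polygons in pixel coordinates; cell tables
and coverage records as CSV; generator configurations as YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Iterable, List, Union

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.measure import find_contours

from .errors import ConfigError
from .image import MultiChannelImage
from .intensity import CoverageRecord
from .segmentation import RoiSet
from .synth import ChannelSpec, SynthConfig

__all__ = [
    "save_multichannel_tiff",
    "load_multichannel_tiff",
    "save_label_mask",
    "load_label_mask",
    "save_roi_masks",
    "outlines_to_geojson",
    "save_outlines_geojson",
    "records_to_frame",
    "save_records_csv",
    "save_config_yaml",
    "load_config_yaml",
]

PathLike = Union[str, Path]


def save_multichannel_tiff(image: MultiChannelImage, path: PathLike) -> None:
    """One TIFF page per channel, channel name in the page description."""
    with tifffile.TiffWriter(str(path)) as tw:
        for name in image.names:
            tw.write(image[name], description=name, contiguous=False)


def load_multichannel_tiff(path: PathLike) -> MultiChannelImage:
    channels: Dict[str, np.ndarray] = {}
    with tifffile.TiffFile(str(path)) as tf:
        for i, page in enumerate(tf.pages):
            name = (page.description or "").strip() or f"ch{i}"
            channels[name] = page.asarray()
    dtype = next(iter(channels.values())).dtype
    bit_depth = 8 if dtype == np.uint8 else 16
    return MultiChannelImage(channels, bit_depth=bit_depth)


def save_label_mask(labels: np.ndarray, path: PathLike) -> None:
    if labels.max() > np.iinfo(np.uint16).max:
        raise ConfigError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def load_label_mask(path: PathLike) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def save_roi_masks(rois: RoiSet, directory: PathLike, prefix: str = "roi") -> List[Path]:
    """Each ROI mask as an 8-bit TIFF (0/255) in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("module_mask", "total_mask", "matrix_mask", "background_mask"):
        mask = getattr(rois, name)
        out = directory / f"{prefix}_{name}.tif"
        tifffile.imwrite(str(out), (mask.astype(np.uint8) * 255))
        written.append(out)
    return written


def outlines_to_geojson(labels: np.ndarray) -> dict:
    """Polygonal outlines of each labelled component, pixel coordinates.

    GeoJSON positions are (x, y) = (column, row); rings are closed.
    """
    features = []
    for value in np.unique(labels):
        if value == 0:
            continue
        for ring in find_contours(labels == value, 0.5):
            coords = [[float(c), float(r)] for r, c in ring]
            if coords[0] != coords[-1]:
                coords.append(coords[0])
            features.append(
                {
                    "type": "Feature",
                    "properties": {"label": int(value)},
                    "geometry": {"type": "Polygon", "coordinates": [coords]},
                }
            )
    return {"type": "FeatureCollection", "features": features}


def save_outlines_geojson(labels: np.ndarray, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(outlines_to_geojson(labels), fh)


def records_to_frame(records: Iterable[CoverageRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])


def save_records_csv(records: Iterable[CoverageRecord], path: PathLike) -> None:
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# YAML configuration schema
#
# Top level mirrors SynthConfig; channels is a mapping name -> ChannelSpec
# fields; coexpression_table keys are "+"-joined marker combinations;
# compartment_preference values may be null (uniform placement).

def save_config_yaml(config: SynthConfig, path: PathLike) -> None:
    data = asdict(config)
    data["channels"] = {k: asdict(v) for k, v in config.channels.items()}
    data["coexpression_table"] = {
        "+".join(combo): float(p) for combo, p in config.coexpression_table.items()
    }
    data["compartment_preference"] = dict(config.compartment_preference)
    data["band_row_range"] = list(config.band_row_range)
    data["module_semi_axes"] = [list(r) for r in config.module_semi_axes]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config_yaml(path: PathLike) -> SynthConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["channels"] = {
        k: ChannelSpec(**v) for k, v in data.get("channels", {}).items()
    }
    data["coexpression_table"] = {
        tuple(k.split("+")): float(p)
        for k, p in data.get("coexpression_table", {}).items()
    }
    data["band_row_range"] = tuple(data["band_row_range"])
    data["module_semi_axes"] = tuple(tuple(r) for r in data["module_semi_axes"])
    cfg = SynthConfig(**data)
    cfg.validate()
    return cfg
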