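"""End-to-end convenience drivers: section analysis and simulated studies."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .image import MultiChannelImage
from .intensity import CoverageRecord, quantify_section
from .segmentation import RoiSet, build_roi_set, segment_modules
from .synth import REFERENCE_CHANNEL, generate_section, preset

__all__ = ["SectionResult", "analyze_section", "simulate_study", "study_ratios"]


@dataclass
class SectionResult:
    """Everything computed for one section."""

    labels: np.ndarray
    rois: RoiSet
    records: List[CoverageRecord]


def analyze_section(
    image: MultiChannelImage,
    *,
    ref_channel: str = REFERENCE_CHANNEL,
    channels: Optional[Sequence[str]] = None,
    total_mask: Optional[np.ndarray] = None,
    margin: int = 32,
    min_area: int = 50,
    closing_radius: int = 2,
    background_box="auto",
    section_id: str = "",
    age: str = "",
) -> SectionResult:
    """Segment modules from the reference channel, build the ROI set, and
    quantify the requested marker channels of one section.

    ``total_mask`` defaults to the whole image minus ``margin`` pixels on
    every side (the synthetic-data convention); supply a hand-drawn mask
    for real material.
    """
    if total_mask is None:
        h, w = image.shape
        total_mask = np.zeros((h, w), dtype=bool)
        total_mask[margin : h - margin, margin : w - margin] = True
    labels = segment_modules(
        image[ref_channel],
        min_area=min_area,
        closing_radius=closing_radius,
        total_mask=total_mask,
    )
    rois = build_roi_set(labels, total_mask, background_box=background_box)
    if channels is None:
        channels = [n for n in image.names if n != ref_channel]
    records = quantify_section(
        image, rois, channels, section_id=section_id, age=age
    )
    return SectionResult(labels=labels, rois=rois, records=records)


def simulate_study(
    marker: str,
    ages: Sequence[str],
    n_sections: int = 15,
    seed: int = 0,
    *,
    channels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Simulate and analyse ``n_sections`` sections per age for one marker.

    Fifteen sections per age mirrors the five-sections-from-three-animals
    sampling design; each section gets an independent child seed so studies
    are reproducible from one integer. Returns the per-section coverage
    records as a data frame (one ratio per section per channel).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for age in ages:
        for i in range(n_sections):
            cfg = replace(preset(marker, age), seed=int(rng.integers(2 ** 31 - 1)))
            image, _gt = generate_section(cfg)
            result = analyze_section(
                image,
                channels=channels or [marker],
                section_id=f"{marker}_{age}_s{i:02d}",
                age=age,
            )
            rows.extend(r.to_dict() for r in result.records)
    return pd.DataFrame(rows)


def study_ratios(records: pd.DataFrame, channel: str) -> Dict[str, np.ndarray]:
    """Per-age ratio arrays for one channel from a study records frame."""
    sub = records[records["channel"] == channel]
    return {
        age: grp["ratio"].to_numpy(dtype=float)
        for age, grp in sub.groupby("age", sort=True)
    }
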