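"""Background-subtracted median coverage ratio and compartmental bias.

The areal-coverage statistic for a marker channel is

    ratio = (module median - background median) / (matrix median - background median)

computed per section on the pixel multisets of the modular, matrix and
background ROIs. Ratios above one indicate largely modular expression,
values near one homogeneous compartmental expression, and values below one
a preference for the surrounding matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import EmptyRoiError, MatrixSignalError, SaturationWarning
from .image import MultiChannelImage
from .segmentation import RoiSet

__all__ = [
    "CompartmentMedians",
    "CoverageRecord",
    "compartment_medians",
    "coverage_ratio",
    "classify_bias",
    "quantify_section",
]

SATURATION_WARN_FRACTION = 0.01


@dataclass(frozen=True)
class CompartmentMedians:
    """Exact medians over the pixel multisets of the three ROIs.

    The even-count median is the mean of the central pair. Pixel counts per
    ROI are retained for reporting.
    """

    module_median: float
    matrix_median: float
    background_median: float
    module_count: int
    matrix_count: int
    background_count: int


@dataclass
class CoverageRecord:
    """One section x channel coverage measurement."""

    section_id: str
    channel: str
    age: str
    medians: CompartmentMedians
    ratio: float
    bias: str
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict[str, object]:
        m = self.medians
        return {
            "section_id": self.section_id,
            "channel": self.channel,
            "age": self.age,
            "module_median": m.module_median,
            "matrix_median": m.matrix_median,
            "background_median": m.background_median,
            "module_count": m.module_count,
            "matrix_count": m.matrix_count,
            "background_count": m.background_count,
            "ratio": self.ratio,
            "bias": self.bias,
            "warnings": ";".join(self.warnings),
        }


def compartment_medians(
    channel: np.ndarray,
    rois: RoiSet,
    *,
    saturation_value: Optional[int] = None,
) -> CompartmentMedians:
    """Medians of the channel over the modular, matrix and background ROIs.

    Raises :class:`EmptyRoiError` naming any empty ROI. Saturated pixels
    (at ``saturation_value``, defaulting to the integer dtype ceiling) are
    included; a :class:`SaturationWarning` is emitted when they exceed 1%
    of a ROI.
    """
    channel = np.asarray(channel)
    if channel.shape != rois.total_mask.shape:
        raise ValueError("channel and ROI shapes differ")
    if saturation_value is None and np.issubdtype(channel.dtype, np.integer):
        saturation_value = int(np.iinfo(channel.dtype).max)

    stats: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    for name, mask in (
        ("module", rois.module_mask),
        ("matrix", rois.matrix_mask),
        ("background", rois.background_mask),
    ):
        values = channel[mask]
        if values.size == 0:
            raise EmptyRoiError(f"the {name} ROI contains no pixels")
        if saturation_value is not None:
            sat = np.count_nonzero(values >= saturation_value) / values.size
            if sat > SATURATION_WARN_FRACTION:
                warnings.warn(
                    f"{sat:.1%} of {name} ROI pixels are saturated",
                    SaturationWarning,
                )
        stats[name] = float(np.median(values))
        counts[name] = int(values.size)
    return CompartmentMedians(
        module_median=stats["module"],
        matrix_median=stats["matrix"],
        background_median=stats["background"],
        module_count=counts["module"],
        matrix_count=counts["matrix"],
        background_count=counts["background"],
    )


def coverage_ratio(m: CompartmentMedians) -> float:
    """(module - background) / (matrix - background) on the three medians.

    Requires the matrix median to exceed the background median strictly;
    otherwise there is no measurable matrix signal and
    :class:`MatrixSignalError` is raised.
    """
    denom = m.matrix_median - m.background_median
    if denom <= 0:
        raise MatrixSignalError(
            f"matrix median {m.matrix_median} does not exceed background "
            f"median {m.background_median}: ratio undefined"
        )
    return (m.module_median - m.background_median) / denom


def classify_bias(ratio: float, tolerance: float = 0.1) -> str:
    """Classify a ratio as ``modular`` (> 1 + tol), ``matrix`` (< 1 - tol)
    or ``homogeneous`` (within tolerance of 1)."""
    if not np.isfinite(ratio):
        raise ValueError(f"ratio must be finite, got {ratio}")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if ratio > 1.0 + tolerance:
        return "modular"
    if ratio < 1.0 - tolerance:
        return "matrix"
    return "homogeneous"


def quantify_section(
    image: MultiChannelImage,
    rois: RoiSet,
    channels: Optional[Sequence[str]] = None,
    *,
    section_id: str = "",
    age: str = "",
    tolerance: float = 0.1,
) -> List[CoverageRecord]:
    """One :class:`CoverageRecord` per requested marker channel.

    The ratio is computed per section, never on pixels pooled across
    sections.
    """
    if channels is None:
        channels = [n for n in image.names if n != "GAD"]
    records = []
    for name in channels:
        caught: List[str] = []
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            medians = compartment_medians(
                image[name], rois, saturation_value=image.saturation_value
            )
            ratio = coverage_ratio(medians)
        caught = [str(w.message) for w in wlist]
        records.append(
            CoverageRecord(
                section_id=section_id,
                channel=name,
                age=age,
                medians=medians,
                ratio=ratio,
                bias=classify_bias(ratio, tolerance),
                warnings=caught,
            )
        )
    return records
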