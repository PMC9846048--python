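"""Synthetic multi-channel section generator with known ground truth.

Emulates the modular-matrix organisation of layer 2 of the lateral cortex of
the inferior colliculus (LCIC): a horizontal band containing a handful of
discrete, non-overlapping elliptical GAD-positive modules embedded in a
surrounding matrix, with tissue-free image margins for background
estimation. Each fluorescence channel is rendered as compartment-weighted
diffuse signal plus disk-shaped labelled cells, blurred by a Gaussian PSF
and corrupted by Poisson shot noise and additive Gaussian read noise.

The :func:`preset` factory encodes the qualitative developmental
trajectories of the markers studied in this system across the early
postnatal critical period (P0-P12):

* C3 (complement component 3): diffuse neuropil label, homogeneous at birth,
  progressively lost from modules (matrix-only by P8), then gone everywhere.
* CD11b (complement receptor subunit) microglia: homogeneous, then modular
  at P8, then shifted to the matrix by P12.
* CX3CR1 (fractalkine receptor) microglia: matrix-dominant through P8, then
  entering modules at P12; never co-expressed with CD11b.
* TMEM119 microglia: absent at birth, modular thereafter, with only rare
  CX3CR1 double labelling at P12.
* Iba1 microglia: a strict subset of the CX3CR1 population.

All preset constants are implementation choices (the source imaging data is
not deposited and prints no intensities); they are collected in the
``_PRESET`` tables below and documented in ``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as disk_coords

from .errors import ConfigError, GeometryError
from .image import MultiChannelImage

__all__ = [
    "ChannelSpec",
    "SynthConfig",
    "GroundTruth",
    "generate_section",
    "preset",
    "MARKERS",
    "AGES",
]

MARKERS = ("C3", "CD11b", "CX3CR1", "TMEM119", "Iba1")
AGES = ("P0", "P4", "P8", "P12")

REFERENCE_CHANNEL = "GAD"


@dataclass(frozen=True)
class ChannelSpec:
    """Diffuse expression means (arbitrary photon units) for one channel.

    ``module_mean`` / ``matrix_mean`` are the expected diffuse intensities
    inside the two tissue compartments; ``outside_mean`` applies to the
    tissue-free margins. ``cell_amplitude`` is added on top of the diffuse
    signal inside each labelled cell body.
    """

    module_mean: float
    matrix_mean: float
    outside_mean: float = 8.0
    cell_amplitude: float = 150.0


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterisation of one synthetic section.

    Geometry is a straight horizontal band of non-overlapping ellipses: the
    curved LCIC shell is simplified to a band because every downstream
    statistic depends only on the modular/matrix topology, not curvature.
    """

    image_height: int = 256
    image_width: int = 512
    margin: int = 32                       # tissue-free border, px
    band_row_range: Tuple[int, int] = (72, 184)
    n_modules: int = 6
    # ((row semi-axis min, max), (col semi-axis min, max)), px
    module_semi_axes: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (12.0, 18.0),
        (16.0, 24.0),
    )
    module_min_gap: float = 6.0            # gap between bounding circles, px
    channels: Mapping[str, ChannelSpec] = field(
        default_factory=lambda: {REFERENCE_CHANNEL: ChannelSpec(160.0, 40.0)}
    )
    n_cells: int = 0
    # probability vector over marker-identity combinations, e.g.
    # {("CX3CR1",): 0.6, ("CX3CR1", "Iba1"): 0.4}; must sum to 1 when
    # n_cells > 0. The first marker of a combination is the "primary" one
    # whose compartment preference places the cell.
    coexpression_table: Mapping[Tuple[str, ...], float] = field(default_factory=dict)
    # probability that a cell of that marker falls in a module; None means
    # uniform placement over the whole analysis region (area-proportional).
    compartment_preference: Mapping[str, Optional[float]] = field(default_factory=dict)
    cell_radius: float = 4.0
    cell_min_separation: float = 9.0       # between cells sharing a channel, px
    psf_sigma: float = 1.0
    poisson_noise: bool = True
    read_noise_sigma: float = 2.0
    bit_depth: int = 16
    seed: int = 0

    def validate(self) -> None:
        h, w, m = self.image_height, self.image_width, self.margin
        if h <= 0 or w <= 0:
            raise ConfigError("image dimensions must be positive")
        if m < 0 or 2 * m >= min(h, w):
            raise ConfigError("margin leaves no analysis region")
        r0, r1 = self.band_row_range
        if not (m <= r0 < r1 <= h - m):
            raise ConfigError(
                f"band_row_range {self.band_row_range} must lie inside the "
                f"analysis region rows [{m}, {h - m})"
            )
        if self.n_modules < 0:
            raise ConfigError("n_modules must be >= 0")
        (ar0, ar1), (ac0, ac1) = self.module_semi_axes
        if not (0 < ar0 <= ar1 and 0 < ac0 <= ac1):
            raise ConfigError("module semi-axis ranges must be positive and ordered")
        if 2 * ar1 > (r1 - r0):
            raise ConfigError("largest module row semi-axis does not fit in the band")
        if not self.channels:
            raise ConfigError("at least one channel is required")
        for name, spec in self.channels.items():
            for val in (spec.module_mean, spec.matrix_mean, spec.outside_mean):
                if val < 0:
                    raise ConfigError(f"channel {name!r} has a negative mean")
        for marker, pref in self.compartment_preference.items():
            if pref is not None and not 0.0 <= pref <= 1.0:
                raise ConfigError(
                    f"compartment_preference[{marker!r}] = {pref} outside [0, 1]"
                )
        if self.n_cells > 0:
            if not self.coexpression_table:
                raise ConfigError("n_cells > 0 requires a coexpression_table")
            total = float(sum(self.coexpression_table.values()))
            if any(p < 0 for p in self.coexpression_table.values()):
                raise ConfigError("coexpression probabilities must be >= 0")
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigError(
                    f"coexpression_table probabilities sum to {total}, expected 1"
                )
            for combo in self.coexpression_table:
                for marker in combo:
                    if marker not in self.channels:
                        raise ConfigError(
                            f"coexpression combination {combo} names unknown "
                            f"channel {marker!r}"
                        )
        if self.cell_radius <= 0:
            raise ConfigError("cell_radius must be positive")
        if self.bit_depth not in (8, 16):
            raise ConfigError("bit_depth must be 8 or 16")

    def cell_count(self, marker: str) -> float:
        """Expected number of cells carrying ``marker``."""
        return self.n_cells * float(
            sum(p for combo, p in self.coexpression_table.items() if marker in combo)
        )


@dataclass
class GroundTruth:
    """Generator-side truth for one rendered section.

    Masks partition the image: modules and matrix are disjoint and their
    union is the total analysis region; the background box lies entirely in
    the tissue-free margin.
    """

    module_label_mask: np.ndarray          # int32, 0 = not a module
    total_mask: np.ndarray                 # bool
    matrix_mask: np.ndarray                # bool
    background_mask: np.ndarray            # bool
    true_means: Dict[str, Dict[str, float]]  # channel -> compartment -> mean
    cells: pd.DataFrame                    # columns x, y, markers, compartment

    @property
    def module_mask(self) -> np.ndarray:
        return self.module_label_mask > 0

    @property
    def n_modules(self) -> int:
        return int(self.module_label_mask.max())

    def validate(self) -> None:
        mod, mat, tot = self.module_mask, self.matrix_mask, self.total_mask
        if np.any(mod & mat):
            raise ConfigError("module and matrix masks overlap")
        if not np.array_equal(mod | mat, tot):
            raise ConfigError("module | matrix != total")
        if np.any(self.background_mask & tot):
            raise ConfigError("background box intersects the analysis region")
        labels = np.unique(self.module_label_mask)
        labels = labels[labels > 0]
        if labels.size and not np.array_equal(labels, np.arange(1, labels.size + 1)):
            raise ConfigError("module labels are not consecutive from 1")
        for _, row in self.cells.iterrows():
            r, c = int(round(row.y)), int(round(row.x))
            if not tot[r, c]:
                raise ConfigError(f"cell at ({row.x}, {row.y}) outside total region")
            comp = "module" if mod[r, c] else "matrix"
            if comp != row.compartment:
                raise ConfigError(
                    f"cell at ({row.x}, {row.y}) labelled {row.compartment!r} "
                    f"but mask says {comp!r}"
                )


# ---------------------------------------------------------------------------
# geometry

def _place_modules(config: SynthConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipse centres and semi-axes.

    Overlap is tested conservatively on bounding circles (radius = larger
    semi-axis) separated by ``module_min_gap``. The whole layout restarts if
    one module cannot be placed, keeping the draw sequence deterministic.
    """
    (ar0, ar1), (ac0, ac1) = config.module_semi_axes
    r_lo, r_hi = config.band_row_range
    m = config.margin
    for _restart in range(20):
        placed = []
        ok = True
        for _i in range(config.n_modules):
            success = False
            for _try in range(2000):
                ar = rng.uniform(ar0, ar1)
                ac = rng.uniform(ac0, ac1)
                cr = rng.uniform(r_lo + ar, r_hi - ar)
                cc_lo = m + ac + 2
                cc_hi = config.image_width - m - ac - 2
                if cc_hi <= cc_lo:
                    continue
                cc = rng.uniform(cc_lo, cc_hi)
                rad = max(ar, ac)
                if all(
                    math.hypot(cr - pr, cc - pc)
                    >= rad + max(par, pac) + config.module_min_gap
                    for pr, pc, par, pac in placed
                ):
                    placed.append((cr, cc, ar, ac))
                    success = True
                    break
            if not success:
                ok = False
                break
        if ok:
            return placed
    raise GeometryError(
        f"could not place {config.n_modules} non-overlapping modules with "
        f"semi-axes {config.module_semi_axes} and gap {config.module_min_gap} "
        f"inside band rows {config.band_row_range}"
    )


def _render_label_mask(placed, shape) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int32)
    rr_grid, cc_grid = np.mgrid[0 : shape[0], 0 : shape[1]]
    for i, (cr, cc, ar, ac) in enumerate(placed, start=1):
        inside = ((rr_grid - cr) / ar) ** 2 + ((cc_grid - cc) / ac) ** 2 <= 1.0
        labels[inside] = i
    return _relabel_scan_order(labels)


def _relabel_scan_order(labels: np.ndarray) -> np.ndarray:
    """Renumber labels consecutively in row-major first-occurrence order."""
    flat = labels.ravel()
    vals, first = np.unique(flat, return_index=True)
    keep = vals > 0
    vals, first = vals[keep], first[keep]
    order = vals[np.argsort(first)]
    out = np.zeros_like(labels)
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def _background_box(config: SynthConfig) -> np.ndarray:
    """A fixed box in the top tissue-free margin."""
    h, w, m = config.image_height, config.image_width, config.margin
    mask = np.zeros((h, w), dtype=bool)
    r0, r1 = 4, max(5, m - 4)
    half = min(64, w // 2 - 8)
    mask[r0:r1, w // 2 - half : w // 2 + half] = True
    return mask


# ---------------------------------------------------------------------------
# cells

def _place_cells(
    config: SynthConfig,
    rng: np.random.Generator,
    label_mask: np.ndarray,
    matrix_mask: np.ndarray,
    total_mask: np.ndarray,
) -> pd.DataFrame:
    rows: list = []
    if config.n_cells == 0:
        return pd.DataFrame(rows, columns=["x", "y", "markers", "compartment"])

    guard = int(math.ceil(config.cell_radius)) + 2
    h, w = total_mask.shape
    inner = np.zeros_like(total_mask)
    inner[guard : h - guard, guard : w - guard] = True
    inner &= total_mask
    # keep whole cell bodies inside the tissue so margins stay signal-free
    edge = config.margin + guard
    inner[: edge, :] = inner[h - edge :, :] = False
    inner[:, : edge] = inner[:, w - edge :] = False

    module_coords = np.argwhere((label_mask > 0) & inner)
    matrix_coords = np.argwhere(matrix_mask & inner)
    total_coords = np.argwhere(inner)

    combos = sorted(config.coexpression_table)
    probs = np.array([config.coexpression_table[c] for c in combos], dtype=float)
    probs = probs / probs.sum()

    # somata exclude each other: minimum separation holds across all cells,
    # whatever their markers, so distinct populations never sit on one spot
    placed: List[Tuple[int, int]] = []
    min_sep2 = config.cell_min_separation ** 2
    for _i in range(config.n_cells):
        combo = combos[int(rng.choice(len(combos), p=probs))]
        pref = config.compartment_preference.get(combo[0])
        if pref is None:
            coords = total_coords
        elif rng.random() < pref:
            coords = module_coords
        else:
            coords = matrix_coords
        if coords.size == 0:
            raise GeometryError(
                f"no admissible pixels for a {'+'.join(combo)} cell"
            )
        pos = None
        for _try in range(2000):
            r, c = coords[int(rng.integers(len(coords)))]
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep2 for pr, pc in placed):
                pos = (int(r), int(c))
                break
        if pos is None:
            raise GeometryError(
                f"could not place cell {_i} with min separation "
                f"{config.cell_min_separation} px"
            )
        r, c = pos
        placed.append(pos)
        compartment = "module" if label_mask[r, c] > 0 else "matrix"
        rows.append({"x": c, "y": r, "markers": "+".join(combo), "compartment": compartment})
    return pd.DataFrame(rows, columns=["x", "y", "markers", "compartment"])


# ---------------------------------------------------------------------------
# rendering

def generate_section(config: SynthConfig) -> Tuple[MultiChannelImage, GroundTruth]:
    """Render one synthetic section and its ground truth.

    Deterministic for a fixed config (including ``seed``): the random draw
    order is module geometry, then cells, then per-channel noise with
    channels visited in sorted name order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w, m = config.image_height, config.image_width, config.margin

    placed = _place_modules(config, rng)
    label_mask = _render_label_mask(placed, (h, w))
    total_mask = np.zeros((h, w), dtype=bool)
    total_mask[m : h - m, m : w - m] = True
    label_mask[~total_mask] = 0
    module_mask = label_mask > 0
    matrix_mask = total_mask & ~module_mask
    background_mask = _background_box(config)

    cells = _place_cells(config, rng, label_mask, matrix_mask, total_mask)

    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    ceiling = 2 ** config.bit_depth - 1
    channels: Dict[str, np.ndarray] = {}
    for name in sorted(config.channels):
        spec = config.channels[name]
        expected = np.full((h, w), spec.outside_mean, dtype=np.float64)
        expected[matrix_mask] = spec.matrix_mean
        expected[module_mask] = spec.module_mean
        for _, cell in cells.iterrows():
            if name in cell.markers.split("+"):
                rr, cc = disk_coords(
                    (cell.y, cell.x), config.cell_radius + 0.5, shape=(h, w)
                )
                expected[rr, cc] += spec.cell_amplitude
        if config.psf_sigma > 0:
            expected = gaussian_filter(expected, config.psf_sigma)
        if config.poisson_noise:
            img = rng.poisson(expected).astype(np.float64)
        else:
            img = expected.copy()
        if config.read_noise_sigma > 0:
            img += rng.normal(0.0, config.read_noise_sigma, size=(h, w))
        channels[name] = np.clip(np.rint(img), 0, ceiling).astype(dtype)

    true_means = {
        name: {
            "module": spec.module_mean,
            "matrix": spec.matrix_mean,
            "outside": spec.outside_mean,
        }
        for name, spec in config.channels.items()
    }
    gt = GroundTruth(
        module_label_mask=label_mask,
        total_mask=total_mask,
        matrix_mask=matrix_mask,
        background_mask=background_mask,
        true_means=true_means,
        cells=cells,
    )
    gt.validate()
    return MultiChannelImage(channels, bit_depth=config.bit_depth), gt


# ---------------------------------------------------------------------------
# presets
#
# One central constant table per marker. Diffuse means are absolute expected
# intensities (module, matrix); preferences are P(cell centre in a module),
# None = area-proportional uniform placement. These constants encode the
# qualitative developmental patterns only; the source study deposits no
# images and prints no intensity values.

_GAD_SPEC = ChannelSpec(module_mean=160.0, matrix_mean=40.0)

_C3_DIFFUSE = {
    "P0": (110.0, 110.0),   # homogeneous neuropil plexus
    "P4": (95.0, 110.0),    # first hint of modular loss
    "P8": (18.0, 110.0),    # matrix-only: modules lack C3
    "P12": (10.0, 10.0),    # cleared from both compartments
}
_CD11B_DIFFUSE = {
    "P0": (70.0, 70.0),
    "P4": (80.0, 70.0),
    "P8": (105.0, 70.0),    # concentrated within modules
    "P12": (48.0, 70.0),    # shifted to the matrix
}
_CD11B_PREF = {"P0": None, "P4": 0.5, "P8": 0.8, "P12": 0.15}
_CX3CR1_PREF = {"P0": None, "P4": 0.08, "P8": 0.08, "P12": 0.7}
_TMEM_PREF = {"P4": 0.7, "P8": 0.7, "P12": 0.7}

_CX3CR1_SPEC = ChannelSpec(15.0, 15.0)
_TMEM_SPEC = ChannelSpec(12.0, 12.0)
_IBA1_SPEC = ChannelSpec(10.0, 10.0)


def preset(marker: str, age: str) -> SynthConfig:
    """Generator configuration reproducing one marker/age pattern.

    Raises :class:`~lcicquant.errors.ConfigError` for an unknown marker or
    age. Every returned config contains the GAD reference channel.
    """
    if marker not in MARKERS:
        raise ConfigError(f"unknown marker {marker!r}; expected one of {MARKERS}")
    if age not in AGES:
        raise ConfigError(f"unknown age {age!r}; expected one of {AGES}")

    base = SynthConfig()
    if marker == "C3":
        return replace(
            base,
            channels={REFERENCE_CHANNEL: _GAD_SPEC, "C3": ChannelSpec(*_C3_DIFFUSE[age])},
        )
    if marker == "CD11b":
        return replace(
            base,
            channels={
                REFERENCE_CHANNEL: _GAD_SPEC,
                "CD11b": ChannelSpec(*_CD11B_DIFFUSE[age]),
            },
            n_cells=40,
            coexpression_table={("CD11b",): 1.0},
            compartment_preference={"CD11b": _CD11B_PREF[age]},
        )
    if marker == "CX3CR1":
        # CX3CR1 and CD11b label strictly separate microglial subsets
        return replace(
            base,
            channels={
                REFERENCE_CHANNEL: _GAD_SPEC,
                "CX3CR1": _CX3CR1_SPEC,
                "CD11b": ChannelSpec(*_CD11B_DIFFUSE[age]),
            },
            n_cells=80,
            coexpression_table={("CX3CR1",): 0.5, ("CD11b",): 0.5},
            compartment_preference={
                "CX3CR1": _CX3CR1_PREF[age],
                "CD11b": _CD11B_PREF[age],
            },
        )
    if marker == "TMEM119":
        if age == "P0":
            # TMEM119 is absent at birth; only CX3CR1 cells exist
            return replace(
                base,
                channels={
                    REFERENCE_CHANNEL: _GAD_SPEC,
                    "TMEM119": _TMEM_SPEC,
                    "CX3CR1": _CX3CR1_SPEC,
                },
                n_cells=45,
                coexpression_table={("CX3CR1",): 1.0},
                compartment_preference={"CX3CR1": _CX3CR1_PREF[age]},
            )
        if age == "P12":
            coexpr = {
                ("TMEM119",): 0.44,
                ("CX3CR1",): 0.53,
                ("TMEM119", "CX3CR1"): 0.03,  # rare double-labelled cells
            }
        else:
            coexpr = {("TMEM119",): 0.45, ("CX3CR1",): 0.55}
        return replace(
            base,
            channels={
                REFERENCE_CHANNEL: _GAD_SPEC,
                "TMEM119": _TMEM_SPEC,
                "CX3CR1": _CX3CR1_SPEC,
            },
            n_cells=80,
            coexpression_table=coexpr,
            compartment_preference={
                "TMEM119": _TMEM_PREF[age],
                "CX3CR1": _CX3CR1_PREF[age],
            },
        )
    # Iba1: every Iba1 cell co-expresses CX3CR1, never the reverse
    return replace(
        base,
        channels={
            REFERENCE_CHANNEL: _GAD_SPEC,
            "Iba1": _IBA1_SPEC,
            "CX3CR1": _CX3CR1_SPEC,
        },
        n_cells=50,
        coexpression_table={("CX3CR1", "Iba1"): 0.4, ("CX3CR1",): 0.6},
        compartment_preference={"CX3CR1": _CX3CR1_PREF[age]},
    )
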