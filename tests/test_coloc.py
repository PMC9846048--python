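"""Cell detection, overlap matrices, occupancy, and chance-level control."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from lcicquant import (
    ChannelSpec,
    SynthConfig,
    assign_compartments,
    build_roi_set,
    chance_overlap_pvalue,
    compartment_occupancy,
    detect_cells,
    generate_section,
    match_tables,
    overlap_matrix,
)
from lcicquant.errors import NoCellsError


def table(points, marker="A"):
    return pd.DataFrame(
        [{"x": x, "y": y, "radius": 4.0, "marker": marker} for x, y in points]
    )


def gt_tables(gt):
    """Cell tables per marker from ground-truth identities."""
    markers = sorted({m for combo in gt.cells.markers for m in combo.split("+")})
    out = {}
    for marker in markers:
        sel = gt.cells[gt.cells.markers.str.split("+").apply(lambda s: marker in s)]
        out[marker] = pd.DataFrame(
            {"x": sel.x, "y": sel.y, "radius": 4.0, "marker": marker}
        ).reset_index(drop=True)
    return out


class TestDetection:
    def test_counts_and_localization_low_noise(self):
        """40 generated cells on a flat background: 40 +/- 2 detections,
        each within 3 px of a true centroid."""
        cfg = SynthConfig(
            channels={"GAD": ChannelSpec(160.0, 40.0), "M": ChannelSpec(40.0, 40.0)},
            n_cells=40,
            coexpression_table={("M",): 1.0},
            compartment_preference={"M": None},
            read_noise_sigma=1.0,
            seed=4,
        )
        img, gt = generate_section(cfg)
        cells = detect_cells(img["M"], marker="M")
        assert abs(len(cells) - 40) <= 2
        true_xy = gt.cells[["x", "y"]].to_numpy(float)
        d, _ = cKDTree(true_xy).query(cells[["x", "y"]].to_numpy(float))
        assert d.max() <= 3.0

    def test_blank_image_no_detections(self):
        assert len(detect_cells(np.zeros((64, 64)))) == 0
        assert len(detect_cells(np.full((64, 64), 90.0))) == 0

    def test_detection_deterministic(self, cd11b_p8):
        image, _ = cd11b_p8
        a = detect_cells(image["CD11b"])
        b = detect_cells(image["CD11b"])
        pd.testing.assert_frame_equal(a, b)


class TestMatching:
    def test_identical_tables_full_overlap(self):
        pts = [(10, 10), (30, 12), (50, 40)]
        om = overlap_matrix({"A": table(pts, "A"), "B": table(pts, "B")},
                            match_radius=4.0)
        assert (om["p_b_given_a"] == 1.0).all()

    def test_zero_distance_cells_in_two_channels_match(self):
        om = overlap_matrix(
            {"A": table([(22, 33)], "A"), "B": table([(22, 33)], "B")},
            match_radius=4.0,
        )
        assert om["n_matched"].tolist() == [1, 1]

    def test_matching_is_one_to_one(self):
        a = table([(10, 10), (12, 10)], "A")
        b = table([(11, 10)], "B")
        matches = match_tables(a, b, match_radius=4.0)
        assert len(matches) == 1
        assert matches[0][0] == 0          # the nearer A cell wins

    @pytest.mark.parametrize("seed", range(3))
    def test_matching_symmetric_in_listing_order(self, seed):
        rng = np.random.default_rng(seed)
        a = table(rng.integers(0, 100, (25, 2)).tolist(), "A")
        b = table(rng.integers(0, 100, (25, 2)).tolist(), "B")
        ab = overlap_matrix({"A": a, "B": b}, match_radius=6.0)
        ba = overlap_matrix({"B": b, "A": a}, match_radius=6.0)
        key = ["marker_a", "marker_b"]
        pd.testing.assert_frame_equal(
            ab.sort_values(key).reset_index(drop=True),
            ba.sort_values(key).reset_index(drop=True),
        )

    def test_ground_truth_identities_iba1_subset(self, iba1_p8):
        """Every Iba1 cell is CX3CR1-positive; the reverse does not hold."""
        _, gt = iba1_p8
        tables = gt_tables(gt)
        om = overlap_matrix(tables, match_radius=4.0).set_index(
            ["marker_a", "marker_b"]
        )
        assert om.loc[("Iba1", "CX3CR1"), "p_b_given_a"] == 1.0
        assert om.loc[("CX3CR1", "Iba1"), "p_b_given_a"] < 1.0


class TestOccupancy:
    def _rois(self, gt):
        return build_roi_set(gt.module_label_mask, gt.total_mask)

    def test_all_cells_in_modules(self, c3_p8):
        _, gt = c3_p8
        rois = self._rois(gt)
        rr, cc = np.nonzero(rois.module_mask)
        cells = table(list(zip(cc[:10].tolist(), rr[:10].tolist())))
        assert compartment_occupancy(cells, rois) == (1.0, 0.0)

    def test_fractions_sum_to_one(self, cd11b_p8):
        image, gt = cd11b_p8
        rois = self._rois(gt)
        cells = assign_compartments(detect_cells(image["CD11b"]), rois)
        mod, mat = compartment_occupancy(cells, rois)
        assert mod + mat == pytest.approx(1.0)

    def test_uniform_placement_matches_area_fraction(self):
        """Uniformly placed cells occupy modules at the areal chance level."""
        n_mod = n_tot = 0
        area_fracs = []
        for seed in range(20):
            cfg = SynthConfig(
                channels={"GAD": ChannelSpec(160.0, 40.0),
                          "M": ChannelSpec(40.0, 40.0)},
                n_cells=60,
                coexpression_table={("M",): 1.0},
                compartment_preference={"M": None},
                seed=seed,
            )
            _, gt = generate_section(cfg)
            n_mod += int((gt.cells.compartment == "module").sum())
            n_tot += len(gt.cells)
            area_fracs.append(gt.module_mask.sum() / gt.total_mask.sum())
        assert abs(n_mod / n_tot - np.mean(area_fracs)) < 0.03

    def test_cd11b_p8_occupancy_above_chance(self, cd11b_p8):
        image, gt = cd11b_p8
        rois = self._rois(gt)
        cells = assign_compartments(detect_cells(image["CD11b"]), rois)
        mod_frac, _ = compartment_occupancy(cells, rois)
        chance = rois.module_area / rois.total_area
        assert mod_frac > 2 * chance

    def test_no_in_region_cells_raises(self, c3_p8):
        _, gt = c3_p8
        rois = self._rois(gt)
        cells = table([(1, 1)])        # in the margin, outside total
        with pytest.raises(NoCellsError):
            compartment_occupancy(cells, rois)


def test_chance_level_permutation_control():
    """Independently, uniformly placed markers show chance-level overlap."""
    cfg = SynthConfig(
        channels={
            "GAD": ChannelSpec(160.0, 40.0),
            "A": ChannelSpec(40.0, 40.0),
            "B": ChannelSpec(40.0, 40.0),
        },
        n_cells=80,
        coexpression_table={("A",): 0.5, ("B",): 0.5},
        compartment_preference={"A": None, "B": None},
        seed=9,
    )
    _, gt = generate_section(cfg)
    tables = gt_tables(gt)
    rois = build_roi_set(gt.module_label_mask, gt.total_mask)
    _, p = chance_overlap_pvalue(
        tables["A"], tables["B"], rois, match_radius=4.0,
        n_permutations=99, seed=0,
    )
    assert p >= 0.05
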