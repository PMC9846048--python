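"""Generator determinism, geometry invariants and preset semantics."""

from dataclasses import replace

import numpy as np
import pytest

from lcicquant import (
    AGES,
    ChannelSpec,
    SynthConfig,
    analyze_section,
    generate_section,
    preset,
)
from lcicquant.errors import ConfigError, GeometryError


def test_same_seed_bit_identical():
    cfg = replace(preset("CD11b", "P8"), seed=42)
    img1, gt1 = generate_section(cfg)
    img2, gt2 = generate_section(cfg)
    for name in img1.names:
        assert np.array_equal(img1[name], img2[name])
    assert np.array_equal(gt1.module_label_mask, gt2.module_label_mask)
    assert gt1.cells.equals(gt2.cells)


def test_different_seeds_differ():
    img1, _ = generate_section(replace(preset("C3", "P8"), seed=0))
    img2, _ = generate_section(replace(preset("C3", "P8"), seed=1))
    assert not np.array_equal(img1["GAD"], img2["GAD"])


@pytest.mark.parametrize("n_modules", [1, 4, 6, 8])
def test_module_count_by_construction(n_modules):
    cfg = replace(SynthConfig(seed=3), n_modules=n_modules)
    _, gt = generate_section(cfg)
    assert gt.n_modules == n_modules
    labels = np.unique(gt.module_label_mask)
    assert np.array_equal(labels, np.arange(n_modules + 1))


@pytest.mark.parametrize("seed", range(5))
def test_mask_algebra_invariants(seed):
    """Modules, matrix and outside are pairwise disjoint; modules + matrix = total."""
    _, gt = generate_section(replace(preset("CD11b", "P8"), seed=seed))
    assert not np.any(gt.module_mask & gt.matrix_mask)
    assert np.array_equal(gt.module_mask | gt.matrix_mask, gt.total_mask)
    assert not np.any(gt.background_mask & gt.total_mask)
    # every cell centroid lies inside the total region with a matching label
    gt.validate()


def test_noise_free_render_is_exact():
    """With PSF and noise off, each compartment renders its configured mean."""
    cfg = SynthConfig(
        channels={"GAD": ChannelSpec(160.0, 40.0, 8.0)},
        psf_sigma=0.0,
        poisson_noise=False,
        read_noise_sigma=0.0,
        seed=2,
    )
    img, gt = generate_section(cfg)
    arr = img["GAD"]
    assert np.all(arr[gt.module_mask] == 160)
    assert np.all(arr[gt.matrix_mask] == 40)
    assert np.all(arr[~gt.total_mask] == 8)


def test_equal_means_give_unit_ratio():
    """module_mean == matrix_mean drives the downstream ratio to ~1."""
    ratios = []
    for seed in range(20):
        cfg = SynthConfig(
            channels={
                "GAD": ChannelSpec(160.0, 40.0),
                "X": ChannelSpec(100.0, 100.0),
            },
            seed=seed,
        )
        img, _ = generate_section(cfg)
        res = analyze_section(img, channels=["X"])
        ratios.append(res.records[0].ratio)
    assert abs(np.mean(ratios) - 1.0) < 0.05


def test_compartment_preference_fraction():
    """Cell module-fraction tracks the configured preference (binomial bounds)."""
    pref = 0.8
    n_mod = 0
    n_tot = 0
    for seed in range(10):
        cfg = SynthConfig(
            channels={"GAD": ChannelSpec(160.0, 40.0), "M": ChannelSpec(40.0, 40.0)},
            n_cells=40,
            coexpression_table={("M",): 1.0},
            compartment_preference={"M": pref},
            seed=seed,
        )
        _, gt = generate_section(cfg)
        n_mod += int((gt.cells.compartment == "module").sum())
        n_tot += len(gt.cells)
    frac = n_mod / n_tot
    # 3 sigma binomial bound at n = 400
    assert abs(frac - pref) < 3 * np.sqrt(pref * (1 - pref) / n_tot) + 1e-9


def test_infeasible_geometry_raises():
    cfg = replace(
        SynthConfig(seed=0),
        n_modules=40,
        module_semi_axes=((30.0, 40.0), (40.0, 55.0)),
        band_row_range=(72, 184),
    )
    with pytest.raises((GeometryError, ConfigError)):
        generate_section(cfg)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        SynthConfig(channels={"GAD": ChannelSpec(-1.0, 40.0)}).validate()
    with pytest.raises(ConfigError):
        SynthConfig(
            channels={"GAD": ChannelSpec(160.0, 40.0)},
            n_cells=5,
            coexpression_table={("GAD",): 0.4},
        ).validate()
    with pytest.raises(ConfigError):
        SynthConfig(band_row_range=(0, 300)).validate()


class TestPresets:
    def test_c3_p8_module_weight_far_below_matrix(self):
        cfg = preset("C3", "P8")
        spec = cfg.channels["C3"]
        assert spec.module_mean < 0.3 * spec.matrix_mean

    def test_c3_trajectory_monotone_loss(self):
        """Modular C3 falls from homogeneous at P0 to near absence at P12."""
        mod = [preset("C3", age).channels["C3"].module_mean for age in AGES]
        assert mod[0] > mod[1] > mod[2] > mod[3]

    def test_cd11b_p8_modular_preference(self):
        cfg = preset("CD11b", "P8")
        assert cfg.compartment_preference["CD11b"] > 0.5

    def test_cd11b_p12_matrix_preference(self):
        cfg = preset("CD11b", "P12")
        assert cfg.compartment_preference["CD11b"] < 0.5

    def test_iba1_is_subset_of_cx3cr1(self):
        cfg = preset("Iba1", "P8")
        iba = sum(p for c, p in cfg.coexpression_table.items() if "Iba1" in c)
        both = sum(
            p for c, p in cfg.coexpression_table.items()
            if "Iba1" in c and "CX3CR1" in c
        )
        only_cx = sum(
            p for c, p in cfg.coexpression_table.items()
            if "CX3CR1" in c and "Iba1" not in c
        )
        assert iba > 0 and both == pytest.approx(iba)  # P(CX3CR1+ | Iba1+) = 1
        assert only_cx > 0                             # P(CX3CR1+ only) > 0

    def test_cx3cr1_and_cd11b_never_coexpressed(self):
        cfg = preset("CX3CR1", "P8")
        assert all(
            not ("CX3CR1" in combo and "CD11b" in combo)
            for combo in cfg.coexpression_table
        )

    def test_tmem119_absent_at_birth_rare_overlap_at_p12(self):
        assert preset("TMEM119", "P0").cell_count("TMEM119") == 0
        p12 = preset("TMEM119", "P12")
        overlap = sum(
            p for c, p in p12.coexpression_table.items()
            if "TMEM119" in c and "CX3CR1" in c
        )
        assert 0 < overlap < 0.1

    def test_unknown_marker_or_age_rejected(self):
        with pytest.raises(ConfigError):
            preset("GFAP", "P8")
        with pytest.raises(ConfigError):
            preset("C3", "P6")
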