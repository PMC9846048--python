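# lcicquant

Compartment-specific fluorescence quantification for the developing lateral
cortex of the inferior colliculus (LCIC).

During the early postnatal critical period (P0–P12), LCIC layer 2 organises
into discrete GAD-positive **modules** embedded in a surrounding **matrix**,
and several immunomarkers — complement component C3, the complement-receptor
subunit CD11b, the fractalkine receptor CX3CR1, TMEM119 and Iba1 — change
their preference for one compartment or the other. Quantifying those shifts
from epifluorescence micrographs is usually done by hand in ImageJ/FIJI:
threshold the GAD channel to outline modules, XOR against the whole-region
outline to get the matrix, drop a background box on tissue-free space,
compare medians, and eyeball paired plot profiles. `lcicquant` automates that
workflow as a tested, scriptable pipeline for anyone analysing
modular/matrix (or any patch/surround) compartmental expression.

## What it computes

**Coverage ratio.** For each section and marker channel, with ROI medians
*M*<sub>mod</sub>, *M*<sub>mat</sub>, *M*<sub>bg</sub>:

    ratio = (M_mod − M_bg) / (M_mat − M_bg)

Ratios above 1 indicate modular bias, near 1 homogeneous expression, below 1
matrix preference. Ratios are computed per section (never on pooled pixels)
and compared across ages with a two-sided Mann–Whitney U test (exact null
for small groups), plus a "disjoint boxes" criterion on Tukey hinge
quartiles: boxes are disjoint when three quarters of one group lie above
three quarters of the other.

**Phase concordance.** Both channels of a section are sampled along one
identical thick contour (default thickness 100 px) threaded through the
modules ventral→dorsal; the zero-lag Pearson correlation *r* of the linearly
detrended profiles quantifies whether the waveforms are in phase (*r* > 0)
or out of phase (*r* < 0, e.g. C3 troughs on GAD peaks).

**Object-based colocalization.** Cells are detected per channel by
multi-scale LoG blob detection; double labelling is a one-to-one
mutual-nearest-neighbour matching of centroids within a small radius,
reported as conditional fractions P(B|A), together with modular/matrix
occupancy of each population.

**Synthetic sections.** A generator renders multi-channel sections with a
known band of elliptical modules, compartment-weighted diffuse signal,
disk-shaped cells with configurable compartment preference and
marker-coexpression tables, Gaussian PSF and Poisson + read noise — so every
stage of the pipeline can be validated against ground truth. `preset(marker,
age)` encodes the qualitative developmental trajectories of the five markers
above.

## Worked example

```python
from dataclasses import replace
import numpy as np
from lcicquant import (preset, generate_section, analyze_section,
                       build_sampling_contour, profile_pair,
                       simulate_study, study_ratios, compare_groups,
                       boxes_disjoint)

# one synthetic P8 section: C3 should be matrix-only
image, truth = generate_section(replace(preset("C3", "P8"), seed=11))
result = analyze_section(image, section_id="demo", age="P8")
rec = result.records[0]
print(rec.channel, round(rec.ratio, 3), rec.bias)
# C3 0.119 matrix

contour = build_sampling_contour(result.labels, thickness=100)
print(round(profile_pair(image, "GAD", "C3", contour).r, 3))
# -0.883

# a full scaled study: 15 sections per age
records = simulate_study("C3", ["P4", "P8"], n_sections=15, seed=1)
r = study_ratios(records, "C3")
u, p = compare_groups(r["P4"], r["P8"])
print(round(float(np.median(r["P4"])), 3), round(float(np.median(r["P8"])), 3))
# 0.863 0.109
print(p < 0.001, boxes_disjoint(r["P4"], r["P8"]))
# True True
```

The first ratio (0.119 ≪ 1) reflects selective C3 loss from modules at P8;
the profile correlation (−0.88) says the C3 and GAD waveforms are strongly
out of phase; the study comparison shows the significant P4→P8 drop in
modular C3 coverage with fully disjoint boxes.

The same operations are available from a shell:

```bash
lcicquant simulate --preset C3:P8 --n-sections 15 --seed 7 --out sections/
lcicquant segment  --image sections/section_000.tif --out seg/
lcicquant quantify --image sections/section_000.tif --channels C3 --age P8 --out records.csv
lcicquant profile  --image sections/section_000.tif --channels GAD,C3 --out profile.csv
lcicquant coloc    --image sections/section_000.tif --markers CX3CR1,CD11b --out coloc/
lcicquant report   --records records.csv --out report/
```

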