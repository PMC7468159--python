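# gliamorph

Morphometry of immunolabelled glial cells (IBA-1 microglia, GFAP
astrocytes) on 2-D fluorescence micrographs, built for studies that compare
genotype groups cell by cell: somata are detected as bright connected
regions above an intensity quantile, processes are traced outward by
skeletonization, and each cell is reduced to the eight parameters used in
hippocampal glia studies — cell density (cells/mm²), number of primary
branches, number of branch points, total branch length (µm), cell radius
(µm), cell area (µm²), soma area (µm²) and soma eccentricity. A statistics
layer reproduces the normality-gated comparison protocol of such studies,
and a densitometry module normalizes Western-blot band intensities to
β-actin and the wild-type blot mean.

Since studies of this kind rarely deposit raw images, the package includes a
first-class synthetic generator: fields of branched cells with *analytic*
ground truth (soma area `πab`, eccentricity `√(1−(b/a)²)`, branch lengths
and bifurcation counts straight from the generating tree), so the entire
measurement chain is testable end to end without any download.

## The measurement in brief

For an image `I` with pixel size `s` (µm/px):

1. thresholds — soma cut `T_soma` and background cut `T_bg` as empirical
   intensity quantiles of `I` (or per-image automatic cuts: triangle
   threshold for background, Otsu within the foreground for somata);
2. somata — 8-connected components of `{I ≥ T_soma}` with at least
   `min_size_px` pixels (100–200 px convention); shape from the
   second-moment ellipse, eccentricity `√(1 − λ₂/λ₁)`;
3. processes — skeleton of the cleaned mask `{I ≥ T_bg}`, pixels assigned
   to their geodesically nearest soma, spurs shorter than 2 µm pruned;
   diagonal steps weigh `√2·s`;
4. per cell — primary branches = skeleton crossings of the soma boundary,
   branch points = degree-≥3 skeleton clusters, plus lengths, radii, areas;
5. groups — per-animal means, Lilliefors-screened (Dallal–Wilkinson p)
   dispatch to a pooled two-tailed Student's t-test or a Mann–Whitney U
   test (exact by enumeration for pooled n ≤ 12), `*` p < 0.05, `**`
   p < 0.01.

Details, tolerances and design rationale: [`docs/methods.md`](docs/methods.md).

## Worked example

```python
import numpy as np
import gliamorph as gm

rng = np.random.default_rng(0)
specs = gm.sample_field_specs(rng, 6, 424.0, gm.CellRegime(noise_sd=200.0))
image, truth = gm.render_field(specs, 424.0, 0.415, rng_seed=1)

fm = gm.measure_field(image, gm.PipelineConfig())
print(f"detected {fm.summary.n_cells} somata, "
      f"density {fm.summary.density_cells_per_mm2:.1f} cells/mm^2")
```

prints

```
detected 6 somata, density 33.4 cells/mm^2
cell 1: 6 primary branches (planted 6), 5 branch points (planted 5)
        total branch length 174.3 um (planted 170.7), soma eccentricity 0.835 (planted 0.842)
```

— six planted cells at a process-contrast SNR of 5, all six detected;
branch and junction counts recovered exactly, length within ~2%,
eccentricity within 0.01 of the generating ellipse.

The same flow from the shell, with a simulated two-genotype study (the
mutant group carries the dentate-gyrus astrocyte effect, total branch
length ×0.58):

```
gliamorph simulate --out data --seed 42
gliamorph measure data/*.tif --samples data/samples.csv --out meas
gliamorph compare --cells meas/cells.csv --fields meas/fields.csv --out report.csv
```

```
region              parameter  wt_mean   wt_sem  n_wt  mut_mean  mut_sem  n_mut    test_used  statistic  p_two_tailed significance
    DG   cell_density_per_mm2    61.15    4.651     5     67.82    2.723      5 mann_whitney        7.5        0.3333           NS
    DG        n_branch_points     5.37   0.1735     5     2.408  0.03306      5    student_t      16.77     1.619e-07           **
    DG     n_primary_branches    5.131  0.04752     5     4.973  0.07592      5    student_t      1.765        0.1156           NS
    DG      soma_eccentricity   0.8221 0.003782     5     0.822 0.003876      5 mann_whitney         12             1           NS
    DG total_branch_length_um    178.6    2.358     5     99.64   0.7072      5    student_t      32.07     9.737e-10           **
```

(abridged) — the planted reductions in branch points and branch length come
out highly significant, while density, primary branches and soma shape are
correctly reported unchanged: the measured mutant/WT branch-length ratio,
99.6/178.6 ≈ 0.56, tracks the planted 0.58. `gliamorph densitometry`
produces the analogous table for blot data.

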