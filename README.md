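# ais-mito-quant

Quantification of mitochondrial distribution in *Drosophila*
mushroom-body (MB) neurons from two-channel confocal stacks, focused on
the axon initial segment (AIS) — the proximal-axon compartment that
gates organelle passage between the somatodendritic and axonal domains.
The package is aimed at researchers quantifying fluorescence images of
MB neurons (or comparable neurite geometries) who need the measurements
behind genotype × age comparisons of mitochondrial localisation, plus a
fully synthetic test bed with known ground truth.

## What it measures

Given a stack with a mitochondrial channel (0) and a structural AIS
marker channel (1, e.g. actin/FasII-like, depleted inside the AIS):

1. **Compartment ratio.** The mitochondrial channel is thresholded to a
   single fixed value *t* (voxels `< t` become NaN). For an ROI *R* the
   mean intensity is the summed intensity of surviving voxels divided by
   their count. The somatodendritic-to-axonal ratio is

   *r* = ⟨I⟩<sub>calyx</sub> / ⟨I⟩<sub>dorsal-lobe</sub>.

2. **AIS profile.** The thresholded stack is max-projected over z; a
   rectangular ROI (37 µm for larvae, 47 µm for adults, about the
   peduncle width) laid across the AIS is resampled into its rotated
   frame, averaged across the width, binned at 0.41 µm along the length,
   and normalised to the trace maximum. Positions are signed µm with 0
   at the ROI centre and the distal axon negative.

3. **Signal dropout.** With AIS edges (x<sub>d</sub>, x<sub>p</sub>) —
   supplied manually or detected as the longest trough of the normalised
   marker profile — a chord c(x) joins the profile values at the edges
   and the dropout area is

   A = ∫ max(c(x) − y(x), 0) dx over [x<sub>d</sub>, x<sub>p</sub>] (µm),

   reported alongside the plain integral ∫ y dx of normalised intensity
   over the AIS.

4. **Statistics.** Hemisphere measurements are technical replicates
   averaged per fly; samples are gated by a Kolmogorov–Smirnov normality
   test and an equality-of-variances test (F-test / Bartlett); two
   groups are compared by unpaired t-test (pooled or Welch) or
   Mann–Whitney U (exact at small n), and genotype × age designs by
   two-way ANOVA (Type-III, sum-to-zero) with Šidák-adjusted pairwise
   contrasts, p<sub>adj</sub> = 1 − (1 − p)<sup>m</sup>.

The synthetic generator builds an MB-like scene (spherical calyx,
cylindrical peduncle containing the AIS, axonal lobe), places
mitochondrial puncta by a Poisson process with per-compartment densities
thinned inside the AIS by an exclusion depth d ∈ [0, 1], renders them as
PSF-blurred Gaussian spots with Poisson + Gaussian noise, and emits the
ground truth (labels, puncta, true AIS interval, true density ratio).

## Worked example

The default configuration is a demo cohort: a wild-type-like group with
AIS exclusion depth 0.8 versus a knockout-like group with depth 0.0
(matched densities elsewhere), n = 8 flies each:

```sh
ais-mito-quant run-all --out demo_out --seed 1
```

`demo_out/report.txt` from that exact command:

```
                 ratio         dropout_area         integrated_intensity
                  mean     sem         mean     sem                 mean     sem
genotype age
KO       larva  1.1053  0.0104       0.6877  0.2575              11.0719  0.2641
WT       larva  1.1171  0.0115       3.6130  0.2107               3.0185  0.0724

ratio                  KO vs WT   unpaired t-test (pooled)  p=0.4596    [ns]
dropout_area           KO vs WT   unpaired t-test (pooled)  p=4.485e-07 [*]
integrated_intensity   KO vs WT   unpaired t-test (Welch)   p=1.774e-09 [*]
```

Reading: losing AIS exclusion (KO-like) collapses the dropout area
(0.69 vs 3.61 µm) and fills the AIS with signal (integrated intensity
11.1 vs 3.0 µm over the 14 µm interval) while leaving the gross
somatodendritic:axonal balance unchanged (ratio ≈ 1.11 in both,
p = 0.46) — the dissociation the measurements are designed to resolve.
Per-fly values are in `measurements.csv`, normalised traces in
`profiles.csv` / `group_profiles.csv`, test decision trails in
`comparisons.csv`, and every threshold, seed and file hash in
`manifest.json`.

Other subcommands (`simulate`, `quantify-ratio`, `profile`,
`profile-aggregate`, `dropout`, `stats`, `make-fixtures`) expose the
individual stages on stored TIFF/ROI/CSV files; the library API mirrors
them (`simulate_stack`, `somatodendritic_axonal_ratio`,
`extract_profile`, `chord_dropout_area`, `compare_two_way`, ...).

## Documentation

`docs/methods.md` describes the measurement model, the synthetic scene
and its parameters, numerical choices, and known limitations.
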