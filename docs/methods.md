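# Methods

## Measurement model

### Thresholding and compartment means

All intensity measurements operate on 32-bit floating point voxels. A
single intensity threshold *t* is fixed per experiment and applied to
the mitochondrial channel of every image: voxels strictly below *t*
become NaN ("missing"), voxels equal to *t* survive. The mean intensity
of an ROI is then Σ(surviving voxels) / #(surviving voxels) — the
"non-zero area" convention, where validity is defined by the threshold
rather than by literal zeros. The somatodendritic:axonal ratio divides
the calyx ROI mean by the dorsal/alpha-lobe ROI mean; only the dorsal
lobe is used on the axonal side because it is the lobe that can be
isolated consistently, and the synthetic scene mirrors that with a
single lobe.

ROIs are 2-D polygons in physical µm applied as a prism through every
z-slice. The prism choice (rather than per-slice redrawing) is safe
because thresholding removes the out-of-structure background that a
prism would otherwise sweep up; it is also the only interpretation that
needs no per-slice input. The threshold value itself is a free
configuration parameter (no published value exists); the default of 15
intensity units sits several noise standard deviations above the
default background of 5, so background is masked while the neuron
interior survives essentially intact. Because one value must serve a
whole experiment, the configuration carries exactly one threshold.

### AIS intensity profiles

The thresholded mitochondrial channel is flattened by maximum projection
over z (a pixel is missing only if missing in every slice). A
rectangular ROI of configurable length per age class (defaults 37 µm
larval, 47 µm adult — spanning the AIS with flanking axon on both
sides) and roughly the peduncle width is laid across the AIS with its
centre at the approximate AIS centre. The image is resampled into the
ROI's rotated frame by bilinear interpolation at 4× oversampling
(samples every bin_width/4 along both axes). Missing pixels are handled
by normalised convolution — values and validity weights are
interpolated separately and a sample survives only while more than half
its interpolation weight comes from valid pixels. Samples are averaged
across the width, then within length bins of 0.41 µm; the bin count is
round(length / bin_width) and bin centres sit symmetrically about the
ROI centre (position 0), signed so the distal axon is negative.
Width-averaging before binning and binning before normalisation are
equivalent to the reverse orders for uniform weights; they are fixed
this way for determinism. Each trace is normalised to its own maximum
(the maximum of the binned trace, not of the whole image — the trace is
the quantity being plotted, and this keeps normalisation independent of
bright structures outside the ROI). Group curves report the per-bin
mean and SEM (sample sd / √n) across flies.

### Dropout statistic

On a normalised profile with AIS edges (x_d, x_p), the chord c(x) joins
(x_d, y(x_d)) and (x_p, y(x_p)); the dropout area is the integral of
max(c − y, 0) over the interval. Only the region where the curve lies
below the chord counts: the quantity is a signal *dropout* (a
depression), and segments rising above the chord contribute nothing.
The companion statistic is the plain integral of y over the interval;
both are reported side by side because published figure legends are
ambiguous about which is plotted. When the profile is pinned to 1 at
both edges and bounded by 1, the two are complementary: dropout +
integral = interval width (this identity is a test).

Integration is trapezoid-rule on the bin centres with linear
interpolation at the interval edges, plus the exact chord/curve crossing
points inserted as nodes so the positive-part integral is exact for the
piecewise-linear trace. NaN bins inside the interval are bridged by
linear interpolation between the neighbouring valid bins.

AIS edges default to a manually supplied interval (mirroring
marker-guided manual practice); an automatic detector exists mainly for
synthetic self-tests. It takes the normalised structural-marker profile,
computes a baseline as the median of the flanking 25% of bins at each
end, and returns the longest contiguous run of bins below
trough_fraction × baseline (default 0.6) that is at least min_run_um
long (default 2 µm); ties keep the most distal run. These detector
parameters are explicitly arbitrary — no published criterion for the
manual edge calls exists to recover.

### Statistics

Hemisphere measurements from one brain are technical replicates,
averaged to one value per fly before testing. Normality is checked with
a Kolmogorov–Smirnov test against a normal with the sample's own mean
and sd; this is the common packaged behaviour and is approximate (no
Lilliefors correction), which matters only near the gate boundary. A
constant sample returns p = 0 (treated as non-normal). Variance
equality uses the F-test for two groups and Bartlett's test otherwise.
Two groups passing both gates are compared with an unpaired two-sided
t-test — pooled variance, or Welch when the variance gate fails;
otherwise a two-sided Mann–Whitney U, exact for combined n ≤ 20 without
ties and a tie-corrected normal approximation beyond that (determinism
at small n motivates the exact branch). Genotype × age designs use
two-way ANOVA with partial (Type-III-style) sums of squares under
sum-to-zero encoding — the cohorts are unbalanced and marginal tests
must not depend on factor order — followed by pairwise genotype
contrasts within each age level on the model's residual mean square,
Šidák-adjusted over the total number of contrasts
(p_adj = 1 − (1 − p)^m). The t-test variant and sums-of-squares type
are this package's explicit choices; published methods sections leave
them unstated.

## Synthetic scene

The generator emulates a two-channel confocal acquisition of one MB
hemisphere: a spherical calyx (soma + dendrites), a cylindrical
peduncle whose sub-interval is the AIS, and a cylindrical axonal lobe,
labelled per voxel with priority calyx > AIS > proximal axon > lobe.
The default scene is scaled down to a 20 × 40 × 120 µm field of view at
(1.0, 0.25, 0.25) µm voxels — the 1 µm z-step matches the acquisition
geometry being emulated, and the ~120 µm long axis keeps a whole
hemisphere-like scene at desk-scale compute. Calyx: radius 9 µm centred
at x = 95 µm; peduncle: radius 3 µm from x = 45 to 87 µm with the AIS
at x = 60–74 µm (14 µm, between the larval and adult AIS extents);
lobe: radius 6 µm from x = 7 to 45 µm. The calyx sits at +x and the
lobe at −x, so signed profile coordinates (distal negative) follow the
x-axis.

Mitochondria are puncta from a Poisson point process: per-compartment
counts are Poisson(density × volume), positions uniform over the
compartment's voxels with sub-voxel jitter. Inside the AIS the base
density is thinned by 1 − d·w(u), with exclusion depth d ∈ [0, 1],
u ∈ [0, 1] the normalised axial position (0 distal, 1 proximal), and
w either uniform (w ≡ 1, depletion throughout the AIS — the larval
pattern) or proximal-weighted (w = u, strongest proximal depletion with
signal recovering toward the distal AIS — the adult pattern).
Wild-type-like groups default to d = 0.8; knockout-like groups to
d = 0. No published mitochondrial densities exist for this tissue, so
the defaults are free parameters chosen for realism, not estimates of
fly data: 1.0 puncta/µm³ in every compartment (a dense axon bundle
yields near-continuous signal), punctum amplitude ~N(100, 20²) with
hard floor 0, punctum sigma 0.5 µm.

Rendering evaluates each punctum as a 3-D Gaussian at voxel centres
with per-axis sigma √(punctum² + PSF²) — a Gaussian spot imaged through
a Gaussian PSF stays Gaussian, so the blur is applied in closed form
and the amplitude is the post-blur peak. Kernels are truncated at 6σ
(error < 2×10⁻⁸ of the peak). The PSF default is (1.0, 0.25, 0.25) µm.
The marker channel fills all neuron labels at level 100, attenuated to
0.3× inside the AIS (strong enough for automated boundary detection)
and blurred by the PSF. Both channels receive background 5, shot noise
as Poisson(intensity × scale)/scale with scale 2 photons per intensity
unit, and additive read noise of sd 1; an optional clip models
saturation. One master seed drives everything; per-stack seeds derive
via `SeedSequence(entropy=master, spawn_key=(group_index,
stack_index))`, so extending a cohort never reshuffles existing stacks.

### What the generator does not emulate

Axon bifurcation fine structure, mitochondrial transport dynamics,
photobleaching, tissue autofluorescence gradients, optical aberrations
and depth-dependent attenuation, and anatomical variability between
hemispheres. Passing tests therefore demonstrate that the measurement
chain recovers known ground truth under an idealised but noisy imaging
model — not that the pipeline is robust to every artefact of real
tissue. ROI placement on real data remains a manual input by design.

## Numerical choices and degenerate inputs

- Voxel centres at (i + 0.5) × voxel size; physical µm everywhere;
  ROIs converted to pixels only at evaluation time.
- Thresholding uses strict `<` (values equal to the threshold survive).
- In-memory intensities are float64 (scale invariance of ratios,
  normalised profiles and dropout areas holds to ~1e-9 under intensity
  rescaling with a co-scaled threshold); on disk stacks are 32-bit
  float TIFF with voxel size in the resolution tags / ImageJ spacing.
- An ROI with no surviving voxel raises an explicit error naming the
  ROI rather than returning NaN; an all-missing or non-positive profile
  cannot be normalised (error); a profile bin with no valid sample is
  NaN and is bridged linearly inside integration intervals.
- Bins with a single contributing fly report SEM 0 with a warning.
- Trough detection ties keep the most distal run; runs shorter than
  min_run_um are ignored.
- Šidák adjustment is computed as −expm1(m·log1p(−p)) for precision at
  small p.

## Known limitations

- The somatodendritic:axonal ratio carries a small positive bias
  (~+10% at ratio 2 under defaults) from background offset and
  compartment-boundary dilution; it is monotone in the true density
  ratio and well within the 15% recovery band, but absolute ratios
  should not be over-interpreted.
- The dropout area is a positive-part statistic: its expectation is
  strictly positive for any noisy profile even without a real AIS
  depression (~0.5–0.8 µm under default noise at d = 0 versus ~4 µm at
  d = 0.9). Comparisons between groups are unaffected, but the
  statistic should not be read as an absolute zero-baselined quantity.
- The KS normality gate with estimated parameters is conservative;
  borderline samples may route to the t-test where a Lilliefors-corrected
  test would route to Mann–Whitney.
- The automated AIS detector assumes a single dominant marker trough;
  fragmented or absent AIS domains (severe disruption phenotypes) should
  use manual intervals, as the original workflow does.
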