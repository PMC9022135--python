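# Methods

## The assay being modelled

High-content screening (HCS) assays for DNA damage image immune cells in
384-well plates, stain them for DAPI plus two double-strand-break markers,
and extract per-cell features by automated image analysis. The two markers
behave differently and are therefore quantified differently:

- **53BP1** pre-exists diffusely in the nucleus and *relocalises* into
  discrete repair foci at break sites. Its per-cell readout is the **sum of
  integrated (background-subtracted) focus intensities** ("sum spot
  intensity").
- **γ-H2AX** is generated *de novo* by phosphorylation of H2AX at Ser139,
  raising nuclear signal globally as well as in foci. Its per-cell readout
  is the **mean nuclear intensity** over the nucleus mask.

A cell is *damage-positive* for a marker when its feature value strictly
exceeds the negative-control mean plus one sample SD (n−1 denominator).
Ties at the threshold are negative; the rule is shift-equivariant, so adding
a constant offset to all intensities changes no call. For a normal control
classified against its own threshold, the expected positive fraction is the
analytic tail Φ(−1) ≈ 0.1587, which the test suite verifies by simulation.

## Pipeline stages

**Segmentation** (`focimetry.segment`). Gaussian smoothing (σ = 2 px) →
global Otsu threshold → hole filling → optional watershed split of touching
nuclei → area gate → border exclusion, with 8-connectivity throughout and
labels relabelled 1..K. Otsu is parameter-free and invariant under positive
rescaling of the image. The watershed floods the negative Euclidean
distance transform from h-maxima seeds (default h = 2 px): maxima whose
prominence is below h merge, so shallow necks do not split. The distance
map is lightly smoothed (σ = 1 px) before seeding — without this,
pixelation of the binarised boundary creates spurious ridge maxima on
elongated nuclei and oversplits several percent of them. The area gate
defaults to the equivalent-disk areas of 2 µm and 7 µm radii converted by
the pixel size, bracketing immune-cell nuclei; border-touching nuclei are
excluded because their features are truncated.

**Spot detection** (`focimetry.foci`). Candidates are local maxima of the
scale-normalised Laplacian-of-Gaussian response (σ² · |LoG|) over five
scales from 1 to 3 px, kept when the response exceeds a deliberately
permissive threshold (default 3.0 A.U.) and the maximum lies inside a
segmented nucleus. Duplicate maxima across scales are merged strongest
first: a weaker maximum closer to a kept one than twice the larger of the
two detection sigmas is a duplicate — two Gaussians closer than ~2σ cannot
produce separate intensity maxima, so anything inside that footprint is a
noise-driven secondary maximum of the same focus. Each candidate is featurised with its integrated intensity
above the local background (median of a 4–8 px annulus) over a 3σ disk,
peak intensity, relative contrast, above-half-max area, roundness (minor/
major axis ratio of the above-half-max pixels), and detection scale.

**Focus classification.** A two-class Fisher Linear Discriminant (FLD)
separates true foci from background detections:
w = (S_W + εI)⁻¹(μ₁ − μ₀), with S_W the summed within-class scatter and
the decision threshold at the midpoint of the projected class means (no
class priors). The default ridge is ε = 10⁻⁶ · trace(S_W)/d. The model
stores per-class sufficient statistics (count, mean, scatter), which are
additive, so fine-tuning on new labelled examples is *exactly* equivalent
to retraining on the pooled data — the mechanism for adapting a pre-trained
model to a new cell type. Intensity-derived features enter the classifier
as log1p transforms: focus amplitudes are log-normal and span decades, and
on the raw scale the two classes violate the equal-covariance geometry the
FLD assumes, costing ~15 precision points in our benchmarks. The log is a
monotone per-feature rescale; the FLD's decisions are invariant under any
positive diagonal rescaling of the feature space, a property the test suite
checks.

**Statistics** (`focimetry.stats`). Two-sided throughout.
Mann–Whitney–Wilcoxon rank-sum for pairwise feature comparisons (exact null
when tie-free and n₁n₂ ≤ 10⁴, else normal approximation with tie and
continuity corrections); Pearson chi-square with Yates continuity
correction (default on) for 2×2 positive/negative × treated/control tables
— the correction subtracts min(0.5, |O−E|) from each cell's deviation;
one-way fixed-effects ANOVA with replicate as the grouping factor, run
separately per treatment group, as the inter-batch stability check; and a
product-Gaussian 2D kernel density with per-axis Scott bandwidths
(h = sd · n^(−1/6)) for the dual-marker analysis, normalised so the grid
integral is 1 within 1%. Reported p-values carry a display floor of
2.2 × 10⁻¹⁶ (the conventional floor of R test printouts); comparisons in
code use exact values. The concerted response of both markers ("diagonal
shift" of the 2D density) is summarised numerically as the signed pair of
treated-minus-control median differences.

Reconstructing published contingency tables from positive-cell fractions
and sample sizes reproduces the published Yates-corrected X² statistics
within rounding error of the printed percentages — for the γ-H2AX Jurkat
table exactly to printed precision, which is also what fixed the
correction's default to "on".

## The synthetic-microscopy simulator

`focimetry.simulate` renders three-channel fields with ground truth so
every stage is testable without real data. The emulated acquisition is a
60× / NA 1.2 confocal with 2×2 binning: 216 nm/px, default field
1080×1280 px. Defaults (all in arbitrary intensity units, A.U.):

| parameter | default | meaning |
|---|---|---|
| `n_cells` | 40 | nuclei per field |
| `nucleus_radius_um` | (3.0, 4.5) | uniform ellipse radii, immune-cell sized |
| `nucleus_intensity` | 500 | DAPI plateau inside the nucleus |
| `foci_rate` 53BP1 | 1 → 8 (control → treated) | Poisson mean foci/cell |
| `foci_rate` γ-H2AX | 1 → 6 | Poisson mean foci/cell |
| `pan_nuclear_gh2ax` | 40 → 100 | ×2.5 induction under treatment |
| `focus_sigma_um` | 0.35 | isotropic Gaussian PSF width |
| `focus_amplitude` | median 300, geometric SD 1.6 | log-normal peak amplitude |
| `background` | 10 | camera offset + non-specific signal |
| `read_noise_sd` | 2 | additive Gaussian read noise |
| `cell_brightness_gsd` | 1.25 | per-cell log-normal brightness factor |

Nuclei are ellipses placed by rejection sampling with centres at least
twice the maximum radius apart (non-overlapping by construction) and a
border margin; focus centres are uniform in the parent ellipse, pulled in
15% from the rim. Noise follows camera physics: Poisson on the noise-free
signal, then additive Gaussian read noise, then clipping at zero. The
vehicle (DMSO) condition is simulated identically to untreated. With noise
off, a focus integrates to amplitude · 2πσ² within 1%, the closed form the
detector's integral is tested against. Per-well/field RNG streams are
derived by hashing the master seed with the well id and field index, so
adding wells to a layout never changes existing wells' pixels.

`simulate_cell_features` draws per-cell features from the same generative
model without rendering pixels (focus mass × 2πσ², pan-nuclear level,
area-scaled read noise). It exists for statistical calibrations that need
many plates' worth of cells — e.g. the 1000-repetition type-I-error check
of the inter-replicate ANOVA, where rendering ~3000 fields of images would
be pointless; the pixel path and the feature path share the distributional
assumptions and the tests verify their condition contrast agrees.

**What the simulator does not emulate.** Real immune-cell images contain
overlapping and touching nuclei, debris and mitotic figures, uneven
illumination, autofluorescence, channel bleed-through, focus-size
heterogeneity, and a bimodal 53BP1 background (small foci in undamaged
cells). Passing recovery benchmarks on the simulator therefore bounds
algorithmic correctness — segmentation topology, detector localisation,
classifier separation, statistical calibration — not performance on real
plates, where the classifier is expected to need fine-tuning per cell type
(the additive-statistics mechanism above) and the absolute A.U. scales are
instrument-dependent.

## Benchmark protocols and problem sizes

The repository's acceptance checks (`focimetry.evaluation`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use these sizes:

- **Recovery benchmark**: classifier trained on six 640×640 px, 12-cell
  fields alternating treated/control conditions (disjoint seed stream),
  evaluated on twelve full-size default-condition fields (480 nuclei,
  ~480 foci). Recall is reported for foci with amplitude ≥ 5× the
  background noise SD, matched 1:1 to ground truth within 3 px, strongest
  detection first; precision counts accepted detections matching any true
  focus. The default (untreated) rate λ = 1 keeps true foci mostly
  isolated; under the treated rate λ = 8, ~13% of true foci lie within one
  PSF width of a neighbour and are physically unresolvable as separate
  intensity maxima, which caps 1:1 recall near 87% no matter the detector —
  a known limitation of focus *counting* (not focus *intensity summing*) in
  crowded nuclei.
- **Effect run**: 25 fields per condition of 640×640 px, 40 cells each
  (~1000 cells/condition) through the full image pipeline, vehicle control
  vs treated, reported via the standard comparison (Wilcoxon, thresholds,
  χ², median shifts). Smaller canvas than the default field, same
  generative parameters.
- **ANOVA calibration**: 1000 repetitions × 3 replicates × 60 cells from
  the per-cell feature sampler, null hypothesis true by construction;
  rejection rate at α = 0.05 should be 5% ± 2%.

## Numerical choices and degenerate inputs

- Constant DAPI image → empty label map, not an error; constant control
  values → SD 0 threshold with a warning; empty wells → n = 0 summary.
- IQR and quartiles use linear interpolation (NumPy default, type 7).
- Median of an even-length sample is the mean of the middle two.
- Identical class means → degenerate-training error; singular scatter with
  ε = 0 → error instructing a positive ridge.
- ANOVA with zero between- and within-group variance is flagged degenerate
  (NaN statistic) rather than 0/0; zero within-variance only → F = ∞, p = 0.
- KDE with a zero-variance axis raises and suggests a manual bandwidth.
- Wilcoxon falls back to the tie-corrected normal approximation whenever
  ties are present, at any sample size.
- The contingency test requires all margins positive; a table with an empty
  row or column is an error, not a zero.

## Open design points resolved in this package

- **Negative control**: the vehicle (DMSO) condition when present, else
  untreated, pooled across replicate wells of the same sample — pooling
  maximises control n and the threshold rule is well defined either way.
- **Positivity for 53BP1** uses the same mean + 1 SD rule on sum spot
  intensity as γ-H2AX uses on mean nuclear intensity.
- **Inter-batch ANOVA** operates on single-cell feature values with
  replicate as the factor, separately per treatment group; per-replicate
  means would leave only 2 within degrees of freedom.
- **File naming** (`<WELL>_f<FIELD>_<CHANNEL>.tif`) is this package's own
  convention; vendor acquisition software writes proprietary layouts that
  are out of scope.
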