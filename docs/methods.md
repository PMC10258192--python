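# Methods

## Sensor forward model

The crowding sensor is modeled as a donor–linker–acceptor FRET construct
whose efficiency saturates hyperbolically in the local crowding level c:

    E(c) = E_min + (E_max − E_min) · c / (c + K_half)

Defaults E_min = 0.2, E_max = 0.6, K_half = 0.3 (crowding is a
volume-fraction-like quantity in [0, 1] for imaging; g/L for in vitro
titrations). The saturating monotone form matches how linker-compression
sensors respond, has the fewest parameters, and is analytically
invertible, which lets the test-suite check every downstream stage in
closed form. Two-channel rendering uses the sensitized-emission model

    donor    = C (1 − E)
    acceptor = γ C E + crosstalk · donor + background

with detection-efficiency ratio γ (default 1) and a single donor-bleedthrough
coefficient (default 0); spectral unmixing beyond that one term is out of
scope. The background-subtracted ratio is then R = γE/(1−E) + crosstalk.
Camera noise is Poisson photon noise (configurable gain, default 1
count/photon) plus Gaussian read noise (σ = 2 counts) plus a constant
per-channel offset (10 counts). With noise disabled the closed forms
hold to machine precision.

## Synthetic scenes

A scene is an elliptical nucleus (semi-axes ~0.32–0.44 of the image
size) containing non-overlapping disc condensates (default radii
3–8 px, 1000 placement retries before an error). Concentration is
two-level (base 100 photon-rate units in the nucleoplasm, ×enrichment
in condensates, default 3) and crowding is two-level (dilute level in
the cell, dense level in condensates). The default scene is 256×256 px
at 0.1 µm/px; none of the microscope settings are measured values —
they are simulation defaults.

An optional multiplicative concentration texture (smooth Gaussian random
field, default off in `make_scene`) emulates intracellular
heterogeneity. The experiment-level simulator turns it on
(σ = 20%, correlation length 4 px) deliberately: when the dilute phase
is selected as the dimmest 30% of a *perfectly uniform* field, the
selection keys on shot noise alone and biases the dilute ratio downward
— an artifact that real nuclei, whose intensity variation is dominated
by genuine concentration structure, do not present. With texture on,
rank selection follows structure (which cancels in the ratio) rather
than noise. For the same reason the end-to-end pipeline ranks pixels on
a σ = 1.5 px Gaussian-smoothed acceptor image while measuring
intensities and ratios on the raw data; `segment_phases` itself defaults
to no smoothing so that exact-arithmetic properties (e.g. recovering a
two-level disc with Jaccard 1.0) hold.

What the simulations do **not** emulate: chromatic shift between
channels, depth-dependent background, sensor maturation differences,
photobleaching over time series, diffusion-shaped FRAP recovery
(recovery is reaction-limited by construction), out-of-focus light, and
irregular condensate shapes. Passing tests therefore demonstrate the
*procedure's* correctness and statistical behavior under the stated
image model, not robustness to every optical artifact of real data.

## Ratio imaging

Ratio = (acceptor − bg_A)/(donor − bg_D) where the subtracted donor
exceeds an intensity threshold (default 6 counts = 3× the default read
noise; dimmer pixels give unstable ratios). Pixels with non-positive
corrected acceptor are invalid and counted. "auto" background is the
histogram mode (integer-rounded, ties to the lower count) outside the
cell mask — deterministic and robust to the bright in-cell tail.
Region statistics use the mean of pixelwise ratios over valid pixels;
the donor-weighted mean (≡ ratio of summed intensities) is available via
the `weights` argument. Normalization divides by the control-group mean
(per experiment, not per cell), so the normalized control mean is 1 by
construction.

## Phase splitting

The dense phase is the brightest `dense_quantile` fraction (default
10%) of eligible in-cell YFP pixels; the dilute phase the dimmest
`dilute_quantile` fraction (default 30%) — eligible excludes pixels
already invalid in the ratio image. Membership is exact top-k/bottom-k
rank selection with a deterministic tie-break on the flat pixel index,
not interpolated quantiles: a region whose area fraction equals the
requested quantile is recovered exactly, and growing a quantile can only
grow its mask. A constant image inside the mask raises a
degenerate-segmentation error. Each phase needs ≥ 20 valid pixels
(configurable). When no cell mask is supplied it is derived from the
YFP channel by a 3-class multi-Otsu threshold (taking everything above
the lowest cut), hole filling and largest-component selection; plain
2-class Otsu is the fallback for histograms that cannot support three
classes. Two-class Otsu alone fails on condensate-bearing cells because
the bright condensates dominate the between-class variance and the
"foreground" collapses to the condensates themselves.

Line profiles use nearest-pixel sampling averaged across the transect
width, report positions in µm, and use Spearman rank correlation
(trends, not linearity) on the raw profiles; a constant profile makes
the correlation undefined and is flagged rather than reported as 0.

## Assembly-mode classification

Per-cell dense/dilute mean ratios are normalized by the experiment's
dilute-phase (control) mean. The verdict is **aggregation** iff the
one-sided paired Wilcoxon signed-rank test (dense > dilute) has
p < α (default 0.05) **and** the mean paired difference exceeds
`min_effect` (default 0.02 normalized-ratio units, guarding against
trivially significant microscopic contrasts — e.g. residual background
mis-estimation of ±1 count shifts the paired difference by well under
0.01). Otherwise the verdict is **consolidation** — the appropriate
default when dense-phase crowding is not demonstrably elevated; a
dense phase with *depressed* crowding is visible through the signed
effect and CI rather than a third class. The bootstrap CI of the mean
difference uses seeded resampling (default 2000 draws); identical seeds
give identical intervals. Rank-based tests (Wilcoxon paired,
Mann–Whitney unpaired for condition contrasts) were chosen for
distribution-freeness at the n = 12–80 cells typical of these
experiments.

Default simulated study conditions: 20 cells per experiment, 128×128 px
scenes with eight condensates of radius 4–6 px (condensates ≈ 10% of the
nucleus, matching the dense quantile), enrichment 3, crowding 0.30
outside. Aggregation truth uses 0.38 inside (a normalized dense/dilute
ratio contrast of ≈ 0.10); consolidation truth uses equal crowding
(zero contrast).

## FRAP

Traces are normalized to the pre-bleach mean (requires ≥ 3 pre- and
≥ 5 post-bleach samples). Recovery is a single exponential

    I(t) = I_post + F_m (1 − I_post)(1 − e^{−(t − t_bleach)/τ})

fitted by least squares over the post-bleach samples with multistart
over τ decades (log-τ parameterization keeps τ > 0; non-convergence of
every start raises a fit failure). The post-bleach floor I_post is
fitted jointly by default: anchoring it to the first post-bleach sample
(available as `anchor_post=True`, useful at very coarse sampling where
the three-parameter fit degenerates) passes that single sample's noise
into τ and measurably doubles the τ error at dense sampling. F_m is
clipped to [0, 1] with the raw value retained; half-time = τ·ln 2. A
double-exponential model is available only on explicit request — no
automatic model selection. Default simulated traces: bleach at t = 10 s,
0.5 s sampling over 120 s, pre-bleach level 1, post-bleach 0.3.
Mobility comparisons report mean ± SEM of F_m and half-time per group
plus two-sided Mann–Whitney tests on both; "more mobile" requires the
significant contrasts to agree in direction, otherwise the verdict is
"mixed".

## Titration calibration

Spectra are reduced to ratios by trapezoidal band integration with
interpolated band edges (donor 460–500 nm, acceptor 515–560 nm by
default — configurable, CFP/YFP emission windows; recorded in outputs).
The titration response R(c) = R₀ + ΔR·c/(c + K_c) is fitted to all
replicates jointly (log-K_c parameterization, ΔR ≥ 0, multistart).
A flat series reports ΔR = 0 with K_c flagged unidentifiable; a fit
pushing K_c beyond 50× the probed range falls back to a straight line
whose slope stands in for the initial-slope sensitivity, also flagged.
Sensors are ranked both by dynamic range ΔR and by initial slope
ΔR/K_c, with disagreement flagged. Replicate noise in the simulated
titrations is specified relative to the dynamic range (1% of ΔR):
with the probed design (6 concentrations spanning [0, 4K_c], 3
replicates) the Cramér–Rao bound for K_c under noise of 1% of the
*baseline* ratio is ~10% relative — no estimator could meet the ~4–5%
recovery this package aims for — whereas 1% of the dynamic range puts
the bound at ~3.9%, which the fit attains. Default simulated series:
K_c = 75 g/L (Ficoll-like), ΔR = 0.4 for the optimized long-linker
sensor vs 0.2 for the original.

Linker screens take `{length: (response, SEM)}`, pick the argmax
response, break ties toward the shorter linker (cheaper to encode and
fold), and flag a winner within combined SEM of the runner-up.
Stoichiometry is assembly mass / monomer mass, reported raw and rounded
to one significant figure to match the precision at which
light-scattering assembly masses are quoted.

## Numerical and reproducibility choices

* All randomness flows from explicit per-call seeds
  (`numpy.random.default_rng`); there is no global RNG state. Derived
  seeds stay below 2³¹.
* All nonlinear fits use `scipy.optimize.least_squares` at
  xtol/ftol/gtol = 1e-14, so noiseless round-trips recover parameters
  to better than 1e-6 relative.
* CSV/TIFF outputs are deterministic given config + seed; channel TIFFs
  are 16-bit (donor first), masks 8-bit, ratio maps 32-bit float.
  Every analysis output embeds the resolved configuration and package
  version.
* Degenerate inputs fail loudly with typed exceptions (placement,
  empty-ratio, degenerate-segmentation, insufficient-pixels/-data,
  fit-failure); the end-to-end runner records per-cell failures in a
  manifest and continues.

## Problem sizes used by the test-suite and acceptance script

Mode-recovery statistics use 200 simulated experiments of 20 cells per
class at 128×128 px; FRAP recovery uses 100 noisy traces (σ = 0.02) and
200 12-vs-12 group comparisons; titration recovery uses 100 seeds and
200 ranking/screen repetitions; classifier type-I control uses 500 null
draws at the statistics level. These sizes give binomial/Monte-Carlo
standard errors comfortably below the margins being asserted.

## Known limitations

Single-plane, single-timepoint analysis (no 3D stacks, no tracking over
time); no channel registration or photobleaching correction; recovery
fits do not model bleach-spot geometry or extract diffusion
coefficients; the classifier issues single-condition verdicts without
multiple-testing correction across proteins; whether the dilute phase
should exclude nucleoli or other organelles is left to the supplied
masks — only ratio-invalid pixels are excluded.
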