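# Methods

`famfeed` implements the quantitative analysis behind a *C. elegans*
food-familiarity study design: worms trained on one bacterium (H =
*E. coli* HB101, D = *Pseudomonas* DA1878) are tested on familiar or
novel food, and three readouts are quantified — the calcium response of
the ADF chemosensory neurons (ratiometric FRET imaging), the pharyngeal
pumping rate (feeding), and the number of serotonin-positive AIM/RIH
neurons (serotonin release). Conditions are coded by two letters,
training food then test food (HH/DD familiar, DH/HD novel).

## Ratiometric calcium imaging

The sensor is a YC3.60-type cameleon with cyan (480 nm) and yellow
(535 nm) emission. Per frame, ROI mean intensities I and surrounding-
annulus background means I′ give the raw emission ratio

    R = (I_535 − I′_535) / (I_480 − I′_480) − 0.65

where 0.65 is the fixed fraction of cyan emission that bleeds into the
yellow channel. ROI membership uses pixel-centre distance with 0-based
coordinates; the background annulus is (roi_radius, bg_outer_radius].

Photobleaching is modelled as a single decaying exponential of the
ratio trace. A·exp(−λt) is fitted by least squares (λ ≥ 0, since
bleaching cannot brighten; initialisation from a log-linear regression)
and the normalised change is

    ΔR/R(t) = R(t) / (A·exp(−λt)) − 1.

**Fit window.** By default the exponential is fitted to the
pre-stimulus frames only and extrapolated under the response. Fitting
through the whole trace is supported (`fit_prestim_only=False`) but it
runs the baseline through the stimulus-locked transient and absorbs
roughly (response duration)/(trace duration) of the response into the
fitted curve: on noiseless synthetic recordings of 200–600 s we measure
50–65 % signed-area attenuation, falling only as the recording grows
(the `tests/test_imaging.py` boxcar case quantifies the long-recording
regime, where a 120 s plateau in a 1500 s trace loses ≲ 20 %). The
pre-stimulus fit recovers noiseless ground truth exactly, which is why
it is the default; both modes are exposed on the model and the CLI.

Time is re-expressed with t = 0 at stimulus delivery. ΔR/R is averaged
in half-open 10 s bins [k·w, (k+1)·w) anchored at t = 0 (negative k =
pre-stimulus); cross-animal averages weight animals equally (mean of
per-animal bin means), not frames. The response statistic is the signed
trapezoidal integral of ΔR/R over 0–120 s on the native sampling grid;
window endpoints falling between frames are included by linear
interpolation, and a recording may stop up to one frame interval short
of the window end. Negative excursions subtract.

## Feeding statistics

Adults contribute three 30 s pump counts; the rate is their mean × 2
(pumps/min). L1 larvae contribute two 55 s counts; the rate is their
mean, deliberately left on the pumps-per-55 s scale. Group summaries
use the unbiased (n − 1) variance and sem = √(variance/n).

Two-group comparisons run both the unpaired t-test and the two-tailed
Mann–Whitney U test and report the larger p-value ("conservative p").
The t-test is Welch by default — consistent with the per-group
variance/n standard errors used throughout — with the pooled Student
variant behind a flag. The Mann–Whitney p is exact when both groups
have ≤ 8 observations and no ties (enumeration-scale; verified against
a full-enumeration oracle in the tests), otherwise the normal
approximation with tie and continuity corrections. Multi-group
comparisons use one-way ANOVA plus Tukey HSD with the Tukey–Kramer
adjustment for unequal n (scipy's implementations stand behind this
module surface).

The headline receptor-effect statistic is a difference of differences.
For groups 1–4 with means m_i, variances v_i and sizes n_i:

    estimate = (m1 − m2) − (m3 − m4)
    sem      = sqrt(Σ v_i / n_i)
    t        = estimate / sem

Degrees of freedom are not implied by the SE formula alone; we use
Welch–Satterthwaite over the four variance/n terms (the SE formula is
Welch-style, per-group variances with no pooling), with a
standard-normal reference available via `df_policy="normal"`. The
two-group variant (g3, g4 omitted) is the plain difference with
sem = √(v1/n1 + v2/n2). Degenerate zero-variance inputs with a zero
estimate return t = 0, p = 1.

Because absolute pumping rates differ between bacteria, only familiar-
and novel-food groups sharing a test food are ever compared (HH vs DH,
DD vs HD); the analysis surface rejects cross-test-food requests.

## Serotonin-positive cell counts

Each animal's count is the number of serotonin-positive cells among the
two AIMs and RIH, an integer in {0..3} (ADF/NSM/HSN are excluded by the
scoring protocol). Per experiment, the starvation-baseline mean (H or
D, matched to the refed group's training food) is subtracted from each
refed group's mean; the familiar and novel increases are compared with
the same four-group difference-of-differences t statistic; and the k
per-experiment two-tailed p-values are combined by Fisher's method:

    χ² = −2 Σ ln p_i   ~   χ²(2k)  under the joint null.

p-values outside (0, 1] are rejected rather than clamped (an explicit
`floor` argument exists for pipeline robustness, off by default). At
k = 1 the combination reduces to the identity p_combined = p, which the
tests assert to 1e−12.

## Synthetic data

Generators produce every input with known ground truth.

*Imaging.* Background-free channel signals are
S_c(t) = I_c·exp(−t/τ_c) and S_y(t) = r(t)·I_c·exp(−t/τ_y), with
yellow = S_y + 0.65·S_c + background + optional Gaussian noise. The
true ratio is r(t) = r0·(1 + a·k(t − onset)) with the smooth kernel
k(t) = (1 − e^{−t/rise})·e^{−t/decay} normalised to peak 1 ("slow yet
substantial" rise). Defaults: 5 Hz (valid 2–10 Hz, warning outside),
onset 40 s (within the 30–50 s solution-switch window), 200 s duration,
a = 0.10, rise 10 s, decay 40 s, τ_c = 600 s, τ_y = 400 s, cyan
baseline 1000 AU over background 50 AU. With equal channel taus the
ratio formula inverts the forward model exactly; unequal taus give the
net ratio decay (τ = 1200 s at the defaults) that photobleach
correction removes. τ_y < τ_c is deliberate: the opposite ordering
makes the ratio brighten, which a decaying-exponential correction
cannot represent. A renderer draws the neuron as a Gaussian spot in a
2-channel TIFF for the ROI-extraction path, scaled so disc means
reproduce the trace within the Gaussian-tail truncation (< 1 %).

*Feeding.* Each animal's rate is drawn Normal(mean, sd) truncated at 0;
the matching total pump count is rounded and split across counting
windows by a symmetric multinomial, so windows vary naturally while the
derived rate stays within rounding error (≤ 2/3 pump/min for adults) of
the draw. Default condition means ~225–265 pumps/min with a familiar >
novel separation, between-animal SD 20 pumps/min, n = 30 per group —
per-animal feeding variance is not constrained by published summaries,
so these are loose, configurable choices in the wild-type adult range.

*Cell counts.* Counts are binomial(3, expected/3), the simplest family
on the {0..3} support. Defaults are three experiments of 25
animals/condition, starvation baselines 2.06 (H) and 1.99 (D) cells,
and refeeding increases of +0.7 (familiar) and +0.1 (novel) cells —
an effect size at which the three-experiment Fisher combination has
≥ 80 % power at α = 0.05 while the no-effect configuration
(`null_cellcount_design`) stays at the nominal 5 % level.

What the generators do **not** emulate: worm motion, shot-noise
statistics and optics (imaging noise is additive Gaussian), within-
animal pump-rate drift, and any correlation between readouts. Passing
recovery and calibration tests therefore demonstrates correctness of
the estimators under the stated models, not robustness to real-world
artifacts.

## Numerical choices and problem sizes

- Integration: trapezoid on native timestamps, no resampling; binning
  uses half-open intervals; bin reported only if it contains ≥ 1 frame.
- curve_fit bounds λ ∈ [0, ∞); a constant trace resolves to the λ = 0
  boundary within solver tolerance (~1e−8).
- Calibration suites use: 2 000 null replicates (4 × n = 30) for the
  contrast, 1 000 for ANOVA/Tukey, 5 000 uniform draws for Fisher
  uniformity, 100 seeds for imaging null bins, 200/1 000 triple-
  experiment runs for cell-count power/size. These sizes put Monte
  Carlo error well inside the asserted bands while keeping the default
  suite fast.
- Determinism: every generator takes an integer seed
  (`numpy.random.default_rng`); identical inputs give bitwise-identical
  outputs, and `run_pipeline` manifests record config hash, seed and
  SHA-256 of every output.

## Known limitations

- The photobleach model is a pure exponential without offset; recordings
  whose baseline drifts non-exponentially will leave structure in ΔR/R.
- The pre-stimulus fit extrapolates; with short pre-stimulus windows and
  high noise the extrapolated baseline (hence late bins) is noisy,
  though unbiased.
- The Welch–Satterthwaite df for the four-group contrast is a
  convention choice; published analyses of this design did not state
  their df, and with the group sizes used here the difference from a
  normal reference is small.
- Count-level analyses treat counts as continuous for the t statistic;
  calibration holds at n ≈ 25 (verified by simulation) but may degrade
  for very small groups or means at the support boundary.
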