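# Methods

This note records the models the package implements, the defaults it
ships, and the reasoning behind the choices that were genuinely open.
Everything quantitative stated here is computed by the test suite, the
analysis scripts or `scripts/acceptance.py`; nothing is asserted that
the code does not reproduce.

## FLIM quantification

**Decay model.** A fluorescence decay is a non-negative mixture of
exponentials, I(t) = Σ Aᵢ exp(−t/τᵢ), convolved with a Gaussian
approximation of the instrument response (centre t₀, width σ). The
per-bin photon probabilities are computed from the exponentially
modified Gaussian CDF in a numerically stable split form (erfcx on the
early branch), normalized over the record with per-component
truncation. Simulated histograms are independent Poisson draws around
these probabilities. Conventions: `amplitudes` are decay amplitudes
Aᵢ; the photon fraction of component i is Aᵢτᵢ/ΣAⱼτⱼ. Defaults: t₀ =
1.5 ns, σ = 0.15 ns, 12.5 ns record in 0.1-ns bins (80-MHz-style
TCSPC).

**Photon-count ratio.** R = C₁/C₂ over the windows [0, 2.0) and
[2.0, 12.5) ns. The boundary was chosen by
`select_window_boundary`, which maximizes the separation of the
Ca-free and Ca-bound signatures in ln R divided by its Poisson
standard error — raw separation alone runs to photon-starved late
boundaries. The windows are stored in every calibration file, so
analyses are self-describing.

**Calibration.** The ratio-vs-[Ca²⁺] relation is fitted as a Hill
curve (a logistic in log concentration; one parameterization,
orientation carried by the order of R₀ and R∞). For the two-state
indicator below, the relation is exactly Möbius in Ca, so the h ≈ 1
fit is essentially perfect (rmse ~1e−3 at 10⁶ photons/level).

**Decay-constant correction.** The dye's decay constants differ
slightly between cells and the calibration cuvette. The correction is
built by computing the noiseless expected ratio for every amplitude
combination on a simplex grid under both τ sets and pairing them. For
two components the pairing is an exact function and is used directly;
with more components the pairs form a narrow band and are pooled into
quantile bins of the intracellular ratio, with strict-monotonicity of
the binned pairing enforced (a non-monotone pairing is a build error).
Applied by linear interpolation before the Hill inversion. When the τ
sets coincide, the map is the identity to ~1e−9.

**Inversion.** Ratios outside the open calibration range are clamped a
configurable epsilon (default 10⁻³ of the dynamic range) inside it and
flagged; flags propagate to event tables. Undefined ratios (no photons
in the late window) propagate as NaN gaps, never zeros.

**Reconvolution fitting.** Poisson maximum likelihood by default (the
correct TCSPC noise model), weighted least squares as an option; free
parameters are log photon-fraction weights and log lifetimes;
components are reported in ascending-τ order. Used for the
amplitude-weighted lifetime τ_A = ΣAᵢτᵢ/ΣAᵢ; the windowed ratio, which
is better conditioned at low photon counts, is what the pipelines use.

## Indicator photophysics (generative model)

The generator is two-state: a fraction Ca/(Ca + K_D) of dye molecules
is Ca-bound, with mono-exponential state signatures τ_free = 0.6 ns and
τ_bound = 3.5 ns (intracellular variants 0.55/3.2 ns) and a
bound-state brightness factor B. The triple-exponential is a fitting
representation downstream, not the generative truth. Defaults K_D =
580 nM and B = 2 place the apparent half-saturation of the *ratio*
curve at k_app ≈ 150 nM, so the largest physiological peaks (~190 nM)
sit mid-range on the curve (~56% of the dynamic span) — the regime the
measurement operates in — while resting levels (~30–110 nM) stay on
the sensitive lower limb.

## Synthetic cells and couplings

Resting [Ca²⁺] per ~5-µm ROI is log-normal with cell-mean 62.7 nM and
within-cell CV 0.36. Volume fraction decays exponentially from the
soma (space constant 40 µm, floor 35%); ROIs beyond an optional cell
radius are outside the cell (VF ≈ 0). Transients ride on the baseline
with a difference-of-exponentials kernel (rise 0.5 s, decay 3 s,
unit-normalized peak).

Three coupling modes generate true amplitudes: linear in the
fractional baseline deviation from the cell mean
(a = a₀(1 + β(b − b̄)/b̄), the default for within-cell correlation
studies), baseline-independent (the null), and a store driving-force
mode where a ∝ ln(Ca_store/b) − const. The modes matter: a
*multiplicative* baseline shift (as uncaging produces) leaves the
mean-centered linear rule's amplitudes unchanged, so uncaging
experiments use the driving-force mode, in which amplitude responds to
the *absolute* baseline. Amplitudes carry multiplicative log-normal
noise (CV 0.2) and are floored at zero. Defaults a₀ = 60 nM, β = −0.5.

**Photon budgets.** FLIM: 12 000 photons per ROI per 600-ms window at
100% VF, so the dimmest in-cell ROIs (VF floor) collect ~4 200 —
comfortably above the 1500-photon cutoff, which then separates
inside-cell from outside-cell ROIs sharply rather than grazing dim
in-cell ROIs. Rendering uses 2–4 pixels per ROI side; since the
pipeline pools pixels within a tile, per-ROI photon statistics are
independent of the rendering resolution (a tractability choice).
Ratiometric: per-pixel gains sized so a full-VF ROI collects ~10³
photons per frame — the working regime of frame-scanned two-photon
GECI recordings; backgrounds of 8 counts/pixel per channel and
Gaussian read noise (σ = 1.5) are added and subtracted by the
background-correction step.

**Uncaging.** Each ROI's total Ca is chosen so the pre-photolysis
multi-buffer equilibrium reproduces its baseline (endogenous fixed
buffering enters as a linear κ = 20); photolysis swaps a fraction f of
the photoactivatable buffer to its post-photolysis K_D and re-solves.
Diazo-2: 2.5 mM, K_D 2.2 µM → 73 nM. NP-EGTA: 5 mM, K_D 80 nM → 1 mM
(photoproduct affinity is a literature-typical value; the cage loads
with 3 mM Ca). f is tuned by a bracketed root find to a requested mean
baseline change (defaults −19.3% for diazo-2, +46.1% for NP-EGTA); the
realized field-mean change differs by a few points because the per-ROI
equilibrium is nonlinear in the baseline.

**Locomotion.** 20-Hz speed traces alternate rest and running bouts.
Bout speeds are drawn from a normal with mean 65.4 and SD 18.3 cm/min
truncated below at 60 cm/min — "moving" is defined by the analysis's
own >1 cm/s criterion, so speeds during locomotion sit above it by
construction. Bout lengths are 6 s minimum (mean 12 s): a bout must
span at least one full 3-s speed bin to remain detectable after
binning; shorter bouts are averaged below threshold and would
contradict the generator's intent of time-locked events.
Locomotion-coupled events place their peaks at running moments with
probability 0.9.

## Pipelines

**FLIM.** Tiles anchored at the image origin, partial edge tiles
dropped (padding would create biased low-photon ROIs). Photons summed
per tile per 600-ms window (conservation is tested). ROIs kept iff
mean photons/window ≥ 1500 (boundary inclusive — the exclusion rule
removes "fewer than 1500") and not mask-excluded; every rejection is
reported with a reason. Evoked measures: baseline = mean over a 5-s
pre-stimulus window, peak = max over a 20-s response window (both
configurable), amplitude = peak − baseline exactly (possibly ≤ 0 for
non-responders). Kinetics are repo conventions: rise = 20–80% of
amplitude, decay = mono-exponential fit from the peak.

**Spontaneous detection** replaces by-eye identification with a MAD
detector: noise σ̂ from the median absolute first-difference /√2
(robust to the events themselves), events are excursions above median
+ kσ̂, adjacent runs merged, per-event baseline from the 5 bins before
onset. The operating point (k = 4, minimum 1 bin above threshold) was
calibrated on the synthetic benchmark to hold both stated targets —
under the null, <1 false event per 10 min (measured 3 per 1000 min);
at 5σ injected amplitude, ≥90% recall (measured 98%). The 600-ms
binning attenuates a 5σ kernel peak to the margin of a 2-bin duration
rule, which is why the duration requirement is one bin.

**Uncaging deltas.** Δ = after − before per ROI for baseline, peak and
amplitude; a ROI is included iff its response amplitude exceeds 6 nM,
judged on the pre-uncaging response by default (the rule is togglable
to "after" or "both").

**Ratiometric.** Scalar per-channel background subtraction (negatives
floored and flagged), ROI-mean G over ROI-mean T per frame, frames
with T at/below background marked missing. Event measures are 3-frame
averages: peak = argmax frame (±3 frames around the nominal event
time) ±1; baseline = 3 frames ending one frame before the event
*onset*. The onset must come from the detector or the stimulus —
inferring it from the noisy argmax lets baseline frames slide into the
rise and biases the baseline upward.

**Saturation correction.** Measured G_B/T and G_P/T are mapped through
the inverse indicator response (Hill; K_D, slope and the ratio range
are explicit configuration an analyst takes from indicator literature
plus a gain calibration) into Ca-equivalent units, and the amplitude
is recomputed there before any rank statistic. The acceptance for this
step is functional: with a saturating indicator and zero true
coupling, the uncorrected R(baseline, amplitude) ≈ −0.6 is spurious
and the corrected statistic is ≈ 0; a genuine negative coupling
survives with its sign. Under a linear response the correction is a
no-op for ranks (tested).

**Locomotion association.** Speed is averaged over non-overlapping
3-s bins aligned to the trace start; an event is associated iff its
peak lies within ±6 s of any bin *interval* with mean speed > 1 cm/s.

## Statistics

Spearman R is the Pearson correlation of average ranks (ties get mean
rank; scipy's implementation, cross-checked against a hand-rolled
rank-then-Pearson oracle to 1e−12). Constant inputs are signalled,
and cells with constant measures are excluded from population tests
with a logged count. The population test is a two-tailed one-sample
Student's t of per-unit Rs against zero (n − 1 df). Pooled-session
correlations reuse the per-cell machinery on concatenated events. CV
is sample SD (ddof = 1)/mean.

## Mechanistic models

Nernst: E = (RT/2F)·ln(Ca_ref/Ca_in), CODATA constants, T = 307 K
(~34 °C bath). The extracellular driving-force bound: DF(c) = E(c) −
V_m with 2 mM external Ca and V_m = −85 mV; a +50 nM baseline shift
changes DF by at most 5.6% over 30–150 nM baselines (maximum at the
low end, by concavity of ln), under 10% for all baselines ≥ 20 nM.
Store driving force: DF = E(cytosol vs store) − V_store; a 30→90 nM
baseline rise cuts DF by ≈48% when the store holds ~300 nM free Ca at
V_store ≈ 0, but only ≈12% at 200 µM — the quantitative contrast that
makes a low-free-Ca store (or a potential-offset store) necessary for
the driving-force explanation. Store–cytosol equilibration under
linearized buffering (total = free·(1+κ)·V per compartment) yields an
equilibrated peak whose implied amplitude is strictly decreasing in
the baseline for every parameter set — the mechanism's signature,
independent of the exact store size.

The free-Ca solver finds the unique root of total = free +
Σ Bᵢ·free/(free + K_Dᵢ) on [0, total] (brentq plus a Newton polish so
the *residual*, not just the root location, is below 1e−12 relative);
it is validated against a dense-grid refinement oracle. Mg²⁺/ATP
competition is omitted: the solver's role is synthetic-data
generation and the Ca-buffer terms dominate at the compositions used;
a competing-species extension would slot into the same residual.

## What the generators do and do not emulate

Emulated: within-cell resting-Ca heterogeneity, Poisson photon
statistics at realistic budgets, indicator saturation and two-state
lifetime mixing, volume-fraction variation and its cancellation in
G/T, buffer-equilibrium uncaging shifts, locomotion-locked event
timing. Not emulated: astrocyte morphology, diffusion and spatial
event propagation, motion artifacts, IP₃R gating kinetics,
photobleaching, detector afterpulsing. Passing tests therefore show
the *analysis chain* is correct and unbiased at its stated conditions;
they do not certify performance on recordings whose noise or geometry
depart from these assumptions.

## Known limitations and measured caveats

- The max-over-windows peak estimator carries a small positive
  amplitude bias under the null coupling (mean per-cell R ≈ +0.013,
  measured over 200 synthetic cells): window noise in nM grows with
  baseline through the Hill inversion, so high-baseline ROIs' peaks
  are slightly more inflated by the max. The effect is conservative
  with respect to the negative baseline–amplitude coupling the
  analysis is built to detect, and at default conditions the
  20-population null nonsignificance rate sits at ~88–93%.
- Single-window [Ca²⁺] estimates at the 1500-photon floor are noisy
  (≈10% relative SD at 20 nM); accuracy claims are about the pooled
  estimator (64 windows ≈ a 40-s recording), whose error stays within
  a few percent over 20–500 nM.
- The decay-constant correction holds decay *amplitudes* fixed across
  τ sets. The generative two-state model varies photon fractions, a
  ≈0.3% mismatch that appears as the ~1–2% residual at the low end of
  the round trip.
- Problem sizes throughout (8×8-ROI cells, 40-cell populations, 20–40
  replicate populations, 200-event ratiometric studies) are the
  package's chosen study scale; all are configurable.
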