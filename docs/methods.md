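# Methods

This note documents the models, calibration defaults, numerical choices and
known limitations of the package. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model

A stimulus-locked calcium transient is modeled as an instantaneous rise at
the pulse time followed by a single-exponential decay:

    ΔF/F₀(x, t) = a(x) · Σₖ cₖ · exp(−(t − tₖ)/τₖ),  t ≥ tₖ

Rise kinetics are not simulated (real transients peak within a few tens of
milliseconds and none of the downstream analysis uses the rising phase). Two
train conventions are supported and recorded in output metadata: in
`superposed` mode (default) every pulse adds a full exponential on top of the
residual of the preceding ones (cₖ = 1); in `absolute` mode each pulse only
tops the response back up to the unit peak. The default is `superposed`
because linear summation is the natural null model for dendritic calcium
influx; whether recorded train peaks ride the preceding decay is not
observable from the analyses implemented here.

Spatial structure: peak amplitude is zero in the nucleus, a small fraction
(default 0.1) of the reference value in the somatic cytoplasm, and increases
linearly along each dendrite (default +2% per centerline pixel beyond the
soma-dendrite border, reproducing distally increasing surface-to-volume
ratio). Baseline F₀ is uniform across the soma and decreases linearly along
the dendrite (default −1.5% per pixel, reproducing distally decreasing
volume and dye content).

## Noise model and camera abstraction

Pixel counts are dark_offset + Gaussian read noise + Poisson shot noise on
the scaled intensity (photon_scale · F₀ · (1 + ΔF/F₀)) — the standard EMCCD
abstraction without excess-noise factor or PSF. Defaults: dark offset 100
counts, read noise 2 counts, photon_scale 4 counts per unit intensity.
photon_scale was set so that a 12-pixel ROI trace has baseline RMS noise
near 0.005 ΔF/F₀ after 15-Hz filtering: in that regime the 5×RMS detection
threshold sits far below a ~0.3 peak and decay fits only rarely fall below
the r² = 0.990 acceptance bound — the operating regime the analysis protocol
presupposes. Twenty shutter-closed frames are emitted per simulated
experiment, as acquired in practice.

For cohort-scale simulations, `synth.simulate_roi_trace` draws the sum of
the 12 independent per-pixel Poisson counts as a single Poisson variate
(exact, by additivity of the Poisson distribution when F₀ is uniform over
the ROI) and aggregates the read noises into one Gaussian; the arithmetic
then mirrors the full pipeline (dark subtraction, pre-stimulus F₀, ratio).
Equality with the rendered-movie route is asserted by a test in noiseless
mode.

## Calibration defaults

The generator's defaults define the simulated study conditions and are fixed
once:

| parameter | default | rationale |
|---|---|---|
| frame interval | 10 ms | 100 frames/s acquisition |
| pixel pitch | 1.18 μm | camera/objective geometry |
| per-pulse amplitude (ROI) | ~0.30 ΔF/F₀ | reference-scale single-pulse response |
| decay constant τ | 0.7 s | places the 10-pulse 1-Hz cumulative load near 200 a.u. (ΔF/F₀·frames), the reported scale |
| baseline F₀ (ROI) | ~300 counts | reported group mean ≈ 299 a.u. |
| somatic area range | 158–537 μm² | range over which responders were observed |
| dendrite width | N(3.22, 0.30) μm | reported group means ≈ 3.22/3.23 μm |
| amplitude heterogeneity | lognormal, σ_log = 0.25 | ~25% CV across dendrites; train-average error bars at n = 84 become barely visible (SEM/mean ≈ 2.7%), as observed |
| genotype effect | ×1.15 on amplitude only | the reported ~15% cumulative-load increase with unchanged τ |

`amplitude_a` and `f0_soma` are specified at the soma-dendrite border
(0.26 ΔF/F₀ and 345 counts); the spatial gradients bring the values seen by
the standard ROI set (centerline pixels 6–11) to ~0.30 and ~300.

Immunostaining populations: class fractions (0.95, 0.04, 0.01) for medium
spiny neurons, GABAergic interneurons and cholinergic interneurons;
log₁₀-uniform somatic areas over ~100–850 μm² (cholinergic cells drawn from
650–820 μm², matching their reported large somata — size is recorded but
never used by the classifier); negative-control intensity −150 + 180·log₁₀
(area) a.u. with Gaussian scatter (SD 40 a.u.), clipped at zero; true
positives are 5-fold brighter. The area-dependent background is the feature
the confidence-band threshold exists to absorb.

## Analysis pipeline choices

* **Filter convention.** "Gaussian-filtered at f Hz" is realized as a
  Gaussian kernel whose −3 dB amplitude point is f: σ_t = √(ln 2)/(2π f).
  The mapping is configurable; the realized attenuation at the cutoff is
  verified by FFT-level tests to within 2%.
* **Numeric promotion.** All arithmetic is float64; the historical
  14-bit→16-bit→32-bit integer promotion chain is not emulated. Dark
  subtraction may produce negative values, which are kept (clipping would
  bias F₀).
* **F₀.** Defined once, from the 1 s before the *first* pulse; never
  recomputed within a train.
* **Per-pulse windows.** (tₖ, tₖ₊₁] for pulses within the train, 1 s after
  the last pulse.
* **Local baseline.** The mean of the trace over [−204, −104] ms before each
  pulse. A 100-ms mean rather than a single sample keeps the detector's
  false-positive rate from hinging on one noise draw, and the 104-ms guard
  (the same end point as the RMS window) keeps temporal smoothing of the
  stimulus-locked rise from leaking backwards into the baseline. Per-pulse
  amplitudes are therefore increments over the preceding residual; a
  `baseline_mode="global"` flag references everything to the pre-train zero
  instead.
* **Decay fits.** The 80%→20% segment is located with crossing times by
  linear interpolation, taking the *last* downward 0.8-crossing and the
  *first* 0.2-crossing (robust to multi-crossing noise). The fit is
  unconstrained (scipy `curve_fit`, initialized from a log-linear
  regression) and referenced to the ΔF/F₀ zero, not the local baseline: the
  two-parameter model has no offset term, and on superposed trains the trace
  decays toward zero — subtracting the pre-pulse residual makes every
  late-pulse decay appear roughly twice as fast on constant-τ ground truth
  (verified against the generator). Segments stop 104 ms before the next
  pulse; segments that never reach 20% are fitted as-is and flagged
  truncated. r² = 1 − SS_res/SS_tot on the fitted segment; fits with
  r² < 0.990 are flagged invalid and excluded from summaries. The detected
  peak amplitude of an instantaneous-rise transient is attenuated ~3% by
  the prescribed 15-Hz filter; this is a deterministic property of the
  measurement path, not an estimation bias, so recovery tests compare the
  detected amplitude against the filtered model's peak while the fit's
  back-extrapolated `a` recovers the true amplitude exactly on noiseless
  input.
* **Cumulative load.** Rectangle rule (sample sum × frame interval) on
  |ΔF/F₀|, no normalization. Values are reported in ΔF/F₀·s by the library;
  dividing by the frame interval gives the samples-summed "a.u." convention
  used for the ~200 a.u. figures.
* **ROI placement.** ROIs are laid end-to-end along the centerline,
  axis-aligned to the dominant local direction; the 6-pixel offset is
  measured along the centerline (the natural traversal of a curved
  dendrite). All three ROIs are 2×2, so ROI-equal and pixel-equal averaging
  coincide. Branch-point exclusion is annotation-driven (synthetic
  geometry) or mask-driven (real data); no automatic branch detection.
  Manually placed ROI sets can be imported from JSON to preserve a blinded
  workflow on real recordings.
* **Spatial profiles.** Per-pixel amplitude uses the 10–70 ms window rule
  (group-2 convention, valid when transients may be absent); F₀ profiles
  are normalized to the per-profile maximum (the soma value is an
  alternative normalizer; the per-profile maximum was chosen because it
  bounds the profile in [0, 1] regardless of path extent, and it is flagged
  in output). "Local discrete peaks during the decay phase" are
  operationalized as post-peak local maxima of the residual around a 2-Hz
  envelope exceeding 5×RMS.
* **Confidence band.** The "95% uniform confidence band" is the
  Working–Hotelling/Scheffé two-parameter simultaneous band:
  halfwidth(x) = √(2·F₀.₉₅(2, n−2)) · SE(fitted value at x). Containment of
  a whole line is evaluated with the closed form sup_x of the standardized
  deviation (n·δ₀² + Sxx·δ₁²)/σ̂², for which the band is exact — Monte-Carlo
  coverage is 95% by construction, and measured so. Negative controls are
  pooled across genotypes; one band is fitted per marker channel (imaging
  conditions differ per fluorophore). Ties at the threshold are negative;
  the lower band limit is computed and reported but unused.
* **Statistics.** Natural-log transform before t-tests (the base does not
  affect t or p — asserted by test); pooled variance by default, Welch by
  flag. No correction across per-pulse tests, mirroring the per-parameter
  reporting convention; Benjamini–Hochberg is available and off by default.
  Dendrites are treated as independent units (2–3 per neuron), replicating
  the reference convention without endorsing it; no mixed-effects modeling.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: stimulus-locked
exponential transients with distal amplitude/F₀ gradients,
responder/non-responder mixtures over a realistic somatic-area range, EMCCD
counting noise with dark frames, and staining populations with
size-dependent background. It does **not** simulate optics (PSF, light
scatter), photobleaching, motion, cell-to-cell crosstalk, finite rise
kinetics, dye buffering/saturation, or spontaneous activity. Passing tests
therefore demonstrate that the analysis chain recovers its own model's
ground truth under realistic counting noise — not that the model captures
every property of real recordings.

## Sizes used by the automated checks

The acceptance computations use 500 simulated dendrites for noisy τ
recovery, 200 replicate two-cohort experiments (84 dendrites per group) for
the genotype power analysis, 10⁴ simulated control populations (100 cells
each) for band coverage, 1000-cell mixtures for classification agreement,
and 500 pure-noise traces (5000 windows) for detector calibration; these
sizes give Monte-Carlo standard errors comfortably below the decision
margins they feed.

## Known limitations

* The mean-band threshold is deliberately a band for the *regression line*,
  not a tolerance band for individual cells: individual true-negative cells
  exceed it with probability ≈ P(Z > crit·√(1/n + d²/Sxx)) ≈ 35–40% at
  n = 100 controls, independent of the background SD. In a 95/4/1 mixture
  this upgrades a third of the interneurons' negative channels, biasing the
  recovered interneuron fraction downward by ~1.5 percentage points —
  invisible at n ≈ 120 cells but systematic at scale. A tolerance-band
  option would change the operating characteristics and is intentionally
  not provided, to keep the implemented threshold faithful.
* Decay-fit τ on truncated segments (trains with τ comparable to the
  inter-pulse interval) relies on extrapolation below the 20% level and is
  correspondingly noisier; such fits are flagged.
* The per-pulse decay acceleration seen in recorded trains is not emulated
  by default; it can be injected via `tau_pulse_multipliers`.
* The CLI's TIFF round trip quantizes counts to uint16 (≤0.5-count error),
  negligible relative to read noise but not bit-exact against the in-memory
  pipeline.
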