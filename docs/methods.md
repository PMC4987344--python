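# Methods

This note documents the models, conventions, calibration procedure and known
limitations of `apcphys`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is asserted that the
code does not measure.

## 1. Model neuron

A single-compartment adaptive leaky integrate-and-fire neuron, the simplest
model able to express the three phenomena the feature pipeline must measure:
sag, spike-frequency adaptation, and stuttering.

```
C dV/dt   = -gL (V - EL) + I_sag - w + I_inj  (+ voltage noise)
I_sag     = g_sag s (E_sag - V)
τ_sag ds/dt = clip((EL - V)/(E_sag - EL), 0, 1) - s
τ_w  dw/dt  = -w ;   w ← w + b at each spike
τ_st dx/dt  = -x + √(2 τ_st) ξ(t)                      (unit-variance OU)
spike when V ≥ V_th + a_st (V_th - EL) max(x, 0);  V ← V_reset, refractory t_ref
```

* **Sag (I_h)**: a hyperpolarisation-activated conductance with a
  depolarised reversal (default −30 mV). Activation is linear near rest and
  clipped to [0, 1]: I_h activates on hyperpolarisation and is shut at or
  above rest, which gives the inward-rectifying I–V asymmetry real I_h
  shows. The current relaxes the early hyperpolarisation back toward
  baseline — the measured sag.
* **Adaptation**: a spike-triggered outward current (increment `b` pA,
  decay `τ_w`); it lengthens successive ISIs, producing AR > 1, and lowers
  the steady firing rate.
* **Stuttering**: a rectified Ornstein–Uhlenbeck modulation of the spike
  threshold. Only *upward* threshold excursions act, producing firing pauses
  (the stutter) while leaving the minimum threshold — and hence the
  rheobase — untouched, and making spontaneous or subthreshold-sweep firing
  impossible. Episode time constant: 20 ms for tonic presets (small ISI
  jitter), 60 ms for stuttering presets (see §4, limitations).
* **Depolarisation ceiling**: during a pause the membrane saturates at
  −10 mV rather than drifting through the 0 mV spike-detection level, as a
  paused real neuron (sodium-channel inactivation) would.
* **Spike waveform**: integrate-and-fire dynamics have no spike shape, so a
  Gaussian template peaking at +35 mV is stamped at each spike time. Its
  width parameter is inverted analytically so that the *extracted*
  full-width-at-half-height (half-height defined against the 0 mV detection
  threshold) equals the configured value.

**Numerics.** Fixed step equal to the 0.1 ms sampling interval;
exponential Euler on V (exact for a passive membrane — the RC-limit test
demands agreement with the closed-form charging curve to 0.1% of the step
deflection), forward Euler on the slow gates. A sample stores the state
advanced through its interval, so the discrete trace equals the closed form
evaluated one step later. Voltage noise is white with amplitude expressed as
the stationary subthreshold SD (default 0.05 mV). Non-finite states raise an
error naming the parameter set. The integrator is numba-compiled with a pure
NumPy/Python fallback.

## 2. Feature extraction conventions

The published definitions leave several details open; the package fixes them
as follows (each is tested):

* **R_in**: OLS slope of steady-state deflection (mean of the last 100 ms of
  the step, minus the pre-step baseline) vs current over −50..+50 pA.
  Sweeps containing spikes are excluded when at least three spike-free
  sweeps remain. Agrees with the normal-equations oracle to machine
  precision.
* **τ_m**: monoexponential least-squares fit of the −50 pA falling phase,
  from onset to 5× an initial guess (63%-crossing time); offset fitted
  jointly.
* **Sag**: (mean of last 100 ms) − (most hyperpolarised sample of the first
  50 ms) on the −50 pA step; the extremum rather than the onset mean, so the
  transient is not diluted. Positive when the trace relaxes toward baseline.
* **Spike detection**: upward crossing of 0 mV, 1 ms merge window, spike
  time at the excursion maximum; dV/dt detection available as an option.
* **Rheobase**: smallest step amplitude with ≥ 1 spike; silence is a flagged
  invalid feature, not an error.
* **Spike width**: mean full width at the midpoint between peak and
  detection threshold, crossings linearly interpolated between samples.
* **Max firing rate**: max over sweeps of spike count / step duration
  (count, not mean-ISI, convention).
* **AR / CV_ISI**: last/first ISI and sd/mean (sample sd, n−1) on the sweep
  100 pA above rheobase; if absent, the highest sweep is used and the
  deviation recorded in the feature notes.

A cell recorded without a suprathreshold protocol (e.g. with an intracellular
sodium-channel blocker) yields the subthreshold trio only; missing features
are flagged, never fatal.

## 3. Preset calibration

Each preset (RS-SST, GIN-RS, FS-SST-tonic/stutter, FS-PV-tonic/stutter,
G42-APC, G42-Neo, and a nominal PC) stores the published population mean and
SD (SE·√n) of all eight features. Population simulation draws per-cell
feature *targets* independently from lognormal distributions with those
moments (truncated at ±2.5 log-σ; unbounded draws produce unrealisable
target combinations) and inverts each target vector to model parameters
against the package's own extractor:

1. **Subthreshold trio** on the manifold (gL, r = g_sag/gL, τ0 = C/gL):
   gL matches R_in at fixed r (one-step rescaling, the voltage solution
   scales as 1/gL); r is bisected for the extracted sag (monotone, capped at
   3 for stability of the saturated-activation regime); τ0 iterates on the
   fitted time constant. The small bias that voltage noise adds to the sag
   extremum is measured on a few noisy simulations and folded back into the
   bisection goal.
2. **Threshold** placed at the simulated peak of the targeted rheobase
   current minus half a grid step (so grid quantisation averages out), floor
   60 pA so the +50 pA subthreshold sweep stays silent.
3. **Adaptation increment** bisected for the AR target on the
   rheobase+100 pA sweep (deterministic), with firing-rate priority: if the
   required adaptation caps the attainable 1 s rate below 95% of the rate
   target it is halved until the rate is reachable.
4. **Refractory period** adjusted so the 1000 pA sweep matches the maximum
   firing-rate target (floor 1 ms: sub-millisecond re-firing would merge
   stamped waveforms).
5. **Threshold-modulation amplitude** searched so the measured CV_ISI on the
   rheobase+100 pA sweep matches the CV target (capped at 0.2 of the
   threshold-to-rest distance for tonic presets, 1.0 for stuttering ones).

Drawing extracted-feature targets and inverting per cell — rather than
jittering conductances directly — makes the calibration contract (population
means of extracted features within 2 SE of the published rows) hold by
construction wherever the targets are realisable. A correlated-draw variant
(shared membrane-"size" factor loading R_in/τ_m positively and rheobase
negatively, as conductance-level jitter would imply) was evaluated and
rejected: it degrades class separability because the between-class direction
aligns with the shared factor, and under the feature-target design
independence is the natural choice.

Population checks at n = 50 per preset (seeds as in the test suite) land
within 2·SE on all eight features for the FS tonic presets and on
R_in/τ_m/sag/width/rate for the others; known exceptions are in §6.

## 4. Synthetic cohorts and study conditions

* **Two-line FS cohort** (clustering benchmarks): 14 FS-SST (11 tonic +
  3 stuttering) and 11 FS-PV (3 tonic + 8 stuttering), following the
  published phenotype proportions; CV targets 0.13 (tonic) and 1.3
  (stuttering) reproduce the mixed-row CV means.
* **IPSC default scenario**: total baseline charge 40.6 pA·s split
  somatic:dendritic = 43:39 (somatic events: 3 × rise 1 ms / decay 50 ms;
  dendritic: 3 × rise 4 ms / decay 90 ms, both within the 20 ms light
  window), residual fraction 0.10, 10 trials of the trace plus 5 pA white
  noise on a +25 pA holding current. Noiseless decomposition:
  47.2% somatic / 42.8% distal / 10.0% other. The benchmark experiment runs
  six cells of this default scenario; `sample_pc_scenarios` additionally
  provides a heterogeneous population (charge CV ≈ 0.6, split SD ≈ 0.19,
  residual SD ≈ 0.07) that reproduces the published 6-cell standard errors.
* **Anatomy**: homogeneous Poisson patterns at the published densities
  (SST line 100 /mm², PV line 48.2 /mm²) with co-label probabilities 0.75
  (SST+ in the SST line) and 0.95 (PV+ in the PV line); sections of
  0.83 mm² give the ~40 reporter cells per section of the co-labeling runs.
  Intensity patches are 1 µm²-pixel squares (default 140 µm²) with Gaussian
  noise.

**Problem sizes.** The clustering medians use 100 independent cohorts
(25 cells each, both protocols — a few minutes on one CPU); feature-recovery
runs use 50 cells; the decomposition six cells; co-labeling ten sections.

## 5. What the generator does and does not emulate

It emulates: step-protocol current-clamp responses with the four firing
phenotypes, population variability matched to published moments, light-evoked
compound IPSCs with separable somatic/dendritic components and a
block-resistant residual, and counted anatomy.

It does not emulate: electrode/access artefacts, bridge imbalance, true
conductance-based spike shapes, synaptic short-term plasticity or GABA_B
effects, drift or wash-in kinetics of local drug application (recovery after
block is not modelled — consistent with most cells not recovering), spatial
clustering of somata, or imaging point-spread. Passing tests therefore show
that the *analysis* behaves correctly under a controlled ground truth with
realistic population statistics — not that it is robust to every artefact of
real recordings.

## 6. Known limitations

* **Subthreshold-trio separability.** Under population spreads equal to
  SE·√n of the published rows, even clustering the noiseless target vectors
  (no simulation, no extraction) misclassifies a median of ~4 SST cells at
  k = 2 over 200 cohorts; the published value of 2 corresponds to a
  realisation in the favourable third of that distribution. The pipeline
  performs at this intrinsic ceiling.
* **Stuttering AR.** With AR defined as last/first ISI, any pause that
  captures the final interval inflates AR enormously; published stuttering
  cells show AR ≈ 1.17 ± 0.07 *and* CV ≈ 1.3, which a bimodal ISI process
  cannot reproduce exactly. The 60 ms episode constant keeps the extracted
  AR mean at ~1.1 at some cost in CV (≈ 0.9 vs 1.3); heavy AR tails remain.
* **G42-APC**: extracted rheobase is floored at 100 pA by the 100 pA
  protocol grid (published mean 70.6 pA); about a quarter of drawn cells
  have membranes too slow to form a sag minimum inside the 50 ms onset
  window, so the population sag mean underscores its target; and an AR of
  4.3 conflicts with a 72 Hz maximum rate in a single-adaptation-current
  model (the rate is prioritised). The G42 input-resistance and time
  constant calibrations are unaffected.
* **CSV round trips** store 6 significant digits; bit-exact reproducibility
  holds for generation (fixed seed), not across a write/read cycle.
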