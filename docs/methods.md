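# Methods

This note documents the models, the numerical and statistical choices, and
the limits of what the test suite demonstrates. Everything quantitative
stated here is computed by the tests or by `scripts/acceptance.py`.

## Microcircuit model

The simulated circuit has 36 leaky integrate-and-fire neurons: 4 VIP, 6 SST
and 6 PV interneurons and 20 pyramidal cells, wired with the disinhibitory
motif (VIP inhibits mostly SST; SST provides feedback inhibition onto
PV/PYR; PV provides strong feedforward inhibition onto PV/PYR). All
connections are class-level and all-to-all except pyramidal→pyramidal,
which uses a random binary matrix with connection probability 0.2 and no
self-connections.

Dynamics are discrete-time on a dt = 0.1 ms grid. Voltages decay with
`exp(-dt/τ_m)` (τ_m = 10 ms) and integrate `dt ×` the weighted sum of
class-level synaptic outputs, the vHPC drive and per-neuron noise; dt enters
in milliseconds, which together with the spike threshold of 10 and the
printed weight scale makes the default network fire at plausible rates. A
neuron crossing threshold spikes; its voltage is forced to the reset value
(−10) on the **next** step, during which its inputs are ignored, and normal
integration resumes the step after. The reset convention (inputs ignored for
exactly one step) is a modeling choice; the alternative (resetting within
the same step) changes spike times by at most one step at these rates.

Class outputs are leaky accumulators (`out ← out·exp(-dt/τ_syn) + P`, P =
fraction of the class that spiked), with τ_syn = 20 ms for interneuron
channels and 10/80 ms for pyramidal AMPA/NMDA; NMDA contributions are scaled
by 0.3 wherever they enter a voltage equation. Per-pyramidal-cell outputs
(increment 1 when that cell spikes) feed the pyramidal→pyramidal term
through the connectivity matrix.

External drive: event rasters are Bernoulli per step with p = rate·dt (at
most one event per step; the constructor rejects rate·dt > 1). The
stimulation raster fires at 100 Hz for 2 s ≤ t ≤ 3 s and decays as
100·exp(−(t−3 s)/1 s) afterwards; background vHPC noise fires at 100 Hz
throughout; per-neuron noise fires at 100 Hz with amplitude 1 (1.2 for PV).
Rasters are filtered with truncated exponential kernels (8 ms over 40 steps;
NMDA 80 ms over 400 steps), exactly as stated — the truncation at 40 steps
(half a time constant) is deliberate and matched by the tests.

Spike-count traces are smoothed with a Gaussian (σ = 25 ms), truncated at
±4σ and renormalized at the record edges so total activity tracks total
spikes (verified to 2%). Reported activity traces average five runs. Evoked
peaks subtract the mean activity over 0.1–2 s and take the maximum from
stimulation onset to the end of the simulation (the response window is a
package choice; results are insensitive to its right edge because responses
peak during or shortly after stimulation).

The inner loop is compiled with numba; a plain-Python per-step transcription
of the same equations (`swmphot.microcircuit_reference`) exists purely as an
independent oracle, and the two are required to agree to 1e-9 on voltages
and exactly on spikes.

**Weight sweep.** The vHPC→VIP weight is lowered from 1.6 to 0.85 over six
evenly spaced values (the endpoints are fixed; the grid density is
configurable). Ten simulations of five runs each per weight by default;
Spearman rank correlation between weight and mean evoked peak summarizes the
direction per class. Seeds derive from a master seed per (weight, sim, run),
so the experiment is exactly reproducible.

## Photometry chain

Processing follows the acquisition model: a spectrometer records photon
counts on a wavelength grid at 20 or 40 Hz. The GCaMP and tdTomato bands are
500–541 and 577–618 nm. Unmixing solves per-frame least squares against
unit-norm reference spectra plus a constant background column (a
non-negativity option exists; unconstrained OLS is the default and is exact
on noise-free synthetic spectra). Detrending removes the fitted line but
restores the record mean, so ΔF/F denominators and ratios keep their scale.
Downsampling is non-overlapping block means. %ΔF/F baselines on the 10-s
pre-stimulation mean of each 30-s trial; evoked magnitude is the trace
maximum in the 10–15 s window. The GCaMP/tdTomato ratio cancels any strictly
positive multiplicative artifact shared by the channels — exactly, by
construction — and is z-scored per trial (trials with near-zero denominators
or zero variance are excluded with a warning, never imputed).

**Transient detection.** Candidate peaks need prominence ≥ 2.91 × MAD of the
analysed trace, where MAD is unscaled — the Gaussian consistency factor is
already folded into the multiplier (1.96/0.6745 ≈ 2.91, asserted in the
tests). Prominence is measured within the 1.6-s feature window; peaks closer
than 1 s keep the larger. Event magnitude is peak height above the trace
median, and half-width is the full width at half that magnitude
(baseline-relative FWHM — the standard half-width of a calcium event),
constrained to 0.5–10 s. The FWHM definition matters: widths measured at
half-*prominence* (a generic peak-finder convention) let narrow noise peaks
through at ~0.2 events per 10 s on white noise, whereas baseline-relative
widths keep the false-event rate below 0.005 per 10 s at the same amplitude
threshold while detecting essentially all generator events.

Peri-event windows snap event times to the nearest sample of the 10-Hz
analysis grid. The distal-delay score is the mean z over the 2 s before
Choice Start. Cross-correlations use ±50 integer lags at 10 Hz with the
convention that a positive lag means calcium leads velocity.

## Functional regression

Five model specifications regress trial-level z-scored traces on covariates
(Training rescaled to [0,1] per mouse; Outcome 0 = correct; Stimulation
0 = control; Genotype 0 = wildtype). Point estimates are per-timepoint OLS
on the pooled trials. The mixed-model random effects of the original
formulation are not estimated explicitly; all between-mouse structure is
absorbed by a cluster bootstrap over mice. This is an approximation, and its
calibration is demonstrated rather than assumed: on null cohorts (12 mice ×
100 trials × 100 timepoints) pointwise 95% bands cover zero ≈ 94–95% of the
time and joint bands flag a false interval in ≈ 5% of fits.

Two few-cluster pitfalls shaped the implementation:

- *Plain percentile intervals undercover.* With 12 mice, per-timepoint
  2.5/97.5% replicate quantiles cover zero only ~89–90% of the time.
  Intervals are therefore bootstrap-t: replicate deviations are studentized
  by their own CR1 cluster-robust standard errors, and the pointwise band is
  `β̂ ± q(0.95 of |t|)·se`.
- *Pairs resampling breaks with mouse-level covariates.* Resampling 12 mice
  with replacement occasionally leaves a group nearly empty, producing
  explosive studentized deviations and useless joint bands. The default is
  the wild cluster bootstrap (per-mouse Rademacher sign flips of residuals,
  design fixed); pairs resampling remains available.

The joint band uses the bootstrap distribution of the maximum |t| over time,
with the variance function pooled to its trace RMS per term: the per-
timepoint SE from 12 clusters is noisy, and that noise — not real signal —
dominates the tail of the max statistic. Replicates are pooled identically,
so the band stays calibrated; it is enlarged where necessary to contain the
pointwise band. Replicates with fewer than two distinct mice or a
rank-deficient design are redrawn (pairs mode only; the wild bootstrap
cannot produce them). Default n_boot = 1000 (tests and simulations use 200
for speed; quantile noise at 200 is visible but small).

Power at the emulated study scale is honest and limited: a 0.5 z-unit
Training×Group interaction confined to the 2-s distal window is recovered
essentially without bias, but a calibrated 95% joint band flags it in only
~65–80% of replicate cohorts (12 mice, 100 trials/mouse; the estimate
varies across seed batches of 20–60 cohorts). The binding constraint is the
trial-to-trial residual SD of per-trial z-scored signals (~0.8 at a fixed
timepoint), which puts the window t-statistic near 3 while any valid
simultaneous threshold sits near 3.5. Constructions that detected more
reliably in simulation did so only by violating their nominal family-wise
error (measured up to 56% instead of 5%) and were rejected.

## Synthetic-data generator

The generator produces every input the pipeline consumes, with ground truth:

- **Spectra.** Unit-norm Gaussian emission profiles peaking at 513 and
  581 nm (width 14 nm) on a 480–650 nm grid; most of each profile's mass
  falls in its summation band. Counts are Poisson samples of coefficient ×
  spectrum + background, after linear bleaching (20%/10% per session for
  green/red) and a shared multiplicative motion artifact
  `exp(0.1 × smooth noise)`. The artifact is identical across fluorophores
  by design, so the ratio invariant is exactly testable; differential
  artifacts, hemodynamics and dark noise beyond Poisson are not modeled —
  passing tests say nothing about those failure modes.
- **Transients.** Single-spike kernel = difference of exponentials (rise
  50 ms, decay 500 ms). Discrete spontaneous events are 1-s spike bursts
  convolved with that kernel (half-widths ≈ 1–1.3 s, inside the detector's
  0.5–10 s band, as in vivo events are), at 0.15 Hz with a 2-s minimum gap —
  a hard-core process, because overlapping bursts sum into a single
  fluorescence event and would make detection "misses" an artifact of the
  bookkeeping rather than the detector.
- **Trials.** DNMS sessions have sample (5 ± 1 s), exactly-10-s delay and
  choice (5 ± 1 s) epochs. Within-trial calcium modulation is a task-locked
  template (onset transients, approach dips) plus smooth noise at the
  indicator timescale (SD 0.6), z-normalized per trial — mirroring what
  per-trial ratio z-scoring emits — with the configured distal-window shift
  added afterwards: fixed effects (outcome, training, their interaction,
  group, training×group) plus a per-mouse random effect (SD 0.3). Outcomes
  are Bernoulli with a logistic link on training fraction, optionally
  coupled to the mouse's distal activity so the score–accuracy correlation
  is controllable. Note that per-trial z-scoring itself attenuates an
  injected window shift by ~10–20% (the shift inflates the trial mean and
  SD); the end-to-end tests assert recovery inside that expected band.
- **Stimulation days** run at 40 Hz: a 10-min baseline with spontaneous
  events, then 30-s trials with an evoked transient at the 10-s mark scaled
  by a per-day plasticity profile (descending profiles emulate the
  depressing VIP phenotype, ascending ones the potentiating SST phenotype).

Every output is reproducible from (params, seed); all randomness flows
through `numpy.random.SeedSequence` spawning.

## Problem sizes in the test suite

The suite exercises the full default model (10-s simulations, 36 neurons,
dt = 0.1 ms) but scales repetition counts to what the checks need: the
weight sweep uses 5 simulations × 5 runs per weight over the 6-value grid;
regression calibration uses 200 null cohorts with n_boot = 200; detection
metrics use 20 ten-minute sessions. Unit tests use 0.1–1.5 s simulations.

## Known limitations

- The simulator is a rate-plausible toy: conductances, dendrites,
  short-term plasticity and spatial structure are out of scope, and the
  weight table is fixed a priori, not fitted to data. The unusually large
  pyramidal→SST weight (8) comes directly from the adopted reading of the
  printed weight table and is surfaced as a config default rather than
  hard-coded.
- The regression replaces likelihood-based functional mixed models with
  pointwise OLS + cluster bootstrap; random-effect covariances are never
  estimated, and with ≤ 12 mice the joint bands are honest but conservative
  (see above).
- The generator's realism claims extend only to the statistical structure
  listed here; it does not simulate video, maze hardware, or spectrometer
  systematics.
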