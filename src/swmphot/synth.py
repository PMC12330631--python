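"""Synthetic-data generator for every input the analysis pipeline consumes.

The generator emulates the statistical structure of the real recordings --
two fluorophore emission spectra mixed onto a spectrometer wavelength grid,
Poisson photon noise, linear photobleaching, a multiplicative motion
artifact shared by both channels, calcium transients with known times and
amplitudes, the 10-s-delay DNMS trial structure, per-mouse random effects
and training-dependent modulation of distal-delay activity -- and returns a
ground-truth record alongside every observable so recovery can be scored.

What it does *not* emulate: spectrometer dark noise beyond Poisson
statistics, hemodynamic contamination, or motion artifacts that differ
between fluorophores (the shared-artifact assumption is deliberate: it is
exactly the condition under which the green/red ratio method is valid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .funcreg import FunctionalDataset
from .behavior import TrainingRecord
from .photometry import ReferenceSpectra, SpectralTimeseries


class GroundTruth(dict):
    """Dict of generator ground-truth entries with attribute access."""

    def __getattr__(self, key):
        try:
            return self[key]
        except KeyError as e:
            raise AttributeError(key) from e


@dataclass
class GeneratorParams:
    """Defaults define the emulated study conditions."""

    # cohort structure
    n_mice_per_group: int = 6
    trials_per_mouse: int = 100
    trials_per_session: int = 10

    # acquisition
    rate_hz: float = 20.0          # behavioral (SWM) sessions
    stim_rate_hz: float = 40.0     # stimulation sessions
    grid_nm: tuple = (480.0, 650.0, 1.0)   # start, stop, step
    peaks_nm: tuple = (513.0, 581.0)
    widths_nm: tuple = (14.0, 14.0)

    # photon budget and slow artifacts
    gcamp_baseline: float = 60.0   # coefficient units (counts scale)
    tdt_baseline: float = 100.0
    background_counts: float = 2.0
    bleach_fraction: tuple = (0.2, 0.1)    # (GCaMP, tdTomato) over a session
    motion_amplitude: float = 0.1
    motion_timescale_s: float = 2.0

    # calcium transients (GCaMP6f-like difference of exponentials); discrete
    # events are short spike bursts convolved with the kernel, as in vivo
    transient_rise_s: float = 0.05
    transient_decay_s: float = 0.5
    burst_s: float = 1.0
    spontaneous_rate_hz: float = 0.15
    min_event_gap_s: float = 2.0
    amp_median: float = 30.0       # coefficient units
    amp_sigma: float = 0.3         # lognormal sigma
    evoked_amp: float = 40.0       # stimulation-evoked transient amplitude

    # trial-level signal model (z scale)
    signal_cv: float = 0.15        # coefficient modulation per z unit
    within_trial_noise_sd: float = 0.6
    mouse_sd: float = 0.3          # random-effect SD on distal activity
    effects: dict = field(default_factory=lambda: {
        "outcome": 0.5,            # incorrect - correct at training onset
        "training": 0.8,           # change across training, correct trials
        "training:outcome": -0.5,
        "group": 0.0,
        "training:group": -0.5,
    })

    # task epochs (delay is exactly 10 s)
    delay_s: float = 10.0
    sample_mean_s: float = 5.0
    sample_sd_s: float = 1.0
    choice_mean_s: float = 5.0
    choice_sd_s: float = 1.0
    iti_s: float = 15.0
    distal_window_s: float = 2.0

    # behavior / accuracy model (logistic)
    acc_logit_base: float = 0.0
    acc_training_gain: float = 2.0
    accuracy_coupling: float = 0.0   # per-mouse distal activity -> accuracy

    # velocity coupling per recorded cell class
    vel_coupling: dict = field(default_factory=lambda: {
        "VIP": {"sign": -1.0, "lag_s": 0.5},
        "SST": {"sign": 1.0, "lag_s": 0.0},
    })
    vel_noise_sd: float = 0.3

    master_seed: int = 0

    def wavelength_grid(self) -> np.ndarray:
        start, stop, step = self.grid_nm
        return np.arange(start, stop + step / 2, step)


def make_reference_spectra(grid_nm, peaks_nm=(513.0, 581.0),
                           widths_nm=(14.0, 14.0)) -> ReferenceSpectra:
    """Unit-norm Gaussian emission profiles on a wavelength grid."""
    grid = np.asarray(grid_nm, dtype=float)
    cols = []
    for peak, width in zip(peaks_nm, widths_nm):
        if not grid[0] <= peak <= grid[-1]:
            raise ValueError(f"peak {peak} nm outside the wavelength grid")
        s = np.exp(-0.5 * ((grid - peak) / width) ** 2)
        cols.append(s / np.linalg.norm(s))
    return ReferenceSpectra(wavelengths_nm=grid,
                            spectra=np.column_stack(cols))


def transient_kernel(rate_hz: float, rise_s: float = 0.05,
                     decay_s: float = 0.5, length_s: float = 4.0) -> np.ndarray:
    """Difference-of-exponentials calcium kernel, peak-normalized to 1."""
    t = np.arange(int(round(length_s * rate_hz))) / rate_hz
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def event_shape(rate_hz: float, rise_s: float = 0.05, decay_s: float = 0.5,
                burst_s: float = 1.0, length_s: float = 5.0) -> np.ndarray:
    """Waveform of one discrete calcium event, peak-normalized to 1.

    A spontaneous fluorescence event reflects a brief burst of spikes, not a
    single action potential: the single-spike kernel is convolved with a
    ``burst_s`` boxcar, which widens the event to the half-widths seen in
    vivo.
    """
    k = transient_kernel(rate_hz, rise_s, decay_s, length_s)
    n_burst = max(1, int(round(burst_s * rate_hz)))
    shape = np.convolve(k, np.ones(n_burst))
    return shape / shape.max()


def _sample_event_times(rng, duration_s, rate_hz, min_gap_s):
    """Event times with an enforced minimum gap (hard-core renewal process).

    Gaps are min_gap + Exponential, with the exponential mean chosen so the
    long-run rate equals ``rate_hz``.
    """
    if rate_hz <= 0:
        return np.array([])
    mean_gap = 1.0 / rate_hz
    if mean_gap <= min_gap_s:
        raise ValueError("event rate incompatible with the minimum gap")
    times = []
    t = float(rng.exponential(mean_gap))
    while t < duration_s:
        times.append(t)
        t += min_gap_s + rng.exponential(mean_gap - min_gap_s)
    return np.array(times)


def _smooth_noise(rng, n, rate_hz, timescale_s):
    """Unit-SD Gaussian noise low-passed at the given timescale."""
    x = gaussian_filter1d(rng.standard_normal(n), timescale_s * rate_hz)
    sd = x.std()
    return x / sd if sd > 0 else x


def _add_events(trace, times_s, amps, kernel, rate_hz):
    for t0, a in zip(np.atleast_1d(times_s), np.atleast_1d(amps)):
        i = int(round(t0 * rate_hz))
        j = min(i + kernel.size, trace.size)
        if 0 <= i < trace.size:
            trace[i:j] += a * kernel[: j - i]


def _mix_to_counts(g, td, refs, params, rng, noise="poisson",
                   motion=None, bleach=True):
    """Coefficients -> wavelength x time photon counts."""
    T = g.size
    t_frac = np.arange(T) / max(T - 1, 1)
    if bleach:
        bg_g, bg_t = params.bleach_fraction
        g = g * (1 - bg_g * t_frac)
        td = td * (1 - bg_t * t_frac)
    lam = (refs.spectra[:, 0][:, None] * g[None, :]
           + refs.spectra[:, 1][:, None] * td[None, :]
           + params.background_counts)
    if motion is not None:
        lam = lam * motion[None, :]
    lam = np.clip(lam, 0, None)
    if noise == "poisson":
        counts = rng.poisson(lam).astype(float)
    elif noise == "none":
        counts = lam
    else:
        raise ValueError("noise must be 'poisson' or 'none'")
    return counts, g, td


def _distal_shift(params, tf, outcome, group, mouse_re):
    e = params.effects
    return (e["outcome"] * outcome
            + e["training"] * tf
            + e["training:outcome"] * tf * outcome
            + e["group"] * group
            + e["training:group"] * tf * group
            + mouse_re)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_swm_session(params: GeneratorParams, mouse_id, seed,
                         n_trials: int | None = None, group: int = 0,
                         training_fractions=None, mouse_re=None,
                         cell_class: str = "VIP", noise: str = "poisson",
                         motion: bool = True):
    """One behavioral recording session for one mouse.

    Builds DNMS trials (sample -> exactly-10-s delay -> choice) and a
    within-trial calcium modulation trace on the z scale: a stereotyped
    task-locked template plus smooth noise, normalized per trial, with the
    configured distal-delay shift added in the 2 s before Choice Start.
    The modulation drives the GCaMP coefficient; both fluorophores are mixed
    through the reference spectra, scaled by a shared motion artifact,
    linearly bleached and Poisson-sampled. Velocity is generated from the
    calcium truth with the configured sign and lead/lag.

    Returns (SpectralTimeseries, trial table, velocity, GroundTruth).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fs = params.rate_hz
    if n_trials is None:
        n_trials = params.trials_per_session
    if training_fractions is None:
        training_fractions = (np.arange(n_trials) / max(n_trials - 1, 1))
    if mouse_re is None:
        mouse_re = rng.normal(0, params.mouse_sd)

    # --- trial event schedule ---
    rows = []
    cursor = params.iti_s
    for e in range(n_trials):
        ss = cursor
        se = ss + max(1.0, rng.normal(params.sample_mean_s, params.sample_sd_s))
        ds = se + 1.0                       # return to start box
        cs = ds + params.delay_s            # delay is exactly 10 s
        ce = cs + max(1.0, rng.normal(params.choice_mean_s, params.choice_sd_s))
        tf = float(training_fractions[e])
        p_correct = _sigmoid(params.acc_logit_base
                             + params.acc_training_gain * tf
                             + params.accuracy_coupling * mouse_re)
        outcome = int(rng.random() > p_correct)   # 0 = correct, 1 = incorrect
        rows.append({"mouse_id": mouse_id, "trial_index": e,
                     "training_fraction": tf, "outcome": outcome,
                     "group": group, "sample_start": ss, "sample_end": se,
                     "delay_start": ds, "choice_start": cs, "choice_end": ce})
        cursor = ce + params.iti_s
    trials = pd.DataFrame(rows)
    duration = cursor + params.iti_s
    T = int(round(duration * fs))
    times = np.arange(T) / fs

    # --- z-scale modulation trace ---
    z = np.zeros(T)
    deltas = np.empty(n_trials)
    kernel = transient_kernel(fs, params.transient_rise_s,
                              params.transient_decay_s)
    win_n = int(round(params.distal_window_s * fs))
    for e, tr in trials.iterrows():
        i0 = int(round(tr.sample_start * fs))
        i1 = int(round(tr.choice_end * fs))
        tt = times[i0:i1] - tr.sample_start
        # task-locked template: onset bumps, approach dips
        template = np.zeros(i1 - i0)
        _add_events(template, [0.0, tr.choice_start - tr.sample_start],
                    [1.0, 1.0], kernel, fs)
        template -= 0.6 * np.exp(-0.5 * ((tt - (tr.sample_end
                                               - tr.sample_start)) / 0.8) ** 2)
        template -= 0.6 * np.exp(-0.5 * ((tt - (tr.choice_end
                                               - tr.sample_start)) / 0.8) ** 2)
        seg = template + params.within_trial_noise_sd * _smooth_noise(
            rng, i1 - i0, fs, params.transient_decay_s)
        seg = (seg - seg.mean()) / seg.std()
        delta = _distal_shift(params, tr.training_fraction, tr.outcome,
                              group, mouse_re)
        cs_i = int(round(tr.choice_start * fs)) - i0
        seg[max(cs_i - win_n, 0):cs_i] += delta
        z[i0:i1] = seg
        deltas[e] = delta

    # --- mix to photon counts ---
    g = params.gcamp_baseline * np.clip(1.0 + params.signal_cv * z, 0.05, None)
    td = np.full(T, params.tdt_baseline)
    m = (np.exp(params.motion_amplitude
                * _smooth_noise(rng, T, fs, params.motion_timescale_s))
         if motion else None)
    refs = make_reference_spectra(params.wavelength_grid(), params.peaks_nm,
                                  params.widths_nm)
    counts, g_obs, td_obs = _mix_to_counts(g, td, refs, params, rng,
                                           noise=noise, motion=m)
    spec = SpectralTimeseries(wavelengths_nm=refs.wavelengths_nm,
                              counts=counts, rate_hz=fs)

    # --- velocity coupled to the calcium truth ---
    vc = params.vel_coupling[cell_class]
    lag_n = int(round(vc["lag_s"] * fs))
    vel = np.full(T, np.nan)
    vel[lag_n:] = vc["sign"] * z[: T - lag_n] if lag_n > 0 else vc["sign"] * z
    vel[:lag_n] = vc["sign"] * z[0]
    vel = vel + params.vel_noise_sd * rng.standard_normal(T)

    truth = GroundTruth(
        z_trace=z, gcamp_coeff=g, tdt_coeff=td,
        gcamp_coeff_bleached=g_obs, tdt_coeff_bleached=td_obs,
        motion=m, distal_deltas=deltas, mouse_re=mouse_re,
        velocity_lag_s=vc["lag_s"], velocity_sign=vc["sign"],
        references=refs,
    )
    return spec, trials, vel, truth


def simulate_stim_day(params: GeneratorParams, day_index: int,
                      plasticity_profile, seed, n_trials: int = 10,
                      baseline_s: float = 600.0, trial_len_s: float = 30.0,
                      stim_at_s: float = 10.0, noise: str = "poisson"):
    """One opto-photometry stimulation day at the stimulation sampling rate.

    A 10-minute baseline with spontaneous transients is followed by
    ``n_trials`` 30-s stimulation trials whose evoked transient (at the 10-s
    mark) is scaled by ``plasticity_profile[day_index]`` (a depressing
    profile emulates the VIP phenotype, a potentiating one SST).

    Returns (SpectralTimeseries, trial start times, GroundTruth).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fs = params.stim_rate_hz
    mult = float(plasticity_profile[day_index]) \
        if not np.isscalar(plasticity_profile) else float(plasticity_profile)
    duration = baseline_s + n_trials * trial_len_s
    T = int(round(duration * fs))

    shape = event_shape(fs, params.transient_rise_s, params.transient_decay_s,
                        params.burst_s)
    g = np.full(T, params.gcamp_baseline)
    spont_times = _sample_event_times(rng, baseline_s - 4.0,
                                      params.spontaneous_rate_hz,
                                      params.min_event_gap_s)
    spont_amps = params.amp_median * np.exp(
        params.amp_sigma * rng.standard_normal(spont_times.size))
    _add_events(g, spont_times, spont_amps, shape, fs)

    trial_starts = baseline_s + trial_len_s * np.arange(n_trials)
    evoked_amps = mult * params.evoked_amp * np.exp(
        0.1 * rng.standard_normal(n_trials))
    _add_events(g, trial_starts + stim_at_s, evoked_amps, shape, fs)

    td = np.full(T, params.tdt_baseline)
    refs = make_reference_spectra(params.wavelength_grid(), params.peaks_nm,
                                  params.widths_nm)
    counts, g_obs, td_obs = _mix_to_counts(g, td, refs, params, rng,
                                           noise=noise, motion=None)
    spec = SpectralTimeseries(wavelengths_nm=refs.wavelengths_nm,
                              counts=counts, rate_hz=fs)
    peak_offset_s = float(np.argmax(shape)) / fs
    truth = GroundTruth(
        gcamp_coeff=g, tdt_coeff=td, gcamp_coeff_bleached=g_obs,
        spont_times=spont_times, spont_amps=spont_amps,
        spont_peak_times=spont_times + peak_offset_s,
        evoked_amps=evoked_amps, evoked_times=trial_starts + stim_at_s,
        baseline_s=baseline_s, references=refs, multiplier=mult,
        event_peak_offset_s=peak_offset_s,
    )
    return spec, trial_starts, truth


def simulate_cohort(params: GeneratorParams, seed, group_name: str = "stim",
                    analysis_rate_hz: float = 10.0, window_s=(-8.0, 2.0)):
    """Full multi-mouse dataset for the regression and behavior modules.

    Trial-level traces are generated directly on the analysis (z) scale,
    mirroring what the photometry pipeline emits for one trial: a full-trial
    task-locked template (onset bumps, approach dips) plus smooth
    within-trial noise, z-scored over the *full trial* -- as the per-trial
    ratio z-scoring does -- then windowed around Choice Start, with the
    configured distal-window shift (fixed effects plus the per-mouse random
    effect) added after normalization. Outcomes follow a logistic model in
    training fraction with optional coupling to the mouse's distal activity
    (``accuracy_coupling``).

    Returns (FunctionalDataset, TrainingRecord, GroundTruth).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fs = analysis_rate_hz
    T = int(round((window_s[1] - window_s[0]) * fs))
    time_s = window_s[0] + np.arange(T) / fs
    distal_mask = (time_s >= -params.distal_window_s) & (time_s < 0)

    # full-trial template on the analysis grid (sample epoch, 10-s delay,
    # choice epoch), from which the peri-choice window is cut
    sample_dur = params.sample_mean_s
    choice_dur = params.choice_mean_s
    trial_len = sample_dur + 1.0 + params.delay_s + choice_dur
    cs_s = sample_dur + 1.0 + params.delay_s      # choice start within trial
    n_full = int(round(trial_len * fs))
    t_full = np.arange(n_full) / fs
    kernel = transient_kernel(fs, params.transient_rise_s,
                              params.transient_decay_s)
    mu = np.zeros(n_full)
    _add_events(mu, [0.0, cs_s], [1.0, 1.0], kernel, fs)
    mu -= 0.6 * np.exp(-0.5 * ((t_full - sample_dur) / 0.8) ** 2)
    mu -= 0.6 * np.exp(-0.5 * ((t_full - trial_len) / 0.8) ** 2)
    cs_i = int(round(cs_s * fs))
    i0 = cs_i + int(round(window_s[0] * fs))
    i1 = cs_i + int(round(window_s[1] * fs))
    win_full = np.zeros(n_full, dtype=bool)
    win_full[cs_i - int(round(params.distal_window_s * fs)):cs_i] = True

    n_mice = 2 * params.n_mice_per_group
    E = params.trials_per_mouse
    Y = np.empty((n_mice * E, T))
    cov_rows = []
    cluster = np.empty(n_mice * E, dtype=object)
    mouse_res = {}
    deltas = np.empty(n_mice * E)
    row = 0
    for mi in range(n_mice):
        mouse = f"m{mi:02d}"
        group = int(mi >= params.n_mice_per_group)
        b = rng.normal(0, params.mouse_sd)
        mouse_res[mouse] = b
        for e in range(E):
            tf = e / (E - 1)
            p_correct = _sigmoid(params.acc_logit_base
                                 + params.acc_training_gain * tf
                                 + params.accuracy_coupling * b)
            outcome = int(rng.random() > p_correct)
            delta = _distal_shift(params, tf, outcome, group, b)
            base = mu + params.within_trial_noise_sd * _smooth_noise(
                rng, n_full, fs, params.transient_decay_s)
            base = (base - base.mean()) / base.std()
            Y[row] = (base + delta * win_full)[i0:i1]
            cov_rows.append({"training": tf, "outcome": outcome,
                             group_name: group})
            cluster[row] = mouse
            deltas[row] = delta
            row += 1
    covariates = pd.DataFrame(cov_rows)
    dataset = FunctionalDataset(Y=Y, covariates=covariates, cluster=cluster,
                                time_s=time_s)

    # behavior record: days of trials_per_session trials, 1 = correct
    outcomes = {}
    groups = {}
    per_day = params.trials_per_session
    for mi in range(n_mice):
        mouse = f"m{mi:02d}"
        sel = cluster == mouse
        oc = 1 - covariates.loc[sel, "outcome"].to_numpy()
        n_days = oc.size // per_day
        outcomes[mouse] = [oc[d * per_day:(d + 1) * per_day].tolist()
                           for d in range(min(n_days, 15))]
        groups[mouse] = "HFS" if mi >= params.n_mice_per_group else "NS"
    record = TrainingRecord(outcomes=outcomes, groups=groups,
                            trials_per_day=per_day)

    truth = GroundTruth(
        effects=dict(params.effects), mouse_re=mouse_res,
        distal_deltas=deltas, distal_mask=distal_mask, template=mu,
        group_name=group_name,
    )
    return dataset, record, truth
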