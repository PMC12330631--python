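"""Spectrometer-based fiber-photometry processing chain.

The acquisition device records a full emission spectrum (photon counts on a
wavelength grid) at every frame. Two fluorophores are present: a calcium
indicator (GCaMP-like, green) and a static reference fluorophore
(tdTomato-like, red). Processing proceeds through:

1. band summation or spectral linear unmixing -> per-fluorophore timeseries;
2. linear detrending (photobleaching correction), mean-preserving;
3. block-mean downsampling to the common 10-Hz analysis grid;
4. either %dF/F against a pre-stimulus baseline (stimulation sessions) or
   the green/red ratio z-scored per trial (behavioral sessions) -- the ratio
   cancels any motion artifact that multiplies both channels equally;
5. transient detection by peak prominence relative to the median absolute
   deviation, peri-event averaging, distal-delay scoring, and lagged
   cross-correlation against locomotion velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

TRIAL_EVENT_COLUMNS = (
    "sample_start", "sample_end", "delay_start", "choice_start", "choice_end",
)


@dataclass
class SpectralTimeseries:
    """Wavelength x time photon-count matrix with its acquisition metadata."""

    wavelengths_nm: np.ndarray
    counts: np.ndarray          # (n_wavelengths, n_frames)
    rate_hz: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.counts.shape[0] != self.wavelengths_nm.size:
            raise ValueError("counts rows must match the wavelength grid")
        if (self.counts < 0).any():
            raise ValueError("photon counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[1]

    def times_s(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.rate_hz


@dataclass
class ReferenceSpectra:
    """Unit-norm emission profiles of the fluorophores on a wavelength grid."""

    wavelengths_nm: np.ndarray
    spectra: np.ndarray         # (n_wavelengths, n_fluorophores)
    names: tuple = ("GCaMP", "tdTomato")

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        if (self.spectra < 0).any():
            raise ValueError("reference spectra must be non-negative")
        norms = np.linalg.norm(self.spectra, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("each reference spectrum must have unit norm")


@dataclass
class TransientParams:
    """Detection parameters for significant calcium events."""

    mad_multiplier: float = 2.91
    min_width_s: float = 0.5
    max_width_s: float = 10.0
    min_separation_s: float = 1.0
    feature_window_s: float = 1.6

    def __post_init__(self) -> None:
        if not 0 < self.min_width_s < self.max_width_s:
            raise ValueError("need 0 < min_width < max_width")
        if self.mad_multiplier <= 0:
            raise ValueError("mad_multiplier must be positive")


@dataclass
class TransientEvent:
    peak_time_s: float
    magnitude: float      # prominence above local baseline, signal units
    half_width_s: float


def band_summed_signal(spec_ts: SpectralTimeseries, band_nm) -> np.ndarray:
    """Per-frame sum of photon counts over a closed wavelength band."""
    lo, hi = band_nm
    sel = (spec_ts.wavelengths_nm >= lo) & (spec_ts.wavelengths_nm <= hi)
    if not sel.any():
        raise ValueError(f"band {band_nm} contains no grid wavelengths")
    return spec_ts.counts[sel].sum(axis=0)


def linear_unmix(spec_ts: SpectralTimeseries, refs: ReferenceSpectra,
                 background: bool = True, nonnegative: bool = False):
    """Per-frame least-squares unmixing against the reference spectra.

    Solves counts[:, t] ~ A @ c_t for every frame, where A stacks the
    reference spectra (plus a constant background column by default).
    Returns (coefficients DataFrame with one column per fluorophore,
    residual norm per frame).
    """
    if not np.array_equal(refs.wavelengths_nm, spec_ts.wavelengths_nm):
        raise ValueError("references must be on the spectrum's grid")
    A = refs.spectra
    if background:
        A = np.column_stack([A, np.ones(A.shape[0])])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("reference matrix is rank deficient")
    if nonnegative:
        from scipy.optimize import nnls
        coef = np.empty((A.shape[1], spec_ts.n_frames))
        for t in range(spec_ts.n_frames):
            coef[:, t], _ = nnls(A, spec_ts.counts[:, t])
    else:
        coef, *_ = np.linalg.lstsq(A, spec_ts.counts, rcond=None)
    resid = np.linalg.norm(spec_ts.counts - A @ coef, axis=0)
    cols = list(refs.names) + (["background"] if background else [])
    return pd.DataFrame(coef.T, columns=cols), resid


def detrend_linear(ts) -> np.ndarray:
    """Remove the OLS-fitted line, keeping the record mean.

    Corrects slow signal fading (photobleaching) while preserving the
    absolute scale needed by dF/F and ratio computations.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.size < 2:
        raise ValueError("need at least 2 samples to detrend")
    x = np.arange(ts.size, dtype=float)
    slope, intercept = np.polyfit(x, ts, 1)
    return ts - (slope * x + intercept) + ts.mean()


def downsample_mean(ts, from_hz: float, to_hz: float) -> np.ndarray:
    """Non-overlapping block means (anti-aliasing by averaging).

    A trailing incomplete block is dropped.
    """
    ratio = from_hz / to_hz
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError("from_hz must be an integer multiple of to_hz")
    r = int(round(ratio))
    ts = np.asarray(ts, dtype=float)
    n = (ts.size // r) * r
    return ts[:n].reshape(-1, r).mean(axis=1)


def dff_per_trial(ts, rate_hz: float, trial_start_s: float,
                  pre_window_s: float = 10.0,
                  trial_len_s: float = 30.0) -> np.ndarray:
    """%dF/F over one trial, baselined on the pre-stimulation period.

    The trial spans ``trial_len_s`` from ``trial_start_s``; the baseline F0
    is the mean over the first ``pre_window_s`` of the trial (stimulation
    occurs after that point).
    """
    ts = np.asarray(ts, dtype=float)
    i0 = int(round(trial_start_s * rate_hz))
    n = int(round(trial_len_s * rate_hz))
    npre = int(round(pre_window_s * rate_hz))
    if i0 < 0 or i0 + n > ts.size:
        raise ValueError("trial window exceeds the record")
    trial = ts[i0:i0 + n]
    f0 = trial[:npre].mean()
    if f0 <= 0:
        raise ValueError("non-positive baseline; cannot form dF/F")
    return 100.0 * (trial - f0) / f0


def peak_response(dff, rate_hz: float, window_s=(10.0, 15.0)) -> float:
    """Maximum of a trial trace inside a window (seconds from trial start)."""
    dff = np.asarray(dff, dtype=float)
    i0 = int(round(window_s[0] * rate_hz))
    i1 = int(round(window_s[1] * rate_hz))
    if i0 >= i1 or i1 > dff.size:
        raise ValueError("empty or out-of-range response window")
    return float(dff[i0:i1].max())


def ratio_zscore_trials(gcamp_coeff, tdt_coeff, trial_bounds,
                        denom_floor: float = 1e-9):
    """Green/red ratio, z-scored per trial.

    ``trial_bounds`` is a sequence of (start, stop) sample indices. Any
    strictly positive artifact that multiplies both channels equally cancels
    in the ratio. Trials whose red channel touches the floor or whose ratio
    has zero variance are excluded (returned as None) with a warning.

    Returns (list of per-trial z arrays, list of excluded trial indices).
    """
    g = np.asarray(gcamp_coeff, dtype=float)
    t = np.asarray(tdt_coeff, dtype=float)
    if g.shape != t.shape:
        raise ValueError("channel lengths differ")
    zs, excluded = [], []
    for k, (i0, i1) in enumerate(trial_bounds):
        tt = t[i0:i1]
        if tt.size == 0 or np.min(np.abs(tt)) <= denom_floor:
            warnings.warn(f"trial {k}: red channel too close to zero; excluded")
            zs.append(None)
            excluded.append(k)
            continue
        ratio = g[i0:i1] / tt
        sd = ratio.std()
        if sd == 0:
            warnings.warn(f"trial {k}: zero-variance ratio; excluded")
            zs.append(None)
            excluded.append(k)
            continue
        zs.append((ratio - ratio.mean()) / sd)
    return zs, excluded


def mad(x) -> float:
    """Unscaled median absolute deviation (no Gaussian consistency factor;
    the 2.91 default multiplier already embeds it)."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def detect_transients(ts, rate_hz: float,
                      params: TransientParams | None = None) -> list:
    """Detect significant calcium transients.

    A transient is a local maximum whose prominence (measured within
    ``feature_window_s``) exceeds ``mad_multiplier * MAD`` of the analysed
    trace. Peaks closer than the minimum separation are resolved in favour
    of the larger. The event magnitude is the peak height above the trace
    median (the baseline), and the half-width is the full width at half that
    magnitude; events with half-widths outside [min_width, max_width] are
    rejected. Baseline-relative half-max width (rather than the
    half-prominence width of a generic peak finder) is the standard
    half-width definition for calcium events and rejects narrow noise peaks
    that happen to clear the amplitude threshold.
    """
    if params is None:
        params = TransientParams()
    ts = np.asarray(ts, dtype=float)
    if ts.size <= params.feature_window_s * rate_hz:
        raise ValueError("record shorter than the feature window")
    threshold = params.mad_multiplier * mad(ts)
    if threshold == 0:
        return []
    med = float(np.median(ts))
    wlen = max(2, int(round(params.feature_window_s * rate_hz)))
    peaks, _ = find_peaks(
        ts,
        prominence=threshold,
        distance=max(1, int(round(params.min_separation_s * rate_hz))),
        wlen=wlen,
    )
    events = []
    for p in peaks:
        magnitude = ts[p] - med
        width = _fwhm(ts, p, med + 0.5 * magnitude) / rate_hz
        if params.min_width_s <= width <= params.max_width_s:
            events.append(TransientEvent(
                peak_time_s=float(p / rate_hz),
                magnitude=float(magnitude),
                half_width_s=float(width),
            ))
    return events


def _fwhm(ts, peak, level) -> float:
    """Full width (samples) of the peak at ``level``, with linear
    interpolation at the crossings; clipped at the record edges."""
    i = peak
    while i > 0 and ts[i] > level:
        i -= 1
    if ts[i] <= level and ts[i + 1] != ts[i]:
        left = i + (level - ts[i]) / (ts[i + 1] - ts[i])
    else:
        left = float(i)
    j = peak
    n = ts.size
    while j < n - 1 and ts[j] > level:
        j += 1
    if ts[j] <= level and ts[j - 1] != ts[j]:
        right = j - (level - ts[j]) / (ts[j - 1] - ts[j])
    else:
        right = float(j)
    return right - left


def spontaneous_stats(ts, rate_hz: float, bin_len_s: float = 150.0,
                      params: TransientParams | None = None,
                      day1_reference: dict | None = None) -> dict:
    """Bin-averaged transient statistics over a baseline record.

    The record is split into consecutive ``bin_len_s`` bins (a 10-minute
    baseline gives four 2.5-minute bins); transients are detected per bin
    and their magnitude, frequency (events/s) and half-width averaged over
    bins. When a first-day reference is supplied the metrics are returned
    as ratios to it.
    """
    ts = np.asarray(ts, dtype=float)
    bin_n = int(round(bin_len_s * rate_hz))
    n_bins = ts.size // bin_n
    if n_bins < 4:
        raise ValueError("record must contain at least four full bins")
    mags, freqs, widths = [], [], []
    for b in range(n_bins):
        events = detect_transients(ts[b * bin_n:(b + 1) * bin_n], rate_hz,
                                   params)
        freqs.append(len(events) / bin_len_s)
        if events:
            mags.append(np.mean([e.magnitude for e in events]))
            widths.append(np.mean([e.half_width_s for e in events]))
    stats = {
        "magnitude": float(np.mean(mags)) if mags else np.nan,
        "frequency": float(np.mean(freqs)),
        "half_width": float(np.mean(widths)) if widths else np.nan,
    }
    if day1_reference is not None:
        for key in stats:
            ref = day1_reference[key]
            if ref == 0:
                raise ValueError(f"day-1 reference {key} is zero")
            stats[key] = stats[key] / ref
    return stats


def peri_event_average(z_ts, rate_hz: float, event_times_s,
                       window_s=(-5.0, 5.0),
                       normalize_unit_range: bool = False):
    """Average fixed windows around events.

    Event times are snapped to the nearest sample of the analysis grid.
    With ``normalize_unit_range`` each event window is affinely mapped to
    [-1, +1] before averaging. Events whose window exceeds the record are
    skipped with a warning. Returns (offsets_s, mean trace, n_used).
    """
    z = np.asarray(z_ts, dtype=float)
    i_lo = int(round(window_s[0] * rate_hz))
    i_hi = int(round(window_s[1] * rate_hz))
    offsets = np.arange(i_lo, i_hi) / rate_hz
    windows = []
    for et in np.atleast_1d(event_times_s):
        c = int(round(et * rate_hz))
        a, b = c + i_lo, c + i_hi
        if a < 0 or b > z.size:
            warnings.warn(f"event at {et:.2f}s: window exceeds record; skipped")
            continue
        w = z[a:b]
        if normalize_unit_range:
            lo, hi = w.min(), w.max()
            w = np.zeros_like(w) if hi == lo else 2 * (w - lo) / (hi - lo) - 1
        windows.append(w)
    if not windows:
        raise ValueError("no usable events")
    return offsets, np.mean(windows, axis=0), len(windows)


def distal_delay_score(z_ts, rate_hz: float, choice_start_times_s,
                       window_s: float = 2.0) -> np.ndarray:
    """Mean z-scored signal in the window preceding each Choice Start.

    The window is [choice_start - window_s, choice_start); trials whose
    window falls outside the record are flagged as NaN.
    """
    z = np.asarray(z_ts, dtype=float)
    n_win = int(round(window_s * rate_hz))
    out = np.empty(len(np.atleast_1d(choice_start_times_s)))
    for k, cs in enumerate(np.atleast_1d(choice_start_times_s)):
        c = int(round(cs * rate_hz))
        a = c - n_win
        if a < 0 or c > z.size:
            warnings.warn(f"trial {k}: distal-delay window outside record")
            out[k] = np.nan
        else:
            out[k] = z[a:c].mean()
    return out


def crosscorr_lagged(ca_ts, vel_ts, max_lag_samples: int = 50):
    """Pearson correlation of calcium vs velocity at integer lags.

    Positive lag means the calcium series *leads* velocity: r(L) correlates
    ca[t] with vel[t + L]. Returns (lags, r). Zero-variance overlap segments
    yield NaN.
    """
    ca = np.asarray(ca_ts, dtype=float)
    vel = np.asarray(vel_ts, dtype=float)
    if ca.shape != vel.shape:
        raise ValueError("series lengths differ")
    n = ca.size
    if n <= max_lag_samples:
        raise ValueError("series shorter than the maximum lag")
    lags = np.arange(-max_lag_samples, max_lag_samples + 1)
    r = np.empty(lags.size)
    for i, L in enumerate(lags):
        if L >= 0:
            a, b = ca[: n - L], vel[L:]
        else:
            a, b = ca[-L:], vel[: n + L]
        if a.std() == 0 or b.std() == 0:
            r[i] = np.nan
        else:
            r[i] = float(np.corrcoef(a, b)[0, 1])
    return lags, r


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the per-trial event table used by the behavioral analyses."""
    required = {"mouse_id", "trial_index", "training_fraction",
                "outcome"} | set(TRIAL_EVENT_COLUMNS)
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    ev = trials[list(TRIAL_EVENT_COLUMNS)].to_numpy()
    if (np.diff(ev, axis=1) < 0).any():
        raise ValueError("trial event timestamps must be ordered")
    tf = trials["training_fraction"]
    if tf.min() < 0 or tf.max() > 1:
        raise ValueError("training_fraction must lie in [0, 1]")
    return trials
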