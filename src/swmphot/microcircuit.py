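"""Leaky integrate-and-fire model of a prefrontal disinhibitory microcircuit.

The simulated circuit contains 36 neurons in four classes -- 4 VIP, 6 SST and
6 PV interneurons plus 20 pyramidal cells -- driven by an external
hippocampal (vHPC) afferent modelled as a stochastic event raster. VIP cells
implement the canonical disinhibitory motif (they inhibit mostly SST cells),
SST cells provide feedback inhibition and PV cells feedforward inhibition.

Membrane dynamics are discrete-time leaky integrators on a ``dt``-millisecond
grid::

    v_i(t) = v_i(t-1) * vdecay + dt * (synaptic + external input at t-1)

with ``vdecay = exp(-dt / tau_m)``. A neuron whose voltage reaches the spike
threshold emits a spike; its voltage is forced to the reset value on the
*next* step (inputs on that step are ignored) and normal integration resumes
afterwards. Class-level synaptic outputs are leaky accumulators of the
fraction of the class that spiked; pyramidal cells additionally carry
per-cell AMPA/NMDA outputs routed through a random connectivity matrix.

Population spike counts are converted to photometry-like activity traces by
Gaussian smoothing (sigma = 25 ms by default).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, oaconvolve

from ._engine import simulate_steps

CLASSES = ("VIP", "SST", "PV", "PYR")
SOURCES = ("vHPC", "VIP", "SST", "PV", "PYR")

#: synaptic-output channels carried by the network state, in storage order
OUT_CHANNELS = ("VIP", "SST", "PV", "PYR_AMPA", "PYR_NMDA")

_DEFAULT_W = np.array(
    [
        # targets:  VIP   SST   PV    PYR
        [1.6, 1.0, 1.6, 1.0],   # vHPC
        [0.0, 1.0, 0.05, 0.0],  # VIP
        [1.0, 0.0, 0.75, 0.75],  # SST
        [0.0, 0.0, 2.25, 2.0],  # PV
        [0.8, 8.0, 0.8, 0.25],  # PYR
    ]
)


def default_weight_matrix() -> pd.DataFrame:
    """Default synaptic weight table, sources (rows) x targets (columns).

    Weights are stored non-negative; inhibitory signs are applied by the
    update rule according to the source class.
    """
    return pd.DataFrame(_DEFAULT_W.copy(), index=list(SOURCES), columns=list(CLASSES))


@dataclass
class NetworkConfig:
    """All constants of the microcircuit model (units in field names)."""

    n_cells: dict = field(
        default_factory=lambda: {"VIP": 4, "SST": 6, "PV": 6, "PYR": 20}
    )
    weights: pd.DataFrame = field(default_factory=default_weight_matrix)
    tau_membrane_ms: float = 10.0
    tau_syn_ms: dict = field(
        default_factory=lambda: {
            "VIP": 20.0,
            "SST": 20.0,
            "PV": 20.0,
            "PYR_AMPA": 10.0,
            "PYR_NMDA": 80.0,
        }
    )
    nmda_scale: float = 0.3
    spike_threshold: float = 10.0
    reset_value: float = -10.0
    dt_ms: float = 0.1
    duration_s: float = 10.0
    stim_window_s: tuple = (2.0, 3.0)
    stim_rate_hz: float = 100.0
    post_stim_decay_tau_ms: float = 1000.0
    vhpc_event_kernel: dict = field(
        default_factory=lambda: {"tau_ms": 8.0, "length_steps": 40}
    )
    vhpc_nmda_kernel: dict = field(
        default_factory=lambda: {"tau_ms": 80.0, "length_steps": 400}
    )
    vhpc_noise_rate_hz: float = 100.0
    neuron_noise: dict = field(
        default_factory=lambda: {
            "rate_hz": 100.0,
            "amplitude": {"VIP": 1.0, "SST": 1.0, "PYR": 1.0, "PV": 1.2},
            "tau_ms": 8.0,
            "length_steps": 40,
        }
    )
    pyr_connection_prob: float = 0.2
    smoothing_sigma_ms: float = 25.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.dt_ms <= 0 or self.duration_s <= 0 or self.tau_membrane_ms <= 0:
            raise ValueError("dt, duration and membrane tau must be positive")
        for name, tau in self.tau_syn_ms.items():
            if tau <= 0:
                raise ValueError(f"tau_syn_ms[{name}] must be positive")
        lo, hi = self.stim_window_s
        if not (0 <= lo < hi <= self.duration_s):
            raise ValueError("stim window must lie inside [0, duration]")
        if not 0 <= self.pyr_connection_prob <= 1:
            raise ValueError("pyr_connection_prob must be in [0, 1]")
        W = np.asarray(self.weights, dtype=float)
        if W.shape != (5, 4):
            raise ValueError("weights must be a 5x4 (source x target) matrix")
        if (W < 0).any():
            raise ValueError("weights must be non-negative (signs are applied "
                             "by the update rule)")
        if not 0 < self.vdecay < 1:
            raise ValueError("exp(-dt/tau_m) must lie in (0, 1)")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_s * 1000.0 / self.dt_ms))

    @property
    def n_neurons(self) -> int:
        return sum(self.n_cells[c] for c in CLASSES)

    @property
    def vdecay(self) -> float:
        return float(np.exp(-self.dt_ms / self.tau_membrane_ms))

    def syndecay(self) -> np.ndarray:
        """exp(-dt/tau_syn) per output channel, in OUT_CHANNELS order."""
        return np.exp(
            -self.dt_ms / np.array([self.tau_syn_ms[c] for c in OUT_CHANNELS])
        )

    def class_index(self) -> np.ndarray:
        """Per-neuron class label (index into CLASSES), neurons ordered
        VIP block, SST block, PV block, PYR block."""
        return np.repeat(
            np.arange(4), [self.n_cells[c] for c in CLASSES]
        ).astype(np.int64)

    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    def step_times_s(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt_ms / 1000.0

    def config_hash(self) -> str:
        payload = repr(
            (
                sorted(self.n_cells.items()),
                np.asarray(self.weights).tolist(),
                self.tau_membrane_ms,
                sorted(self.tau_syn_ms.items()),
                self.nmda_scale,
                self.spike_threshold,
                self.reset_value,
                self.dt_ms,
                self.duration_s,
                tuple(self.stim_window_s),
                self.stim_rate_hz,
                self.post_stim_decay_tau_ms,
                sorted(self.vhpc_event_kernel.items()),
                sorted(self.vhpc_nmda_kernel.items()),
                self.vhpc_noise_rate_hz,
                repr(sorted(self.neuron_noise.items(), key=lambda kv: kv[0])),
                self.pyr_connection_prob,
                self.smoothing_sigma_ms,
            )
        ).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    def with_weight(self, source: str, target: str, value: float) -> "NetworkConfig":
        """Copy of the config with one synaptic weight replaced."""
        W = self.weights.copy()
        W.loc[source, target] = value
        return replace(self, weights=W)


@dataclass
class NetworkState:
    """Instantaneous state of the network between two update steps."""

    v: np.ndarray                  # (n_neurons,) membrane potentials
    out: np.ndarray                # (5,) class outputs, OUT_CHANNELS order
    out2_ampa: np.ndarray          # (n_pyr,) per-pyramidal AMPA outputs
    out2_nmda: np.ndarray          # (n_pyr,) per-pyramidal NMDA outputs
    spiked_last_step: np.ndarray   # (n_neurons,) bool

    @classmethod
    def zeros(cls, config: NetworkConfig) -> "NetworkState":
        n = config.n_neurons
        npyr = config.n_cells["PYR"]
        return cls(
            v=np.zeros(n),
            out=np.zeros(5),
            out2_ampa=np.zeros(npyr),
            out2_nmda=np.zeros(npyr),
            spiked_last_step=np.zeros(n, dtype=bool),
        )


@dataclass
class ExternalDrive:
    """Kernel-filtered external input signals on the step grid."""

    vhpc_ampa: np.ndarray         # (T,)
    vhpc_nmda: np.ndarray         # (T,)
    vhpc_noise: np.ndarray        # (T,)
    neuron_noise: np.ndarray      # (n_neurons, T)
    raw_event_raster: np.ndarray  # (T,) 0/1 stimulation events

    def per_neuron_input(self, config: NetworkConfig) -> np.ndarray:
        """Combined external input per neuron and step:
        w_vHPC,x * (AMPA + nmda_scale*NMDA + noise) + per-neuron noise."""
        W = config.weight_array()
        cls_idx = config.class_index()
        shared = (
            self.vhpc_ampa
            + config.nmda_scale * self.vhpc_nmda
            + self.vhpc_noise
        )
        return W[0, cls_idx][:, None] * shared[None, :] + self.neuron_noise


def build_pyr_connectivity(n: int, p: float, seed) -> np.ndarray:
    """Random binary connectivity among pyramidal cells.

    Off-diagonal entries are independent Bernoulli(p); self-connections are
    excluded (zero diagonal). ``M[i, j] = 1`` means cell i synapses onto j.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p <= 1:
        raise ValueError("connection probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    M = (rng.random((n, n)) < p).astype(np.float64)
    np.fill_diagonal(M, 0.0)
    return M


def vhpc_rate_profile(config: NetworkConfig) -> np.ndarray:
    """Stimulation event rate (Hz) at each step time.

    Zero before stimulation onset, the configured rate during the window,
    then an exponential decay (tau = post_stim_decay_tau_ms) afterwards.
    """
    t = config.step_times_s()
    lo, hi = config.stim_window_s
    rate = np.zeros_like(t)
    during = (t > lo) & (t <= hi)
    rate[during] = config.stim_rate_hz
    after = t > hi
    tau_s = config.post_stim_decay_tau_ms / 1000.0
    rate[after] = config.stim_rate_hz * np.exp(-(t[after] - hi) / tau_s)
    return rate


def _bernoulli_raster(rate_hz, dt_ms: float, rng, size=None) -> np.ndarray:
    p = np.asarray(rate_hz, dtype=float) * dt_ms / 1000.0
    if np.any(p > 1):
        raise ValueError("rate * dt exceeds 1 event/step; decrease dt "
                         "(undersampled event process)")
    u = rng.random(size if size is not None else np.shape(p))
    return (u < p).astype(np.float64)


def sample_vhpc_raster(config: NetworkConfig, seed) -> np.ndarray:
    """Sample the 0/1 vHPC stimulation event raster (at most one event/step).

    Per-step event probability is rate(t) * dt, with the rate profile of
    :func:`vhpc_rate_profile`.
    """
    rng = np.random.default_rng(seed)
    return _bernoulli_raster(vhpc_rate_profile(config), config.dt_ms, rng)


def exp_kernel_filter(raster, amplitude, tau_ms, length_steps, dt_ms) -> np.ndarray:
    """Causal convolution of an event raster with a truncated exponential.

    Kernel k[j] = amplitude * exp(-j*dt/tau) for j = 0..length_steps-1 and
    zero beyond; works on 1-D rasters or (n_signals, T) stacks.
    """
    if tau_ms <= 0 or dt_ms <= 0:
        raise ValueError("tau and dt must be positive")
    if length_steps < 1:
        raise ValueError("length_steps must be >= 1")
    raster = np.asarray(raster, dtype=float)
    j = np.arange(length_steps)
    kernel = amplitude * np.exp(-j * dt_ms / tau_ms)
    if raster.ndim == 1:
        return np.convolve(raster, kernel)[: raster.shape[0]]
    out = oaconvolve(raster, kernel[None, :], axes=1)
    return out[:, : raster.shape[1]]


def _as_seedseq(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)


def make_external_drive(config: NetworkConfig, seed) -> ExternalDrive:
    """Sample all external-input rasters and filter them with their kernels."""
    ss = _as_seedseq(seed)
    rng_stim, rng_vnoise, rng_nnoise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    T = config.n_steps
    raster = _bernoulli_raster(vhpc_rate_profile(config), config.dt_ms, rng_stim)
    ek = config.vhpc_event_kernel
    nk = config.vhpc_nmda_kernel
    ampa = exp_kernel_filter(raster, 1.0, ek["tau_ms"], ek["length_steps"],
                             config.dt_ms)
    nmda = exp_kernel_filter(raster, 1.0, nk["tau_ms"], nk["length_steps"],
                             config.dt_ms)
    vnoise_raster = _bernoulli_raster(
        np.full(T, config.vhpc_noise_rate_hz), config.dt_ms, rng_vnoise
    )
    vnoise = exp_kernel_filter(vnoise_raster, 1.0, ek["tau_ms"],
                               ek["length_steps"], config.dt_ms)
    nn = config.neuron_noise
    n = config.n_neurons
    nn_raster = _bernoulli_raster(
        np.full((n, T), nn["rate_hz"]), config.dt_ms, rng_nnoise
    )
    amp = np.array([nn["amplitude"][CLASSES[c]] for c in config.class_index()])
    nnoise = exp_kernel_filter(nn_raster, 1.0, nn["tau_ms"], nn["length_steps"],
                               config.dt_ms) * amp[:, None]
    return ExternalDrive(
        vhpc_ampa=ampa,
        vhpc_nmda=nmda,
        vhpc_noise=vnoise,
        neuron_noise=nnoise,
        raw_event_raster=raster,
    )


def step_network(state: NetworkState, ext_input: np.ndarray,
                 config: NetworkConfig, pyr_connectivity: np.ndarray):
    """Advance the network one step.

    ``ext_input`` is the per-neuron external input (vHPC terms plus
    per-neuron noise) evaluated at the *previous* step, consistent with the
    update equation using t-1 quantities. Returns the new state and the
    boolean spike vector for this step.
    """
    W = config.weight_array()
    cls_idx = config.class_index()
    n_pyr = config.n_cells["PYR"]
    pyr_start = config.n_neurons - n_pyr
    dt = config.dt_ms
    g = config.nmda_scale

    inhib = -(W[1, cls_idx] * state.out[0]
              + W[2, cls_idx] * state.out[1]
              + W[3, cls_idx] * state.out[2])
    exc = np.empty(config.n_neurons)
    # interneurons read the class-level pyramidal outputs
    inter = cls_idx < 3
    exc[inter] = W[4, cls_idx[inter]] * (state.out[3] + g * state.out[4])
    # pyramidal cells read per-cell outputs routed through the connectivity
    rec = pyr_connectivity.T @ (state.out2_ampa + g * state.out2_nmda)
    exc[pyr_start:] = W[4, 3] * rec

    v_new = state.v * config.vdecay + dt * (inhib + exc + ext_input)
    v_new[state.spiked_last_step] = config.reset_value

    spiked = v_new >= config.spike_threshold

    syndecay = config.syndecay()
    out_new = state.out * syndecay[:5]
    counts = np.bincount(cls_idx[spiked], minlength=4)
    sizes = np.array([config.n_cells[c] for c in CLASSES], dtype=float)
    P = counts / sizes
    out_new[0] += P[0]
    out_new[1] += P[1]
    out_new[2] += P[2]
    out_new[3] += P[3]
    out_new[4] += P[3]

    pyr_spiked = spiked[pyr_start:].astype(float)
    out2a = state.out2_ampa * syndecay[3] + pyr_spiked
    out2n = state.out2_nmda * syndecay[4] + pyr_spiked

    new_state = NetworkState(
        v=v_new, out=out_new, out2_ampa=out2a, out2_nmda=out2n,
        spiked_last_step=spiked,
    )
    return new_state, spiked


def gaussian_smooth(x: np.ndarray, sigma_steps: float) -> np.ndarray:
    """Smooth along the last axis with a truncated (+/-4 sigma) Gaussian,
    renormalizing the kernel mass at the edges."""
    x = np.asarray(x, dtype=float)
    half = int(np.ceil(4 * sigma_steps))
    j = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (j / sigma_steps) ** 2)
    k /= k.sum()
    if x.ndim == 1:
        num = fftconvolve(x, k, mode="same")
        den = fftconvolve(np.ones_like(x), k, mode="same")
    else:
        num = fftconvolve(x, k[None, :], mode="same", axes=-1)
        den = fftconvolve(np.ones((1, x.shape[-1])), k[None, :], mode="same",
                          axes=-1)
    return num / den


@dataclass
class SimulationOutput:
    """Per-class spike counts and smoothed activity traces from one run
    (or a multi-run average)."""

    time_s: np.ndarray
    spike_counts: np.ndarray      # (4, T) summed over neurons per step
    activity: np.ndarray          # (4, T) Gaussian-smoothed counts
    classes: tuple = CLASSES
    config_hash: str = ""
    seed: int | None = None
    neuron_spike_totals: np.ndarray | None = None

    def activity_for(self, cls: str) -> np.ndarray:
        return self.activity[self.classes.index(cls)]

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for i, c in enumerate(self.classes):
            frames.append(pd.DataFrame({
                "time_s": self.time_s,
                "class": c,
                "spike_count": self.spike_counts[i],
                "activity": self.activity[i],
            }))
        return pd.concat(frames, ignore_index=True)


def run_simulation(config: NetworkConfig, seed, *, record_voltage: bool = False,
                   pyr_connectivity: np.ndarray | None = None):
    """Run one full simulation from a zero initial state.

    The master seed is split into independent streams for the pyramidal
    connectivity draw and each external-input raster, so the run is fully
    reproducible from (config, seed).
    """
    ss = _as_seedseq(seed)
    conn_seed, drive_seed = ss.spawn(2)
    if pyr_connectivity is None:
        pyr_connectivity = build_pyr_connectivity(
            config.n_cells["PYR"], config.pyr_connection_prob, conn_seed
        )
    drive = make_external_drive(config, drive_seed)
    ext = drive.per_neuron_input(config)

    spike_counts, neuron_totals, v_trace = simulate_steps(
        ext,
        config.class_index(),
        config.weight_array(),
        config.vdecay,
        config.syndecay(),
        config.dt_ms,
        config.spike_threshold,
        config.reset_value,
        pyr_connectivity,
        np.array([config.n_cells[c] for c in CLASSES], dtype=np.int64),
        config.nmda_scale,
        record_voltage,
    )
    if not np.isfinite(v_trace).all():
        raise FloatingPointError("non-finite membrane potential encountered")

    sigma_steps = config.smoothing_sigma_ms / config.dt_ms
    activity = gaussian_smooth(spike_counts.astype(float), sigma_steps)
    out = SimulationOutput(
        time_s=config.step_times_s(),
        spike_counts=spike_counts,
        activity=activity,
        config_hash=config.config_hash(),
        seed=seed if np.isscalar(seed) else None,
        neuron_spike_totals=neuron_totals,
    )
    if record_voltage:
        return out, v_trace
    return out


def simulate_condition(config: NetworkConfig, n_runs: int = 5,
                       seeds: Sequence | None = None,
                       seed=None) -> SimulationOutput:
    """Average the smoothed activity traces of ``n_runs`` independent runs.

    This is the model's final photometry-like readout: single runs are
    noisy event-driven realizations; their element-wise mean is reported.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seeds is None:
        seeds = _as_seedseq(seed).spawn(n_runs)
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")
    runs = [run_simulation(config, s) for s in seeds]
    T = runs[0].activity.shape[1]
    if any(r.activity.shape[1] != T for r in runs):
        raise RuntimeError("mismatched trace lengths across runs")
    activity = np.mean([r.activity for r in runs], axis=0)
    counts = np.mean([r.spike_counts for r in runs], axis=0)
    return SimulationOutput(
        time_s=runs[0].time_s,
        spike_counts=counts,
        activity=activity,
        config_hash=config.config_hash(),
    )


def evoked_peak(trace: np.ndarray, time_s: np.ndarray,
                baseline_window=(0.1, 2.0),
                response_window=(2.0, 10.0)) -> float:
    """Peak of the baseline-subtracted trace inside the response window.

    Baseline is the mean of the trace over ``baseline_window``.
    """
    time_s = np.asarray(time_s)
    base = (time_s >= baseline_window[0]) & (time_s <= baseline_window[1])
    resp = (time_s >= response_window[0]) & (time_s <= response_window[1])
    if not base.any() or not resp.any():
        raise ValueError("empty baseline or response window")
    trace = np.asarray(trace, dtype=float)
    return float(np.max(trace[resp] - trace[base].mean()))


class MicrocircuitModel:
    """Model object wrapping a :class:`NetworkConfig`.

    ``simulate`` runs a single realization; ``simulate_condition`` returns
    the 5-run-average readout used for downstream summaries.
    """

    def __init__(self, config: NetworkConfig | None = None):
        self.config = config if config is not None else NetworkConfig()

    def simulate(self, seed=None) -> SimulationOutput:
        return run_simulation(self.config, seed)

    def simulate_condition(self, n_runs: int = 5, seed=None) -> SimulationOutput:
        return simulate_condition(self.config, n_runs=n_runs, seed=seed)

    def evoked_peaks(self, output: SimulationOutput,
                     baseline_window=(0.1, 2.0),
                     response_window=None) -> dict:
        """Baseline-subtracted peak activity per cell class."""
        if response_window is None:
            response_window = (self.config.stim_window_s[0],
                               self.config.duration_s)
        return {
            c: evoked_peak(output.activity[i], output.time_s,
                           baseline_window, response_window)
            for i, c in enumerate(CLASSES)
        }
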