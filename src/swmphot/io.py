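"""File formats: YAML configs, tidy CSVs and HDF5 spectral containers."""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .microcircuit import CLASSES, SOURCES, NetworkConfig, SimulationOutput
from .photometry import SpectralTimeseries, validate_trial_table


def save_network_config(config: NetworkConfig, path) -> None:
    d = {
        "n_cells": dict(config.n_cells),
        "weights": {s: {t: float(config.weights.loc[s, t]) for t in CLASSES}
                    for s in SOURCES},
        "tau_membrane_ms": config.tau_membrane_ms,
        "tau_syn_ms": dict(config.tau_syn_ms),
        "nmda_scale": config.nmda_scale,
        "spike_threshold": config.spike_threshold,
        "reset_value": config.reset_value,
        "dt_ms": config.dt_ms,
        "duration_s": config.duration_s,
        "stim_window_s": list(config.stim_window_s),
        "stim_rate_hz": config.stim_rate_hz,
        "post_stim_decay_tau_ms": config.post_stim_decay_tau_ms,
        "vhpc_event_kernel": dict(config.vhpc_event_kernel),
        "vhpc_nmda_kernel": dict(config.vhpc_nmda_kernel),
        "vhpc_noise_rate_hz": config.vhpc_noise_rate_hz,
        "neuron_noise": {k: (dict(v) if isinstance(v, dict) else v)
                         for k, v in config.neuron_noise.items()},
        "pyr_connection_prob": config.pyr_connection_prob,
        "smoothing_sigma_ms": config.smoothing_sigma_ms,
        "rng_seed": config.rng_seed,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_network_config(path) -> NetworkConfig:
    d = yaml.safe_load(Path(path).read_text())
    cfg = NetworkConfig()
    updates = {}
    if "weights" in d:
        W = cfg.weights.copy()
        for s, row in d.pop("weights").items():
            for t, w in row.items():
                W.loc[s, t] = float(w)
        updates["weights"] = W
    for key, val in d.items():
        updates[key] = tuple(val) if isinstance(val, list) else val
    cfg = replace(cfg, **updates)
    cfg.validate()
    return cfg


def save_simulation_csv(output: SimulationOutput, path) -> None:
    output.to_dataframe().to_csv(path, index=False)


def save_spectral_h5(spec: SpectralTimeseries, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("wavelengths", data=spec.wavelengths_nm)
        f.create_dataset("counts", data=spec.counts, compression="gzip")
        f.attrs["rate_hz"] = spec.rate_hz
        f.attrs["t0"] = spec.t0


def load_spectral_h5(path) -> SpectralTimeseries:
    with h5py.File(path, "r") as f:
        return SpectralTimeseries(
            wavelengths_nm=f["wavelengths"][:],
            counts=f["counts"][:],
            rate_hz=float(f.attrs["rate_hz"]),
            t0=float(f.attrs.get("t0", 0.0)),
        )


def save_spectral_csv(spec: SpectralTimeseries, path) -> None:
    """CSV fallback: wavelengths as the first column, frames as columns."""
    df = pd.DataFrame(spec.counts,
                      index=pd.Index(spec.wavelengths_nm, name="wavelength_nm"))
    df.columns = spec.times_s()
    df.to_csv(path)


def load_spectral_csv(path, rate_hz: float) -> SpectralTimeseries:
    df = pd.read_csv(path, index_col=0)
    return SpectralTimeseries(
        wavelengths_nm=df.index.to_numpy(dtype=float),
        counts=df.to_numpy(dtype=float),
        rate_hz=rate_hz,
    )


def load_trial_table(path) -> pd.DataFrame:
    return validate_trial_table(pd.read_csv(path))


def save_transients_csv(events, path) -> None:
    pd.DataFrame([e.__dict__ for e in events]).to_csv(path, index=False)


def save_functional_fit(fit, out_dir) -> None:
    """Per-term coefficient CSVs plus an intervals CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    interval_rows = []
    for term in fit.terms:
        safe = term.replace(":", "_x_")
        fit.to_frame(term).to_csv(out / f"beta_{safe}.csv", index=False)
        for iv in fit.significant_intervals(term):
            interval_rows.append({"term": term, **iv})
    pd.DataFrame(interval_rows,
                 columns=["term", "start_s", "end_s", "sign"]
                 ).to_csv(out / "significant_intervals.csv", index=False)
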