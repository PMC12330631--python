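"""Weight-sweep experiment: graded weakening of the vHPC -> VIP synapse.

The experiment asks how stimulation-evoked activity of each cell class
changes as the hippocampal drive onto VIP interneurons is reduced from its
baseline value. For each weight value a number of independent simulations
are run (each itself a 5-run average), evoked peaks are extracted per class,
and mean +/- SEM across simulations is reported. The expected circuit logic:
weaker vHPC->VIP drive releases SST cells from disinhibition, and the extra
SST inhibition suppresses PV and pyramidal responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .microcircuit import (CLASSES, NetworkConfig, evoked_peak,
                           simulate_condition)

#: directions of the expected rank correlation between the vHPC->VIP weight
#: and evoked peak activity, per cell class
EXPECTED_DIRECTIONS = {"VIP": 1, "SST": -1, "PV": 1, "PYR": 1}


@dataclass
class SweepConfig:
    weight_values: tuple = (1.6, 1.45, 1.3, 1.15, 1.0, 0.85)
    n_sims_per_weight: int = 10
    runs_per_sim: int = 5
    base_config: NetworkConfig = field(default_factory=NetworkConfig)
    seed: int = 0

    def validate(self) -> None:
        w0 = float(self.base_config.weights.loc["vHPC", "VIP"])
        if any(w < 0 or w > w0 + 1e-12 for w in self.weight_values):
            raise ValueError("weight values must lie in [0, baseline weight]")
        if self.n_sims_per_weight < 2:
            raise ValueError("need >= 2 simulations per weight for a SEM")


@dataclass
class SweepResult:
    """Per-(weight, class) evoked peaks with summary statistics."""

    peaks: pd.DataFrame    # columns: weight, class, sim, peak
    config_hash: str
    seed: int

    def summary(self) -> pd.DataFrame:
        """Mean and SEM of the evoked peak per (weight, class)."""
        g = self.peaks.groupby(["weight", "class"])["peak"]
        out = g.agg(mean="mean", sd="std", n="count").reset_index()
        out["sem"] = out["sd"] / np.sqrt(out["n"])
        return out[["weight", "class", "mean", "sem", "n"]]


def run_weight_sweep(sweep_config: SweepConfig) -> SweepResult:
    """Run the full sweep, deterministic under the master seed.

    Seeds are derived per (weight index, simulation index) from the master
    seed so every simulation is independent and reproducible.
    """
    sweep_config.validate()
    ss = np.random.SeedSequence(sweep_config.seed)
    rows = []
    for wi, w in enumerate(sweep_config.weight_values):
        cfg = sweep_config.base_config.with_weight("vHPC", "VIP", float(w))
        for si in range(sweep_config.n_sims_per_weight):
            sim_seed = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(wi, si)
            )
            run_seeds = sim_seed.spawn(sweep_config.runs_per_sim)
            out = simulate_condition(cfg, n_runs=sweep_config.runs_per_sim,
                                     seeds=run_seeds)
            for ci, c in enumerate(CLASSES):
                peak = evoked_peak(
                    out.activity[ci], out.time_s,
                    baseline_window=(0.1, cfg.stim_window_s[0]),
                    response_window=(cfg.stim_window_s[0], cfg.duration_s),
                )
                rows.append({"weight": float(w), "class": c, "sim": si,
                             "peak": peak})
    peaks = pd.DataFrame(rows)
    return SweepResult(peaks=peaks,
                       config_hash=sweep_config.base_config.config_hash(),
                       seed=sweep_config.seed)


def monotonicity_summary(result: SweepResult) -> pd.DataFrame:
    """Spearman rank correlation of mean evoked peak with weight, per class.

    ``consistent`` is True when the correlation sign matches the direction
    expected from the disinhibitory circuit logic (VIP/PV/PYR positive,
    SST negative); it is reported as None when the correlation is undefined
    (all peaks tied).
    """
    summ = result.summary()
    if summ["weight"].nunique() < 3:
        raise ValueError("need >= 3 weight values for a rank correlation")
    rows = []
    for c in CLASSES:
        sub = summ[summ["class"] == c].sort_values("weight")
        if sub["mean"].nunique() == 1:
            rho, consistent, direction = np.nan, None, 0
        else:
            rho = float(spearmanr(sub["weight"], sub["mean"]).statistic)
            direction = int(np.sign(rho))
            consistent = direction == EXPECTED_DIRECTIONS[c]
        rows.append({"class": c, "rho": rho, "direction": direction,
                     "consistent": consistent})
    return pd.DataFrame(rows)


class WeightSweepExperiment:
    """Experiment object: configure once, ``run()`` to get a SweepResult."""

    def __init__(self, config: SweepConfig | None = None, **overrides):
        base = config if config is not None else SweepConfig()
        if overrides:
            base = SweepConfig(**{**base.__dict__, **overrides})
        self.config = base

    def run(self) -> SweepResult:
        return run_weight_sweep(self.config)
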