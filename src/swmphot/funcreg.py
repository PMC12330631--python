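"""Functional regression of trial-level calcium signals.

Trial-level z-scored photometry traces are modelled pointwise: at every
peri-event timepoint ``t`` the trial signals are regressed on trial- and
mouse-level covariates, giving coefficient *functions* beta_k(t). Five model
specifications are supported::

    1  signal ~ stim                          (mouse random intercept)
    2  signal ~ outcome                       (random intercept + outcome slope)
    3  signal ~ training * outcome            (random intercept + outcome slope)
    4  signal ~ training * stim               (mouse random intercept)
    5  signal ~ training * genotype           (mouse random intercept)

Training is a continuous covariate in [0, 1] (first to last trial of each
mouse); outcome / stim / genotype are 0/1 indicators (0 = correct, control
or wildtype).

Point estimates are per-timepoint least squares on the pooled trials; all
uncertainty -- including between-mouse heterogeneity that a likelihood-based
mixed model would assign to random effects -- is captured by a mouse-level
bootstrap (wild cluster bootstrap by default; pairs resampling available).
Because cohorts have few mice, bands are calibrated with the bootstrap-t
(percentile-t) method: replicate deviations are studentized by cluster-robust
standard errors. Pointwise 95% bands use per-timepoint quantiles of |t|;
simultaneous (joint) 95% bands use the distribution of the maximum |t| across
time (studentized by the trace-pooled standard error), so the joint band
contains the pointwise band everywhere and controls the family-wise error
over the whole trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: model id -> (fixed-effect terms beyond the intercept, random-effect label)
MODEL_SPECS = {
    1: (("stim",), "intercept"),
    2: (("outcome",), "intercept+outcome_slope"),
    3: (("training", "outcome", "training:outcome"), "intercept+outcome_slope"),
    4: (("training", "stim", "training:stim"), "intercept"),
    5: (("training", "genotype", "training:genotype"), "intercept"),
}

_BINARY = ("outcome", "stim", "genotype")


@dataclass
class ModelSpec:
    model_id: int
    terms: tuple = ()
    random_effects: str = "intercept"

    @classmethod
    def from_id(cls, model_id: int) -> "ModelSpec":
        if model_id not in MODEL_SPECS:
            raise ValueError(f"unknown model id {model_id}; use 1-5")
        terms, re = MODEL_SPECS[model_id]
        return cls(model_id=model_id, terms=terms, random_effects=re)


@dataclass
class FunctionalDataset:
    """Trials x timepoints signal matrix with per-trial covariates."""

    Y: np.ndarray                  # (n_trials, n_timepoints)
    covariates: pd.DataFrame       # one row per trial
    cluster: np.ndarray            # mouse id per trial
    time_s: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.cluster = np.asarray(self.cluster)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.Y.shape[0] != len(self.covariates) or \
                self.Y.shape[0] != self.cluster.size:
            raise ValueError("trials mismatch between Y, covariates, cluster")
        if self.Y.shape[1] != self.time_s.size:
            raise ValueError("time grid does not match Y columns")
        if self.covariates.isna().any().any():
            raise ValueError("missing covariate values")
        if np.unique(self.cluster).size < 2:
            raise ValueError("need at least 2 clusters (mice)")
        for c in _BINARY:
            if c in self.covariates and \
                    not set(np.unique(self.covariates[c])) <= {0, 1}:
                raise ValueError(f"covariate {c} must be coded 0/1")

    @classmethod
    def from_long(cls, df: pd.DataFrame, value_col: str = "z",
                  time_col: str = "time_s", mouse_col: str = "mouse_id",
                  trial_col: str = "trial") -> "FunctionalDataset":
        """Build from a long-format table (one row per mouse/trial/timepoint)."""
        covar_cols = [c for c in df.columns
                      if c not in (value_col, time_col, mouse_col, trial_col)]
        wide = df.pivot_table(index=[mouse_col, trial_col], columns=time_col,
                              values=value_col, sort=True)
        meta = (df.drop_duplicates([mouse_col, trial_col])
                  .set_index([mouse_col, trial_col])
                  .loc[wide.index, covar_cols]
                  .reset_index())
        return cls(Y=wide.to_numpy(),
                   covariates=meta[covar_cols].reset_index(drop=True),
                   cluster=meta[mouse_col].to_numpy(),
                   time_s=wide.columns.to_numpy(dtype=float))

    def to_long(self, value_col: str = "z") -> pd.DataFrame:
        n, T = self.Y.shape
        df = pd.DataFrame({
            "mouse_id": np.repeat(self.cluster, T),
            "trial": np.repeat(np.arange(n), T),
            "time_s": np.tile(self.time_s, n),
            value_col: self.Y.ravel(),
        })
        for c in self.covariates.columns:
            df[c] = np.repeat(self.covariates[c].to_numpy(), T)
        return df


def compute_training_fraction(mouse_ids, trial_index) -> np.ndarray:
    """Rescale trial indices to [0, 1] within each mouse (0 = first trial,
    1 = last). Mice with a single trial are rejected."""
    mouse_ids = np.asarray(mouse_ids)
    trial_index = np.asarray(trial_index, dtype=float)
    out = np.empty_like(trial_index)
    for m in np.unique(mouse_ids):
        sel = mouse_ids == m
        lo, hi = trial_index[sel].min(), trial_index[sel].max()
        if hi == lo:
            raise ValueError(f"mouse {m} has a single trial; training "
                             "fraction undefined")
        out[sel] = (trial_index[sel] - lo) / (hi - lo)
    return out


def build_design(dataset: FunctionalDataset, spec: ModelSpec):
    """Design matrix (intercept first) and term names for a model spec."""
    n = dataset.Y.shape[0]
    cols = [np.ones(n)]
    names = ["intercept"]
    for term in spec.terms:
        parts = term.split(":")
        col = np.ones(n)
        for p in parts:
            if p not in dataset.covariates:
                raise ValueError(f"covariate '{p}' missing from dataset")
            col = col * dataset.covariates[p].to_numpy(dtype=float)
        cols.append(col)
        names.append(term)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design is rank deficient; collinear terms among "
                         f"{names}")
    return X, names


def fit_pointwise(dataset: FunctionalDataset, spec: ModelSpec) -> np.ndarray:
    """Per-timepoint least-squares fixed-effect estimates, (k, T)."""
    X, _ = build_design(dataset, spec)
    beta, *_ = np.linalg.lstsq(X, dataset.Y, rcond=None)
    return beta


def _resample_clusters(dataset: FunctionalDataset, rng):
    """Pairs cluster bootstrap draw: row indices plus a relabelled cluster id
    per row (a mouse drawn twice contributes two distinct clusters)."""
    ids = np.unique(dataset.cluster)
    draw = rng.choice(ids, size=ids.size, replace=True)
    blocks = [np.flatnonzero(dataset.cluster == m) for m in draw]
    rows = np.concatenate(blocks)
    labels = np.concatenate([np.full(b.size, i) for i, b in enumerate(blocks)])
    return rows, labels, draw


def _ols_and_cluster_se(X, Y, labels):
    """OLS estimates and CR1 cluster-robust standard errors.

    Returns (beta (k, T), se (k, T)). ``labels`` assigns each row to a
    cluster; the sandwich meat sums per-cluster score outer products and the
    small-G correction G/(G-1) is applied.
    """
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    E = Y - X @ beta                              # (N, T) residuals
    uniq, inv = np.unique(labels, return_inverse=True)
    G = uniq.size
    k, T = beta.shape
    var = np.zeros((k, T))
    XB = X @ XtX_inv                              # (N, k)
    for g in range(G):
        sel = inv == g
        a = XB[sel].T @ E[sel]                    # (k, T)
        var += a * a
    if G > 1:
        var *= G / (G - 1)
    return beta, np.sqrt(var)


@dataclass
class FunctionalFit:
    """Coefficient functions with pointwise and joint confidence bands."""

    time_s: np.ndarray
    terms: list
    beta: np.ndarray          # (k, T)
    pw_lo: np.ndarray
    pw_hi: np.ndarray
    joint_lo: np.ndarray
    joint_hi: np.ndarray
    boot: np.ndarray          # (n_boot, k, T)
    n_boot: int
    seed: object = None
    model_id: int | None = None

    def _ix(self, term: str) -> int:
        if term not in self.terms:
            raise ValueError(f"unknown term '{term}'; have {self.terms}")
        return self.terms.index(term)

    def to_frame(self, term: str) -> pd.DataFrame:
        i = self._ix(term)
        return pd.DataFrame({
            "time_s": self.time_s,
            "beta": self.beta[i],
            "pw_lo": self.pw_lo[i], "pw_hi": self.pw_hi[i],
            "joint_lo": self.joint_lo[i], "joint_hi": self.joint_hi[i],
        })

    def significant_intervals(self, term: str) -> list:
        """Maximal runs of timepoints whose joint 95% CI excludes zero.

        Returns a list of dicts with start/end times and the effect sign
        (+1 enhancement, -1 reduction).
        """
        i = self._ix(term)
        sign = np.zeros(self.time_s.size, dtype=int)
        sign[self.joint_lo[i] > 0] = 1
        sign[self.joint_hi[i] < 0] = -1
        intervals = []
        start = None
        for k in range(sign.size + 1):
            cur = sign[k] if k < sign.size else 0
            if start is not None and (k == sign.size or cur != sign[start]):
                intervals.append({
                    "start_s": float(self.time_s[start]),
                    "end_s": float(self.time_s[k - 1]),
                    "sign": int(sign[start]),
                })
                start = None
            if k < sign.size and cur != 0 and start is None:
                start = k
        return intervals

    def summary(self) -> pd.DataFrame:
        """One row per term: coefficient range and significant intervals."""
        rows = []
        for i, term in enumerate(self.terms):
            ints = self.significant_intervals(term)
            rows.append({
                "term": term,
                "beta_min": float(self.beta[i].min()),
                "beta_max": float(self.beta[i].max()),
                "n_significant_intervals": len(ints),
                "significant_time_s": sum(
                    iv["end_s"] - iv["start_s"] for iv in ints),
            })
        return pd.DataFrame(rows)

    def plot(self, term: str, ax=None):
        """Coefficient function with pointwise (dark) and joint (light) bands."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        df = self.to_frame(term)
        ax.fill_between(df.time_s, df.joint_lo, df.joint_hi, alpha=0.2,
                        label="joint 95% CI")
        ax.fill_between(df.time_s, df.pw_lo, df.pw_hi, alpha=0.4,
                        label="pointwise 95% CI")
        ax.plot(df.time_s, df.beta, color="k")
        ax.axhline(0, color="gray", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel(f"beta[{term}](t)")
        ax.legend()
        return ax


def cluster_bootstrap_ci(dataset: FunctionalDataset, spec: ModelSpec,
                         n_boot: int = 1000, seed=None,
                         interval: str = "percentile-t",
                         resample: str = "wild",
                         max_retries: int = 100) -> FunctionalFit:
    """Mouse-level bootstrap confidence bands around the pointwise fit.

    ``resample`` selects the cluster resampling scheme:

    - ``"wild"`` (default): wild cluster bootstrap. The design is held
      fixed and each replicate flips the sign of every mouse's residual
      block with probability 1/2 (Rademacher weights). With few mice and
      mouse-level covariates this avoids the pathological replicates that
      pairs resampling produces when a group ends up nearly empty.
    - ``"pairs"``: mice are resampled with replacement and the model refit
      on the resampled trials; replicates with fewer than two distinct mice
      or a rank-deficient design are redrawn (bounded retries).

    ``interval`` selects the band construction:

    - ``"percentile-t"`` (default): symmetric bootstrap-t. Each replicate's
      deviation from the full-sample estimate is studentized by its own
      cluster-robust standard error; the pointwise band is
      ``beta +/- q(0.95 of |t|) * se`` per timepoint and the joint band
      uses the 95th percentile of the maximum |t| over time, so the joint
      band contains the pointwise band by construction. With a small number
      of mice this calibration is markedly more accurate than raw
      percentiles (the few-cluster problem).
    - ``"percentile"``: plain per-timepoint 2.5/97.5% replicate quantiles
      for the pointwise band and the max studentized deviation for the
      joint band.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable 95% quantiles")
    if interval not in ("percentile-t", "percentile"):
        raise ValueError("interval must be 'percentile-t' or 'percentile'")
    if resample not in ("wild", "pairs"):
        raise ValueError("resample must be 'wild' or 'pairs'")
    X, names = build_design(dataset, spec)
    beta, se_hat = _ols_and_cluster_se(X, dataset.Y, dataset.cluster)
    k, T = beta.shape

    # pooled variance for the joint (max) statistic: the per-timepoint se is
    # a noisy estimate from few clusters, and that noise fattens the tail of
    # the max statistic; the joint band therefore studentizes by the
    # trace-RMS standard error per term. The bootstrap replicates are pooled
    # identically, so the band stays calibrated (its family-wise error is
    # checked against the nominal level in the test suite).
    def _pool_var(se):
        return np.sqrt((se ** 2).mean(axis=1, keepdims=True)) \
            * np.ones_like(se)

    se_joint = _pool_var(se_hat)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, k, T))
    tstat = np.empty((n_boot, k, T))
    tmax = np.empty((n_boot, k))
    if resample == "wild":
        fitted = X @ beta
        resid = dataset.Y - fitted
        ids = np.unique(dataset.cluster)
        row_cluster = np.searchsorted(ids, dataset.cluster)
        for b in range(n_boot):
            w = rng.choice([-1.0, 1.0], size=ids.size)[row_cluster]
            Yb = fitted + resid * w[:, None]
            bb, sb = _ols_and_cluster_se(X, Yb, dataset.cluster)
            boot[b] = bb
            dv = bb - beta
            tstat[b] = dv / np.where(sb > 0, sb, np.inf)
            sbj = _pool_var(sb)
            tmax[b] = np.abs(dv / np.where(sbj > 0, sbj, np.inf)).max(axis=1)
    else:
        for b in range(n_boot):
            for attempt in range(max_retries):
                rows, labels, draw = _resample_clusters(dataset, rng)
                if np.unique(dataset.cluster[rows]).size < 2:
                    continue
                Xb = X[rows]
                if np.linalg.matrix_rank(Xb) < k:
                    continue
                bb, sb = _ols_and_cluster_se(Xb, dataset.Y[rows], labels)
                boot[b] = bb
                dv = bb - beta
                tstat[b] = dv / np.where(sb > 0, sb, np.inf)
                sbj = _pool_var(sb)
                tmax[b] = np.abs(dv / np.where(sbj > 0, sbj,
                                               np.inf)).max(axis=1)
                break
            else:
                raise RuntimeError("could not draw a valid bootstrap replicate")

    se_safe = np.where(se_hat > 0, se_hat, 0.0)
    if interval == "percentile-t":
        q_pw = np.quantile(np.abs(tstat), 0.95, axis=0)        # (k, T)
        pw_lo = beta - q_pw * se_safe
        pw_hi = beta + q_pw * se_safe
        # joint band from the max-|t| distribution (smoothed variance),
        # enlarged where needed so it contains the pointwise band
        q_joint = np.quantile(tmax, 0.95, axis=0)              # (k,)
        joint_lo = np.minimum(beta - q_joint[:, None] * se_joint, pw_lo)
        joint_hi = np.maximum(beta + q_joint[:, None] * se_joint, pw_hi)
    else:
        pw_lo = np.quantile(boot, 0.025, axis=0)
        pw_hi = np.quantile(boot, 0.975, axis=0)
        se_b = boot.std(axis=0, ddof=1)
        se_b_safe = np.where(se_b > 0, se_b, np.inf)
        dev = np.abs(boot - beta[None]) / se_b_safe[None]
        q = np.quantile(dev.max(axis=2), 0.95, axis=0)
        joint_lo = np.minimum(beta - q[:, None] * se_b, pw_lo)
        joint_hi = np.maximum(beta + q[:, None] * se_b, pw_hi)

    return FunctionalFit(
        time_s=dataset.time_s, terms=names, beta=beta,
        pw_lo=pw_lo, pw_hi=pw_hi, joint_lo=joint_lo, joint_hi=joint_hi,
        boot=boot, n_boot=n_boot, seed=seed, model_id=spec.model_id,
    )


def significant_intervals(fit: FunctionalFit, term: str) -> list:
    """Module-level alias for :meth:`FunctionalFit.significant_intervals`."""
    return fit.significant_intervals(term)


class FunctionalMixedModel:
    """Model object: a FunctionalDataset plus one of the five model specs.

    ``fit`` returns a :class:`FunctionalFit` with coefficient functions and
    bootstrap confidence bands.
    """

    def __init__(self, dataset: FunctionalDataset, model: int | ModelSpec = 3):
        self.dataset = dataset
        self.spec = model if isinstance(model, ModelSpec) \
            else ModelSpec.from_id(model)
        # validate covariates and design up front
        build_design(dataset, self.spec)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model: int = 3,
                       **kwargs) -> "FunctionalMixedModel":
        return cls(FunctionalDataset.from_long(df, **kwargs), model=model)

    def fit(self, n_boot: int = 1000, seed=None,
            interval: str = "percentile-t",
            resample: str = "wild") -> FunctionalFit:
        return cluster_bootstrap_ci(self.dataset, self.spec,
                                    n_boot=n_boot, seed=seed,
                                    interval=interval, resample=resample)

    def fit_pointwise(self) -> np.ndarray:
        return fit_pointwise(self.dataset, self.spec)
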