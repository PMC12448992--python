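"""Behavioural analyses: trial exclusion, the audiovisual weight index
w_AV, nonparametric permutation inference and parameter-behaviour
correlations.

The w_AV index locates an incongruent-trial report between the mean reports
of the two corresponding congruent conditions: 0 means the report tracked
the auditory position, 1 the visual position.  Using congruent-trial
*reports* rather than true positions in the normalization absorbs constant
response biases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .observers import RESPONSE_POSITIONS

_RESP_DEG = {"left": -9.0, "centre": 0.0, "right": 9.0}

EXCLUSION_REASONS = ("missed", "premature", "rt_outlier", "saccade")


@dataclass
class ExclusionReport:
    """Per-reason exclusion bookkeeping plus the retained trial table."""

    retained: pd.DataFrame
    counts: dict
    proportions: dict
    n_input: int

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def exclude_trials(trials: pd.DataFrame, rt_min: float = 0.1,
                   rt_sd_mult: float = 3.0, saccade_max: float = 7.0) -> ExclusionReport:
    """Apply the study's trial-exclusion filters in a fixed order.

    Removes, per participant: (1) missed responses; (2) premature responses
    (RT below 100 ms); (3) RT outliers, defined as trials whose RT lies more
    than 3 SD from the participant's across-condition median RT (statistics
    computed after the premature removal); (4) trials with a saccade
    amplitude above 7 degrees.
    """
    required = {"participant", "response", "rt", "saccade_amp"}
    missing = required - set(trials.columns)
    if missing:
        raise KeyError(f"trial table lacks required columns: {sorted(missing)}")

    df = trials.reset_index(drop=True)
    n_input = len(df)
    counts = dict.fromkeys(EXCLUSION_REASONS, 0)

    missed = df["response"] == "missed"
    counts["missed"] = int(missed.sum())
    df = df[~missed]

    premature = df["rt"] < rt_min
    counts["premature"] = int(premature.sum())
    df = df[~premature]

    keep = []
    for _, sub in df.groupby("participant"):
        med = sub["rt"].median()
        sd = sub["rt"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            keep.append(sub)
            continue
        keep.append(sub[(sub["rt"] - med).abs() <= rt_sd_mult * sd])
    kept = pd.concat(keep) if keep else df.iloc[:0]
    counts["rt_outlier"] = int(len(df) - len(kept))
    df = kept

    saccade = df["saccade_amp"] > saccade_max
    counts["saccade"] = int(saccade.sum())
    df = df[~saccade]

    proportions = {k: (v / n_input if n_input else 0.0) for k, v in counts.items()}
    return ExclusionReport(retained=df.reset_index(drop=True), counts=counts,
                           proportions=proportions, n_input=n_input)


def congruent_baselines(trials: pd.DataFrame, mode: str = "pooled") -> pd.DataFrame:
    """Mean reported location in audiovisual congruent trials.

    ``mode='pooled'`` pools over participants and conditions, returning one
    mean per position; ``mode='specific'`` computes one mean per participant
    and (intention, modality) condition, accommodating individual response
    biases.
    """
    df = trials[trials["sA"] == trials["sV"]].copy()
    df["reported"] = df["response"].map(_RESP_DEG)
    df = df.dropna(subset=["reported"])
    if mode == "pooled":
        return df.groupby("sA")["reported"].mean().rename("baseline").reset_index()
    if mode == "specific":
        return (df.groupby(["participant", "intention", "modality", "sA"])["reported"]
                .mean().rename("baseline").reset_index())
    raise ValueError(f"unknown baseline mode {mode!r}")


def compute_wav(trials: pd.DataFrame, baseline_mode: str = "pooled",
                baselines: pd.DataFrame | None = None) -> pd.DataFrame:
    """Audiovisual weight index per participant, intention, modality and disparity.

    Per incongruent trial,

        w_AV = (reported - baseline(s_A)) / (baseline(s_V) - baseline(s_A)),

    where baseline(x) is the mean reported location in congruent trials at
    position x (per ``baseline_mode``, or externally supplied, e.g. the
    study's printed pooled means).  Trial values are averaged across AV
    combinations within each disparity level (9: low, 18: high).
    """
    df = trials[trials["sA"] != trials["sV"]].copy()
    df["reported"] = df["response"].map(_RESP_DEG)
    df = df.dropna(subset=["reported"])
    df["disparity"] = (df["sA"] - df["sV"]).abs()

    if baselines is None:
        baselines = congruent_baselines(trials, baseline_mode)

    if {"participant", "intention", "modality"} <= set(baselines.columns):
        keys = ["participant", "intention", "modality"]
        ba = baselines.rename(columns={"sA": "pos", "baseline": "base_a"})
        df = df.merge(ba, left_on=keys + ["sA"], right_on=keys + ["pos"], how="left")
        bv = baselines.rename(columns={"sA": "pos", "baseline": "base_v"})
        df = df.merge(bv, left_on=keys + ["sV"], right_on=keys + ["pos"], how="left")
    else:
        lut = dict(zip(baselines["sA"], baselines["baseline"]))
        df["base_a"] = df["sA"].map(lut)
        df["base_v"] = df["sV"].map(lut)

    denom = df["base_v"] - df["base_a"]
    if np.any(np.isclose(denom, 0.0)):
        raise ZeroDivisionError("identical congruent baselines leave w_AV undefined")
    df["wav"] = (df["reported"] - df["base_a"]) / denom
    return (df.groupby(["participant", "intention", "modality", "disparity"])["wav"]
            .mean().rename("wav").reset_index())


@dataclass
class PermutationResult:
    """Two-tailed permutation test of a within-participant contrast."""

    observed: float
    p_value: float
    effect_size: float
    ci_low: float
    ci_high: float
    n_permutations: int
    null_mean: float


def permutation_test(cells: pd.DataFrame, contrast: dict, n_perm: int = 4096,
                     seed: int | None = 0, n_boot: int = 2000) -> PermutationResult:
    """Permutation inference on a within-participant condition contrast.

    ``cells`` is a wide table (participants x condition cells); ``contrast``
    maps cell names to weights (e.g. {'com': 1, 'ncom': -1} for a main
    effect, a +1/-1 pattern over four cells for an interaction).  The
    observed statistic is the across-participant mean of the per-participant
    contrast.  The null distribution relabels the contrasted conditions
    independently within each participant — for the two-level contrasts used
    here this is a random sign flip of each participant's contrast value —
    and the two-tailed p-value is (b + 1) / (m + 1) where b counts null
    statistics at least as extreme as the observed one.  The effect size is
    the observed statistic minus the null mean; its 95% CI is a percentile
    interval over participant-level bootstrap resamples.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    weights = pd.Series(contrast, dtype=float)
    missing = set(weights.index) - set(cells.columns)
    if missing:
        raise KeyError(f"contrast names absent from cells: {sorted(missing)}")
    values = cells[weights.index].to_numpy(float) @ weights.to_numpy()
    n = len(values)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = (signs * values[None, :]).mean(axis=1)
    observed = float(values.mean())
    b = int(np.sum(np.abs(null) >= abs(observed)))
    p = (b + 1) / (n_perm + 1)

    boot_idx = rng.integers(0, n, size=(n_boot, n))
    boot = values[boot_idx].mean(axis=1)
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    null_mean = float(null.mean())
    return PermutationResult(observed=observed, p_value=float(p),
                             effect_size=observed - null_mean,
                             ci_low=float(ci_low), ci_high=float(ci_high),
                             n_permutations=n_perm, null_mean=null_mean)


def wav_cells(wav: pd.DataFrame) -> pd.DataFrame:
    """Pivot a w_AV table to participants x 'intention|modality|disparity' cells."""
    wide = wav.pivot_table(index="participant",
                           columns=["intention", "modality", "disparity"],
                           values="wav")
    wide.columns = [f"{i}|{m}|{int(d)}" for i, m, d in wide.columns]
    return wide


@dataclass
class CorrelationResult:
    """Pearson correlation with the regression line and a 95% CI band."""

    r: float
    p_value: float
    slope: float
    intercept: float
    n: int
    x_grid: np.ndarray = field(repr=False, default=None)
    band_low: np.ndarray = field(repr=False, default=None)
    band_high: np.ndarray = field(repr=False, default=None)


def pearson_correlation(x, y, n_grid: int = 50) -> CorrelationResult:
    """Pearson r with two-tailed p, least-squares line and CI band.

    The confidence band is the pointwise 95% t-interval for the conditional
    mean of the simple linear regression, evaluated on an even grid over the
    observed x range (for plotting).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance in x or y")

    r, p = sps.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    s2 = float(resid @ resid) / (n - 2)
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    grid = np.linspace(x.min(), x.max(), n_grid)
    se_mean = np.sqrt(s2 * (1.0 / n + (grid - xbar) ** 2 / sxx))
    tcrit = sps.t.ppf(0.975, n - 2)
    yhat = slope * grid + intercept
    return CorrelationResult(r=float(r), p_value=float(p), slope=float(slope),
                             intercept=float(intercept), n=n, x_grid=grid,
                             band_low=yhat - tcrit * se_mean,
                             band_high=yhat + tcrit * se_mean)
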