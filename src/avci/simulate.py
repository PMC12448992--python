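"""Synthetic trial generator for the audiovisual ventriloquist paradigm.

Builds the 3 (visual position) x 3 (auditory position) x 2 (action
intention) x 2 (response modality) factorial design — by default 4 runs of
18 blocks with 9 trials per block, i.e. 648 trials and 18 per condition —
and simulates trial-level three-alternative localization responses from any
observer architecture.  Contamination (missed/premature responses,
large-saccade trials) can be injected to exercise the exclusion filters.

The generator stands in for a human cohort: per-participant parameters are
drawn around population means (log-normal for noise SDs, logit-normal for
probabilities) and responses follow the chosen generative observer model
exactly, so fitted parameters can be compared against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .observers import (
    ObserverParams,
    discretize_response,
    final_estimates,
)

POSITIONS = (-9.0, 0.0, 9.0)
INTENTIONS = ("communicative", "non-communicative")
MODALITIES = ("auditory", "visual")

#: column order of the trial table written/read as CSV
TRIAL_COLUMNS = [
    "participant", "run", "block", "trial", "intention", "modality",
    "sA", "sV", "response", "rt", "saccade_amp",
]


class DesignError(ValueError):
    """Raised for inconsistent design requests."""


def generate_design(n_runs: int = 4, blocks_per_run: int = 18, trials_per_block: int = 9,
                    seed: int | None = 0, first_intention: str = "communicative",
                    first_modality: str = "auditory") -> pd.DataFrame:
    """Build the factorial trial order for one participant.

    Within each block every (s_A, s_V) combination appears exactly once in a
    seeded random order.  Action intention alternates every block; response
    modality changes every two blocks, with the starting modality alternating
    across runs so that the four intention-by-modality cells are balanced
    (defaults give 18 trials in each of the 36 conditions).
    """
    combos = [(a, v) for a in POSITIONS for v in POSITIONS]
    if trials_per_block != len(combos):
        raise DesignError(
            f"trials_per_block must equal the {len(combos)} spatial combinations, "
            f"got {trials_per_block}")
    if first_intention not in INTENTIONS:
        raise DesignError(f"unknown intention {first_intention!r}")
    if first_modality not in MODALITIES:
        raise DesignError(f"unknown modality {first_modality!r}")

    rng = np.random.default_rng(seed)
    i0 = INTENTIONS.index(first_intention)
    m0 = MODALITIES.index(first_modality)

    rows = []
    for run in range(1, n_runs + 1):
        for block in range(1, blocks_per_run + 1):
            intention = INTENTIONS[(i0 + block - 1) % 2]
            # modality switches every two blocks; alternate the run's start
            # so the factorial cells balance over an even number of runs
            modality = MODALITIES[(m0 + run - 1 + (block - 1) // 2) % 2]
            order = rng.permutation(len(combos))
            for t, idx in enumerate(order, start=1):
                s_a, s_v = combos[idx]
                rows.append((run, block, t, intention, modality, s_a, s_v))
    return pd.DataFrame(rows, columns=["run", "block", "trial", "intention",
                                       "modality", "sA", "sV"])


def simulate_participant(design: pd.DataFrame,
                         params_by_intention: Mapping[str, ObserverParams],
                         architecture: str = "bci",
                         seed: int | None = 0,
                         participant: int = 1,
                         rt_median: float = 0.55,
                         rt_scale: float = 0.25) -> pd.DataFrame:
    """Simulate one participant's trial-level responses over a design table.

    Per trial, noisy internal signals are drawn as x_A ~ N(s_A, sigma_a) and
    x_V ~ N(s_V, sigma_v) under the intention-specific parameters, the
    architecture's decision rule yields the estimate for the cued modality,
    and the estimate is discretized to left/centre/right.  Response times are
    log-normal (clean trials only need to pass the exclusion filters
    plausibly) and clean saccade amplitudes are uniform on [0, 3] degrees.
    """
    rng = np.random.default_rng(seed)
    out = design.copy().reset_index(drop=True)
    n = len(out)
    responses = np.empty(n, dtype=int)

    for intention in out["intention"].unique():
        params = params_by_intention[intention]
        mask = (out["intention"] == intention).to_numpy()
        s_a = out.loc[mask, "sA"].to_numpy(float)
        s_v = out.loc[mask, "sV"].to_numpy(float)
        x_a = rng.normal(s_a, params.sigma_a)
        x_v = rng.normal(s_v, params.sigma_v)
        draw = rng.random(mask.sum()) if architecture == "sf" else None
        est = final_estimates(x_a, x_v, params, architecture, fusion_draw=draw)
        cued_visual = (out.loc[mask, "modality"] == "visual").to_numpy()
        estimate = np.where(cued_visual, est.s_hat_v, est.s_hat_a)
        responses[mask] = discretize_response(estimate)

    out.insert(0, "participant", participant)
    out["response"] = np.array(["left", "centre", "right"])[responses]
    out["rt"] = rt_median * np.exp(rng.normal(0.0, rt_scale, size=n))
    out["saccade_amp"] = rng.uniform(0.0, 3.0, size=n)
    return out[TRIAL_COLUMNS]


def contaminate(trials: pd.DataFrame, premature: float = 0.0, missed: float = 0.0,
                saccade: float = 0.0, seed: int | None = 0) -> pd.DataFrame:
    """Inject contaminated trials the exclusion filters should remove.

    Disjoint seeded random subsets are marked as missed (no response, NaN
    RT), premature (RT drawn uniform below 100 ms) or saccade-contaminated
    (amplitude uniform on [7.5, 15] degrees).  A ``contaminated`` column
    records the ground-truth label ('clean' otherwise) for filter testing.
    """
    for name, rate in (("premature", premature), ("missed", missed), ("saccade", saccade)):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} rate must be in [0,1], got {rate}")
    out = trials.copy().reset_index(drop=True)
    if "contaminated" not in out.columns:
        out["contaminated"] = "clean"
    if premature == missed == saccade == 0.0:
        return out

    rng = np.random.default_rng(seed)
    n = len(out)
    u = rng.random(n)
    lab = out["contaminated"].to_numpy(object)
    is_missed = u < missed
    is_premature = (~is_missed) & (u < missed + premature)
    is_saccade = (~is_missed) & (~is_premature) & (u < missed + premature + saccade)

    lab[is_missed] = "missed"
    lab[is_premature] = "premature"
    lab[is_saccade] = "saccade"
    out["contaminated"] = lab
    out.loc[is_missed, "response"] = "missed"
    out.loc[is_missed, "rt"] = np.nan
    out.loc[is_premature, "rt"] = rng.uniform(0.0, 0.1, size=int(is_premature.sum()))
    out.loc[is_saccade, "saccade_amp"] = rng.uniform(7.5, 15.0, size=int(is_saccade.sum()))
    return out


@dataclass
class CohortSpec:
    """Population-level description of a synthetic cohort.

    ``mean_params`` holds one ObserverParams per action intention; the
    between-participant spread is log-normal for the noise SDs (``sd_log``
    on the log scale) and logit-normal for p_common and eta (``sd_logit``).
    Contamination rates apply to every participant.
    """

    n_participants: int = 34
    architecture: str = "bci"
    mean_params: Mapping[str, ObserverParams] = field(default_factory=dict)
    sd_log_sigma: float = 0.2
    sd_logit_p: float = 0.4
    premature: float = 0.02
    missed: float = 0.03
    saccade: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not self.mean_params:
            self.mean_params = experiment_preset(1)


def experiment_preset(experiment: int = 1) -> dict[str, ObserverParams]:
    """Population mean parameters emulating the two study conditions.

    The communicative condition carries a higher common-cause prior in both
    presets.  In the first preset the non-communicative auditory noise is
    larger (short static stimuli localize poorly); the second preset equates
    auditory noise across intentions, isolating the prior difference.
    Visual noise is small and equal (high visual reliability).
    """
    if experiment == 1:
        return {
            "communicative": ObserverParams(p_common=0.58, sigma_p=12.0,
                                            sigma_a=4.0, sigma_v=1.5,
                                            k_c=8.0, eta=0.6),
            "non-communicative": ObserverParams(p_common=0.50, sigma_p=12.0,
                                                sigma_a=4.85, sigma_v=1.5,
                                                k_c=6.5, eta=0.5),
        }
    if experiment == 2:
        return {
            "communicative": ObserverParams(p_common=0.61, sigma_p=12.0,
                                            sigma_a=4.0, sigma_v=1.5,
                                            k_c=8.5, eta=0.6),
            "non-communicative": ObserverParams(p_common=0.50, sigma_p=12.0,
                                                sigma_a=4.0, sigma_v=1.5,
                                                k_c=6.5, eta=0.5),
        }
    raise ValueError(f"unknown experiment preset {experiment}")


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(z):
    return 1.0 / (1.0 + np.exp(-z))


def draw_participant_params(mean_params: Mapping[str, ObserverParams], rng,
                            sd_log_sigma: float = 0.2,
                            sd_logit_p: float = 0.4) -> dict[str, ObserverParams]:
    """Draw one participant's parameters around population means.

    Noise SDs and k_c vary log-normally, p_common and eta logit-normally, so
    every draw respects the parameter supports.
    """
    out = {}
    for intention, mp in mean_params.items():
        p_common = float(np.clip(_expit(_logit(np.clip(mp.p_common, 1e-6, 1 - 1e-6))
                                        + rng.normal(0, sd_logit_p)), 1e-4, 1 - 1e-4))
        eta = float(np.clip(_expit(_logit(np.clip(mp.eta, 1e-6, 1 - 1e-6))
                                   + rng.normal(0, sd_logit_p)), 1e-4, 1 - 1e-4))
        out[intention] = ObserverParams(
            p_common=p_common,
            sigma_p=float(mp.sigma_p * np.exp(rng.normal(0, sd_log_sigma))),
            sigma_a=float(mp.sigma_a * np.exp(rng.normal(0, sd_log_sigma))),
            sigma_v=float(mp.sigma_v * np.exp(rng.normal(0, sd_log_sigma))),
            mu_p=mp.mu_p,
            k_c=float(mp.k_c * np.exp(rng.normal(0, sd_log_sigma))),
            eta=eta,
        )
    return out


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, list[dict[str, ObserverParams]]]:
    """Simulate a full cohort; returns the trial table and ground-truth parameters."""
    rng = np.random.default_rng(spec.seed)
    tables = []
    truths = []
    for pid in range(1, spec.n_participants + 1):
        params = draw_participant_params(spec.mean_params, rng,
                                         spec.sd_log_sigma, spec.sd_logit_p)
        design = generate_design(seed=rng.integers(2**31))
        trials = simulate_participant(design, params, spec.architecture,
                                      seed=rng.integers(2**31), participant=pid)
        trials = contaminate(trials, spec.premature, spec.missed, spec.saccade,
                             seed=rng.integers(2**31))
        tables.append(trials)
        truths.append(params)
    return pd.concat(tables, ignore_index=True), truths
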