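"""Self-validation studies: parameter recovery, model recovery, statistics
calibration.

These studies exercise the whole pipeline against known ground truth under
the study's design (648 trials per participant, 18 per condition) and are
shared by the test suite and the reproduction script.  Each study fixes its
own generating conditions:

* Parameter recovery runs the winning-model configuration (BCI with
  separate parameter sets per action intention) on a cohort whose
  common-cause prior clearly differs between intentions (0.7 vs 0.4);
  sensory noise SDs are placed in the identifiable interior of the
  three-alternative paradigm (sigma_v = 2.5 deg; below ~2 deg visual
  lapses essentially never cross a response boundary and sigma_v is only
  bounded from above).
* Model recovery simulates pooled cohorts under each of the four
  architectures at a generating point where the architectures are
  discriminable (strong prior, sizeable auditory noise).  In
  weak-prior regimes BCI and its fixed-criterion approximation produce
  nearly identical predictions and confuse with each other — the mimicry
  the heuristic is known for — so recovery there is uninformative.
* Statistics calibration checks the permutation test's type-I error on
  exchangeable null data and the w_AV index's limiting behaviour under
  forced fusion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import fit_model, response_counts
from .observers import ObserverParams
from .selection import rfx_bms
from .simulate import (
    CohortSpec,
    generate_design,
    simulate_cohort,
    simulate_participant,
)
from .stats import compute_wav, permutation_test, pearson_correlation, wav_cells

ARCH_ORDER = ("bci", "ff", "fc", "sf")

#: parameter-recovery cohort: distinct common-cause priors per intention
RECOVERY_MEANS = {
    "communicative": ObserverParams(p_common=0.7, sigma_p=12.0, sigma_a=4.0,
                                    sigma_v=2.5),
    "non-communicative": ObserverParams(p_common=0.4, sigma_p=12.0, sigma_a=4.85,
                                        sigma_v=2.5),
}

#: model-recovery generating points: each architecture simulated at a
#: representative regime where its decision signature is expressed (BCI needs
#: a strong prior and sizeable auditory noise to separate from its
#: fixed-criterion approximation; the heuristics use moderate-noise settings)
MODEL_RECOVERY_PARAMS = {
    "bci": ObserverParams(p_common=0.7, sigma_p=8.0, sigma_a=6.0, sigma_v=1.5),
    "ff": ObserverParams(sigma_p=12.0, sigma_a=4.4, sigma_v=1.5),
    "fc": ObserverParams(k_c=7.0, sigma_p=12.0, sigma_a=4.4, sigma_v=1.5),
    "sf": ObserverParams(eta=0.55, sigma_p=12.0, sigma_a=4.4, sigma_v=1.5),
}


def parameter_recovery_study(n_participants: int = 34, n_sim: int = 2000,
                             seed: int = 0) -> dict:
    """Fit BCI-separated to a synthetic cohort and compare against ground truth.

    Returns a dict with the trial table, per-participant truth/fit table and
    summary errors: cohort-mean p_common error per intention, median relative
    error per noise SD, and the fraction of participants whose fitted
    p_common difference (communicative - non-communicative) is positive.
    """
    spec = CohortSpec(n_participants=n_participants, architecture="bci",
                      mean_params=RECOVERY_MEANS, premature=0.0, missed=0.0,
                      saccade=0.0, seed=seed)
    trials, truth = simulate_cohort(spec)

    rows = []
    for pid, sub in trials.groupby("participant"):
        fit = fit_model(response_counts(sub), "bci", "separated", n_sim=n_sim,
                        seed=(seed + 1000 + int(pid)) % (2**31))
        rec = {"participant": pid, "log_lik": fit.log_lik, "r2": fit.r2_scaled}
        for intention in ("communicative", "non-communicative"):
            t = truth[int(pid) - 1][intention]
            f = fit.params[intention]
            tag = "com" if intention == "communicative" else "ncom"
            rec[f"p_true_{tag}"] = t.p_common
            rec[f"p_fit_{tag}"] = f["p_common"]
            for name, attr in (("sa", "sigma_a"), ("sv", "sigma_v"), ("sp", "sigma_p")):
                rec[f"{name}_true_{tag}"] = getattr(t, attr)
                rec[f"{name}_fit_{tag}"] = f[attr]
        rows.append(rec)
    table = pd.DataFrame(rows)

    summary = {}
    for tag in ("com", "ncom"):
        summary[f"p_common_mean_error_{tag}"] = float(
            table[f"p_fit_{tag}"].mean() - table[f"p_true_{tag}"].mean())
        for name in ("sa", "sv", "sp"):
            rel = (table[f"{name}_fit_{tag}"] - table[f"{name}_true_{tag}"]) \
                / table[f"{name}_true_{tag}"]
            summary[f"{name}_median_rel_error_{tag}"] = float(np.median(rel))
    dp = table["p_fit_com"] - table["p_fit_ncom"]
    summary["frac_delta_p_positive"] = float((dp > 0).mean())
    summary["mean_r2"] = float(table["r2"].mean())
    return {"trials": trials, "table": table, "summary": summary}


def model_recovery_study(n_participants: int = 20, n_sim: int = 2000,
                         seed: int = 0, architectures=ARCH_ORDER) -> dict:
    """Simulate pooled cohorts under each architecture and refit all of them.

    For each generating architecture, reports the fraction of participants
    whose lowest BIC names the generating architecture and the protected
    exceedance probability it obtains in group-level model selection over
    the recovered evidences.
    """
    out = {}
    for g_idx, gen_arch in enumerate(architectures):
        gen = MODEL_RECOVERY_PARAMS[gen_arch]
        mean = {"communicative": gen, "non-communicative": gen}
        spec = CohortSpec(n_participants=n_participants, architecture=gen_arch,
                          mean_params=mean, premature=0.0, missed=0.0,
                          saccade=0.0, seed=seed + 101 * g_idx)
        trials, _ = simulate_cohort(spec)
        evidence = np.zeros((n_participants, len(architectures)))
        wins = []
        for j, (pid, sub) in enumerate(trials.groupby("participant")):
            counts = response_counts(sub)
            bics = [fit_model(counts, fit_arch, "pooled", n_sim=n_sim,
                              seed=(seed + 500 + int(pid)) % (2**31)).bic
                    for fit_arch in architectures]
            evidence[j] = -np.asarray(bics)
            wins.append(architectures[int(np.argmin(bics))])
        bms = rfx_bms(pd.DataFrame(evidence, columns=list(architectures)),
                      seed=seed + 13 * g_idx)
        out[gen_arch] = {
            "win_fraction": float(np.mean([w == gen_arch for w in wins])),
            "pep": float(bms.protected_exceedance_prob[list(architectures).index(gen_arch)]),
            "bor": bms.bor,
            "evidence": evidence,
        }
    return out


def permutation_type1_study(n_datasets: int = 1000, n_participants: int = 34,
                            n_perm: int = 4096, alpha: float = 0.05,
                            seed: int = 0) -> dict:
    """Type-I error of the permutation test on exchangeable null data."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for i in range(n_datasets):
        cells = pd.DataFrame({
            "a": rng.normal(size=n_participants),
            "b": rng.normal(size=n_participants),
        })
        res = permutation_test(cells, {"a": 1.0, "b": -1.0}, n_perm=n_perm,
                               seed=int(rng.integers(2**31)))
        rejections += res.p_value < alpha
    return {"rejection_rate": rejections / n_datasets, "n_datasets": n_datasets}


def wav_limit_study(n_repeats: int = 16, seed: int = 0) -> dict:
    """w_AV limits under forced fusion and its disparity dependence under BCI.

    Simulates ~10^4 forced-fusion trials with visual noise far smaller than
    auditory noise (auditory-report w_AV should approach 1), the reverse
    (approach 0), and a BCI observer (auditory-report w_AV should drop from
    the 9-degree to the 18-degree disparity level).
    """
    rng = np.random.default_rng(seed)

    def mean_wav(architecture, params, by_disparity=False):
        tables = []
        for r in range(n_repeats):
            design = generate_design(seed=int(rng.integers(2**31)))
            tables.append(simulate_participant(
                design, {"communicative": params, "non-communicative": params},
                architecture, seed=int(rng.integers(2**31)), participant=r + 1))
        trials = pd.concat(tables, ignore_index=True)
        # one synthetic observer repeated: treat repeats as one participant pool
        trials["participant"] = 1
        wav = compute_wav(trials, baseline_mode="pooled")
        aud = wav[wav["modality"] == "auditory"]
        if by_disparity:
            return aud.groupby("disparity")["wav"].mean().to_dict()
        return float(aud["wav"].mean())

    visual_dominant = ObserverParams(p_common=0.5, sigma_p=12.0, sigma_a=8.0, sigma_v=0.3)
    auditory_dominant = ObserverParams(p_common=0.5, sigma_p=12.0, sigma_a=0.3, sigma_v=8.0)
    bci_params = ObserverParams(p_common=0.6, sigma_p=12.0, sigma_a=4.0, sigma_v=1.5)

    by_disp = mean_wav("bci", bci_params, by_disparity=True)
    return {
        "ff_wav_visual_dominant": mean_wav("ff", visual_dominant),
        "ff_wav_auditory_dominant": mean_wav("ff", auditory_dominant),
        "bci_wav_low_disparity": float(by_disp[9.0]),
        "bci_wav_high_disparity": float(by_disp[18.0]),
    }


def correlation_study(n_participants: int = 34, n_sim: int = 2000,
                      seed: int = 0) -> dict:
    """Fitted delta-p_common against behavioural delta-w_AV across a cohort.

    Generates a cohort in which the common-cause prior difference between
    intentions is the primary source of between-participant variation: the
    noise SDs are drawn once per participant and shared across intentions,
    while p_common is drawn separately per intention around distinct means
    (0.65 vs 0.45, logit SD 0.5).  Each participant is fitted with the
    BCI-separated model; the fitted p_common difference should correlate
    positively with the observed difference in the auditory-report w_AV.
    """
    rng = np.random.default_rng(seed)

    def _logit(p):
        return np.log(p) - np.log1p(-p)

    def _expit(z):
        return 1.0 / (1.0 + np.exp(-z))

    tables, d_p_fit, d_wav_true = [], [], []
    for pid in range(1, n_participants + 1):
        sig_p = 12.0 * np.exp(rng.normal(0, 0.2))
        sig_a = 4.5 * np.exp(rng.normal(0, 0.2))
        sig_v = 2.5 * np.exp(rng.normal(0, 0.2))
        params = {}
        for intention, mu in (("communicative", 0.65), ("non-communicative", 0.45)):
            p = float(np.clip(_expit(_logit(mu) + rng.normal(0, 0.5)), 1e-3, 1 - 1e-3))
            params[intention] = ObserverParams(p_common=p, sigma_p=sig_p,
                                               sigma_a=sig_a, sigma_v=sig_v)
        design = generate_design(seed=int(rng.integers(2**31)))
        trials = simulate_participant(design, params, "bci",
                                      seed=int(rng.integers(2**31)),
                                      participant=pid)
        tables.append(trials)
        fit = fit_model(response_counts(trials), "bci", "separated", n_sim=n_sim,
                        seed=(seed + 2000 + pid) % (2**31))
        d_p_fit.append(fit.params["communicative"]["p_common"]
                       - fit.params["non-communicative"]["p_common"])

    trials = pd.concat(tables, ignore_index=True)
    wav = compute_wav(trials, baseline_mode="pooled")
    aud = (wav[wav["modality"] == "auditory"]
           .groupby(["participant", "intention"])["wav"].mean().unstack())
    d_wav = (aud["communicative"] - aud["non-communicative"]).to_numpy()
    res = pearson_correlation(np.asarray(d_p_fit), d_wav)
    return {"r": res.r, "p_value": res.p_value, "n": res.n}
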