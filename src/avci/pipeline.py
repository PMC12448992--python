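"""End-to-end orchestration plus small design utilities.

The pipeline chains the stages simulate -> exclude -> behavioural
statistics -> model fitting -> group-level model selection -> parameter/
behaviour correlations, with per-stage seeding so the whole run is a pure
function of its configuration.  The design utilities cover the recording
geometry (lateral camera shift for a given viewing angle) and the a-priori
power analysis that sets the cohort size.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import fitting, selection, simulate, stats

logger = logging.getLogger("avci")


def camera_shift(distance_cm: float, alpha_deg: float) -> float:
    """Horizontal camera displacement S = 2 D tan(alpha / 2).

    ``distance_cm`` is the speaker-to-camera distance and ``alpha_deg`` the
    desired viewing angle of the lateral recording position.
    """
    if distance_cm < 0:
        raise ValueError("distance must be non-negative")
    if not (0.0 <= alpha_deg < 180.0):
        raise ValueError("alpha must lie in [0, 180) degrees")
    return 2.0 * distance_cm * float(np.tan(np.radians(alpha_deg) / 2.0))


def t_test_power(n: int, d: float, alpha_level: float = 0.05, tails: int = 2) -> float:
    """Power of a one-sample / matched-pairs t-test from the noncentral t."""
    if n < 2:
        return 0.0
    df = n - 1
    ncp = d * np.sqrt(n)
    if tails == 2:
        tcrit = sps.t.ppf(1.0 - alpha_level / 2.0, df)
        return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
    tcrit = sps.t.ppf(1.0 - alpha_level, df)
    return float(sps.nct.sf(tcrit, df, ncp))


def required_sample_size(d: float, alpha_level: float = 0.05, power: float = 0.8,
                         tails: int = 2, n_max: int = 100_000) -> int:
    """Smallest N for which the t-test achieves the target power at effect size d.

    Integer search upward over N using the exact noncentral-t power function
    (matched-pairs and one-sample designs coincide for a given d).
    """
    if d == 0.0:
        raise ValueError("no finite sample size achieves power for d = 0")
    if not (0.0 < alpha_level < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha_level and power must lie in (0, 1)")
    d = abs(d)
    for n in range(2, n_max + 1):
        if t_test_power(n, d, alpha_level, tails) >= power:
            return n
    raise ValueError(f"no N <= {n_max} reaches the requested power")


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-cohort analysis run."""

    n_participants: int = 34
    architecture: str = "bci"
    experiment: int = 1
    models: list = field(default_factory=lambda: ["bci_pooled", "bci_separated",
                                                  "ff_pooled", "ff_separated"])
    n_sim: int = 10_000
    n_perm: int = 4096
    baseline_mode: str = "pooled"
    premature: float = 0.02
    missed: float = 0.03
    saccade: float = 0.04
    seed: int = 0
    out_dir: str = "avci_out"

    def parse_models(self):
        out = []
        for label in self.models:
            arch, _, param = label.partition("_")
            if arch not in fitting.FREE_PARAMS or param not in ("pooled", "separated"):
                raise ValueError(f"unknown model name {label!r}")
            out.append((arch, param))
        return out


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the manifest dictionary.

    Writes trials.csv, stats/ (w_AV table + permutation tests), fits/ (fit
    table) and bms.json under ``config.out_dir``, together with a manifest
    listing seeds, stage wall-times, outputs and checksums.
    """
    models = config.parse_models()  # validate before any work
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "stats").mkdir(exist_ok=True)
    (out / "fits").mkdir(exist_ok=True)
    manifest = {"config": asdict(config), "stages": {}, "outputs": {}}

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    t0 = stage("simulate")
    spec = simulate.CohortSpec(
        n_participants=config.n_participants, architecture=config.architecture,
        mean_params=simulate.experiment_preset(config.experiment),
        premature=config.premature, missed=config.missed,
        saccade=config.saccade, seed=config.seed)
    trials, _truth = simulate.simulate_cohort(spec)
    trials.to_csv(out / "trials.csv", index=False)
    manifest["stages"]["simulate"] = {"seconds": time.perf_counter() - t0,
                                      "seed": config.seed, "n_trials": len(trials)}

    t0 = stage("exclude")
    report = stats.exclude_trials(trials)
    manifest["stages"]["exclude"] = {"seconds": time.perf_counter() - t0,
                                     "counts": report.counts,
                                     "n_retained": report.n_retained}
    clean = report.retained

    t0 = stage("stats")
    wav = stats.compute_wav(clean, baseline_mode=config.baseline_mode)
    wav.to_csv(out / "stats" / "wav.csv", index=False)
    cells = stats.wav_cells(wav)
    tests = {}
    aud = [c for c in cells.columns if "|auditory|" in c]
    com = [c for c in aud if c.startswith("communicative")]
    ncom = [c for c in aud if c.startswith("non-communicative")]
    contrast = {c: 1.0 / len(com) for c in com}
    contrast.update({c: -1.0 / len(ncom) for c in ncom})
    res = stats.permutation_test(cells, contrast, n_perm=config.n_perm,
                                 seed=config.seed + 1)
    tests["intention_effect_auditory"] = asdict(res)
    with open(out / "stats" / "permutation_tests.json", "w") as fh:
        json.dump(tests, fh, indent=2)
    manifest["stages"]["stats"] = {"seconds": time.perf_counter() - t0,
                                   "seed": config.seed + 1}

    t0 = stage("fit")
    fits = fitting.fit_participants(clean, models=models, n_sim=config.n_sim,
                                    seed=config.seed + 2)
    fits.assign(params=fits["params"].map(json.dumps)).to_csv(
        out / "fits" / "fits.csv", index=False)
    manifest["stages"]["fit"] = {"seconds": time.perf_counter() - t0,
                                 "seed": config.seed + 2, "n_fits": len(fits)}

    t0 = stage("bms")
    bms = selection.rfx_bms(fitting.evidence_matrix(fits), seed=config.seed + 3)
    with open(out / "bms.json", "w") as fh:
        json.dump({"models": list(map(str, bms.models)),
                   "alpha": bms.alpha.tolist(),
                   "expected_frequency": bms.expected_frequency.tolist(),
                   "exceedance_prob": bms.exceedance_prob.tolist(),
                   "protected_exceedance_prob": bms.protected_exceedance_prob.tolist(),
                   "bor": bms.bor}, fh, indent=2)
    manifest["stages"]["bms"] = {"seconds": time.perf_counter() - t0,
                                 "seed": config.seed + 3}

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _checksum(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
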