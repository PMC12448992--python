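"""Exclusion filters, the w_AV index, permutation inference and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from avci import (
    compute_wav,
    congruent_baselines,
    exclude_trials,
    pearson_correlation,
    permutation_test,
)
from avci.simulate import CohortSpec, contaminate, simulate_cohort
from avci.stats import wav_cells


def _mini_trials(rows):
    base = {"participant": 1, "run": 1, "block": 1, "trial": 1,
            "intention": "communicative", "modality": "auditory",
            "sA": 0.0, "sV": 0.0, "response": "centre", "rt": 0.5,
            "saccade_amp": 1.0}
    return pd.DataFrame([{**base, **r} for r in rows])


# ------------------------------------------------------------- exclusion

def test_exclusion_reasons_and_order():
    trials = _mini_trials([
        {"response": "missed", "rt": np.nan},
        {"rt": 0.05},                      # premature
        {"saccade_amp": 8.0},              # saccade
        {}, {}, {}, {}, {},                # clean
    ])
    report = exclude_trials(trials)
    assert report.counts["missed"] == 1
    assert report.counts["premature"] == 1
    assert report.counts["saccade"] == 1
    assert report.n_retained == 5
    assert report.n_input == 8
    assert sum(report.counts.values()) + report.n_retained == report.n_input


def test_rt_outlier_uses_median_distance():
    rts = [0.5] * 20 + [0.52] * 20 + [5.0]
    trials = _mini_trials([{"rt": r} for r in rts])
    report = exclude_trials(trials)
    assert report.counts["rt_outlier"] == 1
    assert 5.0 not in report.retained["rt"].values


def test_clean_table_identity(small_trials):
    trials, _ = small_trials
    rng = np.random.default_rng(0)
    clean = trials.assign(rt=rng.uniform(0.4, 0.6, len(trials)))
    report = exclude_trials(clean)
    assert report.counts == dict.fromkeys(report.counts, 0)
    pd.testing.assert_frame_equal(report.retained, clean)


def test_contaminated_trials_are_caught():
    spec = CohortSpec(n_participants=2, premature=0.05, missed=0.05, saccade=0.05, seed=3)
    trials, _ = simulate_cohort(spec)
    report = exclude_trials(trials)
    contaminated = trials[trials["contaminated"] != "clean"]
    retained_contaminated = report.retained["contaminated"] != "clean"
    assert report.counts["missed"] == (trials["contaminated"] == "missed").sum()
    assert report.counts["premature"] == (trials["contaminated"] == "premature").sum()
    assert retained_contaminated.sum() == 0
    assert len(contaminated) > 0


def test_missing_columns_raise():
    with pytest.raises(KeyError, match="saccade_amp"):
        exclude_trials(pd.DataFrame({"participant": [1], "response": ["left"],
                                     "rt": [0.4]}))


# ----------------------------------------------------------------- w_AV

# study-reported pooled congruent baselines (first dataset)
BASELINES = pd.DataFrame({"sA": [-9.0, 0.0, 9.0],
                          "baseline": [-8.589, -0.667, 8.208]})


def test_wav_pure_visual_and_auditory_capture():
    trials = _mini_trials([
        {"sA": 9.0, "sV": 0.0, "response": "centre"},   # reported -0.667 -> w = 1
        {"sA": 9.0, "sV": 0.0, "response": "right"},    # reported 8.208 -> w ~ 0
    ])
    wav = compute_wav(trials, baselines=BASELINES)
    # reports map to -9/0/+9 deg; baselines carry the study's printed biases
    w_centre = (0.0 - 8.208) / (-0.667 - 8.208)
    w_right = (9.0 - 8.208) / (-0.667 - 8.208)
    assert wav["wav"].iloc[0] == pytest.approx((w_centre + w_right) / 2, rel=1e-12)


def test_wav_exact_at_baseline_report():
    """A report equal to the congruent baseline of the visual position gives w=1."""
    trials = _mini_trials([{"sA": 9.0, "sV": 0.0}])
    baselines = pd.DataFrame({"sA": [-9.0, 0.0, 9.0], "baseline": [-9.0, 0.0, 8.208]})
    wav = compute_wav(trials, baselines=baselines)  # reported centre = 0 = baseline(V)
    assert wav["wav"].iloc[0] == pytest.approx(1.0)
    trials2 = _mini_trials([{"sA": 9.0, "sV": 0.0, "response": "right"}])
    baselines2 = pd.DataFrame({"sA": [-9.0, 0.0, 9.0], "baseline": [-9.0, 0.0, 9.0]})
    wav2 = compute_wav(trials2, baselines=baselines2)  # reported right = baseline(A)
    assert wav2["wav"].iloc[0] == pytest.approx(0.0)


def test_wav_zero_denominator_flagged():
    trials = _mini_trials([{"sA": 9.0, "sV": 0.0}])
    degenerate = pd.DataFrame({"sA": [-9.0, 0.0, 9.0], "baseline": [0.0, 0.0, 0.0]})
    with pytest.raises(ZeroDivisionError):
        compute_wav(trials, baselines=degenerate)


def test_wav_affine_invariance_under_specific_baselines():
    """A constant +9 deg bias on every report cancels with specific baselines."""
    rng = np.random.default_rng(5)
    rows = []
    # congruent trials pin distinct per-position baselines; responses stay in
    # {left, centre} so a one-bin rightward shift never saturates
    for i in range(12):
        rows.append({"sA": -9.0, "sV": -9.0, "response": "left"})
        rows.append({"sA": 0.0, "sV": 0.0,
                     "response": "left" if i % 2 else "centre"})
        rows.append({"sA": 9.0, "sV": 9.0, "response": "centre"})
    for s_a, s_v in [(0.0, -9.0), (9.0, 0.0), (9.0, -9.0)]:
        for _ in range(12):
            rows.append({"sA": s_a, "sV": s_v,
                         "response": rng.choice(["left", "centre"])})
    trials = _mini_trials(rows)
    shifted = trials.copy()
    shifted["response"] = shifted["response"].map({"left": "centre",
                                                   "centre": "right"})
    w_ref = compute_wav(trials, baseline_mode="specific")
    w_shift = compute_wav(shifted, baseline_mode="specific")
    np.testing.assert_allclose(w_ref["wav"].to_numpy(),
                               w_shift["wav"].to_numpy(), atol=1e-12)


def test_wav_cells_shape(small_trials):
    trials, _ = small_trials
    cells = wav_cells(compute_wav(trials, baseline_mode="pooled"))
    assert cells.shape == (1, 8)  # 2 intentions x 2 modalities x 2 disparities


# ---------------------------------------------------------- permutation

def test_permutation_identical_columns_null():
    rng = np.random.default_rng(0)
    x = rng.normal(size=34)
    cells = pd.DataFrame({"a": x, "b": x})
    res = permutation_test(cells, {"a": 1.0, "b": -1.0}, seed=1)
    assert res.observed == pytest.approx(0.0, abs=1e-12)
    assert res.p_value > 0.9
    assert abs(res.effect_size) < 1e-6


def test_permutation_detects_constant_shift():
    rng = np.random.default_rng(1)
    cells = pd.DataFrame({"a": rng.normal(1.0, 0.1, 34),
                          "b": rng.normal(0.0, 0.1, 34)})
    res = permutation_test(cells, {"a": 1.0, "b": -1.0}, n_perm=4096, seed=2)
    assert res.p_value <= 0.001
    assert res.effect_size == pytest.approx(1.0, abs=0.1)
    assert res.ci_low < 1.0 < res.ci_high


def test_permutation_seed_stability():
    """p-values from two seeds differ by at most 2 binomial SEs."""
    rng = np.random.default_rng(2)
    cells = pd.DataFrame({"a": rng.normal(0.25, 1, 34), "b": rng.normal(0, 1, 34)})
    p1 = permutation_test(cells, {"a": 1, "b": -1}, seed=10).p_value
    p2 = permutation_test(cells, {"a": 1, "b": -1}, seed=20).p_value
    se = np.sqrt(p1 * (1 - p1) / 4096)
    assert abs(p1 - p2) <= max(2 * se, 0.01)


def test_permutation_input_validation():
    cells = pd.DataFrame({"a": [1.0, 2.0]})
    with pytest.raises(KeyError):
        permutation_test(cells, {"zzz": 1.0})
    with pytest.raises(ValueError):
        permutation_test(cells, {"a": 1.0}, n_perm=0)


# ---------------------------------------------------------- correlation

def test_pearson_perfect_and_textbook():
    x = np.arange(10.0)
    res = pearson_correlation(x, x)
    assert res.r == pytest.approx(1.0)
    assert res.slope == pytest.approx(1.0)
    # small worked pairs table
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    r_hand = sxy / np.sqrt(np.sum((x - x.mean())**2) * np.sum((y - y.mean())**2))
    res = pearson_correlation(x, y)
    assert res.r == pytest.approx(r_hand, rel=1e-12)
    t = r_hand * np.sqrt(3 / (1 - r_hand**2))
    assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), 3), rel=1e-9)


def test_pearson_null_calibration():
    """Independent pairs reject at about the nominal 5% rate."""
    rng = np.random.default_rng(3)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        res = pearson_correlation(rng.normal(size=34), rng.normal(size=34))
        rejections += res.p_value < 0.05
    assert 0.03 <= rejections / reps <= 0.07


def test_pearson_errors():
    with pytest.raises(ValueError):
        pearson_correlation([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        pearson_correlation(np.ones(5), np.arange(5.0))
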