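"""Random-effects Bayesian model selection at the group level.

Treats the model identity of each participant as a random effect: model
frequencies r in the population carry a Dirichlet prior, each participant's
model is multinomial in r, and per-participant approximate log model
evidences (here -BIC) enter the likelihood.  A variational-Bayes scheme
estimates the Dirichlet posterior; exceedance probabilities come from
Monte-Carlo sampling of that posterior, and the Bayesian Omnibus Risk (BOR)
compares the frequency model against the null of equal frequencies, giving
protected exceedance probabilities pEP = EP * (1 - BOR) + BOR / K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, psi


@dataclass
class BMSResult:
    """Group-level model-selection summary.

    All vectors are aligned with ``models``; expected frequencies and
    exceedance probabilities each sum to one, and
    pEP_k = EP_k * (1 - BOR) + BOR / K.
    """

    models: list
    alpha: np.ndarray
    expected_frequency: np.ndarray
    exceedance_prob: np.ndarray
    protected_exceedance_prob: np.ndarray
    bor: float
    free_energy: float
    free_energy_null: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "alpha": self.alpha,
            "expected_frequency": self.expected_frequency,
            "exceedance_prob": self.exceedance_prob,
            "protected_exceedance_prob": self.protected_exceedance_prob,
        }, index=pd.Index(self.models, name="model"))


def _vb_dirichlet(log_ev: np.ndarray, alpha0: np.ndarray,
                  tol: float = 1e-8, max_iter: int = 10_000):
    """Variational updates for the Dirichlet over model frequencies.

    Returns the posterior concentrations, the participant-wise model
    assignment responsibilities g (N x K) and the free energy of the
    variational approximation.
    """
    n, k = log_ev.shape
    alpha = alpha0.copy()
    for _ in range(max_iter):
        w = log_ev + (psi(alpha) - psi(alpha.sum()))[None, :]
        g = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    # free energy (ELBO) of the Dirichlet-multinomial approximation
    e_log_r = psi(alpha) - psi(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy_g = -np.sum(np.where(g > 0, g * np.log(g), 0.0))
    kl_dir = (gammaln(alpha.sum()) - gammaln(alpha).sum()
              - gammaln(alpha0.sum()) + gammaln(alpha0).sum()
              + np.sum((alpha - alpha0) * e_log_r))
    free_energy = float(np.sum(g * (log_ev + e_log_r[None, :])) + entropy_g - kl_dir)
    return alpha, g, free_energy


def _free_energy_null(log_ev: np.ndarray) -> float:
    """Log evidence of the null model: all frequencies fixed at 1/K."""
    n, k = log_ev.shape
    return float(np.sum(logsumexp(log_ev - np.log(k), axis=1)))


def rfx_bms(evidence, n_samples: int = 100_000, seed: int | None = 0,
            alpha0: float = 1.0) -> BMSResult:
    """Random-effects Bayesian model selection over an evidence matrix.

    Parameters
    ----------
    evidence : DataFrame or array, participants x models
        Approximate log model evidence per participant and model (-BIC).
    n_samples : int
        Dirichlet Monte-Carlo draws for the exceedance probabilities.
    alpha0 : float
        Symmetric Dirichlet prior concentration per model.
    """
    if isinstance(evidence, pd.DataFrame):
        models = list(evidence.columns)
        log_ev = evidence.to_numpy(float)
    else:
        log_ev = np.asarray(evidence, float)
        models = list(range(log_ev.shape[1]))
    if log_ev.ndim != 2 or log_ev.shape[1] < 2:
        raise ValueError("evidence must be participants x (>= 2) models")
    if not np.all(np.isfinite(log_ev)):
        raise ValueError("evidence entries must be finite")

    k = log_ev.shape[1]
    prior = np.full(k, float(alpha0))
    alpha, _, f1 = _vb_dirichlet(log_ev, prior)
    ef = alpha / alpha.sum()

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winner = np.argmax(draws, axis=1)
    ep = np.bincount(winner, minlength=k) / n_samples

    f0 = _free_energy_null(log_ev)
    # posterior probability of the null (equal-frequency) hypothesis
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pep = ep * (1.0 - bor) + bor / k
    return BMSResult(models=models, alpha=alpha, expected_frequency=ef,
                     exceedance_prob=ep, protected_exceedance_prob=pep,
                     bor=bor, free_energy=f1, free_energy_null=f0)
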