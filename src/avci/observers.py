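"""Generative observer models for audiovisual spatial localization.

The observer receives a noisy auditory sample ``x_A`` and a noisy visual
sample ``x_V`` of the true source position(s) and must report the location
of the cued modality.  Four decision architectures are implemented:

``bci``
    Bayesian Causal Inference: infer the posterior probability that both
    signals share a common cause, then model-average the fused and
    segregated location estimates.
``ff``
    Forced Fusion: mandatory reliability-weighted integration (the
    ``p_common = 1`` special case of BCI).
``fc``
    Fixed Criterion: integrate when the internal disparity ``|x_A - x_V|``
    falls below a fixed threshold ``k_C``, segregate otherwise.
``sf``
    Stochastic Fusion: integrate with probability ``eta`` on each trial,
    irrespective of disparity.

All functions are vectorized over numpy arrays of signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

ARCHITECTURES = ("bci", "ff", "fc", "sf")

#: canonical response positions in degrees visual angle
RESPONSE_POSITIONS = np.array([-9.0, 0.0, 9.0])

#: half-open bin edges separating left / centre / right reports
RESPONSE_EDGES = np.array([-4.5, 4.5])

RESPONSE_LABELS = ("left", "centre", "right")


class InvalidParameterError(ValueError):
    """Raised when observer parameters violate their support."""


@dataclass(frozen=True)
class ObserverParams:
    """Generative and decision parameters of one observer.

    Parameters
    ----------
    p_common : float
        Prior probability that the auditory and visual signals share a
        common cause (BCI only). In [0, 1].
    sigma_p : float
        SD of the central spatial prior N(mu_p, sigma_p), degrees. > 0.
    sigma_a : float
        Auditory noise SD, degrees. > 0.
    sigma_v : float
        Visual noise SD, degrees. > 0.
    mu_p : float
        Mean of the spatial prior; fixed at 0 in all fitted configurations.
    k_c : float
        Fixed-criterion integration threshold, degrees. >= 0; used only by
        the ``fc`` architecture.
    eta : float
        Per-trial fusion probability in [0, 1]; used only by ``sf``.
    """

    p_common: float = 0.5
    sigma_p: float = 12.0
    sigma_a: float = 6.0
    sigma_v: float = 1.5
    mu_p: float = 0.0
    k_c: float = 5.0
    eta: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_common <= 1.0):
            raise InvalidParameterError(f"p_common must be in [0,1], got {self.p_common}")
        if not (0.0 <= self.eta <= 1.0):
            raise InvalidParameterError(f"eta must be in [0,1], got {self.eta}")
        for name in ("sigma_p", "sigma_a", "sigma_v"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise InvalidParameterError(f"{name} must be strictly positive, got {value}")
        if self.k_c < 0.0:
            raise InvalidParameterError(f"k_c must be non-negative, got {self.k_c}")

    def replace(self, **changes) -> "ObserverParams":
        return replace(self, **changes)


@dataclass
class EstimateSet:
    """Structure-conditional and final location estimates for a batch of signals."""

    s_hat_c1: np.ndarray
    s_hat_a_c2: np.ndarray
    s_hat_v_c2: np.ndarray
    posterior_c1: np.ndarray
    s_hat_a: np.ndarray
    s_hat_v: np.ndarray


def _log_lik_common(x_a, x_v, p: ObserverParams):
    # p(x_A, x_V | C=1) = Int N(x_V; s, sV) N(x_A; s, sA) N(s; muP, sP) ds
    va, vv, vp = p.sigma_a**2, p.sigma_v**2, p.sigma_p**2
    det = va * vv + va * vp + vv * vp
    quad = ((x_v - x_a) ** 2 * vp
            + (x_v - p.mu_p) ** 2 * va
            + (x_a - p.mu_p) ** 2 * vv) / det
    return -np.log(2.0 * np.pi * np.sqrt(det)) - 0.5 * quad


def _log_lik_separate(x_a, x_v, p: ObserverParams):
    # p(x_A, x_V | C=2): independent sources each drawn from the spatial prior
    va, vv, vp = p.sigma_a**2, p.sigma_v**2, p.sigma_p**2
    det = (va + vp) * (vv + vp)
    quad = (x_a - p.mu_p) ** 2 / (va + vp) + (x_v - p.mu_p) ** 2 / (vv + vp)
    return -np.log(2.0 * np.pi * np.sqrt(det)) - 0.5 * quad


def posterior_common_cause(x_a, x_v, params: ObserverParams):
    """Posterior probability p(C=1 | x_A, x_V) of a common cause.

    Combines the common-cause prior with the marginal likelihoods of the
    signal pair under the one-source and two-source generative structures
    (sources drawn from the spatial prior, signals corrupted by independent
    Gaussian noise); both marginals are Gaussian and evaluated in closed form.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_v = np.asarray(x_v, dtype=float)
    if params.p_common == 1.0:
        return np.ones(np.broadcast(x_a, x_v).shape)
    if params.p_common == 0.0:
        return np.zeros(np.broadcast(x_a, x_v).shape)
    log_l1 = _log_lik_common(x_a, x_v, params) + np.log(params.p_common)
    log_l2 = _log_lik_separate(x_a, x_v, params) + np.log1p(-params.p_common)
    # logistic of the log odds; numerically stable for large gaps
    return expit(log_l1 - log_l2)


def fused_estimate(x_a, x_v, params: ObserverParams):
    """Reliability-weighted common-cause estimate of the source position.

    Precision-weighted average of the two signals and the spatial prior.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_v = np.asarray(x_v, dtype=float)
    wa = params.sigma_a ** -2
    wv = params.sigma_v ** -2
    wp = params.sigma_p ** -2
    return (x_a * wa + x_v * wv + params.mu_p * wp) / (wa + wv + wp)


def segregated_estimates(x_a, x_v, params: ObserverParams):
    """Independent-cause estimates (S_hat_A, S_hat_V), each shrunk toward the prior."""
    x_a = np.asarray(x_a, dtype=float)
    x_v = np.asarray(x_v, dtype=float)
    wp = params.mu_p * params.sigma_p ** -2
    wa = params.sigma_a ** -2
    wv = params.sigma_v ** -2
    s_a = (x_a * wa + wp) / (wa + params.sigma_p ** -2)
    s_v = (x_v * wv + wp) / (wv + params.sigma_p ** -2)
    return s_a, s_v


def final_estimates(x_a, x_v, params: ObserverParams, architecture: str = "bci",
                    fusion_draw=None) -> EstimateSet:
    """Apply an architecture's decision rule to noisy internal signals.

    Parameters
    ----------
    architecture : {'bci', 'ff', 'fc', 'sf'}
        Decision strategy. BCI model-averages fused and segregated estimates
        by the common-cause posterior; FF always fuses; FC fuses iff the
        internal disparity ``|x_A - x_V|`` is at most ``k_c``; SF fuses iff
        ``fusion_draw < eta``.
    fusion_draw : array-like of float in [0, 1), required for 'sf'
        Per-trial uniform variates governing the stochastic fusion choice.
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}; expected one of {ARCHITECTURES}")
    x_a = np.asarray(x_a, dtype=float)
    x_v = np.asarray(x_v, dtype=float)
    fused = fused_estimate(x_a, x_v, params)
    seg_a, seg_v = segregated_estimates(x_a, x_v, params)

    if architecture == "bci":
        post = posterior_common_cause(x_a, x_v, params)
        s_a = post * fused + (1.0 - post) * seg_a
        s_v = post * fused + (1.0 - post) * seg_v
    elif architecture == "ff":
        post = np.ones(fused.shape)
        s_a = fused
        s_v = fused
    elif architecture == "fc":
        fuse = np.abs(x_a - x_v) <= params.k_c
        post = fuse.astype(float)
        s_a = np.where(fuse, fused, seg_a)
        s_v = np.where(fuse, fused, seg_v)
    else:  # sf
        if fusion_draw is None:
            raise ValueError("the 'sf' architecture requires a fusion_draw array")
        fuse = np.asarray(fusion_draw, dtype=float) < params.eta
        post = fuse.astype(float)
        s_a = np.where(fuse, fused, seg_a)
        s_v = np.where(fuse, fused, seg_v)

    return EstimateSet(
        s_hat_c1=fused,
        s_hat_a_c2=seg_a,
        s_hat_v_c2=seg_v,
        posterior_c1=post,
        s_hat_a=s_a,
        s_hat_v=s_v,
    )


def discretize_response(estimate):
    """Map continuous location estimates to response bins 0/1/2 (left/centre/right).

    Bins are nearest-position intervals around the three response options
    -9/0/+9 degrees: (-inf, -4.5) -> left, [-4.5, 4.5) -> centre,
    [4.5, inf) -> right.
    """
    estimate = np.asarray(estimate, dtype=float)
    return np.digitize(estimate, RESPONSE_EDGES, right=False)


def response_to_degrees(response_index):
    """Convert response bin indices (0/1/2) to their positions in degrees."""
    return RESPONSE_POSITIONS[np.asarray(response_index, dtype=int)]
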