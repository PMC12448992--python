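"""Maximum-likelihood fitting of observer models to localization counts.

Each architecture's predicted response distribution has no closed form, so
it is obtained by forward simulation: internal signals are drawn many times
per condition, passed through the decision rule, and discretized; relative
frequencies give the multinomial category probabilities.  Common random
numbers (a fixed standard-normal substream per condition, rescaled by the
current noise SDs) make the objective a deterministic function of the
parameters, which a coarse grid search plus Nelder-Mead simplex can then
optimize reliably.

Model space: 4 architectures (bci / ff / fc / sf) x 2 parameterizations
('pooled' shares one parameter set across action intentions, 'separated'
fits each intention its own set).  Goodness of fit is summarized by a
likelihood-based R^2 scaled by its attainable maximum under discrete
three-alternative responses, and model evidence is approximated by BIC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .observers import (
    ARCHITECTURES,
    InvalidParameterError,
    ObserverParams,
    discretize_response,
    final_estimates,
)
from .simulate import INTENTIONS, MODALITIES, POSITIONS

#: canonical ordering of the 9 spatial combinations
SPATIAL_COMBOS = [(a, v) for a in POSITIONS for v in POSITIONS]

#: canonical ordering of the 18 (modality, sA, sV) conditions
CONDITIONS = [(m, a, v) for m in MODALITIES for (a, v) in SPATIAL_COMBOS]

RESPONSE_ORDER = ["left", "centre", "right"]

#: free parameters per architecture (order fixes the optimization vector)
FREE_PARAMS = {
    "bci": ("p_common", "sigma_p", "sigma_a", "sigma_v"),
    "ff": ("sigma_p", "sigma_a", "sigma_v"),
    "fc": ("k_c", "sigma_p", "sigma_a", "sigma_v"),
    "sf": ("eta", "sigma_p", "sigma_a", "sigma_v"),
}

_LOGIT_PARAMS = {"p_common", "eta"}

#: default grid-search values in natural units
DEFAULT_GRID = {
    "p_common": (0.1, 0.3, 0.5, 0.7, 0.9),
    "eta": (0.1, 0.3, 0.5, 0.7, 0.9),
    "sigma_p": tuple(np.geomspace(2.0, 32.0, 4)),
    "sigma_a": tuple(np.geomspace(0.5, 32.0, 6)),
    "sigma_v": tuple(np.geomspace(0.5, 32.0, 6)),
    "k_c": (1.0, 5.0, 10.0, 20.0),
}


def response_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Tabulate left/centre/right counts per (intention, modality, sA, sV).

    Missing conditions get zero rows; trials whose response is not one of
    the three options (e.g. 'missed') are ignored.
    """
    valid = trials[trials["response"].isin(RESPONSE_ORDER)]
    table = (valid.groupby(["intention", "modality", "sA", "sV"])["response"]
             .value_counts().unstack(fill_value=0))
    index = pd.MultiIndex.from_tuples(
        [(i, m, a, v) for i in INTENTIONS for (m, a, v) in CONDITIONS],
        names=["intention", "modality", "sA", "sV"])
    table = table.reindex(index, fill_value=0).reindex(columns=RESPONSE_ORDER, fill_value=0)
    return table.astype(int)


def _count_matrix(counts: pd.DataFrame, intention: str | None) -> np.ndarray:
    """Collapse a counts table to an (18, 3) matrix in canonical condition order."""
    if intention is not None:
        sub = counts.xs(intention, level="intention")
    else:  # pooled: category probabilities do not depend on intention
        sub = counts.groupby(level=["modality", "sA", "sV"]).sum()
    sub = sub.reindex(pd.MultiIndex.from_tuples(CONDITIONS,
                                                names=["modality", "sA", "sV"]),
                      fill_value=0)
    return sub[RESPONSE_ORDER].to_numpy(float)


class _SimulationContext:
    """Frozen random substreams for deterministic likelihood evaluation.

    One standard-normal draw pair and one uniform fusion draw per spatial
    combination and simulation; rescaling by the candidate noise SDs yields
    the internal signals, so two evaluations at the same parameters are
    bit-identical.
    """

    def __init__(self, n_sim: int, seed: int | None, prob_floor: float | None = None):
        if n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        rng = np.random.default_rng(seed)
        k = len(SPATIAL_COMBOS)
        self.n_sim = n_sim
        self.z_a = rng.standard_normal((k, n_sim))
        self.z_v = rng.standard_normal((k, n_sim))
        self.u = rng.random((k, n_sim))
        self.s_a = np.array([c[0] for c in SPATIAL_COMBOS])[:, None]
        self.s_v = np.array([c[1] for c in SPATIAL_COMBOS])[:, None]
        self.floor = 1.0 / (10.0 * n_sim) if prob_floor is None else prob_floor

    def predict(self, params: ObserverParams, architecture: str) -> np.ndarray:
        """Predicted probabilities, shape (18, 3) in canonical condition order."""
        x_a = self.s_a + params.sigma_a * self.z_a
        x_v = self.s_v + params.sigma_v * self.z_v
        est = final_estimates(x_a, x_v, params, architecture, fusion_draw=self.u)
        probs = np.empty((2, len(SPATIAL_COMBOS), 3))
        for m, estimates in enumerate((est.s_hat_a, est.s_hat_v)):
            resp = discretize_response(estimates)
            for c in range(3):
                probs[m, :, c] = (resp == c).mean(axis=1)
        probs = probs.reshape(-1, 3)
        if self.floor > 0.0:
            probs = np.maximum(probs, self.floor)
            probs /= probs.sum(axis=1, keepdims=True)
        return probs


def predict_response_distribution(params: ObserverParams, architecture: str = "bci",
                                  n_sim: int = 10_000, seed: int | None = 0,
                                  prob_floor: float | None = None) -> pd.DataFrame:
    """Simulate a model's response distribution for all 18 conditions.

    Returns a DataFrame indexed by (modality, sA, sV) with columns
    left/centre/right; rows sum to one and every entry is strictly positive
    (floored at 1/(10*n_sim) by default, then renormalized).
    """
    ctx = _SimulationContext(n_sim, seed, prob_floor)
    probs = ctx.predict(params, architecture)
    index = pd.MultiIndex.from_tuples(CONDITIONS, names=["modality", "sA", "sV"])
    return pd.DataFrame(probs, index=index, columns=RESPONSE_ORDER)


def log_likelihood(counts: np.ndarray, probs: np.ndarray) -> float:
    """Multinomial log-likelihood sum_conditions sum_categories n_ij log p_ij.

    The multinomial coefficient is omitted: it is constant in the parameters
    and cancels from likelihood differences.
    """
    counts = np.asarray(counts, float)
    probs = np.asarray(probs, float)
    if counts.shape != probs.shape:
        raise ValueError(f"shape mismatch: counts {counts.shape} vs probs {probs.shape}")
    if np.any(probs <= 0.0):
        raise ValueError("predicted probabilities must be strictly positive")
    return float(np.sum(counts * np.log(probs)))


def r_squared(log_lik: float, n: int) -> tuple[float, float, float]:
    """Likelihood-based coefficient of determination against the uniform null.

    R^2 = 1 - exp(-(2/n)(l_fit - l_0)) with l_0 = n ln(1/3) for a random
    three-choice responder; the scaled value divides by the attainable
    maximum max(R^2) = 1 - exp((2/n) l_0).  Returns (scaled, raw, max).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    l0 = n * np.log(1.0 / 3.0)
    raw = 1.0 - np.exp(-(2.0 / n) * (log_lik - l0))
    rmax = 1.0 - np.exp((2.0 / n) * l0)
    return raw / rmax, raw, rmax


def bic(log_lik: float, k: int, n: int, conventional: bool = False) -> float:
    """Bayesian Information Criterion as an approximation to -log evidence.

    The default form is -ln(L) + k ln(n); ``conventional=True`` uses the
    textbook -2 ln(L) + k ln(n).  Lower is better in both conventions.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    scale = 2.0 if conventional else 1.0
    return float(-scale * log_lik + k * np.log(n))


def _to_transformed(values: dict, names) -> np.ndarray:
    out = []
    for name in names:
        v = values[name]
        if name in _LOGIT_PARAMS:
            v = np.clip(v, 1e-6, 1 - 1e-6)
            out.append(np.log(v) - np.log1p(-v))
        else:
            out.append(np.log(v))
    return np.array(out)


def _from_transformed(theta: np.ndarray, names) -> dict:
    out = {}
    for name, t in zip(names, theta):
        if name in _LOGIT_PARAMS:
            out[name] = float(1.0 / (1.0 + np.exp(-t)))
        else:
            out[name] = float(np.exp(np.clip(t, -20.0, 20.0)))
    return out


@dataclass
class FitResult:
    """Outcome of fitting one model to one participant's counts."""

    architecture: str
    parameterization: str
    params: dict
    log_lik: float
    r2_scaled: float
    r2_raw: float
    bic: float
    n: int
    k: int
    converged: bool
    n_eval: int = 0

    @property
    def log_evidence(self) -> float:
        """Approximate log model evidence used by group-level selection."""
        return -self.bic


class ObserverModelEstimator(BaseEstimator):
    """Per-participant observer-model fit with a scikit-learn interface.

    Parameters
    ----------
    architecture : {'bci', 'ff', 'fc', 'sf'}
        Decision strategy of the generative observer.
    parameterization : {'pooled', 'separated'}
        Whether one parameter set covers both action intentions or each
        intention is fitted its own set (doubling k).
    n_sim : int
        Simulations per condition for the predicted response distribution.
    seed : int
        Seed of the frozen simulation substreams (common random numbers).
    prob_floor : float or None
        Lower bound on predicted category probabilities before
        renormalization; default 1/(10*n_sim).
    grid : dict or None
        Per-parameter grid values overriding the defaults.
    n_starts : int
        Number of best grid points used to seed simplex runs.
    bic_conventional : bool
        Use -2 ln L + k ln n instead of the default -ln L + k ln n.

    Attributes
    ----------
    params_ : dict
        Fitted parameters; for 'separated', one sub-dict per intention.
    log_lik_, r2_, r2_raw_, bic_, n_, k_, converged_ : fit diagnostics.
    result_ : FitResult
    """

    def __init__(self, architecture: str = "bci", parameterization: str = "pooled",
                 n_sim: int = 10_000, seed: int = 0, prob_floor: float | None = None,
                 grid: dict | None = None, n_starts: int = 3,
                 n_sim_refine: int | None = None,
                 optimizer_opts: dict | None = None, bic_conventional: bool = False):
        self.architecture = architecture
        self.parameterization = parameterization
        self.n_sim = n_sim
        self.seed = seed
        self.prob_floor = prob_floor
        self.grid = grid
        self.n_starts = n_starts
        self.n_sim_refine = n_sim_refine
        self.optimizer_opts = optimizer_opts
        self.bic_conventional = bic_conventional

    # -- internal ---------------------------------------------------------
    def _context(self) -> _SimulationContext:
        return _SimulationContext(self.n_sim, self.seed, self.prob_floor)

    def _refine_n(self) -> int:
        """Simulations for the final polish stage (0 disables it).

        The coarse grid/simplex stage runs at ``n_sim``; a second short
        simplex from the found optimum at a larger simulation count reduces
        the Monte-Carlo bias of the maximum-likelihood point at a fraction
        of the cost of running everything at the larger count.
        """
        if self.n_sim_refine is not None:
            return int(self.n_sim_refine)
        return min(5 * self.n_sim, 20_000)

    def _refine_context(self) -> _SimulationContext:
        n_ref = self._refine_n()
        if n_ref <= self.n_sim:
            return self._context()
        return _SimulationContext(n_ref, self.seed + 1, self.prob_floor)

    def _grid_values(self, name: str):
        if self.grid and name in self.grid:
            return tuple(self.grid[name])
        return DEFAULT_GRID[name]

    def _fit_one(self, counts_mat: np.ndarray, ctx: _SimulationContext,
                 ctx_refine: _SimulationContext):
        """Grid search + simplex over one parameter set against an (18,3) count matrix."""
        names = FREE_PARAMS[self.architecture]

        def make_objective(context):
            def objective(theta):
                values = _from_transformed(theta, names)
                try:
                    params = ObserverParams(**values)
                except InvalidParameterError:
                    return np.inf
                return -log_likelihood(counts_mat,
                                       context.predict(params, self.architecture))
            return objective

        objective = make_objective(ctx)
        n_eval = 0
        grid_axes = [self._grid_values(name) for name in names]
        scored = []
        for point in itertools.product(*grid_axes):
            theta = _to_transformed(dict(zip(names, point)), names)
            scored.append((objective(theta), theta))
            n_eval += 1
        scored.sort(key=lambda t: t[0])

        opts = {"xatol": 1e-3, "fatol": 1e-4, "maxiter": 2000}
        if self.optimizer_opts:
            opts.update(self.optimizer_opts)
        best = None
        converged = False
        for _, theta0 in scored[: self.n_starts]:
            res = minimize(objective, theta0, method="Nelder-Mead", options=opts)
            n_eval += res.nfev
            key = (res.fun, float(np.linalg.norm(res.x)))  # tie-break: smaller norm
            if best is None or key < best[0]:
                best = (key, res.x)
                converged = bool(res.success)

        theta_best = best[1]
        if ctx_refine is not ctx:
            objective_ref = make_objective(ctx_refine)
            res = minimize(objective_ref, theta_best, method="Nelder-Mead", options=opts)
            n_eval += res.nfev
            theta_best = res.x
            fun_best = res.fun
            converged = converged and bool(res.success)
        else:
            fun_best = best[0][0]

        values = _from_transformed(theta_best, names)
        params = ObserverParams(**values)
        return {name: values[name] for name in names}, params, -fun_best, converged, n_eval

    # -- sklearn API ------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        """Fit the model to one participant's trials or response counts.

        ``X`` is either a tidy trial table (with intention, modality, sA,
        sV, response columns) or the counts table from
        :func:`response_counts`.
        """
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.parameterization not in ("pooled", "separated"):
            raise ValueError(f"unknown parameterization {self.parameterization!r}")
        counts = X if isinstance(X.index, pd.MultiIndex) else response_counts(X)
        ctx = self._context()
        ctx_refine = self._refine_context()
        k_single = len(FREE_PARAMS[self.architecture])
        n = int(counts.to_numpy().sum())
        if n == 0:
            raise ValueError("no valid trials to fit")

        if self.parameterization == "pooled":
            mat = _count_matrix(counts, None)
            values, params, ll, converged, n_eval = self._fit_one(mat, ctx, ctx_refine)
            self.params_ = values
            self._observer_params_ = {i: params for i in INTENTIONS}
            k = k_single
        else:
            self.params_ = {}
            self._observer_params_ = {}
            ll, converged, n_eval = 0.0, True, 0
            for intention in INTENTIONS:
                mat = _count_matrix(counts, intention)
                values, params, ll_i, conv_i, ne = self._fit_one(mat, ctx, ctx_refine)
                self.params_[intention] = values
                self._observer_params_[intention] = params
                ll += ll_i
                converged = converged and conv_i
                n_eval += ne
            k = 2 * k_single

        self.log_lik_ = ll
        self.n_ = n
        self.k_ = k
        self.converged_ = converged
        self.r2_, self.r2_raw_, self.r2_max_ = r_squared(ll, n)
        self.bic_ = bic(ll, k, n, self.bic_conventional)
        self.result_ = FitResult(self.architecture, self.parameterization,
                                 self.params_, ll, self.r2_, self.r2_raw_,
                                 self.bic_, n, k, converged, n_eval)
        return self

    def predict_proba(self, intention: str = "communicative") -> pd.DataFrame:
        """Fitted model's predicted response distribution for one intention."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "params_")
        return predict_response_distribution(self._observer_params_[intention],
                                             self.architecture, self.n_sim,
                                             self.seed, self.prob_floor)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Log-likelihood of (possibly new) counts under the fitted parameters."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "params_")
        counts = X if isinstance(X.index, pd.MultiIndex) else response_counts(X)
        return self.score_params(counts, self._observer_params_)

    def score_params(self, counts: pd.DataFrame, params_by_intention) -> float:
        """Objective value at externally supplied parameters.

        Uses the same simulation substreams that produced the reported
        optimum, so values are directly comparable with ``log_lik_``.
        """
        ctx = self._refine_context()
        if self.parameterization == "pooled":
            any_params = (params_by_intention if isinstance(params_by_intention, ObserverParams)
                          else next(iter(params_by_intention.values())))
            return log_likelihood(_count_matrix(counts, None),
                                  ctx.predict(any_params, self.architecture))
        total = 0.0
        for intention in INTENTIONS:
            total += log_likelihood(_count_matrix(counts, intention),
                                    ctx.predict(params_by_intention[intention],
                                                self.architecture))
        return total


def fit_model(counts: pd.DataFrame, architecture: str = "bci",
              parameterization: str = "pooled", n_sim: int = 10_000,
              seed: int = 0, **kwargs) -> FitResult:
    """Functional wrapper over :class:`ObserverModelEstimator`."""
    est = ObserverModelEstimator(architecture, parameterization, n_sim=n_sim,
                                 seed=seed, **kwargs)
    est.fit(counts)
    return est.result_


def model_space(architectures=("bci", "ff"), parameterizations=("pooled", "separated")):
    """Factorial list of (architecture, parameterization) model labels."""
    return [(a, p) for a in architectures for p in parameterizations]


def fit_participants(trials: pd.DataFrame, models=None, n_sim: int = 10_000,
                     seed: int = 0, **kwargs) -> pd.DataFrame:
    """Fit a set of models to every participant in a trial table.

    Returns a tidy table with one row per participant x model carrying k, n,
    log-likelihood, scaled R^2, BIC and the fitted parameters (JSON-ish dict
    in the ``params`` column).  Per-participant seeds are derived from
    ``seed`` so the common random numbers differ across participants but are
    reproducible.
    """
    if models is None:
        models = model_space()
    rows = []
    for pid, sub in trials.groupby("participant"):
        counts = response_counts(sub)
        for arch, param in models:
            fit = fit_model(counts, arch, param, n_sim=n_sim,
                            seed=(seed + 7919 * int(pid)) % (2**31), **kwargs)
            rows.append({"participant": pid, "architecture": arch,
                         "parameterization": param,
                         "model": f"{arch}_{param}",
                         "k": fit.k, "n": fit.n, "logLik": fit.log_lik,
                         "R2": fit.r2_scaled, "BIC": fit.bic,
                         "converged": fit.converged, "params": fit.params})
    return pd.DataFrame(rows)


def evidence_matrix(fits: pd.DataFrame) -> pd.DataFrame:
    """Pivot a fit table to participants x models of approximate log evidence (-BIC)."""
    return fits.pivot(index="participant", columns="model", values="BIC").mul(-1.0)
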