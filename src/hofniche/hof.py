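"""Huisman-Olff-Fresco (HOF) response-curve modeling and niche-optimum extraction.

A species' (here: an OTU's) relative abundance along an environmental gradient
is modeled by a hierarchy of logistic response shapes of increasing
complexity:

    I    flat:               p(x) = M / (1 + e^a)
    II   monotone sigmoid:   p(x) = M / (1 + e^(a + b x))
    III  sigmoid + plateau:  p(x) = M / [(1 + e^(a + b x)) (1 + e^c)]
    IV   symmetric unimodal: p(x) = M / [(1 + e^(a + b x)) (1 + e^(c - b x))]
    V    skewed unimodal:    p(x) = M / [(1 + e^(a + b x)) (1 + e^(c + d x))]

with M the maximum attainable response (fixed at 1 for proportions) and x the
gradient rescaled internally to the centered interval [-0.5, 0.5].  log p(x) is concave in x for every
model, so each curve is unimodal and the abundance peak — the *niche optimum*
— is unique.  The best shape per OTU x variable is chosen by small-sample AIC
(AICc) stabilized by bootstrap resampling of sites; when the flat model I wins,
no optimum is defined.

The bimodal extensions of the hierarchy (VI, VII) are deliberately not
implemented.

Estimator classes follow scikit-learn conventions (``fit``/``predict``,
``get_params``, fitted attributes with trailing underscore) and the
module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "MODEL_ORDER",
    "HOFCurve",
    "NicheModel",
    "HOFFit",
    "NicheOptimum",
    "fit_hof_model",
    "select_hof_model",
    "extract_optimum",
    "niche_width",
    "optimum_matrix",
    "prevalence_filter",
]

MODEL_ORDER = ("I", "II", "III", "IV", "V")
_N_PARAMS = {"I": 1, "II": 2, "III": 3, "IV": 3, "V": 4}

_INNER_NICHE_FRACTION = math.exp(-0.5)

# optimizer bounds on the internal centered gradient scale
_BOUND_INTERCEPT = 30.0
_BOUND_SLOPE = 200.0


def _to_internal(x: np.ndarray) -> np.ndarray:
    """Map the public [1, 100] gradient scale to the internal centered
    [-0.5, 0.5] scale (zero at the gradient midpoint 50.5, so a symmetric
    model IV with a = c peaks exactly at the midpoint)."""
    return (np.asarray(x, dtype=float) - 50.5) / 99.0


def _to_public(x01) -> float:
    return 50.5 + 99.0 * float(x01)


def _log_response(model: str, params: np.ndarray, x01: np.ndarray, m: float):
    """log p(x) for a parameter vector on the internal scale; vectorized."""
    if model == "I":
        u1 = np.full_like(x01, params[0])
        u2 = None
    elif model == "II":
        u1 = params[0] + params[1] * x01
        u2 = None
    elif model == "III":
        u1 = params[0] + params[1] * x01
        u2 = np.full_like(x01, params[2])
    elif model == "IV":
        u1 = params[0] + params[1] * x01
        u2 = params[2] - params[1] * x01
    elif model == "V":
        u1 = params[0] + params[1] * x01
        u2 = params[2] + params[3] * x01
    else:
        raise ValueError(f"unknown HOF model type {model!r}")
    lp = -np.logaddexp(0.0, u1)
    if u2 is not None:
        lp = lp - np.logaddexp(0.0, u2)
    return lp + math.log(m)


def _binom_nll(params, model, x01, k, n, m):
    lp = _log_response(model, params, x01, m)
    lp = np.minimum(lp, -1e-12)
    l1p = np.log1p(-np.exp(lp))
    return -float(np.sum(k * lp + (n - k) * l1p))


def _sigmoid(u):
    return 0.5 * (1.0 + np.tanh(0.5 * u))


def _binom_nll_grad(params, model, x01, k, n, m):
    """Value and analytic gradient of the binomial NLL.

    d/dtheta = -sum (k - n p)/(1 - p) * dlogp/dtheta, with dlogp/du_i = -sigmoid(u_i).
    """
    if model == "I":
        u1, u2 = np.full_like(x01, params[0]), None
        du1 = (np.ones_like(x01),)
        du2 = (None,)
    elif model == "II":
        u1, u2 = params[0] + params[1] * x01, None
        du1 = (np.ones_like(x01), x01)
        du2 = (None, None)
    elif model == "III":
        u1, u2 = params[0] + params[1] * x01, np.full_like(x01, params[2])
        du1 = (np.ones_like(x01), x01, None)
        du2 = (None, None, np.ones_like(x01))
    elif model == "IV":
        u1, u2 = params[0] + params[1] * x01, params[2] - params[1] * x01
        du1 = (np.ones_like(x01), x01, None)
        du2 = (None, -x01, np.ones_like(x01))
    else:  # V
        u1, u2 = params[0] + params[1] * x01, params[2] + params[3] * x01
        du1 = (np.ones_like(x01), x01, None, None)
        du2 = (None, None, np.ones_like(x01), x01)
    lp = -np.logaddexp(0.0, u1) + math.log(m)
    s2 = None
    if u2 is not None:
        lp = lp - np.logaddexp(0.0, u2)
        s2 = _sigmoid(u2)
    lp = np.minimum(lp, -1e-12)
    p = np.exp(lp)
    nll = -float(np.sum(k * lp + (n - k) * np.log1p(-p)))
    w = (k - n * p) / (1.0 - p)
    s1 = _sigmoid(u1)
    grad = np.empty(len(params))
    for i in range(len(params)):
        dlp = np.zeros_like(x01)
        if du1[i] is not None:
            dlp -= s1 * du1[i]
        if u2 is not None and du2[i] is not None:
            dlp -= s2 * du2[i]
        grad[i] = -float(np.sum(w * dlp))
    return nll, grad


def _gauss_nll(params, model, x01, k, n, m):
    # least squares on observed proportions; profile out sigma
    resid = k / n - np.exp(_log_response(model, params, x01, m))
    rss = float(np.dot(resid, resid))
    nobs = x01.size
    rss = max(rss, 1e-300)
    return 0.5 * nobs * (math.log(2.0 * math.pi * rss / nobs) + 1.0)


def _bounds(model: str):
    bi, bs = _BOUND_INTERCEPT, _BOUND_SLOPE
    table = {
        "I": [(-bi, bi)],
        "II": [(-bi, bi), (-bs, bs)],
        "III": [(-bi, bi), (-bs, bs), (-bi, bi)],
        "IV": [(-bi, bi), (-bs, bs), (-bi - bs, bi + bs)],
        "V": [(-bi - bs, bi + bs), (-bs, bs), (-bi - bs, bi + bs), (-bs, bs)],
    }
    return table[model]


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1.0 - 1e-9)
    return math.log((1.0 - p) / p)  # note: a with p = 1/(1+e^a)


def _starts(model: str, x01, k, n, m, nested: dict) -> list[np.ndarray]:
    """Deterministic coarse-grid starting points, including the best nested
    solution so the log-likelihood is non-decreasing up the model hierarchy."""
    prop = k / n
    pbar = float(np.clip(prop.mean() / m, 1e-6, 1 - 1e-6))
    pmax = float(np.clip(prop.max() / m, 1e-6, 1 - 1e-6))
    a_flat = _logit(pbar)
    s_peak = _logit(pmax)
    # peak height of a unimodal curve 1/(1+e^s)^2 at its optimum
    s_uni = math.log(max(1.0 / math.sqrt(pmax) - 1.0, 1e-9))
    starts: list[np.ndarray] = []
    if model == "I":
        starts = [np.array([a_flat]), np.array([0.0])]
    elif model == "II":
        for b in (-20.0, -5.0, 5.0, 20.0):
            starts.append(np.array([a_flat, b]))
        if "I" in nested:
            starts.append(np.array([nested["I"][0], 0.0]))
    elif model == "III":
        c0 = _logit(pmax)
        for b in (-20.0, -5.0, 5.0, 20.0):
            starts.append(np.array([a_flat, b, c0]))
        if "II" in nested:
            aII, bII = nested["II"]
            starts.append(np.array([aII, bII, -_BOUND_INTERCEPT]))
    elif model == "IV":
        for mpos in (-0.35, -0.15, 0.0, 0.15, 0.35):
            b = 8.0
            starts.append(np.array([s_uni - b * mpos, b, s_uni + b * mpos]))
        if "II" in nested:
            aII, bII = nested["II"]
            starts.append(
                np.array([aII, bII, -_BOUND_INTERCEPT - abs(bII) - 1.0])
            )
    elif model == "V":
        for mpos in (-0.3, -0.15, 0.0, 0.15, 0.3):
            b, d = -10.0, 10.0
            starts.append(
                np.array([s_uni - b * mpos, b, s_uni - d * mpos, d])
            )
        if "IV" in nested:
            aIV, bIV, cIV = nested["IV"]
            starts.append(np.array([aIV, bIV, cIV, -bIV]))
        if "II" in nested:
            aII, bII = nested["II"]
            starts.append(
                np.array([aII, bII, -_BOUND_INTERCEPT - abs(bII) - 1.0, 0.0])
            )
    return starts


@dataclass
class HOFFit:
    """A fitted HOF response curve for one OTU along one gradient."""

    model_type: str
    params: np.ndarray            # shape coefficients (a[,b[,c[,d]]]), internal scale
    max_response: float           # M
    loglik: float
    aicc: float
    n_obs: int
    family: str = "binomial"
    converged: bool = True
    bootstrap_support: Optional[float] = None
    unmodelable: bool = False

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.model_type]

    def predict(self, x) -> np.ndarray:
        """Expected response at gradient positions ``x`` on the [1, 100] scale."""
        return np.exp(
            _log_response(
                self.model_type, self.params, _to_internal(x), self.max_response
            )
        )

    def log_response_internal(self, x01) -> np.ndarray:
        return _log_response(
            self.model_type, self.params, np.asarray(x01, dtype=float), self.max_response
        )


@dataclass
class NicheOptimum:
    """Extracted niche optimum and inner-niche interval on the [1, 100] scale."""

    optimum: Optional[float]          # None when model I (no optimum defined)
    lo: Optional[float] = None
    hi: Optional[float] = None
    model_type: str = "I"
    clamped: bool = False

    @property
    def defined(self) -> bool:
        return self.optimum is not None


def _aicc(loglik: float, k: int, n: int) -> float:
    aic = -2.0 * loglik + 2.0 * k
    denom = n - k - 1
    if denom <= 0:
        return math.inf
    return aic + 2.0 * k * (k + 1) / denom


def _optimize_model(model, start_list, x01, k, n, m, family):
    """Best L-BFGS-B solution over a list of starts (analytic gradient for the
    binomial family)."""
    bounds = _bounds(model)
    lo = [b[0] for b in bounds]
    hi = [b[1] for b in bounds]
    best = None
    for p0 in start_list:
        p0 = np.clip(p0, lo, hi)
        if family == "binomial":
            res = optimize.minimize(
                _binom_nll_grad, p0, args=(model, x01, k, n, m),
                method="L-BFGS-B", jac=True, bounds=bounds,
            )
        else:
            res = optimize.minimize(
                _gauss_nll, p0, args=(model, x01, k, n, m),
                method="L-BFGS-B", bounds=bounds,
            )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("HOF optimization failed from every start")
    return best


def _validate_xy(x, counts, totals):
    x = np.asarray(x, dtype=float).ravel()
    k = np.asarray(counts, dtype=float).ravel()
    if totals is None:
        n = np.ones_like(k)
    else:
        n = np.asarray(totals, dtype=float).ravel()
        if n.size == 1:
            n = np.full_like(k, float(n))
    if not (x.size == k.size == n.size):
        raise ValueError("x, counts and totals must have equal length")
    ok = np.isfinite(x) & np.isfinite(k) & np.isfinite(n)
    x, k, n = x[ok], k[ok], n[ok]
    if np.any(n <= 0):
        raise ValueError("totals must be positive")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("counts must lie in [0, totals]")
    if k.sum() == 0:
        raise ValueError("all-zero counts: no signal to model")
    return x, k, n


class HOFCurve(RegressorMixin, BaseEstimator):
    """Single HOF response curve of a fixed shape, fitted by maximum likelihood.

    Parameters
    ----------
    model_type : {"I", "II", "III", "IV", "V"}
        Response shape to fit.
    max_response : float, default=1.0
        Upper bound M of the response (1 for proportions).
    family : {"binomial", "gaussian"}, default="binomial"
        Error model: binomial counts out of per-site totals, or Gaussian
        least squares on the observed proportions.

    Attributes
    ----------
    params_ : ndarray
        Fitted shape coefficients on the internal [0, 1] gradient scale.
    loglik_, aicc_ : float
        Maximized log-likelihood and small-sample-corrected AIC.
    fit_result_ : HOFFit
        The full fit record.
    """

    def __init__(self, model_type: str = "IV", max_response: float = 1.0,
                 family: str = "binomial"):
        self.model_type = model_type
        self.max_response = max_response
        self.family = family

    def fit(self, X, y, totals=None, starts=None):
        """Fit the curve.

        Parameters
        ----------
        X : array-like, shape (n_sites,) or (n_sites, 1)
            Gradient positions on the [1, 100] scale.
        y : array-like
            Read counts per site (binomial family) or proportions
            (``totals=None``).
        totals : array-like or scalar, optional
            Binomial trials per site (per-site total reads).
        starts : list of ndarray, optional
            Extra starting points (internal scale) added to the deterministic
            coarse grid.
        """
        if self.model_type not in MODEL_ORDER:
            raise ValueError(f"unknown HOF model type {self.model_type!r}")
        if self.family not in ("binomial", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        x, k, n = _validate_xy(X, y, totals)
        x01 = _to_internal(x)
        start_list = _starts(self.model_type, x01, k, n, self.max_response, {})
        if starts:
            start_list = list(starts) + start_list
        best = _optimize_model(self.model_type, start_list, x01, k, n,
                               self.max_response, self.family)
        if best is None:
            raise RuntimeError("HOF optimization failed from every start")
        ll = -best.fun
        kparams = _N_PARAMS[self.model_type] + (1 if self.family == "gaussian" else 0)
        self.params_ = np.asarray(best.x, dtype=float)
        self.loglik_ = ll
        self.aicc_ = _aicc(ll, kparams, x01.size)
        self.n_features_in_ = 1
        self.fit_result_ = HOFFit(
            model_type=self.model_type,
            params=self.params_,
            max_response=self.max_response,
            loglik=ll,
            aicc=self.aicc_,
            n_obs=x01.size,
            family=self.family,
            converged=bool(best.success),
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.fit_result_.predict(X)


def fit_hof_model(x, counts, totals=None, model_type: str = "IV",
                  family: str = "binomial", max_response: float = 1.0,
                  starts=None) -> HOFFit:
    """Fit one HOF model; functional wrapper over :class:`HOFCurve`."""
    est = HOFCurve(model_type=model_type, max_response=max_response, family=family)
    est.fit(x, counts, totals=totals, starts=starts)
    return est.fit_result_


def _fit_all_models(x, counts, totals, family, max_response, warm=None):
    """Fit all five shapes, passing nested solutions up the hierarchy."""
    x = np.asarray(x, dtype=float).ravel()
    xx, k, n = _validate_xy(x, counts, totals)
    x01 = _to_internal(xx)
    fits: dict[str, HOFFit] = {}
    nested: dict[str, np.ndarray] = {}
    for model in MODEL_ORDER:
        if warm and model in warm:
            # bootstrap refits: warm start from the full-data solution only
            start_list = [np.asarray(warm[model], dtype=float)]
        else:
            start_list = _starts(model, x01, k, n, max_response, nested)
        try:
            best = _optimize_model(model, start_list, x01, k, n, max_response,
                                   family)
        except RuntimeError:
            continue
        ll = -best.fun
        kparams = _N_PARAMS[model] + (1 if family == "gaussian" else 0)
        fits[model] = HOFFit(
            model_type=model, params=np.asarray(best.x), max_response=max_response,
            loglik=ll, aicc=_aicc(ll, kparams, x01.size), n_obs=x01.size,
            family=family, converged=bool(best.success),
        )
        nested[model] = np.asarray(best.x)
    return fits


AICC_TIE_BAND = 2.0


def _best_by_aicc(fits: dict[str, HOFFit], restrict=None,
                  band: float = AICC_TIE_BAND) -> str:
    """Lowest AICc with the standard equally-good band: models within
    ``band`` AICc units of the minimum are tied, and the tie goes to the
    simpler model (fewer parameters, then canonical order I..V)."""
    cands = [m for m in MODEL_ORDER if m in fits and (restrict is None or m in restrict)]
    best = min(fits[m].aicc for m in cands)
    tied = [m for m in cands if fits[m].aicc <= best + band]
    # simpler wins within the band; at equal complexity the better fit wins
    return min(tied, key=lambda m: (_N_PARAMS[m], fits[m].aicc,
                                    MODEL_ORDER.index(m)))


class NicheModel(BaseEstimator):
    """HOF model selection with bootstrap stabilization and optimum extraction.

    Fits all five response shapes, selects the lowest-AICc shape on the full
    data, then refits on ``n_bootstrap`` site-resamples; when the modal
    bootstrap choice differs from the full-data choice, the modal choice wins
    (ties broken by lower full-data AICc, then by fewer parameters).

    Attributes
    ----------
    model_type_ : str
        Selected shape.
    fit_ : HOFFit
        Full-data fit of the selected shape.
    candidates_ : dict
        Full-data fits of all shapes.
    bootstrap_support_ : float
        Fraction of successful bootstrap resamples selecting ``model_type_``.
    optimum_ : NicheOptimum
        Extracted niche optimum and inner-niche interval ([1, 100] scale).
    unmodelable_ : bool
        True when optimization failed in more than half of the bootstraps.
    """

    def __init__(self, n_bootstrap: int = 50, family: str = "binomial",
                 max_response: float = 1.0, inner_fraction: float = _INNER_NICHE_FRACTION,
                 random_state: Optional[int] = None):
        self.n_bootstrap = n_bootstrap
        self.family = family
        self.max_response = max_response
        self.inner_fraction = inner_fraction
        self.random_state = random_state

    def fit(self, X, y, totals=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        x, k, n = _validate_xy(X, y, totals)
        # canonical site order: makes bootstrap resampling (and hence the
        # selected model) invariant to the order sites arrive in
        order = np.lexsort((n, k, x))
        x, k, n = x[order], k[order], n[order]
        fits = _fit_all_models(x, k, n, self.family, self.max_response)
        if not fits:
            raise RuntimeError("every HOF model failed to fit")
        full_choice = _best_by_aicc(fits)
        warm = {m: f.params for m, f in fits.items()}

        rng = np.random.default_rng(self.random_state)
        choices = []
        failures = 0
        for _ in range(self.n_bootstrap):
            idx = rng.integers(0, x.size, size=x.size)
            kb = k[idx]
            if kb.sum() == 0:
                failures += 1
                continue
            try:
                bfits = _fit_all_models(x[idx], kb, n[idx], self.family,
                                        self.max_response, warm=warm)
            except (ValueError, RuntimeError):
                failures += 1
                continue
            if not bfits:
                failures += 1
                continue
            choices.append(_best_by_aicc(bfits))

        self.unmodelable_ = failures > self.n_bootstrap / 2
        if choices:
            counts = Counter(choices)
            top = max(counts.values())
            modal_set = [m for m in MODEL_ORDER if counts.get(m, 0) == top]
            modal = _best_by_aicc(fits, restrict=modal_set) if len(modal_set) > 1 \
                else modal_set[0]
            # the bootstrap overturns the full-data choice only with a strict
            # majority: a weak plurality is not a stable signal
            if modal != full_choice and counts[modal] > len(choices) / 2:
                selected = modal
            else:
                selected = full_choice
            support = counts.get(selected, 0) / len(choices)
        else:
            selected = full_choice
            support = math.nan

        best = fits[selected]
        best.bootstrap_support = support
        best.unmodelable = self.unmodelable_
        self.model_type_ = selected
        self.fit_ = best
        self.candidates_ = fits
        self.bootstrap_support_ = support
        self.optimum_ = niche_width(best, fraction=self.inner_fraction) \
            if selected != "I" else NicheOptimum(None, model_type="I")
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return self.fit_.predict(np.asarray(X, dtype=float).ravel())


def select_hof_model(x, counts, totals=None, n_bootstrap: int = 50,
                     family: str = "binomial", seed: Optional[int] = None) -> HOFFit:
    """Select the best HOF shape; functional wrapper over :class:`NicheModel`."""
    est = NicheModel(n_bootstrap=n_bootstrap, family=family, random_state=seed)
    est.fit(x, counts, totals=totals)
    return est.fit_


def _argmax_internal(fit: HOFFit):
    """Unique argmax of the (log-concave) response on the internal [0,1] scale."""
    m = fit.model_type
    p = fit.params
    if m == "I":
        return None, False
    if m in ("II", "III"):
        ends = fit.log_response_internal(np.array([-0.5, 0.5]))
        return (-0.5 if ends[0] >= ends[1] else 0.5), False
    if m == "IV":
        a, b, c = p[0], p[1], p[2]
        if b == 0:
            return 0.0, False
        xstar = (c - a) / (2.0 * b)
    else:  # V — golden-section / Brent on the concave log-response
        res = optimize.minimize_scalar(
            lambda t: -fit.log_response_internal(np.array([t]))[0],
            bounds=(-0.5, 0.5), method="bounded",
            options={"xatol": 1e-10},
        )
        xstar = float(res.x)
        ends = fit.log_response_internal(np.array([-0.5, 0.5, xstar]))
        j = int(np.argmax(ends))
        xstar = (-0.5, 0.5, xstar)[j]
    clamped = xstar < -0.5 or xstar > 0.5
    return float(np.clip(xstar, -0.5, 0.5)), clamped


def extract_optimum(fit: HOFFit) -> NicheOptimum:
    """Extract the niche optimum from a fitted curve.

    Model I yields no optimum; II/III peak at a gradient end; IV has the
    closed-form interior argmax (c - a) / (2b); V is maximized numerically.
    An interior argmax falling outside the gradient is clamped and flagged.
    """
    x01, clamped = _argmax_internal(fit)
    if x01 is None:
        return NicheOptimum(None, model_type="I")
    return NicheOptimum(_to_public(x01), model_type=fit.model_type, clamped=clamped)


def niche_width(fit: HOFFit, fraction: float = _INNER_NICHE_FRACTION) -> NicheOptimum:
    """Optimum plus the inner-niche interval where the response stays at or
    above ``fraction`` of its peak, intersected with the gradient [1, 100].

    Log-concavity of every HOF shape makes the superlevel set an interval, so
    each boundary is found by bisection between the optimum and a gradient end.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    opt = extract_optimum(fit)
    if not opt.defined:
        return opt
    x01 = (opt.optimum - 50.5) / 99.0
    log_thresh = fit.log_response_internal(np.array([x01]))[0] + math.log(fraction)

    def g(t):
        return fit.log_response_internal(np.array([t]))[0] - log_thresh

    lo01 = -0.5 if g(-0.5) >= 0 else optimize.brentq(g, -0.5, x01, xtol=1e-10)
    hi01 = 0.5 if g(0.5) >= 0 else optimize.brentq(g, x01, 0.5, xtol=1e-10)
    return NicheOptimum(opt.optimum, _to_public(lo01), _to_public(hi01),
                        fit.model_type, opt.clamped)


def prevalence_filter(abundance: pd.DataFrame, min_sites: int = 25) -> pd.DataFrame:
    """Keep OTUs (rows) occurring — fractional count > 0 — in at least
    ``min_sites`` sites (columns)."""
    if min_sites > abundance.shape[1]:
        raise ValueError("min_sites exceeds the number of sites")
    occ = (abundance > 0).sum(axis=1)
    return abundance.loc[occ >= min_sites]


def optimum_matrix(abundance: pd.DataFrame, env: pd.DataFrame,
                   min_sites: int = 25, n_bootstrap: int = 50,
                   family: str = "binomial", seed: Optional[int] = None,
                   inner_fraction: float = _INNER_NICHE_FRACTION) -> pd.DataFrame:
    """Fit and select a HOF model for every OTU x variable and tabulate optima.

    Parameters
    ----------
    abundance : DataFrame, OTU x site
        Fractional read counts.  Per-site totals are taken as the column sums.
    env : DataFrame, site x variable
        Gradients rescaled to [1, 100]; missing cells are skipped per variable.

    Returns
    -------
    DataFrame in long format with one row per OTU x variable and columns
    ``otu, variable, model, optimum, lo, hi, support, unmodelable``; the
    optimum is missing (NaN) exactly when the flat model I was selected.
    """
    sites = [s for s in abundance.columns if s in env.index]
    if not sites:
        raise ValueError("abundance columns and environment index share no sites")
    abund = prevalence_filter(abundance[sites], min_sites=min_sites)
    totals = abund.sum(axis=0).to_numpy()
    rows = []
    base = np.random.default_rng(seed)
    for otu in abund.index:
        k_all = abund.loc[otu].to_numpy(dtype=float)
        for var in env.columns:
            x_all = env.loc[sites, var].to_numpy(dtype=float)
            ok = np.isfinite(x_all) & (totals > 0)
            sub_seed = int(base.integers(0, 2**31 - 1))
            est = NicheModel(n_bootstrap=n_bootstrap, family=family,
                             random_state=sub_seed, inner_fraction=inner_fraction)
            est.fit(x_all[ok], k_all[ok], totals=totals[ok])
            opt = est.optimum_
            rows.append((otu, var, est.model_type_, opt.optimum, opt.lo, opt.hi,
                         est.bootstrap_support_, est.unmodelable_))
    return pd.DataFrame(
        rows,
        columns=["otu", "variable", "model", "optimum", "lo", "hi",
                 "support", "unmodelable"],
    )


def optima_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-format optimum table to an OTU x variable matrix."""
    return long.pivot(index="otu", columns="variable", values="optimum")
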