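"""Comparison extractors: auto-ARIMA, stepwise ARFIMA, ETS, NN autoregression.

These are forecasting-style models pressed into service as smoothers: each
is fit to the whole profile and its in-sample one-step fitted values are
taken as the extracted signal.  ARMA/state-space likelihood optimization
and the unit-root/stationarity tests are delegated to statsmodels and the
neural network to scikit-learn; the order-selection loops (AIC search,
KPSS-based differencing), the stepwise fractional-d scheme, fractional
differencing itself, and the restart-averaging contract are owned here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .profiles import ExpressionProfile, SignalExtraction


@dataclass(frozen=True)
class BaselineFit:
    model: str  # "arima" | "arfima" | "ets" | "nn"
    orders: dict
    aic: float
    extraction: SignalExtraction


def _series_arrays(series) -> tuple[np.ndarray, np.ndarray]:
    """Accept an ExpressionProfile or a bare sequence; return (positions, values)."""
    if isinstance(series, ExpressionProfile):
        return series.positions, series.intensities
    y = np.asarray(series, dtype=float)
    return np.arange(y.size, dtype=float), y


# ---------------------------------------------------------------------------
# ARIMA

def ndiffs(y: np.ndarray, test: str = "kpss", alpha: float = 0.05, max_d: int = 2) -> int:
    """Number of ordinary differences needed for stationarity.

    ``kpss`` (default) differences while the KPSS test rejects level
    stationarity; ``adf`` differences while the ADF test fails to reject a
    unit root.
    """
    from statsmodels.tsa.stattools import adfuller, kpss

    y = np.asarray(y, dtype=float)
    d = 0
    while d < max_d:
        if np.allclose(y, y[0]):
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if test == "kpss":
                _, pval, *_ = kpss(y, regression="c", nlags="auto")
                stationary = pval >= alpha
            elif test == "adf":
                _, pval, *_ = adfuller(y, autolag="AIC")
                stationary = pval < alpha
            else:
                raise ValueError(f"unknown unit-root test {test!r}")
        if stationary:
            break
        y = np.diff(y)
        d += 1
    return d


def arima_aic(log_likelihood: float, p: int, q: int, P: int = 0, Q: int = 0,
              constant: bool = False) -> float:
    """AIC = -2 log(L) + 2 (p + q + P + Q + k), with k = 1 iff a constant is fit."""
    k = 1 if constant else 0
    return -2.0 * log_likelihood + 2.0 * (p + q + P + Q + k)


def _fit_sarimax(y: np.ndarray, p: int, d: int, q: int, constant: bool):
    from statsmodels.tsa.arima.model import ARIMA

    if constant:
        trend = "c" if d == 0 else "t" if d == 1 else None
        if trend is None:
            return None
    else:
        trend = "n"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ARIMA(y, order=(p, d, q), trend=trend).fit()
        if not np.isfinite(res.llf):
            return None
        # a numerically diverged fit can report a likelihood yet produce
        # wild one-step predictions; reject it as a candidate
        fitted = np.asarray(res.fittedvalues, dtype=float)[d:]
        span = float(np.max(np.abs(y))) + 1.0
        if not np.all(np.isfinite(fitted)) or np.max(np.abs(fitted)) > 10.0 * span:
            return None
        return res
    except Exception:
        return None


def fit_arima_auto(
    series,
    max_p: int = 5,
    max_q: int = 5,
    d: int | None = None,
    unit_root_test: str = "kpss",
) -> BaselineFit:
    """Automatic non-seasonal ARIMA: KPSS-chosen d, stepwise AIC over (p, q, c).

    The differencing order d comes from a unit-root/stationarity test
    (KPSS by default); (p, q) and the constant are then chosen by
    minimizing AIC = -2 log L + 2(p + q + k) with a stepwise neighbourhood
    search starting from (2,2), (0,0), (1,0), (0,1).  Seasonal terms are
    disabled throughout (P = Q = 0): a spatial series has no season.  The
    extracted signal is the in-sample one-step fitted values; the first d
    fitted values are set to the observed values (no pre-sample prediction
    exists for them).
    """
    x, y = _series_arrays(series)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 points for ARIMA")
    if max_p < 0 or max_q < 0:
        raise ValueError("max orders must be >= 0")
    if d is None:
        d = ndiffs(y, test=unit_root_test)

    cache: dict[tuple[int, int, bool], tuple] = {}

    def evaluate(p: int, q: int, constant: bool):
        key = (p, q, constant)
        if key in cache:
            return cache[key]
        if not (0 <= p <= max_p and 0 <= q <= max_q):
            cache[key] = (None, np.inf)
            return cache[key]
        res = _fit_sarimax(y, p, d, q, constant)
        aic = arima_aic(res.llf, p, q, constant=constant) if res is not None else np.inf
        cache[key] = (res, aic)
        return cache[key]

    allow_const = d < 2
    starts = [(2, 2), (0, 0), (1, 0), (0, 1)]
    best_key, best_aic = None, np.inf
    for p0, q0 in starts:
        p0, q0 = min(p0, max_p), min(q0, max_q)
        for c in ([True, False] if allow_const else [False]):
            _, aic = evaluate(p0, q0, c)
            if aic < best_aic:
                best_key, best_aic = (p0, q0, c), aic
    if best_key is None or not np.isfinite(best_aic):
        raise RuntimeError("all candidate ARIMA fits failed to converge")

    improved = True
    while improved:
        improved = False
        p, q, c = best_key
        neighbours = [
            (p + 1, q, c), (p - 1, q, c), (p, q + 1, c), (p, q - 1, c),
            (p + 1, q + 1, c), (p - 1, q - 1, c),
        ]
        if allow_const:
            neighbours.append((p, q, not c))
        for key in neighbours:
            if key[0] < 0 or key[1] < 0:
                continue
            _, aic = evaluate(key[0], key[1], key[2])
            if aic < best_aic - 1e-10:
                best_key, best_aic = key, aic
                improved = True

    p, q, c = best_key
    res, _ = evaluate(p, q, c)
    fitted = np.asarray(res.fittedvalues, dtype=float)
    if d > 0:
        fitted = fitted.copy()
        fitted[:d] = y[:d]
    extraction = SignalExtraction(
        method="arima", positions=x, observed=y, signal=fitted, residual=y - fitted,
        meta={"p": p, "d": d, "q": q, "constant": c},
    )
    return BaselineFit("arima", {"p": p, "d": d, "q": q, "constant": c}, float(best_aic), extraction)


# ---------------------------------------------------------------------------
# ARFIMA

def fractional_difference(y: Sequence[float] | np.ndarray, d: float) -> np.ndarray:
    """Apply the fractional difference operator (1 - B)^d, truncated at t = 0.

    Expansion coefficients follow the recursion pi_0 = 1,
    pi_k = pi_{k-1} * (k - 1 - d) / k.  A negative d fractionally
    *integrates* (the inverse filter), which is how long-memory test series
    are generated.  d = 0 is the identity.
    """
    y = np.asarray(y, dtype=float)
    if d == 0:
        return y.copy()
    k = np.arange(1, y.size)
    pi = np.concatenate([[1.0], np.cumprod((k - 1 - d) / k)])
    return np.convolve(pi, y)[: y.size]


def estimate_fractional_d(
    series,
    ar_order: int = 2,
    bounds: tuple[float, float] = (0.0, 0.5),
) -> float:
    """Estimate the long-memory parameter d from an ARFIMA(ar_order, d, 0) fit.

    The default search range is the stationary long-memory interval
    [0, 0.5], as in the reference automatic-ARFIMA scheme; widening it
    makes d poorly identified against the free AR polynomial.

    The series is demeaned and, for each candidate d, fractionally
    differenced with the filter truncated at t = 0; a short burn-in prefix
    (where the truncated filter has not yet forgotten the start of the
    series) is excluded and an AR(ar_order) model is fit by Yule-Walker,
    which keeps the AR polynomial stationary so that d alone must account
    for any remaining nonstationarity.  The concentrated
    innovation-variance likelihood is maximized over d by a grid scan plus
    bounded refinement.
    """
    from scipy.linalg import solve_toeplitz
    from scipy.optimize import minimize_scalar

    _, y = _series_arrays(series)
    p = int(ar_order)
    if y.size < p + 10:
        raise ValueError("series too short to estimate d")
    y = y - y.mean()
    nb = min(10, y.size // 10)

    def negll(d: float) -> float:
        z = fractional_difference(y, d)[nb:]
        z = z - z.mean()
        n = z.size
        # biased autocovariances guarantee a stationary Yule-Walker solution
        acov = np.array([np.dot(z[: n - k], z[k:]) / n for k in range(p + 1)])
        if acov[0] <= 0:
            return np.inf
        phi = solve_toeplitz(acov[:p], acov[1 : p + 1])
        sigma2 = float(acov[0] - phi @ acov[1 : p + 1])
        return 0.5 * n * math.log(max(sigma2, 1e-300))

    # the CSS profile over d can be multimodal (e.g. trend-dominated series):
    # coarse grid scan first, then bounded refinement around the best point
    grid = np.linspace(bounds[0], bounds[1], 31)
    vals = [negll(d) for d in grid]
    d_best = grid[int(np.argmin(vals))]
    step = grid[1] - grid[0]
    lo, hi = max(bounds[0], d_best - step), min(bounds[1], d_best + step)
    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


def fit_arfima(series, max_p: int = 5, max_q: int = 5) -> BaselineFit:
    """Stepwise ARFIMA(p, d, q) with fractional d.

    Scheme: (1) estimate d from an ARFIMA(2, d, 0) fit; (2) fractionally
    difference the series with that d; (3) select ARMA(p, q) on the
    differenced series by the automatic AIC search; (4) jointly re-estimate
    d with the selected (p, q) by profiling the ARMA likelihood over d,
    excluding the short burn-in prefix where the truncated fractional
    filter has not yet forgotten the start of the series.  The extracted
    signal is observed minus the final innovations; the burn-in positions
    carry no usable innovation and are fitted by the observed values.
    """
    from scipy.optimize import minimize_scalar
    from statsmodels.tsa.arima.model import ARIMA

    x, y_raw = _series_arrays(series)
    if y_raw.size < 30:
        raise ValueError("need at least 30 points for ARFIMA")
    mu = float(np.mean(y_raw))
    y = y_raw - mu  # the fractional filter acts on deviations from the mean
    nb = min(10, y.size // 10)  # truncated-filter burn-in

    d0 = estimate_fractional_d(y, ar_order=2)
    z0 = fractional_difference(y, d0)
    arma = fit_arima_auto(z0[nb:], max_p=max_p, max_q=max_q, d=0)
    p, q = arma.orders["p"], arma.orders["q"]
    constant = arma.orders["constant"]
    trend = "c" if constant else "n"

    def negll(d: float) -> float:
        z = fractional_difference(y, d)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ARIMA(z, order=(p, 0, q), trend=trend).fit()
            llf = float(np.sum(res.model.loglikeobs(res.params)[nb:]))
            return -llf if np.isfinite(llf) else np.inf
        except Exception:
            return np.inf

    # profile d over the stationary long-memory range [0, 0.5]:
    # coarse scan (the profile can be multimodal), then refine
    grid = np.unique(np.concatenate([np.linspace(0.0, 0.5, 6), [d0]]))
    vals = np.array([negll(d) for d in grid])
    if not np.any(np.isfinite(vals)):
        raise RuntimeError("joint ARFIMA re-estimation failed for every candidate d")
    d_best = float(grid[int(np.argmin(vals))])
    step = 0.11
    opt = minimize_scalar(negll, bounds=(max(0.0, d_best - step), min(0.5, d_best + step)),
                          method="bounded", options={"xatol": 5e-3, "maxiter": 15})
    d_hat = float(opt.x) if np.isfinite(opt.fun) else d_best
    if not -0.5 < d_hat < 1.0:
        raise RuntimeError(f"fractional d estimate {d_hat} outside (-0.5, 1)")
    z = fractional_difference(y, d_hat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = ARIMA(z, order=(p, 0, q), trend=trend).fit()
    innov = np.asarray(res.resid, dtype=float)
    innov[:nb] = 0.0  # burn-in positions: fitted by the observed values
    signal = y_raw - innov
    aic = arima_aic(float(res.llf), p, q, constant=constant) + 2.0  # +2 for d
    extraction = SignalExtraction(
        method="arfima", positions=x, observed=y_raw, signal=signal, residual=innov,
        meta={"p": p, "d": d_hat, "q": q, "constant": constant},
    )
    return BaselineFit("arfima", {"p": p, "d": d_hat, "q": q, "constant": constant},
                       float(aic), extraction)


# ---------------------------------------------------------------------------
# ETS

def fit_ets(series) -> BaselineFit:
    """Exponential-smoothing state-space model chosen by AIC.

    Enumerates additive/multiplicative error with no, additive, or damped
    additive trend (no seasonal component — a spatial series has no
    season); each candidate's smoothing parameters and initial states are
    fit by maximum likelihood, and the lowest-AIC model wins.
    Multiplicative-error candidates require a strictly positive series.
    """
    from statsmodels.tsa.exponential_smoothing.ets import ETSModel

    x, y = _series_arrays(series)
    if y.size < 10:
        raise ValueError("need at least 10 points for ETS")
    errors = ["add"] + (["mul"] if np.all(y > 0) else [])
    candidates = []
    for err in errors:
        for trend, damped in [(None, False), ("add", False), ("add", True)]:
            candidates.append((err, trend, damped))
    best = None
    for err, trend, damped in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ETSModel(y, error=err, trend=trend, damped_trend=damped,
                               seasonal=None).fit(disp=False)
            if not np.isfinite(res.aic):
                continue
            if best is None or res.aic < best[0]:
                best = (float(res.aic), err, trend, damped, res)
        except Exception:
            continue
    if best is None:
        raise RuntimeError("all candidate ETS fits failed")
    aic, err, trend, damped, res = best
    fitted = np.asarray(res.fittedvalues, dtype=float)
    extraction = SignalExtraction(
        method="ets", positions=x, observed=y, signal=fitted, residual=y - fitted,
        meta={"error": err, "trend": trend, "damped": damped},
    )
    return BaselineFit("ets", {"error": err, "trend": trend, "damped": damped}, aic, extraction)


# ---------------------------------------------------------------------------
# NN autoregression

def logistic(u: np.ndarray | float) -> np.ndarray | float:
    """Logistic activation 1 / (1 + exp(-u)); the hidden-node nonlinearity."""
    return 1.0 / (1.0 + np.exp(-np.asarray(u, dtype=float)))


def select_ar_order(y: np.ndarray, max_lag: int = 8) -> int:
    """Optimal linear AR lag order by AIC (at least 1, capped at max_lag)."""
    from statsmodels.tsa.ar_model import ar_select_order

    max_lag = max(1, min(max_lag, y.size // 4))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = ar_select_order(y, maxlag=max_lag, ic="aic", old_names=False)
    lags = sel.ar_lags
    return int(max(lags)) if lags else 1


def fit_nn_autoregression(
    series,
    n_lags_p: int | None = None,
    hidden_layout: Sequence[int] | None = None,
    n_restarts: int = 25,
    seed: int = 0,
    max_iter: int = 200,
) -> BaselineFit:
    """Feed-forward neural autoregression with restart averaging.

    The network regresses y_t on its p lags through logistic hidden layers
    and a linear output.  Training restarts from ``n_restarts`` random
    initializations (seeded, so the whole fit is reproducible) and the
    extracted signal is the mean of the restarts' in-sample predictions —
    averaging tames the variance of any single badly initialized net.  The
    first p positions carry no prediction and are fitted by the observed
    values.

    Defaults: p is the AIC-optimal linear AR order (capped at 8); two
    hidden layers of sizes (k, ceil(k/2)) with k = ceil((p+1)/2).
    """
    from sklearn.neural_network import MLPRegressor

    x, y = _series_arrays(series)
    n = y.size
    p = select_ar_order(y) if n_lags_p is None else int(n_lags_p)
    if p < 1:
        raise ValueError("n_lags_p must be >= 1")
    if n <= p + 5:
        raise ValueError("series too short for the requested lag order")
    if hidden_layout is None:
        k = math.ceil((p + 1) / 2)
        hidden_layout = (k, math.ceil(k / 2))
    hidden_layout = tuple(int(h) for h in hidden_layout)
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    mu, sd = float(np.mean(y)), float(np.std(y))
    sd = sd if sd > 0 else 1.0
    ys = (y - mu) / sd
    X = np.column_stack([ys[p - i - 1 : n - i - 1] for i in range(p)])
    target = ys[p:]

    preds = []
    for r in range(n_restarts):
        rs = int((seed * 100003 + r) % (2**31 - 1))
        net = MLPRegressor(
            hidden_layer_sizes=hidden_layout,
            activation="logistic",
            solver="lbfgs",
            max_iter=max_iter,
            tol=1e-6,
            random_state=rs,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net.fit(X, target)
            pred = net.predict(X)
        except Exception:
            continue
        if np.all(np.isfinite(pred)):
            preds.append(pred * sd + mu)
    if not preds:
        raise RuntimeError("all NN restarts failed to train")
    mean_pred = np.mean(preds, axis=0)
    signal = np.concatenate([y[:p], mean_pred])
    extraction = SignalExtraction(
        method="nn", positions=x, observed=y, signal=signal, residual=y - signal,
        meta={"n_lags_p": p, "hidden_layout": hidden_layout,
              "n_restarts": len(preds), "restart_predictions": np.asarray(preds)},
    )
    return BaselineFit(
        "nn",
        {"n_lags_p": p, "hidden_layout": hidden_layout, "n_restarts": len(preds)},
        float("nan"),
        extraction,
    )
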