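"""Detection of unexpected increases in frequency (UIF).

The detector forecasts the monitored month's report count from the
preceding ``w`` monthly counts (default 6) with a negative binomial
log-linear trend regression,

    count_t ~ NegBin(mu_t, alpha),   log mu_t = beta0 + beta1 * t,

with time coded ``t = -w … -1`` so that the monitored month sits at
``t0 = 0`` and the forecast linear predictor is the intercept.  The NB2
variance is ``mu + alpha * mu**2``; when the dispersion estimate hits the
zero boundary (or the sample variance does not exceed the mean) the model
reduces to a Poisson trend GLM.

A combination is flagged when the observed count ``y0``

* meets the minimum-count threshold tau (3 and 5 are the conventional
  operating points), and
* exceeds the upper bound of the forecast — unless the history is mostly
  null (>= w-2 zero months, i.e. "4 or more of 6"), in which case the
  regression is unreliable and a heuristic rule fires on the threshold
  alone.

Forecasts are only attempted once the threshold is met; combinations below
tau short-circuit without a model fit.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.discrete.discrete_model import NegativeBinomial

from .counting import CountSeries, CoverageError, slice_for_month
from .report_store import ScreenConfig

__all__ = [
    "NbFit",
    "Forecast",
    "UifDetection",
    "is_null_history",
    "fit_nb_trend",
    "forecast_t0",
    "detect",
    "screen",
    "write_detections",
    "load_detections",
]

logger = logging.getLogger("uifscan")

# Dispersion below this is treated as the Poisson boundary: six points
# cannot distinguish such alphas from zero.
_ALPHA_BOUNDARY = 1e-6


@dataclass
class NbFit:
    """A fitted count-trend model.

    ``beta0``/``beta1`` are intercept and slope on the log scale (per
    month); ``alpha`` the NB2 dispersion (0 for the Poisson reduction);
    ``se_eta0`` the standard error of the linear predictor at t0 = 0, i.e.
    of the intercept, from the estimated parameter covariance.
    """

    beta0: float
    beta1: float
    alpha: float
    se_eta0: float
    converged: bool
    family_used: Literal["negbin", "poisson"]
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if (self.alpha == 0.0) != (self.family_used == "poisson"):
            raise ValueError("alpha == 0 exactly when the Poisson family is used")
        if self.se_eta0 < 0:
            raise ValueError("se_eta0 must be >= 0")


@dataclass
class Forecast:
    """Expected count at the monitored month and its upper bound."""

    y_hat: float
    upper_bound: float
    level: float
    bound_type: Literal["ci_mean", "prediction"]
    fit: NbFit

    def __post_init__(self) -> None:
        if not (self.upper_bound >= self.y_hat >= 0.0):
            raise ValueError("require upper_bound >= y_hat >= 0")


@dataclass
class UifDetection:
    """A flagged (drug, event, month): observed count exceeded expectation."""

    drug_key: tuple[str, str]
    event_key: tuple[str, str]
    month: str
    y0: int
    branch: Literal["regression", "heuristic"]
    threshold: int
    forecast: Forecast | None = None

    def __post_init__(self) -> None:
        if self.branch == "heuristic" and self.forecast is not None:
            raise ValueError("heuristic detections carry no forecast")
        if self.branch == "regression" and self.forecast is None:
            raise ValueError("regression detections require a forecast")
        if self.y0 < self.threshold:
            raise ValueError("a detection requires y0 >= threshold")


def is_null_history(history: Sequence[int], window: int) -> bool:
    """True when the history is too sparse to support the trend regression.

    For the default 6-month window this is the "4 or more zeros" rule; in
    general, ``window - 2`` zeros or more, so that fewer than 3 non-zero
    observations never feed the two-parameter fit.
    """
    history = np.asarray(history)
    if len(history) != window:
        raise ValueError(f"history length {len(history)} != window {window}")
    return int(np.sum(history == 0)) >= window - 2


def _validate_history(history: Sequence[int]) -> np.ndarray:
    y = np.asarray(history, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("history must be a 1-D sequence of length >= 3")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("history counts must be non-negative integers")
    return y


def _poisson_fit(y: np.ndarray, X: np.ndarray) -> NbFit:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    cov = np.asarray(res.cov_params())
    se0 = math.sqrt(max(cov[0, 0], 0.0))
    return NbFit(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        alpha=0.0,
        se_eta0=se0,
        converged=bool(res.converged),
        family_used="poisson",
        loglik=float(res.llf),
    )


def fit_nb_trend(history: Sequence[int]) -> NbFit:
    """Maximum-likelihood NB2 log-linear trend fit of a count history.

    Histories whose sample variance does not exceed their mean sit at the
    dispersion boundary and are fitted directly as a Poisson trend GLM.
    Otherwise the joint (beta0, beta1, alpha) likelihood is maximised; a
    Nelder–Mead polish on the profile guards against optimizer stalls on
    short samples, and a boundary or non-improving dispersion estimate
    falls back to the Poisson fit rather than dropping the series.
    """
    y = _validate_history(history)
    w = len(y)
    if is_null_history(y.astype(int), w):
        raise ValueError("history is null (too many zero months) — regression not run")
    t = np.arange(-w, 0, dtype=float)
    X = np.column_stack([np.ones(w), t])

    pois = _poisson_fit(y, X)
    mean, var = float(y.mean()), float(y.var(ddof=1))
    if var <= mean:
        return pois

    mod = NegativeBinomial(y, X, loglike_method="nb2")
    alpha0 = max((var - mean) / mean**2, 1e-3)
    start = np.array([pois.beta0, pois.beta1, alpha0])

    best_params: np.ndarray | None = None
    best_ll = -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "nm"):
            try:
                res = mod.fit(start_params=start, method=method, maxiter=500, disp=0)
            except Exception:  # noqa: BLE001 — optimizer failure, try next
                continue
            params = np.asarray(res.params, dtype=float)
            if not np.all(np.isfinite(params)) or params[2] < 0:
                continue
            ll = float(mod.loglike(params))
            if np.isfinite(ll) and ll > best_ll:
                best_ll, best_params = ll, params
            if method == "bfgs" and best_params is not None:
                break

        # Nelder-Mead polish in (beta0, beta1, log alpha) space.
        seed = best_params if best_params is not None else start
        la0 = math.log(max(seed[2], 1e-8))

        def _negll(theta: np.ndarray) -> float:
            val = mod.loglike(np.array([theta[0], theta[1], math.exp(theta[2])]))
            return -val if np.isfinite(val) else 1e12

        polish = optimize.minimize(
            _negll,
            np.array([seed[0], seed[1], la0]),
            method="Nelder-Mead",
            options={"maxiter": 400, "xatol": 1e-8, "fatol": 1e-10},
        )
        if np.all(np.isfinite(polish.x)) and -polish.fun > best_ll:
            best_ll = -float(polish.fun)
            best_params = np.array(
                [polish.x[0], polish.x[1], math.exp(polish.x[2])]
            )

    if (
        best_params is None
        or best_params[2] <= _ALPHA_BOUNDARY
        or best_ll <= pois.loglik + 1e-9
    ):
        return pois

    b0, b1, alpha = (float(v) for v in best_params)
    se0 = _nb_se_eta0(mod, best_params, y, X, alpha)
    if se0 is None:
        return pois
    return NbFit(
        beta0=b0,
        beta1=b1,
        alpha=alpha,
        se_eta0=se0,
        converged=True,
        family_used="negbin",
        loglik=best_ll,
    )


def _nb_se_eta0(
    mod: NegativeBinomial,
    params: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    alpha: float,
) -> float | None:
    """SE of the intercept from the inverse observed information.

    Falls back to the dispersion-conditional GLM covariance when the joint
    Hessian is singular; returns None only if both routes fail.
    """
    try:
        hess = np.asarray(mod.hessian(params), dtype=float)
        cov = np.linalg.inv(-hess)
        v = cov[0, 0]
        if np.isfinite(v) and v > 0:
            return math.sqrt(v)
    except Exception:  # noqa: BLE001
        pass
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha)
            ).fit()
        v = float(np.asarray(res.cov_params())[0, 0])
        if np.isfinite(v) and v > 0:
            return math.sqrt(v)
    except Exception:  # noqa: BLE001
        pass
    return None


def forecast_t0(
    fit: NbFit,
    level: float = 0.95,
    bound_type: Literal["ci_mean", "prediction"] = "ci_mean",
) -> Forecast:
    """Forecast the monitored month and its upper bound.

    ``ci_mean``: Wald upper confidence bound of the expected count,
    ``exp(beta0 + z * se_eta0)`` with z the upper point of the two-sided
    (1 - level) normal quantile.  ``prediction``: the smallest integer q
    whose count-distribution CDF (at the upper mean bound and the fitted
    dispersion) reaches ``level`` — a conservative bound on the count scale.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if not fit.converged:
        raise ValueError("cannot forecast from a non-converged fit")
    y_hat = math.exp(fit.beta0)
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    mu_up = math.exp(fit.beta0 + z * fit.se_eta0)
    if bound_type == "ci_mean":
        upper = mu_up
    elif bound_type == "prediction":
        if fit.alpha == 0.0:
            upper = float(stats.poisson.ppf(level, mu_up))
        else:
            n = 1.0 / fit.alpha
            p = n / (n + mu_up)
            upper = float(stats.nbinom.ppf(level, n, p))
    else:
        raise ValueError(f"unknown bound_type {bound_type!r}")
    upper = max(upper, y_hat)
    return Forecast(
        y_hat=y_hat, upper_bound=upper, level=level, bound_type=bound_type, fit=fit
    )


def detect(
    history: Sequence[int],
    y0: int,
    config: ScreenConfig,
    drug_key: tuple[str, str] = ("substance", ""),
    event_key: tuple[str, str] = ("pt", ""),
    month: str = "",
) -> UifDetection | None:
    """Apply the decision rule to one combination at one monitored month.

    Below the threshold nothing is evaluated (no fit is attempted).  Null
    histories route to the heuristic branch, which fires on the threshold
    alone; otherwise the regression forecast is produced and the detection
    requires ``y0 > upper_bound``.
    """
    history = np.asarray(history)
    if len(history) != config.window_months:
        raise ValueError(
            f"history length {len(history)} != window {config.window_months}"
        )
    if y0 < 0:
        raise ValueError("y0 must be >= 0")
    if y0 < config.threshold_tau:
        return None
    if is_null_history(history, config.window_months):
        return UifDetection(
            drug_key=drug_key,
            event_key=event_key,
            month=str(month),
            y0=int(y0),
            branch="heuristic",
            threshold=config.threshold_tau,
        )
    fit = fit_nb_trend(history)
    forecast = forecast_t0(fit, level=config.bound_level, bound_type=config.bound_type)
    if y0 > forecast.upper_bound:
        return UifDetection(
            drug_key=drug_key,
            event_key=event_key,
            month=str(month),
            y0=int(y0),
            branch="regression",
            threshold=config.threshold_tau,
            forecast=forecast,
        )
    return None


def screen(
    series: Iterable[CountSeries],
    t0: str | pd.Period,
    config: ScreenConfig,
) -> list[UifDetection]:
    """Run the detector over a screening universe at one monitored month.

    The universe is every series with an observed count at t0 (y0 >= 1);
    per-series fit failures are logged and skipped, never aborting the
    screen.  Output order is deterministic: (drug key, event key).
    """
    t0 = str(_month(t0))
    detections: list[UifDetection] = []
    n_candidates = n_heuristic = n_regression = 0
    for s in sorted(series, key=lambda s: (s.drug_key, s.event_key)):
        try:
            history, y0 = slice_for_month(s, t0, config.window_months)
        except CoverageError as exc:
            logger.warning("skipping series: %s", exc)
            continue
        if y0 < 1:
            continue
        n_candidates += 1
        try:
            det = detect(
                history,
                y0,
                config,
                drug_key=s.drug_key,
                event_key=s.event_key,
                month=t0,
            )
        except Exception as exc:  # noqa: BLE001 — fit failure must not abort
            logger.warning(
                "fit failed for %s/%s at %s: %s", s.drug_key, s.event_key, t0, exc
            )
            continue
        if det is not None:
            detections.append(det)
            if det.branch == "heuristic":
                n_heuristic += 1
            else:
                n_regression += 1
    logger.info(
        "screen %s: %d candidates, %d detections (%d regression, %d heuristic)",
        t0,
        n_candidates,
        len(detections),
        n_regression,
        n_heuristic,
    )
    return detections


def _month(month: str | pd.Period) -> pd.Period:
    return month if isinstance(month, pd.Period) else pd.Period(month, freq="M")


DETECTION_COLUMNS = [
    "drug_level",
    "drug_id",
    "event_level",
    "event_id",
    "month",
    "y0",
    "branch",
    "y_hat",
    "upper_bound",
    "threshold",
    "level",
    "bound_type",
]


def write_detections(detections: Iterable[UifDetection], path) -> None:
    import csv as _csv
    from pathlib import Path as _Path

    with _Path(path).open("w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(DETECTION_COLUMNS)
        for d in detections:
            f = d.forecast
            writer.writerow(
                [
                    d.drug_key[0],
                    d.drug_key[1],
                    d.event_key[0],
                    d.event_key[1],
                    d.month,
                    d.y0,
                    d.branch,
                    f"{f.y_hat:.6f}" if f else "",
                    f"{f.upper_bound:.6f}" if f else "",
                    d.threshold,
                    f"{f.level:g}" if f else "",
                    f.bound_type if f else "",
                ]
            )


def load_detections(path) -> list[UifDetection]:
    import csv as _csv
    from pathlib import Path as _Path

    out: list[UifDetection] = []
    with _Path(path).open(newline="") as fh:
        reader = _csv.DictReader(fh)
        missing = [c for c in DETECTION_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"detections file missing column(s): {missing}")
        for row in reader:
            forecast = None
            if row["branch"] == "regression":
                fit = NbFit(
                    beta0=math.log(max(float(row["y_hat"]), 1e-300)),
                    beta1=0.0,
                    alpha=0.0,
                    se_eta0=0.0,
                    converged=True,
                    family_used="poisson",
                )
                forecast = Forecast(
                    y_hat=float(row["y_hat"]),
                    upper_bound=float(row["upper_bound"]),
                    level=float(row["level"]),
                    bound_type=row["bound_type"],  # type: ignore[arg-type]
                    fit=fit,
                )
            out.append(
                UifDetection(
                    drug_key=(row["drug_level"], row["drug_id"]),
                    event_key=(row["event_level"], row["event_id"]),
                    month=row["month"],
                    y0=int(row["y0"]),
                    branch=row["branch"],  # type: ignore[arg-type]
                    threshold=int(row["threshold"]),
                    forecast=forecast,
                )
            )
    return out
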