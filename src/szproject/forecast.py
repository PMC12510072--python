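"""Rolling ARIMAX projection of the long-term seizure rate.

The smoothed (90-day moving average) seizure rate is modelled with the
AR / MA / ARIMA / ARIMAX family; sine/cosine phases of the significant
IED cycles enter as exogenous regressors. The fitted model projects the
rate 14 days ahead, the origin advancing one day at a time, and each
projection is later compared with the realised rate: the residual stream
is the monitoring signal that separates drug-induced change from natural
cyclical variability.

Model estimation is delegated to :class:`statsmodels` SARIMAX (exact
maximum likelihood in state-space form); this module owns the rolling
protocol, the trailing-window bookkeeping, order selection by repeated
hold-out, and the naive benchmarks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.tsa.statespace.sarimax import SARIMAX

from .types import SmoothedRate

__all__ = [
    "ModelOrder",
    "FitResult",
    "DatasetSplit",
    "fit_model",
    "apply_params",
    "project",
    "rolling_projection",
    "grid_search",
    "naive_benchmarks",
    "mse",
    "PROJECTION_COLUMNS",
]

DEFAULT_HORIZON = 14
PROJECTION_COLUMNS = [
    "origin_date",
    "target_date",
    "point",
    "ci_low",
    "ci_high",
    "observed",
    "residual",
]


@dataclass(frozen=True)
class ModelOrder:
    """(p, d, q) order plus whether cycle-phase regressors are used."""

    p: int
    d: int = 0
    q: int = 0
    use_exog: bool = False

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0:
            raise ValueError("p and q must be >= 0")
        if self.d not in (0, 1, 2):
            raise ValueError("d must be 0, 1 or 2")
        # p + q >= 1 unless differencing alone defines the model (random walk)
        if self.p + self.q < 1 and self.d == 0:
            raise ValueError("need p + q >= 1 (or d >= 1 for a pure random walk)")

    @property
    def tuple(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)

    @property
    def complexity(self) -> int:
        return self.p + self.d + self.q

    @property
    def min_window(self) -> int:
        """Smallest usable trailing window: longest lag duration plus one day."""
        return max(self.p + self.d, self.q + self.d) + 1

    def __str__(self) -> str:
        name = "ARIMAX" if self.use_exog else "ARIMA"
        return f"{name}({self.p},{self.d},{self.q})"


@dataclass
class FitResult:
    """Fitted model: coefficients, innovation variance and residuals."""

    order: ModelOrder
    params: np.ndarray
    ar_coefs: np.ndarray
    ma_coefs: np.ndarray
    exog_coefs: np.ndarray
    intercept: float
    sigma2: float
    in_sample_residuals: pd.Series
    converged: bool
    results: object = field(repr=False, default=None)  # statsmodels results


@dataclass
class DatasetSplit:
    """Date intervals for training/validation and the labelled test
    segments (half-open ``[start, end)``)."""

    train_validation: tuple[pd.Timestamp, pd.Timestamp]
    test_segments: dict[str, tuple[pd.Timestamp, pd.Timestamp]]

    def __post_init__(self) -> None:
        self.train_validation = tuple(pd.Timestamp(t) for t in self.train_validation)
        self.test_segments = {
            k: (pd.Timestamp(a), pd.Timestamp(b)) for k, (a, b) in self.test_segments.items()
        }
        spans = sorted(self.test_segments.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("test segments must not overlap")


def _as_series(series) -> pd.Series:
    if isinstance(series, SmoothedRate):
        return series.valid()
    if isinstance(series, pd.Series):
        return series.dropna()
    raise TypeError("expected SmoothedRate or pandas Series")


def _align_exog(exog: Optional[pd.DataFrame], index: pd.Index) -> Optional[np.ndarray]:
    if exog is None:
        return None
    missing = index.difference(exog.index)
    if len(missing):
        raise ValueError(f"exogenous regressors missing for {len(missing)} dates")
    return exog.loc[index].to_numpy()


def _make_model(endog: pd.Series, exog, order: ModelOrder) -> SARIMAX:
    trend = "c" if order.d == 0 else "n"
    if isinstance(endog.index, pd.DatetimeIndex) and endog.index.freq is None:
        freq = pd.infer_freq(endog.index) if len(endog) > 2 else None
        if freq is not None:
            endog = pd.Series(endog.to_numpy(), index=pd.DatetimeIndex(endog.index, freq=freq))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SARIMAX(
            endog,
            exog=_align_exog(exog, endog.index) if exog is not None else None,
            order=order.tuple,
            trend=trend,
        )


def _wrap_results(order: ModelOrder, res, converged: bool) -> FitResult:
    model = res.model
    params = np.asarray(res.params)
    names = model.param_names
    get = lambda pref: np.array([params[i] for i, n in enumerate(names) if n.startswith(pref)])
    ar = get("ar.")
    ma = get("ma.")
    exog_coefs = np.array(
        [params[i] for i, n in enumerate(names) if n.startswith(("x", "sin", "cos", "beta"))]
    )
    intercept = float(params[names.index("intercept")]) if "intercept" in names else 0.0
    sigma2 = float(params[names.index("sigma2")]) if "sigma2" in names else float("nan")
    resid = pd.Series(np.asarray(res.resid), index=res.model.data.row_labels)
    # discard differencing/AR start-up residuals: they are not innovations
    burn = order.d + order.p
    return FitResult(
        order=order,
        params=params,
        ar_coefs=ar,
        ma_coefs=ma,
        exog_coefs=exog_coefs,
        intercept=intercept,
        sigma2=sigma2,
        in_sample_residuals=resid.iloc[burn:],
        converged=converged,
    )


def fit_model(
    series,
    exog: Optional[pd.DataFrame],
    order: ModelOrder,
    start_params: Optional[np.ndarray] = None,
    maxiter: int = 100,
) -> FitResult:
    """Fit the model by exact maximum likelihood.

    Non-convergence does not raise: the result is returned with
    ``converged=False`` so grid search can exclude it from ranking.
    """
    endog = _as_series(series)
    if len(endog) < order.min_window + 20:
        raise ValueError(
            f"series length {len(endog)} too short for {order} (need >= {order.min_window + 20})"
        )
    model = _make_model(endog, exog if order.use_exog else None, order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=maxiter, start_params=start_params)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            res = model.fit(disp=0, maxiter=maxiter, method="nm")
            converged = False
    out = _wrap_results(order, res, converged)
    out.results = res
    return out


def apply_params(series, exog, order: ModelOrder, params: np.ndarray) -> FitResult:
    """Evaluate the model on ``series`` with fixed coefficients (Kalman
    filter pass, no re-estimation)."""
    endog = _as_series(series)
    model = _make_model(endog, exog if order.use_exog else None, order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.filter(np.asarray(params))
    out = _wrap_results(order, res, True)
    out.results = res
    return out


def project(
    fit: FitResult,
    future_exog: Optional[pd.DataFrame] = None,
    horizon: int = DEFAULT_HORIZON,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Iterated h-step forecast from the end of the fitted sample.

    Returns one row per step 1..horizon with the point projection and the
    Gaussian ``1 - alpha`` interval (point +/- z * sqrt(forecast variance)).
    """
    if fit.results is None:
        raise ValueError("FitResult carries no statsmodels results object")
    exog_arr = None
    if fit.order.use_exog:
        if future_exog is None or len(future_exog) < horizon:
            raise ValueError("future exogenous regressors required for the full horizon")
        exog_arr = np.asarray(future_exog)[:horizon]
    fc = fit.results.get_forecast(steps=horizon, exog=exog_arr)
    ci = fc.conf_int(alpha=alpha)
    ci = np.asarray(ci)
    endog_index = fit.results.model.data.row_labels
    origin = endog_index[-1]
    if isinstance(origin, pd.Timestamp):
        targets = origin + pd.to_timedelta(np.arange(1, horizon + 1), unit="D")
    else:
        targets = origin + np.arange(1, horizon + 1)
    return pd.DataFrame(
        {
            "origin_date": origin,
            "target_date": targets,
            "point": np.asarray(fc.predicted_mean),
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        }
    )


def _rolling_fixed_fast(
    endog: pd.Series,
    exog: Optional[pd.DataFrame],
    order: ModelOrder,
    params: np.ndarray,
    horizon: int,
    start: int,
    stop: int,
) -> pd.DataFrame:
    """All h-step-ahead projections from one Kalman-filter pass.

    With fixed coefficients the forecast from origin t is a linear
    function of the predicted state a_{t+1|t}: y_hat(t+h) = d_{t+h} +
    Z T^{h-1} a_{t+1|t}, with variance Z P_h Z' where P_h follows the
    usual prediction recursion. One filter pass over the full series
    yields every a_{t+1|t} at once, so the whole rolling run costs one
    filter plus a few matrix products. Identical (to numerical precision)
    to calling ``get_forecast`` at every origin with the same coefficients
    and full conditioning history.
    """
    fit = apply_params(endog, exog, order, params)
    res = fit.results
    ssm = res.model.ssm
    T = ssm["transition"][:, :, 0] if ssm["transition"].ndim == 3 else ssm["transition"]
    Z = ssm["design"][:, :, 0] if ssm["design"].ndim == 3 else ssm["design"]
    R = ssm["selection"][:, :, 0] if ssm["selection"].ndim == 3 else ssm["selection"]
    Q = ssm["state_cov"][:, :, 0] if ssm["state_cov"].ndim == 3 else ssm["state_cov"]
    d = ssm["obs_intercept"]
    n = len(endog)
    d = np.broadcast_to(d, (1, n)) if d.shape[-1] == 1 else d

    fr = res.filter_results
    a_pred = fr.predicted_state  # (k, n+1); a_pred[:, t] = a_{t | t-1}
    P_pred = fr.predicted_state_cov  # (k, k, n+1)

    Th = np.linalg.matrix_power(T, horizon - 1)
    m = (Z @ Th).ravel()  # y_hat(t+h) = d_{t+h} + m . a_{t+1|t} + drift
    # state intercept (trend constant): time-invariant for the models built here
    c = ssm["state_intercept"]
    c0 = c[:, 0] if c.ndim == 2 else c
    if c.ndim == 2 and not np.allclose(c, c[:, :1]):
        raise NotImplementedError("time-varying state intercept not supported in fast path")
    # accumulated process noise and drift between t+1 and t+h (origin-independent)
    RQR = R @ Q @ R.T
    acc = np.zeros_like(RQR)
    drift = np.zeros(T.shape[0])
    Tj = np.eye(T.shape[0])
    for _ in range(horizon - 1):
        acc = acc + Tj @ RQR @ Tj.T
        drift = drift + Tj @ c0
        Tj = T @ Tj
    const_var = float((Z @ acc @ Z.T).item())
    const_drift = float((Z @ drift).item())

    origins = np.arange(start, min(stop, n - horizon))
    if origins.size == 0:
        return pd.DataFrame(columns=PROJECTION_COLUMNS)
    a = a_pred[:, origins + 1]  # (k, n_origins)
    P = P_pred[:, :, origins + 1]
    points = d[0, origins + horizon] + m @ a + const_drift
    var = np.einsum("i,ijn,j->n", m, P, m) + const_var
    z = 1.959963984540054  # Phi^{-1}(0.975)
    half = z * np.sqrt(var)
    obs = endog.to_numpy()[origins + horizon]
    idx = endog.index
    return pd.DataFrame(
        {
            "origin_date": idx[origins],
            "target_date": idx[origins + horizon],
            "point": points,
            "ci_low": points - half,
            "ci_high": points + half,
            "observed": obs,
            "residual": obs - points,
        }
    )


def _rolling_fixed_windowed(
    endog: pd.Series,
    exog: Optional[pd.DataFrame],
    order: ModelOrder,
    params: np.ndarray,
    horizon: int,
    window: int,
    start: int,
    stop: int,
) -> pd.DataFrame:
    """h-step projections where every origin conditions on exactly
    ``window`` trailing observations.

    With fixed coefficients the Kalman-filter forecast is an affine
    function of the observations in its window, and with a fixed window
    length that function is the same at every origin. It is recovered
    once from impulse responses (run the filter on a zero window and on
    each unit impulse), after which the whole rolling run is a sliding
    dot product. Exogenous regressors enter as regression effects:
    the ARIMA part operates on u = y - X beta and the forecast adds
    beta' x_{t+h}. Exact against per-origin filtering (tested), and
    translation-invariant: the residual distribution cannot drift with
    the length of the available history.
    """
    n = len(endog)
    window = min(window, n)
    full = apply_params(endog, exog, order, params)
    names = full.results.model.param_names
    k_exog = full.results.model.k_exog if hasattr(full.results.model, "k_exog") else 0
    if order.use_exog and exog is not None and k_exog:
        beta_idx = [i for i, nm in enumerate(names) if nm in full.results.model.exog_names]
        beta = np.asarray(params)[beta_idx]
        u_vals = endog.to_numpy() - exog.loc[endog.index].to_numpy() @ beta
        arima_params = np.delete(np.asarray(params), beta_idx)
        x_all = exog
    else:
        beta = None
        u_vals = endog.to_numpy()
        arima_params = np.asarray(params)
        x_all = None
    sub_order = ModelOrder(order.p, order.d, order.q, use_exog=False)
    widx = pd.RangeIndex(window)

    def _fc(vals: np.ndarray) -> float:
        f = apply_params(pd.Series(vals, index=widx), None, sub_order, arima_params)
        return float(np.asarray(f.results.get_forecast(steps=horizon).predicted_mean)[-1])

    zero = np.zeros(window)
    c0 = _fc(zero)
    weights = np.empty(window)
    for j in range(window):
        impulse = zero.copy()
        impulse[j] = 1.0
        weights[j] = _fc(impulse) - c0
    zres = apply_params(pd.Series(zero, index=widx), None, sub_order, arima_params)
    fcast = zres.results.get_forecast(steps=horizon)
    half = float(np.diff(np.asarray(fcast.conf_int(alpha=0.05))[-1]).item()) / 2.0

    start = max(start, window - 1)
    origins = np.arange(start, min(stop, n - horizon))
    if origins.size == 0:
        return pd.DataFrame(columns=PROJECTION_COLUMNS)
    # sliding dot product of the window weights over u
    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(u_vals, window)[origins - window + 1]
    points = c0 + windows @ weights
    if beta is not None:
        points = points + x_all.loc[endog.index].to_numpy()[origins + horizon] @ beta
    obs = endog.to_numpy()[origins + horizon]
    idx = endog.index
    return pd.DataFrame(
        {
            "origin_date": idx[origins],
            "target_date": idx[origins + horizon],
            "point": points,
            "ci_low": points - half,
            "ci_high": points + half,
            "observed": obs,
            "residual": obs - points,
        }
    )


def rolling_projection(
    series,
    exog: Optional[pd.DataFrame],
    order: ModelOrder,
    horizon: int = DEFAULT_HORIZON,
    refit_policy: str = "fixed",
    window: Optional[int] = None,
    train_len: Optional[int] = None,
    params: Optional[np.ndarray] = None,
    first_origin=None,
    last_origin=None,
) -> pd.DataFrame:
    """Daily-updated h-step-ahead projections.

    For each origin day ``t`` the model sees only the trailing window of
    the smoothed series (the longest lag duration plus one day, or
    ``window``), projects ``t + horizon``, and the realised value — when it
    exists — yields the residual ``observed - point``, indexed by target
    date.

    refit_policy
        ``"fixed"`` (default): coefficients estimated once on the first
        ``train_len`` days (or taken from ``params``) and then held fixed;
        each origin conditions on exactly ``window`` trailing observations,
        so the residual distribution cannot drift with the length of the
        recording. ``"fixed_full"``: fixed coefficients but each origin
        conditions on the full history. ``"daily"``: re-estimated at every
        origin on its trailing window, warm-started from the previous fit.
    """
    endog = _as_series(series)
    n = len(endog)
    if refit_policy not in ("fixed", "fixed_full", "daily"):
        raise ValueError("refit_policy must be 'fixed', 'fixed_full' or 'daily'")
    window = int(window) if window is not None else order.min_window
    window = max(window, order.min_window)
    if train_len is None:
        train_len = max(window + 20, min(n // 2, 369))
    if n <= train_len:
        raise ValueError("series too short for the requested training length")

    use_exog = order.use_exog
    if use_exog and exog is None:
        raise ValueError("order requests exogenous regressors but none given")

    if params is None:
        base = fit_model(endog.iloc[:train_len], exog, order)
        params = base.params
    params = np.asarray(params)

    start = train_len if first_origin is None else int(endog.index.get_loc(first_origin))
    stop = n if last_origin is None else int(endog.index.get_loc(last_origin)) + 1
    if refit_policy == "fixed":
        usable_exog = exog if use_exog else None
        return _rolling_fixed_windowed(
            endog, usable_exog, order, params, horizon, window, start, stop
        )
    if refit_policy == "fixed_full":
        usable_exog = exog if use_exog else None
        return _rolling_fixed_fast(endog, usable_exog, order, params, horizon, start, stop)
    rows = []
    prev_params = params
    for i in range(start, stop):
        lo = max(0, i + 1 - window)
        w_endog = endog.iloc[lo : i + 1]
        if use_exog:
            w_exog = exog.loc[w_endog.index]
            tgt_idx = endog.index[i] + pd.to_timedelta(np.arange(1, horizon + 1), unit="D")
            fut = exog.reindex(tgt_idx)
            if fut.isna().any().any():
                break  # no regressors beyond this origin
        else:
            w_exog = fut = None
        if refit_policy == "daily":
            fit = fit_model(w_endog, w_exog, order, start_params=prev_params, maxiter=50)
            prev_params = fit.params
        else:
            fit = apply_params(w_endog, w_exog, order, params)
        proj = project(fit, fut, horizon=horizon)
        rows.append(proj.iloc[horizon - 1])
    out = pd.DataFrame(rows).reset_index(drop=True)
    if out.empty:
        return pd.DataFrame(columns=PROJECTION_COLUMNS)
    obs = endog.reindex(out["target_date"]).to_numpy()
    out["observed"] = obs
    out["residual"] = out["observed"] - out["point"]
    return out[PROJECTION_COLUMNS]


def mse(records: pd.DataFrame) -> float:
    """Mean squared projection error over records with an observed value."""
    resid = records["residual"].dropna()
    if resid.empty:
        raise ValueError("no records with observed values")
    return float(np.mean(resid.to_numpy() ** 2))


def grid_search(
    series,
    exog: Optional[pd.DataFrame],
    candidate_orders: Sequence[ModelOrder],
    n_iter: int = 100,
    split_frac: float = 0.7,
    horizon: int = DEFAULT_HORIZON,
    seed: int = 0,
) -> tuple[ModelOrder, pd.DataFrame]:
    """Order selection by repeated hold-out on the train/validation span.

    Each iteration draws a random contiguous 30% validation block; each
    candidate is fitted on the data before the block and scored by the MSE
    of its h-step-ahead rolling projections across the block. Candidates
    are ranked by MSE averaged over iterations; ties break toward the
    simpler model (smaller p+d+q). Non-convergent candidates are excluded.
    """
    if not candidate_orders:
        raise ValueError("candidate grid is empty")
    endog = _as_series(series)
    n = len(endog)
    val_len = max(horizon + 1, int(round((1 - split_frac) * n)))
    rng = np.random.default_rng(seed)
    min_train = max(o.min_window for o in candidate_orders) + 20
    if n - val_len <= min_train:
        raise ValueError("series too short for the requested split")
    starts = rng.integers(min_train, n - val_len + 1, size=n_iter)

    scores = {o: [] for o in candidate_orders}
    failed = {o: False for o in candidate_orders}
    for s in starts:
        train = endog.iloc[:s]
        for order in candidate_orders:
            try:
                fit = fit_model(train, exog, order)
            except Exception:
                failed[order] = True
                continue
            if not fit.converged:
                failed[order] = True
                continue
            rec = rolling_projection(
                endog.iloc[: s + val_len],
                exog,
                order,
                horizon=horizon,
                refit_policy="fixed",
                train_len=s,
                params=fit.params,
            )
            rec = rec[rec["observed"].notna()]
            if len(rec):
                scores[order].append(mse(rec))
    table = pd.DataFrame(
        {
            "order": [str(o) for o in candidate_orders],
            "p": [o.p for o in candidate_orders],
            "d": [o.d for o in candidate_orders],
            "q": [o.q for o in candidate_orders],
            "use_exog": [o.use_exog for o in candidate_orders],
            "mean_mse": [np.mean(scores[o]) if scores[o] else np.nan for o in candidate_orders],
            "n_iter_scored": [len(scores[o]) for o in candidate_orders],
        }
    )
    ok = [o for o in candidate_orders if scores[o] and not failed[o]]
    if not ok:
        ok = [o for o in candidate_orders if scores[o]]
    if not ok:
        raise RuntimeError("no candidate converged on any hold-out iteration")
    best = min(ok, key=lambda o: (np.mean(scores[o]), o.complexity))
    return best, table.sort_values("mean_mse").reset_index(drop=True)


def naive_benchmarks(
    series,
    horizon: int = DEFAULT_HORIZON,
    train_len: Optional[int] = None,
    refit_policy: str = "fixed",
) -> dict[str, pd.DataFrame]:
    """Rolling projections of the naive reference models AR(1) and MA(5),
    under the same protocol as the main model (no exogenous input)."""
    return {
        "AR(1)": rolling_projection(
            series, None, ModelOrder(1, 0, 0), horizon, refit_policy, train_len=train_len
        ),
        "MA(5)": rolling_projection(
            series, None, ModelOrder(0, 0, 5), horizon, refit_policy, train_len=train_len
        ),
    }
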