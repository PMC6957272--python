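"""ACMA flux-assay kinetics: normalization, exponential fits, Hill titrations.

The liposome flux assay reads out K+ efflux as quenching of ACMA
fluorescence: ~100 s of baseline, CCCP addition triggering an exponential
quench monitored for ~400 s at 2-s sampling, and optionally a valinomycin
addition that drives the signal to the full-quench floor.  Traces are
normalized to NF = (F - F_floor) / (F_ini - F_floor), where the floor is
either the post-valinomycin minimum or the 450–500 s steady-state mean.
Quench curves are fitted with one- or two-phase exponential decays; the
flux rate constant is k = 1/tau (the fast component for two-phase fits).
Cation titrations of the rate constant are fitted with the Hill equation
y = Start + (End - Start) * x^n / (K_half^n + x^n).

The fitters are scikit-learn style estimators (:class:`ExponentialDecayModel`,
:class:`HillModel`); :func:`fit_exponential` and :func:`fit_hill` are thin
wrappers returning plain result records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize as lmfit_minimize
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DegenerateTraceError, FitFailureError, UsageError

_UNIT_TO_UM = {"uM": 1.0, "µM": 1.0, "mM": 1000.0, "M": 1e6}


# ---------------------------------------------------------------------------
# Trace containers


@dataclass
class FluxTrace:
    """One assay time course: time (s, strictly increasing) vs fluorescence (AU)."""

    time: np.ndarray
    fluorescence: np.ndarray
    cccp_time: float = 100.0
    valinomycin_time: float | None = None
    sampling_interval: float = 2.0
    normalized: bool = False

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.shape != self.fluorescence.shape or self.time.ndim != 1:
            raise UsageError("time and fluorescence must be 1-D arrays of equal length")
        if not np.all(np.diff(self.time) > 0):
            raise UsageError("time must be strictly increasing")
        if np.sum(self.time > self.cccp_time) < 10:
            raise UsageError("need at least 10 points after CCCP addition")


@dataclass
class NormalizationAnchors:
    F_ini: float
    F_val: float | None = None
    F_ss: float | None = None

    def floor(self, mode: str) -> float:
        if mode == "valinomycin":
            if self.F_val is None:
                raise UsageError("valinomycin mode requires F_val")
            return self.F_val
        if mode == "steady_state":
            if self.F_ss is None:
                raise UsageError("steady_state mode requires F_ss")
            return self.F_ss
        raise UsageError(f"unknown normalization mode {mode!r}")


def derive_anchors(trace: FluxTrace, mode: str = "valinomycin", ss_window: float = 50.0) -> NormalizationAnchors:
    """Anchors from the trace itself: F_ini is the last baseline point before
    CCCP; F_val the lowest point after valinomycin; F_ss the mean of the
    final 50 s (450–500 s at the standard schedule)."""
    baseline = trace.time <= trace.cccp_time
    if not baseline.any():
        raise UsageError("no baseline points before CCCP time")
    f_ini = float(trace.fluorescence[baseline][-1])
    f_val = None
    f_ss = None
    if mode == "valinomycin":
        if trace.valinomycin_time is None:
            raise UsageError("trace has no valinomycin segment; use steady_state mode")
        tail = trace.time >= trace.valinomycin_time
        if not tail.any():
            raise UsageError("no points after valinomycin time")
        f_val = float(trace.fluorescence[tail].min())
    elif mode == "steady_state":
        t_end = trace.time[-1]
        window = trace.time > t_end - ss_window
        f_ss = float(trace.fluorescence[window].mean())
    else:
        raise UsageError(f"unknown normalization mode {mode!r}")
    return NormalizationAnchors(F_ini=f_ini, F_val=f_val, F_ss=f_ss)


def normalize(
    trace: FluxTrace,
    anchors: NormalizationAnchors | None = None,
    mode: str = "valinomycin",
) -> FluxTrace:
    """Normalized fluorescence NF = (F - floor) / (F_ini - floor).

    NF is 1 at the last baseline point and 0 at the chosen floor.  The
    normalization is affine-invariant: rescaling raw fluorescence a*F + b
    (a != 0) leaves NF unchanged.
    """
    anchors = anchors if anchors is not None else derive_anchors(trace, mode)
    floor = anchors.floor(mode)
    denom = anchors.F_ini - floor
    if denom == 0:
        raise DegenerateTraceError("F_ini equals the floor value: flat trace")
    nf = (trace.fluorescence - floor) / denom
    return FluxTrace(
        time=trace.time.copy(),
        fluorescence=nf,
        cccp_time=trace.cccp_time,
        valinomycin_time=trace.valinomycin_time,
        sampling_interval=trace.sampling_interval,
        normalized=True,
    )


# ---------------------------------------------------------------------------
# Exponential decay fitting


@dataclass
class ExponentialFit:
    order: int
    y0: float
    x0: float
    A1: float
    tau: float | None = None          # order 1
    A2: float | None = None           # order 2
    tau_fast: float | None = None
    tau_slow: float | None = None
    residual_sse: float = float("nan")
    information_criterion: float = float("nan")  # small-sample-corrected AIC
    n_points: int = 0

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        if self.order == 1:
            return self.y0 + self.A1 * np.exp(-(t - self.x0) / self.tau)
        return (
            self.y0
            + self.A1 * np.exp(-(t - self.x0) / self.tau_fast)
            + self.A2 * np.exp(-(t - self.x0) / self.tau_slow)
        )


@dataclass
class RateResult:
    k: float            # s^-1
    component: str      # "single" | "fast"
    fast_dominant: bool | None = None  # |A_fast| > |A_slow| for order-2 fits


def _model_order1(t, y0, A1, tau, x0):
    return y0 + A1 * np.exp(-(t - x0) / tau)


def _model_order2(t, y0, A1, tau_fast, A2, tau_slow, x0):
    return y0 + A1 * np.exp(-(t - x0) / tau_fast) + A2 * np.exp(-(t - x0) / tau_slow)


def _aicc(sse: float, n: int, k: int) -> float:
    sse = max(sse, 1e-300)
    aic = n * np.log(sse / n) + 2 * k
    denom = n - k - 1
    return aic + (2 * k * (k + 1) / denom if denom > 0 else np.inf)


class ExponentialDecayModel(BaseEstimator, RegressorMixin):
    """One- or two-phase exponential decay fitted by nonlinear least squares.

    Model (one phase):  y = y0 + A1 * exp(-(x - x0) / tau)
    Model (two phase):  y = y0 + A1 * exp(-(x - x0) / tau_fast)
                            + A2 * exp(-(x - x0) / tau_slow)

    ``x0`` is the initial fit point (the CCCP-addition time in the assay);
    only points with x >= x0 are fitted and, following assay practice, the
    first point measured immediately after x0 is excluded because of the
    mixing artefact at compound addition.  Initial guesses come from a
    log-linear regression; tau is bounded positive, and the fit is retried
    from perturbed starts on non-convergence.

    Parameters
    ----------
    order : {1, 2}
        Number of exponential phases.
    x0 : float or None
        Initial fit point; defaults to the trace's CCCP time (or the first
        sample when fitting bare arrays).
    drop_first_point : bool, default True
        Exclude the first point after x0.
    max_restarts : int, default 4
        Perturbed re-initializations before declaring failure.

    Attributes (after ``fit``)
    --------------------------
    y0_, amplitudes_, taus_ : fitted plateau, amplitudes and time constants
        (taus sorted ascending for order 2, amplitudes matched).
    sse_, aicc_, n_points_, x0_ : fit diagnostics.
    """

    def __init__(self, order: int = 1, x0: float | None = None,
                 drop_first_point: bool = True, max_restarts: int = 4):
        self.order = order
        self.x0 = x0
        self.drop_first_point = drop_first_point
        self.max_restarts = max_restarts

    # -- helpers -----------------------------------------------------------

    def _select(self, t, y):
        x0 = self.x0 if self.x0 is not None else float(t[0])
        mask = t >= x0
        t_fit, y_fit = t[mask], y[mask]
        if self.drop_first_point and len(t_fit) and t_fit[0] > x0:
            t_fit, y_fit = t_fit[1:], y_fit[1:]
        elif self.drop_first_point and len(t_fit) > 1 and t_fit[0] == x0:
            # x0 itself is a sample: the artefact point is the next one
            t_fit = np.concatenate([t_fit[:1], t_fit[2:]])
            y_fit = np.concatenate([y_fit[:1], y_fit[2:]])
        return x0, t_fit, y_fit

    def _initial_guess(self, t, y, x0):
        tail = y[-max(5, len(y) // 10):]
        y0 = float(tail.mean())
        a_total = float(y[0] - y0)
        # log-linear regression on the informative early decay only; the
        # long tail is noise-dominated and would corrupt the slope
        resid = (y - y0) / a_total if a_total != 0 else np.full_like(y, np.nan)
        ok = resid > 0.1
        if ok.sum() >= 3:
            slope = np.polyfit(t[ok] - x0, np.log(resid[ok]), 1)[0]
            tau = -1.0 / slope if slope < 0 else (t[-1] - x0) / 3
        else:
            tau = (t[-1] - x0) / 3
        tau = float(np.clip(tau, 1e-3, 10 * (t[-1] - x0 + 1)))
        return y0, a_total, tau

    # -- API ---------------------------------------------------------------

    def fit(self, X, y=None):
        """Fit to a :class:`FluxTrace` or to (t, y) arrays."""
        if isinstance(X, FluxTrace):
            t = X.time
            yv = X.fluorescence
            if self.x0 is None:
                self.x0 = float(X.cccp_time)
        else:
            t = np.asarray(X, dtype=float).ravel()
            yv = np.asarray(y, dtype=float).ravel()
        if self.order not in (1, 2):
            raise UsageError("order must be 1 or 2")
        x0, t_fit, y_fit = self._select(t, yv)
        n_min = 2 * (self.order + 1) + 1
        if len(t_fit) < n_min:
            raise UsageError(f"need at least {n_min} points after x0, have {len(t_fit)}")
        if not y_fit[0] > y_fit[-1]:
            raise DegenerateTraceError("no decay present: first fitted value <= last")
        y0_g, a_g, tau_g = self._initial_guess(t_fit, y_fit, x0)
        span = float(t_fit[-1] - t_fit[0])

        def residual(params):
            if self.order == 1:
                model = _model_order1(t_fit, params["y0"], params["A1"], params["tau"], x0)
            else:
                model = _model_order2(
                    t_fit, params["y0"], params["A1"], params["tau_fast"],
                    params["A2"], params["tau_slow"], x0,
                )
            return model - y_fit

        # deterministic multi-start: the two-phase model has a degenerate
        # local minimum with a vanishing fast phase, so several spreads of
        # (tau_fast, tau_slow) are tried and the best SSE kept
        if self.order == 1:
            starts = [(1.0,)] + [(f,) for f in (0.3, 3.0, 0.1)][: self.max_restarts]
        else:
            starts = [(1 / 3, 3.0), (1.0, 1.0), (1 / 10, 1.0), (1 / 3, 10.0), (1 / 30, 0.3)]
            starts = starts[: self.max_restarts + 1]
        sse_flat = float(np.sum((y_fit - y_fit.mean()) ** 2))
        best = None
        for factors in starts:
            params = Parameters()
            params.add("y0", value=y0_g)
            if self.order == 1:
                params.add("A1", value=a_g)
                params.add("tau", value=tau_g * factors[0], min=1e-6, max=100 * span)
            else:
                params.add("A1", value=a_g * 0.5)
                params.add("A2", value=a_g * 0.5)
                params.add("tau_fast", value=tau_g * factors[0], min=1e-6, max=100 * span)
                params.add("tau_slow", value=tau_g * factors[1], min=1e-6, max=100 * span)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = lmfit_minimize(residual, params, method="leastsq")
            sse = float(np.sum(out.residual**2))
            if out.success and np.isfinite(sse) and (best is None or sse < best[1]):
                best = (out, sse)
            # for the one-phase model, stop once the fit clearly explains
            # the decay; a degenerate tau->0 minimum stays near the flat-model
            # SSE and triggers the remaining starts instead
            if self.order == 1 and best is not None and best[1] < 0.25 * sse_flat:
                break
        if best is None:
            raise FitFailureError("exponential fit did not converge", best_attempt=None)
        out, sse = best
        if not out.success:
            raise FitFailureError("exponential fit did not converge", best_attempt=out)
        p = out.params
        self.x0_ = x0
        self.y0_ = float(p["y0"].value)
        if self.order == 1:
            self.taus_ = np.array([float(p["tau"].value)])
            self.amplitudes_ = np.array([float(p["A1"].value)])
        else:
            taus = np.array([float(p["tau_fast"].value), float(p["tau_slow"].value)])
            amps = np.array([float(p["A1"].value), float(p["A2"].value)])
            order = np.argsort(taus)  # fast first
            self.taus_ = taus[order]
            self.amplitudes_ = amps[order]
        self.sse_ = sse
        self.n_points_ = len(t_fit)
        self.aicc_ = _aicc(sse, len(t_fit), 2 * self.order + 1)
        return self

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.y0_, dtype=float)
        for a, tau in zip(self.amplitudes_, self.taus_):
            y = y + a * np.exp(-(t - self.x0_) / tau)
        return y

    def result(self) -> ExponentialFit:
        if self.order == 1:
            return ExponentialFit(
                order=1, y0=self.y0_, x0=self.x0_, A1=float(self.amplitudes_[0]),
                tau=float(self.taus_[0]), residual_sse=self.sse_,
                information_criterion=self.aicc_, n_points=self.n_points_,
            )
        return ExponentialFit(
            order=2, y0=self.y0_, x0=self.x0_,
            A1=float(self.amplitudes_[0]), A2=float(self.amplitudes_[1]),
            tau_fast=float(self.taus_[0]), tau_slow=float(self.taus_[1]),
            residual_sse=self.sse_, information_criterion=self.aicc_,
            n_points=self.n_points_,
        )


def fit_exponential(trace, order: int = 1, x0: float | None = None) -> ExponentialFit:
    """Fit a one- or two-phase exponential decay to a (normalized) trace."""
    est = ExponentialDecayModel(order=order, x0=x0)
    est.fit(trace)
    return est.result()


def select_model(fit1: ExponentialFit, fit2: ExponentialFit, delta: float = 2.0) -> ExponentialFit:
    """Simplest adequate model: the two-phase fit is chosen only when its
    small-sample-corrected information criterion beats the one-phase fit
    by more than ``delta``; ties go to one phase."""
    if {fit1.order, fit2.order} != {1, 2}:
        raise UsageError("select_model needs one order-1 and one order-2 fit")
    f1, f2 = (fit1, fit2) if fit1.order == 1 else (fit2, fit1)
    if f1.n_points != f2.n_points or f1.x0 != f2.x0:
        raise UsageError("fits were not performed on identical data")
    return f2 if (f1.information_criterion - f2.information_criterion) > delta else f1


def extract_rate(fit: ExponentialFit) -> RateResult:
    """Flux rate constant k = 1/tau; for two-phase fits the fast component
    is reported with a dominance flag (|A_fast| > |A_slow|) — a False flag
    is reported, never suppressed."""
    if fit.order == 1:
        if fit.tau is None or fit.tau <= 0:
            raise FitFailureError("invalid fit: tau must be positive")
        return RateResult(k=1.0 / fit.tau, component="single")
    if fit.tau_fast is None or fit.tau_fast <= 0:
        raise FitFailureError("invalid fit: tau_fast must be positive")
    return RateResult(
        k=1.0 / fit.tau_fast,
        component="fast",
        fast_dominant=bool(abs(fit.A1) > abs(fit.A2)),
    )


# ---------------------------------------------------------------------------
# Hill titrations


@dataclass
class TitrationSeries:
    """Rate constants vs activator concentration; internal math in µM."""

    concentrations: np.ndarray
    rates: np.ndarray
    unit: str = "uM"
    rate_sd: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.unit not in _UNIT_TO_UM:
            raise UsageError(f"unknown concentration unit {self.unit!r}")
        if self.concentrations.shape != self.rates.shape:
            raise UsageError("concentrations and rates must have equal length")
        if np.any(self.concentrations < 0):
            raise UsageError("concentrations must be nonnegative")
        if self.rate_sd is not None:
            self.rate_sd = np.asarray(self.rate_sd, dtype=float)
            if self.rate_sd.shape != self.rates.shape:
                raise UsageError("rate_sd must match rates in length")

    @property
    def conc_um(self) -> np.ndarray:
        return self.concentrations * _UNIT_TO_UM[self.unit]


@dataclass
class HillFit:
    start: float
    end: float
    k_half: float        # in `unit`
    n_hill: float
    unit: str
    stderr: dict = field(default_factory=dict)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        xn = np.power(x, self.n_hill)
        return self.start + (self.end - self.start) * xn / (self.k_half**self.n_hill + xn)


def hill_equation(x, start, end, k_half, n):
    x = np.asarray(x, dtype=float)
    xn = np.where(x > 0, np.power(x, n), 0.0)
    return start + (end - start) * xn / (k_half**n + xn)


class HillModel(BaseEstimator, RegressorMixin):
    """Hill-equation fit of a rate-vs-concentration titration.

    y(x) = Start + (End - Start) * x^n / (K_half^n + x^n), unweighted least
    squares by default, inverse-variance weighted when replicate SDs are
    supplied.  Start is initialized at the minimum rate, End at the maximum,
    K_half at the mid-response concentration; K_half is bounded positive and
    n to (0, 10].

    Attributes after ``fit``: ``start_``, ``end_``, ``k_half_`` (in the
    unit of the fitted concentrations), ``n_hill_``, ``stderr_``.
    """

    def __init__(self, weighted: bool = False, max_restarts: int = 4):
        self.weighted = weighted
        self.max_restarts = max_restarts

    def fit(self, X, y=None, sample_sd=None):
        x = np.asarray(X, dtype=float).ravel()
        yv = np.asarray(y, dtype=float).ravel()
        if x.shape != yv.shape:
            raise UsageError("concentration and rate arrays must match")
        if len(np.unique(x)) < 4:
            raise UsageError("need at least 4 distinct concentrations for a Hill fit")
        if x.min() > 0.05 * x.max():
            warnings.warn("no concentration near zero: Start is poorly constrained")
        w = None
        if self.weighted:
            if sample_sd is None:
                raise UsageError("weighted fit requires replicate SDs")
            sd = np.asarray(sample_sd, dtype=float).ravel()
            w = 1.0 / np.clip(sd, np.max(sd) * 1e-3, None)
        start0, end0 = float(yv.min()), float(yv.max())
        # mid-response concentration as K_half guess
        half = (start0 + end0) / 2
        order = np.argsort(x)
        k0 = float(np.interp(half, yv[order], x[order]))
        pos = x[x > 0]
        k0 = float(np.clip(k0, pos.min() if len(pos) else 1e-3, x.max()))

        def residual(params):
            model = hill_equation(x, params["start"], params["end"], params["k_half"], params["n"])
            r = model - yv
            return r * w if w is not None else r

        rng = np.random.default_rng(0)
        best = None
        for attempt in range(self.max_restarts + 1):
            jit = 1.0 if attempt == 0 else float(rng.uniform(0.3, 3.0))
            params = Parameters()
            params.add("start", value=start0)
            params.add("end", value=end0)
            params.add("k_half", value=k0 * jit, min=1e-9, max=1e9)
            params.add("n", value=1.5, min=1e-3, max=10.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = lmfit_minimize(residual, params, method="leastsq")
            sse = float(np.sum(out.residual**2))
            if best is None or sse < best[1]:
                best = (out, sse)
            if out.success and np.isfinite(sse):
                break
        out, _sse = best
        if not out.success:
            raise FitFailureError("Hill fit did not converge", best_attempt=out)
        p = out.params
        self.start_ = float(p["start"].value)
        self.end_ = float(p["end"].value)
        self.k_half_ = float(p["k_half"].value)
        self.n_hill_ = float(p["n"].value)
        self.stderr_ = {
            name: (float(p[name].stderr) if p[name].stderr is not None else float("nan"))
            for name in ("start", "end", "k_half", "n")
        }
        # flag non-monotonic data beyond noise
        resid = hill_equation(x, self.start_, self.end_, self.k_half_, self.n_hill_) - yv
        if np.std(resid) > 0.5 * abs(self.end_ - self.start_):
            warnings.warn("titration deviates strongly from a monotone Hill curve")
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        return hill_equation(x, self.start_, self.end_, self.k_half_, self.n_hill_)


def fit_hill(series: TitrationSeries, weighted: bool = False) -> HillFit:
    """Fit the Hill equation to a titration; K_half is reported in the
    series' concentration unit."""
    est = HillModel(weighted=weighted)
    est.fit(series.concentrations, series.rates,
            sample_sd=series.rate_sd if weighted else None)
    return HillFit(
        start=est.start_, end=est.end_, k_half=est.k_half_, n_hill=est.n_hill_,
        unit=series.unit, stderr=est.stderr_,
    )


def summarize_rates(rates) -> tuple[float, float]:
    """Replicate handling: per-curve fits, then mean ± SD across replicates."""
    arr = np.asarray(list(rates), dtype=float)
    if arr.size == 0:
        raise UsageError("no rates to summarize")
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0
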