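"""Partitioning-rate analysis: exponential decay fits and rate saturation.

The soluble-protein time course at each chaperonin concentration is fit to a
pseudo-first-order decay ``S(t) = s_inf + (s0 - s_inf) exp(-k_app t)``, and
the apparent rates are then fit against chaperonin concentration to the
saturating hyperbola ``k_app([EL]) = k_max [EL] / (k_half + [EL])``.  Under
the capture model, k_max estimates the intrinsic unfolding rate k_u and
k_half estimates k_f / k_c.

Both fits are exposed as sklearn-style estimators (``FirstOrderDecay``,
``SaturationCurve``) so they compose with pipelines and model selection; the
module-level functions wrap them for the dataclass-based workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .capture import ExperimentCondition
from .errors import DegenerateProfileError, InputError

__all__ = [
    "TimeCourse",
    "DecayFit",
    "RateProfile",
    "SaturationFit",
    "FirstOrderDecay",
    "SaturationCurve",
    "fit_first_order",
    "fit_rate_saturation",
    "fraction_remaining",
]


# --------------------------------------------------------------------------
# domain containers
# --------------------------------------------------------------------------

@dataclass
class TimeCourse:
    """Soluble fraction vs time for one condition, with optional replicate SDs."""

    times: np.ndarray
    soluble_frac: np.ndarray
    sd: np.ndarray | None = None
    condition: ExperimentCondition | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.soluble_frac = np.asarray(self.soluble_frac, dtype=float)
        if self.times.shape != self.soluble_frac.shape:
            raise InputError("times and soluble_frac must have the same length")
        if self.times.size and self.times[0] < 0:
            raise InputError("first time point must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if np.any(self.soluble_frac < 0) or np.any(self.soluble_frac > 1.1):
            raise InputError(
                "soluble_frac must lie in [0, 1.1] (small >1 noise excursions allowed)"
            )
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.times.shape:
                raise InputError("sd must match times in length")


@dataclass
class DecayFit:
    """Result of a pseudo-first-order decay fit."""

    k_app: float
    s0: float
    s_inf: float
    rss: float
    converged: bool
    k_app_err: float | None = None
    degenerate_flat: bool = False


@dataclass
class RateProfile:
    """Apparent rates across chaperonin concentrations."""

    el_concs: np.ndarray
    k_apps: np.ndarray
    k_app_errs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.el_concs = np.asarray(self.el_concs, dtype=float)
        self.k_apps = np.asarray(self.k_apps, dtype=float)
        if self.el_concs.shape != self.k_apps.shape:
            raise InputError("el_concs and k_apps must have the same length")
        if np.any(self.el_concs < 0):
            raise InputError("el_concs must be non-negative")
        if self.k_app_errs is not None:
            self.k_app_errs = np.asarray(self.k_app_errs, dtype=float)
            if self.k_app_errs.shape != self.el_concs.shape:
                raise InputError("k_app_errs must match el_concs in length")


@dataclass
class SaturationFit:
    """Hyperbolic saturation parameters of apparent rate vs [EL]."""

    k_max: float
    k_half: float
    rss: float
    converged: bool
    k_max_err: float | None = None
    k_half_err: float | None = None
    saturation_not_reached: bool = False


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------

def _column_or_1d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        return X[:, 0]
    if X.ndim == 1:
        return X
    raise InputError(f"X must be 1-d or a single column, got shape {X.shape}")


class FirstOrderDecay(RegressorMixin, BaseEstimator):
    """Pseudo-first-order decay ``S(t) = s_inf + (s0 - s_inf) exp(-k_app t)``.

    Parameters
    ----------
    fix_plateau_zero : bool
        Fix s_inf = 0 (simple exponential decay to zero).
    n_starts : int
        Number of log-spaced k_app restarts tried if the first fit fails.

    Attributes
    ----------
    k_app_, s0_, s_inf_ : float
        Fitted parameters (min⁻¹ / fractions).
    k_app_err_ : float or None
        Asymptotic standard error of k_app when estimable.
    rss_ : float
        Residual sum of squares (unweighted).
    converged_ : bool
        False when the optimizer failed from every start (no exception raised).
    degenerate_flat_ : bool
        True when the series was constant and k_app_ = 0 was returned directly.
    """

    def __init__(self, fix_plateau_zero: bool = False, n_starts: int = 3):
        self.fix_plateau_zero = fix_plateau_zero
        self.n_starts = n_starts

    @staticmethod
    def _model(t, k_app, s0, s_inf):
        return s_inf + (s0 - s_inf) * np.exp(-k_app * t)

    def _initial_k(self, t: np.ndarray, y: np.ndarray) -> float:
        # half-life heuristic: first crossing of the midpoint between extremes
        mid = 0.5 * (y.max() + y.min())
        below = np.nonzero(y <= mid)[0]
        t_half = t[below[0]] if below.size and t[below[0]] > 0 else 0.5 * (t[-1] or 1.0)
        return np.log(2.0) / max(t_half, 1e-6)

    def fit(self, X, y, sample_weight=None):
        t = _column_or_1d(X)
        y = np.asarray(y, dtype=float)
        if t.size < 4:
            raise InputError(f"need at least 4 time points, got {t.size}")
        if y.shape != t.shape:
            raise InputError("y must match X in length")

        if np.ptp(y) == 0.0:
            # flat series carries no rate information; report zero decay
            self.k_app_, self.s0_, self.s_inf_ = 0.0, float(y[0]), float(y[0])
            self.k_app_err_ = None
            self.rss_ = 0.0
            self.converged_ = True
            self.degenerate_flat_ = True
            return self
        self.degenerate_flat_ = False

        weights = None
        if sample_weight is not None:
            weights = np.sqrt(np.asarray(sample_weight, dtype=float))

        k0 = self._initial_k(t, y)
        starts = [k0] + list(
            np.geomspace(max(k0 / 10, 1e-5), k0 * 10, self.n_starts)
        )
        best = None
        for k_start in starts:
            params = lmfit.Parameters()
            params.add("k_app", value=k_start, min=0.0)
            params.add("s0", value=float(y[0]))
            if self.fix_plateau_zero:
                params.add("s_inf", value=0.0, vary=False)
            else:
                params.add("s_inf", value=float(y[-1]))

            def resid(p):
                r = self._model(t, p["k_app"], p["s0"], p["s_inf"]) - y
                return r * weights if weights is not None else r

            try:
                res = lmfit.minimize(resid, params, method="leastsq")
            except Exception:
                continue
            # near-flat series can trip leastsq's tolerance heuristics even at
            # a perfectly good minimum; keep the best finite result regardless
            if np.isfinite(res.chisqr) and (best is None or res.chisqr < best.chisqr):
                best = res

        if best is None:
            self.k_app_, self.s0_, self.s_inf_ = np.nan, np.nan, np.nan
            self.k_app_err_ = None
            self.rss_ = np.nan
            self.converged_ = False
            return self

        p = best.params
        self.k_app_ = float(p["k_app"].value)
        self.s0_ = float(p["s0"].value)
        self.s_inf_ = float(p["s_inf"].value)
        self.k_app_err_ = (
            float(p["k_app"].stderr) if p["k_app"].stderr is not None else None
        )
        self.rss_ = float(np.sum((self._model(t, self.k_app_, self.s0_, self.s_inf_) - y) ** 2))
        self.converged_ = True
        return self

    def predict(self, X):
        t = _column_or_1d(X)
        return self._model(t, self.k_app_, self.s0_, self.s_inf_)

    def result_(self) -> DecayFit:
        """Package the fitted attributes as a :class:`DecayFit`."""
        return DecayFit(
            k_app=self.k_app_,
            s0=self.s0_,
            s_inf=self.s_inf_,
            rss=self.rss_,
            converged=self.converged_,
            k_app_err=self.k_app_err_,
            degenerate_flat=self.degenerate_flat_,
        )


class SaturationCurve(RegressorMixin, BaseEstimator):
    """Hyperbolic saturation ``k_app([EL]) = k_max [EL] / (k_half + [EL])``.

    A fit whose k_half exceeds ``unsaturated_factor`` times the largest tested
    concentration is flagged ``saturation_not_reached_`` (the profile does not
    constrain the plateau).
    """

    def __init__(self, unsaturated_factor: float = 10.0):
        self.unsaturated_factor = unsaturated_factor

    @staticmethod
    def _model(el, k_max, k_half):
        return k_max * el / (k_half + el)

    def fit(self, X, y, sample_weight=None):
        el = _column_or_1d(X)
        k = np.asarray(y, dtype=float)
        if k.shape != el.shape:
            raise InputError("y must match X in length")
        if np.any(el < 0):
            raise InputError("chaperonin concentrations must be non-negative")
        if np.unique(el[el > 0]).size < 3:
            raise InputError("need at least 3 distinct positive concentrations")
        if np.all(k == 0):
            raise DegenerateProfileError(
                "all apparent rates are zero; no saturation curve can be fit"
            )

        weights = None
        if sample_weight is not None:
            weights = np.sqrt(np.asarray(sample_weight, dtype=float))

        params = lmfit.Parameters()
        params.add("k_max", value=float(k.max()) or 1e-3, min=0.0)
        params.add("k_half", value=float(np.median(el[el > 0])), min=1e-12)

        def resid(p):
            r = self._model(el, p["k_max"], p["k_half"]) - k
            return r * weights if weights is not None else r

        res = lmfit.minimize(resid, params, method="leastsq")
        p = res.params
        self.k_max_ = float(p["k_max"].value)
        self.k_half_ = float(p["k_half"].value)
        self.k_max_err_ = (
            float(p["k_max"].stderr) if p["k_max"].stderr is not None else None
        )
        self.k_half_err_ = (
            float(p["k_half"].stderr) if p["k_half"].stderr is not None else None
        )
        self.rss_ = float(np.sum((self._model(el, self.k_max_, self.k_half_) - k) ** 2))
        self.converged_ = bool(res.success)
        self.saturation_not_reached_ = bool(
            self.k_half_ > self.unsaturated_factor * el.max()
        )
        if self.saturation_not_reached_:
            warnings.warn(
                "saturation not reached: fitted k_half exceeds "
                f"{self.unsaturated_factor}x the largest tested concentration",
                stacklevel=2,
            )
        return self

    def predict(self, X):
        el = _column_or_1d(X)
        return self._model(el, self.k_max_, self.k_half_)

    def result_(self) -> SaturationFit:
        return SaturationFit(
            k_max=self.k_max_,
            k_half=self.k_half_,
            rss=self.rss_,
            converged=self.converged_,
            k_max_err=self.k_max_err_,
            k_half_err=self.k_half_err_,
            saturation_not_reached=self.saturation_not_reached_,
        )


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------

def fit_first_order(tc: TimeCourse, fix_plateau_zero: bool = False) -> DecayFit:
    """Fit one time course to the pseudo-first-order decay model.

    When per-point SDs are available the residuals are weighted by 1/sd².
    """
    weights = None
    if tc.sd is not None and np.all(tc.sd > 0):
        weights = 1.0 / tc.sd**2
    est = FirstOrderDecay(fix_plateau_zero=fix_plateau_zero)
    est.fit(tc.times, tc.soluble_frac, sample_weight=weights)
    return est.result_()


def fit_rate_saturation(profile: RateProfile) -> SaturationFit:
    """Fit apparent rates vs chaperonin concentration to the hyperbola."""
    weights = None
    if profile.k_app_errs is not None and np.all(profile.k_app_errs > 0):
        weights = 1.0 / profile.k_app_errs**2
    est = SaturationCurve()
    est.fit(profile.el_concs, profile.k_apps, sample_weight=weights)
    return est.result_()


def fraction_remaining(fit: DecayFit, t: float) -> float:
    """Evaluate the fitted decay at time ``t`` (minutes)."""
    if t < 0:
        raise InputError(f"t must be >= 0, got {t!r}")
    return float(fit.s_inf + (fit.s0 - fit.s_inf) * np.exp(-fit.k_app * t))
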