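"""Two-state thermal unfolding: van 't Hoff melts, Tm shifts, osmolyte trends.

Unfolding is treated as a two-state equilibrium N <-> U with

    K(T) = exp[(ΔH_vH / R) (1/T_m - 1/T)],   f_u(T) = K / (1 + K)

(T in kelvin, ΔCp = 0).  The observed signal is the population-weighted sum
of two linear baselines::

    y(T) = (a_n + b_n T)(1 - f_u) + (a_u + b_u T) f_u

which covers both raw DSF fluorescence traces (free baselines) and
equilibrium denaturation curves already normalised to fraction unfolded
(baselines fixed to 0 and 1).  ΔTm relative to a no-additive control and the
Tm-vs-osmolyte-concentration slope summarise stabilisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import linregress
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InputError, NoTransitionError, ParameterError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "MeltCurve",
    "TwoStateFit",
    "OsmolyteSeries",
    "TrendResult",
    "TwoStateMelt",
    "fraction_unfolded",
    "melt_signal",
    "fit_melt",
    "delta_tm",
    "stabilization_trend",
    "FRATAXIN_DSF_TM_TABLE",
    "reference_osmolyte_series",
    "dtm_consistency_report",
]

#: Gas constant in kcal·mol⁻¹·K⁻¹.
GAS_CONSTANT_KCAL = 1.987e-3

_C_TO_K = 273.15


def fraction_unfolded(t: float | np.ndarray, tm: float, dh_vh: float):
    """Fraction unfolded at temperature ``t`` (°C) for a two-state transition.

    ``dh_vh`` is the van 't Hoff enthalpy in kcal/mol; it must be positive
    for a cooperative (signal-increasing) transition.  Exactly 0.5 at t = tm.
    """
    if dh_vh <= 0:
        raise ParameterError(f"dh_vh must be > 0, got {dh_vh!r}")
    t_k = np.asarray(t, dtype=float) + _C_TO_K
    tm_k = tm + _C_TO_K
    # log-space form avoids overflow far from Tm
    x = (dh_vh / GAS_CONSTANT_KCAL) * (1.0 / tm_k - 1.0 / t_k)
    out = 1.0 / (1.0 + np.exp(-x))
    return float(out) if np.isscalar(t) else out


@dataclass
class MeltCurve:
    """One thermal scan: temperature grid (°C) and signal (a.u. or fraction)."""

    temps: np.ndarray
    signal: np.ndarray
    heating_rate: float = 1.5  # °C/min, metadata
    probe: str = ""

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temps.shape != self.signal.shape:
            raise InputError("temps and signal must have the same length")
        if np.any(np.diff(self.temps) <= 0):
            raise InputError("temps must be strictly increasing (no repeats)")

    def validate_for_fitting(self) -> None:
        if self.temps.size < 20:
            raise InputError(f"need >= 20 points for fitting, got {self.temps.size}")
        if np.ptp(self.temps) < 20:
            raise InputError("scan must span >= 20 °C for fitting")


@dataclass
class TwoStateFit:
    """Fitted two-state melt: Tm (°C), ΔH_vH (kcal/mol) and linear baselines."""

    tm: float
    dh_vh: float
    a_n: float
    b_n: float
    a_u: float
    b_u: float
    rss: float
    converged: bool
    tm_stderr: float | None = None
    edge_flag: bool = False


def melt_signal(t: float | np.ndarray, fit: TwoStateFit):
    """Evaluate the baseline-weighted two-state observation model at ``t`` °C."""
    fu = fraction_unfolded(t, fit.tm, fit.dh_vh)
    t = np.asarray(t, dtype=float)
    out = (fit.a_n + fit.b_n * t) * (1.0 - fu) + (fit.a_u + fit.b_u * t) * fu
    return float(out) if out.ndim == 0 else out


class TwoStateMelt(RegressorMixin, BaseEstimator):
    """Least-squares two-state melt fit as an sklearn-style estimator.

    Parameters
    ----------
    fix_baselines : bool
        Fix the folded/unfolded baselines to 0 and 1 (use for equilibrium
        curves already normalised to fraction unfolded).
    truncate_post_max : bool
        Drop points after the signal maximum before fitting.  DSF traces often
        decay past the transition (dye release / aggregation), which the
        two-state model does not describe.
    min_amplitude_snr : float
        A fit whose transition amplitude at Tm is below this multiple of the
        residual RMS is rejected as showing no transition.
    edge_margin_frac : float
        Tm within this fraction of the scan range from either edge sets the
        edge flag and emits a warning.

    Attributes (after ``fit``)
    --------------------------
    tm_, dh_vh_, a_n_, b_n_, a_u_, b_u_, rss_, converged_, tm_stderr_,
    edge_flag_.
    """

    def __init__(
        self,
        fix_baselines: bool = False,
        truncate_post_max: bool = False,
        min_amplitude_snr: float = 5.0,
        edge_margin_frac: float = 0.05,
    ):
        self.fix_baselines = fix_baselines
        self.truncate_post_max = truncate_post_max
        self.min_amplitude_snr = min_amplitude_snr
        self.edge_margin_frac = edge_margin_frac

    # -- initialisation heuristics ------------------------------------
    @staticmethod
    def _tm_init(t: np.ndarray, y: np.ndarray) -> float:
        window = min(11, t.size - (t.size + 1) % 2)  # odd, <= n
        smooth = savgol_filter(y, window, 2) if window >= 5 else y
        dy = np.gradient(smooth, t)
        return float(t[np.argmax(np.abs(dy))])

    @staticmethod
    def _baseline_init(t: np.ndarray, y: np.ndarray, frac: float = 0.15):
        k = max(2, int(frac * t.size))
        lo = np.polyfit(t[:k], y[:k], 1)
        hi = np.polyfit(t[-k:], y[-k:], 1)
        return (lo[1], lo[0]), (hi[1], hi[0])  # (intercept, slope) pairs

    def fit(self, X, y, sample_weight=None):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise InputError("y must match X in length")

        if self.truncate_post_max:
            imax = int(np.argmax(y))
            if imax >= 4:
                t, y = t[: imax + 1], y[: imax + 1]

        if np.ptp(y) == 0.0:
            raise NoTransitionError("signal is constant; no transition to fit")

        params = lmfit.Parameters()
        params.add("tm", value=self._tm_init(t, y), min=t[0], max=t[-1])
        params.add("dh_vh", value=45.0, min=1.0, max=500.0)
        if self.fix_baselines:
            params.add("a_n", value=0.0, vary=False)
            params.add("b_n", value=0.0, vary=False)
            params.add("a_u", value=1.0, vary=False)
            params.add("b_u", value=0.0, vary=False)
        else:
            (a_n0, b_n0), (a_u0, b_u0) = self._baseline_init(t, y)
            params.add("a_n", value=a_n0)
            params.add("b_n", value=b_n0)
            params.add("a_u", value=a_u0)
            params.add("b_u", value=b_u0)

        def model(p):
            fu = fraction_unfolded(t, p["tm"].value, p["dh_vh"].value)
            return (p["a_n"] + p["b_n"] * t) * (1 - fu) + (p["a_u"] + p["b_u"] * t) * fu

        def resid(p):
            r = model(p) - y
            if sample_weight is not None:
                r = r * np.sqrt(np.asarray(sample_weight, dtype=float))
            return r

        res = lmfit.minimize(resid, params, method="leastsq")
        p = res.params
        yhat = model(p)
        rms = float(np.sqrt(np.mean((yhat - y) ** 2)))
        tm = float(p["tm"].value)
        amplitude = abs(
            (p["a_u"].value + p["b_u"].value * tm)
            - (p["a_n"].value + p["b_n"].value * tm)
        )
        if amplitude < self.min_amplitude_snr * rms:
            raise NoTransitionError(
                "no resolvable transition: fitted amplitude "
                f"{amplitude:.3g} below {self.min_amplitude_snr}x residual RMS {rms:.3g}"
            )

        self.tm_ = tm
        self.dh_vh_ = float(p["dh_vh"].value)
        self.a_n_ = float(p["a_n"].value)
        self.b_n_ = float(p["b_n"].value)
        self.a_u_ = float(p["a_u"].value)
        self.b_u_ = float(p["b_u"].value)
        self.rss_ = float(np.sum((yhat - y) ** 2))
        self.converged_ = bool(res.success)
        self.tm_stderr_ = float(p["tm"].stderr) if p["tm"].stderr is not None else None

        margin = self.edge_margin_frac * np.ptp(t)
        self.edge_flag_ = bool(tm < t[0] + margin or tm > t[-1] - margin)
        if self.edge_flag_:
            warnings.warn(
                f"transition at scan edge (Tm = {tm:.1f} °C within {margin:.1f} °C "
                "of the scanned range boundary)",
                stacklevel=2,
            )
        return self

    def predict(self, X):
        return melt_signal(np.asarray(X, dtype=float).ravel(), self.result_())

    def result_(self) -> TwoStateFit:
        return TwoStateFit(
            tm=self.tm_,
            dh_vh=self.dh_vh_,
            a_n=self.a_n_,
            b_n=self.b_n_,
            a_u=self.a_u_,
            b_u=self.b_u_,
            rss=self.rss_,
            converged=self.converged_,
            tm_stderr=self.tm_stderr_,
            edge_flag=self.edge_flag_,
        )


def fit_melt(
    curve: MeltCurve,
    fix_baselines: bool = False,
    truncate_post_max: bool = False,
) -> TwoStateFit:
    """Fit a melt curve to the two-state model; see :class:`TwoStateMelt`."""
    curve.validate_for_fitting()
    est = TwoStateMelt(fix_baselines=fix_baselines, truncate_post_max=truncate_post_max)
    est.fit(curve.temps, curve.signal)
    return est.result_()


def delta_tm(fit: TwoStateFit, control: TwoStateFit) -> float:
    """Melting-temperature shift vs the no-additive control (°C)."""
    if not (fit.converged and control.converged):
        raise InputError("delta_tm requires converged fits on both sides")
    return fit.tm - control.tm


# --------------------------------------------------------------------------
# osmolyte concentration-response summaries
# --------------------------------------------------------------------------

@dataclass
class OsmolyteSeries:
    """Tm across osmolyte concentrations, referenced to a no-osmolyte control."""

    osmolyte: str
    concs: np.ndarray
    tms: np.ndarray
    control_tm: float
    dtms: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.concs = np.asarray(self.concs, dtype=float)
        self.tms = np.asarray(self.tms, dtype=float)
        if self.concs.shape != self.tms.shape:
            raise InputError("concs and tms must have the same length")
        if np.any(self.concs < 0) or np.any(np.diff(self.concs) <= 0):
            raise InputError("concs must be non-negative and increasing")
        self.dtms = self.tms - self.control_tm


@dataclass
class TrendResult:
    """OLS slope of Tm vs osmolyte concentration with a sign classification."""

    slope: float  # °C per molar
    stderr: float
    sign: str  # "stabilizing" | "neutral" | "destabilizing"


def stabilization_trend(series: OsmolyteSeries, z: float = 2.0) -> TrendResult:
    """Ordinary least-squares Tm-vs-concentration slope and its sign.

    The sign is "stabilizing" when the slope exceeds ``z`` standard errors
    above zero, "destabilizing" below, "neutral" otherwise.
    """
    if series.concs.size < 3:
        raise InputError("need at least 3 concentrations for a trend")
    res = linregress(series.concs, series.tms)
    slope, stderr = float(res.slope), float(res.stderr)
    if slope > z * stderr:
        sign = "stabilizing"
    elif slope < -z * stderr:
        sign = "destabilizing"
    else:
        sign = "neutral"
    return TrendResult(slope=slope, stderr=stderr, sign=sign)


# --------------------------------------------------------------------------
# published reference Tm table (frataxin variants, DSF, two-state fits)
# --------------------------------------------------------------------------

#: Published DSF melting temperatures (°C) for wild-type frataxin and the
#: clinical variants D122Y and I154F, with and without osmolytes, as reported
#: for the two-state fits; used as reference input for ΔTm arithmetic.
#: Each entry: control Tm, then per-osmolyte (conc_M, tm_c, dtm_printed) rows.
FRATAXIN_DSF_TM_TABLE: dict[str, dict] = {
    "WT": {
        "control_tm": 55.1,
        "trehalose": [
            (0.025, 54.6, -0.5),
            (0.050, 54.9, -0.2),
            (0.125, 55.3, 0.2),
            (0.250, 56.5, 1.4),
            (0.500, 57.8, 2.7),
            (0.750, 60.2, 5.1),
        ],
        "tmao": [
            (0.05, 50.1, 0.5),
            (0.2, 51.3, 1.0),
            (0.5, 52.0, 3.0),
            (0.75, 54.0, 4.8),
            (1.0, 48.8, 5.8),
        ],
    },
    "D122Y": {
        "control_tm": 48.8,
        "trehalose": [
            (0.025, 50.1, 3.9),
            (0.050, 50.7, 4.5),
            (0.125, 50.3, 4.1),
            (0.250, 50.3, 4.1),
            (0.500, 53.4, 7.2),
            (0.750, 54.1, 7.9),
        ],
        "tmao": [
            (0.05, 48.8, 2.6),
            (0.2, 50.1, 4.0),
            (0.5, 51.3, 5.1),
            (0.75, 52.0, 5.8),
            (1.0, 54.0, 7.8),
        ],
    },
    "I154F": {
        "control_tm": 39.1,
        "trehalose": [
            (0.025, 39.6, 0.5),
            (0.050, 39.5, 0.4),
            (0.125, 38.3, -0.8),
            (0.250, 39.6, 0.5),
            (0.500, 40.3, 1.2),
            (0.750, 39.3, 0.2),
        ],
        "tmao": [
            (0.05, 39.7, 0.6),
            (0.2, 38.4, 1.3),
            (0.5, 40.9, 1.8),
            (0.75, 42.2, 3.1),
            (1.0, 41.6, 2.5),
        ],
    },
}


def reference_osmolyte_series(variant: str, osmolyte: str) -> OsmolyteSeries:
    """Build an :class:`OsmolyteSeries` from the published reference Tm table.

    ΔTm is recomputed as Tm − control from the Tm column (the authoritative
    arithmetic); use :func:`dtm_consistency_report` to compare against the
    ΔTm values as printed.
    """
    try:
        entry = FRATAXIN_DSF_TM_TABLE[variant]
        rows = entry[osmolyte.lower()]
    except KeyError as exc:
        raise InputError(f"no reference series for {variant!r}/{osmolyte!r}") from exc
    concs = [r[0] for r in rows]
    tms = [r[1] for r in rows]
    return OsmolyteSeries(
        osmolyte=osmolyte.lower(), concs=np.array(concs), tms=np.array(tms),
        control_tm=entry["control_tm"],
    )


def dtm_consistency_report(atol: float = 0.1) -> pd.DataFrame:
    """Cross-check the reference table's printed ΔTm against Tm − control.

    Several printed ΔTm entries are not equal to Tm minus the printed control
    (e.g. the D122Y trehalose column is consistent with a ~46.2 °C reference
    rather than the 48.8 °C control row, and the low-concentration WT TMAO
    rows disagree in sign).  This report surfaces those rows; it does not
    attempt to resolve them.  ``consistent`` is True when the recomputed and
    printed shifts agree within ``atol`` °C.
    """
    rows = []
    for variant, entry in FRATAXIN_DSF_TM_TABLE.items():
        control = entry["control_tm"]
        for osmolyte in ("trehalose", "tmao"):
            for conc, tm, dtm_printed in entry[osmolyte]:
                computed = round(tm - control, 10)
                rows.append(
                    {
                        "variant": variant,
                        "osmolyte": osmolyte,
                        "conc_M": conc,
                        "tm_c": tm,
                        "dtm_printed": dtm_printed,
                        "dtm_computed": computed,
                        "consistent": abs(computed - dtm_printed) <= atol,
                    }
                )
    return pd.DataFrame(rows)
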