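"""Forward kinetic model of chaperonin capture.

A natively folded protein N exchanges with a partially folded intermediate I
(the chaperonin-binding conformer).  Nucleotide-free GroEL binds I with
sub-nanomolar affinity, so capture is treated as irreversible; I can also be
lost to a competing second-order aggregation channel::

    N  <--k_u / k_f-->  I  --k_c [EL]-->  C   (captured on beads)
                        I + I --k_agg-->  A   (aggregate, monomer units)

Under the steady-state approximation for I, the depletion of soluble protein
(N + I) is a single exponential with apparent rate

    k_app = k_u * k_c * [EL] / (k_f + k_c * [EL])

which rises hyperbolically with chaperonin concentration and saturates at the
intrinsic unfolding rate k_u: at high [EL] unfolding becomes rate-limiting.

Units are minutes and µM throughout.  Temperature and urea are metadata only;
they enter the model through the choice of rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import NumericalError, ParameterError

__all__ = [
    "CaptureParams",
    "ExperimentCondition",
    "SpeciesTrajectory",
    "simulate_capture",
    "apparent_rate",
]

#: Integrator tolerances (stiff-safe defaults).
_RTOL = 1e-8
_ATOL = 1e-10  # µM


@dataclass(frozen=True)
class CaptureParams:
    """Microscopic rate constants of the folding/capture/aggregation scheme.

    Parameters
    ----------
    k_u : float
        Unfolding rate N -> I (min⁻¹).
    k_f : float
        Refolding rate I -> N (min⁻¹).
    k_c : float
        Capture association rate of I onto chaperonin (µM⁻¹·min⁻¹); site
        multiplicity of the oligomer is absorbed into this constant.
    k_agg : float
        Second-order aggregation rate of I (µM⁻¹·min⁻¹).
    """

    k_u: float
    k_f: float
    k_c: float
    k_agg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_u", "k_f", "k_c", "k_agg"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ParameterError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class ExperimentCondition:
    """One partitioning condition: chaperonin and protein concentrations.

    ``temperature_c`` and ``urea_m`` are recorded for provenance; the kinetic
    model carries no explicit temperature dependence.
    """

    el_conc: float
    protein0: float = 2.0
    temperature_c: float = 45.0
    urea_m: float = 1.0

    def __post_init__(self) -> None:
        if self.el_conc < 0:
            raise ParameterError(f"el_conc must be >= 0, got {self.el_conc!r}")
        if self.protein0 <= 0:
            raise ParameterError(f"protein0 must be > 0, got {self.protein0!r}")


@dataclass
class SpeciesTrajectory:
    """Time courses of the four species pools (µM) for one condition."""

    times: np.ndarray
    n: np.ndarray
    i: np.ndarray
    c: np.ndarray
    a: np.ndarray
    protein0: float

    @property
    def soluble(self) -> np.ndarray:
        """Soluble pool N + I (µM): what survives the bead spin-down."""
        return self.n + self.i

    @property
    def soluble_frac(self) -> np.ndarray:
        """Soluble pool as a fraction of the starting concentration."""
        return self.soluble / self.protein0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "n_uM": self.n,
                "i_uM": self.i,
                "c_uM": self.c,
                "a_uM": self.a,
                "soluble_frac": self.soluble_frac,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def apparent_rate(params: CaptureParams, el_conc: float) -> float:
    """Closed-form apparent (macroscopic) partitioning rate, min⁻¹.

    Steady-state in the intermediate gives
    ``k_app = k_u k_c [EL] / (k_f + k_c [EL])``: zero without chaperonin,
    monotone in [EL], bounded above by ``k_u``.
    """
    if el_conc < 0:
        raise ParameterError(f"el_conc must be >= 0, got {el_conc!r}")
    denom = params.k_f + params.k_c * el_conc
    if denom <= 0:
        raise ParameterError(
            "k_f + k_c*[EL] must be > 0 for the steady-state rate "
            f"(k_f={params.k_f}, k_c={params.k_c}, el_conc={el_conc})"
        )
    return params.k_u * params.k_c * el_conc / denom


def _rhs(t: float, y: np.ndarray, p: CaptureParams, el: float) -> list[float]:
    n, i, c, a = y
    flux_agg = 2.0 * p.k_agg * i * i
    return [
        -p.k_u * n + p.k_f * i,
        p.k_u * n - p.k_f * i - p.k_c * el * i - flux_agg,
        p.k_c * el * i,
        flux_agg,
    ]


def simulate_capture(
    params: CaptureParams,
    cond: ExperimentCondition,
    times: Sequence[float],
) -> SpeciesTrajectory:
    """Integrate the capture scheme and return all species trajectories.

    Initial state is all-native: N(0) = protein0, I = C = A = 0.  The ODE is
    mildly stiff when k_f + k_c[EL] >> k_u, so LSODA is used with rtol 1e-8 /
    atol 1e-10 µM; mass (N+I+C+A) is conserved to that tolerance.

    Raises
    ------
    ParameterError
        On negative rates/concentrations or a degenerate time grid.
    NumericalError
        If the integrator fails; the solver message is included.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ParameterError("times must be a 1-d sequence of at least 2 points")
    if t[0] != 0:
        raise ParameterError(f"times must start at 0, got first point {t[0]!r}")
    if np.any(np.diff(t) <= 0):
        raise ParameterError("times must be strictly increasing")

    y0 = [cond.protein0, 0.0, 0.0, 0.0]
    sol = solve_ivp(
        _rhs,
        (t[0], t[-1]),
        y0,
        t_eval=t,
        args=(params, cond.el_conc),
        method="LSODA",
        rtol=_RTOL,
        atol=_ATOL,
    )
    if not sol.success:
        raise NumericalError(
            f"capture ODE integration failed: {sol.message} "
            f"(params={params}, el_conc={cond.el_conc})"
        )
    n, i, c, a = sol.y
    # Integration noise can leave tiny negatives at the atol scale.
    clip = lambda x: np.clip(x, 0.0, None)
    return SpeciesTrajectory(
        times=t, n=clip(n), i=clip(i), c=clip(c), a=clip(a), protein0=cond.protein0
    )
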