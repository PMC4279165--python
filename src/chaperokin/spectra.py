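"""UV-vis QC: baseline-corrected A280 and light-scattering aggregation metrics.

Soluble protein is quantified as A(280) − A(350): the 350 nm reading carries
no protein absorbance and subtracting it cancels instrument/baseline drift.
Aggregation produces Rayleigh-type scattering, a smooth baseline rising
towards short wavelengths (approximately c·λ⁻β with β ≈ 4 for small
particles).  Because that baseline is curved, the flat two-point subtraction
under-corrects in the presence of genuine scatter — which is exactly why the
scatter diagnostics here are kept separate from the concentration readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = [
    "UVSpectrum",
    "AggregationMetrics",
    "baseline_corrected_a280",
    "scatter_profile",
    "aggregation_index",
    "aggregation_metrics",
]

#: ΔA350 above which a spectrum pair is classified as aggregating (AU).
DEFAULT_AGGREGATION_THRESHOLD = 0.01

#: Default wavelength window (nm) free of protein absorbance, for scatter fits.
DEFAULT_SCATTER_WINDOW = (320.0, 400.0)


@dataclass
class UVSpectrum:
    """One absorbance spectrum: wavelengths (nm, increasing) and AU values."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise InputError("wavelengths and absorbance must have the same length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise InputError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise InputError("absorbance must be finite")
        if self.wavelengths.size >= 2 and np.max(np.diff(self.wavelengths)) > 2.0:
            raise InputError("wavelength grid step must be <= 2 nm")

    def at(self, wavelength: float) -> float:
        """Linearly interpolated absorbance at ``wavelength`` (nm)."""
        w = self.wavelengths
        if not (w[0] <= wavelength <= w[-1]):
            raise InputError(
                f"spectrum {self.label!r} does not cover {wavelength} nm "
                f"(range {w[0]}-{w[-1]} nm)"
            )
        return float(np.interp(wavelength, w, self.absorbance))


@dataclass
class AggregationMetrics:
    """QC summary for one spectrum (optionally referenced to a t=0 spectrum)."""

    a280: float
    a350: float
    corrected_a280: float
    scatter_exponent: float | None
    scatter_amplitude: float
    scatter_index: float | None  # ΔA350 vs reference, if one was given
    aggregating: bool | None


def baseline_corrected_a280(spec: UVSpectrum) -> float:
    """A(280) − A(350): drift-corrected protein absorbance.

    Invariant under any wavelength-independent offset.  Note that curved
    scattering baselines are only partially removed by this two-point
    correction (see module docstring).
    """
    return spec.at(280.0) - spec.at(350.0)


def scatter_profile(
    spec: UVSpectrum, window: tuple[float, float] = DEFAULT_SCATTER_WINDOW
) -> tuple[float | None, float]:
    """Power-law characterisation of the scattering baseline.

    Fits ``log A = log c − β log λ`` over a protein-absorbance-free window
    and returns ``(β, c)``.  If any absorbance in the window is non-positive
    the log-log fit is undefined and a flagged no-scatter result
    ``(None, 0.0)`` is returned.
    """
    lo, hi = window
    mask = (spec.wavelengths >= lo) & (spec.wavelengths <= hi)
    if mask.sum() < 3:
        raise InputError(f"window {window} covers fewer than 3 grid points")
    lam = spec.wavelengths[mask]
    a = spec.absorbance[mask]
    if np.any(a <= 0):
        return None, 0.0
    slope, intercept = np.polyfit(np.log(lam), np.log(a), 1)
    return float(-slope), float(np.exp(intercept))


def aggregation_index(spec_t: UVSpectrum, spec_0: UVSpectrum) -> float:
    """ΔA350 between a later spectrum and its t=0 reference (AU).

    Positive values indicate growing light-scattering contributions;
    antisymmetric under swapping the arguments.
    """
    return spec_t.at(350.0) - spec_0.at(350.0)


def aggregation_metrics(
    spec: UVSpectrum,
    reference: UVSpectrum | None = None,
    noise_floor: float = 0.002,
    threshold: float = DEFAULT_AGGREGATION_THRESHOLD,
    window: tuple[float, float] = DEFAULT_SCATTER_WINDOW,
) -> AggregationMetrics:
    """Full QC readout for one spectrum.

    The scatter exponent is only reported when A(350) exceeds three times the
    ``noise_floor`` (AU); below that the log-log fit is noise-dominated.
    When ``reference`` is given, ΔA350 against it is computed and classified
    as aggregating when above ``threshold``.
    """
    a280 = spec.at(280.0)
    a350 = spec.at(350.0)
    if a350 > 3.0 * noise_floor:
        beta, amp = scatter_profile(spec, window=window)
    else:
        beta, amp = None, 0.0
    index = aggregating = None
    if reference is not None:
        index = aggregation_index(spec, reference)
        aggregating = index > threshold
    return AggregationMetrics(
        a280=a280,
        a350=a350,
        corrected_a280=a280 - a350,
        scatter_exponent=beta,
        scatter_amplitude=amp,
        scatter_index=index,
        aggregating=aggregating,
    )
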