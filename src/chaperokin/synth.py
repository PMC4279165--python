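"""Seeded synthetic-data generators for every input the pipeline consumes.

The variant presets encode the study conditions: capture rate constants
calibrated so that the published partitioning endpoints emerge from the
forward model (I154F ~25% and D122Y ~55% soluble after 60 min at 3 µM
chaperonin; wild type essentially unpartitioned), and the published DSF and
equilibrium melting temperatures.  The van 't Hoff enthalpy (45 kcal/mol for
all variants) and the baseline/noise constants are package choices — no raw
fluorescence or enthalpy values are published — kept here in one place so
they are trivially changeable.

Every generator is a pure function of its parameters and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .capture import CaptureParams, ExperimentCondition, simulate_capture
from .errors import InputError, ParameterError
from .partition import TimeCourse
from .solubility import DensitometryRecord
from .spectra import UVSpectrum
from .thermal import MeltCurve, TwoStateFit, fraction_unfolded, melt_signal

__all__ = [
    "VariantPreset",
    "PRESETS",
    "preset",
    "gen_timecourse",
    "gen_meltcurve",
    "gen_equilibrium_curve",
    "gen_spectrum",
    "gen_densitometry",
    "DEFAULT_TIMECOURSE_TIMES",
    "DEFAULT_EL_CONCS",
]

#: Sampling grid used for partitioning assays (minutes).
DEFAULT_TIMECOURSE_TIMES = (0.0, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0)

#: Chaperonin oligomer concentrations scanned in the saturation experiment (µM).
DEFAULT_EL_CONCS = (0.5, 1.0, 2.0, 3.0, 6.0, 12.0)

#: Default DSF baseline constants (a_n, b_n, a_u, b_u) in fluorescence a.u.
DEFAULT_DSF_BASELINES = (1000.0, 1.0, 9000.0, -4.0)


@dataclass(frozen=True)
class VariantPreset:
    """Calibrated constants for one frataxin variant.

    ``tm_dsf`` is the apparent kinetic Tm from dye-based scanning
    fluorimetry; ``tm_equilibrium`` the equilibrium denaturation Tm (the DSF
    values sit well below equilibrium because the dye shifts the folded ⇌
    unfolded balance).  ``capture`` holds the partitioning rate constants.
    """

    name: str
    capture: CaptureParams
    tm_dsf: float
    tm_equilibrium: float
    dh_vh: float


PRESETS: dict[str, VariantPreset] = {
    "WT": VariantPreset(
        name="WT",
        capture=CaptureParams(k_u=1e-4, k_f=1.0, k_c=0.3, k_agg=0.0),
        tm_dsf=55.1,
        tm_equilibrium=66.3,
        dh_vh=45.0,
    ),
    "D122Y": VariantPreset(
        name="D122Y",
        capture=CaptureParams(k_u=0.015, k_f=0.450, k_c=0.30, k_agg=0.005),
        tm_dsf=48.8,
        tm_equilibrium=50.4,
        dh_vh=45.0,
    ),
    "I154F": VariantPreset(
        name="I154F",
        capture=CaptureParams(k_u=0.030, k_f=0.300, k_c=0.35, k_agg=0.02),
        tm_dsf=39.1,
        tm_equilibrium=50.7,
        dh_vh=45.0,
    ),
}


def preset(name: str) -> VariantPreset:
    """Return the immutable preset for ``name`` (WT, D122Y or I154F)."""
    try:
        return PRESETS[name]
    except KeyError as exc:
        raise InputError(
            f"unknown variant {name!r}; choose from {sorted(PRESETS)}"
        ) from exc


def gen_timecourse(
    variant: VariantPreset | str,
    cond: ExperimentCondition,
    times=DEFAULT_TIMECOURSE_TIMES,
    noise_sd: float = 0.02,
    n_replicates: int = 3,
    seed: int = 0,
    aggregate_escape_frac: float = 0.0,
) -> TimeCourse:
    """Simulated soluble-fraction time course with replicate Gaussian noise.

    ``aggregate_escape_frac`` counts that fraction of the aggregated pool as
    soluble, emulating small aggregates that survive the brief spin-down; it
    defaults to 0 (full aggregate removal).

    Returns per-point replicate means and SDs (n−1 denominator); the output
    is deterministic for a fixed seed, and ``noise_sd = 0`` reproduces the
    noiseless simulation exactly.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if not 0 <= aggregate_escape_frac <= 1:
        raise ParameterError("aggregate_escape_frac must be in [0, 1]")
    v = preset(variant) if isinstance(variant, str) else variant
    traj = simulate_capture(v.capture, cond, times)
    truth = traj.soluble_frac + aggregate_escape_frac * traj.a / cond.protein0

    if noise_sd == 0:
        return TimeCourse(
            times=np.asarray(times, float),
            soluble_frac=truth,
            sd=np.zeros_like(truth),
            condition=cond,
        )
    rng = np.random.default_rng(seed)
    reps = truth[None, :] + rng.normal(0.0, noise_sd, size=(n_replicates, truth.size))
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1)
    # keep means inside the admissible band; noise_sd defaults make this rare
    mean = np.clip(mean, 0.0, 1.1)
    return TimeCourse(
        times=np.asarray(times, float), soluble_frac=mean, sd=sd, condition=cond
    )


def _melt_grid(t_range: tuple[float, float], step: float) -> np.ndarray:
    lo, hi = t_range
    if step <= 0:
        raise ParameterError("step must be > 0")
    if hi - lo < 2 * step:
        raise ParameterError(f"degenerate temperature range {t_range!r}")
    return np.arange(lo, hi + step / 2, step)


def gen_meltcurve(
    variant: VariantPreset | str,
    t_range: tuple[float, float] = (25.0, 80.0),
    step: float = 0.5,
    noise_frac: float = 0.01,
    seed: int = 0,
    baselines: tuple[float, float, float, float] = DEFAULT_DSF_BASELINES,
) -> MeltCurve:
    """Synthetic DSF trace for a variant: two-state melt with linear baselines.

    Noise is Gaussian with SD ``noise_frac`` times the transition amplitude
    at Tm.  Deterministic per seed.
    """
    v = preset(variant) if isinstance(variant, str) else variant
    temps = _melt_grid(t_range, step)
    a_n, b_n, a_u, b_u = baselines
    fit = TwoStateFit(
        tm=v.tm_dsf, dh_vh=v.dh_vh, a_n=a_n, b_n=b_n, a_u=a_u, b_u=b_u,
        rss=0.0, converged=True,
    )
    signal = melt_signal(temps, fit)
    if noise_frac:
        amplitude = abs((a_u + b_u * v.tm_dsf) - (a_n + b_n * v.tm_dsf))
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_frac * amplitude, size=temps.size)
    return MeltCurve(temps=temps, signal=signal, probe=f"synthetic DSF {v.name}")


def gen_equilibrium_curve(
    variant: VariantPreset | str,
    t_range: tuple[float, float] = (40.0, 85.0),
    step: float = 0.5,
    noise_frac: float = 0.01,
    seed: int = 0,
) -> MeltCurve:
    """Synthetic equilibrium denaturation curve, normalised to fraction unfolded.

    Baselines are 0 and 1 (fit with ``fix_baselines=True``); uses the
    variant's equilibrium Tm, not the dye-shifted DSF value.
    """
    v = preset(variant) if isinstance(variant, str) else variant
    temps = _melt_grid(t_range, step)
    signal = fraction_unfolded(temps, v.tm_equilibrium, v.dh_vh)
    if noise_frac:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_frac, size=temps.size)
    return MeltCurve(temps=temps, signal=signal, probe=f"synthetic equilibrium {v.name}")


def gen_spectrum(
    conc_au: float,
    scatter_a350: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    label: str = "",
) -> UVSpectrum:
    """Synthetic UV-vis spectrum on a 240–400 nm, 1 nm grid.

    A Gaussian protein band at 280 nm (σ = 15 nm, peak ``conc_au`` AU) plus a
    Rayleigh-type c·λ⁻⁴ scattering baseline scaled so A(350) = ``scatter_a350``,
    plus optional Gaussian noise.
    """
    if conc_au < 0 or scatter_a350 < 0 or noise_sd < 0:
        raise ParameterError("conc_au, scatter_a350 and noise_sd must be >= 0")
    lam = np.arange(240.0, 401.0, 1.0)
    band = conc_au * np.exp(-((lam - 280.0) ** 2) / (2.0 * 15.0**2))
    scatter = scatter_a350 * (350.0 / lam) ** 4
    absorbance = band + scatter
    if noise_sd:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, noise_sd, size=lam.size)
    return UVSpectrum(wavelengths=lam, absorbance=absorbance, label=label)


def gen_densitometry(
    true_fraction: float,
    variant: str = "synthetic",
    condition: str = "control",
    n_replicates: int = 3,
    cv: float = 0.1,
    seed: int = 0,
    total_intensity: float = 1000.0,
) -> list[DensitometryRecord]:
    """Triplicate soluble/pellet band pairs with multiplicative Gaussian noise.

    Each replicate's bands are ``total_intensity * f * (1 + cv·z)`` and
    ``total_intensity * (1-f) * (1 + cv·z')`` with independent standard
    normal z; intensities are floored at 0.  ``cv = 0`` reproduces
    ``true_fraction`` exactly, and the replicate-mean fraction converges to
    it as n grows.
    """
    if not 0 < true_fraction < 1:
        raise ParameterError("true_fraction must be in (0, 1)")
    if cv < 0:
        raise ParameterError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(1, n_replicates + 1):
        s = total_intensity * true_fraction
        p = total_intensity * (1.0 - true_fraction)
        if cv:
            s *= 1.0 + cv * rng.standard_normal()
            p *= 1.0 + cv * rng.standard_normal()
        records.append(
            DensitometryRecord(
                variant=variant,
                condition=condition,
                replicate=rep,
                s_band=max(s, 0.0),
                p_band=max(p, 0.0),
            )
        )
    return records
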