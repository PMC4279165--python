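"""CSV schemas, run configuration and the end-to-end analysis driver.

All files are long-format, decimal-point, UTF-8 CSV:

* time courses:  ``el_uM,time_min,soluble_frac,sd``
* rate profiles: ``el_uM,k_app_per_min,k_app_err``
* melt curves:   ``temp_c,signal``
* spectra:       ``wavelength_nm,absorbance_au``
* densitometry:  ``variant,condition,replicate,s_band,p_band``

``run_full_analysis`` chains the stages of a full synthetic study —
partitioning decays per chaperonin concentration, rate-saturation fit, melt
fits, ΔTm table, light-scattering QC and solubility table — into one
machine-readable report.  Stage failures are recorded in the report instead
of aborting the independent stages.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .capture import ExperimentCondition
from .errors import ChaperokinError, InputError, SchemaError
from .partition import (
    RateProfile,
    TimeCourse,
    fit_first_order,
    fit_rate_saturation,
)
from .solubility import DensitometryRecord, solubility_table
from .spectra import UVSpectrum, aggregation_metrics
from .thermal import (
    MeltCurve,
    dtm_consistency_report,
    fit_melt,
    reference_osmolyte_series,
    stabilization_trend,
)

__all__ = [
    "RunConfig",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_rate_profile_csv",
    "read_meltcurve_csv",
    "read_spectrum_csv",
    "read_densitometry_csv",
    "run_full_analysis",
]

log = logging.getLogger("chaperokin")

REPORT_SCHEMA_VERSION = 1

#: Buffer composition recorded for provenance in every report.
DEFAULT_BUFFER = "50 mM Tris, 50 mM KCl, 5 mM MgCl2, 0.5 mM EDTA, 1 mM DTT, pH 7.5"


@dataclass
class RunConfig:
    """Configuration of a full (synthetic) partitioning + stability study."""

    buffer: str = DEFAULT_BUFFER
    urea_m: float = 1.0
    temperature_c: float = 45.0
    protein0_partition: float = 2.0  # µM, partitioning assays
    protein0_dsf: float = 4.0  # µM, scanning fluorimetry
    el_concs: list[float] = field(default_factory=lambda: [0.5, 1.0, 2.0, 3.0, 6.0, 12.0])
    variants: list[str] = field(default_factory=lambda: ["I154F", "D122Y"])
    noise_sd: float = 0.02
    dsf_noise_frac: float = 0.01
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.el_concs:
            raise InputError("el_concs must not be empty")
        if any(c < 0 for c in self.el_concs):
            raise InputError("el_concs must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2)
            raw = {k: v for k, v in raw.items() if k in known}
        return cls(**raw)


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def _pyify(obj):
    """Recursively convert numpy scalars/arrays to plain Python for JSON."""
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def write_timecourse_csv(tcs: list[TimeCourse], path) -> None:
    rows = []
    for tc in tcs:
        el = tc.condition.el_conc if tc.condition is not None else np.nan
        sd = tc.sd if tc.sd is not None else np.full_like(tc.times, np.nan)
        for t, s, e in zip(tc.times, tc.soluble_frac, sd):
            rows.append({"el_uM": el, "time_min": t, "soluble_frac": s, "sd": e})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_timecourse_csv(path) -> list[TimeCourse]:
    """Read a long-format time-course CSV, grouped by chaperonin concentration."""
    df = pd.read_csv(path)
    if df.empty:
        raise InputError(f"{path}: empty input")
    _require_columns(df, ["el_uM", "time_min", "soluble_frac"], path)
    bad = df.index[(df["soluble_frac"] < 0) | (df["soluble_frac"] > 1.1)]
    if len(bad):
        raise SchemaError(
            f"{path}: soluble_frac outside [0, 1.1] at row(s) {list(bad + 2)} "
            "(1-based, counting the header)"
        )
    out = []
    for el, grp in df.groupby("el_uM", sort=True):
        grp = grp.sort_values("time_min")
        if grp["time_min"].duplicated().any():
            raise SchemaError(f"{path}: repeated time points for el_uM={el}")
        sd = grp["sd"].to_numpy() if "sd" in grp.columns else None
        if sd is not None and np.all(np.isnan(sd)):
            sd = None
        out.append(
            TimeCourse(
                times=grp["time_min"].to_numpy(),
                soluble_frac=grp["soluble_frac"].to_numpy(),
                sd=sd,
                condition=ExperimentCondition(el_conc=float(el)),
            )
        )
    return out


def read_rate_profile_csv(path) -> RateProfile:
    df = pd.read_csv(path)
    if df.empty:
        raise InputError(f"{path}: empty input")
    _require_columns(df, ["el_uM", "k_app_per_min"], path)
    errs = None
    if "k_app_err" in df.columns and not df["k_app_err"].isna().all():
        errs = df["k_app_err"].to_numpy()
    return RateProfile(
        el_concs=df["el_uM"].to_numpy(),
        k_apps=df["k_app_per_min"].to_numpy(),
        k_app_errs=errs,
    )


def read_meltcurve_csv(path) -> MeltCurve:
    df = pd.read_csv(path)
    if df.empty:
        raise InputError(f"{path}: empty input")
    _require_columns(df, ["temp_c", "signal"], path)
    return MeltCurve(temps=df["temp_c"].to_numpy(), signal=df["signal"].to_numpy())


def read_spectrum_csv(path, label: str = "") -> UVSpectrum:
    df = pd.read_csv(path)
    if df.empty:
        raise InputError(f"{path}: empty input")
    _require_columns(df, ["wavelength_nm", "absorbance_au"], path)
    return UVSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(),
        absorbance=df["absorbance_au"].to_numpy(),
        label=label or str(path),
    )


def read_densitometry_csv(path) -> list[DensitometryRecord]:
    df = pd.read_csv(path)
    if df.empty:
        raise InputError(f"{path}: empty input")
    _require_columns(df, ["variant", "condition", "replicate", "s_band", "p_band"], path)
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                DensitometryRecord(
                    variant=str(row["variant"]),
                    condition=str(row["condition"]),
                    replicate=int(row["replicate"]),
                    s_band=float(row["s_band"]),
                    p_band=float(row["p_band"]),
                )
            )
        except ChaperokinError as exc:
            raise SchemaError(f"{path}: row {idx + 2}: {exc}") from exc
    return records


# --------------------------------------------------------------------------
# end-to-end driver
# --------------------------------------------------------------------------

def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole synthetic study and return a JSON-serialisable report.

    Stages (each guarded; a failure is recorded under ``errors`` and the
    remaining stages still run):

    1. per-variant partitioning time courses at each chaperonin
       concentration, decay fits, and the rate-saturation fit;
    2. DSF melt fits per variant and the reference ΔTm / trend tables;
    3. UV light-scattering QC on a clean vs aggregating spectrum pair;
    4. densitometry solubility table.

    Deterministic for a fixed ``config.seed`` (no timestamps in the body).
    """
    from . import synth  # local import to avoid a cycle at module load

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            "buffer": config.buffer,
            "urea_m": config.urea_m,
            "temperature_c": config.temperature_c,
            "el_concs": list(config.el_concs),
            "variants": list(config.variants),
        },
        "errors": {},
    }
    log.info("run_full_analysis: seed=%d variants=%s", config.seed, config.variants)

    # -- stage 1: partitioning -----------------------------------------
    try:
        partitioning = {}
        for vi, name in enumerate(config.variants):
            v = synth.preset(name)
            decays = []
            for ci, el in enumerate(config.el_concs):
                cond = ExperimentCondition(
                    el_conc=el,
                    protein0=config.protein0_partition,
                    temperature_c=config.temperature_c,
                    urea_m=config.urea_m,
                )
                tc = synth.gen_timecourse(
                    v, cond, noise_sd=config.noise_sd,
                    seed=config.seed + 1000 * vi + ci,
                )
                fit = fit_first_order(tc)
                decays.append(
                    {
                        "el_uM": el,
                        "k_app_per_min": fit.k_app,
                        "k_app_err": fit.k_app_err,
                        "s0": fit.s0,
                        "s_inf": fit.s_inf,
                        "converged": fit.converged,
                    }
                )
            profile = RateProfile(
                el_concs=[d["el_uM"] for d in decays],
                k_apps=[d["k_app_per_min"] for d in decays],
            )
            sat = fit_rate_saturation(profile)
            partitioning[name] = {
                "decays": decays,
                "saturation": {
                    "k_max_per_min": sat.k_max,
                    "k_half_uM": sat.k_half,
                    "converged": sat.converged,
                    "saturation_not_reached": sat.saturation_not_reached,
                },
            }
        report["partitioning"] = partitioning
    except ChaperokinError as exc:
        log.error("partitioning stage failed: %s", exc)
        report["errors"]["partitioning"] = str(exc)

    # -- stage 2: thermal stability ------------------------------------
    try:
        melts = {}
        for vi, name in enumerate(["WT", "D122Y", "I154F"]):
            curve = synth.gen_meltcurve(
                name, noise_frac=config.dsf_noise_frac, seed=config.seed + 7000 + vi
            )
            fit = fit_melt(curve)
            melts[name] = {"tm_c": fit.tm, "dh_vh_kcal_mol": fit.dh_vh,
                           "converged": fit.converged}
        trends = {}
        for name in ["WT", "D122Y", "I154F"]:
            for osmolyte in ["trehalose", "tmao"]:
                series = reference_osmolyte_series(name, osmolyte)
                trend = stabilization_trend(series)
                trends[f"{name}/{osmolyte}"] = {
                    "slope_c_per_M": trend.slope,
                    "stderr": trend.stderr,
                    "sign": trend.sign,
                }
        report["thermal"] = {
            "dsf_fits": melts,
            "osmolyte_trends": trends,
            "dtm_inconsistent_rows": int(
                (~dtm_consistency_report()["consistent"]).sum()
            ),
        }
    except ChaperokinError as exc:
        log.error("thermal stage failed: %s", exc)
        report["errors"]["thermal"] = str(exc)

    # -- stage 3: light-scattering QC ----------------------------------
    try:
        spec0 = synth.gen_spectrum(0.30, scatter_a350=0.0, seed=config.seed + 31,
                                   noise_sd=0.001, label="t0")
        spec60 = synth.gen_spectrum(0.30, scatter_a350=0.05, seed=config.seed + 32,
                                    noise_sd=0.001, label="t60")
        qc = aggregation_metrics(spec60, reference=spec0)
        report["spectra_qc"] = {
            "corrected_a280": qc.corrected_a280,
            "scatter_exponent": qc.scatter_exponent,
            "delta_a350": qc.scatter_index,
            "aggregating": qc.aggregating,
        }
    except ChaperokinError as exc:
        log.error("spectra stage failed: %s", exc)
        report["errors"]["spectra_qc"] = str(exc)

    # -- stage 4: solubility -------------------------------------------
    try:
        records = []
        for vi, name in enumerate(["D122Y", "I154F"]):
            for ci, (condition, frac) in enumerate(
                [("control", 0.5), ("tmao_0.5M", 0.7), ("glycerol_0.5M", 0.6)]
            ):
                records.extend(
                    synth.gen_densitometry(
                        frac, variant=name, condition=condition,
                        seed=config.seed + 500 + 10 * vi + ci,
                    )
                )
        table = solubility_table(records)
        report["solubility"] = table.to_dict(orient="records")
    except ChaperokinError as exc:
        log.error("solubility stage failed: %s", exc)
        report["errors"]["solubility"] = str(exc)

    report = _pyify(report)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        import json

        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
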