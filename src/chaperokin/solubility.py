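"""In vivo solubility arithmetic from SDS-PAGE densitometry.

Each lysate yields a soluble (S) and pellet (P) band; the fraction expressed
in soluble form is S/(S+P), averaged over replicates (n = 3 by default).
Osmolyte effects are summarised as log2 of the ratio of soluble fractions
with and without the additive, so +1 means a doubling of solubility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "DensitometryRecord",
    "SolubilityResult",
    "fraction_soluble",
    "summarize_replicates",
    "log2_solubility_ratio",
    "solubility_table",
]


@dataclass(frozen=True)
class DensitometryRecord:
    """One gel lane pair: soluble and pellet band intensities (density units)."""

    variant: str
    condition: str  # e.g. "tmao_0.5M" or "control"
    replicate: int
    s_band: float
    p_band: float

    def __post_init__(self) -> None:
        if self.s_band < 0 or self.p_band < 0:
            raise InputError("band intensities must be >= 0")
        if self.s_band + self.p_band == 0:
            raise InputError("both bands zero: lane carries no signal")


@dataclass
class SolubilityResult:
    """Replicate-averaged soluble fraction, and log2 ratio vs control if set."""

    variant: str
    condition: str
    fraction_soluble: float
    sd: float
    n: int
    log2_ratio: float | None = None


def fraction_soluble(rec: DensitometryRecord) -> float:
    """S/(S+P) for one lane."""
    return rec.s_band / (rec.s_band + rec.p_band)


def summarize_replicates(records: Iterable[DensitometryRecord]) -> SolubilityResult:
    """Mean and SD (n−1 denominator) of the soluble fraction over replicates."""
    records = list(records)
    if not records:
        raise InputError("no densitometry records supplied")
    labels = {(r.variant, r.condition) for r in records}
    if len(labels) > 1:
        raise InputError(f"records mix variants/conditions: {sorted(labels)}")
    fracs = np.array([fraction_soluble(r) for r in records])
    sd = float(np.std(fracs, ddof=1)) if fracs.size > 1 else 0.0
    return SolubilityResult(
        variant=records[0].variant,
        condition=records[0].condition,
        fraction_soluble=float(np.mean(fracs)),
        sd=sd,
        n=fracs.size,
    )


def log2_solubility_ratio(cond: SolubilityResult, control: SolubilityResult) -> float:
    """log2(fraction_condition / fraction_control); +1 means doubled solubility."""
    if control.fraction_soluble <= 0:
        raise InputError("control soluble fraction must be > 0 for a log ratio")
    if cond.fraction_soluble <= 0:
        raise InputError("condition soluble fraction must be > 0 for a log ratio")
    return float(np.log2(cond.fraction_soluble / control.fraction_soluble))


def solubility_table(
    records: Iterable[DensitometryRecord], control_condition: str = "control"
) -> pd.DataFrame:
    """Per-(variant, condition) solubility summary with log2 ratios vs control.

    Columns: variant, condition, fraction_soluble, sd, n, log2_ratio.  The
    control rows carry log2_ratio 0 by construction.
    """
    groups: dict[tuple[str, str], list[DensitometryRecord]] = {}
    for rec in records:
        groups.setdefault((rec.variant, rec.condition), []).append(rec)
    if not groups:
        raise InputError("no densitometry records supplied")

    summaries = {key: summarize_replicates(g) for key, g in groups.items()}
    rows = []
    for (variant, condition), summary in sorted(summaries.items()):
        control = summaries.get((variant, control_condition))
        if control is None:
            raise InputError(f"no {control_condition!r} rows for variant {variant!r}")
        summary.log2_ratio = log2_solubility_ratio(summary, control)
        rows.append(
            {
                "variant": variant,
                "condition": condition,
                "fraction_soluble": summary.fraction_soluble,
                "sd": summary.sd,
                "n": summary.n,
                "log2_ratio": summary.log2_ratio,
            }
        )
    return pd.DataFrame(rows)
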