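"""Contrasts between chemicals, experiment-vs-prediction deltas, volatility classes.

Three kinds of comparison built on log10 Kaw values:

* structural contrasts -- per-condition absolute differences between two
  chemicals (e.g. ether vs thioether congeners, or CF3- vs C3F7- chain
  length), summarized by their mean and max;
* experimental minus in-silico-predicted log10 Kaw (signed), the usual way
  QSPR/LSER/quantum-chemical Henry's-law predictors are benchmarked;
* the OECD 309 indicative volatility classes: nonvolatile below
  log10 Kaw = -3.39, volatile above -1.39, semivolatile between (boundary
  values fall in the semivolatile class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "PredictionRecord",
    "DeltaResult",
    "VolatilityClass",
    "NONVOLATILE_THRESHOLD",
    "VOLATILE_THRESHOLD",
    "delta_log_kaw_pair",
    "delta_experimental_vs_predicted",
    "classify_volatility",
]

NONVOLATILE_THRESHOLD = -3.39
VOLATILE_THRESHOLD = -1.39


@dataclass(frozen=True)
class PredictionRecord:
    """One in-silico model's log10 Kaw prediction for one chemical.

    ``in_domain=False`` marks predictions outside the model's application
    domain; they are carried through comparisons but flagged in reports.
    ``uncertainty`` is an optional (minus, plus) pair in log10 units.
    """

    chemical: str
    model: str
    log10_kaw: float
    in_domain: bool = True
    uncertainty: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.model:
            raise ValueError("model name must be non-empty")


@dataclass(frozen=True)
class DeltaResult:
    """Per-condition log10 Kaw differences for one pair, with mean/max."""

    pair: tuple[str, str]
    per_condition: dict[str, float] = field(hash=False)
    mean_abs: float = 0.0
    max_abs: float = 0.0


def delta_log_kaw_pair(
    a: dict[str, float], b: dict[str, float], pair: tuple[str, str] = ("a", "b")
) -> DeltaResult:
    """Absolute per-condition differences of two log10 Kaw maps.

    ``a`` and ``b`` map a condition key (e.g. "40C", "25C_indirect") to a
    log10 Kaw point estimate; both must carry identical keys.  Returns the
    per-condition |a - b| plus the mean and max across conditions.
    """
    if set(a) != set(b):
        raise ValueError(
            f"condition keys differ: {sorted(set(a) ^ set(b))} not shared"
        )
    if not a:
        raise ValueError("empty condition maps")
    per = {k: abs(a[k] - b[k]) for k in a}
    vals = list(per.values())
    return DeltaResult(
        pair=pair,
        per_condition=per,
        mean_abs=sum(vals) / len(vals),
        max_abs=max(vals),
    )


def delta_experimental_vs_predicted(
    experimental: float, predicted: PredictionRecord | float
) -> float:
    """Signed difference: experimental minus predicted log10 Kaw."""
    p = predicted.log10_kaw if isinstance(predicted, PredictionRecord) else float(predicted)
    if not (math.isfinite(experimental) and math.isfinite(p)):
        raise ValueError("both log10 Kaw values must be finite")
    return experimental - p


class VolatilityClass(str, Enum):
    NONVOLATILE = "nonvolatile"
    SEMIVOLATILE = "semivolatile"
    VOLATILE = "volatile"


def classify_volatility(log10_kaw: float) -> VolatilityClass:
    """OECD 309 indicative volatility class of a log10 Kaw value.

    Strictly below -3.39: nonvolatile; strictly above -1.39: volatile;
    otherwise (boundaries included) semivolatile.
    """
    if not math.isfinite(log10_kaw):
        raise ValueError("log10_kaw must be finite")
    if log10_kaw < NONVOLATILE_THRESHOLD:
        return VolatilityClass.NONVOLATILE
    if log10_kaw > VOLATILE_THRESHOLD:
        return VolatilityClass.VOLATILE
    return VolatilityClass.SEMIVOLATILE
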