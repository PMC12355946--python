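"""Temperature dependence of Kaw: Van't Hoff regression and extrapolation.

The "indirect" method.  Over a modest temperature range the dimensionless
air-water partition coefficient follows

    ln Kaw = -dU / (R * T) + constant

where dU (kJ/mol) is the molar internal energy change of transferring the
molecule from water to air at constant system volume (the constant-volume
analogue of the enthalpy of volatilization in a sealed vial) and
R = 8.3145 J/(mol K).  Regressing ln Kaw on 1/T therefore gives dU from the
slope, and evaluating the line at 1/298.15 K extrapolates the partition
coefficient to 25 degC -- useful when a chemical is too involatile for the
direct fit at room temperature.

:class:`VantHoffModel` wraps an ordinary (optionally weighted) least-squares
regression; its :meth:`~VantHoffModel.fit` returns :class:`VantHoffResults`
with slope/intercept CIs, the derived dU, and extrapolation with the
confidence band of the regression mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

GAS_CONSTANT = 8.3145  # J mol^-1 K^-1
T_REF_25C = 298.15  # K
LN10 = math.log(10.0)

__all__ = [
    "GAS_CONSTANT",
    "T_REF_25C",
    "ExtrapolatedKaw",
    "VantHoffResults",
    "VantHoffModel",
    "fit_vant_hoff",
    "delta_u_from_slope",
    "extrapolate_log_kaw",
    "direct_vs_indirect",
]


def delta_u_from_slope(slope: float) -> float:
    """Internal energy of air-water partitioning, kJ/mol, from the regression slope (K).

    dU = -slope * R / 1000; a slope of -2864 K gives 23.8 kJ/mol.
    """
    if not math.isfinite(slope):
        raise ValueError("slope must be finite")
    return -slope * GAS_CONSTANT / 1000.0


@dataclass(frozen=True)
class ExtrapolatedKaw:
    """log10 Kaw at one temperature with its 95% CI and provenance tag."""

    chemical: str
    temperature: float  # K
    log10_kaw: float
    ci95: tuple[float, float]
    method: str  # "direct" or "indirect"
    extrapolated: bool = False  # True when outside the fitted 1/T range


@dataclass(frozen=True)
class VantHoffResults:
    """OLS/WLS fit of ln Kaw on 1/T with derived quantities."""

    chemical: str
    slope: float  # K
    slope_ci95: tuple[float, float]
    intercept: float
    intercept_ci95: tuple[float, float]
    r_squared: float
    temperatures: tuple[float, ...]  # K, as fitted
    n_points: int

    @property
    def delta_u(self) -> float:
        """dU in kJ/mol (= -slope * R / 1000)."""
        return delta_u_from_slope(self.slope)

    @property
    def delta_u_ci95(self) -> tuple[float, float]:
        """CI endpoints map linearly from the slope CI (order swaps)."""
        lo, hi = self.slope_ci95
        return (delta_u_from_slope(hi), delta_u_from_slope(lo))

    def predict_ln_kaw(self, temperature: float) -> float:
        return self.slope / temperature + self.intercept

    def extrapolate(self, temperature: float = T_REF_25C) -> ExtrapolatedKaw:
        """log10 Kaw at ``temperature`` with the regression-mean confidence band.

        The 95% band uses the t quantile at (n - 2) degrees of freedom and
        widens with the distance of 1/T from the mean of the fitted 1/T
        values; evaluation outside the fitted range is permitted and
        flagged ``extrapolated=True``.
        """
        x = np.array([1.0 / temperature])
        pred = self._sm_results.get_prediction(sm.add_constant(x, has_constant="add"))
        mean = float(pred.predicted_mean[0])
        lo, hi = (float(v) for v in pred.conf_int(alpha=0.05)[0])
        inv_t = [1.0 / t for t in self.temperatures]
        outside = not (min(inv_t) <= 1.0 / temperature <= max(inv_t))
        return ExtrapolatedKaw(
            chemical=self.chemical,
            temperature=temperature,
            log10_kaw=mean / LN10,
            ci95=(lo / LN10, hi / LN10),
            method="indirect",
            extrapolated=outside,
        )

    def summary(self) -> str:
        lo, hi = self.slope_ci95
        ulo, uhi = self.delta_u_ci95
        return "\n".join(
            [
                "Van't Hoff regression (ln Kaw = slope/T + intercept)",
                f"  chemical: {self.chemical}",
                f"  slope     {self.slope:.1f} K  95% CI [{lo:.1f}, {hi:.1f}]",
                f"  intercept {self.intercept:.4f}",
                f"  R^2       {self.r_squared:.4f}   n = {self.n_points}",
                f"  dU        {self.delta_u:.1f} kJ/mol  95% CI [{ulo:.1f}, {uhi:.1f}]",
            ]
        )


class VantHoffModel:
    """Linear model of ln Kaw against inverse absolute temperature.

    Parameters
    ----------
    temperatures_k : array-like
        Absolute temperatures, K, at least 3 distinct values.
    ln_kaw : array-like
        Natural log of the per-temperature Kaw point estimates.
    weights : array-like, optional
        Inverse-variance weights for WLS; unweighted OLS by default.
    """

    def __init__(self, temperatures_k, ln_kaw, weights=None, chemical: str = ""):
        t = np.asarray(temperatures_k, dtype=float)
        y = np.asarray(ln_kaw, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("temperatures and ln_kaw must be 1-D, equal length")
        if np.unique(t).size < 3:
            raise ValueError("need >= 3 distinct temperatures")
        if np.any(t <= 0):
            raise ValueError("temperatures must be in K and positive")
        self.temperatures_k = t
        self.ln_kaw = y
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        self.chemical = chemical

    @classmethod
    def from_fits(cls, fits, weighted: bool = False) -> "VantHoffModel":
        """Build from reportable :class:`~kawfit.estimation.KawFitResults`.

        With ``weighted=True``, inverse-variance weights for ln Kaw are
        derived by the delta method (var(ln K) ~ (se_K / K)^2, with se_K
        recovered from the CI half-width).
        """
        fits = [f for f in fits if f.reportable]
        if len(fits) < 3:
            raise ValueError("need >= 3 reportable fits")
        t = [f.temperature for f in fits]
        y = [math.log(f.kaw_hat) for f in fits]
        w = None
        if weighted:
            from scipy import stats

            w = []
            for f in fits:
                tq = stats.t.ppf(0.975, f.n_used - 2)
                se_k = (f.kaw_ci95[1] - f.kaw_ci95[0]) / (2 * tq)
                w.append((f.kaw_hat / se_k) ** 2)
        return cls(t, y, weights=w, chemical=fits[0].chemical)

    def fit(self) -> VantHoffResults:
        x = sm.add_constant(1.0 / self.temperatures_k)
        if self.weights is None:
            res = sm.OLS(self.ln_kaw, x).fit()
        else:
            res = sm.WLS(self.ln_kaw, x, weights=self.weights).fit()
        ci = res.conf_int(alpha=0.05)
        out = VantHoffResults(
            chemical=self.chemical,
            slope=float(res.params[1]),
            slope_ci95=(float(ci[1][0]), float(ci[1][1])),
            intercept=float(res.params[0]),
            intercept_ci95=(float(ci[0][0]), float(ci[0][1])),
            r_squared=float(res.rsquared),
            temperatures=tuple(float(t) for t in self.temperatures_k),
            n_points=int(self.temperatures_k.size),
        )
        object.__setattr__(out, "_sm_results", res)
        return out


def fit_vant_hoff(points, weights=None, chemical: str = "") -> VantHoffResults:
    """Fit ln Kaw = slope/T + intercept from (temperature K, ln Kaw) pairs."""
    t, y = zip(*points)
    return VantHoffModel(t, y, weights=weights, chemical=chemical).fit()


def extrapolate_log_kaw(fit: VantHoffResults, temperature: float = T_REF_25C) -> ExtrapolatedKaw:
    """Evaluate the Van't Hoff line at ``temperature`` (K), in log10 with CI."""
    return fit.extrapolate(temperature)


def direct_vs_indirect(direct: ExtrapolatedKaw, indirect: ExtrapolatedKaw) -> float:
    """Signed difference (log10) between direct and indirect estimates."""
    if direct.chemical != indirect.chemical:
        raise ValueError(
            f"chemical mismatch: {direct.chemical!r} vs {indirect.chemical!r}"
        )
    if not math.isclose(direct.temperature, indirect.temperature):
        raise ValueError(
            f"temperature mismatch: {direct.temperature} vs {indirect.temperature}"
        )
    return direct.log10_kaw - indirect.log10_kaw
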