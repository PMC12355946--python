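"""Direct estimation of Kaw at one temperature from phase-ratio-varied areas.

The "direct" method: replicate peak areas measured across vials with
different headspace/solution ratios r are fitted with the two-parameter
depletion model ``area = A0 / (1 + Kaw * r)`` by weighted nonlinear least
squares.  The default weighting ``w_i = 1 / y_i^2`` treats the relative
measurement error as constant, which matches multiplicative LC-MS noise.

Triplicate groups whose scatter exceeds the signal difference to the
neighbouring ratio are excluded before fitting (``qc_filter``), mirroring
how low-quality points are discarded in practice.

The entry point is :class:`HeadspaceKawModel`, a statsmodels-style model
object whose :meth:`~HeadspaceKawModel.fit` returns a
:class:`KawFitResults` carrying the estimates, their 95% confidence
intervals, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "VialObservation",
    "RatioGroup",
    "KawFitResults",
    "HeadspaceKawModel",
    "group_by_ratio",
    "qc_filter",
    "fit_kaw",
    "log10_kaw",
]


@dataclass(frozen=True)
class VialObservation:
    """One replicate measurement: a peak area at one headspace ratio."""

    chemical: str
    temperature: float  # K
    ratio: float  # V_hs / V_sol, dimensionless
    replicate: int
    area: float

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError(f"area must be > 0, got {self.area}")
        if self.ratio < 0:
            raise ValueError(f"ratio must be >= 0, got {self.ratio}")
        if not self.temperature > 0:
            raise ValueError(f"temperature (K) must be > 0, got {self.temperature}")
        if self.replicate < 1:
            raise ValueError(f"replicate index must be >= 1, got {self.replicate}")


@dataclass(frozen=True)
class RatioGroup:
    """Replicate areas sharing one headspace/solution ratio."""

    ratio: float
    areas: tuple[float, ...]

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.areas))

    @property
    def rsd(self) -> float:
        """Relative standard deviation (sample SD / mean); 0 for n = 1."""
        if len(self.areas) < 2:
            return 0.0
        return float(np.std(self.areas, ddof=1) / np.mean(self.areas))


def group_by_ratio(observations: list[VialObservation]) -> list[RatioGroup]:
    """Group replicate observations by ratio, ascending.

    All observations must belong to one chemical at one temperature --
    mixing conditions in a single fit is a caller error.
    """
    if not observations:
        raise ValueError("no observations")
    chems = {o.chemical for o in observations}
    temps = {o.temperature for o in observations}
    if len(chems) > 1:
        raise ValueError(f"observations mix chemicals: {sorted(chems)}")
    if len(temps) > 1:
        raise ValueError(f"observations mix temperatures: {sorted(temps)}")
    by_ratio: dict[float, list[float]] = {}
    for o in observations:
        by_ratio.setdefault(o.ratio, []).append(o.area)
    return [RatioGroup(r, tuple(by_ratio[r])) for r in sorted(by_ratio)]


def _pair_relative_deviation(m_i: float, m_j: float) -> float:
    return abs(m_i - m_j) / ((m_i + m_j) / 2.0)


def qc_filter(groups: list[RatioGroup]) -> tuple[list[RatioGroup], list[RatioGroup]]:
    """Exclude ratio groups whose replicate scatter drowns the signal.

    A group is excluded iff its RSD is >= the smallest relative deviation
    between its mean area and the mean areas of its adjacent ("vicinal")
    ratio groups; terminal groups have a single neighbour.  The decision is
    made in one pass over the original (pre-exclusion) group sequence.
    """
    if len(groups) < 2:
        raise ValueError("qc_filter needs >= 2 ratio groups")
    ratios = [g.ratio for g in groups]
    if ratios != sorted(ratios):
        raise ValueError("groups must be sorted ascending by ratio")
    kept: list[RatioGroup] = []
    excluded: list[RatioGroup] = []
    means = [g.mean_area for g in groups]
    for i, g in enumerate(groups):
        neigh = []
        if i > 0:
            neigh.append(_pair_relative_deviation(means[i], means[i - 1]))
        if i < len(groups) - 1:
            neigh.append(_pair_relative_deviation(means[i], means[i + 1]))
        (excluded if g.rsd >= min(neigh) else kept).append(g)
    return kept, excluded


@dataclass(frozen=True)
class KawFitResults:
    """Weighted-NLS estimate of (amplitude, Kaw) at one temperature.

    ``kaw_ci95`` / ``amplitude_ci95`` are asymptotic Wald-type intervals
    from the weighted-least-squares covariance with a t quantile at
    (n - 2) degrees of freedom.  ``r_squared`` is the unweighted
    coefficient of determination on the raw areas.  A fit with a negative
    Kaw estimate or a failed optimizer is reported with ``converged=False``
    rather than clamped, preserving the "too low to determine" diagnostic.
    """

    chemical: str
    temperature: float
    kaw_hat: float
    kaw_ci95: tuple[float, float]
    amplitude_hat: float
    amplitude_ci95: tuple[float, float]
    r_squared: float
    n_used: int
    excluded_ratios: tuple[float, ...]
    converged: bool
    weighting_exponent: int = 2

    @property
    def reportable(self) -> bool:
        """Whether a log10 Kaw with CI can be quoted from this fit."""
        return bool(self.converged and self.kaw_hat > 0 and self.kaw_ci95[0] > 0)

    def log10(self) -> tuple[float, tuple[float, float]]:
        return log10_kaw(self)

    def summary(self) -> str:
        lines = [
            "Headspace depletion fit (area = A0 / (1 + Kaw*r))",
            f"  chemical: {self.chemical}   temperature: {self.temperature:.2f} K",
            f"  Kaw       {self.kaw_hat:.6g}  95% CI [{self.kaw_ci95[0]:.6g}, {self.kaw_ci95[1]:.6g}]",
            f"  A0        {self.amplitude_hat:.6g}  95% CI [{self.amplitude_ci95[0]:.6g}, {self.amplitude_ci95[1]:.6g}]",
            f"  R^2 (unweighted) {self.r_squared:.4f}   n = {self.n_used}"
            f"   weighting 1/y^{self.weighting_exponent}",
            f"  excluded ratios: {list(self.excluded_ratios) or 'none'}"
            f"   converged: {self.converged}",
        ]
        return "\n".join(lines)


class HeadspaceKawModel:
    """Weighted NLS model for Kaw from areas at varying headspace ratios.

    Parameters
    ----------
    ratios, areas : array-like
        Replicate-level observations (one entry per vial, not per group).
    weighting_exponent : {0, 1, 2}
        Weights ``w_i = area_i ** -exponent``; 2 (relative error) by default.
    chemical, temperature :
        Carried through to the results for bookkeeping.
    excluded_ratios :
        Ratios removed upstream (e.g. by ``qc_filter``), recorded in results.
    """

    def __init__(
        self,
        ratios,
        areas,
        weighting_exponent: int = 2,
        chemical: str = "",
        temperature: float = math.nan,
        excluded_ratios: tuple[float, ...] = (),
    ):
        self.ratios = np.asarray(ratios, dtype=float)
        self.areas = np.asarray(areas, dtype=float)
        if self.ratios.shape != self.areas.shape or self.ratios.ndim != 1:
            raise ValueError("ratios and areas must be 1-D arrays of equal length")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be > 0")
        if np.any(self.ratios < 0):
            raise ValueError("ratios must be >= 0")
        if self.ratios.size < 3:
            raise ValueError("need >= 3 observations to fit 2 parameters")
        if np.unique(self.ratios).size < 2:
            raise ValueError("all ratios equal: Kaw is unidentifiable")
        if weighting_exponent not in (0, 1, 2):
            raise ValueError("weighting_exponent must be 0, 1 or 2")
        self.weighting_exponent = int(weighting_exponent)
        self.chemical = chemical
        self.temperature = temperature
        self.excluded_ratios = tuple(excluded_ratios)

    @classmethod
    def from_observations(
        cls,
        observations: list[VialObservation],
        weighting_exponent: int = 2,
        qc: bool = True,
    ) -> "HeadspaceKawModel":
        """Build from replicate observations, applying the triplicate QC rule.

        QC works on group means, but the model is fitted to the individual
        replicate areas of the kept groups.
        """
        groups = group_by_ratio(observations)
        if qc and len(groups) >= 2:
            kept, excluded = qc_filter(groups)
        else:
            kept, excluded = groups, []
        if len(kept) < 3 or len({g.ratio for g in kept}) < 2:
            raise ValueError(
                f"insufficient ratio groups after QC ({len(kept)} kept, "
                f"{len(excluded)} excluded)"
            )
        ratios = np.concatenate([[g.ratio] * len(g.areas) for g in kept])
        areas = np.concatenate([g.areas for g in kept])
        return cls(
            ratios,
            areas,
            weighting_exponent=weighting_exponent,
            chemical=observations[0].chemical,
            temperature=observations[0].temperature,
            excluded_ratios=tuple(g.ratio for g in excluded),
        )

    def _start_values(self) -> tuple[float, float]:
        # 1/area is linear in r: 1/A = (1 + Kaw*r)/A0.  OLS on the
        # linearized form gives robust starting values.
        y = 1.0 / self.areas
        x = self.ratios
        slope, intercept = np.polyfit(x, y, 1)
        if intercept <= 0:
            intercept = float(np.mean(y))
        a0 = 1.0 / intercept
        kaw = max(slope / intercept, 0.0)
        return a0, kaw

    def fit(self) -> KawFitResults:
        a0_0, kaw_0 = self._start_values()
        p = self.weighting_exponent
        # curve_fit minimizes sum(((y - f)/sigma)^2); sigma = y^(p/2)
        # reproduces weights w = y^-p.  Covariance is scaled by the
        # reduced chi-square (absolute_sigma=False), the convention of
        # common curve-fitting software.
        sigma = self.areas ** (p / 2.0) if p else None
        converged = True
        try:
            popt, pcov = optimize.curve_fit(
                lambda r, a0, kaw: a0 / (1.0 + kaw * r),
                self.ratios,
                self.areas,
                p0=[a0_0, kaw_0],
                sigma=sigma,
                absolute_sigma=False,
                maxfev=20000,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            converged = False
            popt = np.array([a0_0, kaw_0])
            pcov = np.full((2, 2), np.nan)
        a0_hat, kaw_hat = float(popt[0]), float(popt[1])
        if not np.all(np.isfinite(popt)):
            converged = False
        if kaw_hat < 0:
            converged = False

        n = self.areas.size
        dof = n - 2
        tq = stats.t.ppf(0.975, dof)
        se = np.sqrt(np.diag(pcov))
        a0_ci = (a0_hat - tq * se[0], a0_hat + tq * se[0])
        kaw_ci = (kaw_hat - tq * se[1], kaw_hat + tq * se[1])

        fitted = a0_hat / (1.0 + kaw_hat * self.ratios)
        ss_res = float(np.sum((self.areas - fitted) ** 2))
        ss_tot = float(np.sum((self.areas - self.areas.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)

        return KawFitResults(
            chemical=self.chemical,
            temperature=self.temperature,
            kaw_hat=kaw_hat,
            kaw_ci95=(float(kaw_ci[0]), float(kaw_ci[1])),
            amplitude_hat=a0_hat,
            amplitude_ci95=(float(a0_ci[0]), float(a0_ci[1])),
            r_squared=r2,
            n_used=n,
            excluded_ratios=self.excluded_ratios,
            converged=converged,
            weighting_exponent=p,
        )

    def weighted_sse(self, amplitude: float, kaw: float) -> float:
        """Weighted residual sum of squares at a given parameter point."""
        f = amplitude / (1.0 + kaw * self.ratios)
        w = self.areas ** (-float(self.weighting_exponent))
        return float(np.sum(w * (self.areas - f) ** 2))


def fit_kaw(
    groups: list[RatioGroup],
    weighting_exponent: int = 2,
    chemical: str = "",
    temperature: float = math.nan,
    excluded_ratios: tuple[float, ...] = (),
) -> KawFitResults:
    """Fit Kaw from (already QC-filtered) ratio groups.

    Functional facade over :class:`HeadspaceKawModel`; fits replicate-level
    points, not group means.
    """
    if len(groups) < 3 or len({g.ratio for g in groups}) < 2:
        raise ValueError("need >= 3 groups spanning >= 2 distinct ratios")
    ratios = np.concatenate([[g.ratio] * len(g.areas) for g in groups])
    areas = np.concatenate([g.areas for g in groups])
    return HeadspaceKawModel(
        ratios,
        areas,
        weighting_exponent=weighting_exponent,
        chemical=chemical,
        temperature=temperature,
        excluded_ratios=excluded_ratios,
    ).fit()


def log10_kaw(fit: KawFitResults) -> tuple[float, tuple[float, float]]:
    """log10 of the Kaw estimate and of both CI endpoints.

    Raises ``ValueError`` when the estimate or the lower CI bound is not
    positive -- the "too low to be directly determined" case; callers that
    want a soft flag should consult ``fit.reportable`` first.
    """
    if not fit.reportable:
        raise ValueError(
            f"Kaw fit for {fit.chemical or '?'} at {fit.temperature} K is "
            "not reportable on the log scale (non-positive estimate or CI bound)"
        )
    lo, hi = fit.kaw_ci95
    return math.log10(fit.kaw_hat), (math.log10(lo), math.log10(hi))
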