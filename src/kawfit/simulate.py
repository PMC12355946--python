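"""Seeded generator of synthetic static-headspace studies.

Emulates the full experimental design: 20 mL vials filled with 1, 2, 5, 10,
15 and 18 mL of test solution in triplicate, equilibrated at 25, 40, 50, 60,
70 and 80 degC.  For each chemical a "true" partition coefficient at every
temperature follows the Van't Hoff law from (dU, log10 Kaw at 25 degC); the
expected peak area of a vial is the depletion curve A0 / (1 + Kaw(T) * r),
optionally attenuated by a sorption-loss artifact, and observed under
multiplicative lognormal noise of configurable CV.

Two loss artifacts are available:

* ``constant_fraction`` -- a fixed fraction of analyte lost in every vial
  (wall/lid sorption of the dissolved fraction).  It scales the whole curve,
  so the fitted amplitude is biased low but Kaw is untouched: the estimator
  reads only the shape in r.
* ``ratio_dependent`` -- loss growing with the headspace ratio,
  f_max * r / (r + r_half), a saturating surrogate for air-water interface
  sorption.  This distorts the shape, biasing Kaw and degrading R^2 -- the
  qualitative signature by which sorption-prone chemicals are recognized and
  their fits dismissed.

Lognormal noise is mean-one: a CV of 0.02 perturbs each area by ~2% without
biasing its expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import VialObservation
from .partition import area_model
from .vanthoff import GAS_CONSTANT, LN10, T_REF_25C

__all__ = [
    "ChemicalTruth",
    "LossModel",
    "SimulationConfig",
    "SyntheticStudy",
    "true_kaw_at",
    "simulate_study",
]

DEFAULT_FILL_VOLUMES = (1.0, 2.0, 5.0, 10.0, 15.0, 18.0)  # mL
DEFAULT_TEMPERATURES_C = (25.0, 40.0, 50.0, 60.0, 70.0, 80.0)


@dataclass(frozen=True)
class ChemicalTruth:
    """Ground truth for one simulated chemical."""

    id: str
    delta_u: float  # kJ/mol
    log10_kaw_ref: float  # at t_ref
    amplitude: float = 1.0e6  # RF * c0, arbitrary signal units


@dataclass(frozen=True)
class LossModel:
    """Sorption-loss artifact applied to expected areas.

    kind "none": no loss.  "constant_fraction": every vial loses fraction
    ``f`` of signal.  "ratio_dependent": loss f_max * r / (r + r_half).
    """

    kind: str = "none"
    f: float = 0.0
    f_max: float = 0.0
    r_half: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "constant_fraction", "ratio_dependent"):
            raise ValueError(f"unknown loss model kind {self.kind!r}")
        if not 0.0 <= self.f < 1.0:
            raise ValueError("constant loss fraction f must be in [0, 1)")
        if not 0.0 <= self.f_max < 1.0:
            raise ValueError("f_max must be in [0, 1)")
        if self.r_half <= 0:
            raise ValueError("r_half must be > 0")

    def retained(self, ratio: float) -> float:
        """Fraction of signal surviving the loss in a vial of given ratio."""
        if self.kind == "none":
            return 1.0
        if self.kind == "constant_fraction":
            return 1.0 - self.f
        return 1.0 - self.f_max * ratio / (ratio + self.r_half)


@dataclass(frozen=True)
class SimulationConfig:
    """Complete generative description of one synthetic study."""

    chemicals: tuple[ChemicalTruth, ...]
    total_volume: float = 20.0  # mL
    fill_volumes: tuple[float, ...] = DEFAULT_FILL_VOLUMES
    replicates: int = 3
    temperatures_c: tuple[float, ...] = DEFAULT_TEMPERATURES_C
    noise_cv: float = 0.02
    loss: LossModel = field(default_factory=LossModel)
    seed: int = 0
    t_ref: float = T_REF_25C

    def __post_init__(self) -> None:
        if not self.chemicals:
            raise ValueError("at least one chemical required")
        if self.total_volume <= 0:
            raise ValueError("total_volume must be > 0")
        if any(not 0 < f <= self.total_volume for f in self.fill_volumes):
            raise ValueError("fill volumes must be in (0, total_volume]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @property
    def ratios(self) -> tuple[float, ...]:
        return tuple((self.total_volume - f) / f for f in self.fill_volumes)


def true_kaw_at(
    temperature: float,
    delta_u: float,
    log10_kaw_ref: float,
    t_ref: float = T_REF_25C,
) -> float:
    """Kaw at ``temperature`` (K) from its value at ``t_ref`` and dU (kJ/mol).

    ln Kaw(T) = ln Kaw(t_ref) - (dU * 1000 / R) * (1/T - 1/t_ref).
    """
    if temperature <= 0 or t_ref <= 0:
        raise ValueError("temperatures must be positive (K)")
    ln_ref = log10_kaw_ref * LN10
    ln_k = ln_ref - (delta_u * 1000.0 / GAS_CONSTANT) * (1.0 / temperature - 1.0 / t_ref)
    return math.exp(ln_k)


@dataclass(frozen=True)
class SyntheticStudy:
    """Simulated observations plus the generating truth."""

    config: SimulationConfig
    observations: tuple[VialObservation, ...]
    true_kaw: dict[str, dict[float, float]] = field(hash=False)  # id -> {T_K: Kaw}

    def to_measurements_frame(self) -> pd.DataFrame:
        """Measurements table in the schema the estimation pipeline reads."""
        cfg = self.config
        fill_by_ratio = {
            (cfg.total_volume - f) / f: f for f in cfg.fill_volumes
        }
        rows = [
            {
                "chemical": o.chemical,
                "temperature_C": round(o.temperature - 273.15, 6),
                "vial_total_mL": cfg.total_volume,
                "fill_mL": fill_by_ratio[o.ratio],
                "replicate": o.replicate,
                "area": o.area,
            }
            for o in self.observations
        ]
        return pd.DataFrame(rows)

    def to_truth_frame(self) -> pd.DataFrame:
        """Truth table (chemical, dU, per-temperature Kaw) for recovery scoring."""
        rows = []
        truth_by_id = {c.id: c for c in self.config.chemicals}
        for chem_id, kaw_by_t in self.true_kaw.items():
            c = truth_by_id[chem_id]
            for t_k, kaw in kaw_by_t.items():
                rows.append(
                    {
                        "chemical": chem_id,
                        "temperature_C": round(t_k - 273.15, 6),
                        "true_kaw": kaw,
                        "true_delta_u": c.delta_u,
                        "true_log10_kaw_ref": c.log10_kaw_ref,
                    }
                )
        return pd.DataFrame(rows)


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Draw one full synthetic study; identical seeds give identical studies."""
    rng = np.random.default_rng(config.seed)
    cv = config.noise_cv
    # mean-one lognormal: sigma^2 = ln(1 + cv^2), mu = -sigma^2 / 2
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    mu = -0.5 * sigma * sigma

    observations: list[VialObservation] = []
    true_kaw: dict[str, dict[float, float]] = {}
    for chem in config.chemicals:
        kaw_by_t: dict[float, float] = {}
        for t_c in config.temperatures_c:
            t_k = t_c + 273.15
            kaw = true_kaw_at(t_k, chem.delta_u, chem.log10_kaw_ref, config.t_ref)
            kaw_by_t[t_k] = kaw
            for ratio in config.ratios:
                expected = area_model(chem.amplitude, kaw, ratio)
                expected *= config.loss.retained(ratio)
                for rep in range(1, config.replicates + 1):
                    factor = math.exp(rng.normal(mu, sigma)) if cv > 0 else 1.0
                    observations.append(
                        VialObservation(
                            chemical=chem.id,
                            temperature=t_k,
                            ratio=ratio,
                            replicate=rep,
                            area=expected * factor,
                        )
                    )
        true_kaw[chem.id] = kaw_by_t
    return SyntheticStudy(
        config=config, observations=tuple(observations), true_kaw=true_kaw
    )
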