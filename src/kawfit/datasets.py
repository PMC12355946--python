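"""Bundled reference data: five fluorinated alcohols studied with this method.

Per-temperature mean log10 Kaw values (direct fits at 25-80 degC where the
chemical was volatile enough, Van't Hoff slopes, and indirect 25 degC
extrapolations) for four novel ether/thioether perfluoroalkyl alcohols and
the well-studied 4:2 fluorotelomer alcohol, together with log10 Kaw
predictions of five in-silico Henry's-law tools for the same chemicals.

These tables serve as a worked example and as regression anchors: rerunning
the indirect method on the per-temperature means must reproduce the recorded
25 degC extrapolations to within rounding.  The two CF3 chemicals have no
direct 25 degC entry -- their Kaw at room temperature is too low for the
depletion fit, the very case the indirect method exists for.
"""

from __future__ import annotations

from .comparison import PredictionRecord

__all__ = [
    "CHEMICALS",
    "DIRECT_LOG10_KAW",
    "VANTHOFF_SLOPES",
    "DELTA_U",
    "INDIRECT_LOG10_KAW_25C",
    "example_predictions",
]

CHEMICALS = ("C3F7-O-ALC", "C3F7-S-ALC", "CF3-O-ALC", "CF3-S-ALC", "4:2 FTOH")

#: Direct-method mean log10 Kaw by temperature (degC); None = not reportable.
DIRECT_LOG10_KAW: dict[str, dict[float, float | None]] = {
    "C3F7-O-ALC": {25: -1.04, 40: -0.91, 50: -0.76, 60: -0.65, 70: -0.53, 80: -0.45},
    "C3F7-S-ALC": {25: -0.97, 40: -0.88, 50: -0.75, 60: -0.66, 70: -0.57, 80: -0.49},
    "CF3-O-ALC": {25: None, 40: -2.29, 50: -2.19, 60: -1.93, 70: -1.84, 80: -1.59},
    "CF3-S-ALC": {25: None, 40: -2.22, 50: -2.05, 60: -1.94, 70: -1.81, 80: -1.62},
    "4:2 FTOH": {25: -1.45, 40: -1.13, 50: -0.92, 60: -0.78, 70: -0.67, 80: -0.57},
}

#: Slope (K) of ln Kaw vs 1/T fitted to replicate-level 40-80 degC data.
VANTHOFF_SLOPES: dict[str, float] = {
    "C3F7-O-ALC": -2864.0,
    "C3F7-S-ALC": -2449.0,
    "CF3-O-ALC": -4502.0,
    "CF3-S-ALC": -3729.0,
    "4:2 FTOH": -3374.0,
}

#: Internal energy of air-water partitioning, kJ/mol (= -slope * R / 1000).
DELTA_U: dict[str, float] = {
    "C3F7-O-ALC": 23.8,
    "C3F7-S-ALC": 20.4,
    "CF3-O-ALC": 37.4,
    "CF3-S-ALC": 31.0,
    "4:2 FTOH": 28.1,
}

#: Indirect-method log10 Kaw at 25 degC (Van't Hoff extrapolation).
INDIRECT_LOG10_KAW_25C: dict[str, float] = {
    "C3F7-O-ALC": -1.09,
    "C3F7-S-ALC": -1.04,
    "CF3-O-ALC": -2.64,
    "CF3-S-ALC": -2.49,
    "4:2 FTOH": -1.32,
}

#: (model, log10 Kaw, in application domain) per chemical, at 25 degC.
_PREDICTIONS: dict[str, list[tuple[str, float, bool]]] = {
    "C3F7-O-ALC": [
        ("IFSQSAR", -1.61, False),
        ("UFZ-LSER", -3.17, False),
        ("OPERA", -4.16, False),
        ("HenryWin", -4.34, True),
        ("COSMOtherm", -0.99, True),
    ],
    "C3F7-S-ALC": [
        ("IFSQSAR", -3.24, False),
        ("UFZ-LSER", -4.43, False),
        ("OPERA", -4.16, False),
        ("HenryWin", -4.38, True),
        ("COSMOtherm", -1.77, True),
    ],
    "CF3-O-ALC": [
        ("IFSQSAR", -3.11, True),
        ("UFZ-LSER", -4.64, False),
        ("OPERA", -5.53, False),
        ("HenryWin", -5.78, True),
        ("COSMOtherm", -2.42, True),
    ],
    "CF3-S-ALC": [
        ("IFSQSAR", -4.75, False),
        ("UFZ-LSER", -5.89, False),
        ("OPERA", -4.34, False),
        ("HenryWin", -5.82, True),
        ("COSMOtherm", -2.85, True),
    ],
    "4:2 FTOH": [
        ("IFSQSAR", -1.38, False),
        ("UFZ-LSER", -1.54, False),
        ("OPERA", -3.95, False),
        ("HenryWin", -0.65, True),
        ("COSMOtherm", -1.99, True),
    ],
}


def example_predictions() -> list[PredictionRecord]:
    """In-silico log10 Kaw predictions for the five reference chemicals."""
    return [
        PredictionRecord(chemical=chem, model=m, log10_kaw=v, in_domain=dom)
        for chem, rows in _PREDICTIONS.items()
        for m, v, dom in rows
    ]
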