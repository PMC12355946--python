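"""End-to-end study analysis: direct fits, Van't Hoff, contrasts, predictions.

``run_pipeline`` takes replicate-level observations (plus an optional
in-silico prediction table) and produces, per chemical:

* a direct Kaw fit with 95% CI at every temperature (QC exclusions logged);
* the Van't Hoff regression over the configured high-temperature subset,
  with the derived internal energy of partitioning dU;
* the indirect (extrapolated) log10 Kaw at the target temperature,
  reported even when the direct fit there is not reportable;
* OECD 309 volatility classification;
* structural Delta-log10-Kaw contrasts for declared chemical pairs and
  signed experimental-minus-predicted deltas per in-silico model.

The machine-readable report is a plain JSON-style dict; identical inputs
and options give byte-identical serialisations (keys sorted, no
timestamps).  ``validate_report`` checks it against the schema document
shipped as ``report_schema.json``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from itertools import combinations

from .comparison import (
    PredictionRecord,
    classify_volatility,
    delta_experimental_vs_predicted,
    delta_log_kaw_pair,
)
from .estimation import HeadspaceKawModel, KawFitResults, VialObservation
from .vanthoff import VantHoffModel

__all__ = ["PipelineOptions", "FitFailure", "run_pipeline", "validate_report",
           "render_summary_table", "render_prediction_table"]

logger = logging.getLogger("kawfit.pipeline")

CELSIUS_OFFSET = 273.15


class FitFailure(RuntimeError):
    """No usable fit could be produced for a chemical."""


@dataclass(frozen=True)
class PipelineOptions:
    """Tunables of the full analysis.

    ``vanthoff_temperatures_c`` selects which per-temperature fits enter
    the indirect regression (the target temperature itself is excluded by
    default because that is precisely the value being extrapolated).
    """

    weighting_exponent: int = 2
    qc: bool = True
    target_temperature_c: float = 25.0
    vanthoff_temperatures_c: tuple[float, ...] = (40.0, 50.0, 60.0, 70.0, 80.0)
    pairs: tuple[tuple[str, str], ...] | None = None  # None -> all pairs
    vanthoff_weighted: bool = False


def _fit_record(fit: KawFitResults, temperature_c: float) -> dict:
    rec = {
        "temperature_C": temperature_c,
        "kaw": fit.kaw_hat,
        "kaw_ci95": list(fit.kaw_ci95),
        "amplitude": fit.amplitude_hat,
        "r_squared": fit.r_squared,
        "n_used": fit.n_used,
        "excluded_ratios": [round(r, 9) for r in fit.excluded_ratios],
        "converged": fit.converged,
        "reportable": fit.reportable,
        "log10_kaw": None,
        "log10_kaw_ci95": None,
    }
    if fit.reportable:
        val, ci = fit.log10()
        rec["log10_kaw"] = val
        rec["log10_kaw_ci95"] = list(ci)
    return rec


def run_pipeline(
    observations: list[VialObservation],
    predictions: list[PredictionRecord] | None = None,
    options: PipelineOptions = PipelineOptions(),
) -> dict:
    """Analyse a full study and return the machine-readable report."""
    if not observations:
        raise ValueError("no observations")
    predictions = predictions or []
    by_chem: dict[str, dict[float, list[VialObservation]]] = {}
    for o in observations:
        by_chem.setdefault(o.chemical, {}).setdefault(o.temperature, []).append(o)

    orphan_predictions = sorted(
        {p.chemical for p in predictions} - set(by_chem)
    )
    for chem in orphan_predictions:
        logger.warning("prediction for %s has no measurements; skipped", chem)

    target_k = options.target_temperature_c + CELSIUS_OFFSET
    vanthoff_k = {round(t + CELSIUS_OFFSET, 6) for t in options.vanthoff_temperatures_c}

    chemicals: dict[str, dict] = {}
    for chem in sorted(by_chem):
        fits: list[KawFitResults] = []
        fit_records = []
        for t_k in sorted(by_chem[chem]):
            t_c = t_k - CELSIUS_OFFSET
            try:
                model = HeadspaceKawModel.from_observations(
                    by_chem[chem][t_k],
                    weighting_exponent=options.weighting_exponent,
                    qc=options.qc,
                )
            except ValueError as exc:
                logger.info("fit skipped: %s at %.1f C: %s", chem, t_c, exc)
                continue
            fit = model.fit()
            for r in fit.excluded_ratios:
                logger.info(
                    "QC exclusion: %s at %.1f C, ratio %.4g (triplicate RSD "
                    ">= vicinal mean deviation)", chem, t_c, r
                )
            if not fit.converged:
                logger.info(
                    "non-converged fit: %s at %.1f C (kaw_hat=%.4g)",
                    chem, t_c, fit.kaw_hat,
                )
            fits.append(fit)
            fit_records.append(_fit_record(fit, round(t_c, 6)))
        if not fits:
            raise FitFailure(f"no temperature of {chem} could be fitted")

        entry: dict = {"direct_fits": fit_records}

        direct_at_target = next(
            (f for f in fits if math.isclose(f.temperature, target_k)), None
        )
        if direct_at_target is not None and direct_at_target.reportable:
            val, ci = direct_at_target.log10()
            entry["direct_target"] = {"log10_kaw": val, "ci95": list(ci)}
        else:
            entry["direct_target"] = None
            if direct_at_target is not None:
                logger.info(
                    "%s: direct %.1f C estimate not reportable (Kaw too low)",
                    chem, options.target_temperature_c,
                )

        vh_fits = [
            f
            for f in fits
            if round(f.temperature, 6) in vanthoff_k and f.reportable
        ]
        entry["vanthoff"] = None
        entry["indirect_target"] = None
        if len(vh_fits) >= 3:
            vh = VantHoffModel.from_fits(
                vh_fits, weighted=options.vanthoff_weighted
            ).fit()
            extrap = vh.extrapolate(target_k)
            entry["vanthoff"] = {
                "slope": vh.slope,
                "slope_ci95": list(vh.slope_ci95),
                "intercept": vh.intercept,
                "r_squared": vh.r_squared,
                "delta_u": vh.delta_u,
                "delta_u_ci95": list(vh.delta_u_ci95),
                "n_points": vh.n_points,
                "temperatures_C": [round(t - CELSIUS_OFFSET, 6) for t in vh.temperatures],
            }
            entry["indirect_target"] = {
                "log10_kaw": extrap.log10_kaw,
                "ci95": list(extrap.ci95),
                "extrapolated": extrap.extrapolated,
            }
        else:
            logger.info(
                "%s: only %d reportable fits in the Van't Hoff temperature "
                "subset; indirect estimate unavailable", chem, len(vh_fits)
            )

        basis = entry["indirect_target"] or entry["direct_target"]
        entry["volatility_class"] = (
            classify_volatility(basis["log10_kaw"]).value if basis else None
        )
        if entry["direct_target"] and entry["indirect_target"]:
            entry["direct_minus_indirect"] = (
                entry["direct_target"]["log10_kaw"]
                - entry["indirect_target"]["log10_kaw"]
            )
        else:
            entry["direct_minus_indirect"] = None
        chemicals[chem] = entry

    report = {
        "options": {
            "weighting_exponent": options.weighting_exponent,
            "qc": options.qc,
            "target_temperature_C": options.target_temperature_c,
            "vanthoff_temperatures_C": list(options.vanthoff_temperatures_c),
        },
        "chemicals": chemicals,
        "contrasts": _contrasts(chemicals, options),
    }
    if predictions:
        report["predictions"] = _prediction_block(chemicals, predictions)
    return report


def _condition_map(entry: dict, target_c: float) -> dict[str, float]:
    cond = {}
    for rec in entry["direct_fits"]:
        if rec["log10_kaw"] is not None and not math.isclose(
            rec["temperature_C"], target_c
        ):
            cond[f"direct_{rec['temperature_C']:g}C"] = rec["log10_kaw"]
    if entry["direct_target"]:
        cond[f"direct_{target_c:g}C"] = entry["direct_target"]["log10_kaw"]
    if entry["indirect_target"]:
        cond[f"indirect_{target_c:g}C"] = entry["indirect_target"]["log10_kaw"]
    return cond


def _contrasts(chemicals: dict[str, dict], options: PipelineOptions) -> list[dict]:
    pairs = options.pairs
    if pairs is None:
        pairs = tuple(combinations(sorted(chemicals), 2))
    out = []
    for a, b in pairs:
        if a not in chemicals or b not in chemicals:
            logger.warning("contrast pair (%s, %s) not fully measured; skipped", a, b)
            continue
        ca = _condition_map(chemicals[a], options.target_temperature_c)
        cb = _condition_map(chemicals[b], options.target_temperature_c)
        shared = sorted(set(ca) & set(cb))
        if not shared:
            continue
        res = delta_log_kaw_pair(
            {k: ca[k] for k in shared}, {k: cb[k] for k in shared}, pair=(a, b)
        )
        out.append(
            {
                "pair": [a, b],
                "per_condition": {k: res.per_condition[k] for k in shared},
                "mean_abs": res.mean_abs,
                "max_abs": res.max_abs,
            }
        )
    return out


def _prediction_block(
    chemicals: dict[str, dict], predictions: list[PredictionRecord]
) -> list[dict]:
    out = []
    for p in sorted(predictions, key=lambda p: (p.chemical, p.model)):
        entry = chemicals.get(p.chemical)
        if entry is None:
            continue
        rec = {
            "chemical": p.chemical,
            "model": p.model,
            "log10_kaw_predicted": p.log10_kaw,
            "in_domain": p.in_domain,
            "delta_vs_direct": None,
            "delta_vs_indirect": None,
        }
        if entry["direct_target"]:
            rec["delta_vs_direct"] = delta_experimental_vs_predicted(
                entry["direct_target"]["log10_kaw"], p
            )
        if entry["indirect_target"]:
            rec["delta_vs_indirect"] = delta_experimental_vs_predicted(
                entry["indirect_target"]["log10_kaw"], p
            )
        out.append(rec)
    return out


def report_to_json(report: dict) -> str:
    """Deterministic serialisation (sorted keys, fixed float repr)."""
    return json.dumps(report, sort_keys=True, indent=2, allow_nan=False)


# --- schema validation (structural subset: type / required / properties /
#     items / enum / nullable) -------------------------------------------------

def _check(instance, schema, path, errors):
    if schema.get("nullable") and instance is None:
        return
    stype = schema.get("type")
    pytypes = {
        "object": dict,
        "array": list,
        "string": str,
        "number": (int, float),
        "integer": int,
        "boolean": bool,
    }
    if stype:
        ok = isinstance(instance, pytypes[stype])
        if stype == "number":
            ok = ok and not isinstance(instance, bool)
        if stype in ("integer", "boolean"):
            ok = type(instance) is pytypes[stype]
        if not ok:
            errors.append(f"{path}: expected {stype}, got {type(instance).__name__}")
            return
    if "enum" in schema and instance not in schema["enum"]:
        errors.append(f"{path}: {instance!r} not in {schema['enum']}")
    if stype == "object":
        for key in schema.get("required", []):
            if key not in instance:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], sub, f"{path}.{key}", errors)
        if "additionalProperties" in schema and isinstance(
            schema["additionalProperties"], dict
        ):
            known = set(schema.get("properties", {}))
            for key, value in instance.items():
                if key not in known:
                    _check(value, schema["additionalProperties"], f"{path}.{key}", errors)
    elif stype == "array" and "items" in schema:
        for i, item in enumerate(instance):
            _check(item, schema["items"], f"{path}[{i}]", errors)


def validate_report(report: dict) -> list[str]:
    """Validate a pipeline report against the shipped schema document.

    Returns the list of violations (empty when the report conforms).
    """
    schema = json.loads(
        resources.files("kawfit").joinpath("report_schema.json").read_text()
    )
    errors: list[str] = []
    _check(report, schema, "$", errors)
    return errors


# --- plain-text renderings ---------------------------------------------------

def _fmt_ci(value, ci, nd=2):
    if value is None:
        return "n/a"
    return f"{value:.{nd}f} [{ci[0]:.{nd}f}, {ci[1]:.{nd}f}]"


def render_summary_table(report: dict) -> str:
    """Per-chemical summary: Van't Hoff line, dU, indirect and direct log10 Kaw."""
    target = report["options"]["target_temperature_C"]
    lines = [
        f"{'chemical':<14} {'slope (K)':>22} {'R^2':>7} {'dU (kJ/mol)':>20} "
        f"{'indirect ' + format(target, 'g') + 'C':>22} {'direct ' + format(target, 'g') + 'C':>22}  class"
    ]
    for chem, e in report["chemicals"].items():
        vh = e["vanthoff"]
        slope = _fmt_ci(vh["slope"], vh["slope_ci95"], 0) if vh else "n/a"
        r2 = f"{vh['r_squared']:.4f}" if vh else "n/a"
        du = _fmt_ci(vh["delta_u"], vh["delta_u_ci95"], 1) if vh else "n/a"
        ind = (
            _fmt_ci(e["indirect_target"]["log10_kaw"], e["indirect_target"]["ci95"])
            if e["indirect_target"]
            else "n/a"
        )
        dire = (
            _fmt_ci(e["direct_target"]["log10_kaw"], e["direct_target"]["ci95"])
            if e["direct_target"]
            else "n/a"
        )
        lines.append(
            f"{chem:<14} {slope:>22} {r2:>7} {du:>20} {ind:>22} {dire:>22}  "
            f"{e['volatility_class'] or 'n/a'}"
        )
        directs = ", ".join(
            f"{rec['temperature_C']:g}C: "
            + (f"{rec['log10_kaw']:.2f}" if rec["log10_kaw"] is not None else "n/a")
            for rec in e["direct_fits"]
        )
        lines.append(f"{'':<14}   direct log10 Kaw by T: {directs}")
    for c in report.get("contrasts", []):
        lines.append(
            f"Delta log10 Kaw ({c['pair'][0]} vs {c['pair'][1]}): "
            f"mean {c['mean_abs']:.2f}, max {c['max_abs']:.2f}"
        )
    return "\n".join(lines)


def render_prediction_table(report: dict) -> str:
    """Experimental vs in-silico log10 Kaw comparison."""
    if "predictions" not in report:
        return "(no in-silico predictions supplied)"
    lines = [
        f"{'chemical':<14} {'model':<12} {'predicted':>10} {'d_direct':>9} "
        f"{'d_indirect':>10}  domain"
    ]
    for rec in report["predictions"]:
        dd = f"{rec['delta_vs_direct']:+.2f}" if rec["delta_vs_direct"] is not None else "n/a"
        di = (
            f"{rec['delta_vs_indirect']:+.2f}"
            if rec["delta_vs_indirect"] is not None
            else "n/a"
        )
        flag = "in" if rec["in_domain"] else "OUT"
        lines.append(
            f"{rec['chemical']:<14} {rec['model']:<12} "
            f"{rec['log10_kaw_predicted']:>10.2f} {dd:>9} {di:>10}  {flag}"
        )
    return "\n".join(lines)
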