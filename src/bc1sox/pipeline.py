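"""End-to-end orchestration of the analysis chain.

Stages run in dependency order — spin classification, binding kinetics,
linear-response free energy, FEP/BAR, rates — each consuming the CSV
inputs named in the configuration and contributing a section to a single
JSON report.  A stage whose inputs are absent is skipped; a failing stage
is recorded as failed and its dependents are skipped.  The rate stage
prefers the FEP estimate of dG0 (the lower-variance route) and the
product-state reorganization energy Lambda_p from the linear-response
stage, both overridable from the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__, fep, kinetics, linres, rates, spin
from .thermo import Thermo

logger = logging.getLogger(__name__)

#: Reference parameter set for the two candidate electron-transfer models
#: (model I: semiquinone donor; model II: Fe2S2 donor).  dG values are the
#: FEP estimates, Lambda the product-/reactant-state reorganization
#: energies, k_et the ruler-averaged electron-transfer rate; binding and
#: unbinding rates of O2 at the Q_o-site pocket are under physiological
#: oxygen concentration, and x_sq is the semiquinone-state occupancy.
REFERENCE_PARAMS = {
    "model_I": {
        "delta_g_reorg_kcal_mol": -24.5,
        "lambda_p_kcal_mol": 84.5,
        "lambda_r_kcal_mol": 107.9,
        "delta_g_fep_kcal_mol": -21.6,
        "k_et_s1": 6.1e5,
    },
    "model_II": {
        "delta_g_reorg_kcal_mol": 122.9,
        "lambda_p_kcal_mol": 62.7,
        "lambda_r_kcal_mol": 88.3,
        "delta_g_fep_kcal_mol": 162.7,
        "k_et_s1": 1.0e-98,
    },
    "k_bind_s1": 2.0e5,
    "k_unbind_s1": 1.0e8,
    "x_sq": 4.0e-8,
    "r_range_A": (2.0, 10.0),
}


class PipelineConfig(BaseModel):
    """Stage inputs, thresholds and physical settings for a pipeline run."""

    model_config = ConfigDict(frozen=True)

    spin_csv: str | None = None
    trace_csv: str | None = None
    gap_csv: str | None = None
    fep_csv: str | None = None
    r_series_csv: str | None = None

    temperature_K: float = Field(default=300.0, gt=0)
    spin_threshold: float = Field(default=1.5, gt=0)
    outlier_threshold_kcal_mol: float = Field(default=50.0, gt=0)
    r_on_A: float = Field(default=9.0, gt=0)
    r_keep_A: float = Field(default=13.0, gt=0)
    r_off_A: float = Field(default=20.0, gt=0)
    escape_shell_A: float = Field(default=20.0, gt=0)
    kinetics_fit_method: str = Field(default="lsq", pattern="^(lsq|mle)$")
    fep_method: str = Field(default="bar", pattern="^(bar|exp)$")
    lambda_state: str = Field(default="product", pattern="^(product|reactant)$")

    k_bind_s1: float | None = Field(default=None, ge=0)
    k_unbind_s1: float | None = Field(default=None, ge=0)
    x_sq: float | None = Field(default=None, ge=0)
    delta_g0_kcal_mol: float | None = None  # overrides stage-derived dG0
    lambda_kcal_mol: float | None = None  # overrides stage-derived Lambda

    seed: int = 0
    out_dir: str = "."

    @model_validator(mode="after")
    def _check(self):
        if not self.r_on_A < self.r_keep_A < self.r_off_A:
            raise ValueError("binding thresholds must be ordered r_on < r_keep < r_off")
        for name in ("spin_csv", "trace_csv", "gap_csv", "fep_csv", "r_series_csv"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValueError(f"{name}: path {path!r} does not exist")
        return self


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages whose inputs are present; return the report dict.

    The report is also written to ``<out_dir>/report.json``.  Identical
    config and inputs give byte-identical reports.
    """
    thermo = Thermo(config.temperature_K)
    report: dict = {
        "provenance": {
            "package": "bc1sox",
            "version": __version__,
            "config": config.model_dump(),
            "config_hash": _config_hash(config),
            "seed": config.seed,
        },
        "stages": {},
    }
    failed: set[str] = set()

    if config.spin_csv is not None:
        try:
            records = spin.read_spin_table(config.spin_csv)
            classifications = spin.classify_records(
                records, config.spin_threshold, config.outlier_threshold_kcal_mol
            )
            stats = spin.class_energy_stats(records, classifications)
            report["stages"]["spin_classify"] = {
                "status": "ok",
                "n_records": len(records),
                "classes": {
                    label: asdict(st) for label, st in sorted(stats.classes.items())
                },
            }
        except Exception as exc:
            logger.exception("spin_classify failed")
            failed.add("spin_classify")
            report["stages"]["spin_classify"] = {"status": "failed", "error": str(exc)}

    if config.trace_csv is not None:
        try:
            trace = kinetics.read_distance_trace(config.trace_csv)
            events = kinetics.detect_binding_events(
                trace, config.r_on_A, config.r_keep_A, config.r_off_A
            )
            section: dict = {"status": "ok", "n_events": len(events)}
            resolved = [e for e in events if e.resolved]
            if trace.z is not None:
                for e in resolved:
                    e.escape_side = kinetics.classify_escape_side(
                        trace, e, config.escape_shell_A
                    )
                section["escape_sides"] = {
                    side: sum(1 for e in resolved if e.escape_side == side)
                    for side in ("positive", "negative", "unresolved")
                }
            if resolved:
                curve = kinetics.survival_histogram(resolved)
                section["n0"] = curve.n0
                try:
                    tau, n0_fit = kinetics.fit_binding_time(
                        curve, config.kinetics_fit_method
                    )
                    section["tau_ns"] = tau
                    section["n0_fit"] = n0_fit
                    section["fit_method"] = config.kinetics_fit_method
                except ValueError as exc:
                    section["fit_error"] = str(exc)
            report["stages"]["binding_kinetics"] = section
        except Exception as exc:
            logger.exception("binding_kinetics failed")
            failed.add("binding_kinetics")
            report["stages"]["binding_kinetics"] = {"status": "failed", "error": str(exc)}

    diagram = None
    if config.gap_csv is not None:
        try:
            reactant, product = read_gap_table(config.gap_csv)
            diagram = linres.full_linear_response(reactant, product, thermo)
            report["stages"]["linear_response"] = {
                "status": "ok",
                "delta_g0_kcal_mol": diagram.delta_g0,
                "lambda_p_kcal_mol": diagram.lambda_p,
                "lambda_r_kcal_mol": diagram.lambda_r,
                "reactant": asdict(diagram.reactant_summary),
                "product": asdict(diagram.product_summary),
            }
        except Exception as exc:
            logger.exception("linear_response failed")
            failed.add("linear_response")
            report["stages"]["linear_response"] = {"status": "failed", "error": str(exc)}

    fep_total, fep_sigma = None, None
    if config.fep_csv is not None:
        try:
            transformations = fep.read_fep_table(config.fep_csv)
            estimates = [
                fep.accumulate(tr, config.fep_method, thermo) for tr in transformations
            ]
            section = {
                "status": "ok",
                "legs": [
                    {
                        "leg": e.leg,
                        "model": e.model,
                        "method": e.method,
                        "total_kcal_mol": e.total,
                        "hysteresis_kcal_mol": e.hysteresis,
                        "uncertainty_kcal_mol": e.uncertainty,
                        "per_window_kcal_mol": [float(x) for x in e.per_window],
                    }
                    for e in estimates
                ],
            }
            if len(estimates) == 2:
                fep_total, fep_sigma = fep.combine_legs(*estimates)
                section["combined_delta_g0_kcal_mol"] = fep_total
                section["combined_uncertainty_kcal_mol"] = fep_sigma
            report["stages"]["fep_bar"] = section
        except Exception as exc:
            logger.exception("fep_bar failed")
            failed.add("fep_bar")
            report["stages"]["fep_bar"] = {"status": "failed", "error": str(exc)}

    # rate stage: needs dG0 + Lambda (from config or upstream) and rate constants
    dg0 = config.delta_g0_kcal_mol
    if dg0 is None and fep_total is not None:
        dg0 = fep_total
    if dg0 is None and diagram is not None:
        dg0 = diagram.delta_g0
    lam = config.lambda_kcal_mol
    if lam is None and diagram is not None:
        lam = diagram.lambda_p if config.lambda_state == "product" else diagram.lambda_r
    upstream_failed = {"linear_response", "fep_bar"} & failed
    if dg0 is not None and lam is not None and not upstream_failed:
        try:
            section = {"status": "ok", "delta_g0_kcal_mol": dg0, "lambda_kcal_mol": lam,
                       "lambda_state": config.lambda_state}
            if config.r_series_csv is not None:
                r = pd.read_csv(config.r_series_csv)["r_A"].to_numpy(float)
                params = rates.EtRateParams(dg0, lam, r_A=r, thermo=thermo)
                series, k_et = rates.average_rate_over_snapshots(params)
                section["n_snapshots"] = int(r.size)
                section["k_et_mean_s1"] = k_et
            else:
                k_et = None
            if (
                k_et is not None
                and config.k_bind_s1 is not None
                and config.k_unbind_s1 is not None
            ):
                result = rates.production_rate(
                    rates.ProductionRateParams(
                        config.k_bind_s1, config.k_unbind_s1, k_et, config.x_sq
                    )
                )
                section["production_rate_s1"] = result.production_rate
                if result.per_complex_rate is not None:
                    section["per_complex_rate_s1"] = result.per_complex_rate
            report["stages"]["rates"] = section
        except Exception as exc:
            logger.exception("rates failed")
            failed.add("rates")
            report["stages"]["rates"] = {"status": "failed", "error": str(exc)}
    elif upstream_failed:
        report["stages"]["rates"] = {
            "status": "skipped",
            "reason": f"upstream stage(s) failed: {sorted(upstream_failed)}",
        }

    report["failed_stages"] = sorted(failed)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def read_gap_table(path) -> tuple[linres.GapSampleSet, linres.GapSampleSet]:
    """Read the two-state gap CSV: state, delta_u_kcal_mol (or the pair
    u_product_kcal_mol, u_reactant_kcal_mol)."""
    df = pd.read_csv(path)
    if "state" not in df.columns:
        raise ValueError("gap CSV needs a 'state' column")
    sets = {}
    for state, grp in df.groupby("state"):
        if "delta_u_kcal_mol" in grp.columns and grp["delta_u_kcal_mol"].notna().all():
            samples = grp["delta_u_kcal_mol"].to_numpy(float)
        else:
            samples = linres.gap_from_energies(
                grp["u_product_kcal_mol"].to_numpy(float),
                grp["u_reactant_kcal_mol"].to_numpy(float),
            )
        sets[state] = linres.GapSampleSet(state, samples)
    if set(sets) != {"reactant", "product"}:
        raise ValueError(f"gap CSV must hold reactant and product states, got {sorted(sets)}")
    return sets["reactant"], sets["product"]


def write_gap_table(reactant: linres.GapSampleSet, product: linres.GapSampleSet, path) -> None:
    rows = [
        {"state": s.state, "delta_u_kcal_mol": v}
        for s in (reactant, product)
        for v in s.samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def demo_reference_numbers() -> dict:
    """Evaluate the rate chain on the bundled reference parameter set.

    Uses only embedded constants: for each electron-transfer model the
    Moser-Dutton ruler is evaluated at the endpoints of the 2-10 A
    distance fluctuation range, the implied donor-acceptor distance of the
    reference k_et is recovered by inverting the ruler, and the combined
    superoxide production rate in the semiquinone state is computed from
    the reference binding/unbinding rates.
    """
    ref = REFERENCE_PARAMS
    r_lo, r_hi = ref["r_range_A"]
    report: dict = {"r_range_A": [r_lo, r_hi], "models": {}}
    for model in ("model_I", "model_II"):
        p = ref[model]
        params = rates.EtRateParams(
            p["delta_g_fep_kcal_mol"], p["lambda_p_kcal_mol"]
        )
        rate_at = {
            r: rates.moser_dutton_rate(
                rates.EtRateParams(
                    p["delta_g_fep_kcal_mol"], p["lambda_p_kcal_mol"], r_A=r
                )
            )
            for r in (r_lo, r_hi)
        }
        report["models"][model] = {
            "reference": dict(p),
            "rate_at_r_lo_s1": rate_at[r_lo],
            "rate_at_r_hi_s1": rate_at[r_hi],
            "brackets_reference_ket": bool(
                rate_at[r_lo] >= p["k_et_s1"] >= rate_at[r_hi]
            ),
            "implied_distance_A": rates.implied_distance(params, p["k_et_s1"]),
        }
    production = rates.production_rate(
        rates.ProductionRateParams(
            ref["k_bind_s1"],
            ref["k_unbind_s1"],
            ref["model_I"]["k_et_s1"],
            ref["x_sq"],
        )
    )
    report["production"] = {
        "k_bind_s1": ref["k_bind_s1"],
        "k_unbind_s1": ref["k_unbind_s1"],
        "k_et_s1": ref["model_I"]["k_et_s1"],
        "production_rate_s1": production.production_rate,
        "per_complex_rate_s1": production.per_complex_rate,
    }
    return report


def published_schemas() -> dict:
    """JSON schemas for the machine-readable configuration objects."""
    return {"PipelineConfig": PipelineConfig.model_json_schema()}
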