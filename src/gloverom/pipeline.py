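"""End-to-end orchestration: extraction, cohort validation, report bundle.

``validate_cohort`` runs the full clinimetric battery on a cohort table:
test–retest reliability between the first two analysis timepoints, group
comparison and ROC discrimination at the cross-sectional timepoint
(default T2), construct-validity correlations restricted to the impaired
subgroup, and longitudinal stability models. ``run_pipeline`` wires
extraction and/or validation behind one config and writes a manifest,
results JSON and a plain-text report.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinimetrics as cm
from .io import RunManifest, read_cohort, read_glove_stream, write_cohort
from .kinematics import apply_zero_reset, default_hand_model, joint_angle_series
from .rom import PATTERNS, Pattern, extract_assessment
from .simulate import ROM_COLUMNS

__all__ = ["extract_from_stream", "validate_cohort", "run_pipeline"]

CLINICAL_SCORES = {
    # column -> (correlation method, higher value = better function)
    "vigorimeter_kpa": ("pearson", True),
    "mrc_arm": ("kendall_tau_b", True),
    "incat_arm": ("kendall_tau_b", False),
    "rods_logits": ("pearson", True),
}


def extract_from_stream(
    stream_path,
    pattern: Pattern,
    model=None,
    subject_id: str | None = None,
    timepoint: str | None = None,
):
    """Read a glove stream file, calibrate, and extract one assessment."""
    model = model or default_hand_model()
    reset, frames = read_glove_stream(stream_path)
    if reset is None:
        raise ValueError(f"{stream_path}: no reset frame (zero-degree position)")
    calibrated = apply_zero_reset(frames, reset)
    mp = PATTERNS[Pattern(pattern)]
    series = {a: joint_angle_series(calibrated, model, a) for a in mp.angle_names}
    return extract_assessment(series, pattern, subject_id=subject_id,
                              timepoint=timepoint)


def _icc_matrix(table: pd.DataFrame, column: str, t_a: str, t_b: str):
    wide = table.pivot_table(index="subject_id", columns="timepoint",
                             values=column, aggfunc="first")
    if t_a not in wide or t_b not in wide:
        raise ValueError(f"timepoints {t_a}/{t_b} absent for {column}")
    return wide[[t_a, t_b]].to_numpy()


def validate_cohort(
    table: pd.DataFrame,
    cross_sectional_tp: str = "T2",
    reliability_tps: tuple[str, str] = ("T1", "T2"),
) -> dict:
    """Run the full validation battery; returns a JSON-serializable dict."""
    results: dict = {"reliability": {}, "group_comparison": {},
                     "roc": {}, "correlations": {}, "longitudinal": {}}
    t2 = table[table["timepoint"] == cross_sectional_tp]
    impaired = t2[t2["group"] == "impaired"]

    # --- reliability -------------------------------------------------------
    for col in [*ROM_COLUMNS.values(), "vigorimeter_kpa", "rods_logits"]:
        if col not in table:
            continue
        try:
            icc = cm.icc_absolute_agreement(
                _icc_matrix(table, col, *reliability_tps)
            )
        except (ValueError, ZeroDivisionError) as exc:
            warnings.warn(f"ICC for {col} skipped: {exc}", stacklevel=2)
            continue
        results["reliability"][col] = {
            "statistic": "ICC(A,1)", "estimate": icc.estimate,
            "ci95": list(icc.ci95), "rating": icc.rating,
            "n": icc.n_subjects,
        }
    for col in ("mrc_arm", "incat_arm"):
        if col not in table:
            continue
        wide = table.pivot_table(index="subject_id", columns="timepoint",
                                 values=col, aggfunc="first")
        pair = wide[list(reliability_tps)].dropna()
        try:
            kap = cm.weighted_kappa(pair.iloc[:, 0].astype(int),
                                    pair.iloc[:, 1].astype(int))
        except (ValueError, ZeroDivisionError) as exc:
            warnings.warn(f"kappa for {col} skipped: {exc}", stacklevel=2)
            continue
        results["reliability"][col] = {
            "statistic": "weighted_kappa", "estimate": kap.estimate,
            "ci95": list(kap.ci95), "rating": kap.rating, "n": kap.n,
        }

    # --- group comparison & discrimination at the cross-sectional TP -------
    labels = (t2["group"] == "impaired").astype(int).to_numpy()
    for pattern, col in ROM_COLUMNS.items():
        if col not in t2:
            continue
        x_imp = t2.loc[t2["group"] == "impaired", col].dropna()
        x_ctl = t2.loc[t2["group"] == "control", col].dropna()
        if len(x_imp) >= 2 and len(x_ctl) >= 2:
            w = cm.welch_from_samples(x_imp, x_ctl)
            results["group_comparison"][col] = {
                "impaired_mean": w.mean1, "impaired_sd": w.sd1, "n_impaired": w.n1,
                "control_mean": w.mean2, "control_sd": w.sd2, "n_control": w.n2,
                "t": w.t, "df": w.df, "p": w.p,
            }
        try:
            roc = cm.roc_analysis(t2[col].to_numpy(), labels)
            results["roc"][col] = {
                "auc": roc.auc, "cutoff_deg": roc.cutoff,
                "sensitivity": roc.sensitivity, "specificity": roc.specificity,
                "n_impaired": roc.n_positive, "n_control": roc.n_negative,
            }
        except ValueError as exc:
            warnings.warn(f"ROC for {col} skipped: {exc}", stacklevel=2)

    # composite ROC: glove patterns vs NCV vs CSA feature sets
    composites = {
        "glove_composite": (list(ROM_COLUMNS.values()), True),
        "ncv": (["ncv_ms"], True),
        "csa": (["csa_mm2"], False),
    }
    for name, (cols, higher_better) in composites.items():
        cols = [c for c in cols if c in t2]
        if not cols or t2[cols].notna().sum().sum() == 0:
            continue
        try:
            roc = cm.composite_roc(
                t2[cols].reset_index(drop=True), labels,
                {c: higher_better for c in cols},
            )
            results["roc"][name] = {
                "auc": roc.auc, "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
            }
        except ValueError as exc:
            warnings.warn(f"composite ROC {name} skipped: {exc}", stacklevel=2)

    # --- construct validity (impaired subgroup only) -----------------------
    for pattern, rom_col in ROM_COLUMNS.items():
        if rom_col not in impaired:
            continue
        results["correlations"][rom_col] = {}
        for score, (method, _) in CLINICAL_SCORES.items():
            if score not in impaired:
                continue
            try:
                c = cm.correlation(impaired[rom_col], impaired[score], method)
            except ValueError as exc:
                warnings.warn(
                    f"correlation {rom_col} vs {score} skipped: {exc}",
                    stacklevel=2,
                )
                continue
            results["correlations"][rom_col][score] = {
                "method": c.method, "r": c.estimate, "p": c.p,
                "n": c.n, "effect_size": c.effect_size,
            }

    # --- longitudinal stability -------------------------------------------
    for col in [*ROM_COLUMNS.values(), "vigorimeter_kpa"]:
        if col not in table:
            continue
        try:
            fit = cm.lmm_longitudinal(
                table.rename(columns={col: "value"}), categorical_time=True
            )
            results["longitudinal"][col] = {
                "time_omnibus_p": fit.time_p,
                "random_intercept_var": fit.random_intercept_var,
                "residual_var": fit.residual_var,
                "pairwise_holm_min_p": (
                    float(fit.pairwise["p_holm"].min())
                    if fit.pairwise is not None else None
                ),
            }
        except (ValueError, cm.LMMConvergenceError) as exc:
            warnings.warn(f"LMM for {col} skipped: {exc}", stacklevel=2)
    for pattern, rom_col in ROM_COLUMNS.items():
        if rom_col not in table or "vigorimeter_kpa" not in table:
            continue
        try:
            fit = cm.slope_comparison(table, "vigorimeter_kpa", rom_col)
            results["longitudinal"][f"slope_vigorimeter_vs_{rom_col}"] = {
                "interaction_p": fit.interaction_p,
            }
        except (ValueError, cm.LMMConvergenceError) as exc:
            warnings.warn(f"slope comparison for {rom_col} skipped: {exc}",
                          stacklevel=2)
    return results


def _render_report(results: dict) -> str:
    lines = ["Cohort validation report", "=" * 24, ""]
    for section, content in results.items():
        lines.append(section)
        lines.append("-" * len(section))
        for key, row in content.items():
            if isinstance(row, dict) and row and all(
                isinstance(v, dict) for v in row.values()
            ):
                lines.append(f"  {key}:")
                for k2, v2 in row.items():
                    lines.append(f"    {k2}: " + ", ".join(
                        f"{a}={_fmt(b)}" for a, b in v2.items()))
            else:
                lines.append(f"  {key}: " + ", ".join(
                    f"{a}={_fmt(b)}" for a, b in row.items()))
        lines.append("")
    return "\n".join(lines)


def _fmt(v):
    if isinstance(v, float):
        return f"{v:.4g}"
    if isinstance(v, list):
        return "[" + ", ".join(f"{x:.3g}" for x in v) + "]"
    return str(v)


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute extract → merge → validate per a pipeline config.

    Config keys: ``streams`` (optional list of {path, pattern, subject_id,
    timepoint}), ``cohort`` (optional cohort CSV path), ``seed``,
    ``cross_sectional_tp``. Extracted mean ROMs are merged into the cohort
    table (overwriting the pattern column for matching subject/timepoint
    rows) before validation. Writes manifest.json, results.json and
    report.txt; returns the results dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = {}
    extracted_rows = []
    for spec in config.get("streams", []):
        assessment = extract_from_stream(
            spec["path"], Pattern(spec["pattern"]),
            subject_id=spec.get("subject_id"), timepoint=spec.get("timepoint"),
        )
        inputs[str(spec["path"])] = spec["path"]
        extracted_rows.append({
            "subject_id": assessment.subject_id,
            "timepoint": assessment.timepoint,
            "pattern": assessment.pattern.value,
            "n_raw": len(assessment.deltas),
            "n_kept": assessment.n_movements_kept,
            "rom_mean_deg": assessment.rom_mean_deg,
        })
    if extracted_rows:
        pd.DataFrame(extracted_rows).to_csv(out_dir / "assessments.csv",
                                            index=False)
    results: dict = {}
    if config.get("cohort"):
        table = read_cohort(config["cohort"])
        inputs[str(config["cohort"])] = config["cohort"]
        for row in extracted_rows:
            col = ROM_COLUMNS[Pattern(row["pattern"])]
            mask = (
                (table["subject_id"] == row["subject_id"])
                & (table["timepoint"] == row["timepoint"])
            )
            table.loc[mask, col] = row["rom_mean_deg"]
        results = validate_cohort(
            table, cross_sectional_tp=config.get("cross_sectional_tp", "T2")
        )
    manifest = RunManifest.create(
        config={k: v for k, v in config.items() if k != "streams"}
        | {"n_streams": len(extracted_rows)},
        seeds={"seed": config.get("seed", 0)},
        inputs=inputs,
    )
    manifest.write(out_dir / "manifest.json")
    (out_dir / "results.json").write_text(json.dumps(results, indent=2))
    (out_dir / "report.txt").write_text(_render_report(results))
    return results
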