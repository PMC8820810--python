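"""End-to-end orchestration: QC, four-group coding, adjusted models and the
interaction table, with full provenance.

``run_analysis`` walks every SNP of the panel crossed with every requested
drug stratum and emits one results row each: the four-group case/control
counts with cell percentages, the three adjusted group odds ratios versus the
doubly-unexposed reference, and RERI / synergy index with confidence
intervals.  Monovariant SNPs and QC-failed SNPs are skipped with an explicit
reason; sparse exposed-carrier cells keep their counts but mark the estimates
"not applicable".  A descriptive covariate table (crude and model-based odds
ratios) and a QC report accompany the interaction table, and a run record
stores seed, configuration hash, package version and per-model convergence.

No multiple-testing adjustment is applied -- the candidate-SNP panel is
selected a priori and every performed test is reported; the run record counts
the tests so users can apply their own correction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .confounders import select_confounders
from .core_data import (
    AnalysisConfig,
    GenotypeCall,
    ParticipantRecord,
    SNPDefinition,
    ValidationError,
    participants_frame,
)
from .effects import (
    CollinearityError,
    FittedModel,
    crude_or,
    fit_logistic,
    fit_nested_glmm,
    or_from_model,
)
from .exposure import Group, assign_groups, derive_exposure
from .genotype_qc import qc_report
from .interaction import interaction_ci_bootstrap, interaction_ci_delta

__all__ = ["ResultsBundle", "run_analysis", "write_results", "read_results",
           "build_design"]

GROUP_TERMS = ("g1_drug_wild", "g2_drug_variant", "g3_nodrug_variant")

#: expansion of covariate names into design-matrix columns
_COVARIATE_COLUMNS = {
    "arthrosis": ("arthrosis",),
    "h_pylori": ("h_pylori_yes",),
    "gi_history": ("gi_ulcer", "gi_bleeding"),
    "ppi_use": ("ppi_use",),
    "antiaggregant_use": ("antiaggregant_use",),
    "anticoagulant_use": ("anticoagulant_use",),
    "n_interviews": ("multiple_interviews",),
    "interview_reliability": ("interview_reliability",),
    "sex": ("sex_female",),
}


def _covariate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate columns with NaN for explicit missing values."""
    out = pd.DataFrame(index=frame.index)
    for name in ("arthrosis", "ppi_use", "antiaggregant_use", "anticoagulant_use"):
        out[name] = frame[name].map(lambda v: float(v) if v is not None and not pd.isna(v) else np.nan)
    out["h_pylori_yes"] = frame["h_pylori"].map(
        lambda v: np.nan if v is None or pd.isna(v) else float(v == "yes"))
    out["gi_ulcer"] = frame["gi_history"].map(
        lambda v: np.nan if v is None or pd.isna(v) else float(v == "ulcer"))
    out["gi_bleeding"] = frame["gi_history"].map(
        lambda v: np.nan if v is None or pd.isna(v) else float(v == "bleeding"))
    out["multiple_interviews"] = frame["n_interviews"].map(
        lambda v: np.nan if v is None or pd.isna(v) else float(v >= 2))
    out["interview_reliability"] = pd.to_numeric(
        frame["interview_reliability"], errors="coerce")
    out["sex_female"] = frame["sex"].map(
        lambda v: np.nan if v is None or pd.isna(v) else float(v == "female"))
    return out


def build_design(
    frame: pd.DataFrame,
    group_of: dict[str, Group],
    covariate_terms: Sequence[str],
):
    """Design matrix for one SNP x drug-stratum analysis.

    Rows are participants with a non-missing genotype (keys of ``group_of``);
    columns are intercept, the three group indicators and the expanded
    covariates.  Rows with any missing covariate are dropped listwise;
    constant columns are dropped with a note.  Returns
    (y, X, names, groups_frame, n_dropped, notes).
    """
    sub = frame.loc[frame["participant_id"].isin(group_of)].copy()
    groups = sub["participant_id"].map(group_of)
    design = pd.DataFrame(index=sub.index)
    design["intercept"] = 1.0
    design["g1_drug_wild"] = (groups == Group.G1_DRUG_WILD).astype(float)
    design["g2_drug_variant"] = (groups == Group.G2_DRUG_VARIANT).astype(float)
    design["g3_nodrug_variant"] = (groups == Group.G3_NODRUG_VARIANT).astype(float)
    covars = _covariate_frame(sub)
    for term in covariate_terms:
        for col in _COVARIATE_COLUMNS.get(term, (term,)):
            design[col] = covars[col]

    complete = design.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    design = design.loc[complete]
    sub = sub.loc[complete]

    notes: list[str] = []
    if n_dropped:
        notes.append(f"{n_dropped} rows dropped for missing covariates")
    keep = []
    for col in design.columns:
        if col != "intercept" and design[col].nunique() <= 1:
            notes.append(f"dropped constant column {col}")
        else:
            keep.append(col)
    design = design[keep]
    y = sub["is_case"].astype(float).to_numpy()
    X = design.to_numpy(dtype=float)
    levels = sub[["stratum_id", "hospital_id", "period_id"]].copy()
    # nest the hospital level inside recruitment period
    levels["hospital_id"] = levels["period_id"].astype(str) + "/" + levels["hospital_id"].astype(str)
    return y, X, list(design.columns), levels, n_dropped, notes


def _fit(config: AnalysisConfig, y, X, names, levels) -> FittedModel:
    if config.model == "logistic":
        return fit_logistic(y, X, names)
    return fit_nested_glmm(
        y, X, names,
        stratum=levels["stratum_id"].to_numpy(),
        hospital=levels["hospital_id"].to_numpy(),
        period=levels["period_id"].to_numpy(),
    )


@dataclass
class ResultsBundle:
    results: pd.DataFrame
    descriptive: pd.DataFrame
    qc: pd.DataFrame
    skip_log: pd.DataFrame
    run_info: dict


_RESULT_COLUMNS = [
    "rs_id", "gene", "drug_class",
    "n_g4_cases", "pct_g4_cases", "n_g4_controls", "pct_g4_controls",
    "n_g3_cases", "pct_g3_cases", "n_g3_controls", "pct_g3_controls",
    "n_g1_cases", "pct_g1_cases", "n_g1_controls", "pct_g1_controls",
    "n_g2_cases", "pct_g2_cases", "n_g2_controls", "pct_g2_controls",
    "or10", "or10_low", "or10_high", "or10_p",
    "or01", "or01_low", "or01_high", "or01_p",
    "or11", "or11_low", "or11_high", "or11_p",
    "reri", "reri_low", "reri_high",
    "s", "s_low", "s_high",
    "ci_method", "adjusted_for", "n_used", "n_dropped_missing_covariates",
    "sd_stratum", "sd_hospital", "sd_period",
    "converged", "skip_reason", "notes",
]


def _is_monovariant(calls: Sequence[GenotypeCall], snp: SNPDefinition) -> bool:
    observed = {c.alleles for c in calls if c.rs_id == snp.rs_id and c.alleles is not None}
    return len(observed) <= 1


def descriptive_table(
    frame: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Case/control composition per covariate level with crude and model ORs.

    Crude ORs are Woolf 2x2 odds ratios against the variable's reference
    level; model-based ORs refit each variable alone under the configured
    model (random intercepts included for the mixed model).
    """
    covars = _covariate_frame(frame)
    is_case = frame["is_case"].astype(bool)
    n_cases = int(is_case.sum())
    n_controls = int((~is_case).sum())

    variables: list[tuple[str, str, pd.Series]] = []  # (variable, level, indicator)
    age = pd.to_numeric(frame["age"], errors="coerce")
    bands = pd.cut(age, [-np.inf, 45, 65, np.inf], labels=["<45", "45-65", ">65"])
    for level in ["45-65", ">65"]:
        ind = (bands == level).astype(float).where(bands.notna() & (bands.isin([level, "<45"])))
        variables.append(("age", level, ind))
    variables.append(("sex", "female", covars["sex_female"]))
    simple = [
        ("arthrosis", "yes", covars["arthrosis"]),
        ("h_pylori", "yes", covars["h_pylori_yes"]),
        ("ppi_use", "yes", covars["ppi_use"]),
        ("antiaggregant_use", "yes", covars["antiaggregant_use"]),
        ("anticoagulant_use", "yes", covars["anticoagulant_use"]),
        ("n_interviews", ">=2", covars["multiple_interviews"]),
    ]
    variables.extend(simple)
    gi = frame["gi_history"]
    for level, col in (("ulcer", "gi_ulcer"), ("bleeding", "gi_bleeding")):
        ind = covars[col].where(gi.isna() | gi.isin([level, "none_or_dyspepsia"]))
        variables.append(("gi_history", level, ind))

    rows = []
    for variable, level, indicator in variables:
        mask = indicator.notna()
        ind = indicator[mask].astype(bool)
        cases_lv = int((ind & is_case[mask]).sum())
        controls_lv = int((ind & ~is_case[mask]).sum())
        cases_ref = int((~ind & is_case[mask]).sum())
        controls_ref = int((~ind & ~is_case[mask]).sum())
        crude = crude_or(cases_lv, controls_lv, cases_ref, controls_ref,
                         ci_level=config.ci_level)
        model_or = model_low = model_high = np.nan
        try:
            sub = frame.loc[mask]
            y = is_case[mask].astype(float).to_numpy()
            X = np.column_stack([np.ones(len(sub)), ind.astype(float).to_numpy()])
            levels = sub[["stratum_id", "hospital_id", "period_id"]].copy()
            levels["hospital_id"] = (levels["period_id"].astype(str) + "/"
                                     + levels["hospital_id"].astype(str))
            model = _fit(config, y, X, ["intercept", "term"], levels)
            res = or_from_model(model, "term", config.ci_level)
            model_or, model_low, model_high = res.or_point, res.ci_low, res.ci_high
        except Exception:
            pass  # degenerate level (e.g. constant) -> crude OR only
        rows.append({
            "variable": variable,
            "level": level,
            "n_cases": cases_lv,
            "pct_cases": 100.0 * cases_lv / n_cases if n_cases else np.nan,
            "n_controls": controls_lv,
            "pct_controls": 100.0 * controls_lv / n_controls if n_controls else np.nan,
            "crude_or": crude.or_point,
            "crude_low": crude.ci_low,
            "crude_high": crude.ci_high,
            "model_or": model_or,
            "model_low": model_low,
            "model_high": model_high,
        })
    return pd.DataFrame(rows)


def run_analysis(
    config: AnalysisConfig,
    participants: Sequence[ParticipantRecord],
    genotypes: Sequence[GenotypeCall],
    panel: Sequence[SNPDefinition],
) -> ResultsBundle:
    """Full interaction analysis over every panel SNP and drug stratum."""
    frame = participants_frame(participants)
    if frame.empty:
        raise ValidationError("no participants to analyse")
    qc = qc_report(genotypes, participants, panel,
                   config.call_rate_threshold, config.hwe_alpha)
    qc_by_rs = qc.set_index("rs_id") if not qc.empty else pd.DataFrame()
    descriptive = descriptive_table(frame, config)

    selected_covariates: tuple[str, ...] | None = None
    result_rows: list[dict] = []
    skip_rows: list[dict] = []
    convergence: dict[str, bool] = {}
    n_tests = 0

    for snp in panel:
        snp_calls = [c for c in genotypes if c.rs_id == snp.rs_id]
        if _is_monovariant(snp_calls, snp):
            reason = "monovariant: a single genotype observed in the whole sample"
            skip_rows.append({"rs_id": snp.rs_id, "drug_class": "", "reason": reason})
            for drug_class in config.drug_strata:
                result_rows.append({"rs_id": snp.rs_id, "gene": snp.gene,
                                    "drug_class": drug_class, "skip_reason": reason})
            continue
        if not qc_by_rs.loc[snp.rs_id, "qc_pass"] and not config.include_qc_failed:
            reason = ("failed QC (call rate "
                      f"{qc_by_rs.loc[snp.rs_id, 'call_rate']:.3f}, HWE p "
                      f"{qc_by_rs.loc[snp.rs_id, 'hwe_p_exact']:.4g})")
            skip_rows.append({"rs_id": snp.rs_id, "drug_class": "", "reason": reason})
            for drug_class in config.drug_strata:
                result_rows.append({"rs_id": snp.rs_id, "gene": snp.gene,
                                    "drug_class": drug_class, "skip_reason": reason})
            continue

        for drug_class in config.drug_strata:
            row: dict = {"rs_id": snp.rs_id, "gene": snp.gene, "drug_class": drug_class}
            codings, table = assign_groups(participants, snp_calls, snp,
                                           drug_class, config)
            for group, tag in ((Group.G4_NODRUG_WILD, "g4"),
                               (Group.G3_NODRUG_VARIANT, "g3"),
                               (Group.G1_DRUG_WILD, "g1"),
                               (Group.G2_DRUG_VARIANT, "g2")):
                nc, pc, nk, pk = table.cell(group)
                row.update({f"n_{tag}_cases": nc, f"pct_{tag}_cases": pc,
                            f"n_{tag}_controls": nk, f"pct_{tag}_controls": pk})
            if table.not_applicable:
                row["skip_reason"] = "; ".join(table.notes)
                result_rows.append(row)
                skip_rows.append({"rs_id": snp.rs_id, "drug_class": drug_class,
                                  "reason": row["skip_reason"]})
                continue

            group_of = {c.participant_id: c.group for c in codings}
            covariates = config.forced_adjustment
            if config.selection_enabled:
                if config.selection_scope == "per_model" or selected_covariates is None:
                    def fitter(terms):
                        y_, X_, names_, levels_, _, _ = build_design(
                            frame, group_of, terms)
                        return _fit(config, y_, X_, names_, levels_)
                    sel = select_confounders(
                        fitter, base_terms=[], candidates=config.adjustment_candidates,
                        group_terms=GROUP_TERMS, threshold=config.selection_threshold)
                    selected_covariates = tuple(sel.selected)
                covariates = selected_covariates

            y, X, names, levels, n_dropped, notes = build_design(
                frame, group_of, covariates)
            try:
                model = _fit(config, y, X, names, levels)
            except (CollinearityError, ValidationError) as exc:
                row["skip_reason"] = f"model not estimable: {exc}"
                result_rows.append(row)
                skip_rows.append({"rs_id": snp.rs_id, "drug_class": drug_class,
                                  "reason": row["skip_reason"]})
                continue
            convergence[f"{snp.rs_id}/{drug_class}"] = model.converged
            n_tests += 1

            for term, tag in (("g1_drug_wild", "or10"),
                              ("g3_nodrug_variant", "or01"),
                              ("g2_drug_variant", "or11")):
                res = or_from_model(model, term, config.ci_level)
                row.update({tag: res.or_point, f"{tag}_low": res.ci_low,
                            f"{tag}_high": res.ci_high, f"{tag}_p": res.p_value})
            if config.interaction_method == "bootstrap":
                est = interaction_ci_bootstrap(
                    model, *GROUP_TERMS, n_draws=config.bootstrap_draws,
                    seed=config.rng_seed, ci_level=config.ci_level)
            else:
                est = interaction_ci_delta(model, *GROUP_TERMS, config.ci_level)
            row.update({
                "reri": est.reri, "reri_low": est.reri_ci[0], "reri_high": est.reri_ci[1],
                "s": est.s if est.s is not None else np.nan,
                "s_low": est.s_ci[0] if est.s_ci else np.nan,
                "s_high": est.s_ci[1] if est.s_ci else np.nan,
                "ci_method": est.method,
                "adjusted_for": "+".join(covariates),
                "n_used": model.n_used,
                "n_dropped_missing_covariates": n_dropped,
                "sd_stratum": model.variance_components.get("stratum", np.nan),
                "sd_hospital": model.variance_components.get("hospital", np.nan),
                "sd_period": model.variance_components.get("period", np.nan),
                "converged": model.converged,
                "notes": "; ".join([*notes, *model.notes, *est.notes]),
            })
            result_rows.append(row)

    results = pd.DataFrame(result_rows, columns=_RESULT_COLUMNS)
    skip_log = pd.DataFrame(skip_rows, columns=["rs_id", "drug_class", "reason"])
    config_json = json.dumps(asdict(config), sort_keys=True, default=str)
    run_info = {
        "seed": config.rng_seed,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "software_version": __version__,
        "n_interaction_tests": n_tests,
        "multiple_testing_adjustment": "none (a-priori candidate panel; all tests reported)",
        "model_convergence": convergence,
    }
    return ResultsBundle(results=results, descriptive=descriptive, qc=qc,
                         skip_log=skip_log, run_info=run_info)


_NA_HEADER = ("# Missing/NA policy: empty cells mean not-estimated or "
              "not-applicable; see skip_reason and notes columns.\n")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_NA_HEADER)
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def write_results(bundle: ResultsBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write results.csv, descriptive.csv, qc_report.csv, skip_log.csv, run.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out / "results.csv",
        "descriptive": out / "descriptive.csv",
        "qc": out / "qc_report.csv",
        "skip_log": out / "skip_log.csv",
        "run": out / "run.json",
    }
    _write_csv(bundle.results, paths["results"])
    _write_csv(bundle.descriptive, paths["descriptive"])
    _write_csv(bundle.qc, paths["qc"])
    _write_csv(bundle.skip_log, paths["skip_log"])
    with open(paths["run"], "w") as fh:
        json.dump(bundle.run_info, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_results(out_dir: str | Path) -> ResultsBundle:
    """Reparse a written results directory (inverse of :func:`write_results`)."""
    out = Path(out_dir)
    read = lambda p: pd.read_csv(p, comment="#")
    with open(out / "run.json") as fh:
        run_info = json.load(fh)
    return ResultsBundle(
        results=read(out / "results.csv"),
        descriptive=read(out / "descriptive.csv"),
        qc=read(out / "qc_report.csv"),
        skip_log=read(out / "skip_log.csv"),
        run_info=run_info,
    )
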