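"""End-to-end orchestration: simulate → stratify → DE → score → clinical.

Every stage reads/writes plain files with documented schemas so stages can
be run and tested independently; the consolidated run report echoes the
effective configuration and the exact numbers each stage produced.
Seeds propagate deterministically from the single global seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical as cl
from . import de
from . import mixture as mx
from . import scoring as sc
from . import simulate as sim
from .errors import ParameterError, StateError

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_inputs",
           "read_cohort", "read_expression"]

log = logging.getLogger("plaquestrat")


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run; defaults are the study conditions."""

    seed: int = 0
    outdir: str = "plaquestrat_run"
    stages: tuple = ("simulate", "stratify", "de", "score", "clinical")
    cohort_path: str | None = None      # skip simulation and read this CSV
    threshold_override: float | None = None  # e.g. 250.0 for reproduction runs
    alpha: float = 0.05
    k_max: int = 4
    n_boot: int = 1000
    n_restarts: int = 10
    expression_subjects: int | None = 65     # subcohort size for DE stages
    fch: float = 2.0
    fdr: float = 0.05
    weight: str = "k"
    cohort: sim.CohortSimParams = field(default_factory=sim.CohortSimParams)
    expression: sim.ExpressionSimParams = field(default_factory=sim.ExpressionSimParams)
    clinical: sim.ClinicalSimParams = field(default_factory=sim.ClinicalSimParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        for name, sub in (
            ("cohort", sim.CohortSimParams),
            ("expression", sim.ExpressionSimParams),
            ("clinical", sim.ClinicalSimParams),
        ):
            if name in kw and isinstance(kw[name], dict):
                block = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in kw[name].items()
                }
                kw[name] = sub(**block)
        if "stages" in kw:
            kw["stages"] = tuple(kw["stages"])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def spawn_seeds(self) -> dict:
        ss = np.random.SeedSequence(self.seed)
        names = ["cohort", "stratify", "expression", "clinical"]
        return {
            n: int(s.generate_state(1)[0] % (2**31))
            for n, s in zip(names, ss.spawn(len(names)))
        }


@dataclass
class RunReport:
    config: dict
    sections: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "sections": self.sections}, fh,
                      indent=2, default=_jsonable)

    def to_markdown(self, path) -> None:
        lines = ["# plaquestrat run report", ""]
        for name, sec in self.sections.items():
            lines.append(f"## {name}")
            lines.append("```json")
            lines.append(json.dumps(sec, indent=2, default=_jsonable))
            lines.append("```")
            lines.append("")
        Path(path).write_text("\n".join(lines))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


# ---------------------------------------------------------------------------
# file IO for stage artifacts


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "lesional_um", "nonlesional_um"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"cohort file missing columns: {sorted(missing)}")
    return df


def read_expression(expr_path, meta_path) -> sim.ExpressionStudy:
    matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
    samples = pd.read_csv(meta_path)
    study = sim.ExpressionStudy(matrix=matrix, samples=samples)
    study.validate()
    return study


def validate_inputs(
    cohort: pd.DataFrame | None = None,
    samples: pd.DataFrame | None = None,
    courses: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Schema diagnostics (row-level, non-throwing) for pipeline inputs."""
    issues = []
    if cohort is not None:
        for col in ("patient_id", "lesional_um", "nonlesional_um"):
            if col not in cohort.columns:
                issues.append({"table": "cohort", "row": -1,
                               "issue": f"missing column {col}"})
        if "lesional_um" in cohort:
            for i in cohort.index[pd.to_numeric(
                    cohort["lesional_um"], errors="coerce").isna()]:
                issues.append({"table": "cohort", "row": int(i),
                               "issue": "non-numeric lesional_um"})
    if samples is not None:
        dup = samples.groupby(["subject_id", "tissue"]).size()
        for (sid, tissue), n in dup.items():
            if n > 1:
                issues.append({"table": "samples", "row": -1,
                               "issue": f"subject {sid} has {n} {tissue} samples"})
        bad = set(samples["tissue"]) - {"LS", "NL"}
        if bad:
            issues.append({"table": "samples", "row": -1,
                           "issue": f"unknown tissue values {sorted(bad)}"})
    if courses is not None:
        for i, v in courses["pasi"].items():
            if not (0 <= v <= 72):
                issues.append({"table": "courses", "row": int(i),
                               "issue": f"PASI {v} outside [0, 72]"})
    return pd.DataFrame(issues, columns=["table", "row", "issue"])


# ---------------------------------------------------------------------------
# stages


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    Any prefix of (simulate, stratify, de, score, clinical) may be run; a
    stage requiring an upstream artifact raises a dependency error naming
    the stage if that artifact is neither in memory nor on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.spawn_seeds()
    report = RunReport(config=config.as_dict())
    stages = list(config.stages)

    cohort = None
    strat = None
    study = None
    table_fdr = None

    if config.cohort_path:
        cohort = read_cohort(config.cohort_path)
        log.info("stage=load_cohort n=%d", len(cohort))

    if "simulate" in stages and cohort is None:
        params = dataclasses.replace(config.cohort, seed=seeds["cohort"])
        cohort = sim.simulate_thickness(params)
        cohort.to_csv(out / "cohort.csv", index=False)
        report.sections["simulate"] = {
            "n_patients": len(cohort),
            "params": dataclasses.asdict(params),
        }
        log.info("stage=simulate n=%d seed=%d", len(cohort), seeds["cohort"])

    if "stratify" in stages:
        if cohort is None:
            raise StateError("stratify requires a cohort (simulate stage or cohort_path)")
        kept, removed = mx.exclude_invalid(cohort)
        x = kept["diff_um"].to_numpy()
        if config.threshold_override is not None:
            fit, trail, ceiling = None, [], False
            tau = float(config.threshold_override)
            tau_source = "override"
        else:
            fit, trail, ceiling = mx.select_k(
                x, alpha=config.alpha, k_max=config.k_max, n_boot=config.n_boot,
                seed=seeds["stratify"], n_restarts=config.n_restarts,
            )
            if fit.k == 2:
                tau = mx.density_intersection(fit)
                tau_source = "density_intersection"
            else:
                tau = float("nan")
                tau_source = f"unavailable (k={fit.k})"
        if np.isfinite(tau):
            strat = mx.classify(kept, tau, fit=fit)
            summary = mx.group_summary(strat, kept)
            strat_df = pd.DataFrame(
                {
                    "patient_id": kept["patient_id"],
                    "diff_um": kept["diff_um"],
                    "label": strat.labels.values,
                }
            )
            if fit is not None and fit.k == 2:
                strat_df["posterior_thick"] = fit.responsibilities[:, 1]
            strat_df.to_csv(out / "stratification.csv", index=False)
            summary.to_csv(out / "group_summary.csv", index=False)
        else:
            summary = None
        fit_json = fit.to_dict() if fit is not None else {"k": None}
        fit_json["threshold_um"] = tau
        fit_json["threshold_source"] = tau_source
        fit_json["test_trail"] = [
            {"k_null": t.k_null, "lrt_observed": t.lrt_observed,
             "p_value": t.p_value, "n_boot": t.n_boot}
            for t in trail
        ]
        (out / "mixture_fit.json").write_text(
            json.dumps(fit_json, indent=2, default=_jsonable)
        )
        report.sections["stratify"] = {
            "n_excluded": len(removed),
            "k": fit.k if fit is not None else None,
            "hit_k_max": ceiling,
            "threshold_um": tau,
            "threshold_source": tau_source,
            "group_summary": summary.to_dict("records") if summary is not None else None,
            "test_trail": fit_json["test_trail"],
        }
        log.info("stage=stratify k=%s tau=%.1f",
                 fit.k if fit is not None else "-", tau)
        cohort = kept

    if "de" in stages or "score" in stages:
        if strat is None:
            raise StateError("de/score stages require the stratify stage")
        labelled = sim.attach_groups(cohort, strat.labels)
        if config.expression_subjects and config.expression_subjects < len(labelled):
            rng = np.random.default_rng(seeds["expression"])
            idx = rng.choice(len(labelled), config.expression_subjects, replace=False)
            labelled = labelled.iloc[np.sort(idx)]
        eparams = dataclasses.replace(config.expression, seed=seeds["expression"])
        study = sim.simulate_expression(labelled, eparams)
        study.matrix.round(4).to_csv(out / "expression.tsv", sep="\t")
        study.samples.to_csv(out / "samples.csv", index=False)

    if "de" in stages:
        matrix, filt_report = de.filter_probes(study.matrix)
        matrix = de.quantile_normalize(matrix)
        fits = de.fit_gene_models(
            sim.ExpressionStudy(matrix=matrix, samples=study.samples)
        )
        table = de.apply_contrasts(fits)
        table, mod = de.moderate(table, fits)
        table_fdr = de.add_fdr(table)
        degs = de.call_degs(table_fdr, fch=config.fch, fdr=config.fdr)
        ov = de.overlap_summary(degs["LSvsNL_thin"], degs["LSvsNL_thick"])
        r = de.fc_correlation(
            table_fdr,
            genes=set(degs["LSvsNL_thin"]["gene"]) | set(degs["LSvsNL_thick"]["gene"]),
        )
        slim = table_fdr[["gene", "contrast", "estimate", "se", "t", "p", "q"]].copy()
        slim["fc_linear"] = de.signed_fold_change(slim["estimate"].to_numpy())
        slim.to_csv(out / "contrasts.tsv", sep="\t", index=False)
        for name, frame in degs.items():
            frame["gene"].to_csv(out / f"degs_{name}.txt", index=False, header=False)
        report.sections["de"] = {
            "filter": filt_report,
            "moderation": {"d0": mod.d0, "s0_sq": mod.s0_sq},
            "n_degs": {k: len(v) for k, v in degs.items()},
            "overlap": ov,
            "fc_correlation": r,
        }
        log.info("stage=de degs_thin=%d degs_thick=%d overlap=%.1f%%",
                 len(degs["LSvsNL_thin"]), len(degs["LSvsNL_thick"]),
                 ov["overlap_pct"])

    if "score" in stages:
        truth = study.truth
        gene_set = sc.GeneSet(
            "SIGNATURE",
            up=list(truth.loc[truth.role == "up", "gene"]),
            down=list(truth.loc[truth.role == "down", "gene"]),
        )
        scores, info = sc.score_gene_sets(
            study.matrix, [gene_set], weight=config.weight, split_directions=True
        )
        contrast = sc.compare_scores(scores, study.samples)
        scores.to_csv(out / "scores.tsv", sep="\t")
        contrast.to_csv(out / "score_contrasts.tsv", sep="\t", index=False)
        report.sections["score"] = {
            "weight": config.weight,
            "sets": info.to_dict("records"),
            "contrasts": contrast[["set", "tissue", "estimate", "p", "stars"]]
            .to_dict("records"),
        }
        log.info("stage=score n_sets=%d", len(info))

    if "clinical" in stages:
        if strat is None:
            raise StateError("clinical stage requires the stratify stage")
        labelled = sim.attach_groups(cohort, strat.labels)
        cparams = dataclasses.replace(config.clinical, seed=seeds["clinical"])
        tables = sim.simulate_clinical(labelled, cparams)
        for name, frame in tables.items():
            frame.to_csv(out / f"{name}.csv", index=False)
        anova, tukey, skipped = cl.compare_cell_counts(
            tables["cell_counts"], strat.labels
        )
        wide = (
            tables["cell_counts"]
            .query("tissue == 'LS'")
            .pivot(index="patient_id", columns="marker", values="count")
            .join(
                labelled.set_index("patient_id")["lesional_um"].rename("thickness_um")
            )
        )
        stepwise = cl.stepwise_thickness_regression(wide)
        cyto = cl.cytokine_group_contrast(tables["cytokines"], strat.labels)
        pasi = cl.pasi_improvement(tables["courses"], strat.labels)
        tnfa = cl.cytokine_change_contrast(tables["courses"], strat.labels)
        anova.to_csv(out / "cell_anova.csv", index=False)
        tukey.to_csv(out / "cell_tukey.csv", index=False)
        cyto.to_csv(out / "cytokine_contrasts.csv", index=False)
        pasi.to_csv(out / "pasi_improvement.csv", index=False)
        tnfa.to_csv(out / "tnfa_change.csv", index=False)
        report.sections["clinical"] = {
            "anova": anova.to_dict("records"),
            "markers_skipped": skipped,
            "stepwise_selected": stepwise.selected,
            "stepwise_std_coefs": stepwise.std_coefs.to_dict(),
            "cytokines": cyto.to_dict("records"),
            "pasi": pasi.to_dict("records"),
            "tnfa_change": tnfa.to_dict("records"),
        }
        log.info("stage=clinical markers=%d", anova.shape[0])

    report.to_json(out / "report.json")
    report.to_markdown(out / "report.md")
    return report
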