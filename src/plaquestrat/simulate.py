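"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes:

* per-patient paired epidermal thickness where the lesional − non-lesional
  difference follows a two-component Gaussian mixture (thin / thick plaque
  subpopulations);
* paired lesional (LS) / non-lesional (NL) log2 expression sharing one
  signature whose fold-change amplitude is scaled up in the thick group,
  with subject random intercepts;
* clinical tables: dermal cell counts linearly related to thickness,
  log-normal serum cytokines with a group shift, and two-visit PASI
  courses under two biologic treatments.

Default mixture parameters are derived from the published cohort summary:
component weights 285/609 and 324/609, difference means 255.5 − 90.0 =
165.5 μm and 450.6 − 89.8 = 360.8 μm, component SDs 60 and 93 μm, and a
non-lesional mean of 89.9 μm with SD 24.7 μm (total SEM 1.0 at n = 609).
At these defaults the weighted component densities intersect near 250 μm.

Thickness values are drawn from untruncated Gaussians and negative draws
are resampled; at the defaults the components sit several SDs above zero
so the induced bias is negligible (the thin component loses < 0.3% of its
left tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ParameterError, StateError
from .mixture import THICK, THIN

__all__ = [
    "CohortSimParams",
    "ExpressionSimParams",
    "ClinicalSimParams",
    "ExpressionStudy",
    "simulate_thickness",
    "attach_groups",
    "simulate_expression",
    "simulate_clinical",
]


def _resample_nonneg(rng, draw, lo=0.0, max_rounds=1000):
    """Redraw entries < lo until none remain (truncation by resampling)."""
    x = draw(rng)
    for _ in range(max_rounds):
        bad = x < lo
        if not bad.any():
            return x
        x[bad] = draw(rng)[bad]
    raise RuntimeError("resampling failed to clear negative values")


# ---------------------------------------------------------------------------
# thickness


@dataclass
class CohortSimParams:
    """Parameters of the simulated thickness cohort (all lengths in μm)."""

    n_patients: int = 609
    mix_weights: tuple = (285 / 609, 324 / 609)
    diff_means: tuple = (165.5, 360.8)
    diff_sds: tuple = (60.0, 93.0)
    nl_mean: float = 89.9
    nl_sd: float = 24.7
    seed: int = 0

    def validate(self) -> None:
        w = np.asarray(self.mix_weights, float)
        mu = np.asarray(self.diff_means, float)
        sd = np.asarray(self.diff_sds, float)
        if self.n_patients < 2:
            raise ParameterError("n_patients: must be >= 2")
        if not (len(w) == len(mu) == len(sd)):
            raise ParameterError(
                "mix_weights/diff_means/diff_sds: lengths must agree"
            )
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ParameterError("mix_weights: must be > 0 and sum to 1")
        if np.any(sd <= 0):
            raise ParameterError("diff_sds: must be > 0")
        if np.any(np.diff(mu) <= 0):
            raise ParameterError("diff_means: must be strictly increasing")
        if self.nl_sd < 0:
            raise ParameterError("nl_sd: must be >= 0")


def simulate_thickness(params: CohortSimParams) -> pd.DataFrame:
    """Simulate a paired-thickness cohort.

    Returns one row per patient with ``patient_id``, ``nonlesional_um``,
    ``lesional_um``, ``diff_um`` and the hidden ``true_component``
    (0-based, sorted by component mean).  lesional = nonlesional + diff,
    with the difference drawn from the mixture; both thickness draws are
    truncated at 0 by resampling.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    w = np.asarray(params.mix_weights, float)
    mu = np.asarray(params.diff_means, float)
    sd = np.asarray(params.diff_sds, float)

    comp = rng.choice(len(w), size=n, p=w)
    diff = _resample_nonneg(rng, lambda r: r.normal(mu[comp], sd[comp]))
    nl = _resample_nonneg(rng, lambda r: r.normal(params.nl_mean, params.nl_sd, n))
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(1, n + 1)],
            "nonlesional_um": nl,
            "lesional_um": nl + diff,
            "diff_um": diff,
            "true_component": comp,
        }
    )


def attach_groups(cohort: pd.DataFrame, labels: pd.Series | None = None) -> pd.DataFrame:
    """Add a ``group`` column (thin/thick) from explicit labels or truth.

    With ``labels`` (a patient_id-indexed Series, e.g. from a fitted
    stratification) those are used; otherwise the hidden ``true_component``
    is mapped 0 → thin, last → thick.
    """
    out = cohort.copy()
    if labels is not None:
        out["group"] = labels.reindex(out["patient_id"]).values
    elif "true_component" in out:
        k = int(out["true_component"].max())
        out["group"] = np.where(out["true_component"] == k, THICK, THIN)
    else:
        raise StateError("cohort has neither labels nor true_component")
    if out["group"].isna().any():
        raise StateError("labels missing for some patients")
    return out


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionSimParams:
    """Parameters of the paired LS/NL log2 expression simulation.

    ``base_lfc`` is the LS − NL log2 fold change of signature genes in the
    thin group; the thick group gets ``amplitude × base_lfc`` — the two
    groups share one signature dysregulated to different degrees.
    """

    n_genes: int = 2000
    n_signature: int = 200
    base_lfc: float = 1.5
    amplitude: float = 1.6
    subject_sd: float = 0.3
    noise_sd: float = 0.25
    baseline_range: tuple = (4.0, 12.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_signature > self.n_genes:
            raise ParameterError("n_signature: must be <= n_genes")
        if self.n_signature < 0 or self.n_genes < 1:
            raise ParameterError("n_genes/n_signature: must be positive")
        if self.amplitude <= 0:
            raise ParameterError("amplitude: must be > 0")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ParameterError("subject_sd/noise_sd: must be >= 0")


@dataclass
class ExpressionStudy:
    """Log2 expression matrix (genes × samples) plus sample metadata.

    ``samples`` columns: sample_id, subject_id, tissue (LS/NL), group
    (thin/thick).  ``truth`` (present for simulated studies) records each
    gene's role and expected LS − NL effect per group.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame | None = None

    def validate(self) -> None:
        if set(self.matrix.columns) != set(self.samples["sample_id"]):
            raise StateError("matrix columns and sample metadata disagree")
        per = self.samples.groupby(["subject_id", "tissue"]).size()
        if (per > 1).any():
            raise StateError("a subject contributes more than one sample per tissue")


def simulate_expression(
    cohort: pd.DataFrame, params: ExpressionSimParams
) -> ExpressionStudy:
    """Simulate one LS and one NL log2 expression sample per subject.

    Signature genes (half up, half down) have E[LS − NL] = ±base_lfc in
    thin subjects and ±amplitude·base_lfc in thick subjects; all other
    genes are null.  A subject random intercept is shared by a subject's
    two samples.
    """
    params.validate()
    if "group" not in cohort.columns:
        cohort = attach_groups(cohort)
    rng = np.random.default_rng(params.seed)

    subjects = cohort["patient_id"].to_numpy()
    groups = cohort["group"].to_numpy()
    n_sub = len(subjects)
    g = params.n_genes
    genes = np.array([f"G{i:05d}" for i in range(1, g + 1)])

    n_up = params.n_signature // 2
    n_dn = params.n_signature - n_up
    role = np.array(["null"] * g, dtype=object)
    role[:n_up] = "up"
    role[n_up : n_up + n_dn] = "down"
    sign = np.where(role == "up", 1.0, np.where(role == "down", -1.0, 0.0))

    baseline = rng.uniform(*params.baseline_range, size=g)
    subj_int = rng.normal(0.0, params.subject_sd, size=(g, n_sub))
    amp = np.where(groups == THICK, params.amplitude, 1.0)
    delta = sign[:, None] * params.base_lfc * amp[None, :]

    nl = baseline[:, None] + subj_int + rng.normal(0, params.noise_sd, (g, n_sub))
    ls = (
        baseline[:, None]
        + subj_int
        + delta
        + rng.normal(0, params.noise_sd, (g, n_sub))
    )

    cols, data = [], []
    meta = []
    for j, (sid, grp) in enumerate(zip(subjects, groups)):
        for tissue, block in (("LS", ls), ("NL", nl)):
            cols.append(f"{sid}_{tissue}")
            data.append(block[:, j])
            meta.append(
                {"sample_id": f"{sid}_{tissue}", "subject_id": sid,
                 "tissue": tissue, "group": grp}
            )
    matrix = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    samples = pd.DataFrame(meta)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "role": role,
            "lfc_thin": sign * params.base_lfc,
            "lfc_thick": sign * params.base_lfc * params.amplitude,
        }
    )
    return ExpressionStudy(matrix=matrix, samples=samples, truth=truth)


# ---------------------------------------------------------------------------
# clinical


@dataclass
class ClinicalSimParams:
    """Parameters of the clinical-table simulation.

    Cell counts (per microscope field) are linear in the relevant tissue's
    epidermal thickness; serum cytokines are log-normal with an additive
    thick − thin shift on the log scale; PASI courses have a baseline near
    the moderate-to-severe range and a treatment-specific fractional
    improvement at week 12.  TNF-α change under treatment is simulated on
    the log scale per treatment × group.
    """

    cell_slopes: dict = field(
        default_factory=lambda: {"CD3": 0.25, "CD11c": 0.35, "BDCA1": 0.15}
    )
    cell_intercept: float = 20.0
    cell_noise_sd: float = 15.0
    cytokine_group_shift: dict = field(
        default_factory=lambda: {"TNFa": 0.4, "IL6": 1.0, "IL8": 1.0}
    )
    cytokine_log_mean: float = 1.0
    cytokine_log_sd: float = 0.7
    n_cohorts: int = 2
    pasi_baseline_mean: float = 21.0
    pasi_baseline_sd: float = 5.0
    pasi_improvement: dict = field(
        default_factory=lambda: {"etanercept": 0.70, "ustekinumab": 0.75}
    )
    pasi_noise_sd: float = 2.0
    tnfa_change: dict = field(
        default_factory=lambda: {
            "etanercept": {"thin": 0.15, "thick": 0.60},
            "ustekinumab": {"thin": -0.50, "thick": -0.50},
        }
    )
    tnfa_change_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.pasi_baseline_mean <= 72):
            raise ParameterError("pasi_baseline_mean: must be in (0, 72]")
        for t, f in self.pasi_improvement.items():
            if not (0.0 <= f <= 1.0):
                raise ParameterError(f"pasi_improvement[{t}]: must be in [0, 1]")
        if self.n_cohorts < 1:
            raise ParameterError("n_cohorts: must be >= 1")


def simulate_clinical(
    cohort: pd.DataFrame, params: ClinicalSimParams
) -> dict[str, pd.DataFrame]:
    """Simulate cell-count, cytokine and treatment-course tables.

    Requires a stratified cohort (``group`` column or hidden truth).
    Returns ``{"cell_counts": ..., "cytokines": ..., "courses": ...}`` in
    long format.  Sub-tables draw from independently spawned RNG streams
    so each is reproducible on its own.
    """
    params.validate()
    if "group" not in cohort.columns:
        cohort = attach_groups(cohort)
    streams = np.random.SeedSequence(params.seed).spawn(3)
    pid = cohort["patient_id"].to_numpy()
    grp = cohort["group"].to_numpy()
    n = len(pid)

    # cell counts: count = intercept + slope * thickness + noise, floored at 0
    rng = np.random.default_rng(streams[0])
    rows = []
    for marker, slope in params.cell_slopes.items():
        for tissue, thick_col in (("LS", "lesional_um"), ("NL", "nonlesional_um")):
            th = cohort[thick_col].to_numpy(float)
            counts = np.maximum(
                params.cell_intercept + slope * th
                + rng.normal(0, params.cell_noise_sd, n),
                0.0,
            )
            rows.append(
                pd.DataFrame(
                    {"patient_id": pid, "marker": marker, "tissue": tissue,
                     "count": counts, "thickness_um": th}
                )
            )
    cell_counts = pd.concat(rows, ignore_index=True)

    # serum cytokines (baseline visit), log-normal with a thick-group shift
    rng = np.random.default_rng(streams[1])
    cohort_id = rng.integers(1, params.n_cohorts + 1, size=n)
    rows = []
    for cyt, shift in params.cytokine_group_shift.items():
        logc = (
            params.cytokine_log_mean
            + np.where(grp == THICK, shift, 0.0)
            + rng.normal(0, params.cytokine_log_sd, n)
        )
        rows.append(
            pd.DataFrame(
                {"patient_id": pid, "cytokine": cyt,
                 "concentration": np.exp(logc),
                 "cohort_id": [f"C{c}" for c in cohort_id], "week": 0}
            )
        )
    cytokines = pd.concat(rows, ignore_index=True)

    # PASI + TNF-α two-visit courses under two treatments
    rng = np.random.default_rng(streams[2])
    treatments = list(params.pasi_improvement)
    treat = np.array([treatments[i % len(treatments)] for i in range(n)])
    base = np.clip(
        rng.normal(params.pasi_baseline_mean, params.pasi_baseline_sd, n), 1.0, 72.0
    )
    improv = np.array([params.pasi_improvement[t] for t in treat])
    wk12 = np.clip(
        base * (1.0 - improv) + rng.normal(0, params.pasi_noise_sd, n), 0.0, 72.0
    )
    log_tnfa0 = params.cytokine_log_mean + rng.normal(0, params.cytokine_log_sd, n)
    d_tnfa = np.array(
        [params.tnfa_change[t][g] for t, g in zip(treat, grp)]
    ) + rng.normal(0, params.tnfa_change_sd, n)
    courses = pd.concat(
        [
            pd.DataFrame(
                {"patient_id": pid, "treatment": treat, "week": 0,
                 "pasi": base, "tnfa": np.exp(log_tnfa0)}
            ),
            pd.DataFrame(
                {"patient_id": pid, "treatment": treat, "week": 12,
                 "pasi": wk12, "tnfa": np.exp(log_tnfa0 + d_tnfa)}
            ),
        ],
        ignore_index=True,
    )
    return {"cell_counts": cell_counts, "cytokines": cytokines, "courses": courses}
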