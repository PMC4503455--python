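"""Clinical comparisons: cell infiltrates, serum cytokines, treatment response.

* Cell counts: one-way ANOVA over the group × tissue cells per marker with
  Tukey's HSD post-hoc test (Tukey–Kramer for unequal cell sizes, via the
  studentized-range distribution).
* Thickness regression: forward stepwise selection of inflammation markers
  predicting epidermal thickness (partial-F entry test), with standardized
  coefficients and classical partial correlations both reported.
* Cytokines: log-concentration ~ group with a random intercept per study
  cohort (statsmodels MixedLM); a single-cohort panel degrades to a pooled
  two-sample t-test with a warning.
* Treatment response: two-visit PASI / cytokine courses are analyzed with
  the same paired random-intercept machinery as expression (week 0/12 in
  the tissue role), giving least-squares means — equal to cell means on a
  balanced grid — percent improvement, and group-difference contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import de
from .errors import DesignError, ParameterError, StateError
from .mixture import THICK, THIN
from .simulate import ExpressionStudy

__all__ = [
    "compare_cell_counts",
    "StepwiseResult",
    "stepwise_thickness_regression",
    "cytokine_group_contrast",
    "pasi_improvement",
    "cytokine_change_contrast",
]


# ---------------------------------------------------------------------------
# cell infiltrates


def compare_cell_counts(
    table: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-marker one-way ANOVA and Tukey HSD across group × tissue cells.

    ``labels`` maps patient_id → thin/thick.  Markers with any cell below
    two observations are skipped and reported.  Returns (anova_table,
    tukey_table, skipped_markers); Tukey adjusted p-values come from the
    studentized-range distribution with Tukey–Kramer handling of unequal
    cell sizes.
    """
    df = table.copy()
    df["group"] = labels.reindex(df["patient_id"]).to_numpy()
    if df["group"].isna().any():
        raise StateError("labels missing for some patients in the count table")
    df["cell"] = df["group"] + ":" + df["tissue"]

    anova_rows, tukey_rows, skipped = [], [], []
    for marker, sub in df.groupby("marker", sort=True):
        cells = {name: g["count"].to_numpy(float) for name, g in sub.groupby("cell")}
        if len(cells) < 2 or min(len(v) for v in cells.values()) < 2:
            warnings.warn(f"marker {marker}: a cell has < 2 observations; skipped",
                          RuntimeWarning, stacklevel=2)
            skipped.append(marker)
            continue
        names = sorted(cells)
        groups = [cells[n] for n in names]
        F, p = stats.f_oneway(*groups)
        anova_rows.append({"marker": marker, "F": float(F), "p": float(p)})

        hsd = stats.tukey_hsd(*groups)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                tukey_rows.append(
                    {
                        "marker": marker,
                        "cell_a": names[i],
                        "cell_b": names[j],
                        "diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                        "p_adj": float(hsd.pvalue[i, j]),
                    }
                )
    return pd.DataFrame(anova_rows), pd.DataFrame(tukey_rows), skipped


# ---------------------------------------------------------------------------
# forward stepwise regression


@dataclass
class StepwiseResult:
    selected: list
    entry_pvalues: list
    std_coefs: pd.Series
    partial_correlations: pd.Series
    dropped_collinear: list = field(default_factory=list)


def _ols_sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def stepwise_thickness_regression(
    wide: pd.DataFrame,
    response: str = "thickness_um",
    entry_alpha: float = 0.05,
    cond_max: float = 1e8,
) -> StepwiseResult:
    """Forward stepwise selection of markers predicting thickness.

    At each step the candidate with the smallest partial-F p-value enters
    if that p-value is below ``entry_alpha``; no removal step.  Candidates
    making the design ill-conditioned (condition number > ``cond_max``)
    are dropped with a warning.  Standardized (beta) coefficients come
    from the final model on z-scored variables; classical partial
    correlations of each selected marker given the others are reported
    alongside.
    """
    candidates = [c for c in wide.columns if c != response]
    if not candidates:
        raise ParameterError("no candidate markers")
    y = wide[response].to_numpy(float)
    n = y.size
    Xall = {c: wide[c].to_numpy(float) for c in candidates}

    selected: list = []
    entry_p: list = []
    dropped: list = []
    while True:
        base = np.column_stack([np.ones(n)] + [Xall[c] for c in selected])
        sse_r = _ols_sse(base, y)
        best = None
        for c in candidates:
            if c in selected or c in dropped:
                continue
            Xf = np.column_stack([base, Xall[c]])
            if np.linalg.cond(Xf) > cond_max:
                warnings.warn(f"candidate {c} collinear with selected set; dropped",
                              RuntimeWarning, stacklevel=2)
                dropped.append(c)
                continue
            sse_f = _ols_sse(Xf, y)
            df2 = n - Xf.shape[1]
            if df2 <= 0:
                continue
            F = max(sse_r - sse_f, 0.0) / (sse_f / df2) if sse_f > 0 else np.inf
            p = float(stats.f.sf(F, 1, df2))
            if best is None or p < best[1]:
                best = (c, p)
        if best is None or best[1] >= entry_alpha:
            break
        selected.append(best[0])
        entry_p.append(best[1])

    if selected:
        Z = np.column_stack(
            [stats.zscore(Xall[c], ddof=1) for c in selected]
        )
        zy = stats.zscore(y, ddof=1)
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(n), Z]), zy, rcond=None
        )
        std_coefs = pd.Series(beta[1:], index=selected)
        pcors = {}
        for c in selected:
            others = [o for o in selected if o != c]
            Xo = np.column_stack([np.ones(n)] + [Xall[o] for o in others])
            ry = y - Xo @ np.linalg.lstsq(Xo, y, rcond=None)[0]
            rx = Xall[c] - Xo @ np.linalg.lstsq(Xo, Xall[c], rcond=None)[0]
            pcors[c] = float(stats.pearsonr(rx, ry)[0])
        partial = pd.Series(pcors)
    else:
        std_coefs = pd.Series(dtype=float)
        partial = pd.Series(dtype=float)
    return StepwiseResult(
        selected=selected,
        entry_pvalues=entry_p,
        std_coefs=std_coefs,
        partial_correlations=partial,
        dropped_collinear=dropped,
    )


# ---------------------------------------------------------------------------
# serum cytokines


def cytokine_group_contrast(
    panel: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Thick-vs-thin contrast of log concentration per cytokine.

    With ≥ 2 study cohorts, fits log(conc) ~ group with a random intercept
    per cohort and reports the Wald test on the group coefficient; a
    single-cohort panel falls back to a pooled two-sample t-test with a
    warning.  Concentrations must be positive (modeled on the log scale).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = panel.copy()
    if (df["concentration"] <= 0).any():
        raise ParameterError("concentrations must be > 0 (log scale model)")
    df["group"] = labels.reindex(df["patient_id"]).to_numpy()
    if df["group"].isna().any():
        raise StateError("labels missing for some patients in the panel")
    df["logc"] = np.log(df["concentration"])

    rows = []
    for cyt, sub in df.groupby("cytokine", sort=True):
        present = set(sub["group"])
        if present != {THIN, THICK}:
            raise StateError(f"cytokine {cyt}: a group is absent ({present})")
        sub = sub.copy()
        sub["is_thick"] = (sub["group"] == THICK).astype(float)
        n_cohorts = sub["cohort_id"].nunique() if "cohort_id" in sub else 1
        fit = None
        if n_cohorts >= 2:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = smf.mixedlm("logc ~ is_thick", sub,
                                        groups=sub["cohort_id"])
                    fit = model.fit(reml=True, method="lbfgs")
                if not np.isfinite(fit.bse["is_thick"]):
                    fit = None
            except (np.linalg.LinAlgError, ValueError):
                fit = None  # singular random-effects fit; use the fixed model
        if fit is not None:
            est = float(fit.params["is_thick"])
            se = float(fit.bse["is_thick"])
            p = float(fit.pvalues["is_thick"])
            method = "mixedlm_cohort_intercept"
        else:
            reason = "single cohort" if n_cohorts < 2 else "singular mixed fit"
            warnings.warn(
                f"cytokine {cyt}: {reason}; two-sample t fallback",
                RuntimeWarning, stacklevel=2,
            )
            a = sub.loc[sub.is_thick == 1, "logc"]
            b = sub.loc[sub.is_thick == 0, "logc"]
            t, p = stats.ttest_ind(a, b, equal_var=True)
            est = float(a.mean() - b.mean())
            sp = np.sqrt(
                ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                / (len(a) + len(b) - 2)
            )
            se = float(sp * np.sqrt(1 / len(a) + 1 / len(b)))
            p = float(p)
            method = "two_sample_t"
        rows.append(
            {"cytokine": cyt, "estimate": est, "se": se, "p": p, "method": method}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# treatment response


def _course_study(sub: pd.DataFrame, value: str, labels: pd.Series | None):
    """Recast a two-visit course table as a paired 'expression' study.

    week 0 plays the NL role and week 12 the LS role, so the existing
    closed-form random-intercept machinery applies; patients missing a
    visit are dropped and counted by the fit.
    """
    sub = sub[sub.week.isin([0, 12])]
    meta, cols, vals = [], [], []
    for (pid, week), g in sub.groupby(["patient_id", "week"]):
        sid = f"{pid}_w{week}"
        meta.append(
            {
                "sample_id": sid,
                "subject_id": pid,
                "tissue": "LS" if week == 12 else "NL",
                "group": (labels.get(pid) if labels is not None else THIN),
            }
        )
        cols.append(sid)
        vals.append(float(g[value].iloc[0]))
    matrix = pd.DataFrame([vals], index=[value], columns=cols)
    samples = pd.DataFrame(meta)
    if samples["group"].isna().any():
        raise StateError("labels missing for some patients in the courses")
    return ExpressionStudy(matrix=matrix, samples=samples)


def pasi_improvement(
    courses: pd.DataFrame, labels: pd.Series | None = None
) -> pd.DataFrame:
    """Percent PASI improvement at week 12 per treatment (× group).

    Improvement = 100 × (LSmean_week0 − LSmean_week12) / LSmean_week0,
    with least-squares means from the random-intercept model (equal to
    cell means for the balanced two-visit design).  With labels, the
    thick-vs-thin difference in week-0 → week-12 change is tested within
    each treatment (the model's week × group interaction).
    """
    rows = []
    for treat, sub in courses.groupby("treatment", sort=True):
        study = _course_study(sub, "pasi", labels)
        fits = de.fit_gene_models(study)
        coef = fits.coef[0]
        if fits.single_group:
            table = de.apply_contrasts(fits)
            nl_mean, change = coef[0], coef[1]  # week0 mean, week12-week0
            rows.append(
                {
                    "treatment": treat,
                    "group": "all",
                    "pasi_week0": nl_mean,
                    "pasi_week12": nl_mean + change,
                    "percent_improvement": 100.0 * (-change) / nl_mean,
                    "group_contrast_p": np.nan,
                }
            )
        else:
            table = de.apply_contrasts(fits)
            inter = table[table.contrast == "interaction"].iloc[0]
            for grp, base, chg in (
                (THIN, coef[0], coef[1]),
                (THICK, coef[0] + coef[2], coef[1] + coef[3]),
            ):
                rows.append(
                    {
                        "treatment": treat,
                        "group": grp,
                        "pasi_week0": base,
                        "pasi_week12": base + chg,
                        "percent_improvement": 100.0 * (-chg) / base,
                        "group_contrast_p": float(inter["p"]),
                    }
                )
    return pd.DataFrame(rows)


def cytokine_change_contrast(
    courses: pd.DataFrame,
    labels: pd.Series,
    cytokine: str = "tnfa",
    log_scale: bool = True,
) -> pd.DataFrame:
    """Group contrast of the week-12 − week-0 cytokine change per treatment.

    The change is modeled on the log scale by default (positive, skewed
    concentrations).  The reported estimate is the thick − thin difference
    in change (the week × group interaction of the paired model).
    """
    df = courses.copy()
    if cytokine not in df.columns:
        raise ParameterError(f"column {cytokine!r} not in courses")
    if log_scale:
        if (df[cytokine] <= 0).any():
            raise ParameterError("cytokine values must be > 0 for the log scale")
        df[cytokine] = np.log(df[cytokine])
    rows = []
    for treat, sub in df.groupby("treatment", sort=True):
        study = _course_study(sub, cytokine, labels)
        fits = de.fit_gene_models(study)
        table = de.apply_contrasts(fits)
        inter = table[table.contrast == "interaction"].iloc[0]
        chg_thin = fits.coef[0][1]
        chg_thick = fits.coef[0][1] + fits.coef[0][3]
        rows.append(
            {
                "treatment": treat,
                "cytokine": cytokine,
                "change_thin": chg_thin,
                "change_thick": chg_thick,
                "estimate": float(inter["estimate"]),
                "se": float(inter["se"]),
                "p": float(inter["p"]),
            }
        )
    return pd.DataFrame(rows)
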