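"""Differential expression for paired lesional/non-lesional designs.

Gene-wise model: log2 expression ~ tissue + group + tissue:group with a
random intercept per subject.  Because every subject contributes exactly
one LS and one NL sample, the model separates into two orthogonal strata —
within-subject differences (LS − NL) and subject means — which yields the
REML variance-component estimates and GLS fixed effects in closed form,
vectorized across genes:

    σ̂²_e  = pooled within-group variance of the differences / 2
    σ̂²_b  = pooled within-group variance of the subject means − σ̂²_e / 2
             (truncated at 0; boundary fits collapse to OLS and are flagged)

Five named contrasts are built in: LS vs NL within each group, thick vs
thin within each tissue, and the tissue×group interaction.  Moderated
statistics shrink the per-gene residual variance toward a common prior by
the standard empirical-Bayes construction (prior df estimated by matching
moments of log s² via digamma/trigamma inversion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .errors import DesignError, ParameterError, StateError
from .mixture import THICK, THIN
from .simulate import ExpressionStudy

__all__ = [
    "CONTRASTS",
    "GeneModelFits",
    "ModerationParams",
    "filter_probes",
    "quantile_normalize",
    "fit_gene_models",
    "apply_contrasts",
    "moderate",
    "bh_adjust",
    "call_degs",
    "overlap_summary",
    "fc_correlation",
    "wpgma_cluster",
]

# coefficient basis: (intercept=NL,thin; tissueLS; groupThick; tissueLS:groupThick)
CONTRASTS: dict[str, np.ndarray] = {
    "LSvsNL_thin": np.array([0.0, 1.0, 0.0, 0.0]),
    "LSvsNL_thick": np.array([0.0, 1.0, 0.0, 1.0]),
    "ThickvsThin_NL": np.array([0.0, 0.0, 1.0, 0.0]),
    "ThickvsThin_LS": np.array([0.0, 0.0, 1.0, 1.0]),
    "interaction": np.array([0.0, 0.0, 0.0, 1.0]),
}


# ---------------------------------------------------------------------------
# preprocessing


def filter_probes(
    matrix: pd.DataFrame, min_expr: float = 3.0, min_sd: float = 0.1
) -> tuple[pd.DataFrame, dict]:
    """Keep genes expressed above ``min_expr`` in ≥1 sample AND with SD > ``min_sd``.

    Returns the filtered matrix and a report of counts removed per rule
    (a gene failing both rules is counted under each).
    """
    vals = matrix.to_numpy(float)
    pass_expr = vals.max(axis=1) > min_expr
    pass_sd = vals.std(axis=1, ddof=1) > min_sd
    keep = pass_expr & pass_sd
    report = {
        "n_input": int(len(matrix)),
        "n_kept": int(keep.sum()),
        "n_removed_expression": int((~pass_expr).sum()),
        "n_removed_sd": int((~pass_sd).sum()),
    }
    out = matrix.loc[keep]
    if out.empty:
        raise StateError("no genes survive probe filtering")
    return out, report


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean empirical distribution.

    Each column's sorted values are replaced by the row-wise mean of all
    columns' sorted values; ties within a column receive the average of
    the reference values at their tied ranks.
    """
    vals = matrix.to_numpy(float)
    if np.isnan(vals).any():
        raise ParameterError("quantile_normalize requires a complete matrix")
    n = vals.shape[0]
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(vals.shape[1]):
        ranks = stats.rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# paired mixed model, closed form


@dataclass
class GeneModelFits:
    """Vectorized per-gene fits of the paired random-intercept model."""

    genes: pd.Index
    coef: np.ndarray           # n_genes × 4, basis as in CONTRASTS
    sigma2_e: np.ndarray       # residual variance per gene
    sigma2_b: np.ndarray       # subject-intercept variance per gene (≥ 0)
    df_resid: int
    n_thin: int
    n_thick: int
    boundary: np.ndarray       # σ²_b truncated at 0
    single_group: bool
    A: np.ndarray              # 4×4: coefficient of σ²_e in Cov(β̂)
    B: np.ndarray              # 4×4: coefficient of σ²_b in Cov(β̂)
    n_dropped_subjects: int = 0


def _paired_arrays(study: ExpressionStudy):
    """Align LS and NL columns per subject; drop incomplete pairs."""
    meta = study.samples
    ls = meta[meta.tissue == "LS"].set_index("subject_id")
    nl = meta[meta.tissue == "NL"].set_index("subject_id")
    common = ls.index.intersection(nl.index)
    dropped = len(set(meta.subject_id)) - len(common)
    if len(common) < 2:
        raise DesignError("need at least 2 subjects with complete LS/NL pairs")
    grp = ls.loc[common, "group"]
    Y_ls = study.matrix[ls.loc[common, "sample_id"]].to_numpy(float)
    Y_nl = study.matrix[nl.loc[common, "sample_id"]].to_numpy(float)
    return Y_ls, Y_nl, grp.to_numpy(), dropped


def fit_gene_models(study: ExpressionStudy) -> GeneModelFits:
    """REML fit of expression ~ tissue * group + (1 | subject), per gene.

    Exact closed form via the difference/mean stratum decomposition of the
    complete-pairs design (see module docstring).  Subjects lacking one
    tissue are dropped and counted.  A study containing a single group is
    fitted as expression ~ tissue + (1 | subject); group-dependent
    contrasts are then unavailable.
    """
    Y_ls, Y_nl, grp, dropped = _paired_arrays(study)
    d = Y_ls - Y_nl                      # genes × subjects
    m = 0.5 * (Y_ls + Y_nl)
    groups = np.unique(grp)
    single_group = len(groups) == 1
    if not single_group and set(groups) != {THIN, THICK}:
        raise DesignError(f"unrecognized group labels: {sorted(groups)}")

    if single_group:
        n = d.shape[1]
        if n < 2:
            raise DesignError("need >= 2 complete pairs")
        df = n - 1
        dbar = d.mean(axis=1)
        ss_d = ((d - dbar[:, None]) ** 2).sum(axis=1)
        mbar = m.mean(axis=1)
        ss_m = ((m - mbar[:, None]) ** 2).sum(axis=1)
        sigma2_e = ss_d / (2.0 * df)
        sigma2_m = ss_m / df
        sigma2_b = np.maximum(sigma2_m - sigma2_e / 2.0, 0.0)
        nlbar = mbar - dbar / 2.0
        coef = np.column_stack(
            [nlbar, dbar, np.zeros_like(dbar), np.zeros_like(dbar)]
        )
        # θ = (nl, d); Cov in θ: A_θ = [[1,-1],[-1,2]]/n, B_θ = diag(1/n, 0)
        A_t = np.array([[1.0, -1.0], [-1.0, 2.0]]) / n
        B_t = np.array([[1.0, 0.0], [0.0, 0.0]]) / n
        L = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0], [0.0, 0.0]])
        A = L @ A_t @ L.T
        B = L @ B_t @ L.T
        return GeneModelFits(
            genes=study.matrix.index,
            coef=coef,
            sigma2_e=sigma2_e,
            sigma2_b=sigma2_b,
            df_resid=df,
            n_thin=int(np.sum(grp == THIN)),
            n_thick=int(np.sum(grp == THICK)),
            boundary=sigma2_m - sigma2_e / 2.0 < 0,
            single_group=True,
            A=A,
            B=B,
            n_dropped_subjects=dropped,
        )

    i1 = grp == THIN
    i2 = grp == THICK
    n1, n2 = int(i1.sum()), int(i2.sum())
    if min(n1, n2) < 2:
        raise DesignError("each group needs >= 2 complete pairs")
    df = n1 + n2 - 2

    d1bar, d2bar = d[:, i1].mean(axis=1), d[:, i2].mean(axis=1)
    m1bar, m2bar = m[:, i1].mean(axis=1), m[:, i2].mean(axis=1)
    ss_d = ((d[:, i1] - d1bar[:, None]) ** 2).sum(axis=1) + (
        (d[:, i2] - d2bar[:, None]) ** 2
    ).sum(axis=1)
    ss_m = ((m[:, i1] - m1bar[:, None]) ** 2).sum(axis=1) + (
        (m[:, i2] - m2bar[:, None]) ** 2
    ).sum(axis=1)
    sigma2_e = ss_d / (2.0 * df)
    sigma2_m = ss_m / df
    sigma2_b = np.maximum(sigma2_m - sigma2_e / 2.0, 0.0)

    nl1 = m1bar - d1bar / 2.0
    nl2 = m2bar - d2bar / 2.0
    coef = np.column_stack([nl1, d1bar, nl2 - nl1, d2bar - d1bar])

    # θ = (nl1, d1, nl2, d2); strata independent between groups.
    def blocks(n):
        return (
            np.array([[1.0, -1.0], [-1.0, 2.0]]) / n,
            np.array([[1.0, 0.0], [0.0, 0.0]]) / n,
        )

    A_t = np.zeros((4, 4))
    B_t = np.zeros((4, 4))
    (A_t[:2, :2], B_t[:2, :2]) = blocks(n1)
    (A_t[2:, 2:], B_t[2:, 2:]) = blocks(n2)
    L = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [-1.0, 0.0, 1.0, 0.0],
            [0.0, -1.0, 0.0, 1.0],
        ]
    )
    A = L @ A_t @ L.T
    B = L @ B_t @ L.T
    return GeneModelFits(
        genes=study.matrix.index,
        coef=coef,
        sigma2_e=sigma2_e,
        sigma2_b=sigma2_b,
        df_resid=df,
        n_thin=n1,
        n_thick=n2,
        boundary=sigma2_m - sigma2_e / 2.0 < 0,
        single_group=False,
        A=A,
        B=B,
        n_dropped_subjects=dropped,
    )


def apply_contrasts(
    fits: GeneModelFits, contrasts: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """Estimate cᵀβ̂ with its standard error and t/p per gene and contrast.

    Returns a long table (gene, contrast, estimate, se, t, df, p) plus the
    variance decomposition columns ``var_e_coef``/``var_b_coef`` used later
    by :func:`moderate`.  A zero contrast yields estimate 0 with the t
    flagged undefined (NaN).
    """
    if contrasts is None:
        contrasts = (
            {"LSvsNL": CONTRASTS["LSvsNL_thin"]} if fits.single_group else CONTRASTS
        )
    frames = []
    for name, c in contrasts.items():
        c = np.asarray(c, float)
        if c.shape != (4,):
            raise ParameterError(
                f"contrast {name!r}: expected length-4 vector, got shape {c.shape}"
            )
        if fits.single_group and (c[2] != 0 or c[3] != 0):
            raise ParameterError(
                f"contrast {name!r} involves group terms but the study has one group"
            )
        est = fits.coef @ c
        a = float(c @ fits.A @ c)
        b = float(c @ fits.B @ c)
        var = a * fits.sigma2_e + b * fits.sigma2_b
        se = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, np.nan)
        if not np.any(c != 0):
            t = np.full_like(est, np.nan)
        p = 2.0 * stats.t.sf(np.abs(t), fits.df_resid)
        frames.append(
            pd.DataFrame(
                {
                    "gene": fits.genes,
                    "contrast": name,
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "df": float(fits.df_resid),
                    "p": p,
                    "var_e_coef": a,
                    "var_b_coef": b,
                    "sigma2_e": fits.sigma2_e,
                    "sigma2_b": fits.sigma2_b,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# empirical-Bayes moderation


@dataclass
class ModerationParams:
    d0: float                 # prior df (inf → complete pooling)
    s0_sq: float              # prior variance
    s2_post: np.ndarray       # shrunken per-gene variances
    df_total: float
    pooled_fallback: bool = False


def _trigamma_inverse(y: float) -> float:
    """Solve ψ'(x) = y for x > 0 (ψ' is strictly decreasing; bisect)."""
    if y <= 0:
        return np.inf
    from scipy.optimize import brentq

    lo, hi = 1e-8, 1e8
    if special.polygamma(1, lo) < y:
        return float(lo)
    if special.polygamma(1, hi) > y:
        return np.inf
    return float(brentq(lambda x: special.polygamma(1, x) - y, lo, hi,
                        xtol=1e-12, rtol=1e-12))


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-inverse-χ² variance prior.

    Matches mean and variance of log s² using digamma/trigamma identities;
    returns (d0, s0²).  When the observed spread of log s² is no larger
    than expected under a common variance, d0 = ∞ (complete pooling).
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 10:
        raise ParameterError("moderation needs >= 10 genes with positive variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        # spread of log s² no larger than χ² sampling noise → one common
        # variance (geometric mean keeps constant inputs fixed exactly)
        return np.inf, float(np.exp(np.mean(z)))
    d0 = 2.0 * _trigamma_inverse(evar)
    if not np.isfinite(d0) or d0 <= 0:
        return np.inf, float(np.exp(np.mean(z)))
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderate(
    table: pd.DataFrame, fits: GeneModelFits
) -> tuple[pd.DataFrame, ModerationParams]:
    """Empirical-Bayes moderated t-statistics for a contrast table.

    Per-gene residual variances are shrunk toward the estimated prior,
    s̃² = (d0·s0² + df·s²)/(d0 + df); each contrast's variance is rebuilt
    with s̃² in place of s² (the subject-variance part is untouched) and
    the t reference df becomes d0 + df.
    """
    try:
        d0, s0_sq = estimate_prior(fits.sigma2_e, fits.df_resid)
        pooled = False
    except ParameterError:
        raise
    except Exception:  # pragma: no cover - numerical fallback
        warnings.warn("prior estimation failed; pooling variances", RuntimeWarning)
        d0, s0_sq, pooled = np.inf, float(np.mean(fits.sigma2_e)), True

    df = fits.df_resid
    if np.isinf(d0):
        s2_post = np.full_like(fits.sigma2_e, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * fits.sigma2_e) / (d0 + df)
        df_total = d0 + df

    post = pd.Series(s2_post, index=fits.genes)
    out = table.copy()
    var = out["var_e_coef"] * post.reindex(out["gene"]).to_numpy() + (
        out["var_b_coef"] * out["sigma2_b"]
    )
    out["se"] = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["t"] = np.where(out["se"] > 0, out["estimate"] / out["se"], np.nan)
    out["df"] = df_total
    if np.isinf(df_total):
        out["p"] = 2.0 * stats.norm.sf(np.abs(out["t"]))
    else:
        out["p"] = 2.0 * stats.t.sf(np.abs(out["t"]), df_total)
    params = ModerationParams(
        d0=d0, s0_sq=s0_sq, s2_post=s2_post, df_total=df_total,
        pooled_fallback=pooled,
    )
    return out, params


# ---------------------------------------------------------------------------
# multiple testing + DEG summaries


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min_{j ≥ i} p_(j)·m/j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ParameterError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def add_fdr(table: pd.DataFrame) -> pd.DataFrame:
    """Append a BH ``q`` column, adjusting across genes within each contrast."""
    out = table.copy()
    out["q"] = np.nan
    for name, idx in out.groupby("contrast").groups.items():
        out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    return out


def signed_fold_change(lfc: np.ndarray) -> np.ndarray:
    """Linear fold change with the signed convention: −2^|lfc| for lfc < 0."""
    lfc = np.asarray(lfc, float)
    return np.sign(lfc) * 2.0 ** np.abs(lfc)


def call_degs(
    table: pd.DataFrame,
    fch: float = 2.0,
    p: float = 0.05,
    fdr: float = 0.05,
    contrasts: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """DEG sets per contrast at |linear FC| > fch AND p < p AND q < fdr.

    Returns per-contrast frames (gene, estimate, direction, p, q); empty
    input yields empty sets.
    """
    if "q" not in table.columns:
        table = add_fdr(table)
    out: dict[str, pd.DataFrame] = {}
    names = contrasts or list(table["contrast"].unique())
    for name in names:
        sub = table[table.contrast == name]
        hit = (
            (2.0 ** sub["estimate"].abs() > fch)
            & (sub["p"] < p)
            & (sub["q"] < fdr)
        )
        sel = sub.loc[hit, ["gene", "estimate", "p", "q"]].copy()
        sel["direction"] = np.where(sel["estimate"] > 0, "up", "down")
        out[name] = sel.reset_index(drop=True)
    return out


def overlap_summary(
    deg_a: pd.DataFrame | set,
    deg_b: pd.DataFrame | set,
    reference: set | None = None,
) -> dict:
    """Venn counts and overlap proportions for two DEG sets.

    The headline ``overlap_pct`` is |A∩B|/|A∪B|; ``overlap_min_pct``
    (|A∩B|/min(|A|,|B|)) is also reported since published overlap figures
    rarely state their denominator.  With a reference list, the fraction
    of reference genes called in both sets is added.
    """
    a = set(deg_a["gene"]) if isinstance(deg_a, pd.DataFrame) else set(deg_a)
    b = set(deg_b["gene"]) if isinstance(deg_b, pd.DataFrame) else set(deg_b)
    inter, union = a & b, a | b
    out = {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(inter),
        "n_union": len(union),
        "n_a_only": len(a - b),
        "n_b_only": len(b - a),
        "overlap_pct": 100.0 * len(inter) / len(union) if union else np.nan,
        "overlap_min_pct": (
            100.0 * len(inter) / min(len(a), len(b)) if a and b else np.nan
        ),
    }
    if reference is not None:
        ref = set(reference)
        out["n_reference"] = len(ref)
        out["reference_in_both_pct"] = (
            100.0 * len(ref & inter) / len(ref) if ref else np.nan
        )
    return out


def fc_correlation(
    table: pd.DataFrame,
    contrast_a: str = "LSvsNL_thin",
    contrast_b: str = "LSvsNL_thick",
    genes=None,
) -> float:
    """Pearson r between two contrasts' log2 fold changes over a gene set."""
    wide = table.pivot(index="gene", columns="contrast", values="estimate")
    if genes is not None:
        wide = wide.loc[wide.index.intersection(pd.Index(list(genes)))]
    if len(wide) < 3:
        raise ParameterError("fc_correlation needs >= 3 genes")
    x = wide[contrast_a].to_numpy(float)
    y = wide[contrast_b].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("zero variance in a fold-change vector")
    return float(stats.pearsonr(x, y)[0])


def wpgma_cluster(matrix: pd.DataFrame | np.ndarray):
    """WPGMA (McQuitty) hierarchical clustering on Euclidean distances.

    d(u∪v, w) = (d(u,w) + d(v,w)) / 2.  Returns the linkage matrix and the
    dendrogram leaf order.
    """
    vals = matrix.to_numpy(float) if isinstance(matrix, pd.DataFrame) else np.asarray(
        matrix, float
    )
    if vals.shape[0] < 2:
        raise ParameterError("clustering needs >= 2 items")
    Z = linkage(vals, method="weighted", metric="euclidean")
    return Z, leaves_list(Z)
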