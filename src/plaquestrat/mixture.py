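"""Univariate Gaussian-mixture stratification of epidermal thickness.

The observable is the per-patient difference between lesional and
non-lesional epidermal thickness (μm).  A k-component Gaussian mixture with
unequal variances is fitted by EM, the number of components is chosen by a
sequential parametric-bootstrap likelihood-ratio test (k vs k+1), and
patients are labelled "thin"/"thick" by the intersection point of the two
weighted component densities.

All fits are deterministic given a seed; components are always stored
sorted by ascending mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import (
    DegenerateDataError,
    ParameterError,
    StateError,
    ThresholdError,
)

__all__ = [
    "MixtureFit",
    "BootstrapLRT",
    "Stratification",
    "exclude_invalid",
    "fit_em",
    "loglik_mixture",
    "bootstrap_lrt",
    "select_k",
    "density_intersection",
    "classify",
    "group_summary",
]

THIN, THICK = "thin", "thick"


@dataclass
class MixtureFit:
    """A fitted k-component univariate Gaussian mixture.

    ``weights``/``means``/``sds`` are length-k arrays sorted by mean;
    ``responsibilities`` is the n × k posterior membership matrix.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    responsibilities: np.ndarray
    loglik_trace: np.ndarray | None = None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n observations from the fitted mixture."""
        comp = rng.choice(self.k, size=n, p=self.weights)
        return rng.normal(self.means[comp], self.sds[comp])

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "weights": [float(w) for w in self.weights],
            "means": [float(m) for m in self.means],
            "sds": [float(s) for s in self.sds],
            "loglik": float(self.loglik),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
        }


@dataclass
class BootstrapLRT:
    """Parametric-bootstrap likelihood-ratio test of k vs k+1 components."""

    k_null: int
    k_alt: int
    lrt_observed: float
    lrt_boot: np.ndarray
    p_value: float
    n_boot: int
    seed: int | None
    n_retried: int = 0
    high_failure_rate: bool = False


@dataclass
class Stratification:
    """Threshold-based thin/thick assignment plus the accepted fit."""

    threshold_um: float
    labels: pd.Series
    fit: MixtureFit | None = None
    tie_rule: str = "ties (diff == threshold) labelled thin"


# ---------------------------------------------------------------------------
# cohort filtering


def exclude_invalid(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop patients whose lesional skin is not thicker than non-lesional.

    Lesional plaques are by definition hyperplastic, so a non-positive
    lesional − non-lesional difference indicates a measurement problem and
    the patient is excluded.  Missing values are excluded as well.

    Returns the retained cohort (with a ``diff_um`` column) and an
    exclusion report with one row per removed patient and the reason.
    """
    required = {"patient_id", "lesional_um", "nonlesional_um"}
    missing_cols = required - set(cohort.columns)
    if missing_cols:
        raise ParameterError(f"cohort missing columns: {sorted(missing_cols)}")

    les = pd.to_numeric(cohort["lesional_um"], errors="coerce")
    nl = pd.to_numeric(cohort["nonlesional_um"], errors="coerce")
    miss = les.isna() | nl.isna()
    nonpos = ~miss & (les <= nl)

    reasons = pd.Series("", index=cohort.index, dtype=object)
    reasons[miss] = "missing"
    reasons[nonpos] = "lesional <= nonlesional"
    removed = cohort.loc[miss | nonpos, ["patient_id"]].copy()
    removed["reason"] = reasons[miss | nonpos]

    kept = cohort.loc[~(miss | nonpos)].copy()
    kept["lesional_um"] = les[kept.index]
    kept["nonlesional_um"] = nl[kept.index]
    kept["diff_um"] = kept["lesional_um"] - kept["nonlesional_um"]
    if kept.empty:
        raise StateError("no valid patients after exclusion filtering")
    return kept.reset_index(drop=True), removed.reset_index(drop=True)


# ---------------------------------------------------------------------------
# EM


def _log_density(x: np.ndarray, w, mu, sd) -> np.ndarray:
    """k × n matrix of log(λ_j N(x_i; μ_j, σ_j))."""
    z = (x[None, :] - mu[:, None]) / sd[:, None]
    return (
        np.log(w)[:, None]
        - 0.5 * np.log(2.0 * np.pi)
        - np.log(sd)[:, None]
        - 0.5 * z * z
    )


def loglik_mixture(x: np.ndarray, weights, means, sds) -> float:
    lp = _log_density(
        np.asarray(x, float),
        np.asarray(weights, float),
        np.asarray(means, float),
        np.asarray(sds, float),
    )
    m = lp.max(axis=0)
    return float(np.sum(m + np.log(np.exp(lp - m).sum(axis=0))))


def _em_single(x, k, mu, sd, w, tol, max_iter, sd_floor):
    """One EM run from a given start; returns params + trace."""
    n = x.size
    trace = np.empty(max_iter)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(max_iter):
        lp = _log_density(x, w, mu, sd)
        m = lp.max(axis=0)
        lse = m + np.log(np.exp(lp - m).sum(axis=0))
        ll = float(lse.sum())
        trace[it] = ll
        gamma = np.exp(lp - lse[None, :])  # k x n
        nk = gamma.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = (gamma @ x) / nk
        var = (gamma * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk
        sd = np.sqrt(np.maximum(var, sd_floor**2))
        if np.isfinite(ll_old) and abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll
    ll_final = loglik_mixture(x, w, mu, sd)
    return w, mu, sd, ll_final, it + 1, converged, trace[: it + 1]


def fit_em(
    x,
    k: int,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    var_floor: float = 1e-3,
    seed: int | np.random.Generator | None = None,
    keep_trace: bool = False,
) -> MixtureFit:
    """Maximum-likelihood fit of a k-component Gaussian mixture by EM.

    The best of ``n_restarts`` runs is returned.  Starting means are the
    evenly spaced sample quantiles; restarts beyond the first add random
    jitter.  Component SDs are floored at ``var_floor * sd(x)`` to block
    the classical unequal-variance likelihood degeneracy.

    Parameters are data-scale μm (or any single unit); convergence is
    declared when the relative log-likelihood change drops below ``tol``.
    """
    x = np.asarray(x, dtype=float).ravel()
    if k < 1:
        raise ParameterError("k must be >= 1")
    if x.size < 2 * k:
        raise ParameterError(f"need at least 2k={2 * k} observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ParameterError("x contains non-finite values")

    sx = float(np.std(x))
    if k == 1:
        # closed-form Gaussian MLE
        mu = np.array([float(np.mean(x))])
        sd = np.array([max(sx, var_floor * max(sx, 1e-12), 1e-12)])
        ll = loglik_mixture(x, [1.0], mu, sd)
        return MixtureFit(
            k=1,
            weights=np.array([1.0]),
            means=mu,
            sds=sd,
            loglik=ll,
            n_iter=0,
            converged=True,
            responsibilities=np.ones((x.size, 1)),
        )

    if sx == 0.0:
        raise DegenerateDataError("all observations identical; cannot fit k > 1")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd_floor = var_floor * sx
    q = np.quantile(x, (np.arange(k) + 0.5) / k)

    best = None
    for r in range(n_restarts):
        mu0 = q.copy()
        if r > 0:
            mu0 = mu0 + rng.normal(0.0, 0.5 * sx, size=k)
        sd0 = np.full(k, sx)
        w0 = np.full(k, 1.0 / k)
        out = _em_single(x, k, mu0, sd0, w0, tol, max_iter, sd_floor)
        if best is None or out[3] > best[3]:
            best = out

    w, mu, sd, ll, n_iter, converged, trace = best
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    lp = _log_density(x, w, mu, sd)
    m = lp.max(axis=0)
    gamma = np.exp(lp - (m + np.log(np.exp(lp - m).sum(axis=0)))[None, :]).T
    return MixtureFit(
        k=k,
        weights=w,
        means=mu,
        sds=sd,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        responsibilities=gamma,
        loglik_trace=trace if keep_trace else None,
    )


# ---------------------------------------------------------------------------
# model selection


def bootstrap_lrt(
    x,
    k_null: int,
    n_boot: int = 1000,
    seed: int | None = None,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 800,
    var_floor: float = 1e-3,
) -> BootstrapLRT:
    """Parametric-bootstrap LRT of k components against k + 1.

    The observed statistic is 2(ℓ_{k+1} − ℓ_k), floored at 0.  Each of the
    ``n_boot`` replicates draws n observations from the fitted null model
    and refits both models; the p-value uses the (1 + #{boot ≥ obs}) /
    (n_boot + 1) convention so it is never exactly 0.
    """
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    em_kw = dict(n_restarts=n_restarts, tol=tol, max_iter=max_iter, var_floor=var_floor)

    fit0 = fit_em(x, k_null, seed=rng, **em_kw)
    fit1 = fit_em(x, k_null + 1, seed=rng, **em_kw)
    lrt_obs = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))

    lrt_boot = np.empty(n_boot)
    n_retried = 0
    for b in range(n_boot):
        xb = fit0.sample(x.size, rng)
        for attempt in range(2):
            b0 = fit_em(xb, k_null, seed=rng, **em_kw)
            b1 = fit_em(xb, k_null + 1, seed=rng, **em_kw)
            if b0.converged and b1.converged:
                break
            n_retried += 1
        lrt_boot[b] = max(0.0, 2.0 * (b1.loglik - b0.loglik))

    high_failure = n_retried > 0.1 * n_boot
    if high_failure:
        warnings.warn(
            f"bootstrap_lrt: {n_retried} EM retries over {n_boot} replicates",
            RuntimeWarning,
            stacklevel=2,
        )
    p = (1.0 + float(np.sum(lrt_boot >= lrt_obs))) / (n_boot + 1.0)
    return BootstrapLRT(
        k_null=k_null,
        k_alt=k_null + 1,
        lrt_observed=lrt_obs,
        lrt_boot=lrt_boot,
        p_value=p,
        n_boot=n_boot,
        seed=seed,
        n_retried=n_retried,
        high_failure_rate=high_failure,
    )


def select_k(
    x,
    alpha: float = 0.05,
    k_max: int = 4,
    n_boot: int = 1000,
    seed: int | None = None,
    n_restarts: int = 10,
    **em_kw,
) -> tuple[MixtureFit, list[BootstrapLRT], bool]:
    """Choose the number of components by sequential bootstrap LRTs.

    Starting at k = 1, tests k vs k + 1 and increments k while the test
    rejects (p ≤ alpha) and k < k_max.  Returns the accepted fit, the full
    test trail, and a flag set when k_max was reached still rejecting.
    """
    if k_max < 1:
        raise ParameterError("k_max must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    ss = np.random.SeedSequence(seed)
    trail: list[BootstrapLRT] = []
    k = 1
    while k < k_max:
        sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        test = bootstrap_lrt(
            x, k_null=k, n_boot=n_boot, seed=sub, n_restarts=max(2, n_restarts // 2),
            **em_kw,
        )
        trail.append(test)
        if test.p_value <= alpha:
            k += 1
        else:
            break
    hit_ceiling = bool(k == k_max and trail and trail[-1].p_value <= alpha)
    if hit_ceiling:
        warnings.warn(
            f"select_k reached k_max={k_max} still rejecting", RuntimeWarning,
            stacklevel=2,
        )
    fit_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
    fit = fit_em(x, k, n_restarts=n_restarts, seed=fit_seed, **em_kw)
    return fit, trail, hit_ceiling


# ---------------------------------------------------------------------------
# threshold + classification


def density_intersection(fit: MixtureFit, rel_tol: float = 1e-8) -> float:
    """Crossing point of the two weighted component densities.

    Solves λ₁N(x; μ₁, σ₁) = λ₂N(x; μ₂, σ₂) for the root strictly between
    the component means.  With unequal σ the log-equation is quadratic in
    x; with equal σ it is linear.  The returned τ is verified by direct
    density evaluation.
    """
    if fit.k != 2:
        raise ParameterError(f"density_intersection requires k=2, got k={fit.k}")
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    if not m1 < m2:
        raise ParameterError("component means must be strictly increasing")

    const = np.log(w1 / w2) + np.log(s2 / s1)
    if np.isclose(s1, s2, rtol=1e-12, atol=0.0):
        s2c = s1 * s1
        # linear: x (m1 - m2)/s² + (m2² - m1²)/(2 s²) + const = 0
        tau = ((m2**2 - m1**2) / (2 * s2c) + const) * s2c / (m2 - m1)
        roots = np.array([tau])
    else:
        a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
        b = m1 / s1**2 - m2 / s2**2
        c = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + const
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ThresholdError(
                "weighted densities do not intersect between the means; "
                "classify by posterior responsibility instead"
            )
        roots = (-b + np.array([-1.0, 1.0]) * np.sqrt(disc)) / (2 * a)

    inside = roots[(roots > m1) & (roots < m2)]
    if inside.size == 0:
        raise ThresholdError(
            "no density intersection in (μ1, μ2) — one component dominates; "
            "classify by posterior responsibility instead"
        )
    tau = float(inside[0])
    d1 = w1 * norm.pdf(tau, m1, s1)
    d2 = w2 * norm.pdf(tau, m2, s2)
    if abs(d1 - d2) > rel_tol * max(d1, d2):
        raise ThresholdError("intersection verification failed")
    return tau


def classify(
    cohort: pd.DataFrame, threshold: float, fit: MixtureFit | None = None
) -> Stratification:
    """Label patients thick iff diff_um > threshold (ties → thin).

    "Thick" is defined strictly above the threshold, so a difference equal
    to τ is labelled thin.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be > 0")
    diff = cohort["diff_um"] if "diff_um" in cohort else (
        cohort["lesional_um"] - cohort["nonlesional_um"]
    )
    labels = pd.Series(
        np.where(diff > threshold, THICK, THIN),
        index=cohort["patient_id"].values if "patient_id" in cohort else cohort.index,
        name="label",
    )
    return Stratification(threshold_um=float(threshold), labels=labels, fit=fit)


def group_summary(strat: Stratification, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-group n, mean and SEM of lesional / non-lesional thickness.

    Mirrors the layout of a clinical cohort-characteristics table: one row
    per group plus a total row.  Groups with n < 2 have undefined moments
    (NaN) and are flagged in the ``degenerate`` column.
    """
    df = cohort.copy()
    if "diff_um" not in df:
        df["diff_um"] = df["lesional_um"] - df["nonlesional_um"]
    key = df["patient_id"] if "patient_id" in df else df.index
    df = df.assign(label=strat.labels.reindex(key).values)

    rows = []
    for name, sub in [(THIN, df[df.label == THIN]), (THICK, df[df.label == THICK]),
                      ("total", df)]:
        n = len(sub)
        row = {"group": name, "n": n, "degenerate": n < 2}
        for col, pretty in [
            ("lesional_um", "lesional"),
            ("nonlesional_um", "nonlesional"),
            ("diff_um", "diff"),
        ]:
            if n == 0:
                row[f"{pretty}_mean"] = np.nan
                row[f"{pretty}_sem"] = np.nan
            else:
                v = sub[col].to_numpy(float)
                row[f"{pretty}_mean"] = float(np.mean(v))
                row[f"{pretty}_sem"] = (
                    float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)
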