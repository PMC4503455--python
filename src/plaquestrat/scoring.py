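"""Per-sample combined z-score gene-set enrichment.

A "transcriptome score" for sample s and gene set G is a weighted sum of
gene-standardized expression values,

    score_s = w · ( Σ_{g ∈ up} z_gs − Σ_{g ∈ down} z_gs ),

with z the per-gene z-score over all samples pooled (population SD) and
w = 1/k by default, k being the number of set genes present in the matrix.
The alternative w = 1/√k convention of the combined z-score literature is
available via ``weight="sqrt"``; the convention used is recorded with the
scores.  Standardization makes scores invariant to per-gene affine
transforms of the input.

Group comparison of scores reuses the paired mixed-model machinery of the
differential-expression module with scores as the response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, StateError
from . import de
from .simulate import ExpressionStudy

__all__ = [
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "zscore_genes",
    "combined_zscore",
    "score_gene_sets",
    "compare_scores",
]


@dataclass
class GeneSet:
    """A (possibly signed) gene set; either direction list may be empty."""

    name: str
    up: list = field(default_factory=list)
    down: list = field(default_factory=list)

    def __post_init__(self):
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ParameterError(
                f"gene set {self.name!r}: genes in both directions: {sorted(overlap)[:5]}"
            )


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file, pairing NAME_UP / NAME_DN rows into signed sets.

    Standard GMT: one set per line, tab-separated name, description, then
    genes.  Rows whose names differ only by an ``_UP``/``_DN`` suffix are
    merged into a single signed set named by the common stem.
    """
    raw: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            raw[parts[0]] = [g for g in parts[2:] if g]
    sets: dict[str, GeneSet] = {}
    for name, genes in raw.items():
        if name.endswith("_UP") or name.endswith("_DN"):
            stem, suffix = name[:-3], name[-2:]
            gs = sets.setdefault(stem, GeneSet(stem))
            (gs.up if suffix == "UP" else gs.down).extend(genes)
        else:
            sets[name] = GeneSet(name, up=list(genes))
    return list(sets.values())


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            if gs.up:
                fh.write("\t".join([f"{gs.name}_UP" if gs.down else gs.name, ""]
                                   + list(gs.up)) + "\n")
            if gs.down:
                fh.write("\t".join([f"{gs.name}_DN", ""] + list(gs.down)) + "\n")


def zscore_genes(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Standardize each gene to mean 0, SD 1 across all samples pooled.

    Uses the population SD (divide by n).  Constant genes cannot be
    standardized and are dropped; their names are returned.
    """
    vals = matrix.to_numpy(float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # population convention
    keep = sd[:, 0] > 0
    dropped = list(matrix.index[~keep])
    z = (vals[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns), dropped


def _weight(k: int, weight: str) -> float:
    if weight in ("k", "1/k"):
        return 1.0 / k
    if weight in ("sqrt", "1/sqrt(k)"):
        return 1.0 / np.sqrt(k)
    raise ParameterError(f"unknown weight convention {weight!r}")


def combined_zscore(
    zmat: pd.DataFrame, gene_set: GeneSet, weight: str = "k"
) -> pd.Series:
    """Per-sample combined z-score of one gene set (see module docstring)."""
    up = zmat.index.intersection(pd.Index(gene_set.up))
    down = zmat.index.intersection(pd.Index(gene_set.down))
    k = len(up) + len(down)
    if k == 0:
        raise ParameterError(
            f"gene set {gene_set.name!r}: no genes present in the matrix"
        )
    w = _weight(k, weight)
    s = zmat.loc[up].sum(axis=0) - zmat.loc[down].sum(axis=0)
    out = w * s
    out.name = gene_set.name
    return out


def score_gene_sets(
    matrix: pd.DataFrame,
    sets: list[GeneSet],
    weight: str = "k",
    split_directions: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every gene set on every sample.

    Returns (scores, info): ``scores`` is samples × sets; ``info`` records
    per set the weight convention and number of genes used.  With
    ``split_directions`` the up- and down-gene sub-scores are emitted as
    additional ``NAME_UP`` / ``NAME_DN`` columns, each with its own local k.
    """
    zmat, dropped = zscore_genes(matrix)
    cols, info = {}, []
    for gs in sets:
        s = combined_zscore(zmat, gs, weight)
        k = len(zmat.index.intersection(pd.Index(gs.up))) + len(
            zmat.index.intersection(pd.Index(gs.down))
        )
        cols[gs.name] = s
        info.append(
            {"set": gs.name, "n_genes_used": k, "weight": weight,
             "n_constant_genes_dropped": len(dropped)}
        )
        if split_directions:
            # sub-scores are reported in the raw orientation: the DN score is
            # the weighted mean z of the down genes, so it is negative where
            # those genes are suppressed (a down-regulation panel)
            for direction, genes in (("UP", gs.up), ("DN", gs.down)):
                present = zmat.index.intersection(pd.Index(genes))
                if len(present) == 0:
                    continue
                sub = GeneSet(f"{gs.name}_{direction}", up=list(present))
                cols[sub.name] = combined_zscore(zmat, sub, weight)
                info.append(
                    {"set": sub.name, "n_genes_used": len(present),
                     "weight": weight, "n_constant_genes_dropped": len(dropped)}
                )
    return pd.DataFrame(cols), pd.DataFrame(info)


def _stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def compare_scores(
    scores: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Thick-vs-thin contrast of each gene-set score within each tissue.

    Scores (samples × sets) are fed through the paired random-intercept
    model used for gene-level expression, and the thick-vs-thin contrasts
    within LS and within NL are reported with significance bands
    (* p<0.1, ** p<0.05, *** p<0.01).
    """
    missing = set(scores.index) - set(samples["sample_id"])
    if missing:
        raise StateError(f"metadata missing for samples: {sorted(missing)[:5]}")
    study = ExpressionStudy(matrix=scores.T, samples=samples)
    fits = de.fit_gene_models(study)
    table = de.apply_contrasts(
        fits,
        {
            "ThickvsThin_LS": de.CONTRASTS["ThickvsThin_LS"],
            "ThickvsThin_NL": de.CONTRASTS["ThickvsThin_NL"],
        },
    )
    out = table[["gene", "contrast", "estimate", "se", "t", "df", "p"]].rename(
        columns={"gene": "set", "contrast": "tissue_contrast"}
    )
    out["tissue"] = out["tissue_contrast"].str.replace("ThickvsThin_", "", regex=False)
    out["stars"] = [_stars(p) for p in out["p"]]
    return out
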