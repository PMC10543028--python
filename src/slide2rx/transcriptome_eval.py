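"""Evaluation of imputed transcriptomes against measured expression.

Per-gene Pearson correlations with two-sided t-distribution p-values,
Holm-Sidak step-down correction ("significantly predicted" = corrected
p < 0.05), subsampled significant-gene counting, hypergeometric hallmark
enrichment, rank-based signature scores, and Cox proportional-hazards
survival association of those scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expr_prep import ExpressionMatrix

__all__ = [
    "GenePredictionReport",
    "per_gene_correlation",
    "holm_sidak",
    "significant_genes",
    "subsample_significant_counts",
    "read_gmt",
    "hallmark_enrichment",
    "signature_score",
    "survival_association",
    "hr_concordance",
]

ALPHA = 0.05


@dataclass
class GenePredictionReport:
    """Per-gene R, raw p, Holm-Sidak adjusted p and significance flags."""

    table: pd.DataFrame  # index gene; columns r, p, p_adj, significant
    alpha: float = ALPHA

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def per_gene_correlation(pred: ExpressionMatrix | pd.DataFrame,
                         actual: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson R and two-sided p per gene across matched samples.

    The p-value is the t-distribution transform of R with n-2 degrees of
    freedom.  Genes with zero variance in either matrix get R = p = NaN and
    are excluded from downstream correction.
    """
    p = pred.values if isinstance(pred, ExpressionMatrix) else pred
    a = actual.values if isinstance(actual, ExpressionMatrix) else actual
    genes = [g for g in p.index if g in set(a.index)]
    samples = [s for s in p.columns if s in set(a.columns)]
    if len(samples) < 4:
        raise ValueError("need at least 4 matched samples")
    x = p.loc[genes, samples].to_numpy(dtype=float)
    y = a.loc[genes, samples].to_numpy(dtype=float)
    n = len(samples)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / (sx * sy)
    r = np.where((sx > 0) & (sy > 0), np.clip(r, -1.0, 1.0), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    pval = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pval = np.where(np.isnan(r), np.nan, np.where(np.abs(r) >= 1.0, 0.0, pval))
    return pd.DataFrame({"r": r, "p": pval}, index=pd.Index(genes, name="gene"))


def holm_sidak(pvals, alpha: float = ALPHA) -> pd.DataFrame:
    """Holm-Sidak step-down adjustment.

    Sorted ascending, adjusted_i = max_{j<=i} 1 - (1 - p_j)^(m - j + 1)
    (1-based j), clipped to 1; rejection while adjusted < alpha.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return pd.DataFrame({"p_adj": [], "reject": []})
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm-sidak")
    return pd.DataFrame({"p_adj": p_adj, "reject": reject})


def significant_genes(pred, actual, alpha: float = ALPHA) -> GenePredictionReport:
    """Correlate, correct and flag: the "significantly predicted" pipeline."""
    corr = per_gene_correlation(pred, actual)
    ok = corr["p"].notna()
    adj = holm_sidak(corr.loc[ok, "p"].to_numpy(), alpha=alpha)
    table = corr.copy()
    table["p_adj"] = np.nan
    table["significant"] = False
    table.loc[ok, "p_adj"] = adj["p_adj"].to_numpy()
    table.loc[ok, "significant"] = adj["reject"].to_numpy()
    return GenePredictionReport(table=table, alpha=alpha)


def subsample_significant_counts(
    pred, actual, subset_size: int = 200, reps: int = 30, seed: int = 0,
    alpha: float = ALPHA,
) -> dict:
    """Significant-gene counts over random sample subsets.

    Draws ``reps`` random subsets of ``subset_size`` samples, runs the
    significance pipeline on each and reports mean and standard error of the
    counts.  Cohorts smaller than ``subset_size`` are rejected.
    """
    p = pred.values if isinstance(pred, ExpressionMatrix) else pred
    a = actual.values if isinstance(actual, ExpressionMatrix) else actual
    samples = [s for s in p.columns if s in set(a.columns)]
    if len(samples) < subset_size:
        raise ValueError(f"cohort has {len(samples)} samples, need >= {subset_size}")
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(reps):
        sub = list(np.array(samples)[rng.choice(len(samples), size=subset_size, replace=False)])
        counts.append(significant_genes(p[sub], a[sub], alpha=alpha).n_significant)
    counts = np.array(counts, dtype=float)
    sem = float(counts.std(ddof=1) / np.sqrt(reps)) if reps > 1 else float("nan")
    return {"counts": counts, "mean": float(counts.mean()), "sem": sem}


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def hallmark_enrichment(
    significant: list[str], gene_sets: dict[str, list[str]], background: list[str],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per gene set.

    Sets are intersected with the background (all genes evaluated by the
    model); p-values are Holm-Sidak corrected across sets.  A set identical
    to the whole background is degenerate (no enrichment possible, p = 1)
    and flagged.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    sig = set(significant) & bg
    rows = []
    for name, genes in gene_sets.items():
        in_bg = set(genes) & bg
        k = len(sig & in_bg)
        p = stats.hypergeom.sf(k - 1, len(bg), len(in_bg), len(sig)) if in_bg else 1.0
        rows.append((name, len(in_bg), k, float(min(p, 1.0)), in_bg == bg))
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p", "degenerate"]).set_index("set")
    adj = holm_sidak(df["p"].to_numpy(), alpha=alpha)
    df["p_adj"] = adj["p_adj"].to_numpy()
    df["enriched"] = adj["reject"].to_numpy()
    return df


def signature_score(expr: ExpressionMatrix | pd.DataFrame, gene_set: list[str],
                    name: str = "signature") -> pd.Series:
    """Mean gene-wise ranked expression across the genes of a signature.

    Per gene, patients are ranked (average ranks on ties) and normalized to
    [0, 1] by (rank - 1) / (n - 1); the score is the mean over the signature
    genes present in the matrix.  Rank-based, hence invariant to monotone
    per-gene transformations.
    """
    v = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if v.shape[1] < 2:
        raise ValueError("need at least 2 patients")
    present = [g for g in gene_set if g in v.index]
    if not present:
        raise ValueError(f"no signature gene present in the matrix: {list(gene_set)}")
    n = v.shape[1]
    ranks = np.apply_along_axis(stats.rankdata, 1, v.loc[present].to_numpy(dtype=float))
    norm = (ranks - 1.0) / (n - 1.0)
    return pd.Series(norm.mean(axis=0), index=v.columns, name=name)


def survival_association(scores: pd.Series, survival: pd.DataFrame) -> dict:
    """Univariate Cox proportional-hazards fit of a signature score.

    ``survival`` has columns ``time`` (days, > 0) and ``event`` (0/1),
    indexed by patient.  Partial-likelihood maximization with Breslow tie
    handling; returns the log hazard ratio of the score with its Wald p.
    """
    from lifelines import CoxPHFitter

    common = [p for p in scores.index if p in survival.index]
    df = pd.DataFrame({
        "score": scores.loc[common].astype(float),
        "time": survival.loc[common, "time"].astype(float),
        "event": survival.loc[common, "event"].astype(int),
    })
    if len(df) < 10:
        raise ValueError("need at least 10 patients")
    if df["event"].sum() < 3:
        raise ValueError("need at least 3 events")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return {
        "log_hr": float(cph.params_["score"]),
        "se": float(cph.standard_errors_["score"]),
        "z": float(cph.params_["score"] / cph.standard_errors_["score"]),
        "p": float(cph.summary.loc["score", "p"]),
        "ties": "breslow",
    }


def hr_concordance(
    actual_scores: dict[str, pd.Series],
    predicted_scores: dict[str, pd.Series],
    survival: dict[str, pd.DataFrame],
) -> float:
    """Pearson correlation of per-cohort log hazard ratios, actual vs
    predicted signature scores (>= 3 cohorts required)."""
    cohorts = sorted(set(actual_scores) & set(predicted_scores) & set(survival))
    if len(cohorts) < 3:
        raise ValueError("need at least 3 cohorts")
    hr_a = [survival_association(actual_scores[c], survival[c])["log_hr"] for c in cohorts]
    hr_p = [survival_association(predicted_scores[c], survival[c])["log_hr"] for c in cohorts]
    return float(stats.pearsonr(hr_a, hr_p)[0])
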