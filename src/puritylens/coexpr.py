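"""Purity confounding in gene-gene co-expression and its removal.

In a bulk admixture, two genes that both track the microenvironment fraction
appear co-expressed even if no regulatory link exists: their raw Spearman
correlation is inflated by roughly the product of their individual
correlations with purity.  Partialling purity out of each pair,

    r_partial = (r_xy - r_xp * r_yp) / sqrt((1 - r_xp**2) * (1 - r_yp**2)),

removes that shared component.  ``confounding_summary`` quantifies the
effect cohort-wide: how many strongly co-expressed pairs (|r| above a
threshold) survive partialling, and how the per-pair correlation decrease
scales with the purity-correlation product (kernel-smoothed slope; in
admixture-dominated cohorts the decrease is ~0.1 per 0.1 of product).

Partial correlations are Spearman-flavoured: expression and purity are rank
transformed first, then the Pearson partial-correlation identity is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoexprParams",
    "CoexpressionReport",
    "log_normalize",
    "correlation_with_purity",
    "coexpression_pairs",
    "partial_correlation",
    "smoothed_slope",
    "confounding_summary",
]

log = logging.getLogger(__name__)


@dataclass
class CoexprParams:
    """Thresholds and sizes of the co-expression confounding analysis."""

    top_n_genes: int = 1000
    pair_threshold: float = 0.5
    gene_threshold: float = 0.3
    bandwidth: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.pair_threshold < 1.0 or not 0.0 < self.gene_threshold < 1.0:
            raise ValueError("thresholds must lie in (0, 1)")
        if self.top_n_genes < 2:
            raise ValueError("top_n_genes must be >= 2")


@dataclass
class CoexpressionReport:
    """Per-pair statistics and cohort-level confounding summary.

    ``pairs`` has one row per retained pair (|r_raw| > pair_threshold) with
    columns gene_i, gene_j, r_raw, r_partial, r_ip, r_jp, product, decrease;
    ``purity_correlation`` is the per-gene Spearman r with purity over the
    analysed gene subset.
    """

    pairs: pd.DataFrame
    purity_correlation: pd.Series
    summary: dict = field(default_factory=dict)


def log_normalize(counts: pd.DataFrame, size_factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(size-factor-normalized counts + 1)."""
    from .de import size_factors as _sf

    sf = _sf(counts) if size_factors is None else size_factors
    return np.log2(counts.div(sf, axis=1) + 1.0)


def correlation_with_purity(expr: pd.DataFrame, purity: pd.Series) -> pd.Series:
    """Per-gene Spearman correlation with purity.

    Uses samples where both expression and purity are non-missing; genes with
    constant expression get NaN with a warning.  Requires >= 3 usable samples.
    """
    common = expr.columns.intersection(purity.dropna().index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 samples with purity, got {len(common)}")
    sub = expr[common]
    p_rank = stats.rankdata(purity[common].to_numpy())
    x = sub.to_numpy(dtype=float)
    ranks = stats.rankdata(x, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xc = ranks - ranks.mean(axis=1, keepdims=True)
        pc = p_rank - p_rank.mean()
        num = xc @ pc
        den = np.sqrt((xc**2).sum(axis=1) * (pc**2).sum())
        r = num / den
    constant = x.std(axis=1) == 0
    if constant.any():
        log.warning("%d constant gene(s) have undefined purity correlation", int(constant.sum()))
        r[constant] = np.nan
    return pd.Series(r, index=expr.index, name="purity_correlation")


def top_variable_genes(expr: pd.DataFrame, top_n: int) -> pd.Index:
    """Gene subset with the largest expression s.d. (ties by gene ID)."""
    sd = expr.std(axis=1, ddof=1)
    # stable sort on sd after lexicographic index sort -> ties broken by gene ID
    order = sd.sort_index().sort_values(ascending=False, kind="mergesort")
    return order.index[: min(top_n, len(order))]


def coexpression_pairs(expr: pd.DataFrame, params: CoexprParams | None = None) -> pd.DataFrame:
    """All-pairs Spearman correlation matrix over the top-s.d. gene subset.

    Degenerate (constant) genes inside the subset are excluded with a
    warning before pairing.  The result is symmetric with unit diagonal.
    """
    params = params or CoexprParams()
    subset = top_variable_genes(expr, params.top_n_genes)
    sub = expr.loc[subset]
    constant = sub.std(axis=1) == 0
    if constant.any():
        log.warning("excluding %d constant gene(s) from pairing", int(constant.sum()))
        sub = sub.loc[~constant]
    if len(sub) < 2:
        raise ValueError("fewer than 2 usable genes in the subset")
    ranks = stats.rankdata(sub.to_numpy(dtype=float), axis=1)
    mat = np.corrcoef(ranks)
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=sub.index, columns=sub.index)


def partial_correlation(r_xy, r_xz, r_yz):
    """First-order partial correlation of x and y controlling z.

    ``(r_xy - r_xz * r_yz) / sqrt((1 - r_xz**2) * (1 - r_yz**2))``, clamped
    to [-1, 1] against floating-point overshoot.  Accepts scalars or arrays.
    """
    r_xy, r_xz, r_yz = (np.asarray(a, dtype=float) for a in (r_xy, r_xz, r_yz))
    if np.any(np.abs(r_xz) >= 1.0) or np.any(np.abs(r_yz) >= 1.0):
        raise ValueError("|r_xz| and |r_yz| must be < 1 (the confounder fully determines a gene)")
    out = (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    out = np.clip(out, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def smoothed_slope(
    x: np.ndarray, y: np.ndarray, bandwidth: float = 0.05, central_fraction: float = 0.8
) -> float:
    """Average derivative of a Nadaraya-Watson regression of y on x.

    A Gaussian-kernel local mean is evaluated on a grid spanning the central
    ``central_fraction`` of the x range (trimming the sparse tails) and the
    slope is the mean finite-difference derivative over that grid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.ptp(x) == 0:
        raise ValueError("need >= 3 points with spread in x to estimate a slope")
    tail = (1.0 - central_fraction) / 2.0
    lo, hi = np.quantile(x, [tail, 1.0 - tail])
    if hi <= lo:
        raise ValueError("degenerate x range after trimming")
    grid = np.linspace(lo, hi, 41)
    w = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bandwidth) ** 2)
    m = (w @ y) / w.sum(axis=1)
    return float(np.mean(np.diff(m) / np.diff(grid)))


def confounding_summary(
    expr: pd.DataFrame,
    purity: pd.Series,
    params: CoexprParams | None = None,
) -> CoexpressionReport:
    """Cohort-wide purity-confounding analysis of co-expression.

    Computes, over the top-s.d. gene subset: per-gene purity correlations,
    all pairwise raw Spearman correlations, purity-partialled correlations
    (rank-transform then Pearson partial identity), and for pairs with
    |r_raw| > pair_threshold the product of purity correlations and the
    decrease r_raw - r_partial.  The summary reports pair counts before and
    after partialling, the fraction of retained pairs where both genes pass
    the gene threshold, and the kernel-smoothed decrease-vs-product slope
    (scaled per 0.1 of product).
    """
    params = params or CoexprParams()
    raw = coexpression_pairs(expr, params)
    genes = raw.index
    # rank-based purity correlation restricted to the paired subset
    r_gp = correlation_with_purity(expr.loc[genes], purity)
    if np.any(np.abs(r_gp.to_numpy()) >= 1.0):
        raise ValueError("a gene is perfectly correlated with purity; partialling undefined")

    r = raw.to_numpy()
    g = r_gp.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        partial = partial_correlation(r, g[:, None] * np.ones_like(r), g[None, :] * np.ones_like(r))

    iu = np.triu_indices(len(genes), k=1)
    r_raw = r[iu]
    r_partial = partial[iu]
    r_ip, r_jp = g[iu[0]], g[iu[1]]

    n_raw = int((np.abs(r_raw) > params.pair_threshold).sum())
    n_partial = int((np.abs(r_partial) > params.pair_threshold).sum())

    keep = np.abs(r_raw) > params.pair_threshold
    pairs = pd.DataFrame(
        {
            "gene_i": genes[iu[0]][keep],
            "gene_j": genes[iu[1]][keep],
            "r_raw": r_raw[keep],
            "r_partial": r_partial[keep],
            "r_ip": r_ip[keep],
            "r_jp": r_jp[keep],
        }
    )
    pairs["product"] = pairs["r_ip"] * pairs["r_jp"]
    pairs["decrease"] = pairs["r_raw"] - pairs["r_partial"]

    both_loaded = (
        (pairs["r_ip"].abs() > params.gene_threshold)
        & (pairs["r_jp"].abs() > params.gene_threshold)
    )
    summary = {
        "n_genes": len(genes),
        "n_pairs_raw": n_raw,
        "n_pairs_partial": n_partial,
        "fraction_pairs_lost": (n_raw - n_partial) / n_raw if n_raw else np.nan,
        "fraction_both_purity_correlated": float(both_loaded.mean()) if len(pairs) else np.nan,
    }
    try:
        slope = smoothed_slope(
            pairs["product"].to_numpy(), pairs["decrease"].to_numpy(), params.bandwidth
        )
        summary["decrease_per_0.1_product"] = 0.1 * slope
    except ValueError:
        summary["decrease_per_0.1_product"] = np.nan
    return CoexpressionReport(pairs=pairs, purity_correlation=r_gp, summary=summary)
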