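"""Purity-adjusted negative-binomial differential expression.

Tumour-vs-normal DE is run twice on the same counts: once with condition as
the only factor ("purity-") and once with the per-sample purity fraction as
an additional covariate ("purity+").  Because bulk tumour samples are
admixtures, genes expressed by the microenvironment masquerade as
differentially expressed in the unadjusted design, while genuinely
tumour-intrinsic effects can be diluted; the covariate absorbs the mixture
term.  Genes are then ranked by P value in each design and classified:
a gene is *newly discovered* if it is significant after adjustment, moved
forward in rank by a factor of at least ``rank_factor`` (default 2) and by
at least ``rank_jump`` positions (default 200); *lost* is the mirror image.

Model per gene g, sample s (log link, size-factor offset, fixed dispersion):

    log mu_gs = log sf_s + b0 + b1 * [condition_s = tumour] (+ b2 * purity_s)

with NB variance ``mu + phi * mu**2``; the condition coefficient is tested
by a Wald z-test and BH-adjusted across genes.  Dispersions come from a
method-of-moments estimator pooled across condition groups with a floor —
deliberately simpler than shrinkage estimators, and documented as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEParams",
    "size_factors",
    "estimate_dispersions",
    "nb_glm_de",
    "bh_adjust",
    "rank_change_classify",
]

log = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


@dataclass
class DEParams:
    """Significance and rank-change thresholds."""

    alpha: float = 0.05
    rank_factor: float = 2.0
    rank_jump: int = 200
    min_count_filter: int = 10
    dispersion_floor: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.rank_factor < 1.0 or self.rank_jump < 0:
            raise ValueError("rank_factor must be >= 1 and rank_jump >= 0")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    For each sample, the factor is the median over reference-usable genes
    (nonzero in every sample) of the ratio of the sample's count to the
    gene's geometric mean; factors are rescaled to geometric mean 1.  When
    no gene is usable the total-count ratio is used as a fallback.
    """
    x = counts.to_numpy(dtype=float)
    usable = (x > 0).all(axis=1)
    if usable.any():
        logx = np.log(x[usable])
        log_gm = logx.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logx - log_gm, axis=0))
    else:
        log.warning("no gene nonzero in all samples; falling back to total-count size factors")
        totals = x.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("a sample has zero total count; size factors undefined")
        sf = totals
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame,
    sf: pd.Series,
    groups: pd.Series | None = None,
    floor: float = 1e-8,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments on normalized counts.

    Within each condition group, ``phi = (s2 - mu) / mu**2`` with the
    df-corrected sample variance; group estimates are averaged and floored.
    All-zero genes get NaN (excluded from testing downstream).
    """
    y = counts.div(sf, axis=1).to_numpy(dtype=float)
    if groups is None:
        groups = pd.Series("all", index=counts.columns)
    ests = []
    for _, members in groups.groupby(groups).groups.items():
        idx = counts.columns.get_indexer(members)
        sub = y[:, idx]
        if sub.shape[1] < 2:
            continue
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ests.append((s2 - mu) / mu**2)
    if not ests:
        raise ValueError("need at least one group with >= 2 samples")
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN genes
        phi = np.nanmean(np.vstack(ests), axis=0)
    phi = np.maximum(phi, floor)
    phi[counts.sum(axis=1).to_numpy() == 0] = np.nan
    return pd.Series(phi, index=counts.index, name="dispersion")


def bh_adjust(p: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN propagated)."""
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr)
    if ok.any():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name="adjusted_p")
    return out


def _rank_by_p(p: np.ndarray, stat: np.ndarray, gene_ids: pd.Index) -> np.ndarray:
    """Ranks (1 = smallest p) with ties by descending |stat| then gene ID."""
    order = pd.DataFrame(
        {"p": p, "negabs": -np.abs(stat)}, index=gene_ids
    ).sort_index().sort_values(["p", "negabs"], kind="mergesort")
    tested = order.index[np.isfinite(order["p"].to_numpy())]
    rank = pd.Series(np.nan, index=gene_ids)
    rank[tested] = np.arange(1, len(tested) + 1, dtype=float)
    return rank.to_numpy()


def nb_glm_de(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    covariate: pd.Series | None = None,
    params: DEParams | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Tumour-vs-normal NB GLM Wald test, optionally purity-adjusted.

    Parameters
    ----------
    counts : genes x samples non-negative integers.
    annotation : sample table with a ``condition`` column holding
        ``tumour`` / ``normal`` labels.
    covariate : optional per-sample purity fraction entered untransformed;
        samples with a missing covariate are dropped (logged).
    dispersions : optional precomputed per-gene dispersions; estimated by
        method of moments when omitted.

    Returns
    -------
    DataFrame indexed by gene with columns ``base_mean``,
    ``log2_fold_change`` (tumour vs normal), ``standard_error`` (of the
    log2 fold change), ``wald_statistic``, ``p_value``, ``adjusted_p`` and
    ``rank`` (1 = smallest p; NaN for untested or non-converged genes).
    """
    params = params or DEParams()
    if "condition" not in annotation.columns:
        raise ValueError("annotation must have a 'condition' column")
    samples = counts.columns.intersection(annotation.index)
    if covariate is not None:
        have = covariate.reindex(samples).notna()
        if not have.all():
            log.warning("dropping %d sample(s) with missing covariate", int((~have).sum()))
        samples = samples[have.to_numpy()]
    cond = annotation.loc[samples, "condition"]
    for level in ("tumour", "normal"):
        if (cond == level).sum() < 2:
            raise ValueError(f"need >= 2 samples in condition {level!r}")

    sub = counts[samples]
    sf = size_factors(sub)
    offset = np.log(sf.to_numpy())
    if dispersions is None:
        dispersions = estimate_dispersions(sub, sf, groups=cond, floor=params.dispersion_floor)

    X = np.column_stack([np.ones(len(samples)), (cond == "tumour").to_numpy(dtype=float)])
    if covariate is not None:
        X = np.column_stack([X, covariate.reindex(samples).to_numpy(dtype=float)])

    keep = sub.sum(axis=1) >= params.min_count_filter
    base_mean = sub.div(sf, axis=1).mean(axis=1)

    n_genes = len(sub)
    beta1 = np.full(n_genes, np.nan)
    se1 = np.full(n_genes, np.nan)
    y_all = sub.to_numpy(dtype=float)
    phi_all = dispersions.reindex(sub.index).to_numpy()
    for i in range(n_genes):
        if not keep.iloc[i] or not np.isfinite(phi_all[i]):
            continue
        fam = sm.families.NegativeBinomial(alpha=max(phi_all[i], params.dispersion_floor))
        try:
            with np.errstate(all="ignore"):
                res = sm.GLM(y_all[i], X, family=fam, offset=offset).fit(maxiter=100, tol=1e-8)
            if not res.converged or not np.all(np.isfinite(res.bse)) or res.bse[1] == 0:
                raise ValueError("non-convergence")
            beta1[i] = res.params[1]
            se1[i] = res.bse[1]
        except Exception:  # noqa: BLE001 - flagged, p stays missing
            log.debug("GLM failed for gene %s", sub.index[i])

    from scipy import stats as sps

    with np.errstate(invalid="ignore", divide="ignore"):
        wald = beta1 / se1
        pvals = 2.0 * sps.norm.sf(np.abs(wald))
    padj = bh_adjust(pvals)
    rank = _rank_by_p(pvals, wald, sub.index)

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fold_change": beta1 / LN2,
            "standard_error": se1 / LN2,
            "wald_statistic": wald,
            "p_value": pvals,
            "adjusted_p": padj,
            "rank": rank,
        },
        index=sub.index,
    )


#: rank-change labels
LABELS = ("newly_discovered", "lost", "stable_up", "stable_down", "not_de")


def rank_change_classify(
    result_without: pd.DataFrame,
    result_with: pd.DataFrame,
    params: DEParams | None = None,
) -> dict:
    """Classify genes by how purity adjustment changed their DE evidence.

    ``newly_discovered``: significant in the adjusted design AND rank moved
    forward by a factor >= ``rank_factor`` AND by >= ``rank_jump`` positions.
    ``lost`` is the mirror image (significant unadjusted, rank worsened by
    the same margins).  Remaining significant-after-adjustment genes are
    ``stable_up`` / ``stable_down`` by fold-change sign; the rest ``not_de``.

    Returns a dict with ``labels`` (per-gene Series) and ``counts`` (one-row
    DataFrame: up/down per design, design-specific counts, and the
    newly-discovered split by direction).
    """
    params = params or DEParams()
    if not result_without.index.equals(result_with.index):
        raise ValueError("the two results must cover the same gene universe")
    rw = result_without
    ra = result_with
    sig_without = rw["adjusted_p"] < params.alpha
    sig_with = ra["adjusted_p"] < params.alpha

    forward = (ra["rank"] <= rw["rank"] / params.rank_factor) & (
        rw["rank"] - ra["rank"] >= params.rank_jump
    )
    backward = (rw["rank"] <= ra["rank"] / params.rank_factor) & (
        ra["rank"] - rw["rank"] >= params.rank_jump
    )
    newly = sig_with & forward.fillna(False)
    lost = sig_without & backward.fillna(False) & ~newly

    labels = pd.Series("not_de", index=rw.index, name="label")
    labels[sig_with & (ra["log2_fold_change"] > 0)] = "stable_up"
    labels[sig_with & (ra["log2_fold_change"] <= 0)] = "stable_down"
    labels[lost] = "lost"
    labels[newly] = "newly_discovered"

    counts = pd.DataFrame(
        {
            "up_unadjusted": [int((sig_without & (rw["log2_fold_change"] > 0)).sum())],
            "down_unadjusted": [int((sig_without & (rw["log2_fold_change"] < 0)).sum())],
            "up_adjusted": [int((sig_with & (ra["log2_fold_change"] > 0)).sum())],
            "down_adjusted": [int((sig_with & (ra["log2_fold_change"] < 0)).sum())],
            "only_unadjusted": [int((sig_without & ~sig_with).sum())],
            "only_adjusted": [int((sig_with & ~sig_without).sum())],
            "rank_change_up": [int((newly & (ra["log2_fold_change"] > 0)).sum())],
            "rank_change_down": [int((newly & (ra["log2_fold_change"] < 0)).sum())],
        }
    )
    return {"labels": labels, "counts": counts}
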