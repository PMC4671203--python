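"""Associations between tumour purity and clinical features, and purity
enrichment of gene signatures.

Categorical features (histological subtype, grade, ...) are tested by
one-way ANOVA of purity across the feature's levels; continuous features by
the Spearman correlation test; two-level features can optionally use
Mann-Whitney.  P values are BH-adjusted across all tested features and
flagged at a 1% false discovery rate.

``gene_set_purity_enrichment`` asks whether a gene signature (e.g. a
molecular-subtyping panel) is enriched for purity-correlated genes: it
compares the fraction of signature genes with |r| above a threshold against
the background, and the full |r| distributions by a two-sample
Kolmogorov-Smirnov test (signature vs complement by default, so the two
samples are independent; vs all scored genes optionally).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = ["purity_feature_association", "gene_set_purity_enrichment"]

log = logging.getLogger(__name__)

FDR_THRESHOLD = 0.01
MIN_LEVEL_SIZE = 2


def _is_categorical(col: pd.Series) -> bool:
    return (
        col.dtype == object
        or isinstance(col.dtype, pd.CategoricalDtype)
        or col.dtype == bool
    )


def purity_feature_association(
    purity: pd.Series,
    features: pd.DataFrame,
    fdr: float = FDR_THRESHOLD,
    two_level_test: str = "anova",
) -> pd.DataFrame:
    """Test purity against each clinical feature.

    Parameters
    ----------
    purity : per-sample purity fractions (NaN allowed).
    features : per-sample feature table; object/categorical/bool columns are
        treated as categorical, numeric columns as continuous.
    fdr : BH false-discovery-rate threshold for the ``significant`` flag.
    two_level_test : ``"anova"`` (default) or ``"mannwhitney"`` for
        categorical features with exactly two usable levels.

    Returns
    -------
    One row per tested feature: ``test``, ``statistic``, ``p_value``,
    ``adjusted_p``, ``significant``, ``n``, and ``group_means`` (a
    ``level=mean`` listing for categorical features).  Features with fewer
    than 2 usable levels or fewer than 3 samples are skipped with a warning.
    """
    if two_level_test not in ("anova", "mannwhitney"):
        raise ValueError("two_level_test must be 'anova' or 'mannwhitney'")
    rows = []
    for name in features.columns:
        col = features[name]
        ok = purity.notna() & col.notna()
        p_use, f_use = purity[ok], col[ok]
        if len(p_use) < 3:
            log.warning("feature %r skipped (<3 usable samples)", name)
            continue
        if _is_categorical(f_use):
            sizes = f_use.value_counts()
            levels = sizes.index[sizes >= MIN_LEVEL_SIZE]
            if len(levels) < 2:
                log.warning("feature %r skipped (<2 usable levels)", name)
                continue
            groups = [p_use[f_use == lv].to_numpy() for lv in levels]
            if len(levels) == 2 and two_level_test == "mannwhitney":
                test = "mannwhitney"
                res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            else:
                test = "anova"
                res = stats.f_oneway(*groups)
            means = "; ".join(f"{lv}={p_use[f_use == lv].mean():.4f}" for lv in sorted(levels))
            rows.append((name, test, float(res.statistic), float(res.pvalue), len(p_use), means))
        else:
            rho, pval = stats.spearmanr(p_use.to_numpy(), f_use.to_numpy(dtype=float))
            rows.append((name, "spearman", float(rho), float(pval), len(p_use), ""))
    if not rows:
        raise ValueError("no testable feature")
    out = pd.DataFrame(
        rows, columns=["feature", "test", "statistic", "p_value", "n", "group_means"]
    ).set_index("feature")
    out["adjusted_p"] = bh_adjust(out["p_value"])
    out["significant"] = out["adjusted_p"] < fdr
    return out[["test", "statistic", "p_value", "adjusted_p", "significant", "n", "group_means"]]


def gene_set_purity_enrichment(
    purity_correlations: pd.Series,
    gene_set: Iterable[str],
    gene_threshold: float = 0.3,
    background: str = "complement",
) -> dict:
    """Is a gene signature enriched for purity-correlated genes?

    Parameters
    ----------
    purity_correlations : per-gene Spearman correlation with purity.
    gene_set : signature gene IDs (must overlap the scored genes).
    gene_threshold : |r| cut-off for calling a gene purity-correlated.
    background : ``"complement"`` (default; KS of set vs non-set genes,
        independent samples) or ``"all"`` (set vs all scored genes).

    Returns
    -------
    dict with ``set_fraction`` and ``background_fraction`` of genes with
    |r| > threshold, the KS ``statistic`` and ``p_value``, and sizes.
    """
    if background not in ("complement", "all"):
        raise ValueError("background must be 'complement' or 'all'")
    scored = purity_correlations.dropna()
    set_ids = pd.Index(list(gene_set)).unique()
    if len(set_ids) == 0:
        raise ValueError("gene_set is empty")
    in_set = scored.index.intersection(set_ids)
    if len(in_set) == 0:
        raise ValueError("gene_set does not overlap the scored genes")
    rest = scored.index.difference(in_set)

    abs_r = scored.abs()
    set_frac = float((abs_r[in_set] > gene_threshold).mean())
    bg_frac = float((abs_r > gene_threshold).mean())

    if background == "complement":
        if len(rest) == 0:
            raise ValueError("gene_set covers every scored gene; complement is empty")
        other = abs_r[rest].to_numpy()
    else:
        other = abs_r.to_numpy()
    ks = stats.ks_2samp(abs_r[in_set].to_numpy(), other, alternative="two-sided")
    return {
        "set_fraction": set_frac,
        "background_fraction": bg_frac,
        "ks_statistic": float(ks.statistic),
        "ks_p_value": float(ks.pvalue),
        "n_set": int(len(in_set)),
        "n_background": int(len(other)),
    }
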