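"""Tumour purity estimation from DNA methylation and multi-method consensus.

Two estimators:

* **LUMP** (leukocytes unmethylation for purity).  CpG sites that are
  consistently unmethylated in leukocytes but methylated in cancer cells act
  as a linear dipstick for the non-immune fraction of a bulk sample: the mean
  beta value over those sites, divided by 0.85 (the mean methylation of the
  sites in pure tumour), estimates purity.
* **CPE** (consensus purity estimation).  Purity calls from several methods
  (e.g. ABSOLUTE, ESTIMATE, LUMP, IHC) are each rescaled to a common mean and
  s.d. and the per-sample median of the rescaled calls is taken, requiring at
  least two available methods per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "InformativeSiteSet",
    "CpeParams",
    "select_informative_sites",
    "lump",
    "cpe",
]

log = logging.getLogger(__name__)

LUMP_DIVISOR = 0.85
LEUKOCYTE_THRESHOLD = 0.05
TUMOUR_THRESHOLD = 0.30


@dataclass
class InformativeSiteSet:
    """CpG probes unmethylated in leukocytes and methylated in tumours."""

    probe_ids: list[str]
    leukocyte_threshold: float = LEUKOCYTE_THRESHOLD
    tumour_threshold: float = TUMOUR_THRESHOLD
    per_site_tumour_mean: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        if not 0.0 < self.leukocyte_threshold < 1.0 or not 0.0 < self.tumour_threshold < 1.0:
            raise ValueError("thresholds must lie in (0, 1)")

    def __len__(self) -> int:
        return len(self.probe_ids)


@dataclass
class CpeParams:
    """Consensus estimator parameters.

    ``target_mean``/``target_sd`` are the common scale every method is mapped
    onto; the defaults are the published cohort-wide combined statistics
    (75.3 +- 18.9%).  With ``recompute_targets`` the targets are instead the
    mean/s.d. of all pooled non-missing values in the supplied table.
    """

    target_mean: float = 0.753
    target_sd: float = 0.189
    min_methods: int = 2
    clamp: bool = True
    recompute_targets: bool = False

    def __post_init__(self) -> None:
        if self.target_sd <= 0:
            raise ValueError("target_sd must be positive")
        if self.min_methods < 1:
            raise ValueError("min_methods must be >= 1")


def select_informative_sites(
    leukocyte_betas: pd.DataFrame,
    tumour_betas_by_type: Mapping[str, pd.DataFrame],
    leukocyte_threshold: float = LEUKOCYTE_THRESHOLD,
    tumour_threshold: float = TUMOUR_THRESHOLD,
) -> InformativeSiteSet:
    """Select probes unmethylated in every leukocyte reference sample and
    methylated on average in every cancer type.

    A probe is kept iff its beta is below ``leukocyte_threshold`` in EVERY
    leukocyte reference sample (missing values ignored) AND its mean beta
    exceeds ``tumour_threshold`` in EVERY cancer-type panel.

    Parameters
    ----------
    leukocyte_betas : probes x samples reference panel of sorted leukocytes.
    tumour_betas_by_type : mapping cancer type -> probes x samples panel.

    Returns
    -------
    InformativeSiteSet with ``per_site_tumour_mean`` the grand mean beta of
    each selected probe over all tumour samples pooled.
    """
    if not 0.0 < leukocyte_threshold < 1.0 or not 0.0 < tumour_threshold < 1.0:
        raise ValueError("thresholds must lie in (0, 1)")
    if not tumour_betas_by_type:
        raise ValueError("at least one tumour reference panel is required")

    probes = leukocyte_betas.index
    for panel in tumour_betas_by_type.values():
        probes = probes.intersection(panel.index)
    if len(probes) == 0:
        raise ValueError("reference panels share no probes")

    leuk = leukocyte_betas.loc[probes]
    leuk_ok = (leuk < leukocyte_threshold).where(leuk.notna(), True).all(axis=1)

    tum_ok = pd.Series(True, index=probes)
    for panel in tumour_betas_by_type.values():
        tum_ok &= panel.loc[probes].mean(axis=1, skipna=True) > tumour_threshold

    selected = probes[leuk_ok & tum_ok]
    if len(selected) == 0:
        raise ValueError(
            "no probe passes both criteria "
            f"({int(leuk_ok.sum())} pass the leukocyte criterion, "
            f"{int(tum_ok.sum())} pass the tumour criterion)"
        )

    pooled = pd.concat(
        [panel.loc[selected] for panel in tumour_betas_by_type.values()], axis=1
    )
    return InformativeSiteSet(
        probe_ids=list(selected),
        leukocyte_threshold=leukocyte_threshold,
        tumour_threshold=tumour_threshold,
        per_site_tumour_mean=pooled.mean(axis=1, skipna=True),
    )


def lump(
    betas: pd.DataFrame,
    sites: InformativeSiteSet | list[str],
    divisor: float = LUMP_DIVISOR,
    min_sites: int = 10,
) -> pd.Series:
    """LUMP purity: mean beta over informative sites divided by ``divisor``.

    The estimate is floored at 0 and capped at 1 (purity is a proportion and
    the fixed divisor can push the raw ratio above 1).  Samples with fewer
    than ``min_sites`` non-missing informative probes get NaN.
    """
    probe_ids = sites.probe_ids if isinstance(sites, InformativeSiteSet) else list(sites)
    present = betas.index.intersection(probe_ids)
    if len(present) == 0:
        raise ValueError("none of the informative probes is present in the beta matrix")
    sub = betas.loc[present]
    n_obs = sub.notna().sum(axis=0)
    est = (sub.mean(axis=0, skipna=True) / divisor).clip(0.0, 1.0)
    est[n_obs < min_sites] = np.nan
    return est.rename("LUMP")


def cpe(purity: pd.DataFrame, params: CpeParams | None = None) -> pd.Series:
    """Consensus purity: per-sample median of rescaled per-method estimates.

    Each method column (data mean ``mu_m``, s.d. ``sigma_m``) is mapped by
    ``x -> (x - mu_m) / sigma_m * target_sd + target_mean`` so all methods
    share a common location and spread; the consensus is the median over the
    methods available for a sample, reported only when at least
    ``min_methods`` methods are available, and clamped to [0, 1].

    Zero-variance method columns are dropped with a warning.
    """
    params = params or CpeParams()
    usable = {}
    for method in purity.columns:
        col = purity[method]
        vals = col.dropna()
        if len(vals) < 2 or vals.std(ddof=1) == 0.0:
            log.warning("method %r dropped from CPE (fewer than 2 values or zero variance)", method)
            continue
        usable[method] = col
    if not usable:
        raise ValueError("no method column with at least 2 distinct non-missing values")

    table = pd.DataFrame(usable)
    if params.recompute_targets:
        pooled = table.to_numpy().ravel()
        pooled = pooled[~np.isnan(pooled)]
        target_mean, target_sd = float(pooled.mean()), float(pooled.std(ddof=1))
    else:
        target_mean, target_sd = params.target_mean, params.target_sd

    z = (table - table.mean()) / table.std(ddof=1) * target_sd + target_mean
    consensus = z.median(axis=1, skipna=True)
    consensus[table.notna().sum(axis=1) < params.min_methods] = np.nan
    if params.clamp:
        consensus = consensus.clip(0.0, 1.0)
    return consensus.rename("CPE")
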