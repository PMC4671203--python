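"""Reading and writing the pipeline's TSV formats.

All matrices are tab-separated with a header row of sample IDs and row IDs
in the first column.  ``read_matrix`` validates by kind: counts must be
non-negative integers; betas and purity must lie in [0, 1] (missing values
allowed); feature tables may tag column types in the header as
``name:categorical`` / ``name:continuous`` (untagged columns are inferred
from dtype).  Validation errors name the offending row and column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .purity import InformativeSiteSet
from .simulate import SyntheticCohort, config_to_dict

__all__ = ["read_matrix", "write_matrix", "read_sites", "write_sites", "write_cohort"]

KINDS = ("counts", "betas", "purity", "features")


def _name_cell(df: pd.DataFrame, mask: pd.DataFrame) -> str:
    rows = mask.any(axis=1)
    row = mask.index[rows][0]
    col = mask.columns[mask.loc[row]][0]
    return f"row {row!r}, column {col!r} (value {df.loc[row, col]!r})"


def read_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a TSV matrix of the given kind."""
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row ID {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate column ID {dup!r}")

    if kind == "counts":
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() | (numeric < 0) | (numeric != numeric.round())
        if bad.to_numpy().any():
            raise ValueError(f"{path}: non-negative integer expected at {_name_cell(df, bad)}")
        return numeric.astype(np.int64)
    if kind in ("betas", "purity"):
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = ((numeric < 0) | (numeric > 1)) & numeric.notna()
        bad |= numeric.isna() & df.notna() & (df != "NA")
        if bad.to_numpy().any():
            raise ValueError(f"{path}: value in [0, 1] expected at {_name_cell(df, bad)}")
        return numeric.astype(float)
    # features: honour header type tags
    out = {}
    for col in df.columns:
        name, _, tag = col.partition(":")
        series = df[col]
        if tag == "continuous":
            series = pd.to_numeric(series)
        elif tag == "categorical":
            series = series.astype(object)
        elif tag:
            raise ValueError(f"{path}: unknown type tag {tag!r} in column {col!r}")
        out[name] = series
    return pd.DataFrame(out, index=df.index)


def write_matrix(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """Write a matrix as TSV (row IDs in the first column)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=float_format, na_rep="NA")


def write_sites(sites: InformativeSiteSet, path: str | Path) -> None:
    """One probe per line; thresholds recorded in a comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(f"# leukocyte_threshold={sites.leukocyte_threshold}\n")
        fh.write(f"# tumour_threshold={sites.tumour_threshold}\n")
        for probe in sites.probe_ids:
            mean = sites.per_site_tumour_mean.get(probe, np.nan)
            fh.write(f"{probe}\t{mean:.6g}\n")


def read_sites(path: str | Path) -> InformativeSiteSet:
    """Read an informative-site file written by :func:`write_sites`."""
    thresholds = {"leukocyte_threshold": 0.05, "tumour_threshold": 0.30}
    probes, means = [], {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            if key in thresholds:
                thresholds[key] = float(val)
            continue
        parts = line.split("\t")
        probes.append(parts[0])
        if len(parts) > 1:
            means[parts[0]] = float(parts[1])
    return InformativeSiteSet(
        probe_ids=probes,
        leukocyte_threshold=thresholds["leukocyte_threshold"],
        tumour_threshold=thresholds["tumour_threshold"],
        per_site_tumour_mean=pd.Series(means, dtype=float),
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, str]:
    """Write a synthetic cohort as TSV files plus the echoed config.

    Files: counts.tsv (genes x samples), betas.tsv (sites x samples),
    purity.tsv (samples x methods), samples.tsv (condition, true purity,
    clinical features), truth.tsv (per-gene DE label and profiles), and
    config.txt (key-value echo of the generating configuration).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.counts, out / "counts.tsv")
    write_matrix(cohort.betas, out / "betas.tsv")
    write_matrix(cohort.purity_table, out / "purity.tsv")
    samples = cohort.annotation().join(cohort.clinical_features)
    write_matrix(samples, out / "samples.tsv")
    truth = pd.DataFrame(
        {
            "de_truth": cohort.de_truth,
            "tumour_profile": cohort.tumour_profile,
            "environment_profile": cohort.environment_profile,
        }
    )
    write_matrix(truth, out / "truth.tsv")
    with (out / "config.txt").open("w") as fh:
        for key, value in config_to_dict(cohort.config).items():
            fh.write(f"{key}={value}\n")
    return {name: str(out / f"{name}.tsv") for name in ("counts", "betas", "purity", "samples", "truth")}
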