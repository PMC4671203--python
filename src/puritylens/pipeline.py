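"""End-to-end driver: simulate -> LUMP -> CPE -> co-expression -> DE -> associations.

The pipeline mirrors the study design: estimate purity per sample from
methylation (LUMP), fuse it with surrogate method calls into a consensus
(CPE), then use the consensus to deconfound co-expression, adjust
differential expression, and test clinical features.  All stage randomness
derives from the single configured seed via named substreams, so every
stage is reproducible in isolation.  A JSON manifest records the
configuration, package version, per-stage outputs and row counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clinical import purity_feature_association
from .coexpr import CoexprParams, confounding_summary, log_normalize
from .de import DEParams, nb_glm_de, rank_change_classify
from .io import read_matrix, write_cohort, write_matrix
from .purity import CpeParams, cpe, lump
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["AnalysisParams", "PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """All analysis constants in one place (see module docstrings for each)."""

    lump_divisor: float = 0.85
    leukocyte_threshold: float = 0.05
    tumour_threshold: float = 0.30
    cpe_target_mean: float = 0.753
    cpe_target_sd: float = 0.189
    cpe_min_methods: int = 2
    coexpr_top_n: int = 1000
    pair_threshold: float = 0.5
    gene_threshold: float = 0.3
    de_alpha: float = 0.05
    rank_factor: float = 2.0
    rank_jump: int = 200
    clinical_fdr: float = 0.01


@dataclass
class PipelineConfig:
    """Paths, analysis constants and the master seed of one run."""

    out_dir: str = "puritylens_run"
    simulate: bool = True
    counts_path: str | None = None
    betas_path: str | None = None
    purity_path: str | None = None
    samples_path: str | None = None
    seed: int = 0
    params: AnalysisParams = field(default_factory=AnalysisParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML / key-value file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    params = AnalysisParams(**raw.pop("params", {}))
    sim = SimulationConfig(**raw.pop("simulation", {}))
    return PipelineConfig(params=params, simulation=sim, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all artifacts plus a run manifest.

    Returns the manifest dict.  Any stage failure raises with a message
    naming the stage; files written before the failure are listed in a
    partial manifest saved alongside.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "params": dataclasses.asdict(config.params),
        "stages": {},
        "files": [],
    }

    def record(stage: str, files: dict[str, str], counts: dict[str, int]) -> None:
        manifest["stages"][stage] = {"files": files, "counts": counts}
        manifest["files"].extend(files.values())

    def fail(stage: str, err: Exception):
        manifest["incomplete_at"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    p = config.params

    # --- inputs -----------------------------------------------------------
    try:
        if config.simulate:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            cohort = simulate_cohort(sim_cfg)
            files = write_cohort(cohort, out / "cohort")
            counts_df, betas, surrogate = cohort.counts, cohort.betas, cohort.purity_table
            annotation = cohort.annotation()
            features = cohort.clinical_features
            record(
                "simulate",
                files,
                {
                    "genes": len(counts_df),
                    "sites": len(betas),
                    "samples": counts_df.shape[1],
                },
            )
        else:
            if not (config.counts_path and config.betas_path and config.samples_path):
                raise ValueError("counts_path, betas_path and samples_path are required")
            counts_df = read_matrix(config.counts_path, "counts")
            betas = read_matrix(config.betas_path, "betas")
            surrogate = (
                read_matrix(config.purity_path, "purity")
                if config.purity_path
                else pd.DataFrame(index=counts_df.columns)
            )
            samples = pd.read_csv(config.samples_path, sep="\t", index_col=0)
            annotation = samples[["condition"]]
            features = samples.drop(columns=["condition"], errors="ignore")
            record("load", {}, {"genes": len(counts_df), "samples": counts_df.shape[1]})
    except Exception as err:  # noqa: BLE001
        fail("inputs", err)

    # --- purity: LUMP then CPE -------------------------------------------
    try:
        lump_est = lump(betas, list(betas.index), divisor=p.lump_divisor)
        table = surrogate.copy()
        table["LUMP"] = lump_est
        consensus = cpe(
            table,
            CpeParams(
                target_mean=p.cpe_target_mean,
                target_sd=p.cpe_target_sd,
                min_methods=p.cpe_min_methods,
            ),
        )
        purity_out = table.assign(CPE=consensus)
        write_matrix(purity_out, out / "purity_estimates.tsv")
        record(
            "purity",
            {"purity_estimates": str(out / "purity_estimates.tsv")},
            {"samples": len(consensus), "cpe_available": int(consensus.notna().sum())},
        )
    except Exception as err:  # noqa: BLE001
        fail("purity", err)

    # --- co-expression confounding (tumour samples) -----------------------
    try:
        tumour = annotation.index[annotation["condition"] == "tumour"]
        expr = log_normalize(counts_df[tumour])
        report = confounding_summary(
            expr,
            consensus[tumour],
            CoexprParams(
                top_n_genes=min(p.coexpr_top_n, len(expr)),
                pair_threshold=p.pair_threshold,
                gene_threshold=p.gene_threshold,
            ),
        )
        write_matrix(report.pairs, out / "coexpression_pairs.tsv")
        summary_df = pd.DataFrame([report.summary])
        write_matrix(summary_df, out / "coexpression_summary.tsv")
        record(
            "coexpression",
            {
                "pairs": str(out / "coexpression_pairs.tsv"),
                "summary": str(out / "coexpression_summary.tsv"),
            },
            {"pairs_retained": len(report.pairs), "pairs_raw": report.summary["n_pairs_raw"]},
        )
    except Exception as err:  # noqa: BLE001
        fail("coexpression", err)

    # --- differential expression -----------------------------------------
    try:
        de_params = DEParams(alpha=p.de_alpha, rank_factor=p.rank_factor, rank_jump=p.rank_jump)
        covariate = consensus.fillna(lump_est)
        res_without = nb_glm_de(counts_df, annotation, covariate=None, params=de_params)
        res_with = nb_glm_de(counts_df, annotation, covariate=covariate, params=de_params)
        changes = rank_change_classify(res_without, res_with, de_params)
        write_matrix(res_without, out / "de_unadjusted.tsv")
        write_matrix(res_with, out / "de_purity_adjusted.tsv")
        write_matrix(changes["labels"].to_frame(), out / "de_rank_change.tsv")
        write_matrix(changes["counts"], out / "de_summary.tsv")
        record(
            "differential_expression",
            {
                "unadjusted": str(out / "de_unadjusted.tsv"),
                "adjusted": str(out / "de_purity_adjusted.tsv"),
                "rank_change": str(out / "de_rank_change.tsv"),
                "summary": str(out / "de_summary.tsv"),
            },
            {
                "genes_tested": int(res_with["p_value"].notna().sum()),
                "newly_discovered": int((changes["labels"] == "newly_discovered").sum()),
            },
        )
    except Exception as err:  # noqa: BLE001
        fail("differential_expression", err)

    # --- clinical associations (tumour samples) ---------------------------
    try:
        assoc = purity_feature_association(
            consensus[tumour], features.loc[tumour], fdr=p.clinical_fdr
        )
        write_matrix(assoc, out / "clinical_associations.tsv")
        record(
            "clinical_association",
            {"associations": str(out / "clinical_associations.tsv")},
            {"features_tested": len(assoc), "significant": int(assoc["significant"].sum())},
        )
    except Exception as err:  # noqa: BLE001
        fail("clinical_association", err)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["files"].append(str(manifest_path))
    return manifest
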