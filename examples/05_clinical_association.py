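"""Test purity against clinical features and score a signature for purity.

Categorical features use one-way ANOVA of purity across levels, continuous
features the Spearman test, all BH-adjusted at a 1% FDR. A gene signature
is 'purity-enriched' when its genes' purity correlations are shifted
relative to the rest of the transcriptome (two-sample KS test).
"""

from puritylens import (
    SimulationConfig,
    correlation_with_purity,
    gene_set_purity_enrichment,
    log_normalize,
    purity_feature_association,
    simulate_cohort,
)

cohort = simulate_cohort(SimulationConfig(seed=5, n_tumour=150))
tumour = cohort.condition[cohort.condition == "tumour"].index

assoc = purity_feature_association(
    cohort.true_purity[tumour], cohort.clinical_features.loc[tumour], fdr=0.01
)
print("purity vs clinical features (subtype is coupled by construction,")
print("batch and age are negative controls):")
print(assoc[["test", "statistic", "p_value", "adjusted_p", "significant"]].round(4).to_string())

expr = log_normalize(cohort.counts[tumour])
scores = correlation_with_purity(expr, cohort.true_purity[tumour])
env_signature = cohort.de_truth.index[cohort.de_truth == "environment_driven"]
res = gene_set_purity_enrichment(scores, env_signature, gene_threshold=0.3)
print(f"\nmicroenvironment signature: {res['set_fraction']:.1%} of genes "
      f"purity-correlated (|r| > 0.3) vs {res['background_fraction']:.1%} background; "
      f"KS p = {res['ks_p_value']:.2e}")
# A significant KS here warns that a subtyping signature built from these
# genes would classify samples partly by their purity, not their biology.
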