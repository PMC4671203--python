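"""Show how purity inflates co-expression and remove it by partial correlation.

Two genes that both track the microenvironment fraction look co-expressed
even without any regulatory link; partialling purity out of every pair
removes the shared component. The decrease in correlation grows by ~0.1 for
every 0.1 of the product of the two genes' purity correlations.
"""

from puritylens import (
    CoexprParams,
    SimulationConfig,
    confounding_summary,
    log_normalize,
    simulate_cohort,
)

cohort = simulate_cohort(SimulationConfig(seed=3, n_tumour=200, n_normal=0, n_genes=1000))
expr = log_normalize(cohort.counts)

report = confounding_summary(
    expr, cohort.true_purity, CoexprParams(top_n_genes=1000, pair_threshold=0.5)
)
s = report.summary
print(f"strongly co-expressed pairs (|r| > 0.5): {s['n_pairs_raw']}")
print(f"surviving after partialling purity:     {s['n_pairs_partial']} "
      f"({s['fraction_pairs_lost']:.1%} lost)")
print(f"pairs where both genes correlate with purity (|r| > 0.3): "
      f"{s['fraction_both_purity_correlated']:.1%}")
print(f"correlation decrease per 0.1 of purity-correlation product: "
      f"{s['decrease_per_0.1_product']:.3f}")
# In this cohort, essentially all strong co-expression is admixture-driven,
# so nearly every pair dissolves once purity is controlled; the ~0.1-per-0.1
# slope says the inflation equals the product of the purity loadings.
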