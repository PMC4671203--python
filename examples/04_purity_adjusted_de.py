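"""Differential expression with and without the purity covariate.

In a cohort where tumour samples are impure and tumour-intrinsic genes are
absent from the microenvironment, the admixture dilutes the true effects
and environment genes flood the unadjusted ranking. Adding purity as a GLM
covariate recovers the masked genes; the rank-change rule (significant
after adjustment, rank improved by a factor >= 2 and by >= 200 positions)
labels them 'newly discovered'.
"""

from puritylens import (
    DEParams,
    lump,
    masked_cohort_config,
    nb_glm_de,
    rank_change_classify,
    simulate_cohort,
)

cohort = simulate_cohort(masked_cohort_config(seed=4))
purity = lump(cohort.betas, list(cohort.betas.index))
params = DEParams()

unadjusted = nb_glm_de(cohort.counts, cohort.annotation(), params=params)
adjusted = nb_glm_de(cohort.counts, cohort.annotation(), covariate=purity, params=params)

intrinsic = cohort.de_truth.index[cohort.de_truth.str.startswith("tumour_intrinsic")]
r0 = (unadjusted.loc[intrinsic, "adjusted_p"] < params.alpha).mean()
r1 = (adjusted.loc[intrinsic, "adjusted_p"] < params.alpha).mean()
print(f"recall of true tumour-intrinsic genes: {r0:.2f} unadjusted -> {r1:.2f} adjusted")

changes = rank_change_classify(unadjusted, adjusted, params)
print("\nrank-change summary (Table-style counts):")
print(changes["counts"].T.rename(columns={0: "genes"}).to_string())
newly = changes["labels"] == "newly_discovered"
true_pos = cohort.de_truth[newly[newly].index].str.startswith("tumour_intrinsic")
print(f"\nnewly discovered genes: {newly.sum()}, of which {true_pos.mean():.0%} "
      "are genuinely tumour-intrinsic")
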