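"""Purity-adjusted NB differential expression: normalization, dispersion,
the Wald GLM, BH adjustment and rank-change classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from puritylens import (
    DEParams,
    SimulationConfig,
    bh_adjust,
    estimate_dispersions,
    nb_glm_de,
    rank_change_classify,
    simulate_cohort,
    size_factors,
)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 10, 3], "s2": [5, 10, 3]})
        np.testing.assert_allclose(size_factors(counts).to_numpy(), 1.0)

    def test_doubled_column_gets_double_factor(self):
        base = pd.DataFrame({"s1": [5, 10, 3], "s2": [5, 10, 3]})
        base["s3"] = 2 * base["s1"]
        sf = size_factors(base)
        assert sf["s3"] / sf["s1"] == pytest.approx(2.0)

    def test_toy_matrix_matches_hand_computed_median_of_ratios(self):
        # every sample is c * (1, 2, 4) per gene -> ratios 0.5, 1, 2 and the
        # geometric-mean rescaling leaves them unchanged
        counts = pd.DataFrame(
            {"s1": [100, 10, 50, 5], "s2": [200, 20, 100, 10], "s3": [400, 40, 200, 20]},
            index=["g1", "g2", "g3", "g4"],
        )
        np.testing.assert_allclose(size_factors(counts).to_numpy(), [0.5, 1.0, 2.0])

    def test_fallback_to_total_counts_when_no_reference_gene(self):
        counts = pd.DataFrame({"s1": [10, 0], "s2": [0, 30]}, index=["g1", "g2"])
        sf = size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(3.0)


class TestDispersions:
    def test_poisson_gene_hits_the_floor(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, size=(1, 400)), index=["g1"])
        sf = pd.Series(1.0, index=counts.columns)
        phi = estimate_dispersions(counts, sf, floor=1e-8)
        assert phi["g1"] <= 0.01

    def test_known_truth_recovered_within_band(self):
        rng = np.random.default_rng(1)
        mu, true_phi, n = 100.0, 0.5, 200
        lam = rng.gamma(1 / true_phi, true_phi * mu, size=(300, n))
        counts = pd.DataFrame(rng.poisson(lam))
        sf = pd.Series(1.0, index=counts.columns)
        phi = estimate_dispersions(counts, sf)
        assert 0.4 <= phi.median() <= 0.6

    def test_all_zero_gene_excluded(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [0, 8]}, index=["g0", "g1"])
        phi = estimate_dispersions(counts, pd.Series(1.0, index=counts.columns))
        assert np.isnan(phi["g0"]) and np.isfinite(phi["g1"])


class TestBhAdjust:
    def test_hand_computed_step_up_values(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust(np.array([1.0, 1.0, 1.0])), 1.0)
        np.testing.assert_allclose(bh_adjust(np.array([0.037])), [0.037])

    def test_nan_propagated(self):
        out = bh_adjust(pd.Series([0.01, np.nan, 0.5]))
        assert np.isnan(out.iloc[1]) and np.isfinite(out.iloc[0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_p_and_monotone(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def nb_negloglik(beta, y, X, offset, phi):
    mu = np.exp(offset + X @ beta)
    return -np.sum(y * np.log(mu) - (y + 1.0 / phi) * np.log1p(phi * mu))


class TestNbGlm:
    def _cohort(self, seed=0, **kw):
        cfg = SimulationConfig(seed=seed, n_genes=60, n_tumour=30, n_normal=30, **kw)
        return simulate_cohort(cfg)

    def test_coefficients_match_direct_likelihood_maximization(self):
        """The fitted condition coefficient agrees with independent direct
        maximization of the NB log-likelihood on 20-sample instances."""
        c = simulate_cohort(SimulationConfig(seed=13, n_genes=15, n_tumour=10, n_normal=10))
        params = DEParams(min_count_filter=10)
        sf = size_factors(c.counts)
        phi = estimate_dispersions(c.counts, sf, groups=c.condition, floor=params.dispersion_floor)
        res = nb_glm_de(c.counts, c.annotation(), covariate=c.true_purity, params=params,
                        dispersions=phi)
        offset = np.log(sf.to_numpy())
        X = np.column_stack(
            [
                np.ones(20),
                (c.condition == "tumour").to_numpy(float),
                c.true_purity.to_numpy(),
            ]
        )
        checked = 0
        for g in c.counts.index:
            b1 = res.loc[g, "log2_fold_change"] * np.log(2.0)
            if not np.isfinite(b1):
                continue
            y = c.counts.loc[g].to_numpy(float)
            ph = max(phi[g], 1e-8)

            def score(beta, y=y, ph=ph):
                mu = np.exp(offset + X @ beta)
                return -X.T @ ((y - mu) / (1.0 + ph * mu))

            opt = optimize.minimize(
                lambda b, y=y, ph=ph: nb_negloglik(b, y, X, offset, ph),
                np.zeros(3),
                jac=score,
                method="BFGS",
                options={"gtol": 1e-12, "maxiter": 1000},
            )
            assert b1 == pytest.approx(opt.x[1], abs=1e-4)
            checked += 1
        assert checked >= 10

    def test_known_fold_change_recovered(self):
        """Pure two-group design (no admixture): median log2 fold change of
        the up-regulated genes is ~1 for a true fold change of 2."""
        cfg = SimulationConfig(
            seed=21,
            n_genes=200,
            n_tumour=50,
            n_normal=50,
            frac_tumour_intrinsic_de=0.2,
            intrinsic_up_fraction=0.5,
            intrinsic_env_ratio=1.0,  # E=T: expression independent of purity
            env_log_ratio_sd=0.0,
            frac_environment_driven=0.0,
            log2fc_magnitude=1.0,
            purity_alpha=1e6,
            purity_beta=1e-2,  # purity ~ 1: no mixture dilution
            normal_purity_alpha=1e6,
            normal_purity_beta=1e-2,
        )
        c = simulate_cohort(cfg)
        res = nb_glm_de(c.counts, c.annotation())
        up = c.de_truth[c.de_truth == "tumour_intrinsic_up"].index
        down = c.de_truth[c.de_truth == "tumour_intrinsic_down"].index
        assert res.loc[up, "log2_fold_change"].median() == pytest.approx(1.0, abs=0.1)
        assert res.loc[down, "log2_fold_change"].median() == pytest.approx(-1.0, abs=0.1)

    def test_environment_gene_absorbed_by_purity_covariate(self):
        """A gene expressed by the microenvironment is strongly DE without
        the covariate and has |lfc| near zero with it."""
        cfg = SimulationConfig(
            seed=30,
            n_genes=80,
            n_tumour=40,
            n_normal=40,
            frac_tumour_intrinsic_de=0.0,
            frac_environment_driven=0.2,
            env_log_ratio_sd=0.0,
            purity_alpha=4.0,
            purity_beta=4.0,  # tumour purity ~0.5 vs normal ~0.85
        )
        c = simulate_cohort(cfg)
        without = nb_glm_de(c.counts, c.annotation())
        within = nb_glm_de(c.counts, c.annotation(), covariate=c.true_purity)
        env = c.de_truth[c.de_truth == "environment_driven"].index
        assert (without.loc[env, "adjusted_p"] < 0.05).mean() > 0.8
        assert (
            within.loc[env, "log2_fold_change"].abs().median()
            < without.loc[env, "log2_fold_change"].abs().median() / 2
        )

    def test_independent_covariate_leaves_type_i_error_stable(self):
        """Adding purity when it is independent of condition moves the raw
        type-I error by < 2 percentage points."""
        cfg = SimulationConfig(
            seed=17,
            n_genes=1000,
            n_tumour=30,
            n_normal=30,
            frac_tumour_intrinsic_de=0.0,
            frac_environment_driven=0.0,
            env_log_ratio_sd=0.0,
            normal_purity_alpha=SimulationConfig().purity_alpha,
            normal_purity_beta=SimulationConfig().purity_beta,
        )
        c = simulate_cohort(cfg)
        without = nb_glm_de(c.counts, c.annotation())
        within = nb_glm_de(c.counts, c.annotation(), covariate=c.true_purity)
        f0 = (without["p_value"].dropna() < 0.05).mean()
        f1 = (within["p_value"].dropna() < 0.05).mean()
        assert abs(f0 - f1) < 0.02

    def test_missing_covariate_samples_dropped(self):
        c = self._cohort(seed=2)
        cov = c.true_purity.copy()
        cov.iloc[:3] = np.nan
        res = nb_glm_de(c.counts, c.annotation(), covariate=cov)
        assert res["p_value"].notna().sum() > 0

    def test_single_condition_rejected(self):
        c = self._cohort(seed=3)
        ann = c.annotation()
        ann["condition"] = "tumour"
        with pytest.raises(ValueError, match="normal"):
            nb_glm_de(c.counts, ann)


def _result_frame(ranks, padj, lfc):
    ids = [f"g{i}" for i in range(len(ranks))]
    return pd.DataFrame(
        {
            "rank": ranks,
            "adjusted_p": padj,
            "log2_fold_change": lfc,
            "p_value": padj,
        },
        index=ids,
    )


class TestRankChangeClassify:
    def test_rule_examples(self):
        # gene 0: 1000 -> 400 significant: newly discovered (factor 2.5, jump 600)
        # gene 1: 100 -> 80: fails both rank rules
        # gene 2: 1000 -> 400 but adjusted p 0.2: fails significance
        without = _result_frame([1000, 100, 1000], [0.5, 0.01, 0.5], [1.0, 1.0, 1.0])
        with_ = _result_frame([400, 80, 400], [0.01, 0.01, 0.2], [1.0, 1.0, 1.0])
        out = rank_change_classify(without, with_, DEParams())
        labels = out["labels"]
        assert labels["g0"] == "newly_discovered"
        assert labels["g1"] == "stable_up"
        assert labels["g2"] == "not_de"
        assert out["counts"]["rank_change_up"].iloc[0] == 1

    def test_lost_is_the_mirror_image(self):
        without = _result_frame([50, 10], [0.001, 0.001], [-1.0, 1.0])
        with_ = _result_frame([700, 10], [0.9, 0.001], [-1.0, 1.0])
        labels = rank_change_classify(without, with_, DEParams())["labels"]
        assert labels["g0"] == "lost"
        assert labels["g1"] == "stable_up"

    def test_counts_consistent_with_labels(self):
        rng = np.random.default_rng(11)
        n = 500
        ranks0 = rng.permutation(n) + 1.0
        ranks1 = rng.permutation(n) + 1.0
        padj0 = rng.uniform(0, 0.2, n)
        padj1 = rng.uniform(0, 0.2, n)
        lfc = rng.normal(size=n)
        without = _result_frame(ranks0, padj0, lfc)
        with_ = _result_frame(ranks1, padj1, lfc)
        out = rank_change_classify(without, with_, DEParams(alpha=0.05, rank_jump=100))
        labels, counts = out["labels"], out["counts"].iloc[0]
        newly = labels == "newly_discovered"
        assert counts["rank_change_up"] + counts["rank_change_down"] == int(newly.sum())
        assert set(labels.unique()) <= {
            "newly_discovered",
            "lost",
            "stable_up",
            "stable_down",
            "not_de",
        }

    def test_mismatched_universe_rejected(self):
        a = _result_frame([1, 2], [0.1, 0.1], [0.0, 0.0])
        b = a.iloc[:1]
        with pytest.raises(ValueError, match="universe"):
            rank_change_classify(a, b)
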