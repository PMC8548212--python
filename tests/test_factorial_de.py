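"""Factorial ANOVA, FDR, effect-size gates, curation, PCA, pattern clusters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from fusionsplice.factorial_de import (
    DEConfig,
    call_differential,
    cluster_patterns,
    curate_probes,
    default_contrasts,
    fit_factorial_anova,
    pca_on_significant,
    posthoc_pairwise,
    quantile_normalize,
    validate_design,
)
from fusionsplice.synthetic_data import ExpressionSpec, simulate_expression


def _bh_oracle(p):
    """Hand-rolled Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


@pytest.fixture(scope="module")
def null_fit():
    spec = ExpressionSpec(n_null=2000, probes_per_cluster=0, patterns={})
    mat, design, _ = simulate_expression(spec, seed=11)
    return fit_factorial_anova(mat, design), mat, design


class TestDesignValidation:
    def test_default_simulated_design_is_valid(self):
        _, design, _ = simulate_expression(seed=0)
        validate_design(design)
        assert len(design) == 16
        assert (design.groupby("genotype").size() == 8).all()

    def test_missing_cell_rejected(self):
        _, design, _ = simulate_expression(seed=0)
        broken = design[design["sample"] != "M-WT-Cb-1"]
        with pytest.raises(ValueError):
            validate_design(broken)

    def test_config_bounds(self):
        with pytest.raises(ValueError):
            DEConfig(fdr_alpha=0)
        with pytest.raises(ValueError):
            DEConfig(snr_lfc=-1)


class TestOmnibus:
    def test_matches_scipy_f_oneway_per_probe(self, null_fit):
        fit, mat, design = null_fit
        groups = design.groupby(["sex", "genotype", "organ"])["sample"].apply(list)
        sub = mat.iloc[:50]
        expected = stats.f_oneway(
            *[sub[cols].to_numpy().T for cols in groups], axis=0
        ).pvalue
        assert np.allclose(fit["p_omnibus"].iloc[:50], expected, atol=1e-12)

    def test_constant_probe_flagged_with_zero_lfc(self):
        _, design, _ = simulate_expression(seed=0)
        mat = pd.DataFrame(
            np.full((3, 16), 7.0), index=list("abc"), columns=design["sample"]
        )
        fit = fit_factorial_anova(mat, design)
        assert fit["flag_zero_variance"].all()
        assert fit["p_omnibus"].isna().all()
        lfc_cols = [c for c in fit.columns if c.startswith("lfc_")]
        assert (fit[lfc_cols] == 0).all().all()

    def test_type_one_error_near_nominal_under_null(self, null_fit):
        fit, _, _ = null_fit
        rate = (fit["p_omnibus"] < 0.05).mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / len(fit))
        assert abs(rate - 0.05) < half

    def test_bh_matches_step_up_oracle(self, null_fit):
        fit, _, _ = null_fit
        assert np.allclose(fit["q"], _bh_oracle(fit["p_omnibus"]), atol=1e-12)
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(2, 400)))
            from statsmodels.stats.multitest import multipletests

            assert np.allclose(multipletests(p, method="fdr_bh")[1], _bh_oracle(p),
                               atol=1e-12)

    def test_power_for_one_group_shift_at_n4(self):
        # 1.0 log2-unit shift in one cell, sigma 0.25, four replicates/cell
        spec = ExpressionSpec(
            replicates=4, n_null=1800, probes_per_cluster=200,
            patterns={"shift": {"F-KO-Cb": 1.0}},
        )
        mat, design, truth = simulate_expression(spec, seed=12)
        fit = fit_factorial_anova(mat, design)
        planted = (truth["cluster"] == "shift").to_numpy()
        assert (fit["q"][planted] < 0.05).mean() > 0.9

    def test_planted_lfc_estimates_unbiased(self):
        spec = ExpressionSpec(
            replicates=4, n_null=0, probes_per_cluster=200,
            patterns={"shift": {"F-KO-Cb": 1.0}},
        )
        mat, design, truth = simulate_expression(spec, seed=21)
        fit = fit_factorial_anova(mat, design)
        # planted offset of +1 in one of 8 cells => +0.875 versus grand mean;
        # the estimator's bias (mean deviation over 200 probes) is ~0
        bias = (fit["lfc_F-KO-Cb"] - 0.875).mean()
        assert abs(bias) < 0.02


class TestGates:
    def _frame(self, q, lfc_grand, lfc_pair, p_post):
        anova = pd.DataFrame({"q": [q], "p_omnibus": [q], "lfc_g": [lfc_grand]},
                             index=["p1"])
        post = pd.DataFrame(
            {"probe": ["p1"], "contrast": ["F-Cb"], "lfc": [lfc_pair],
             "p_posthoc": [p_post]}
        )
        return call_differential(anova, post).iloc[0]

    def test_small_effect_fails_snr_gate_despite_significance(self):
        row = self._frame(q=0.01, lfc_grand=0.20, lfc_pair=0.20, p_post=0.001)
        assert not row["multivariate_significant"]

    def test_all_gates_pass(self):
        row = self._frame(q=0.01, lfc_grand=0.30, lfc_pair=0.30, p_post=0.001)
        assert row["multivariate_significant"]
        assert row["pairwise_differential"]
        assert row["robust"]

    def test_nonsignificant_fdr_blocks_everything(self):
        row = self._frame(q=0.2, lfc_grand=3.0, lfc_pair=3.0, p_post=1e-6)
        assert not row[["multivariate_significant", "pairwise_differential",
                        "robust"]].any()

    def test_practical_but_not_robust(self):
        row = self._frame(q=0.01, lfc_grand=0.30, lfc_pair=0.15, p_post=0.01)
        assert row["pairwise_differential"] and not row["robust"]

    def test_flags_recomputable_and_idempotent(self):
        spec = ExpressionSpec()
        mat, design, _ = simulate_expression(spec, seed=6)
        anova = fit_factorial_anova(mat, design)
        post = posthoc_pairwise(mat, design)
        once = call_differential(anova, post)
        again = call_differential(anova, once[post.columns])
        assert once.equals(again)

    def test_robust_implies_pairwise_differential(self):
        mat, design, _ = simulate_expression(ExpressionSpec(), seed=6)
        calls = call_differential(
            fit_factorial_anova(mat, design), posthoc_pairwise(mat, design)
        )
        assert (~calls["robust"] | calls["pairwise_differential"]).all()


class TestCuration:
    def test_multi_gene_probe_removed(self):
        ann = pd.DataFrame(
            {"probe": ["a", "b"], "genes": ["G1;G2", "G3"], "riken": [False, False]}
        )
        kept, removed = curate_probes(["a", "b"], ann)
        assert kept == ["b"] and removed["multi_gene"] == 1

    def test_all_single_gene_unchanged(self):
        ann = pd.DataFrame(
            {"probe": list("ab"), "genes": ["G1", "G2"], "riken": [False, False]}
        )
        kept, removed = curate_probes(["a", "b"], ann)
        assert kept == ["a", "b"] and sum(removed.values()) == 0

    def test_planted_category_tallies_match_construction(self):
        from fusionsplice.synthetic_data import simulate_annotation

        probes = [f"p{i}" for i in range(500)]
        ann = simulate_annotation(probes, seed=9)
        kept, removed = curate_probes(probes, ann)
        expected = ann["category"].value_counts()
        assert removed["multi_gene"] == expected.get("multi_gene", 0)
        assert removed["riken"] == expected.get("riken", 0)
        assert removed["no_gene"] == expected.get("no_gene", 0)
        assert len(kept) == expected.get("single", 0)

    def test_unannotated_probe_counts_as_no_gene(self):
        ann = pd.DataFrame({"probe": ["a"], "genes": ["G1"], "riken": [False]})
        kept, removed = curate_probes(["a", "mystery"], ann)
        assert kept == ["a"] and removed["no_gene"] == 1


class TestPCA:
    def test_planted_organ_then_sex_structure(self):
        # organ shift much larger than sex shift: PC1 separates organ, PC2 sex
        patterns = {
            "organ": {f"{s}-{g}-Cb": 4.0 for s in "MF" for g in ("WT", "KO")},
            "sex": {f"F-{g}-{o}": 1.0 for g in ("WT", "KO") for o in ("Cb", "Br")},
        }
        spec = ExpressionSpec(n_null=100, probes_per_cluster=100, patterns=patterns)
        mat, design, _ = simulate_expression(spec, seed=4)
        summary = pca_on_significant(mat)
        scores = summary.scores.join(design.set_index("sample"))
        for pc, factor in (("PC1", "organ"), ("PC2", "sex")):
            means = scores.groupby(factor)[pc].mean()
            spread = scores.groupby(factor)[pc].std().max()
            assert abs(means.iloc[0] - means.iloc[1]) > 2 * spread
        assert summary.variance_pct[0] > summary.variance_pct[1]

    def test_variance_percentages_monotone_and_bounded(self):
        mat, design, _ = simulate_expression(ExpressionSpec(), seed=1)
        summary = pca_on_significant(mat)
        v = summary.variance_pct
        assert (np.diff(v) <= 1e-9).all() and v.sum() <= 100 + 1e-9

    def test_duplicate_samples_drop_zero_variance_component(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(30, 3))
        mat = pd.DataFrame(
            np.column_stack([base, base[:, 2]]), columns=["s1", "s2", "s3", "s3b"]
        )
        summary = pca_on_significant(mat)
        assert summary.flag_rank_deficient
        assert len(summary.variance_pct) < 3

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            pca_on_significant(pd.DataFrame(np.ones((1, 5))))


class TestClustering:
    @staticmethod
    def _planted_profiles(seed=13):
        mat, design, truth = simulate_expression(ExpressionSpec(), seed=seed)
        fit = fit_factorial_anova(mat, design)
        lfc = fit[[c for c in fit.columns if c.startswith("lfc_")]]
        planted = (truth["cluster"] != "null").to_numpy()
        return lfc[planted], truth.loc[planted, "cluster"]

    def test_four_planted_patterns_recovered(self):
        lfc, truth = self._planted_profiles()
        labels, summary = cluster_patterns(lfc, k=4)
        assert adjusted_rand_score(truth, labels) > 0.9
        assert summary["n_probes"].sum() == len(lfc)

    def test_single_cluster_k1(self):
        lfc, _ = self._planted_profiles()
        labels, summary = cluster_patterns(lfc.iloc[:10], k=1)
        assert set(labels) == {1} and summary.loc[1, "n_probes"] == 10

    def test_permutation_invariance(self):
        lfc, _ = self._planted_profiles()
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(lfc))
        a, _ = cluster_patterns(lfc, k=4)
        b, _ = cluster_patterns(lfc.iloc[perm], k=4)
        # same partition up to label names
        assert adjusted_rand_score(a, b.loc[a.index]) == 1.0

    def test_k_exceeding_probes_rejected(self):
        lfc, _ = self._planted_profiles()
        with pytest.raises(ValueError):
            cluster_patterns(lfc.iloc[:3], k=5)

    def test_cluster_summaries_bound_member_lfc(self):
        lfc, _ = self._planted_profiles()
        labels, summary = cluster_patterns(lfc, k=4)
        for c, row in summary.iterrows():
            vals = lfc.loc[labels[labels == c].index].to_numpy()
            assert row["lfc_min"] == pytest.approx(vals.min())
            assert row["lfc_max"] == pytest.approx(vals.max())


class TestWelchPosthoc:
    def test_matches_scipy_per_contrast(self):
        mat, design, _ = simulate_expression(ExpressionSpec(n_null=50), seed=2)
        post = posthoc_pairwise(mat, design)
        label, ga, gb = default_contrasts()[0]
        sub = post[post["contrast"] == label].set_index("probe")
        cols_a = design[design["sample"].str.startswith(ga)]["sample"]
        cols_b = design[design["sample"].str.startswith(gb)]["sample"]
        probe = mat.index[0]
        t = stats.ttest_ind(mat.loc[probe, cols_a], mat.loc[probe, cols_b],
                            equal_var=False)
        assert sub.loc[probe, "p_posthoc"] == pytest.approx(t.pvalue)


def test_quantile_normalize_equalises_distributions():
    rng = np.random.default_rng(1)
    mat = pd.DataFrame(rng.normal(size=(200, 4)) * [1, 2, 3, 4], columns=list("abcd"))
    qn = quantile_normalize(mat)
    ref = np.sort(qn["a"].to_numpy())
    for c in "bcd":
        assert np.allclose(np.sort(qn[c].to_numpy()), ref, atol=1e-9)
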