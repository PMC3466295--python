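import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drynet.differential import (
    EFFECT_CLASSES,
    EFFECTS,
    ROLLUPS,
    adjust_bonferroni,
    classify_effects,
    cross_tabulate_scenarios,
    fit_anova,
    hierarchical_bicluster,
    pool_residual_variance,
    tukey_hsd_by_genotype,
)


def gene_frame(rows, design):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return pd.DataFrame(
        rows, index=[f"g{i}" for i in range(rows.shape[0])], columns=design.index
    )


class TestAnovaFit:
    def test_matches_statsmodels_type2_oracle(self, balanced_design, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        y = rng.normal(size=len(balanced_design))
        y += np.where(balanced_design["treatment"] == "stressed", 0.8, 0.0)
        res = fit_anova(gene_frame(y, balanced_design), balanced_design, pool=False)
        df = balanced_design.copy()
        df["y"] = y
        fit = smf.ols(
            "y ~ C(block) + C(genotype) + C(treatment) + C(genotype):C(treatment)", df
        ).fit()
        oracle = sm.stats.anova_lm(fit, typ=2)
        for key, eff in [
            ("C(block)", "block"),
            ("C(genotype)", "genotype"),
            ("C(treatment)", "treatment"),
            ("C(genotype):C(treatment)", "gxt"),
        ]:
            assert res.table[f"F_{eff}"].iloc[0] == pytest.approx(
                oracle.loc[key, "F"], abs=1e-8
            )

    def test_pure_treatment_shift_zero_noise(self, balanced_design):
        y = np.where(balanced_design["treatment"] == "stressed", 1.0, 0.0)
        res = fit_anova(gene_frame(y, balanced_design), balanced_design, pool=False)
        assert res.table["p_treatment"].iloc[0] == 0.0
        assert res.table["F_genotype"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert res.table["p_genotype"].iloc[0] == pytest.approx(1.0)
        assert res.table["F_gxt"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_constant_gene(self, balanced_design):
        res = fit_anova(
            gene_frame(np.full(len(balanced_design), 5.0), balanced_design),
            balanced_design,
            pool=False,
        )
        for e in EFFECTS:
            assert res.table[f"F_{e}"].iloc[0] == 0.0
            assert res.table[f"p_{e}"].iloc[0] == 1.0

    def test_invariances(self, balanced_design, rng):
        y = rng.normal(size=len(balanced_design))
        base = fit_anova(gene_frame(y, balanced_design), balanced_design, pool=False)
        perm = rng.permutation(len(balanced_design))
        shuffled = fit_anova(
            gene_frame(y[perm], balanced_design.iloc[perm]).set_axis(
                balanced_design.index[perm], axis=1
            ),
            balanced_design.iloc[perm],
            pool=False,
        )
        shifted = fit_anova(gene_frame(y + 10, balanced_design), balanced_design, pool=False)
        for e in EFFECTS:
            assert shuffled.table[f"F_{e}"].iloc[0] == pytest.approx(
                base.table[f"F_{e}"].iloc[0], rel=1e-9
            )
            assert shifted.table[f"F_{e}"].iloc[0] == pytest.approx(
                base.table[f"F_{e}"].iloc[0], rel=1e-9
            )

    def test_unbalanced_falls_back_to_type2(self, balanced_design, rng):
        sub = balanced_design.drop(balanced_design.index[0])  # one chip missing
        y = rng.normal(size=len(sub))
        res = fit_anova(gene_frame(y, sub), sub, pool=False)
        assert np.isfinite(res.table[[f"F_{e}" for e in EFFECTS]].to_numpy()).all()

    def test_empty_cell_rejected(self, balanced_design, rng):
        sub = balanced_design[
            ~(
                (balanced_design["genotype"] == "G01")
                & (balanced_design["treatment"] == "stressed")
            )
        ]
        with pytest.raises(ValueError, match="empty genotype"):
            fit_anova(gene_frame(rng.normal(size=len(sub)), sub), sub)


class TestVariancePooling:
    def test_equal_variances_all_pooled(self):
        variances = np.full(50, 0.8)
        mask, pooled, df = pool_residual_variance(variances, np.full(50, 30.0))
        assert mask.all()
        assert pooled == pytest.approx(0.8)
        assert df == pytest.approx(50 * 30)

    def test_outlier_variance_trimmed(self, rng):
        # oracle check that Bartlett rejects with the outlier present
        groups = [rng.normal(0, 1, 31) for _ in range(30)] + [rng.normal(0, 10, 31)]
        assert stats.bartlett(*groups).pvalue < 0.05
        variances = np.array([g.var(ddof=1) for g in groups])
        mask, _, _ = pool_residual_variance(variances, np.full(31, 30.0))
        assert not mask[-1]
        assert mask[:-1].all()

    def test_pooled_f_matches_reference_distribution(self, balanced_design, rng):
        # homoscedastic null: pooled-denominator F should follow F(df1, pooled df)
        values = gene_frame(rng.normal(0, 1, (1000, len(balanced_design))), balanced_design)
        res = fit_anova(values, balanced_design)
        assert res.pooled.mean() > 0.9
        f = res.table.loc[res.pooled, "F_genotype"].to_numpy()
        ks = stats.kstest(f, "f", args=(7, res.pooled_df))
        assert ks.pvalue > 0.01

    def test_fewer_than_two_genes_warns(self, balanced_design, rng):
        with pytest.warns(UserWarning, match="not pooled"):
            fit_anova(
                gene_frame(rng.normal(size=len(balanced_design)), balanced_design),
                balanced_design,
            )


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.001, 32423, 1.0), (1e-6, 32423, 0.032423), (0.0, 32423, 0.0)],
    )
    def test_examples(self, p, m, expected):
        assert adjust_bonferroni(np.array([p]), m)[0] == pytest.approx(expected)


class TestTukeyHsd:
    def test_single_genotype_shift_detected(self, balanced_design, rng):
        y = rng.normal(0, 0.1, size=len(balanced_design))
        shift = (balanced_design["genotype"] == "G03") & (
            balanced_design["treatment"] == "stressed"
        )
        y = y + np.where(shift, 5.0, 0.0)
        res = fit_anova(gene_frame(y, balanced_design), balanced_design, pool=False)
        hsd = tukey_hsd_by_genotype(
            y, balanced_design, res.table["resid_var"].iloc[0], res.residual_df
        )
        assert hsd.loc["G03", "significant"]
        assert not hsd.drop("G03")["significant"].any()
        # studentized-range oracle: q = |diff| / sqrt(MSE/n) for equal cells
        mse = res.table["resid_var"].iloc[0]
        q_oracle = abs(hsd.loc["G03", "difference"]) / np.sqrt(mse / 3.0)
        assert hsd.loc["G03", "q"] == pytest.approx(q_oracle, rel=1e-9)
        p_oracle = stats.studentized_range.sf(q_oracle, 16, res.residual_df)
        assert hsd.loc["G03", "p"] == pytest.approx(p_oracle, rel=1e-9)

    def test_identical_cells_not_significant(self, balanced_design):
        y = np.arange(len(balanced_design)) % 2 * 1e-6  # tiny within-cell noise
        hsd = tukey_hsd_by_genotype(y, balanced_design, 1.0, 30)
        assert not hsd["significant"].any()
        assert (hsd["q"] < 1e-3).all()

    def test_null_familywise_error_controlled(self, balanced_design, rng):
        hits = 0
        n_genes = 500
        for _ in range(n_genes):
            y = rng.normal(size=len(balanced_design))
            hsd = tukey_hsd_by_genotype(y, balanced_design, y.var(ddof=1), 30)
            hits += int(hsd["significant"].any())
        assert hits / n_genes <= 0.07

    def test_zero_mse_rejected(self, balanced_design):
        with pytest.raises(ValueError, match="MSE"):
            tukey_hsd_by_genotype(np.zeros(len(balanced_design)), balanced_design, 0.0, 30)


class TestClassification:
    @pytest.mark.parametrize(
        "bits,label",
        [
            ((1, 0, 0), "g_o"),
            ((0, 0, 0), "none"),
            ((1, 1, 1), "All"),
            ((0, 1, 0), "t_o"),
            ((0, 0, 1), "g*t_o"),
            ((1, 1, 0), "g_t"),
            ((1, 0, 1), "g*t_g"),
            ((0, 1, 1), "g*t_t"),
        ],
    )
    def test_bit_pattern_mapping(self, bits, label):
        table = pd.DataFrame(
            {"sig_genotype": [bool(bits[0])], "sig_treatment": [bool(bits[1])], "sig_gxt": [bool(bits[2])]}
        )
        assert classify_effects(table).iloc[0] == label

    def test_pure_function_of_flags(self, rng):
        flags = pd.DataFrame(
            rng.integers(0, 2, size=(40, 3)).astype(bool),
            columns=["sig_genotype", "sig_treatment", "sig_gxt"],
            index=[f"g{i}" for i in range(40)],
        )
        perm = rng.permutation(40)
        direct = classify_effects(flags)
        permuted = classify_effects(flags.iloc[perm])
        assert (direct.iloc[perm].to_numpy() == permuted.to_numpy()).all()


class TestCrossTab:
    def test_all_none(self):
        classes = pd.Series(["none"] * 10, index=[f"g{i}" for i in range(10)])
        tab = cross_tabulate_scenarios(classes, classes)
        assert tab.loc["none", "none"] == 10
        assert tab.loc["Eff", "Eff"] == 0

    def test_rollup_identities(self, rng):
        idx = [f"g{i}" for i in range(200)]
        fds = pd.Series(rng.choice(EFFECT_CLASSES, 200), index=idx)
        fis = pd.Series(rng.choice(EFFECT_CLASSES, 200), index=idx)
        tab = cross_tabulate_scenarios(fds, fis)
        for roll, members in ROLLUPS.items():
            assert tab.loc[roll, roll] == sum(
                tab.loc[r, c] for r in members for c in members
            )
            # marginal roll-up against the exclusive column classes
            assert tab.loc[roll, "none"] == sum(tab.loc[m, "none"] for m in members)

    def test_gene_set_mismatch_rejected(self):
        a = pd.Series(["none"], index=["g1"])
        b = pd.Series(["none"], index=["g2"])
        with pytest.raises(ValueError):
            cross_tabulate_scenarios(a, b)


class TestBicluster:
    def test_identical_samples_merge_first(self, rng):
        base = rng.normal(size=(20, 1))
        mat = np.hstack([base, base, rng.normal(size=(20, 2))])
        values = pd.DataFrame(mat, columns=["a", "b", "c", "d"])
        out = hierarchical_bicluster(values)
        link = out["samples"]["linkage"]
        assert set(link[0, :2].astype(int)) == {0, 1}
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_block_structure_separates_groups(self, rng):
        signal = np.repeat([1.0, -1.0], 5)
        mat = np.outer(rng.normal(size=30), signal) + rng.normal(0, 0.05, (30, 10))
        values = pd.DataFrame(mat, columns=[f"s{i}" for i in range(10)])
        order = hierarchical_bicluster(values)["samples"]["order"]
        positions = {s: i for i, s in enumerate(order)}
        group1 = sorted(positions[f"s{i}"] for i in range(5))
        assert group1 in ([0, 1, 2, 3, 4], [5, 6, 7, 8, 9])

    def test_single_gene_trivial_tree(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g1"], columns=list("abc"))
        out = hierarchical_bicluster(values)
        assert out["genes"]["order"] == ["g1"]
        assert out["genes"]["newick"] == "g1;"

    def test_constant_profile_warns(self, rng):
        values = pd.DataFrame(
            np.vstack([np.ones(4), rng.normal(size=(2, 4))]), columns=list("abcd")
        )
        with pytest.warns(UserWarning, match="constant"):
            hierarchical_bicluster(values)

    def test_newick_serialization_parses(self, rng):
        values = pd.DataFrame(
            rng.normal(size=(5, 6)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(6)],
        )
        out = hierarchical_bicluster(values)
        nwk = out["genes"]["newick"]
        assert nwk.endswith(";") and nwk.count("(") == 4
        for g in values.index:
            assert g in nwk
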