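import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import projection_sequential_ss
from plasmapep import (
    EffectSpec,
    PlantedEffect,
    analyze_gene,
    fit_two_way_anova,
    qq_normality,
    run_all_genes,
    simulate_cohort,
    summarize_treatment,
    tukey_kramer_hsd,
    accept_psms,
)
from plasmapep.anova import (
    InsufficientDataError,
    compact_letter_display,
    standard_error,
)
from conftest import null_two_treatment_design


def random_observations(
    rng, n_peptides=4, n_treatments=3, min_n=1, max_n=6, effects=None
):
    """Unbalanced two-factor data with random missing cells."""
    rows = []
    for p in range(n_peptides):
        for t in range(n_treatments):
            n = int(rng.integers(min_n, max_n + 1))
            mu = 5.0 + 0.2 * p + (effects[t] if effects else 0.0)
            for _ in range(n):
                rows.append(
                    {
                        "peptide": f"PEP{p}K",
                        "treatment_id": t + 1,
                        "log10_intensity": mu + rng.normal(0, 0.3),
                    }
                )
    return pd.DataFrame(rows)


class TestQQNormality:
    def test_gaussian_sample_high_correlation(self):
        rng = np.random.default_rng(1)
        res = qq_normality(rng.normal(5, 0.4, 1000))
        assert res.correlation >= 0.995

    def test_constant_sample_degenerate(self):
        res = qq_normality(np.full(10, 5.0))
        assert res.degenerate
        assert np.isnan(res.correlation)

    def test_heavy_tail_below_gaussian(self):
        rng = np.random.default_rng(2)
        gauss = qq_normality(rng.normal(0, 1, 500)).correlation
        heavy = qq_normality(10 ** rng.uniform(-2, 2, 500)).correlation
        assert heavy < gauss

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            qq_normality([1.0, 2.0])


class TestSummaries:
    @pytest.mark.parametrize(
        "sd,n,printed_se",
        [(0.35, 20, 0.08), (0.91, 9, 0.30), (0.19, 3, 0.11)],
    )
    def test_se_identity_reproduces_printed_rows(self, sd, n, printed_se):
        assert round(standard_error(sd, n), 2) == printed_se

    def test_n1_gives_na(self):
        s = summarize_treatment([5.07], treatment_id=3)
        assert s.n == 1
        assert np.isnan(s.sd) and np.isnan(s.se)

    def test_constant_observations(self):
        s = summarize_treatment([4.4, 4.4, 4.4])
        assert s.sd == 0.0 and s.se == 0.0

    def test_se_times_sqrt_n_equals_sd(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(5, 0.5, int(rng.integers(2, 30)))
            s = summarize_treatment(x)
            assert s.se * np.sqrt(s.n) == pytest.approx(s.sd, rel=1e-12)


class TestTwoWayAnova:
    def test_equal_means_f_near_zero(self):
        obs = pd.DataFrame(
            {
                "peptide": ["AK"] * 8,
                "treatment_id": [1, 1, 1, 1, 2, 2, 2, 2],
                "log10_intensity": [5.0, 5.1, 4.9, 5.0, 5.0, 5.1, 4.9, 5.0],
            }
        )
        table = fit_two_way_anova(obs)
        assert "Peptide_Sequence" not in table.index  # single peptide dropped
        assert table.loc["Treatment_ID", "F"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["Treatment_ID", "p"] == pytest.approx(1.0)

    def test_balanced_interaction_df(self):
        rng = np.random.default_rng(4)
        a, b, reps = 4, 3, 3
        rows = [
            {
                "peptide": f"P{i}K",
                "treatment_id": j + 1,
                "log10_intensity": 5 + rng.normal(),
            }
            for i in range(a)
            for j in range(b)
            for _ in range(reps)
        ]
        table = fit_two_way_anova(pd.DataFrame(rows))
        assert table.loc["Peptide_Sequence", "df"] == a - 1
        assert table.loc["Treatment_ID", "df"] == b - 1
        assert table.loc["Peptide_Sequence:Treatment_ID", "df"] == (a - 1) * (b - 1)
        assert table["df"].sum() == len(rows) - 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_projection_oracle_unbalanced(self, seed):
        rng = np.random.default_rng(seed)
        obs = random_observations(rng, min_n=0, max_n=4)  # random missing cells
        table = fit_two_way_anova(obs)
        oracle = projection_sequential_ss(obs)
        for term, vals in oracle.items():
            assert table.loc[term, "sum_sq"] == pytest.approx(
                vals["sum_sq"], rel=1e-8, abs=1e-10
            )
            assert table.loc[term, "df"] == vals["df"]

    def test_ss_conservation(self):
        rng = np.random.default_rng(7)
        obs = random_observations(rng)
        table = fit_two_way_anova(obs)
        y = obs["log10_intensity"].to_numpy()
        total_ss = ((y - y.mean()) ** 2).sum()
        assert table["sum_sq"].sum() == pytest.approx(total_ss, rel=1e-8)

    def test_matches_statsmodels_on_full_rank_design(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(8)
        obs = random_observations(rng, n_peptides=3, n_treatments=3, min_n=2, max_n=5)
        table = fit_two_way_anova(obs)
        fit = smf.ols(
            "log10_intensity ~ C(peptide) + C(treatment_id) + C(peptide):C(treatment_id)",
            data=obs,
        ).fit()
        ref = anova_lm(fit, typ=1)
        assert table.loc["Peptide_Sequence", "sum_sq"] == pytest.approx(
            ref.loc["C(peptide)", "sum_sq"], rel=1e-8
        )
        assert table.loc["Treatment_ID", "sum_sq"] == pytest.approx(
            ref.loc["C(treatment_id)", "sum_sq"], rel=1e-8
        )
        assert table.loc["Residuals", "sum_sq"] == pytest.approx(
            ref.loc["Residual", "sum_sq"], rel=1e-8
        )

    def test_zero_residual_df_warns_and_nans(self):
        obs = pd.DataFrame(
            {
                "peptide": ["AK", "AK"],
                "treatment_id": [1, 2],
                "log10_intensity": [5.0, 6.0],
            }
        )
        with pytest.warns(RuntimeWarning, match="residual"):
            table = fit_two_way_anova(obs)
        assert np.isnan(table.loc["Treatment_ID", "F"])

    def test_single_treatment_is_error(self):
        obs = pd.DataFrame(
            {"peptide": ["AK"] * 3, "treatment_id": [1, 1, 1], "log10_intensity": [5, 5, 5]}
        )
        with pytest.raises(InsufficientDataError):
            fit_two_way_anova(obs)


class TestTukeyKramer:
    def test_k2_limit_equals_pooled_t_test(self):
        rng = np.random.default_rng(9)
        agree = 0
        trials = 100
        for _ in range(trials):
            n = int(rng.integers(3, 10))
            shift = rng.choice([0.0, 0.5])
            x = rng.normal(0, 1, n)
            y = rng.normal(shift, 1, n)
            obs = pd.DataFrame(
                {
                    "peptide": ["AK"] * (2 * n),
                    "treatment_id": [1] * n + [2] * n,
                    "log10_intensity": np.concatenate([x, y]),
                }
            )
            table = fit_two_way_anova(obs)
            ms = table.loc["Residuals", "sum_sq"] / table.loc["Residuals", "df"]
            res = tukey_kramer_hsd(
                {1: x.mean(), 2: y.mean()},
                {1: n, 2: n},
                ms_resid=ms,
                df_resid=int(table.loc["Residuals", "df"]),
            )
            t_sig = stats.ttest_ind(x, y).pvalue < 0.05
            if bool(res.pairs.iloc[0]["significant"]) == bool(t_sig):
                agree += 1
        assert agree == trials

    def test_identical_means_share_single_letter(self):
        res = tukey_kramer_hsd(
            {1: 5.0, 2: 5.0, 3: 5.0}, {1: 5, 2: 5, 3: 5}, ms_resid=0.1, df_resid=12
        )
        assert all(v == "a" for v in res.letters.values())

    def test_strongly_shifted_mean_gets_private_letter(self):
        rng = np.random.default_rng(10)
        base = {t: float(rng.normal(5.0, 0.01)) for t in (1, 2, 3)}
        base[4] = 5.0 + 10 * np.sqrt(0.04)  # 10 pooled SDs away
        res = tukey_kramer_hsd(
            base, {t: 8 for t in base}, ms_resid=0.04, df_resid=28
        )
        shifted = set(res.letters[4])
        for t in (1, 2, 3):
            assert not (shifted & set(res.letters[t]))

    def test_letters_match_pairwise_relation(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            k = int(rng.integers(3, 7))
            means = {t: float(rng.normal(5, 0.3)) for t in range(1, k + 1)}
            ns = {t: int(rng.integers(2, 10)) for t in means}
            res = tukey_kramer_hsd(means, ns, ms_resid=0.05, df_resid=30)
            sig = {
                frozenset((r["treatment_i"], r["treatment_j"])): r["significant"]
                for _, r in res.pairs.iterrows()
            }
            for pair, is_sig in sig.items():
                i, j = tuple(pair)
                share = bool(set(res.letters[i]) & set(res.letters[j]))
                assert share != bool(is_sig)

    def test_residual_df_below_one_is_error(self):
        with pytest.raises(InsufficientDataError):
            tukey_kramer_hsd({1: 5.0, 2: 6.0}, {1: 3, 2: 3}, 0.1, 0)


class TestCompactLetterDisplay:
    def test_no_significance_single_letter(self):
        letters = compact_letter_display([1, 2, 3], set())
        assert set(letters.values()) == {"a"}

    def test_chain_structure(self):
        # 1 != 3 significant, 2 overlaps both
        letters = compact_letter_display([1, 2, 3], {frozenset((1, 3))})
        assert set(letters[1]) & set(letters[2])
        assert set(letters[2]) & set(letters[3])
        assert not set(letters[1]) & set(letters[3])


class TestRunAllGenes:
    def test_empty_gene_list(self, demo_accepted):
        results, skipped = run_all_genes(demo_accepted, [])
        assert results == {}
        assert len(skipped) == 0

    def test_single_treatment_gene_skipped(self):
        accepted = pd.DataFrame(
            {
                "gene_symbols": ["G1"] * 4,
                "peptide": ["AAAK"] * 4,
                "treatment_id": [1] * 4,
                "precursor_intensity": [2e4] * 4,
                "pool": ["TRYP"] * 4,
                "spectrum_id": list("abcd"),
            }
        )
        results, skipped = run_all_genes(accepted, ["G1"])
        assert results == {}
        assert skipped.iloc[0]["reason"] == "single treatment"

    def test_too_few_observations_skipped(self, demo_accepted):
        results, skipped = run_all_genes(demo_accepted, ["ABSENT"])
        assert skipped.iloc[0]["reason"] == "too few observations"

    def test_summary_letters_consistent_with_tukey(self, demo_accepted):
        genes = ["GS0001", "GS0002"]
        results, _ = run_all_genes(demo_accepted, genes)
        for res in results.values():
            if res.tukey is None:
                continue
            letters = res.summaries.set_index("treatment_id")["letters"]
            for _, row in res.tukey.pairs.iterrows():
                share = bool(
                    set(letters[row["treatment_i"]]) & set(letters[row["treatment_j"]])
                )
                assert share != bool(row["significant"])

    def test_intensity_shift_detected_across_seeds(self, demo_library):
        design = null_two_treatment_design(
            spectra_per_fraction=300, samples=4, fractions=10
        )
        effects = EffectSpec(
            enriched=(PlantedEffect("GS0002", 1, 1.0, intensity_log10_shift=0.6),)
        )
        separated = 0
        for seed in range(20):
            psms, _ = simulate_cohort(demo_library, design, effects, seed=seed)
            accepted = accept_psms(psms, demo_library).accepted
            results, _ = run_all_genes(accepted, ["GS0002"])
            res = results.get("GS0002")
            if res is None or res.tukey is None:
                continue
            letters = res.summaries.set_index("treatment_id")["letters"]
            if not (set(letters[1]) & set(letters[2])):
                separated += 1
        assert separated >= 17

    def test_treatment_mean_differences_unbiased(self):
        rng = np.random.default_rng(12)
        true_shift = 0.5
        biases = []
        for _ in range(200):
            obs = random_observations(
                rng,
                n_peptides=3,
                n_treatments=2,
                min_n=3,
                max_n=4,
                effects=[0.0, true_shift],
            )
            est = analyze_gene(obs).summaries.set_index("treatment_id")["mean"]
            biases.append((est[2] - est[1]) - true_shift)
        assert abs(np.mean(biases)) < 0.02
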