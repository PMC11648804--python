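"""Combined ANOVA: df layout, SS partition, oracles and descriptives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metstab import combined_anova, cv_percent, pct_ss, random_spec, simulate_trial
from metstab.anova import SOURCE_ORDER
from metstab.core import ValidationError
from conftest import make_balanced_table

NON_TOTAL = [s for s in SOURCE_ORDER if s != "Total"]


class TestDfLayout:
    def test_study_shape_reproduces_printed_df_column(self, study_table):
        """24 genotypes × 2 seasons × 3 systems × 3 reps gives the classic
        (12, 1, 2, 2, 23, 23, 46, 46, 276; total 431) partition."""
        an = combined_anova(study_table, "Y")
        dfs = an.rows.set_index("source")["df"]
        assert dfs[NON_TOTAL].tolist() == [12, 1, 2, 2, 23, 23, 46, 46, 276]
        assert dfs["Total"] == 431

    def test_df_additivity_generic(self, rng):
        an = combined_anova(make_balanced_table(5, 3, 2, 4, rng), "Y")
        dfs = an.rows.set_index("source")["df"]
        assert dfs[NON_TOTAL].sum() == dfs["Total"]


class TestSumsOfSquares:
    def test_matches_brute_force_oracle(self, rng, anova_oracle):
        """Vectorized SS equal the per-plot enumeration oracle on a small
        balanced design (the two computations share no code)."""
        table = make_balanced_table(4, 2, 3, 2, rng)  # 48 plots
        an = combined_anova(table, "Y")
        oracle = anova_oracle(table.data, "Y")
        for src in NON_TOTAL + ["Total"]:
            got = float(an.rows.set_index("source").loc[src, "SS"])
            assert got == pytest.approx(oracle[src], rel=1e-9), src

    def test_matches_statsmodels_type1(self, study_table):
        """Sequential (Type I) SS from an OLS fit agree on balanced data."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = study_table.data
        # replication nested in environment = every rep-containing term of
        # the full season × system × rep crossing (2 + 2 + 4 + 4 = 12 df)
        model = smf.ols(
            "Y ~ C(season) * C(system) * C(rep)"
            " + C(genotype) + C(genotype):C(season) + C(genotype):C(system)"
            " + C(genotype):C(season):C(system)",
            data=df,
        ).fit()
        aov = sm.stats.anova_lm(model, typ=1)
        an = combined_anova(study_table, "Y").rows.set_index("source")
        pairs = {
            "C(season)": "Season",
            "C(system)": "System",
            "C(season):C(system)": "Season:System",
            "C(genotype)": "Genotype",
            "C(genotype):C(season)": "Genotype:Season",
            "C(genotype):C(system)": "Genotype:System",
            "C(genotype):C(season):C(system)": "Genotype:Season:System",
            "Residual": "Error",
        }
        for sm_name, our_name in pairs.items():
            assert an.loc[our_name, "SS"] == pytest.approx(
                float(aov.loc[sm_name, "sum_sq"]), rel=1e-8
            ), our_name
            assert an.loc[our_name, "df"] == int(aov.loc[sm_name, "df"])
        rep_terms = [
            "C(rep)",
            "C(season):C(rep)",
            "C(system):C(rep)",
            "C(season):C(system):C(rep)",
        ]
        assert an.loc["Rep", "SS"] == pytest.approx(
            float(aov.loc[rep_terms, "sum_sq"].sum()), rel=1e-8
        )
        assert an.loc["Rep", "df"] == int(aov.loc[rep_terms, "df"].sum())

    @settings(max_examples=15, deadline=None)
    @given(
        g=st.integers(3, 5),
        s=st.integers(2, 3),
        c=st.integers(2, 3),
        r=st.integers(2, 3),
        seed=st.integers(0, 2**20),
    )
    def test_ss_and_df_additivity_property(self, g, s, c, r, seed):
        table = make_balanced_table(g, s, c, r, np.random.default_rng(seed))
        an = combined_anova(table, "Y")
        rows = an.rows.set_index("source")
        assert rows.loc[NON_TOTAL, "SS"].sum() == pytest.approx(
            rows.loc["Total", "SS"], rel=1e-8
        )
        assert rows.loc[NON_TOTAL, "df"].sum() == rows.loc["Total", "df"]
        assert rows.loc[NON_TOTAL, "pct_SS"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_zero_noise_gives_zero_error_and_rep_ss(self):
        spec = random_spec(seed=13, noise_sd=0.0, rep_effect_sd=0.0, grand_mean=50.0)
        table = simulate_trial(spec)
        rows = combined_anova(table, spec.trait_name).rows.set_index("source")
        assert rows.loc["Error", "SS"] == pytest.approx(0.0, abs=1e-8)
        assert rows.loc["Rep", "SS"] == pytest.approx(0.0, abs=1e-8)

    def test_unbalanced_rejected_with_guidance(self, rng):
        table = make_balanced_table(3, 2, 2, 2, rng)
        df = table.data.drop(index=0).drop(columns=["env"])
        from metstab import TrialTable

        broken = TrialTable(df, traits=["Y"], allow_unbalanced=True)
        with pytest.raises(ValidationError, match="impute"):
            combined_anova(broken, "Y")


class TestFTests:
    def test_null_f_statistics_center_near_one(self):
        """Pure-noise simulations: each effect's F has mean ≈ df_e/(df_e−2)."""
        fs = []
        for seed in range(150):
            rng = np.random.default_rng(seed)
            table = make_balanced_table(6, 2, 2, 3, rng)
            rows = combined_anova(table, "Y").rows.set_index("source")
            fs.append(rows.loc["Genotype", "F"])
        df_err = 40  # 72 plots: 71 − (8+1+1+1+5+5+5+5)
        expected = df_err / (df_err - 2)
        assert np.mean(fs) == pytest.approx(expected, abs=0.2)

    def test_alternative_denominator_flag(self, study_table):
        default = combined_anova(study_table, "Y").rows.set_index("source")
        strict = combined_anova(
            study_table, "Y", env_effects_against_rep=True
        ).rows.set_index("source")
        ms_rep = strict.loc["Rep", "MS"]
        assert strict.loc["Season", "F"] == pytest.approx(
            strict.loc["Season", "MS"] / ms_rep
        )
        # genotype tests are unaffected by the flag
        assert strict.loc["Genotype", "F"] == pytest.approx(
            default.loc["Genotype", "F"]
        )


class TestDescriptives:
    @pytest.mark.parametrize(
        "ss_err, df_err, mean, expected",
        [(601.38, 276, 7.43, 19.87), (118.41, 276, 4.36, 15.02), (0.0, 276, 5.0, 0.0)],
    )
    def test_cv_percent_worked_values(self, ss_err, df_err, mean, expected):
        assert round(cv_percent(ss_err, df_err, mean), 2) == expected

    def test_cv_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            cv_percent(10.0, 5, 0.0)

    def test_pct_ss_worked_values(self):
        rows = pd.DataFrame(
            {
                "source": ["System", "Genotype", "Zero", "Total"],
                "SS": [1412.49, 285.1, 0.0, 2017.81],
            }
        )
        assert pct_ss(rows, "System") == 70.00
        assert pct_ss(rows, "Zero") == 0.00
        with pytest.raises(KeyError):
            pct_ss(rows, "Nope")

    def test_descriptives_match_plot_values(self, study_table):
        an = combined_anova(study_table, "Y")
        y = study_table.data["Y"]
        assert an.grand_mean == pytest.approx(y.mean())
        assert an.min == pytest.approx(y.min())
        assert an.max == pytest.approx(y.max())
        assert an.sd == pytest.approx(y.std(ddof=1))
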