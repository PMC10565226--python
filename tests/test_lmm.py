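import numpy as np
import pandas as pd
import pytest

from snakegaze.lmm import (
    FULL_TERMS,
    ThreatBiasLMM,
    backward_reduce,
    build_design,
    lrt,
    lrt_pvalue,
)

from _oracles import dense_loglik, random_lmm_dataset


def study_like_frame(
    rng,
    n_participants=30,
    n_species=6,
    beta_morph=(1.5, 0.4, 0.1),
    sigma_b=1.0,
    sigma=1.0,
    delta=0.0,
    nat_effect=0.0,
):
    """Observations drawn directly from the mixed model (no gaze simulation)."""
    morphs = ["cobra", "viper", "other"]
    eff = dict(zip(morphs, beta_morph))
    rows = []
    for i in range(n_participants):
        nat = "somali" if i % 2 else "czech"
        g = 1.0 if nat == "somali" else 0.0
        b = rng.normal(0, sigma_b)
        gender = "woman" if (i // 2) % 2 == 0 else "man"
        age = float(rng.integers(18, 45))
        for j in range(n_species):
            morph = morphs[j % 3]
            w = int(rng.integers(1, 3))
            sd = sigma * np.exp(delta * g) / np.sqrt(w)
            rows.append(
                dict(
                    participant_id=f"P{i:03d}",
                    species_id=f"s{j}",
                    nationality=nat,
                    gender=gender,
                    age=age,
                    morphotype=morph,
                    weight=w,
                    y=eff[morph] + nat_effect * g + b + rng.normal(0, sd),
                )
            )
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_treatment_coding_column_counts(self):
        df = study_like_frame(np.random.default_rng(0), n_participants=6)
        d1 = build_design(df, terms=("intercept", "morphotype"), response="y")
        assert d1.X.shape[1] == 3
        assert d1.columns == ("intercept", "morphotype[other]", "morphotype[viper]")
        d2 = build_design(
            df,
            terms=("intercept", "morphotype", "nationality",
                   "morphotype:nationality"),
            response="y",
        )
        assert d2.X.shape[1] == 6  # +1 nationality +2 interaction

    def test_within_between_classification(self):
        df = study_like_frame(np.random.default_rng(0), n_participants=6)
        d = build_design(df, terms=FULL_TERMS, response="y")
        assert d.varies_within["morphotype"]
        assert d.varies_within["morphotype:nationality"]
        assert not d.varies_within["nationality"]
        assert not d.varies_within["gender"]
        assert not d.varies_within["age"]

    def test_missing_values_error_names_column(self):
        df = study_like_frame(np.random.default_rng(0), n_participants=4)
        df.loc[3, "age"] = np.nan
        with pytest.raises(ValueError, match="age"):
            build_design(df, terms=FULL_TERMS, response="y")

    def test_interaction_requires_main_effects(self):
        df = study_like_frame(np.random.default_rng(0), n_participants=4)
        with pytest.raises(ValueError, match="main effect"):
            build_design(
                df, terms=("intercept", "morphotype:nationality"), response="y"
            )


class TestLoglik:
    def test_matches_dense_oracle_on_small_datasets(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            df = random_lmm_dataset(rng)
            mod = ThreatBiasLMM.from_dataframe(
                df, response="y", terms=("intercept", "morphotype")
            )
            gc = np.repeat(
                np.arange(len(mod._starts)),
                np.diff(np.r_[mod._starts, len(mod._y)]),
            )
            for lam, delta in [(0.0, 0.0), (0.5, 0.3), (2.0, -0.4), (7.0, 0.8)]:
                for method in ("ML", "REML"):
                    got = mod.loglik(lam, delta, method)[0]
                    want = dense_loglik(
                        mod._X, mod._y, gc, mod._g, mod._w, lam, delta, method
                    )
                    assert got == pytest.approx(want, abs=1e-8)

    def test_wls_limit(self):
        """lam = 0, delta = 0, unit weights: ML loglik equals the OLS
        Gaussian loglik."""
        rng = np.random.default_rng(1)
        df = study_like_frame(rng, n_participants=8, n_species=4)
        df["weight"] = 1
        mod = ThreatBiasLMM.from_dataframe(
            df, response="y", terms=("intercept", "morphotype"),
            var_group_col=None,
        )
        ll, beta, s2 = mod.loglik(0.0, 0.0, "ML")
        X, y = mod._X, mod._y
        bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ bhat) ** 2))
        n = len(y)
        ols_ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
        assert ll == pytest.approx(ols_ll, abs=1e-10)
        assert beta == pytest.approx(bhat, abs=1e-8)

    def test_reml_translation_invariance(self):
        rng = np.random.default_rng(2)
        df = study_like_frame(rng, n_participants=8)
        mod1 = ThreatBiasLMM.from_dataframe(
            df, response="y", terms=("intercept", "morphotype")
        )
        df2 = df.assign(y=df["y"] + 57.0)
        mod2 = ThreatBiasLMM.from_dataframe(
            df2, response="y", terms=("intercept", "morphotype")
        )
        for lam, delta in [(0.3, 0.1), (1.5, -0.2)]:
            assert mod1.loglik(lam, delta, "REML")[0] == pytest.approx(
                mod2.loglik(lam, delta, "REML")[0], abs=1e-8
            )

    def test_invalid_theta_rejected(self):
        df = study_like_frame(np.random.default_rng(0), n_participants=4)
        mod = ThreatBiasLMM.from_dataframe(df, response="y",
                                           terms=("intercept",))
        with pytest.raises(ValueError):
            mod.loglik(np.nan, 0.0)
        with pytest.raises(ValueError):
            mod.loglik(-1.0, 0.0)


class TestFit:
    def test_balanced_reml_matches_closed_form(self):
        """On balanced one-way data (unit weights, one variance group) the
        REML variance components equal the ANOVA closed forms
        sigma^2 = MSW, sigma_b^2 = (MSB - MSW) / m."""
        rng = np.random.default_rng(3)
        a, m = 12, 6
        y = (rng.normal(0, 2.0, size=(a, 1)) + rng.normal(0, 1.0, size=(a, m)))
        df = pd.DataFrame(
            {
                "participant_id": np.repeat([f"P{i:02d}" for i in range(a)], m),
                "y": y.ravel(),
            }
        )
        res = ThreatBiasLMM.from_dataframe(
            df, response="y", terms=("intercept",),
            var_group_col=None, weight_col=None,
        ).fit("REML")
        gmeans = y.mean(axis=1)
        msb = m * np.sum((gmeans - gmeans.mean()) ** 2) / (a - 1)
        msw = np.sum((y - gmeans[:, None]) ** 2) / (a * (m - 1))
        assert res.sigma2 == pytest.approx(msw, abs=1e-6)
        assert res.sigma_b2 == pytest.approx((msb - msw) / m, abs=1e-6)

    def test_noiseless_data_recovers_fixed_effects(self):
        morphs = ["cobra", "viper", "other"]
        eff = {"cobra": 2.0, "viper": 0.5, "other": -1.0}
        rows = [
            dict(participant_id=f"P{i}", morphotype=mo, weight=1, y=eff[mo])
            for i in range(6)
            for mo in morphs
        ]
        res = ThreatBiasLMM.from_dataframe(
            pd.DataFrame(rows), response="y", terms=("intercept", "morphotype"),
            var_group_col=None,
        ).fit("REML")
        assert res.params["intercept"] == pytest.approx(2.0, abs=1e-6)
        assert res.params["morphotype[other]"] == pytest.approx(-3.0, abs=1e-6)
        assert res.params["morphotype[viper]"] == pytest.approx(-1.5, abs=1e-6)

    def test_variance_ratio_recovery(self):
        """delta is recovered across replicate simulated datasets."""
        hits = 0
        n_rep = 40
        for r in range(n_rep):
            rng = np.random.default_rng(100 + r)
            df = study_like_frame(
                rng, n_participants=60, n_species=10, delta=0.5
            )
            res = ThreatBiasLMM.from_dataframe(
                df, response="y", terms=("intercept", "morphotype")
            ).fit("REML")
            if abs(res.delta - 0.5) <= 0.15:
                hits += 1
        assert hits >= int(0.9 * n_rep)

    def test_boundary_sigma_b_zero(self):
        rng = np.random.default_rng(4)
        rows = [
            dict(participant_id=f"P{i}", weight=1, y=rng.normal())
            for i in range(20) for _ in range(4)
        ]
        res = ThreatBiasLMM.from_dataframe(
            pd.DataFrame(rows), response="y", terms=("intercept",),
            var_group_col=None,
        ).fit("REML")
        assert res.sigma_b2 >= 0.0
        assert res.sigma_b2 < 0.2  # at/near the boundary, not an error


class TestComparisons:
    def _two_fits(self):
        df = study_like_frame(np.random.default_rng(5), n_participants=12)
        full = ThreatBiasLMM.from_dataframe(
            df, response="y", terms=("intercept", "morphotype", "nationality")
        ).fit("ML")
        red = ThreatBiasLMM.from_dataframe(
            df, response="y", terms=("intercept", "morphotype")
        ).fit("ML")
        return full, red

    def test_lrt_identical_specs(self):
        full, _ = self._two_fits()
        stat, df_, p = lrt(full, full)
        assert stat == 0.0 and p == 1.0

    def test_lrt_and_aic_identity(self):
        full, red = self._two_fits()
        stat, dof, p = lrt(full, red)
        assert dof == 1
        assert stat >= 0.0
        # for nested ML fits: AIC difference = LRT stat - 2 df
        assert red.aic - full.aic == pytest.approx(stat - 2 * dof, abs=1e-8)

    def test_lrt_requires_ml_and_nesting(self):
        df = study_like_frame(np.random.default_rng(6), n_participants=8)
        reml = ThreatBiasLMM.from_dataframe(
            df, response="y", terms=("intercept", "morphotype")
        ).fit("REML")
        with pytest.raises(ValueError, match="ML"):
            lrt(reml, reml)
        full, _ = self._two_fits()
        other = ThreatBiasLMM.from_dataframe(
            df, response="y", terms=("intercept", "morphotype")
        ).fit("ML")
        with pytest.raises(ValueError, match="same data"):
            lrt(full, other)

    def test_lrt_pvalue_monotone(self):
        ps = [lrt_pvalue(s, 3) for s in (0.0, 1.0, 3.0, 9.0)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert lrt_pvalue(0.0, 0) == 1.0


class TestDenominatorDf:
    def test_inner_outer_rule_at_study_dimensions(self):
        """142 participants x 20 species with 103 whole-pair losses gives the
        within/between dfs printed by the study: 2593/2591 within and
        138/141 between."""
        rng = np.random.default_rng(7)
        df = study_like_frame(rng, n_participants=142, n_species=20,
                              sigma_b=0.5)
        # drop 103 participant x species cells entirely
        drop = rng.choice(len(df), size=103, replace=False)
        df = df.drop(index=drop).reset_index(drop=True)
        assert len(df) == 2737

        fix_final = ThreatBiasLMM.from_dataframe(
            df, response="y", terms=("intercept", "morphotype")
        ).fit("REML")
        assert fix_final.denominator_df("morphotype") == 2593

        full = ThreatBiasLMM.from_dataframe(
            df, response="y", terms=FULL_TERMS
        ).fit("REML")
        assert full.denominator_df("gender") == 138
        assert full.denominator_df("nationality") == 138
        assert full.denominator_df("morphotype:nationality") == 2591

        dwell_final = ThreatBiasLMM.from_dataframe(
            df, response="y",
            terms=("intercept", "morphotype", "nationality",
                   "morphotype:nationality"),
        ).fit("REML")
        assert dwell_final.denominator_df("morphotype") == 2591
        assert dwell_final.denominator_df("nationality") == 141

    def test_unknown_term_rejected(self):
        df = study_like_frame(np.random.default_rng(8), n_participants=6)
        res = ThreatBiasLMM.from_dataframe(
            df, response="y", terms=("intercept", "morphotype")
        ).fit("REML")
        with pytest.raises(ValueError, match="not in the fitted model"):
            res.denominator_df("gender")


class TestReduction:
    def test_alpha_one_keeps_full_model(self):
        df = study_like_frame(np.random.default_rng(9), n_participants=12)
        red = backward_reduce(df, response="y", full_terms=FULL_TERMS, alpha=1.0)
        assert set(red.final.terms) == set(FULL_TERMS)

    def test_strong_morphotype_effect_only_is_retained(self):
        df = study_like_frame(
            np.random.default_rng(10),
            n_participants=40,
            beta_morph=(4.0, 1.5, 0.0),
            sigma_b=0.3,
            sigma=0.5,
        )
        red = backward_reduce(df, response="y", full_terms=FULL_TERMS)
        assert set(red.final.terms) == {"intercept", "morphotype"}
        dropped = red.trace.loc[red.trace["action"] == "dropped", "term"]
        assert set(dropped) == {"nationality", "gender", "age",
                                "morphotype:nationality", "gender:nationality"}

    def test_morphotype_nationality_interaction_pattern_is_recovered(self):
        """Nationality-dependent morphotype effects keep morphotype,
        nationality, and their interaction in the final model."""
        df = study_like_frame(
            np.random.default_rng(11),
            n_participants=60,
            n_species=12,
            beta_morph=(2.0, 0.3, 0.2),
            sigma_b=0.3,
            sigma=0.5,
        )
        # add a nationality-specific viper effect
        somali = (df["nationality"] == "somali") & (df["morphotype"] == "viper")
        df.loc[somali, "y"] += 1.5
        red = backward_reduce(df, response="y", full_terms=FULL_TERMS)
        assert {"morphotype", "nationality", "morphotype:nationality"} <= set(
            red.final.terms
        )
        assert "gender" not in red.final.terms

    def test_reduction_invariant_to_term_order(self):
        df = study_like_frame(np.random.default_rng(12), n_participants=24)
        shuffled = ("intercept", "gender:nationality", "age", "morphotype",
                    "gender", "morphotype:nationality", "nationality")
        r1 = backward_reduce(df, response="y", full_terms=FULL_TERMS)
        r2 = backward_reduce(df, response="y", full_terms=shuffled)
        assert set(r1.final.terms) == set(r2.final.terms)


class TestMarginalMeans:
    def test_saturated_emm_equals_cell_estimates(self):
        df = study_like_frame(np.random.default_rng(13), n_participants=10)
        res = ThreatBiasLMM.from_dataframe(
            df, response="y", terms=("intercept", "morphotype")
        ).fit("REML")
        emm = res.emmeans("morphotype").set_index("morphotype")
        b = res.params
        assert emm.loc["cobra", "estimate"] == pytest.approx(b["intercept"])
        assert emm.loc["viper", "estimate"] == pytest.approx(
            b["intercept"] + b["morphotype[viper]"]
        )
        assert emm.loc["other", "estimate"] == pytest.approx(
            b["intercept"] + b["morphotype[other]"]
        )
        # CI = estimate +/- t * SE
        from scipy import stats as sps
        row = emm.loc["cobra"]
        tcrit = sps.t.ppf(0.975, row["df"])
        assert row["ci_hi"] - row["estimate"] == pytest.approx(
            tcrit * row["se"], abs=1e-10
        )

    def test_contrast_consistency_and_symmetry(self):
        df = study_like_frame(np.random.default_rng(14), n_participants=16)
        # make the two nationalities exactly symmetric by mirroring rows
        flipped = df.copy()
        flipped["participant_id"] = flipped["participant_id"] + "x"
        flipped["nationality"] = np.where(
            flipped["nationality"] == "somali", "czech", "somali"
        )
        sym = pd.concat([df, flipped], ignore_index=True)
        res = ThreatBiasLMM.from_dataframe(
            sym, response="y",
            terms=("intercept", "morphotype", "nationality",
                   "morphotype:nationality"),
        ).fit("REML")
        con = res.contrasts("nationality", by=["morphotype"])
        emm = res.emmeans(["morphotype", "nationality"])
        for _, row in con.iterrows():
            la, lb = row["contrast"].split(" - ")
            cell = emm[emm["morphotype"] == row["morphotype"]]
            diff = (
                cell.loc[cell["nationality"] == la, "estimate"].iloc[0]
                - cell.loc[cell["nationality"] == lb, "estimate"].iloc[0]
            )
            assert row["estimate"] == pytest.approx(diff, abs=1e-10)
            # data are nationality-symmetric: contrast vanishes
            assert abs(row["estimate"]) < 1e-8
            assert row["p"] == pytest.approx(1.0, abs=1e-6)

    def test_absent_factor_rejected(self):
        df = study_like_frame(np.random.default_rng(15), n_participants=6)
        res = ThreatBiasLMM.from_dataframe(
            df, response="y", terms=("intercept", "morphotype")
        ).fit("REML")
        with pytest.raises(ValueError, match="not in the fitted model"):
            res.emmeans("gender")
        with pytest.raises(ValueError, match="not in the fitted model"):
            res.contrasts("gender")

    def test_summary_renders(self):
        df = study_like_frame(np.random.default_rng(16), n_participants=8)
        res = ThreatBiasLMM.from_dataframe(
            df, response="y", terms=("intercept", "morphotype")
        ).fit("REML")
        text = res.summary()
        assert "logLik" in text and "morphotype[viper]" in text
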