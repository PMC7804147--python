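import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from faceshape.landmark_io import ValidationError
from faceshape.preference_models import (
    GROUP_PAIRS,
    PreferenceModelFit,
    PreferenceModelSpec,
    fit_preference_model,
    group_contrasts,
    standardize,
)
from faceshape.synthetic_data import simulate_ratings
from conftest import small_config


class TestStandardize:
    def test_forced_example(self):
        np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1], atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValidationError):
            standardize([2.0, 2.0, 2.0])

    def test_idempotent(self, rng):
        x = rng.normal(3, 5, size=40)
        once = standardize(x)
        np.testing.assert_allclose(standardize(once), once, atol=1e-12)


@pytest.fixture(scope="module")
def fitted(small_study):
    fit = fit_preference_model(
        small_study["ratings"], small_study["scores"], PreferenceModelSpec(face_sex="F")
    )
    return fit


class TestFit:
    def test_term_layout(self, fitted):
        terms = list(fitted.fixed_effects["term"])
        assert terms[0] == "(Intercept)"
        assert "avrg:ratergroupAVN" in terms
        assert "sshd:ratergroupCZVN" in terms
        assert len(terms) == 15

    def test_random_components_nonnegative(self, fitted):
        assert (fitted.random_effects["variance"] >= 0).all()

    def test_zero_variance_limit_matches_ols(self, small_study):
        cfg = small_config(
            rater_intercept_sd=0.0, face_intercept_sd=0.0, residual_sd=0.9, seed=13
        )
        ratings = simulate_ratings(small_study["scores"], cfg)
        sub = ratings[ratings["rater_sex"] == "M"]
        spec = PreferenceModelSpec(face_sex="F")
        mixed = fit_preference_model(sub, small_study["scores"], spec)
        ols = fit_preference_model(
            sub,
            small_study["scores"],
            dataclasses.replace(spec, random_structure=False),
        )
        np.testing.assert_allclose(
            mixed.fixed_effects["estimate"],
            ols.fixed_effects["estimate"],
            atol=1e-6,
        )

    def test_rating_scale_contract(self, small_study):
        # doubling all ratings doubles every fixed effect
        spec = PreferenceModelSpec(face_sex="F", random_structure=False)
        sub = small_study["ratings"]
        base = fit_preference_model(sub, small_study["scores"], spec)
        doubled = sub.copy()
        doubled["rating"] = doubled["rating"] * 2.0
        fit2 = fit_preference_model(doubled, small_study["scores"], spec)
        np.testing.assert_allclose(
            fit2.fixed_effects["estimate"],
            2.0 * base.fixed_effects["estimate"],
            atol=1e-8,
        )

    def test_null_interactions_covered_by_two_se(self, small_study):
        # identical group weights: interaction terms should sit within 2 SE
        # of zero in the overwhelming majority of seeded replicates
        w = (0.0, -0.2, -0.2, -0.4, -0.1)
        inter_cov: dict[str, int] = {}
        n_rep = 20
        for rep in range(n_rep):
            cfg = small_config(
                group_weights={"CZ": w, "CZVN": w, "AVN": w}, seed=9000 + rep
            )
            ratings = simulate_ratings(small_study["scores"], cfg)
            sub = ratings[ratings["rater_sex"] == "M"]
            fit = fit_preference_model(
                sub, small_study["scores"], PreferenceModelSpec(face_sex="F")
            )
            fe = fit.fixed_effects
            inter = fe[fe["term"].str.contains(":")]
            for term, est, se in zip(inter["term"], inter["estimate"], inter["se"]):
                inter_cov[term] = inter_cov.get(term, 0) + (abs(est) <= 2 * se)
        for term, count in inter_cov.items():
            assert count / n_rep >= 0.9, (term, count)

    def test_rated_faces_need_scores(self, small_study):
        scores = small_study["scores"].iloc[:-3]
        with pytest.raises(ValidationError):
            fit_preference_model(
                small_study["ratings"], scores, PreferenceModelSpec(face_sex="M")
            )


def _fixture_fit(beta: dict[str, float], cov_diag: float = 0.01) -> PreferenceModelFit:
    """Hand-set coefficient vector with a known diagonal covariance."""
    terms = PreferenceModelSpec().term_names(["CZ", "AVN", "CZVN"])
    est = np.array([beta.get(t, 0.0) for t in terms])
    cov = pd.DataFrame(np.eye(len(terms)) * cov_diag, index=terms, columns=terms)
    fe = pd.DataFrame(
        {"term": terms, "estimate": est, "se": np.sqrt(np.diag(cov)), "df": 500.0,
         "t": 0.0, "p": 1.0}
    )
    return PreferenceModelFit(
        fixed_effects=fe,
        random_effects=pd.DataFrame(columns=["component", "variance", "sd"]),
        cov_fixed=cov,
        converged=True,
        n_obs=1000,
        n_raters=60,
        face_sex="F",
        groups=["CZ", "AVN", "CZVN"],
        spec=PreferenceModelSpec(),
    )


class TestContrasts:
    def test_matrix_oracle(self):
        fit = _fixture_fit(
            {"avrg": -0.4, "avrg:ratergroupCZVN": 0.1, "avrg:ratergroupAVN": 0.25}
        )
        res = group_contrasts(fit, "avrg").table.set_index("pair")
        # delta(CZ-CZVN) = -(interaction CZVN); SE = sqrt(c' Sigma c) = 0.1
        assert res.loc["CZ-CZVN", "delta"] == pytest.approx(-0.1, abs=1e-12)
        assert res.loc["CZ-CZVN", "se"] == pytest.approx(0.1, abs=1e-12)
        assert res.loc["CZVN-AVN", "delta"] == pytest.approx(0.1 - 0.25, abs=1e-12)
        assert res.loc["CZVN-AVN", "se"] == pytest.approx(np.sqrt(0.02), abs=1e-12)

    def test_antisymmetry_via_relabeled_fixture(self):
        fit = _fixture_fit({"ratergroupCZVN": 0.3, "ratergroupAVN": -0.2})
        res = group_contrasts(fit, "intercept").table.set_index("pair")
        assert res.loc["CZ-CZVN", "delta"] == pytest.approx(-0.3)
        assert res.loc["CZ-AVN", "delta"] == pytest.approx(0.2)
        assert res.loc["CZVN-AVN", "delta"] == pytest.approx(0.5)
        # antisymmetry: delta(A-B) is the negated delta of the reversed pair,
        # i.e. group effects reconstruct consistently from any direction
        assert res.loc["CZ-CZVN", "delta"] + res.loc["CZVN-AVN", "delta"] == (
            pytest.approx(res.loc["CZ-AVN", "delta"], abs=1e-12)
        )

    def test_adjusted_p_not_smaller_than_single_test(self):
        fit = _fixture_fit({"ratergroupCZVN": 0.25})
        res = group_contrasts(fit, "intercept").table
        for _, row in res.iterrows():
            single = 2 * stats.t.sf(abs(row["t"]), row["df"])
            assert row["p_adj"] >= single - 1e-3

    def test_two_group_degenerate_equals_unadjusted(self, small_study):
        ratings = small_study["ratings"]
        sub = ratings[
            (ratings["rater_sex"] == "M") & (ratings["rater_group"] != "AVN")
        ]
        fit = fit_preference_model(
            sub, small_study["scores"], PreferenceModelSpec(face_sex="F")
        )
        res = group_contrasts(fit, "intercept").table
        assert len(res) == 1
        row = res.iloc[0]
        single = 2 * stats.t.sf(abs(row["t"]), row["df"])
        assert row["p_adj"] == pytest.approx(single, abs=2e-3)

    def test_unknown_family_rejected(self, fitted):
        with pytest.raises(ValidationError):
            group_contrasts(fitted, "height")

    def test_reference_relabeling_leaves_contrasts_invariant(self, small_study):
        sub = small_study["ratings"][small_study["ratings"]["rater_sex"] == "M"]
        spec_cz = PreferenceModelSpec(face_sex="F", random_structure=False)
        spec_avn = dataclasses.replace(spec_cz, reference_group="AVN")
        fit_cz = fit_preference_model(sub, small_study["scores"], spec_cz)
        fit_avn = fit_preference_model(sub, small_study["scores"], spec_avn)
        for family in ("intercept", "avrg"):
            a = group_contrasts(fit_cz, family).table.set_index("pair")
            b = group_contrasts(fit_avn, family).table.set_index("pair")
            for pair in a.index:
                assert a.loc[pair, "delta"] == pytest.approx(
                    b.loc[pair, "delta"], abs=1e-6
                )
                assert a.loc[pair, "se"] == pytest.approx(b.loc[pair, "se"], abs=1e-6)
                assert a.loc[pair, "p_adj"] == pytest.approx(
                    b.loc[pair, "p_adj"], abs=1e-4
                )
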