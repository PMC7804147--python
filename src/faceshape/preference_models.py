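"""Linear mixed models of individual attractiveness ratings by rater group.

One model per face sex: rating ~ z(age) + z(bmi) + z(avrg) + z(sshd), with
rater-group main effects and group x predictor interactions (varying
intercepts and slopes among groups, reference group CZ), plus random
intercepts for raters, random rater slopes on each predictor, and random
intercepts for faces.  Raters and faces are crossed, which is handled by
fitting the model as a single-group mixed model with one variance component
per random term; the components are therefore mutually uncorrelated (the
full correlated rater random-effects covariance is not identified in this
formulation).  Ratings are modeled as numeric despite their ordinal origin.

Pairwise rater-group contrasts per coefficient family use the fixed-effect
covariance matrix with a single-step multivariate-normal max-|z| adjustment
over the three simultaneous comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from faceshape.landmark_io import ValidationError

__all__ = [
    "PreferenceModelSpec",
    "PreferenceModelFit",
    "ContrastResult",
    "standardize",
    "fit_preference_model",
    "group_contrasts",
    "GROUP_PAIRS",
]

PREDICTORS = ("age", "bmi", "avrg", "sshd")
GROUP_PAIRS = (("CZ", "CZVN"), ("CZ", "AVN"), ("CZVN", "AVN"))


def standardize(values) -> np.ndarray:
    """z-scores with the n-1 variance denominator; rejects constant input."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("standardize needs a 1-D array of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


@dataclass
class PreferenceModelSpec:
    """Specification of the per-face-sex preference model."""

    face_sex: str = "F"
    reference_group: str = "CZ"
    standardize_predictors: bool = True
    rater_slopes: bool = True
    random_structure: bool = True

    def term_names(self, groups: list[str]) -> list[str]:
        others = [g for g in groups if g != self.reference_group]
        names = ["(Intercept)", *PREDICTORS]
        names += [f"ratergroup{g}" for g in others]
        for p in PREDICTORS:
            names += [f"{p}:ratergroup{g}" for g in others]
        return names


@dataclass
class PreferenceModelFit:
    """Fitted preference model: estimates, covariance, variance components."""

    fixed_effects: pd.DataFrame
    random_effects: pd.DataFrame
    cov_fixed: pd.DataFrame
    converged: bool
    n_obs: int
    n_raters: int
    face_sex: str
    groups: list[str]
    spec: PreferenceModelSpec
    fit_warnings: list[str] = field(default_factory=list)


@dataclass
class ContrastResult:
    """Pairwise rater-group contrasts for one coefficient family."""

    family: str
    table: pd.DataFrame  # pair, delta, se, z, p_adj


def _build_design(
    ratings: pd.DataFrame, scores: pd.DataFrame, spec: PreferenceModelSpec
) -> tuple[pd.DataFrame, list[str]]:
    faces = scores[scores["sex"] == spec.face_sex].copy()
    if faces.empty:
        raise ValidationError(f"no faces of sex {spec.face_sex!r} in the score table")
    # rated faces must all be scored (faces never rated are fine)
    unknown = set(ratings["face_id"]) - set(scores["specimen_id"])
    if unknown:
        raise ValidationError(f"rated faces lack scores: {sorted(unknown)[:5]}")
    df = ratings.merge(
        faces[["specimen_id", "age", "bmi", "avrg", "sshd"]],
        left_on="face_id",
        right_on="specimen_id",
        how="inner",
    )
    if df.empty:
        raise ValidationError("no ratings match faces of the requested sex")
    rated_faces = faces[faces["specimen_id"].isin(df["face_id"])]
    for p in PREDICTORS:
        v = rated_faces[p].to_numpy(dtype=float)
        z = standardize(v) if spec.standardize_predictors else v
        zmap = dict(zip(rated_faces["specimen_id"], z))
        df[f"{p}_z"] = df["face_id"].map(zmap)
    groups = sorted(df["rater_group"].unique(), key=lambda g: (g != spec.reference_group, g))
    if spec.reference_group not in groups:
        raise ValidationError(f"reference group {spec.reference_group!r} absent from data")
    counts = df.groupby("rater_group")["rater_id"].nunique()
    low = counts[counts < 2]
    if not low.empty:
        raise ValidationError(f"rater groups with < 2 raters: {list(low.index)}")
    return df, groups


def fit_preference_model(
    ratings: pd.DataFrame,
    scores: pd.DataFrame,
    spec: PreferenceModelSpec | None = None,
) -> PreferenceModelFit:
    """Fit the rating model for one face sex by REML.

    The estimation engine is :class:`statsmodels` ``MixedLM``; this module
    owns the design construction (treatment coding against the reference
    group, face-level standardization of predictors) and the assembly of the
    output tables.  Degrees of freedom for fixed-effect t tests are the
    residual df (n_obs minus the number of fixed effects); Satterthwaite
    approximations are not available in this engine, so p-values for small
    group counts are mildly liberal.
    """
    spec = spec or PreferenceModelSpec()
    df, groups = _build_design(ratings, scores, spec)
    others = [g for g in groups if g != spec.reference_group]
    term_names = spec.term_names(groups)

    x_cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(len(df))}
    for p in PREDICTORS:
        x_cols[p] = df[f"{p}_z"].to_numpy()
    for g in others:
        x_cols[f"ratergroup{g}"] = (df["rater_group"] == g).to_numpy(dtype=float)
    for p in PREDICTORS:
        for g in others:
            x_cols[f"{p}:ratergroup{g}"] = x_cols[p] * x_cols[f"ratergroup{g}"]
    exog = pd.DataFrame(x_cols, index=df.index)[term_names]
    endog = df["rating"].astype(float)
    n, p_fixed = exog.shape
    df_resid = n - p_fixed
    fit_warnings: list[str] = []

    if not spec.random_structure:
        res = sm.OLS(endog, exog).fit()
        params, bse, cov = res.params, res.bse, res.cov_params()
        converged = True
        re_table = pd.DataFrame(columns=["component", "variance", "sd"])
    else:
        # safe column names for the formula interface; mapped back afterwards
        safe = {t: f"fe_{i}" for i, t in enumerate(term_names)}
        model_df = pd.DataFrame(
            {safe[t]: exog[t].to_numpy() for t in term_names if t != "(Intercept)"}
        )
        model_df["rating_num"] = endog.to_numpy()
        model_df["rater_id"] = df["rater_id"].to_numpy()
        model_df["face_id"] = df["face_id"].to_numpy()
        for p in PREDICTORS:
            model_df[f"{p}_z"] = df[f"{p}_z"].to_numpy()
        vc = {
            "rater": "0 + C(rater_id)",
            "face": "0 + C(face_id)",
        }
        if spec.rater_slopes:
            for p in PREDICTORS:
                vc[f"rater_{p}"] = f"0 + C(rater_id):{p}_z"
        fixed_formula = "rating_num ~ " + " + ".join(
            safe[t] for t in term_names if t != "(Intercept)"
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = smf.mixedlm(
                fixed_formula,
                model_df,
                groups=np.ones(len(model_df)),
                vc_formula=vc,
            )
            # gradient methods flag non-convergence when variance components
            # sit on the zero boundary; Powell handles the boundary cleanly
            res = model.fit(reml=True, method="lbfgs")
            if not res.converged:
                res = model.fit(reml=True, method="powell")
            fit_warnings = [str(w.message) for w in caught]
        converged = bool(res.converged)
        params = res.fe_params
        cov = res.cov_params().iloc[: len(params), : len(params)]
        bse = pd.Series(np.sqrt(np.diag(cov)), index=params.index)
        re_rows = [("residual", float(res.scale), float(np.sqrt(res.scale)))]
        for name, var in zip(model.exog_vc.names, np.atleast_1d(res.vcomp)):
            re_rows.append((name, float(var), float(np.sqrt(max(var, 0.0)))))
        re_table = pd.DataFrame(re_rows, columns=["component", "variance", "sd"])
        rename = {v: k for k, v in safe.items()}
        rename["Intercept"] = "(Intercept)"
        params = params.rename(index=rename)
        bse = bse.rename(index=rename)
        cov = cov.rename(index=rename, columns=rename)

    params = params[term_names]
    bse = bse[term_names]
    cov = cov.loc[term_names, term_names]
    tvals = params / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    fixed = pd.DataFrame(
        {
            "term": term_names,
            "estimate": params.to_numpy(),
            "se": bse.to_numpy(),
            "df": float(df_resid),
            "t": tvals.to_numpy(),
            "p": pvals,
        }
    )
    if not converged:
        fit_warnings.append("mixed model did not converge; estimates are provisional")
    return PreferenceModelFit(
        fixed_effects=fixed,
        random_effects=re_table,
        cov_fixed=cov,
        converged=converged,
        n_obs=n,
        n_raters=int(df["rater_id"].nunique()),
        face_sex=spec.face_sex,
        groups=groups,
        spec=spec,
    )


def _family_base(family: str) -> str:
    if family == "intercept":
        return "(Intercept)"
    if family in PREDICTORS:
        return family
    raise ValidationError(f"unknown coefficient family {family!r}")


def _effect_vector(fit: PreferenceModelFit, family: str, group: str) -> np.ndarray:
    terms = list(fit.fixed_effects["term"])
    vec = np.zeros(len(terms))
    base = _family_base(family)
    vec[terms.index(base)] = 1.0
    if group != fit.spec.reference_group:
        inter = f"ratergroup{group}" if family == "intercept" else f"{family}:ratergroup{group}"
        if inter not in terms:
            raise ValidationError(f"group {group!r} not in the fitted model")
        vec[terms.index(inter)] = 1.0
    return vec


def _max_modulus_p(t_obs: float, corr: np.ndarray, df: float) -> float:
    """P(max_j |T_j| >= |t_obs|) for equicorrelated-ish simultaneous contrasts.

    Uses the multivariate t distribution with the contrasts' estimated
    correlation matrix (Gauss quadrature over the chi scale mixing variable,
    trivariate-normal rectangle probabilities inside), the single-step
    adjustment of the general-linear-hypothesis framework.
    """
    a = abs(float(t_obs))
    m = corr.shape[0]

    def _box(limit: float) -> float:
        # quasi-MC integration with a fixed stream so results are reproducible
        return float(
            stats.multivariate_normal.cdf(
                np.full(m, limit),
                mean=np.zeros(m),
                cov=corr,
                lower_limit=np.full(m, -limit),
                allow_singular=True,
                maxpts=10_000,
                abseps=1e-7,
                releps=0,
                rng=np.random.default_rng(1905),
            )
        )

    if df > 1e6 or not np.isfinite(df):
        return min(1.0, max(0.0, 1.0 - _box(a)))
    # integrate the normal rectangle probability over s ~ chi(df)/sqrt(df)
    nodes, weights = np.polynomial.legendre.leggauss(32)
    # map (0, 1) quantile scale: s = sqrt(chi2.ppf(q, df) / df)
    q = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    s = np.sqrt(stats.chi2.ppf(q, df) / df)
    total = sum(wi * _box(a * si) for si, wi in zip(s, w))
    return min(1.0, max(0.0, 1.0 - total))


def group_contrasts(
    fit: PreferenceModelFit, family: str, df: float | None = None
) -> ContrastResult:
    """Pairwise rater-group differences for one coefficient family.

    delta(A - B) is the difference of the group-specific coefficients, its SE
    comes from the fixed-effect covariance, and adjusted p-values are
    single-step max-|t| probabilities under the multivariate t with the
    contrasts' estimated correlation (the Tukey-style simultaneous test of
    the general-linear-hypothesis framework, applicable to slopes as well as
    means).  The reference df defaults to a containment-style choice,
    n_raters - n_groups: every rater-group contrast is a between-rater
    comparison, so the rater level bounds the information.
    """
    if not fit.converged:
        raise ValidationError("cannot compute contrasts from a non-converged fit")
    beta = fit.fixed_effects["estimate"].to_numpy()
    cov = fit.cov_fixed.to_numpy()
    pairs = [
        (a, b)
        for a, b in GROUP_PAIRS
        if a in fit.groups and b in fit.groups
    ]
    if df is None:
        df = max(fit.n_raters - len(fit.groups), 2)
    cvecs = []
    for a, b in pairs:
        cvecs.append(_effect_vector(fit, family, a) - _effect_vector(fit, family, b))
    c_mat = np.asarray(cvecs)
    deltas = c_mat @ beta
    cov_d = c_mat @ cov @ c_mat.T
    ses = np.sqrt(np.diag(cov_d))
    ts = deltas / ses
    corr = cov_d / np.outer(ses, ses)
    # numerical guard: force a valid correlation matrix
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    w, v = np.linalg.eigh(corr)
    corr = (v * np.clip(w, 1e-10, None)) @ v.T
    d = np.sqrt(np.diag(corr))
    corr = corr / np.outer(d, d)
    p_adj = np.array([_max_modulus_p(t, corr, df) for t in ts])
    table = pd.DataFrame(
        {
            "pair": [f"{a}-{b}" for a, b in pairs],
            "family": family,
            "delta": deltas,
            "se": ses,
            "t": ts,
            "df": float(df),
            "p_adj": p_adj,
        }
    )
    return ContrastResult(family=family, table=table)
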