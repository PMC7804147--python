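"""Interrater agreement, group-mean ratings, and the Pearson correlation screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from faceshape.landmark_io import ValidationError

__all__ = [
    "rater_by_face_matrix",
    "cronbach_alpha",
    "group_mean_ratings",
    "correlation_screen",
]


def rater_by_face_matrix(
    ratings: pd.DataFrame, rater_group: str | None = None, rater_sex: str | None = None
) -> pd.DataFrame:
    """Pivot long ratings into a raters x faces matrix (NaN where missing)."""
    df = ratings
    if rater_group is not None:
        df = df[df["rater_group"] == rater_group]
    if rater_sex is not None:
        df = df[df["rater_sex"] == rater_sex]
    if df.empty:
        raise ValidationError("no ratings match the requested group/sex")
    return df.pivot(index="rater_id", columns="face_id", values="rating")


def cronbach_alpha(matrix: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha for interrater agreement, raters as items.

    Raters with any missing cell are dropped (listwise deletion), then

        alpha = N/(N-1) * (1 - sum_r var_r / var_total)

    where N is the number of raters, var_r the sample variance (ddof=1) of
    rater r's scores across faces and var_total the variance across faces of
    the per-face sum over raters.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("rating matrix must be 2-D (raters x faces)")
    complete = ~np.isnan(arr).any(axis=1)
    arr = arr[complete]
    n_raters, n_faces = arr.shape
    if n_raters < 2 or n_faces < 2:
        raise ValidationError(
            f"need >= 2 complete raters and >= 2 faces, got {n_raters} x {n_faces}"
        )
    var_total = np.var(arr.sum(axis=0), ddof=1)
    if var_total == 0:
        raise ValidationError("total score variance is zero; alpha undefined")
    var_raters = np.var(arr, axis=1, ddof=1).sum()
    return float(n_raters / (n_raters - 1) * (1.0 - var_raters / var_total))


def group_mean_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean rating per (face, rater group), with counts.

    Returns a long table (face_id, rater_group, mean_rating, n_ratings).
    """
    if ratings.empty:
        raise ValidationError("ratings table is empty")
    out = (
        ratings.groupby(["face_id", "rater_group"], sort=True)["rating"]
        .agg(mean_rating="mean", n_ratings="count")
        .reset_index()
    )
    return out


def correlation_screen(
    score_table: pd.DataFrame,
    group_means: pd.DataFrame,
    method: str = "holm",
) -> pd.DataFrame:
    """Pearson zero-order correlations among attractiveness and face variables.

    Variables are the per-group mean attractiveness (one column per rater
    group, named ``attr_<group>``) plus age, bmi, sshd and avrg.  Two-sided
    p-values come from the t transform of r; the multiple-test adjustment
    (Holm by default, ``method="bonferroni"`` available) is applied across
    the full set of tested pairs.  Pairs involving a constant variable are
    flagged (r and p are NaN, ``degenerate`` True) and excluded from the
    adjustment.
    """
    if method not in ("holm", "bonferroni"):
        raise ValueError(f"unsupported adjustment method {method!r}")
    wide = group_means.pivot(index="face_id", columns="rater_group", values="mean_rating")
    wide.columns = [f"attr_{g}" for g in wide.columns]
    df = score_table.set_index("specimen_id").join(wide, how="inner")
    variables = list(wide.columns) + ["age", "bmi", "sshd", "avrg"]
    rows = []
    for i, v1 in enumerate(variables):
        for v2 in variables[i + 1 :]:
            sub = df[[v1, v2]].dropna()
            n = len(sub)
            if n < 4:
                raise ValidationError(f"pair ({v1}, {v2}): fewer than 4 complete cases")
            x, y = sub[v1].to_numpy(), sub[v2].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append((v1, v2, np.nan, np.nan, n, True))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((v1, v2, float(r), float(p), n, False))
    out = pd.DataFrame(
        rows, columns=["var1", "var2", "r", "p_raw", "n", "degenerate"]
    )
    ok = ~out["degenerate"]
    p_adj = np.full(len(out), np.nan)
    if ok.any():
        p_adj[ok.to_numpy()] = multipletests(out.loc[ok, "p_raw"], method=method)[1]
    out["p_adj"] = p_adj
    return out[["var1", "var2", "r", "p_raw", "p_adj", "n", "degenerate"]]
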