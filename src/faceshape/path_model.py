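"""Recursive path analysis with Monte-Carlo permutation p-values.

The model is a directed acyclic system over the observed variables age, BMI,
SShD, averageness and (group-mean) attractiveness; with no latent variables
a recursive path model is estimated equation-by-equation: each endogenous
variable is regressed by ordinary least squares on its parents after all
variables are z-standardized, which makes the coefficients the standardized
path coefficients (for a single-parent equation the coefficient equals the
Pearson correlation exactly).

Because such models are often fit at modest n, analytic p-values are
complemented by "robust" permutation p-values: each variable's column is
independently permuted (destroying all inter-variable association while
preserving marginals), the full model is refit on each randomized dataset,
and the two-sided tail probability of each observed coefficient is computed
with the add-one correction p = (1 + #{|b*| >= |b|}) / (n_perm + 1).
A residual-permutation variant (Freedman-Lane) is available for conditional
nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from faceshape.landmark_io import ValidationError

__all__ = [
    "DEFAULT_EDGES",
    "PathSpec",
    "PathFit",
    "fit_path_model",
    "permutation_pvalues",
    "to_dot",
]

#: Age is exogenous; BMI, SShD and averageness mediate between age and
#: attractiveness; SShD and averageness also mediate the BMI effect; age
#: keeps a direct path to attractiveness.
DEFAULT_EDGES: tuple[tuple[str, str], ...] = (
    ("age", "bmi"),
    ("age", "sshd"),
    ("age", "avrg"),
    ("age", "attractiveness"),
    ("bmi", "sshd"),
    ("bmi", "avrg"),
    ("bmi", "attractiveness"),
    ("sshd", "attractiveness"),
    ("avrg", "attractiveness"),
)


@dataclass
class PathSpec:
    """Directed edge list of a recursive (acyclic, latent-free) path model."""

    edges: tuple[tuple[str, str], ...] = DEFAULT_EDGES

    def __post_init__(self) -> None:
        g = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("path model edges must form a DAG")
        self.edges = tuple((str(a), str(b)) for a, b in self.edges)

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for a, b in self.edges:
            for v in (a, b):
                if v not in seen:
                    seen.append(v)
        return seen

    @property
    def parents(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a, b in self.edges:
            out.setdefault(b, []).append(a)
        return out


@dataclass
class PathFit:
    """Standardized path coefficients with analytic and permutation p-values."""

    edges: pd.DataFrame  # from, to, beta_std, se, p_analytic, p_perm
    r_squared: dict[str, float]
    n_observations: int
    n_perm: int | None = None
    seed: int | None = None
    condition_flags: dict[str, bool] = field(default_factory=dict)


def _standardized(
    data: pd.DataFrame, variables: list[str], standardized: bool = True
) -> np.ndarray:
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise ValidationError(f"data lacks path variables {missing}")
    sub = data[variables].dropna()
    x = sub.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValidationError(f"constant columns cannot enter the path model: {bad}")
    centered = x - x.mean(axis=0)
    return centered / sd if standardized else centered


def _equation_betas(z: np.ndarray, parent_idx: list[int], child_idx: int) -> np.ndarray:
    x = z[:, parent_idx]
    y = z[:, child_idx]
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return beta


def fit_path_model(
    data: pd.DataFrame, spec: PathSpec | None = None, standardized: bool = True
) -> PathFit:
    """Fit the recursive path model by equation-wise OLS on standardized data.

    For a recursive latent-free path model the equation-by-equation least
    squares solution coincides with the maximum-likelihood path solution, so
    no joint covariance-structure optimization is needed.  Analytic SEs and
    two-sided p-values come from the classical OLS t test of each equation
    (fit without an intercept on centered, unit-variance data).  With
    ``standardized=False`` variables are only centered, so coefficients stay
    on the raw scale of the inputs.
    """
    spec = spec or PathSpec()
    variables = spec.variables
    z = _standardized(data, variables, standardized)
    n = z.shape[0]
    parents = spec.parents
    max_parents = max(len(p) for p in parents.values())
    if n <= max_parents + 2:
        raise ValidationError(
            f"need n > largest equation size + 2 (= {max_parents + 2}), got n = {n}"
        )
    idx = {v: i for i, v in enumerate(variables)}
    by_edge: dict[tuple[str, str], tuple[float, float, float]] = {}
    r2: dict[str, float] = {}
    flags: dict[str, bool] = {}
    for child, pars in parents.items():
        pidx = [idx[p] for p in pars]
        x = z[:, pidx]
        y = z[:, idx[child]]
        cond = np.linalg.cond(x.T @ x)
        flags[child] = bool(cond > 1e8)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        dof = n - len(pars) - 1  # one df spent on the (implicit) intercept
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(x.T @ x)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore"):  # se = 0 for noise-free equations
            tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        ss_tot = float(y @ y)
        r2[child] = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan
        for p, b, s, pv in zip(pars, beta, se, pvals):
            by_edge[(p, child)] = (float(b), float(s), float(pv))
    edges = pd.DataFrame(
        [(a, b, *by_edge[(a, b)]) for a, b in spec.edges],
        columns=["from", "to", "beta_std", "se", "p_analytic"],
    )
    return PathFit(edges=edges, r_squared=r2, n_observations=n, condition_flags=flags)


def permutation_pvalues(
    data: pd.DataFrame,
    spec: PathSpec | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    scheme: str = "full",
) -> PathFit:
    """Permutation ("robust") p-values for every path coefficient.

    ``scheme="full"`` independently permutes every variable's column in each
    of the ``n_perm`` randomized datasets and refits the full model, giving
    the distribution of coefficients expected under no association at all;
    ``scheme="freedman_lane"`` permutes each equation's residuals under the
    reduced model instead (a conditional null per edge).  Two-sided p-values
    use the add-one correction, so they lie in [1/(n_perm+1), 1] and can
    never be zero.
    """
    if n_perm < 100:
        raise ValidationError(f"n_perm must be >= 100, got {n_perm}")
    if scheme not in ("full", "freedman_lane"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    spec = spec or PathSpec()
    observed = fit_path_model(data, spec)
    variables = spec.variables
    z = _standardized(data, variables)
    n = z.shape[0]
    idx = {v: i for i, v in enumerate(variables)}
    parents = spec.parents
    rng = np.random.default_rng(seed)

    obs_beta = observed.edges["beta_std"].to_numpy()
    edge_slices: list[tuple[str, list[int], int, slice]] = []
    pos = 0
    for child, pars in parents.items():
        pidx = [idx[p] for p in pars]
        edge_slices.append((child, pidx, idx[child], slice(pos, pos + len(pars))))
        pos += len(pars)
    # equation iteration order vs the declared edge order
    eq_order = [(p, child) for child, pars in parents.items() for p in pars]
    eq_pos = {e: i for i, e in enumerate(eq_order)}
    obs_in_eq_order = np.empty(len(eq_order))
    for i, (a, b) in enumerate(zip(observed.edges["from"], observed.edges["to"])):
        obs_in_eq_order[eq_pos[(a, b)]] = obs_beta[i]

    exceed_eq = np.zeros(len(eq_order), dtype=int)
    if scheme == "full":
        for _ in range(n_perm):
            zp = np.empty_like(z)
            for j in range(z.shape[1]):
                zp[:, j] = z[rng.permutation(n), j]
            for child, pidx, cidx, sl in edge_slices:
                beta = _equation_betas(zp, pidx, cidx)
                # tiny slack so floating-point ties (common at small n, where
                # permutations reproduce |beta| exactly) count as exceedances
                exceed_eq[sl] += np.abs(beta) >= np.abs(obs_in_eq_order[sl]) - 1e-12
    else:
        # Freedman-Lane: per equation, permute residuals of the reduced
        # (parent-free) model — on standardized data that reduces to
        # permuting the child column while keeping parents fixed.
        for _ in range(n_perm):
            for child, pidx, cidx, sl in edge_slices:
                zp_child = z[rng.permutation(n), cidx]
                x = z[:, pidx]
                beta, *_ = np.linalg.lstsq(x, zp_child, rcond=None)
                exceed_eq[sl] += np.abs(beta) >= np.abs(obs_in_eq_order[sl]) - 1e-12

    p_perm_eq = (1.0 + exceed_eq) / (n_perm + 1.0)
    p_perm = np.empty(len(obs_beta))
    for i, (a, b) in enumerate(zip(observed.edges["from"], observed.edges["to"])):
        p_perm[i] = p_perm_eq[eq_pos[(a, b)]]
    edges = observed.edges.copy()
    edges["p_perm"] = p_perm
    return PathFit(
        edges=edges,
        r_squared=observed.r_squared,
        n_observations=n,
        n_perm=n_perm,
        seed=seed,
        condition_flags=observed.condition_flags,
    )


def to_dot(fit: PathFit, alpha: float = 0.05, trend: float = 0.1) -> str:
    """DOT description of the fitted DAG with signed, significance-marked edges.

    Significant positive paths are green, significant negative paths red,
    p in [alpha, trend) is labeled as a nonsignificant trend (apostrophe),
    and p >= trend paths are gray.
    """
    lines = ["digraph path_model {", "  rankdir=LR;"]
    pcol = "p_perm" if "p_perm" in fit.edges.columns else "p_analytic"
    for _, row in fit.edges.iterrows():
        p = row[pcol]
        beta = row["beta_std"]
        if p < alpha:
            color = "green" if beta > 0 else "red"
            label = f"{beta:.2f}"
        elif p < trend:
            color = "green" if beta > 0 else "red"
            label = f"{beta:.2f}'"
        else:
            color = "gray"
            label = ""
        attr = f"color={color}" + (f', label="{label}"' if label else "")
        lines.append(f'  {row["from"]} -> {row["to"]} [{attr}];')
    lines.append("}")
    return "\n".join(lines)
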