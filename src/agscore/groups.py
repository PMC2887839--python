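"""Between-dose-group inference: covariate-adjusted group means of the AGS
with Bonferroni pairwise contrasts, chi-square tests on metaboliser-count
tables, and the two-mean sample-size calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .scoring import CountDistribution

__all__ = [
    "AdjustedMeans",
    "ChisqResult",
    "SampleSizeResult",
    "ancova_adjusted_means",
    "chisq_count_table",
    "sample_size_two_means",
]


@dataclass
class AdjustedMeans:
    """Covariate-adjusted group means of AGS with pairwise contrasts.

    Means are model predictions with every covariate held at its sample
    mean; contrast p-values carry Bonferroni multiplication for the three
    pairwise comparisons.
    """

    groups: tuple[str, ...]
    means: dict[str, float]
    se: dict[str, float]
    covariates: tuple[str, ...]
    contrasts: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    n_obs: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"adjusted_mean": self.means, "se": self.se}
        ).loc[list(self.groups)]


def ancova_adjusted_means(
    data: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "age"),
    response: str = "ags",
    group_col: str = "dose_group",
) -> AdjustedMeans:
    """One-way analysis of covariance of AGS on dose group.

    Fits a least-squares linear model of ``response`` on group indicators
    plus the covariates (sex enters as an indicator, age linearly, optional
    co-medication flags as 0/1).  Adjusted means are predictions at
    covariate means; all pairwise group contrasts are Wald-tested with
    Bonferroni correction (factor = number of pairs).

    Raises on a singular design, naming the collinear columns.
    """
    df = data.copy()
    if df[group_col].isna().any() or df[list(covariates)].isna().any().any():
        raise ValueError("group labels and covariates must be complete")
    groups = [g for g in ("low", "medium", "high") if g in set(df[group_col])]
    if len(groups) < 2:
        raise ValueError("ANCOVA needs at least two dose groups")
    for g in groups:
        if (df[group_col] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")

    terms = [f"C({group_col}, levels={groups!r})"]
    for c in covariates:
        terms.append(f"C({c})" if df[c].dtype == object else c)
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        raise ValueError(
            "singular ANCOVA design (collinear columns among "
            f"{model.exog_names}); is a group confounded with a covariate?"
        )
    fit = model.fit()

    # Design row per group with covariates at their sample means: average
    # the observed design rows after forcing every subject into that group.
    design_info = model.data.design_info
    from patsy import build_design_matrices

    xbar: dict[str, np.ndarray] = {}
    for g in groups:
        forced = df.copy()
        forced[group_col] = g
        (mat,) = build_design_matrices([design_info], forced)
        xbar[g] = np.asarray(mat).mean(axis=0)

    cov = fit.cov_params().to_numpy()
    beta = fit.params.to_numpy()
    means = {g: float(xbar[g] @ beta) for g in groups}
    se = {g: float(np.sqrt(xbar[g] @ cov @ xbar[g])) for g in groups}

    n_pairs = len(list(combinations(groups, 2)))
    contrasts: dict[tuple[str, str], dict[str, float]] = {}
    for g1, g2 in combinations(groups, 2):
        c = xbar[g2] - xbar[g1]
        tt = fit.t_test(c)
        p = float(tt.pvalue)
        contrasts[(g1, g2)] = {
            "estimate": float(tt.effect[0]),
            "se": float(tt.sd[0, 0]),
            "p_unadjusted": p,
            "p_bonferroni": min(1.0, n_pairs * p),
        }
    return AdjustedMeans(
        groups=tuple(groups),
        means=means,
        se=se,
        covariates=tuple(covariates),
        contrasts=contrasts,
        n_obs=int(fit.nobs),
    )


@dataclass
class ChisqResult:
    statistic: float
    df: int
    p_value: float
    method: str
    n_rows_used: int
    n_expected_below_5: int

    @property
    def small_cells_flagged(self) -> bool:
        return self.n_expected_below_5 > 0


def chisq_count_table(dist: CountDistribution, method: str = "pearson") -> ChisqResult:
    """Chi-square test of homogeneity on a groups-by-k count table.

    ``pearson``: the ordinary test of independence on the contingency table
    after dropping all-zero rows (no continuity correction); expected cells
    below 5 are counted and flagged, but no pooling is applied.
    ``trend``: the linear-by-linear association test on 1 df, treating both
    the genotype count k and the dose group as ordinal — better powered
    against the ordered alternatives this table layout invites, and far
    less sensitive to sparse outer cells.
    """
    table = dist.counts[dist.counts.sum(axis=1) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 retained rows and 2 groups")
    if method == "pearson":
        chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
        return ChisqResult(
            statistic=float(chi2),
            df=int(dof),
            p_value=float(p),
            method="pearson",
            n_rows_used=table.shape[0],
            n_expected_below_5=int((expected < 5).sum()),
        )
    if method == "trend":
        n_rows, n_cols = table.shape
        cells = [(i, j) for i in range(n_rows) for j in range(n_cols)]
        row_scores = np.concatenate([np.full(int(table[i, j]), i) for i, j in cells])
        col_scores = np.concatenate([np.full(int(table[i, j]), j) for i, j in cells])
        n = len(row_scores)
        r = np.corrcoef(row_scores, col_scores)[0, 1]
        m2 = (n - 1) * r * r
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        return ChisqResult(
            statistic=float(m2),
            df=1,
            p_value=float(stats.chi2.sf(m2, 1)),
            method="trend",
            n_rows_used=n_rows,
            n_expected_below_5=int((expected < 5).sum()),
        )
    raise ValueError(f"unknown method {method!r}")


@dataclass
class SampleSizeResult:
    n_per_group: int
    n_unrounded: float
    effect_size: float
    pooled_sd: float
    inputs: dict[str, float]


def sample_size_two_means(
    mean1: float,
    mean2: float,
    sd1: float,
    sd2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    sided: int = 2,
    sd_method: str = "pooled",
) -> SampleSizeResult:
    """Per-group n to detect a difference of two means, normal approximation.

    ``n = ceil(2 * (z_{1-alpha/side} + z_power)^2 / d^2)`` with
    ``d = |mean1 - mean2| / s`` and ``s`` either the root-mean-square of the
    two SDs (``pooled``, the equal-n pooled SD) or their plain average
    (``averaged``).  A zero effect size is an error (n would be infinite).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if sided not in (1, 2):
        raise ValueError("sided must be 1 or 2")
    if sd_method == "pooled":
        s = math.sqrt((sd1**2 + sd2**2) / 2.0)
    elif sd_method == "averaged":
        s = (sd1 + sd2) / 2.0
    else:
        raise ValueError(f"unknown sd_method {sd_method!r}")
    diff = abs(mean1 - mean2)
    if diff == 0:
        raise ValueError("zero effect size: required n is infinite")
    d = diff / s
    z_a = stats.norm.ppf(1 - alpha / sided)
    z_b = stats.norm.ppf(power)
    n = 2.0 * (z_a + z_b) ** 2 / d**2
    return SampleSizeResult(
        n_per_group=math.ceil(n),
        n_unrounded=float(n),
        effect_size=float(d),
        pooled_sd=float(s),
        inputs={
            "mean1": mean1,
            "mean2": mean2,
            "sd1": sd1,
            "sd2": sd2,
            "alpha": alpha,
            "power": power,
            "sided": sided,
        },
    )
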