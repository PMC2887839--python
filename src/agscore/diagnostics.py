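"""ROC analysis of the AGS as a dose-group classifier, Youden cut-off
discovery, and odds-ratio estimation for the dichotomised score.

The AUC is computed with the Mann-Whitney convention (tied case/control
pairs get half credit), which equals the trapezoid area under the empirical
ROC curve.  Confidence intervals for the AUC use the Hanley-McNeil standard
error by default, with DeLong's covariance-based estimator as an option.
Odds ratios come either from the 2x2 cross-product with a Woolf (log-scale)
interval, or from a maximum-likelihood logistic fit by iteratively
reweighted least squares.

Because the AGS is discrete (multiples of 10), candidate thresholds are
evaluated midway between adjacent observed scores and reported as the
inclusive bound on the observed scale, so a cut-off reads like ">70" for the
high-dose analysis or "<=60" for the low-dose one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RocCurve",
    "CutoffResult",
    "Association",
    "LogisticFit",
    "roc_curve",
    "youden_cutoff",
    "odds_ratio_2x2",
    "logistic_fit",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class CutoffResult:
    """A chosen ROC threshold: the midpoint actually evaluated, the
    paper-style inclusive bound on the observed score scale, and the
    operating characteristics achieved there."""

    threshold: float
    bound: float
    direction: str
    sensitivity: float
    specificity: float
    youden: float

    def describe(self) -> str:
        op = ">" if self.direction == "greater" else "<="
        return f"score {op} {self.bound:g}"


@dataclass
class RocCurve:
    """Empirical ROC curve with AUC, its CI, and a test against AUC = 0.5."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    auc_ci: tuple[float, float]
    p_value: float
    direction: str
    ci_method: str
    n_cases: int
    n_controls: int
    cutoff: Optional[CutoffResult] = None

    def plot(self, ax=None):
        """Plot the ROC curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fpr = 1.0 - self.specificity
        order = np.argsort(fpr, kind="stable")
        ax.plot(fpr[order], self.sensitivity[order], drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"AUC = {self.auc:.3f}")
        return ax


def _mann_whitney_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """AUC as the probability a random case outscores a random control,
    ties counting one half — computed by midranks, equal to the trapezoid
    area under the empirical curve."""
    pooled = np.concatenate([cases, controls])
    ranks = stats.rankdata(pooled)
    r_cases = ranks[: len(cases)].sum()
    n1, n0 = len(cases), len(controls)
    u = r_cases - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    return math.sqrt(max(var, 0.0))


def _delong_se(cases: np.ndarray, controls: np.ndarray) -> float:
    """DeLong placement-based variance of the AUC."""
    # V10[i] = P(case_i > control) with half credit for ties, and vice versa
    v10 = np.array(
        [np.mean((c > controls) + 0.5 * (c == controls)) for c in cases]
    )
    v01 = np.array(
        [np.mean((cases > c) + 0.5 * (cases == c)) for c in controls]
    )
    var = np.var(v10, ddof=1) / len(cases) + np.var(v01, ddof=1) / len(controls)
    return math.sqrt(max(var, 0.0))


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[int],
    direction: str = "greater",
    ci_method: str = "hanley",
) -> RocCurve:
    """Build the empirical ROC curve of ``scores`` against binary ``labels``.

    ``direction='greater'`` treats higher scores as indicating the positive
    class (a subject is test-positive when score > threshold);
    ``'less'`` flips the orientation (positive when score <= threshold),
    used for the low-dose analysis where low scores mark the cases.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be non-empty")

    sign = 1.0 if direction == "greater" else -1.0
    auc = _mann_whitney_auc(sign * cases, sign * controls)

    # Threshold sweep: midpoints between adjacent unique scores, plus
    # sentinels outside the observed range so the curve runs (0,0)->(1,1).
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.array([])
    lo, hi = uniq[0] - 1.0, uniq[-1] + 1.0
    thresholds = np.concatenate([[lo], mids, [hi]])
    sens = np.empty_like(thresholds)
    spec = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        positive = scores > t if direction == "greater" else scores <= t
        sens[i] = positive[labels == 1].mean()
        spec[i] = (~positive)[labels == 0].mean()

    if ci_method == "hanley":
        se = _hanley_mcneil_se(auc, len(cases), len(controls))
    elif ci_method == "delong":
        se = _delong_se(sign * cases, sign * controls)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    ci = (max(0.0, auc - Z95 * se), min(1.0, auc + Z95 * se))
    z = (auc - 0.5) / se if se > 0 else math.inf * np.sign(auc - 0.5)
    p = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0

    curve = RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_se=se,
        auc_ci=ci,
        p_value=float(p),
        direction=direction,
        ci_method=ci_method,
        n_cases=len(cases),
        n_controls=len(controls),
    )
    curve.cutoff = youden_cutoff(curve, scores)
    return curve


def youden_cutoff(curve: RocCurve, scores: Optional[Sequence[float]] = None) -> CutoffResult:
    """The threshold maximising Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher sensitivity, then toward the lower
    threshold.  The reported ``bound`` is the largest observed score at or
    below the chosen midpoint, so it reads as the inclusive bound
    (">bound" for direction 'greater', "<=bound" for 'less').
    """
    j = curve.sensitivity + curve.specificity - 1.0
    best = 0
    for i in range(1, len(curve.thresholds)):
        if (j[i], curve.sensitivity[i], -curve.thresholds[i]) > (
            j[best],
            curve.sensitivity[best],
            -curve.thresholds[best],
        ):
            best = i
    t = float(curve.thresholds[best])
    if scores is not None:
        obs = np.unique(np.asarray(scores, dtype=float))
        below = obs[obs <= t]
        bound = float(below[-1]) if len(below) else float(obs[0])
    else:
        bound = t
    return CutoffResult(
        threshold=t,
        bound=bound,
        direction=curve.direction,
        sensitivity=float(curve.sensitivity[best]),
        specificity=float(curve.specificity[best]),
        youden=float(j[best]),
    )


@dataclass
class Association:
    """An exposure-outcome association: 2x2 counts (a=exposed case,
    b=exposed control, c=unexposed case, d=unexposed control), the odds
    ratio with its 95% CI and two-sided p-value."""

    exposure: str
    table: tuple[float, float, float, float]
    odds_ratio: float
    ci: tuple[float, float]
    p_value: float
    method: str
    covariates: tuple[str, ...] = ()


def odds_ratio_2x2(
    table: Sequence[float], correction: str = "none", exposure: str = ""
) -> Association:
    """Odds ratio from a 2x2 table with Woolf 95% CI and Wald p-value.

    ``table`` is (a, b, c, d) = (exposed cases, exposed controls, unexposed
    cases, unexposed controls); OR = ad/bc.  ``correction='haldane'`` adds
    0.5 to every cell when any cell is zero; with ``'none'`` a zero cell is
    an error (the OR or its variance is undefined).
    """
    a, b, c, d = (float(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if correction not in ("none", "haldane"):
        raise ValueError(f"unknown correction {correction!r}")
    if correction == "haldane" and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        raise ValueError(
            "zero cell in the 2x2 table; use correction='haldane' or the logistic path"
        )
    oddsr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(oddsr)
    ci = (math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se))
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    return Association(
        exposure=exposure,
        table=(a, b, c, d),
        odds_ratio=float(oddsr),
        ci=ci,
        p_value=float(p),
        method=f"2x2 cross-product, Woolf CI ({correction})",
    )


@dataclass
class LogisticFit:
    """Full IRLS logistic fit: coefficients (intercept first), their
    standard errors, Wald statistics, and convergence diagnostics."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    n_iter: int
    converged: bool
    log_likelihood: float

    def wald(self, index: int) -> tuple[float, float]:
        z = self.coef[index] / self.se[index]
        return float(z), float(2.0 * stats.norm.sf(abs(z)))


def _irls_logistic(
    y: np.ndarray, x: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Newton-Raphson / IRLS for the binomial logit; returns (beta, cov,
    iterations, converged).  Convergence: max |score| < tol."""
    n, p = x.shape
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = x.T @ (y - mu)
        xtwx = x.T @ (x * w[:, None])
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular information matrix in IRLS: {exc}") from exc
        beta = beta + step
        if np.max(np.abs(score)) < tol:
            # score already inside tolerance; the step above is the final
            # quadratic-convergence polish
            converged = True
            break
        if np.max(np.abs(beta)) > 30:
            raise ValueError(
                "diverging coefficients: complete or quasi-separation; "
                "use odds_ratio_2x2 with correction='haldane' instead"
            )
    eta = np.clip(x @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(x.T @ (x * w[:, None]))
    return beta, cov, it, converged


def logistic_fit(
    outcome: Sequence[int],
    predictors: "np.ndarray | Sequence[Sequence[float]]",
    names: Optional[Sequence[str]] = None,
    exposure: str = "",
) -> Association:
    """Binary logistic regression by IRLS; OR for the first predictor.

    ``predictors`` is an (n, p) array whose first column is the exposure of
    interest (typically the dichotomised AGS); further columns are optional
    covariates such as co-medication flags.  An intercept is prepended.
    Returns the exposure association: OR = exp(beta_1), Wald 95% CI and
    two-sided p.  Complete or quasi-separation is a hard error advising the
    corrected 2x2 path.
    """
    y = np.asarray(outcome, dtype=float)
    xmat = np.atleast_2d(np.asarray(predictors, dtype=float))
    if xmat.shape[0] != len(y):
        xmat = xmat.T
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    x = np.column_stack([np.ones(len(y)), xmat])
    beta, cov, n_iter, converged = _irls_logistic(y, x)
    if not converged:
        raise ValueError("IRLS did not converge in 50 iterations (possible separation)")
    se = np.sqrt(np.diag(cov))
    log_or, s = beta[1], se[1]
    z = log_or / s
    p = 2.0 * stats.norm.sf(abs(z))
    cov_names = tuple(names[1:]) if names else tuple(f"x{i}" for i in range(2, x.shape[1]))
    return Association(
        exposure=exposure or (names[0] if names else "x1"),
        table=(math.nan,) * 4,
        odds_ratio=float(math.exp(log_or)),
        ci=(float(math.exp(log_or - Z95 * s)), float(math.exp(log_or + Z95 * s))),
        p_value=float(p),
        method=f"logistic regression (IRLS, {n_iter} iterations)",
        covariates=cov_names,
    )
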