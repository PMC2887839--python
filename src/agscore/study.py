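"""End-to-end study object: scoring -> dose grouping -> count tables and
chi-square tests -> covariate-adjusted group means -> ROC analyses (low- and
high-dose codings) -> dichotomised-score associations.

Modelled on the statsmodels idiom: :class:`AgsStudy` is built from data and
options, ``fit()`` runs the full analysis sequence and returns an
:class:`AgsStudyResults` carrying every estimate with its uncertainty, a
``summary()`` table, and JSON/TSV export.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import Association, RocCurve, logistic_fit, odds_ratio_2x2, roc_curve
from .groups import AdjustedMeans, ChisqResult, ancova_adjusted_means, chisq_count_table
from .io import build_cohort, load_score_map, read_genotype_table, read_phenotype_table
from .panel import Cohort, DOSE_GROUPS
from .scoring import CountDistribution, category_count_distribution, ags_table

__all__ = ["AgsStudy", "AgsStudyResults", "PipelineError", "run_pipeline"]

PathLike = Union[str, Path]


class PipelineError(RuntimeError):
    """An analysis-stage failure, prefixed with the stage name."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc

        return wrapped

    return deco


@dataclass
class AgsStudy:
    """The analysis model: a cohort plus the analysis options.

    Parameters
    ----------
    cohort
        Subjects with genotype profiles, doses and demographics, plus the
        marker panel and score map.
    covariates
        Covariates for the adjusted-means model (default sex and age).
    include_comedications
        Add each co-medication flag seen in the cohort as a 0/1 covariate.
    cutoff_low, cutoff_high
        Dichotomisation bounds for the association stage: exposure is
        ``AGS <= cutoff_low`` for the low-dose outcome and
        ``AGS > cutoff_high`` for the high-dose outcome.  These are
        data-derived quantities, not constants, hence options.
    seed
        Recorded in the provenance block (the analysis itself is
        deterministic given the cohort).
    """

    cohort: Cohort
    covariates: tuple[str, ...] = ("sex", "age")
    include_comedications: bool = False
    cutoff_low: float = 60.0
    cutoff_high: float = 70.0
    roc_ci_method: str = "hanley"
    seed: Optional[int] = None

    @classmethod
    def from_files(
        cls,
        genotypes: PathLike,
        phenotypes: PathLike,
        score_map: Optional[PathLike] = None,
        **options,
    ) -> "AgsStudy":
        """Build a study from a genotype table, phenotype table and
        score-map JSON (packaged default when omitted)."""
        panel, smap = load_score_map(score_map)
        profiles = read_genotype_table(genotypes, panel)
        pheno = read_phenotype_table(phenotypes)
        cohort = build_cohort(profiles, pheno, panel, smap)
        return cls(cohort=cohort, **options)

    def fit(self) -> "AgsStudyResults":
        """Run the full analysis sequence; any stage failure raises
        :class:`PipelineError` naming the stage."""
        scores = _stage("scoring")(ags_table)(self.cohort)
        if scores.empty:
            raise PipelineError("stage 'scoring': empty cohort")

        dists = {
            cat: _stage("count_distributions")(category_count_distribution)(
                self.cohort, cat
            )
            for cat in ("very_slow", "slow", "normal")
        }
        chisq = {
            cat: {
                method: _stage("chi_square")(chisq_count_table)(dist, method)
                for method in ("pearson", "trend")
            }
            for cat, dist in dists.items()
        }

        covs = list(self.covariates)
        df = scores.reset_index()
        if self.include_comedications:
            flags = sorted({c for s in self.cohort for c in s.comedications})
            for flag in flags:
                df[flag] = [
                    1 if flag in s.comedications else 0 for s in self.cohort
                ]
            covs.extend(flags)
        adjusted = _stage("ancova")(ancova_adjusted_means)(df, covariates=covs)

        ags = df["ags"].to_numpy()
        y_high = (df["dose_group"] == "high").astype(int).to_numpy()
        y_low = (df["dose_group"] == "low").astype(int).to_numpy()
        roc_high = _stage("roc_high")(roc_curve)(
            ags, y_high, direction="greater", ci_method=self.roc_ci_method
        )
        roc_low = _stage("roc_low")(roc_curve)(
            ags, y_low, direction="less", ci_method=self.roc_ci_method
        )

        assoc_high = _stage("association_high")(self._association)(
            ags > self.cutoff_high, y_high, f"AGS > {self.cutoff_high:g}"
        )
        assoc_low = _stage("association_low")(self._association)(
            ags <= self.cutoff_low, y_low, f"AGS <= {self.cutoff_low:g}"
        )

        provenance = {
            "package_version": __version__,
            "seed": self.seed,
            "n_subjects": len(self.cohort),
            "score_map_sha256": hashlib.sha256(
                json.dumps(self.cohort.score_map.as_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "options": {
                "covariates": covs,
                "cutoff_low": self.cutoff_low,
                "cutoff_high": self.cutoff_high,
                "roc_ci_method": self.roc_ci_method,
            },
        }
        return AgsStudyResults(
            model=self,
            scores=scores,
            count_distributions=dists,
            chisq=chisq,
            adjusted_means=adjusted,
            roc_low=roc_low,
            roc_high=roc_high,
            association_low=assoc_low,
            association_high=assoc_high,
            provenance=provenance,
        )

    def _association(
        self, exposed: np.ndarray, outcome: np.ndarray, label: str
    ) -> dict[str, Association]:
        """Both estimation routes for one dichotomised exposure: the 2x2
        cross-product and the IRLS logistic fit (which must agree on the
        saturated model); on separation the corrected 2x2 stands alone."""
        exposed = np.asarray(exposed, dtype=int)
        a = int(((exposed == 1) & (outcome == 1)).sum())
        b = int(((exposed == 1) & (outcome == 0)).sum())
        c = int(((exposed == 0) & (outcome == 1)).sum())
        d = int(((exposed == 0) & (outcome == 0)).sum())
        correction = "none" if min(a, b, c, d) > 0 else "haldane"
        out: dict[str, Association] = {
            "table_2x2": odds_ratio_2x2((a, b, c, d), correction=correction, exposure=label)
        }
        try:
            out["logistic"] = logistic_fit(
                outcome, exposed[:, None], names=[label], exposure=label
            )
        except ValueError:
            out["logistic"] = None  # separation; 2x2 with correction stands alone
        return out


@dataclass
class AgsStudyResults:
    """Fitted study: every estimate the analysis sequence produces."""

    model: AgsStudy
    scores: pd.DataFrame
    count_distributions: dict[str, CountDistribution]
    chisq: dict[str, dict[str, ChisqResult]]
    adjusted_means: AdjustedMeans
    roc_low: RocCurve
    roc_high: RocCurve
    association_low: dict[str, Optional[Association]]
    association_high: dict[str, Optional[Association]]
    provenance: dict = field(default_factory=dict)

    # -- presentation ----------------------------------------------------
    def group_summary(self) -> pd.DataFrame:
        g = self.scores.groupby("dose_group")
        out = pd.DataFrame(
            {
                "n": g.size(),
                "mean_ags": g["ags"].mean(),
                "sem_ags": g["ags"].sem(),
                "mean_dose": g["weekly_dose_mg"].mean(),
                "mean_age": g["age"].mean(),
                "pct_male": g["sex"].apply(lambda s: 100.0 * (s == "male").mean()),
            }
        )
        return out.loc[[x for x in DOSE_GROUPS if x in out.index]]

    def summary(self) -> str:
        lines = []
        w = lines.append
        w("Acenocoumarol-dose genotype score: study summary")
        w("=" * 60)
        w(f"subjects: {len(self.scores)}   groups (mg/week): low <7, medium 7-28, high >28")
        w("")
        w("Per-group AGS")
        w(self.group_summary().round(2).to_string())
        w("")
        w(f"Adjusted means (covariates: {', '.join(self.adjusted_means.covariates)})")
        w(self.adjusted_means.to_frame().round(2).to_string())
        for (g1, g2), c in self.adjusted_means.contrasts.items():
            w(
                f"  {g1} vs {g2}: diff={c['estimate']:+.2f}  "
                f"p(Bonferroni)={c['p_bonferroni']:.4f}"
            )
        w("")
        w("Metaboliser-count tables (chi-square)")
        for cat, methods in self.chisq.items():
            pe, tr = methods["pearson"], methods["trend"]
            flag = " [expected<5 present]" if pe.small_cells_flagged else ""
            w(
                f"  {cat:10s} Pearson chi2={pe.statistic:7.3f} df={pe.df:2d} "
                f"p={pe.p_value:.4f}{flag};  trend p={tr.p_value:.4f}"
            )
        w("")
        for label, curve in (("high-dose", self.roc_high), ("low-dose", self.roc_low)):
            cut = curve.cutoff
            w(
                f"ROC ({label} coding): AUC={curve.auc:.3f} "
                f"[{curve.auc_ci[0]:.3f}, {curve.auc_ci[1]:.3f}] p={curve.p_value:.4f}; "
                f"cut-off {cut.describe()} (sens={cut.sensitivity:.3f}, spec={cut.specificity:.3f})"
            )
        w("")
        for label, assoc in (
            ("high-dose", self.association_high),
            ("low-dose", self.association_low),
        ):
            t = assoc["table_2x2"]
            w(
                f"Association ({label}): {t.exposure}: OR={t.odds_ratio:.3f} "
                f"95%CI [{t.ci[0]:.3f}, {t.ci[1]:.3f}] p={t.p_value:.4f} ({t.method})"
            )
            lg = assoc.get("logistic")
            if lg is not None:
                w(
                    f"  logistic: OR={lg.odds_ratio:.3f} "
                    f"95%CI [{lg.ci[0]:.3f}, {lg.ci[1]:.3f}] p={lg.p_value:.4f}"
                )
        return "\n".join(lines)

    # -- export ----------------------------------------------------------
    def to_dict(self) -> dict:
        def assoc_dict(a: Optional[Association]):
            if a is None:
                return None
            return {
                "exposure": a.exposure,
                "table": list(a.table),
                "odds_ratio": a.odds_ratio,
                "ci95": list(a.ci),
                "p_value": a.p_value,
                "method": a.method,
            }

        def roc_dict(r: RocCurve):
            return {
                "auc": r.auc,
                "auc_se": r.auc_se,
                "auc_ci95": list(r.auc_ci),
                "p_value_vs_0.5": r.p_value,
                "direction": r.direction,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
                "cutoff": {
                    "bound": r.cutoff.bound,
                    "rule": r.cutoff.describe(),
                    "sensitivity": r.cutoff.sensitivity,
                    "specificity": r.cutoff.specificity,
                    "youden": r.cutoff.youden,
                },
            }

        return {
            "provenance": self.provenance,
            "group_summary": json.loads(self.group_summary().to_json(orient="index")),
            "adjusted_means": {
                "means": self.adjusted_means.means,
                "se": self.adjusted_means.se,
                "covariates": list(self.adjusted_means.covariates),
                "contrasts": {
                    f"{g1}_vs_{g2}": c
                    for (g1, g2), c in self.adjusted_means.contrasts.items()
                },
            },
            "chi_square": {
                cat: {
                    m: {
                        "statistic": r.statistic,
                        "df": r.df,
                        "p_value": r.p_value,
                        "n_expected_below_5": r.n_expected_below_5,
                    }
                    for m, r in methods.items()
                }
                for cat, methods in self.chisq.items()
            },
            "roc": {"high": roc_dict(self.roc_high), "low": roc_dict(self.roc_low)},
            "associations": {
                "high": {k: assoc_dict(v) for k, v in self.association_high.items()},
                "low": {k: assoc_dict(v) for k, v in self.association_low.items()},
            },
        }

    def save(self, outdir: PathLike) -> None:
        """Write report.json, report.txt and the intermediate tables."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        (out / "report.txt").write_text(self.summary() + "\n")
        self.scores.to_csv(out / "ags.tsv", sep="\t")
        counts = pd.concat(
            [d.to_frame() for d in self.count_distributions.values()], ignore_index=True
        )
        counts.to_csv(out / "metaboliser_counts.tsv", sep="\t", index=False)
        for name, curve in (("roc_high", self.roc_high), ("roc_low", self.roc_low)):
            pd.DataFrame(
                {
                    "threshold": curve.thresholds,
                    "sensitivity": curve.sensitivity,
                    "specificity": curve.specificity,
                }
            ).to_csv(out / f"{name}.tsv", sep="\t", index=False)


def run_pipeline(
    genotypes: PathLike,
    phenotypes: PathLike,
    score_map: Optional[PathLike] = None,
    **options,
) -> AgsStudyResults:
    """File-level convenience wrapper: build an :class:`AgsStudy` from the
    input files and fit it."""
    try:
        study = AgsStudy.from_files(genotypes, phenotypes, score_map, **options)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'input': {exc}") from exc
    return study.fit()
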