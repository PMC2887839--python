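"""The acenocoumarol-dose genotype score (AGS).

Each of the five panel polymorphisms contributes a genotype score
GS in {0, 1, 2} counting the alleles associated with higher stable
acenocoumarol dose (0 = very slow metaboliser, 1 = slow, 2 = normal).
The AGS is the normalised additive total

    AGS = 100 * sum(GS) / (2 * m)

for m scored markers, i.e. ``(100/10) * sum(GS)`` for the full five-marker
panel, giving a 0-100 score in steps of 10.  A profile scoring 100 carries,
at every marker, the genotype associated with the highest dose requirement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .panel import Cohort, DoseGroup, DOSE_GROUPS, GenotypeProfile, Polymorphism, ScoreMap

__all__ = [
    "AGSResult",
    "CountDistribution",
    "CATEGORY_SCORES",
    "genotype_score",
    "compute_ags",
    "ags_count_identity",
    "category_count_distribution",
    "mean_ags_from_marginals",
    "ags_table",
]

#: Metaboliser-category labels tied to GS values: a marker scored 0 is a
#: "very slow metaboliser" genotype (lowest dose), 2 a "normal" one.
CATEGORY_SCORES = {"very_slow": 0, "slow": 1, "normal": 2}


@dataclass
class AGSResult:
    """Per-subject scoring outcome: per-marker GS, raw sum, normalised AGS,
    and the counts of markers in each metaboliser category."""

    per_snp_gs: dict[str, Optional[int]]
    raw_sum: int
    ags: float
    n_very_slow: int
    n_slow: int
    n_normal: int
    n_missing: int

    @property
    def n_markers(self) -> int:
        return len(self.per_snp_gs)


def genotype_score(marker: Polymorphism, genotype: str, score_map: ScoreMap) -> int:
    """The configured GS in {0,1,2} for an unordered genotype at ``marker``."""
    return score_map.score(marker.key, genotype)


def compute_ags(
    profile: GenotypeProfile,
    panel: Sequence[Polymorphism],
    score_map: ScoreMap,
    strict: bool = False,
) -> AGSResult:
    """Score a profile over the panel and normalise to 0-100.

    With complete calls this is the published formula
    ``(100/10) * sum(GS)``; with missing calls the score is rescaled to the
    scored markers, ``100 * raw_sum / (2 * m_scored)``, preserving the 0-100
    interpretation (``strict=True`` refuses any missing call instead).
    A profile with no scorable marker is an error.
    """
    per_snp: dict[str, Optional[int]] = {}
    for p in panel:
        g = profile.get(p.key)
        if g is None:
            if strict:
                raise ValueError(f"missing genotype call at {p.key} (strict mode)")
            per_snp[p.key] = None
        else:
            per_snp[p.key] = score_map.score(p.key, g)
    scored = [s for s in per_snp.values() if s is not None]
    if not scored:
        raise ValueError("no scorable markers: all genotype calls are missing")
    raw = int(sum(scored))
    ags = 100.0 * raw / (2 * len(scored))
    return AGSResult(
        per_snp_gs=per_snp,
        raw_sum=raw,
        ags=ags,
        n_very_slow=sum(1 for s in scored if s == 0),
        n_slow=sum(1 for s in scored if s == 1),
        n_normal=sum(1 for s in scored if s == 2),
        n_missing=sum(1 for s in per_snp.values() if s is None),
    )


def ags_count_identity(result: AGSResult) -> dict[str, float]:
    """Check the two algebraic identities linking AGS to category counts.

    On a complete five-marker profile,
    ``ags = 10*(2*n_normal + n_slow)`` and equivalently
    ``ags = 10*(5 + n_normal - n_very_slow)``.  Returns both evaluations;
    any violation is an internal-consistency failure and raises.
    """
    if result.n_missing:
        raise ValueError("count identities require a complete profile")
    if result.n_markers != 5:
        raise ValueError("count identities are specific to the five-marker panel")
    via_sum = 10.0 * (2 * result.n_normal + result.n_slow)
    via_diff = 10.0 * (5 + result.n_normal - result.n_very_slow)
    if not (via_sum == via_diff == result.ags):
        raise AssertionError(
            f"AGS count identities violated: ags={result.ags}, "
            f"10*(2n2+n1)={via_sum}, 10*(5+n2-n0)={via_diff}"
        )
    return {"via_category_sum": via_sum, "via_category_difference": via_diff}


@dataclass
class CountDistribution:
    """Per dose group, the number of subjects carrying exactly k genotypes
    (k = 0..5) of one metaboliser category — one of the three tables of the
    published count layout."""

    category: str
    groups: tuple[str, ...]
    counts: np.ndarray  # shape (6, n_groups), rows k = 0..5

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (6, len(self.groups)):
            raise ValueError(
                f"counts must be 6 x {len(self.groups)}, got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def group_total(self, group: str) -> int:
        return int(self.counts[:, self.groups.index(group)].sum())

    def group_vector(self, group: str) -> np.ndarray:
        return self.counts[:, self.groups.index(group)].copy()

    def to_frame(self) -> pd.DataFrame:
        """Long-format serialisation: category, k, group, count."""
        rows = [
            {"category": self.category, "k": k, "group": g, "count": int(self.counts[k, j])}
            for j, g in enumerate(self.groups)
            for k in range(6)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, category: str) -> "CountDistribution":
        sub = df[df["category"] == category]
        if sub.empty:
            raise ValueError(f"no rows for category {category!r}")
        groups = tuple(g for g in DOSE_GROUPS if g in set(sub["group"]))
        counts = np.zeros((6, len(groups)), dtype=int)
        for _, row in sub.iterrows():
            counts[int(row["k"]), groups.index(row["group"])] = int(row["count"])
        return cls(category=category, groups=groups, counts=counts)


def category_count_distribution(cohort: Cohort, category: str) -> CountDistribution:
    """Count, per dose group, subjects with exactly k markers of a category.

    ``category`` is one of very_slow/slow/normal, keyed off GS values 0/1/2.
    Column sums equal the dose-group sizes.
    """
    if category not in CATEGORY_SCORES:
        raise ValueError(f"unknown category {category!r}; expected {sorted(CATEGORY_SCORES)}")
    target = CATEGORY_SCORES[category]
    counts = np.zeros((6, len(DOSE_GROUPS)), dtype=int)
    for subj in cohort:
        res = compute_ags(subj.profile, cohort.panel, cohort.score_map)
        k = sum(1 for s in res.per_snp_gs.values() if s == target)
        counts[k, DOSE_GROUPS.index(subj.dose_group)] += 1
    return CountDistribution(category=category, groups=DOSE_GROUPS, counts=counts)


def mean_ags_from_marginals(
    normal_dist: CountDistribution, slow_dist: CountDistribution, group: str
) -> float:
    """Expected mean AGS of a dose group from its category-count marginals.

    By linearity of the scoring formula, the group mean is
    ``10 * (2*E[n_normal] + E[n_slow])`` where the expectations are
    count-weighted means over k — valid whatever the joint distribution of
    the two counts.  Note the published marginal tables each omit one
    genotype per group, so the two algebraic forms of the mean differ
    slightly on that fixture.
    """
    n_total = normal_dist.group_total(group)
    s_total = slow_dist.group_total(group)
    if n_total != s_total:
        raise ValueError(
            f"marginal totals differ for group {group!r}: {n_total} vs {s_total}"
        )
    if n_total == 0:
        raise ValueError(f"group {group!r} is empty")
    k = np.arange(6)
    e_normal = float(k @ normal_dist.group_vector(group)) / n_total
    e_slow = float(k @ slow_dist.group_vector(group)) / s_total
    return 10.0 * (2.0 * e_normal + e_slow)


def ags_table(cohort: Cohort, strict: bool = False) -> pd.DataFrame:
    """Per-subject AGS table: one row per subject with marker GS columns,
    raw sum, AGS, category counts, dose and dose group."""
    rows = []
    for s in cohort:
        res = compute_ags(s.profile, cohort.panel, cohort.score_map, strict=strict)
        row = {"subject_id": s.id}
        for key in cohort.marker_keys:
            row[f"GS_{key}"] = res.per_snp_gs[key]
        row.update(
            raw_sum=res.raw_sum,
            ags=res.ags,
            n_very_slow=res.n_very_slow,
            n_slow=res.n_slow,
            n_normal=res.n_normal,
            n_missing=res.n_missing,
            weekly_dose_mg=s.weekly_dose,
            dose_group=s.dose_group,
            sex=s.sex,
            age=s.age,
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
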