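"""Domain types for pharmacogenetic marker panels and patient cohorts.

The package models a five-marker panel of biallelic CYP2C9/VKORC1
polymorphisms, each with an unordered genotype call per subject and a
configured genotype->score assignment (the score map).  Genotypes are
canonicalised to alphabetical allele order throughout, so ``"TC"`` and
``"CT"`` denote the same heterozygote.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Polymorphism",
    "ScoreMap",
    "GenotypeProfile",
    "Subject",
    "Cohort",
    "DoseGroup",
    "DOSE_GROUPS",
    "LOW_DOSE_MAX",
    "HIGH_DOSE_MIN",
    "classify_dose_group",
    "canonical_genotype",
]

#: Dose-group boundaries in mg acenocoumarol per week.  ``low`` is strictly
#: below 7, ``high`` strictly above 28; doses exactly on a boundary fall in
#: ``medium`` (the closed interval [7, 28]).
LOW_DOSE_MAX = 7.0
HIGH_DOSE_MIN = 28.0

DoseGroup = str
DOSE_GROUPS: tuple[DoseGroup, ...] = ("low", "medium", "high")


def canonical_genotype(genotype: str) -> str:
    """Return the genotype with its two allele characters sorted.

    Genotype calls are unordered (no phase information), so ``"GA"`` and
    ``"AG"`` are the same call; the canonical form is alphabetical.
    """
    if len(genotype) != 2:
        raise ValueError(f"genotype must be two allele characters, got {genotype!r}")
    a, b = sorted(genotype)
    return a + b


def classify_dose_group(weekly_dose: float) -> DoseGroup:
    """Assign a weekly acenocoumarol dose (mg/week) to low/medium/high.

    low: dose < 7; high: dose > 28; medium: the closed interval [7, 28].
    Boundary doses (exactly 7 or 28) are medium, complementing the strict
    inequalities that define the outer groups.
    """
    if weekly_dose < 0:
        raise ValueError(f"weekly dose must be nonnegative, got {weekly_dose}")
    if weekly_dose < LOW_DOSE_MAX:
        return "low"
    if weekly_dose > HIGH_DOSE_MIN:
        return "high"
    return "medium"


@dataclass(frozen=True)
class Polymorphism:
    """A biallelic SNP: short key (e.g. ``"CYP2C9*2"``), dbSNP rsID, gene
    symbol, and its unordered allele pair."""

    key: str
    rsid: str
    gene: str
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a == b:
            raise ValueError(f"{self.key}: alleles must be distinct, got {self.alleles}")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def genotypes(self) -> tuple[str, str, str]:
        """The three possible unordered genotypes, canonical order."""
        a, b = self.alleles
        return (a + a, a + b, b + b)


class ScoreMap:
    """Genotype -> score assignments for a panel of polymorphisms.

    Each marker maps its three genotypes (two homozygotes plus the
    heterozygote) to a genotype score in {0, 1, 2}: 0 = very slow
    metaboliser (lowest dose), 1 = slow (medium), 2 = normal (highest dose).
    """

    def __init__(self, scores: Mapping[str, Mapping[str, int]], panel: Sequence[Polymorphism]):
        by_key = {p.key: p for p in panel}
        if len(by_key) != len(panel):
            raise ValueError("duplicate marker keys in panel")
        rsids = {p.rsid for p in panel}
        if len(rsids) != len(panel):
            raise ValueError("duplicate rsIDs in panel")
        self._scores: dict[str, dict[str, int]] = {}
        for key, marker in by_key.items():
            if key not in scores:
                raise ValueError(f"score map missing marker {key!r}")
            entry = {canonical_genotype(g): int(s) for g, s in scores[key].items()}
            if set(entry) != set(marker.genotypes):
                raise ValueError(
                    f"{key}: score map must cover exactly the genotypes "
                    f"{marker.genotypes}, got {sorted(entry)}"
                )
            if not set(entry.values()) <= {0, 1, 2}:
                raise ValueError(f"{key}: scores must be in {{0,1,2}}, got {entry}")
            self._scores[key] = entry

    def score(self, key: str, genotype: str) -> int:
        """Score for a genotype at marker ``key``; order-insensitive."""
        try:
            table = self._scores[key]
        except KeyError:
            raise KeyError(f"marker {key!r} not in score map") from None
        g = canonical_genotype(genotype)
        if g not in table:
            raise ValueError(f"genotype {genotype!r} not scorable at {key}")
        return table[g]

    def genotype_for_score(self, key: str, score: int) -> str:
        """Inverse lookup: the genotype at ``key`` carrying ``score``."""
        for g, s in self._scores[key].items():
            if s == score:
                return g
        raise ValueError(f"no genotype with score {score} at {key}")

    def as_dict(self) -> dict[str, dict[str, int]]:
        return {k: dict(v) for k, v in self._scores.items()}

    def __contains__(self, key: str) -> bool:
        return key in self._scores


@dataclass
class GenotypeProfile:
    """Per-subject genotype calls keyed by marker key; ``None`` marks an
    explicitly missing call."""

    calls: dict[str, Optional[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = {
            k: (canonical_genotype(g) if g is not None else None)
            for k, g in self.calls.items()
        }

    def get(self, key: str) -> Optional[str]:
        return self.calls.get(key)

    def validate_against(self, panel: Sequence[Polymorphism]) -> None:
        keys = {p.key for p in panel}
        alleles = {p.key: set(p.alleles) for p in panel}
        for k, g in self.calls.items():
            if k not in keys:
                raise ValueError(f"profile references unknown marker {k!r}")
            if g is not None and not set(g) <= alleles[k]:
                raise ValueError(
                    f"genotype {g!r} at {k} uses characters outside the "
                    f"allele pair {sorted(alleles[k])}"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeProfile):
            return NotImplemented
        return self.calls == other.calls


@dataclass
class Subject:
    """One patient: stable weekly dose (mg/week), sex, age in years,
    co-medication flags, and the genotype profile."""

    id: str
    weekly_dose: float
    sex: str
    age: float
    profile: GenotypeProfile
    comedications: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.weekly_dose < 0:
            raise ValueError(f"subject {self.id}: weekly dose must be >= 0")
        if self.age <= 0:
            raise ValueError(f"subject {self.id}: age must be > 0")
        if self.sex not in ("male", "female"):
            raise ValueError(f"subject {self.id}: sex must be 'male' or 'female'")
        self.comedications = frozenset(self.comedications)

    @property
    def dose_group(self) -> DoseGroup:
        return classify_dose_group(self.weekly_dose)


@dataclass
class Cohort:
    """An ordered collection of subjects together with the marker panel and
    score map under which their profiles are interpreted."""

    subjects: list[Subject]
    panel: tuple[Polymorphism, ...]
    score_map: ScoreMap

    def __post_init__(self) -> None:
        self.panel = tuple(self.panel)
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")
        for s in self.subjects:
            s.profile.validate_against(self.panel)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterable[Subject]:
        return iter(self.subjects)

    @property
    def marker_keys(self) -> tuple[str, ...]:
        return tuple(p.key for p in self.panel)

    def group_sizes(self) -> dict[DoseGroup, int]:
        sizes = {g: 0 for g in DOSE_GROUPS}
        for s in self.subjects:
            sizes[s.dose_group] += 1
        return sizes
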