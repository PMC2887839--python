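"""Seeded synthetic-cohort generator.

Emulates the statistical structure the analysis assumes: dose groups of
fixed size, per-group genotype frequencies for each panel marker, uniform
dose sampling within each group's mg/week interval, and simple phenotype
distributions (sex ratio, normal age, Bernoulli co-medication flags).

Markers are sampled independently within a subject from each group's
genotype (not allele) frequencies — the observed per-group structure is
preserved without assuming Hardy-Weinberg equilibrium, but within-gene
linkage disequilibrium between the VKORC1 SNPs is not reproduced.  A
haplotype-style joint mode is available by passing joint genotype
frequencies over GS vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .io import default_panel
from .panel import Cohort, DoseGroup, DOSE_GROUPS, GenotypeProfile, Subject
from .scoring import CountDistribution

__all__ = [
    "SimulationConfig",
    "default_simulation_config",
    "simulate_cohort",
    "simulate_null_cohort",
    "table2_fixture",
]

_FREQ_TOL = 1e-9


@dataclass
class SimulationConfig:
    """Cohort-generation parameters.

    ``genotype_freqs[group][marker]`` is a probability triplet over the
    genotypes ordered by their score (GS 0, 1, 2); each triplet must sum to
    1 within 1e-9.  Dose ranges must be consistent with the <7 / [7,28] /
    >28 mg/week partition; the open-ended high group is capped (default
    twice the 28 mg/week threshold).
    """

    group_sizes: dict[DoseGroup, int]
    genotype_freqs: dict[DoseGroup, dict[str, tuple[float, float, float]]]
    dose_ranges: dict[DoseGroup, tuple[float, float]] = field(
        default_factory=lambda: {"low": (0.0, 7.0), "medium": (7.0, 28.0), "high": (28.0, 56.0)}
    )
    sex_male_fraction: float = 0.518
    age_mean: float = 64.0
    age_sd: float = 13.9
    comedication_prevalences: dict[str, float] = field(default_factory=dict)
    seed: int = 20100618

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in DOSE_GROUPS:
                raise ValueError(f"unknown dose group {g!r}")
            if n <= 0:
                raise ValueError(f"group size for {g!r} must be positive")
        for g in self.group_sizes:
            for marker, triplet in self.genotype_freqs[g].items():
                t = np.asarray(triplet, dtype=float)
                if t.shape != (3,) or (t < 0).any():
                    raise ValueError(f"{g}/{marker}: frequency triplet must be 3 nonnegative values")
                if abs(t.sum() - 1.0) > _FREQ_TOL:
                    raise ValueError(
                        f"{g}/{marker}: frequencies sum to {t.sum():.12f}, not 1"
                    )
        lo, hi = self.dose_ranges["low"], self.dose_ranges["high"]
        mid = self.dose_ranges["medium"]
        if not (0 <= lo[0] < lo[1] <= 7.0):
            raise ValueError("low-group dose range must sit inside [0, 7)")
        if not (7.0 <= mid[0] < mid[1] <= 28.0):
            raise ValueError("medium-group dose range must sit inside [7, 28]")
        if not (28.0 <= hi[0] < hi[1]):
            raise ValueError("high-group dose range must sit above 28")


def default_simulation_config(seed: Optional[int] = None) -> SimulationConfig:
    """The packaged configuration: observed group sizes (34/141/18),
    per-group genotype frequencies, and cohort demographics.

    One printed frequency (rs9923231, high-dose GG) is restored from an
    evident typo and every triplet is renormalised to sum exactly to 1; the
    adjustments are listed in the config file's ``notes``.
    """
    text = resources.files("agscore.data").joinpath("simulation_default.json").read_text()
    doc = json.loads(text)
    freqs: dict[str, dict[str, tuple[float, float, float]]] = {}
    for group, markers in doc["genotype_freqs_percent"].items():
        freqs[group] = {}
        for marker, triplet in markers.items():
            t = np.asarray(triplet, dtype=float)
            t = t / t.sum()
            freqs[group][marker] = tuple(t)
    cfg = SimulationConfig(
        group_sizes={g: int(n) for g, n in doc["group_sizes"].items()},
        genotype_freqs=freqs,
        dose_ranges={g: tuple(r) for g, r in doc["dose_ranges"].items()},
        sex_male_fraction=float(doc["sex_male_fraction"]),
        age_mean=float(doc["age_mean"]),
        age_sd=float(doc["age_sd"]),
        comedication_prevalences=dict(doc["comedication_prevalences"]),
        seed=int(doc["seed"]) if seed is None else int(seed),
    )
    cfg.validate()
    return cfg


def _sample_group(
    group: DoseGroup,
    n: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    panel,
    score_map,
    start_index: int,
) -> list[Subject]:
    lo, hi = config.dose_ranges[group]
    if group == "high":
        # strictly above the 28 mg/week threshold
        doses = rng.uniform(np.nextafter(lo, hi), hi, size=n)
    elif group == "low":
        doses = rng.uniform(lo, np.nextafter(hi, lo), size=n)
    else:
        doses = rng.uniform(lo, hi, size=n)
    sexes = np.where(rng.random(n) < config.sex_male_fraction, "male", "female")
    ages = rng.normal(config.age_mean, config.age_sd, size=n)
    ages = np.clip(ages, 18.0, 100.0)
    gs_by_marker = {}
    for p in panel:
        probs = np.asarray(config.genotype_freqs[group][p.key], dtype=float)
        gs_by_marker[p.key] = rng.choice(3, size=n, p=probs)
    comed_draws = {
        drug: rng.random(n) < prev for drug, prev in config.comedication_prevalences.items()
    }
    subjects = []
    for i in range(n):
        calls = {
            p.key: score_map.genotype_for_score(p.key, int(gs_by_marker[p.key][i]))
            for p in panel
        }
        comeds = frozenset(d for d, mask in comed_draws.items() if mask[i])
        subjects.append(
            Subject(
                id=f"S{start_index + i:04d}",
                weekly_dose=float(doses[i]),
                sex=str(sexes[i]),
                age=float(ages[i]),
                profile=GenotypeProfile(calls),
                comedications=comeds,
            )
        )
    return subjects


def simulate_cohort(
    config: SimulationConfig, seed: Optional[int] = None
) -> Cohort:
    """Draw a cohort under ``config``; fully reproducible for a given seed.

    Subjects are generated group by group (low, medium, high): dose uniform
    within the group interval, genotypes independent across markers from the
    group's triplets, sex/age/co-medications as configured.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    panel, score_map = default_panel()
    subjects: list[Subject] = []
    idx = 0
    for group in DOSE_GROUPS:
        n = config.group_sizes.get(group, 0)
        if n:
            subjects.extend(
                _sample_group(group, n, config, rng, panel, score_map, idx)
            )
            idx += n
    return Cohort(subjects=subjects, panel=panel, score_map=score_map)


def pooled_frequencies(config: SimulationConfig) -> dict[str, tuple[float, float, float]]:
    """Size-weighted average of the per-group genotype triplets."""
    total = sum(config.group_sizes.values())
    markers = next(iter(config.genotype_freqs.values())).keys()
    pooled = {}
    for m in markers:
        acc = np.zeros(3)
        for g, n in config.group_sizes.items():
            acc += n * np.asarray(config.genotype_freqs[g][m], dtype=float)
        pooled[m] = tuple(acc / total)
    return pooled


def simulate_null_cohort(
    config: SimulationConfig, seed: Optional[int] = None
) -> Cohort:
    """Cohort with genotype frequencies forced identical across dose groups
    (the pooled averages), so the AGS is independent of dose group — the
    reference condition for type-I-error and AUC = 0.5 checks."""
    pooled = pooled_frequencies(config)
    null_cfg = replace(
        config,
        genotype_freqs={g: dict(pooled) for g in config.group_sizes},
    )
    return simulate_cohort(null_cfg, seed=seed)


def table2_fixture() -> tuple[dict[str, CountDistribution], dict[DoseGroup, int]]:
    """The published metaboliser-count tables as packaged data.

    Returns the three CountDistributions (very_slow, slow, normal) over the
    low/medium/high dose groups, plus the group sizes (34, 141, 18).  The
    medium group is 141 per the internal counts; the published column header
    prints 142, inconsistent with the stated cohort size of 193.
    """
    text = resources.files("agscore.data").joinpath("metaboliser_counts.tsv").read_text()
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t")
    dists = {
        cat: CountDistribution.from_frame(df, cat)
        for cat in ("very_slow", "slow", "normal")
    }
    sizes = {g: dists["normal"].group_total(g) for g in DOSE_GROUPS}
    return dists, sizes
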