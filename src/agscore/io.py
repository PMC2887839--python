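"""Readers and writers for genotype tables, phenotype tables, VCF subsets
and score-map configuration.

File dialects
-------------
Genotype table
    UTF-8 delimited text (comma or tab, autodetected from the header line),
    header ``subject_id`` plus one column per marker key or rsID.  Genotype
    cells are two allele characters, order-insensitive; an empty cell is an
    explicitly missing call.
Phenotype table
    Delimited text with columns ``subject_id``, ``weekly_dose_mg``, ``sex``,
    ``age``, plus zero or more 0/1 co-medication columns.
VCF
    Standard VCF 4.x; records are matched to the panel by rsID (the ID
    column), never by coordinates, and only the GT subfield is consulted.
    No strand flipping is attempted: a REF/ALT pair that does not equal the
    panel's allele pair is an error, never a silent complement (A/T and C/G
    markers make silent flipping unsafe).
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import pysam

from .panel import (
    Cohort,
    GenotypeProfile,
    Polymorphism,
    ScoreMap,
    Subject,
    canonical_genotype,
)

logger = logging.getLogger("agscore")

PathLike = Union[str, Path]

__all__ = [
    "load_score_map",
    "default_panel",
    "read_genotype_table",
    "write_genotype_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_vcf_subset",
    "build_cohort",
]


def load_score_map(path: Optional[PathLike] = None) -> tuple[tuple[Polymorphism, ...], ScoreMap]:
    """Load a panel + score map from JSON; the packaged default if no path.

    The JSON document carries one object per marker: key, rsid, gene, the
    allele pair, and the three genotype->score entries.
    """
    if path is None:
        text = resources.files("agscore.data").joinpath("score_map.json").read_text()
    else:
        text = Path(path).read_text()
    doc = json.loads(text)
    panel = tuple(
        Polymorphism(
            key=m["key"], rsid=m["rsid"], gene=m["gene"], alleles=tuple(m["alleles"])
        )
        for m in doc["panel"]
    )
    score_map = ScoreMap({m["key"]: m["scores"] for m in doc["panel"]}, panel)
    return panel, score_map


def default_panel() -> tuple[tuple[Polymorphism, ...], ScoreMap]:
    """The packaged five-marker CYP2C9/VKORC1 panel and its score map."""
    return load_score_map(None)


def _detect_sep(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def _resolve_marker_columns(
    columns: Sequence[str], panel: Sequence[Polymorphism]
) -> dict[str, str]:
    """Map table column names to marker keys, matching by key or rsID."""
    lookup: dict[str, str] = {}
    for p in panel:
        lookup[p.key] = p.key
        lookup[p.rsid] = p.key
    resolved: dict[str, str] = {}
    for col in columns:
        if col == "subject_id":
            continue
        if col in lookup:
            resolved[col] = lookup[col]
        else:
            logger.warning("ignoring unknown genotype-table column %r", col)
    return resolved


def read_genotype_table(
    path: PathLike, panel: Sequence[Polymorphism]
) -> dict[str, GenotypeProfile]:
    """Read per-subject genotype calls from delimited text.

    Returns profiles keyed by subject id.  Malformed genotypes (characters
    outside the marker's allele pair) and duplicate subject ids are hard
    errors naming the offending row and column.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
    sep = _detect_sep(header)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: genotype table must have a 'subject_id' column")
    colmap = _resolve_marker_columns(df.columns, panel)
    alleles = {p.key: set(p.alleles) for p in panel}
    profiles: dict[str, GenotypeProfile] = {}
    for _, row in df.iterrows():
        sid = row["subject_id"].strip()
        if sid in profiles:
            raise ValueError(f"{path}: duplicate subject id {sid!r}")
        calls: dict[str, Optional[str]] = {}
        for col, key in colmap.items():
            cell = row[col].strip()
            if cell == "":
                calls[key] = None
                continue
            if len(cell) != 2 or not set(cell) <= alleles[key]:
                raise ValueError(
                    f"{path}: malformed genotype {cell!r} for subject {sid!r} "
                    f"in column {col!r} (alleles {sorted(alleles[key])})"
                )
            calls[key] = canonical_genotype(cell)
        profiles[sid] = GenotypeProfile(calls)
    return profiles


def write_genotype_table(
    path: PathLike,
    profiles: dict[str, GenotypeProfile],
    panel: Sequence[Polymorphism],
    sep: str = "\t",
) -> None:
    """Write profiles in the genotype-table dialect (empty cell = missing)."""
    keys = [p.key for p in panel]
    rows = []
    for sid, prof in profiles.items():
        row = {"subject_id": sid}
        for k in keys:
            g = prof.get(k)
            row[k] = "" if g is None else g
        rows.append(row)
    pd.DataFrame(rows, columns=["subject_id", *keys]).to_csv(path, sep=sep, index=False)


def read_phenotype_table(path: PathLike) -> pd.DataFrame:
    """Read the phenotype table; returns a DataFrame indexed by subject_id.

    Required columns: subject_id, weekly_dose_mg, sex, age.  Any additional
    column is interpreted as a 0/1 co-medication flag.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty phenotype file")
    sep = _detect_sep(header)
    df = pd.read_csv(path, sep=sep)
    required = {"subject_id", "weekly_dose_mg", "sex", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: phenotype table has no rows")
    df["subject_id"] = df["subject_id"].astype(str)
    return df.set_index("subject_id")


def write_phenotype_table(path: PathLike, df: pd.DataFrame, sep: str = "\t") -> None:
    df.reset_index().to_csv(path, sep=sep, index=False)


def read_vcf_subset(
    path: PathLike, panel: Sequence[Polymorphism]
) -> dict[str, GenotypeProfile]:
    """Read genotype calls for the panel's rsIDs from a VCF file.

    GT fields are translated to unordered allele-pair genotypes using the
    record's REF/ALT symbols; phasing is ignored.  Records whose ID is not
    in the panel are skipped; panel markers absent from the VCF are missing
    for every sample (logged).  Multi-allelic records matching a panel rsID,
    and REF/ALT pairs that differ from the panel's allele pair, are errors.
    """
    by_rsid = {p.rsid: p for p in panel}
    seen: set[str] = set()
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        profiles = {s: GenotypeProfile({}) for s in samples}
        for rec in vcf:
            marker = by_rsid.get(rec.id)
            if marker is None:
                continue
            alts = rec.alts or ()
            if len(alts) != 1:
                raise ValueError(
                    f"{path}: record {rec.id} is multi-allelic (ALT={','.join(alts) or '.'})"
                )
            symbols = (rec.ref, alts[0])
            if set(symbols) != set(marker.alleles):
                raise ValueError(
                    f"{path}: record {rec.id} REF/ALT {symbols} does not match the "
                    f"panel allele pair {marker.alleles}; strand flipping is not attempted"
                )
            seen.add(marker.key)
            for s in samples:
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    profiles[s].calls[marker.key] = None
                    continue
                genotype = "".join(symbols[a] for a in gt)
                profiles[s].calls[marker.key] = canonical_genotype(genotype)
    for p in panel:
        if p.key not in seen:
            logger.warning("panel marker %s (%s) absent from VCF; missing for all samples", p.key, p.rsid)
            for s in samples:
                profiles[s].calls[p.key] = None
    return profiles


def build_cohort(
    profiles: dict[str, GenotypeProfile],
    phenotypes: pd.DataFrame,
    panel: Sequence[Polymorphism],
    score_map: ScoreMap,
) -> Cohort:
    """Join genotype profiles with phenotypes into a Cohort.

    Subjects present in both tables are kept, in phenotype-table order;
    co-medication flags are every extra 0/1 phenotype column set to 1.
    """
    comed_cols = [
        c for c in phenotypes.columns if c not in ("weekly_dose_mg", "sex", "age")
    ]
    subjects = []
    for sid, row in phenotypes.iterrows():
        if sid not in profiles:
            logger.warning("subject %s has phenotypes but no genotypes; dropped", sid)
            continue
        comeds = frozenset(c for c in comed_cols if int(row[c]) == 1)
        subjects.append(
            Subject(
                id=str(sid),
                weekly_dose=float(row["weekly_dose_mg"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                profile=profiles[sid],
                comedications=comeds,
            )
        )
    return Cohort(subjects=subjects, panel=tuple(panel), score_map=score_map)
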