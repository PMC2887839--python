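"""Domain types, dose-group partition, and file-format round trips."""

import textwrap

import pytest
from hypothesis import given, settings, strategies as st

from agscore import (
    classify_dose_group,
    read_genotype_table,
    read_phenotype_table,
    read_vcf_subset,
    write_genotype_table,
)
from agscore.panel import Cohort, GenotypeProfile, Polymorphism, ScoreMap, Subject


@pytest.mark.parametrize(
    "dose,group",
    [
        (6.9, "low"),
        (0.0, "low"),
        (7.0, "medium"),  # boundary doses fall in the closed middle interval
        (28.0, "medium"),
        (28.5, "high"),
        (15.0, "medium"),
    ],
)
def test_dose_group_boundaries(dose, group):
    assert classify_dose_group(dose) == group


def test_negative_dose_rejected():
    with pytest.raises(ValueError):
        classify_dose_group(-0.1)


@settings(max_examples=200, derandomize=True)
@given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
def test_dose_partition_is_exhaustive_and_exclusive(dose):
    """Every nonnegative dose lands in exactly one group."""
    group = classify_dose_group(dose)
    memberships = [dose < 7, 7 <= dose <= 28, dose > 28]
    assert sum(memberships) == 1
    assert ["low", "medium", "high"][memberships.index(True)] == group


def test_polymorphism_rejects_equal_alleles():
    with pytest.raises(ValueError):
        Polymorphism(key="X", rsid="rs1", gene="G", alleles=("A", "A"))


def test_score_map_requires_full_genotype_coverage(panel):
    marker = panel[0]
    with pytest.raises(ValueError, match="cover exactly"):
        ScoreMap({marker.key: {"CC": 2, "CT": 1}}, [marker])


def test_duplicate_subject_ids_rejected(panel, smap, make_profile):
    subj = lambda i: Subject(
        id="S1", weekly_dose=10, sex="male", age=60, profile=make_profile((2,) * 5)
    )
    with pytest.raises(ValueError, match="duplicate"):
        Cohort(subjects=[subj(0), subj(1)], panel=panel, score_map=smap)


# ---------------------------------------------------------------- tables


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(textwrap.dedent(text))
    return p


def test_genotype_table_parse_and_symmetry(tmp_path, panel):
    path = _write(
        tmp_path,
        "g.csv",
        """\
        subject_id,CYP2C9*2,CYP2C9*3,VKORC1_-1639G>A,VKORC1_497T>G,VKORC1_1173C>T
        S1,CC,AA,GG,TT,CC
        S2,TC,CA,AG,GT,TC
        S3,,AA,GG,TT,CC
        """,
    )
    profiles = read_genotype_table(path, panel)
    assert profiles["S1"].calls["CYP2C9*2"] == "CC"
    # order-insensitive: "TC" is the same call as "CT"
    assert profiles["S2"].calls["CYP2C9*2"] == "CT"
    assert profiles["S2"].calls["CYP2C9*3"] == "AC"
    assert profiles["S3"].calls["CYP2C9*2"] is None


def test_genotype_table_rsid_headers(tmp_path, panel):
    path = _write(
        tmp_path,
        "g.tsv",
        """\
        subject_id\trs1799853\trs1057910\trs9923231\trs2884737\trs9934438
        S1\tCC\tAA\tGG\tTT\tCC
        """,
    )
    profiles = read_genotype_table(path, panel)
    assert profiles["S1"].calls["VKORC1_-1639G>A"] == "GG"


def test_genotype_table_malformed_cell_names_row_and_column(tmp_path, panel):
    path = _write(
        tmp_path,
        "g.csv",
        """\
        subject_id,CYP2C9*2
        S1,NN
        """,
    )
    with pytest.raises(ValueError, match=r"S1.*CYP2C9\*2"):
        read_genotype_table(path, panel)


def test_genotype_table_duplicate_subject(tmp_path, panel):
    path = _write(
        tmp_path,
        "g.csv",
        """\
        subject_id,CYP2C9*2
        S1,CC
        S1,CT
        """,
    )
    with pytest.raises(ValueError, match="duplicate"):
        read_genotype_table(path, panel)


def test_unknown_column_warns_but_parses(tmp_path, panel, caplog):
    path = _write(
        tmp_path,
        "g.csv",
        """\
        subject_id,CYP2C9*2,rs0000000
        S1,CC,AA
        """,
    )
    with caplog.at_level("WARNING", logger="agscore"):
        profiles = read_genotype_table(path, panel)
    assert "rs0000000" in caplog.text
    assert profiles["S1"].calls == {"CYP2C9*2": "CC"}


def test_genotype_table_round_trip(tmp_path, panel, make_profile):
    profiles = {
        "S1": make_profile((2, 2, 2, 2, 2)),
        "S2": make_profile((0, 1, 2, 0, 1)),
        "S3": GenotypeProfile({"CYP2C9*2": None, "CYP2C9*3": "AA"}),
    }
    # writer emits every panel column; absent keys become missing
    out = tmp_path / "rt.tsv"
    write_genotype_table(out, profiles, panel)
    back = read_genotype_table(out, panel)
    assert back["S1"] == profiles["S1"]
    assert back["S2"] == profiles["S2"]
    assert back["S3"].calls["CYP2C9*3"] == "AA"
    assert back["S3"].calls["CYP2C9*2"] is None


# ---------------------------------------------------------------- VCF

VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""


def _vcf(tmp_path, body):
    p = tmp_path / "x.vcf"
    p.write_text(VCF_HEADER + body)
    return p


def test_vcf_matches_genotype_table_encoding(tmp_path, panel):
    path = _vcf(
        tmp_path,
        "10\t1\trs1799853\tC\tT\t.\t.\t.\tGT\t0/0\t0/1\n"
        "10\t2\trs1057910\tA\tC\t.\t.\t.\tGT\t0/0\t1|1\n"
        "16\t3\trs9923231\tG\tA\t.\t.\t.\tGT\t0/1\t1/0\n"
        "16\t4\trs2884737\tT\tG\t.\t.\t.\tGT\t0/0\t./.\n"
        "16\t5\trs9934438\tC\tT\t.\t.\t.\tGT\t0/0\t0/0\n",
    )
    vcf_profiles = read_vcf_subset(path, panel)
    table = _write(
        tmp_path,
        "same.csv",
        """\
        subject_id,rs1799853,rs1057910,rs9923231,rs2884737,rs9934438
        S1,CC,AA,GA,TT,CC
        S2,CT,CC,AG,,CC
        """,
    )
    table_profiles = read_genotype_table(table, panel)
    assert vcf_profiles == table_profiles
    # phase-insensitive decode and unordered canonicalisation
    assert vcf_profiles["S2"].calls["CYP2C9*3"] == "CC"
    assert vcf_profiles["S1"].calls["VKORC1_-1639G>A"] == "AG"


def test_vcf_multiallelic_record_rejected(tmp_path, panel):
    path = _vcf(tmp_path, "16\t4\trs2884737\tT\tG,A\t.\t.\t.\tGT\t0/1\t0/0\n")
    with pytest.raises(ValueError, match="multi-allelic"):
        read_vcf_subset(path, panel)


def test_vcf_allele_mismatch_rejected_not_flipped(tmp_path, panel):
    # complement of the panel pair: must error, never silently strand-flip
    path = _vcf(tmp_path, "10\t1\trs1799853\tG\tA\t.\t.\t.\tGT\t0/1\t0/0\n")
    with pytest.raises(ValueError, match="strand"):
        read_vcf_subset(path, panel)


def test_vcf_absent_marker_is_missing_for_all(tmp_path, panel, caplog):
    path = _vcf(tmp_path, "10\t1\trs1799853\tC\tT\t.\t.\t.\tGT\t0/0\t0/1\n")
    with caplog.at_level("WARNING", logger="agscore"):
        profiles = read_vcf_subset(path, panel)
    assert profiles["S1"].calls["CYP2C9*3"] is None
    assert "rs1057910" in caplog.text


# ---------------------------------------------------------------- phenotypes


def test_phenotype_table_requires_columns(tmp_path):
    path = _write(tmp_path, "p.csv", "subject_id,weekly_dose_mg\nS1,10\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_phenotype_table(path)


def test_phenotype_table_empty_file(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("")
    with pytest.raises(ValueError, match="empty"):
        read_phenotype_table(path)
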