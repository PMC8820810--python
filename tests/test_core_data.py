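import textwrap

import pytest

from gxepi import (
    DataFormatError,
    GenotypeCall,
    SNPDefinition,
    ValidationError,
    read_genotypes,
    read_panel,
    read_participants,
    write_genotypes,
    write_panel,
    write_participants,
)

HEADER = ("participant_id,is_case,stratum_id,hospital_id,period_id,age,sex,"
          "arthrosis,h_pylori,gi_history,ppi_use,antiaggregant_use,"
          "anticoagulant_use,n_interviews,interview_reliability")


def _write(tmp_path, rows, name="participants.csv"):
    path = tmp_path / name
    path.write_text(HEADER + "\n" + "\n".join(rows) + "\n")
    return path


GOOD_ROWS = [
    "c1,1,s1,h1,t1,60,male,0,yes,ulcer,0,0,0,1,8",
    "k1,0,s1,h1,t1,62,male,1,no_or_uncertain,none_or_dyspepsia,0,0,0,1,9",
    "k2,0,s1,h1,t1,58,male,0,yes,none_or_dyspepsia,1,0,1,2,7",
]


def test_well_formed_table_loads_without_rejections(tmp_path):
    result = read_participants(_write(tmp_path, GOOD_ROWS))
    assert len(result.records) == 3
    assert result.rejected == []
    assert result.records[0].gi_history == "ulcer"
    assert result.records[2].anticoagulant_use is True


@pytest.mark.parametrize(
    "row, reason_fragment",
    [
        ("c2,1,s2,h1,t1,60,male,0,yes,ulcer,0,0,0,1,0", "zero-reliability"),
        ("c2,1,s2,h1,t1,60,male,0,yes,gastritis,0,0,0,1,8", "gi_history"),
        ("c2,1,s2,h1,t1,60,male,0,maybe,ulcer,0,0,0,1,8", "h_pylori"),
        ("c2,1,s2,h1,t1,60,male,0,yes,ulcer,0,0,0,1,11", "interview_reliability"),
        ("c2,1,s2,h1,t1,60,unknown,0,yes,ulcer,0,0,0,1,8", "sex"),
    ],
)
def test_invalid_rows_are_rejected_not_fatal(tmp_path, row, reason_fragment):
    # the matched control keeps stratum s2 valid so only the bad row is lost
    control = "k9,0,s2,h1,t1,61,male,0,yes,ulcer,0,0,0,1,8"
    result = read_participants(_write(tmp_path, GOOD_ROWS + [row, control]))
    assert len(result.rejected) >= 1
    assert any(reason_fragment in r.reason for r in result.rejected)
    assert all(r.participant_id != "c2" for r in result.records)


def test_missing_column_is_a_format_error(tmp_path):
    path = tmp_path / "broken.csv"
    path.write_text("participant_id,is_case\np1,1\n")
    with pytest.raises(DataFormatError):
        read_participants(path)


def test_duplicate_participant_id_raises(tmp_path):
    rows = GOOD_ROWS + [GOOD_ROWS[0]]
    with pytest.raises(ValidationError, match="duplicate"):
        read_participants(_write(tmp_path, rows))


def test_stratum_with_two_cases_rejected_whole(tmp_path):
    rows = GOOD_ROWS + ["c9,1,s1,h1,t1,59,male,0,yes,ulcer,0,0,0,1,8"]
    result = read_participants(_write(tmp_path, rows))
    assert result.records == []
    assert len(result.rejected) == 4
    assert all("cases" in r.reason for r in result.rejected)


def test_rejection_report_is_exhaustive(tmp_path):
    rows = GOOD_ROWS + [
        "c2,1,s2,h1,t1,60,male,0,yes,ulcer,0,0,0,1,0",  # zero reliability
        "k3,0,s3,h2,t1,60,female,0,yes,ulcer,0,0,0,1,8",  # case-less stratum
    ]
    result = read_participants(_write(tmp_path, rows))
    assert len(result.records) + len(result.rejected) == result.n_rows == 5
    kept = {r.participant_id for r in result.records}
    lost = {r.participant_id for r in result.rejected}
    assert kept.isdisjoint(lost)


def test_drug_records_attach_and_validate(tmp_path):
    drugs = tmp_path / "drugs.csv"
    drugs.write_text(
        "participant_id,drug_class,days_before_index\n"
        "c1,aspirin,3\nc1,other,20\nk1,non_aspirin_nsaid,-1\n"
    )
    result = read_participants(_write(tmp_path, GOOD_ROWS), drugs)
    (c1,) = [r for r in result.records if r.participant_id == "c1"]
    assert [d.drug_class for d in c1.drug_records] == ["aspirin", "other"]
    assert any("negative days_before_index" in r.reason for r in result.rejected)


SNP = SNPDefinition("rs2180314", "C", ("G",), gene="GSTA2")
DUAL = SNPDefinition("rs1060463", "C", ("G", "T"), gene="CYP4F11")


def test_genotype_cells_normalize_and_flag_missing(tmp_path):
    path = tmp_path / "geno.csv"
    path.write_text("participant_id,rs2180314\np1,CG\np2,GC\np3,\n")
    calls = read_genotypes(path, [SNP])
    assert calls[0].alleles == ("C", "G")
    assert calls[1].alleles == ("C", "G")  # order-insensitive
    assert calls[2].is_missing


def test_genotype_bad_allele_names_snp(tmp_path):
    path = tmp_path / "geno.csv"
    path.write_text("participant_id,rs2180314\np1,AT\n")
    with pytest.raises(ValidationError, match="rs2180314"):
        read_genotypes(path, [SNP])


def test_participant_and_genotype_round_trip(tmp_path, tiny_synergy):
    ppath, dpath, gpath = (tmp_path / n for n in
                           ("p.csv", "d.csv", "g.csv"))
    write_participants(tiny_synergy.participants, ppath, dpath)
    write_genotypes(tiny_synergy.genotypes, gpath, tiny_synergy.panel)
    back = read_participants(ppath, dpath)
    assert back.rejected == []
    assert back.records == tiny_synergy.participants
    calls = read_genotypes(gpath, tiny_synergy.panel)
    assert sorted(calls, key=lambda c: (c.rs_id, c.participant_id)) == sorted(
        tiny_synergy.genotypes, key=lambda c: (c.rs_id, c.participant_id))


def test_panel_round_trip_and_duplicate_detection(tmp_path):
    path = tmp_path / "panel.yaml"
    write_panel([SNP, DUAL], path)
    assert read_panel(path) == [SNP, DUAL]
    path.write_text(textwrap.dedent("""\
        snps:
          - {rs_id: rs1, wild: A, variants: [G]}
          - {rs_id: rs1, wild: A, variants: [C]}
    """))
    with pytest.raises(ValidationError, match="duplicate"):
        read_panel(path)


def test_snp_definition_rejects_wild_equal_variant():
    with pytest.raises(ValidationError):
        SNPDefinition("rsx", "C", ("C",))


def test_vcf_reader_gt_only(tmp_path):
    vcf = tmp_path / "calls.vcf"
    vcf.write_text(textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##contig=<ID=1,length=1000>
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tp1\tp2\tp3
        1\t100\trs2180314\tC\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t./.
        1\t200\trs1060463\tC\tG,T\t.\tPASS\t.\tGT\t0/2\t0/0\t1/2
    """))
    pytest.importorskip("cyvcf2")
    from gxepi.core_data import read_genotypes_vcf

    calls = {(c.participant_id, c.rs_id): c.alleles
             for c in read_genotypes_vcf(vcf, [SNP, DUAL])}
    assert calls[("p1", "rs2180314")] == ("C", "G")
    assert calls[("p2", "rs2180314")] == ("G", "G")
    assert calls[("p3", "rs2180314")] is None
    assert calls[("p1", "rs1060463")] == ("C", "T")
    assert calls[("p3", "rs1060463")] == ("G", "T")
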