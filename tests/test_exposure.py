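import pytest

from gxepi import (
    AnalysisConfig,
    GenotypeCall,
    SNPDefinition,
    ValidationError,
    assign_groups,
    carrier_status,
    derive_exposure,
)
from gxepi.core_data import DrugRecord, ParticipantRecord
from gxepi.exposure import Group

SNP = SNPDefinition("rs2180314", "C", ("G",), gene="GSTA2")
DUAL = SNPDefinition("rs1060463", "C", ("G", "T"), gene="CYP4F11")


def _participant(pid="p1", is_case=False, records=(), stratum="s1"):
    return ParticipantRecord(
        participant_id=pid, is_case=is_case, stratum_id=stratum,
        hospital_id="h1", period_id="t1", age=60.0, sex="male",
        drug_records=list(records),
    )


@pytest.mark.parametrize("records, drug_class, expected", [
    ([DrugRecord("aspirin", 3)], "aspirin", True),
    ([DrugRecord("aspirin", 3)], "any_nsaid", True),
    ([DrugRecord("aspirin", 3)], "non_aspirin", False),
    ([DrugRecord("non_aspirin_nsaid", 10)], "non_aspirin", False),  # outside window
    ([DrugRecord("non_aspirin_nsaid", 7)], "non_aspirin", True),  # boundary day
    ([DrugRecord("other", 1)], "any_nsaid", False),
    ([], "any_nsaid", False),
])
def test_exposure_window_rules(records, drug_class, expected):
    assert derive_exposure(_participant(records=records), drug_class, 7) is expected


def test_negative_days_is_a_validation_error():
    bad = _participant(records=[DrugRecord("aspirin", 0)])
    bad.drug_records[0] = DrugRecord("aspirin", -1)
    with pytest.raises(ValidationError, match="negative"):
        derive_exposure(bad, "aspirin", 7)


def test_any_nsaid_is_union_of_class_exposures(tiny_synergy):
    for participant in tiny_synergy.participants:
        any_ = derive_exposure(participant, "any_nsaid", 7)
        union = (derive_exposure(participant, "aspirin", 7)
                 or derive_exposure(participant, "non_aspirin", 7))
        assert any_ == union


@pytest.mark.parametrize("cell, snp, expected", [
    (("C", "C"), SNP, "wild_type"),
    (("C", "G"), SNP, "variant_carrier"),
    (("G", "G"), SNP, "variant_carrier"),
    (("C", "T"), DUAL, "variant_carrier"),  # second alternate allele
    (("C", "G"), DUAL, "variant_carrier"),
    (("C", "C"), DUAL, "wild_type"),
    (None, SNP, "missing"),
])
def test_dominant_model_carrier_status(cell, snp, expected):
    call = GenotypeCall("p1", snp.rs_id, cell)
    assert carrier_status(call, snp) == expected


def test_carrier_status_rejects_mismatched_snp():
    with pytest.raises(ValidationError):
        carrier_status(GenotypeCall("p1", "rs_other", ("C", "C")), SNP)


def _published_cell_fixture():
    """Participants realizing the published any-NSAID 2x4 cell counts."""
    cells = {  # (exposed, carrier) -> (cases, controls)
        (False, False): (91, 258),
        (False, True): (99, 363),
        (True, False): (48, 60),
        (True, True): (80, 50),
    }
    participants, calls = [], []
    i = 0
    for (exposed, carrier), (n_case, n_control) in cells.items():
        for is_case, k in ((True, n_case), (False, n_control)):
            for _ in range(k):
                pid = f"p{i}"; i += 1
                records = [DrugRecord("non_aspirin_nsaid", 2)] if exposed else []
                participants.append(_participant(pid, is_case, records, stratum=pid))
                geno = ("C", "G") if carrier else ("C", "C")
                calls.append(GenotypeCall(pid, SNP.rs_id, geno))
    return participants, calls


def test_group_table_reproduces_published_cell_percentages():
    participants, calls = _published_cell_fixture()
    codings, table = assign_groups(participants, calls, SNP, "any_nsaid")
    n_cases, pct_cases, n_controls, pct_controls = table.cell(Group.G2_DRUG_VARIANT)
    assert (n_cases, n_controls) == (80, 50)
    assert pct_cases == pytest.approx(61.5, abs=0.05)
    assert pct_controls == pytest.approx(38.5, abs=0.05)
    assert not table.not_applicable


def test_partition_and_invertibility(tiny_synergy, config):
    snp = tiny_synergy.panel[0]
    codings, table = assign_groups(
        tiny_synergy.participants, tiny_synergy.genotypes, snp, "any_nsaid", config)
    n_genotyped = sum(
        1 for c in tiny_synergy.genotypes
        if c.rs_id == snp.rs_id and c.alleles is not None)
    assert len(codings) == n_genotyped
    assert sum(c + k for c, k in table.counts.values()) == n_genotyped
    # exposure and carriage are recoverable from the group label
    by_pid = {c.participant_id: c.group for c in codings}
    calls = {c.participant_id: c for c in tiny_synergy.genotypes
             if c.rs_id == snp.rs_id}
    for participant in tiny_synergy.participants:
        group = by_pid.get(participant.participant_id)
        if group is None:
            continue
        assert group.exposed == derive_exposure(participant, "any_nsaid", 7)
        assert group.carrier == (carrier_status(calls[participant.participant_id], snp)
                                 == "variant_carrier")


def test_all_unexposed_wild_type_land_in_reference():
    participants = [_participant(f"p{i}", i == 0, stratum=f"s{i}") for i in range(6)]
    calls = [GenotypeCall(p.participant_id, SNP.rs_id, ("C", "C"))
             for p in participants]
    codings, table = assign_groups(participants, calls, SNP, "any_nsaid")
    assert all(c.group is Group.G4_NODRUG_WILD for c in codings)


def test_sparse_exposed_carrier_cell_flags_not_applicable():
    participants, calls = [], []
    specs = [(True, True, True), (True, True, False),  # 1 case + 1 control in G2
             (False, False, True)] + [(False, False, False)] * 6
    for i, (exposed, carrier, is_case) in enumerate(specs):
        pid = f"p{i}"
        records = [DrugRecord("aspirin", 1)] if exposed else []
        participants.append(_participant(pid, is_case, records, stratum=pid))
        calls.append(GenotypeCall(pid, SNP.rs_id,
                                  ("C", "G") if carrier else ("C", "C")))
    _, table = assign_groups(participants, calls, SNP, "aspirin",
                             AnalysisConfig(min_cell_count=3))
    assert table.not_applicable
    assert any("not applicable" in note for note in table.notes)


def test_missing_genotypes_are_excluded_and_empty_raises():
    participants = [_participant(f"p{i}", False, stratum=f"s{i}") for i in range(3)]
    calls = [GenotypeCall(p.participant_id, SNP.rs_id, None) for p in participants]
    with pytest.raises(ValidationError, match="no genotyped"):
        assign_groups(participants, calls, SNP, "any_nsaid")
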