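"""Drug-exposure derivation, dominant-model carrier status, and the four-group
exposure x genotype coding.

Each participant is classified, per SNP and per drug stratum, into one of
four mutually exclusive groups:

* G1 drug(+), wild-type
* G2 drug(+), variant carrier
* G3 drug(-), variant carrier
* G4 drug(-), wild-type  (the reference category)

Exposure means at least one consumption record of the drug class within the
window preceding the index date (default 7 days, window-inclusive);
"any NSAID" is the union of aspirin and non-aspirin NSAID exposure.  Carriage
follows the dominant genetic model: one or more variant alleles (either
alternate, for dual-variant loci).  Participants with a missing genotype at a
SNP are excluded from that SNP's coding.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .core_data import (
    AnalysisConfig,
    GenotypeCall,
    ParticipantRecord,
    SNPDefinition,
    ValidationError,
)

__all__ = [
    "Group",
    "FourGroupCoding",
    "GroupCountTable",
    "derive_exposure",
    "carrier_status",
    "assign_groups",
]

_CLASS_MEMBERS: Mapping[str, tuple[str, ...]] = {
    "any_nsaid": ("aspirin", "non_aspirin_nsaid"),
    "non_aspirin": ("non_aspirin_nsaid",),
    "aspirin": ("aspirin",),
}


class Group(str, Enum):
    G1_DRUG_WILD = "g1_drug_wild"
    G2_DRUG_VARIANT = "g2_drug_variant"
    G3_NODRUG_VARIANT = "g3_nodrug_variant"
    G4_NODRUG_WILD = "g4_nodrug_wild"  # reference

    @property
    def exposed(self) -> bool:
        return self in (Group.G1_DRUG_WILD, Group.G2_DRUG_VARIANT)

    @property
    def carrier(self) -> bool:
        return self in (Group.G2_DRUG_VARIANT, Group.G3_NODRUG_VARIANT)

    @staticmethod
    def from_status(exposed: bool, carrier: bool) -> "Group":
        if exposed:
            return Group.G2_DRUG_VARIANT if carrier else Group.G1_DRUG_WILD
        return Group.G3_NODRUG_VARIANT if carrier else Group.G4_NODRUG_WILD


@dataclass(frozen=True)
class FourGroupCoding:
    participant_id: str
    rs_id: str
    drug_class: str
    group: Group


@dataclass
class GroupCountTable:
    """Case/control counts per group with within-cell percentages.

    ``cell(group)`` returns (n_cases, pct_cases, n_controls, pct_controls)
    where the percentages are case and control shares of that cell, the layout
    of the published interaction tables.
    """

    rs_id: str
    drug_class: str
    counts: dict[Group, tuple[int, int]]  # group -> (cases, controls)
    n_genotyped: int
    not_applicable: bool
    notes: list[str]

    def cell(self, group: Group) -> tuple[int, float, int, float]:
        cases, controls = self.counts[group]
        total = cases + controls
        if total == 0:
            return 0, float("nan"), 0, float("nan")
        return cases, 100.0 * cases / total, controls, 100.0 * controls / total


def derive_exposure(
    participant: ParticipantRecord, drug_class: str, window_days: int = 7
) -> bool:
    """True iff any record of the class falls within the exposure window.

    A record counts when 0 <= days_before_index <= window_days.  The class
    strata are independent dichotomies: aspirin use never reclassifies a
    subject in the non-aspirin stratum and vice versa.
    """
    if drug_class not in _CLASS_MEMBERS:
        raise ValidationError(f"unknown drug class {drug_class!r}")
    members = _CLASS_MEMBERS[drug_class]
    for record in participant.drug_records:
        if record.days_before_index < 0:
            raise ValidationError(
                f"{participant.participant_id}: negative days_before_index"
            )
        if record.drug_class in members and record.days_before_index <= window_days:
            return True
    return False


def carrier_status(call: GenotypeCall, snp: SNPDefinition) -> str:
    """Dominant model: 'variant_carrier' iff >=1 variant allele; else 'wild_type'.

    Missing calls propagate as 'missing' (the subject is excluded from this
    SNP's analysis).
    """
    if call.rs_id != snp.rs_id:
        raise ValidationError(
            f"call for {call.rs_id} passed with definition of {snp.rs_id}"
        )
    if call.alleles is None:
        return "missing"
    if any(a in snp.variant_alleles for a in call.alleles):
        return "variant_carrier"
    return "wild_type"


def assign_groups(
    participants: Sequence[ParticipantRecord],
    calls: Sequence[GenotypeCall],
    snp: SNPDefinition,
    drug_class: str,
    config: AnalysisConfig | None = None,
) -> tuple[list[FourGroupCoding], GroupCountTable]:
    """Four-group coding for one SNP and drug stratum, plus its count table.

    Every participant with a non-missing genotype lands in exactly one group.
    The table is flagged ``not_applicable`` when the exposed-carrier (G2) cell
    holds fewer than ``config.min_cell_count`` cases or controls: interaction
    measures are not estimable from such sparse cells.
    """
    config = config or AnalysisConfig()
    call_by_pid = {
        c.participant_id: c for c in calls if c.rs_id == snp.rs_id
    }
    codings: list[FourGroupCoding] = []
    counts: dict[Group, list[int]] = {g: [0, 0] for g in Group}
    for participant in participants:
        call = call_by_pid.get(
            participant.participant_id,
            GenotypeCall(participant.participant_id, snp.rs_id, None),
        )
        status = carrier_status(call, snp)
        if status == "missing":
            continue
        exposed = derive_exposure(participant, drug_class, config.exposure_window_days)
        group = Group.from_status(exposed, status == "variant_carrier")
        codings.append(FourGroupCoding(
            participant.participant_id, snp.rs_id, drug_class, group
        ))
        counts[group][0 if participant.is_case else 1] += 1
    if not codings:
        raise ValidationError(
            f"{snp.rs_id}/{drug_class}: no genotyped participants to assign"
        )

    notes: list[str] = []
    g2_cases, g2_controls = counts[Group.G2_DRUG_VARIANT]
    not_applicable = min(g2_cases, g2_controls) < config.min_cell_count
    if not_applicable:
        notes.append(
            "not applicable: exposed-carrier cell below minimum count "
            f"({g2_cases} cases/{g2_controls} controls < {config.min_cell_count})"
        )
    table = GroupCountTable(
        rs_id=snp.rs_id,
        drug_class=drug_class,
        counts={g: (c[0], c[1]) for g, c in counts.items()},
        n_genotyped=len(codings),
        not_applicable=not_applicable,
        notes=notes,
    )
    return codings, table
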