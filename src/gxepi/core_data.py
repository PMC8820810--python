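"""Domain types, validation and table IO for matched case-control gene-drug studies.

The study design modelled here is a multicenter matched case-control study of
upper gastrointestinal haemorrhage (UGIH): each case is matched with controls
from the same hospital, of the same sex and of similar age, and the matched set
("stratum") is one grouping level of the analysis model, nested inside hospital
and recruitment period.  Participants carry clinical covariates and a history
of drug consumption (days before an index date); genotypes are unphased diploid
calls for a small candidate-SNP panel.

File formats
------------
participants.csv : one row per subject (see :data:`PARTICIPANT_COLUMNS`)
drugs.csv        : long format, one row per consumption record
                   (participant_id, drug_class, days_before_index)
genotypes.csv    : wide format, one column per rs id, cells are two-letter
                   genotypes ("CG" == "GC"), empty cell = missing call
panel.yaml       : the SNP panel (rs id, gene, wild allele, variant allele(s))

Rows that violate row-level or stratum-level invariants are *rejected into a
report*, never silently dropped, and never abort the load; only a malformed
file (missing columns, duplicated ids) raises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "DataFormatError",
    "ValidationError",
    "DrugRecord",
    "ParticipantRecord",
    "SNPDefinition",
    "GenotypeCall",
    "AnalysisConfig",
    "RejectedRow",
    "ParticipantReadResult",
    "read_participants",
    "write_participants",
    "read_genotypes",
    "read_genotypes_vcf",
    "write_genotypes",
    "read_panel",
    "write_panel",
    "participants_frame",
    "SEX_LEVELS",
    "GI_HISTORY_LEVELS",
    "H_PYLORI_LEVELS",
    "DRUG_CLASSES",
    "DRUG_STRATA",
    "DEFAULT_ADJUSTMENT_SET",
]


class DataFormatError(Exception):
    """The file itself is malformed (wrong columns, unreadable)."""


class ValidationError(Exception):
    """The file parses but its content breaks a hard contract."""


SEX_LEVELS = ("male", "female")
GI_HISTORY_LEVELS = ("none_or_dyspepsia", "ulcer", "bleeding")
H_PYLORI_LEVELS = ("yes", "no_or_uncertain")
#: drug classes recorded in consumption histories
DRUG_CLASSES = ("aspirin", "non_aspirin_nsaid", "other")
#: exposure strata analysed (any NSAID = aspirin or non-aspirin NSAID)
DRUG_STRATA = ("any_nsaid", "non_aspirin", "aspirin")

#: Adjustment set of the final reported models: history of arthrosis,
#: H. pylori infection, gastrointestinal disorders (ulcer/bleeding), proton
#: pump inhibitors, antiaggregants, anticoagulants and the interview variables
#: (number of interviews, interviewer-rated reliability).  Recruitment period
#: is handled by the period-level random intercept, not as a fixed covariate.
DEFAULT_ADJUSTMENT_SET = (
    "arthrosis",
    "h_pylori",
    "gi_history",
    "ppi_use",
    "antiaggregant_use",
    "anticoagulant_use",
    "n_interviews",
    "interview_reliability",
)

PARTICIPANT_COLUMNS = (
    "participant_id",
    "is_case",
    "stratum_id",
    "hospital_id",
    "period_id",
    "age",
    "sex",
    "arthrosis",
    "h_pylori",
    "gi_history",
    "ppi_use",
    "antiaggregant_use",
    "anticoagulant_use",
    "n_interviews",
    "interview_reliability",
)

DRUG_COLUMNS = ("participant_id", "drug_class", "days_before_index")


@dataclass(frozen=True)
class DrugRecord:
    """One consumption record: drug class and days before the index date.

    The index date is symptom onset for cases and the interview day for
    controls; ``days_before_index`` is a non-negative integer day count.
    """

    drug_class: str
    days_before_index: int


@dataclass
class ParticipantRecord:
    participant_id: str
    is_case: bool
    stratum_id: str
    hospital_id: str
    period_id: str
    age: float
    sex: str
    arthrosis: bool | None = None
    h_pylori: str | None = None
    gi_history: str | None = None
    ppi_use: bool | None = None
    antiaggregant_use: bool | None = None
    anticoagulant_use: bool | None = None
    n_interviews: int | None = 1
    interview_reliability: float | None = None
    drug_records: list[DrugRecord] = field(default_factory=list)


@dataclass(frozen=True)
class SNPDefinition:
    """A panel SNP: wild (reference) allele and one or two variant alleles.

    Dual-variant loci (e.g. a C>G/C>T site) list both alternates; any variant
    allele makes a subject a carrier under the dominant model.
    """

    rs_id: str
    wild_allele: str
    variant_alleles: tuple[str, ...]
    gene: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.variant_alleles, str):
            object.__setattr__(self, "variant_alleles", (self.variant_alleles,))
        else:
            object.__setattr__(self, "variant_alleles", tuple(self.variant_alleles))
        if self.wild_allele in self.variant_alleles:
            raise ValidationError(
                f"{self.rs_id}: wild allele equals a variant allele ({self.wild_allele})"
            )

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.wild_allele, *self.variant_alleles)


@dataclass(frozen=True)
class GenotypeCall:
    """An unphased diploid call; ``alleles`` is a sorted pair or None (missing)."""

    participant_id: str
    rs_id: str
    alleles: tuple[str, str] | None

    @staticmethod
    def from_cell(participant_id: str, snp: SNPDefinition, cell: str | None) -> "GenotypeCall":
        if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
            return GenotypeCall(participant_id, snp.rs_id, None)
        text = str(cell).strip().upper()
        if len(text) != 2:
            raise ValidationError(
                f"{snp.rs_id}: genotype cell {text!r} for {participant_id} is not two alleles"
            )
        pair = tuple(sorted(text))
        for allele in pair:
            if allele not in snp.alleles:
                raise ValidationError(
                    f"{snp.rs_id}: allele {allele!r} for {participant_id} not in "
                    f"{snp.alleles}"
                )
        return GenotypeCall(participant_id, snp.rs_id, pair)  # type: ignore[arg-type]

    @property
    def is_missing(self) -> bool:
        return self.alleles is None


@dataclass
class AnalysisConfig:
    """Tunable analysis settings with the defaults of the reported study."""

    exposure_window_days: int = 7
    genetic_model: str = "dominant"
    adjustment_candidates: tuple[str, ...] = DEFAULT_ADJUSTMENT_SET
    forced_adjustment: tuple[str, ...] = DEFAULT_ADJUSTMENT_SET
    ci_level: float = 0.95
    min_cell_count: int = 3
    rng_seed: int = 0
    drug_strata: tuple[str, ...] = DRUG_STRATA
    call_rate_threshold: float = 0.98
    hwe_alpha: float = 0.001
    include_qc_failed: bool = False
    selection_enabled: bool = False
    selection_threshold: float = 0.10
    selection_scope: str = "global"  # or "per_model"
    model: str = "glmm"  # "glmm" (nested random intercepts) or "logistic"
    interaction_method: str = "delta"  # or "bootstrap"
    bootstrap_draws: int = 10000

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError("ci_level must lie strictly between 0 and 1")
        if self.exposure_window_days < 1:
            raise ValidationError("exposure_window_days must be >= 1")
        if self.genetic_model != "dominant":
            raise ValidationError(f"unsupported genetic model {self.genetic_model!r}")
        unknown = set(self.drug_strata) - set(DRUG_STRATA)
        if unknown:
            raise ValidationError(f"unknown drug strata: {sorted(unknown)}")
        self.adjustment_candidates = tuple(self.adjustment_candidates)
        self.forced_adjustment = tuple(self.forced_adjustment)
        self.drug_strata = tuple(self.drug_strata)


@dataclass(frozen=True)
class RejectedRow:
    row_index: int
    participant_id: str
    reason: str


@dataclass
class ParticipantReadResult:
    records: list[ParticipantRecord]
    rejected: list[RejectedRow]
    n_rows: int


def _as_bool(value, column: str):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip().lower()
    if text in {"", "na", "nan", "none"}:
        return None
    if text in {"true", "1", "yes", "t"}:
        return True
    if text in {"false", "0", "no", "f"}:
        return False
    raise ValueError(f"{column}: cannot interpret {value!r} as boolean")


def _validate_row(row: pd.Series) -> tuple[ParticipantRecord | None, str | None]:
    """Return (record, None) for a valid row, (None, reason) otherwise."""
    try:
        reliability = row["interview_reliability"]
        reliability = None if pd.isna(reliability) else float(reliability)
    except (TypeError, ValueError):
        return None, "interview_reliability is not numeric"
    if reliability is not None:
        if not 0.0 <= reliability <= 10.0:
            return None, "interview_reliability outside [0, 10]"
        if reliability == 0.0:
            return None, "zero-reliability interview"

    sex = str(row["sex"]).strip().lower()
    if sex not in SEX_LEVELS:
        return None, f"invalid sex {row['sex']!r}"

    gi = row["gi_history"]
    gi = None if pd.isna(gi) else str(gi).strip().lower()
    if gi is not None and gi not in GI_HISTORY_LEVELS:
        return None, f"invalid gi_history category {row['gi_history']!r}"

    hp = row["h_pylori"]
    hp = None if pd.isna(hp) else str(hp).strip().lower()
    if hp is not None and hp not in H_PYLORI_LEVELS:
        return None, f"invalid h_pylori category {row['h_pylori']!r}"

    n_int = row["n_interviews"]
    if pd.isna(n_int):
        n_int = None
    else:
        try:
            n_int = int(n_int)
        except (TypeError, ValueError):
            return None, "n_interviews is not an integer"
        if n_int < 1:
            return None, "n_interviews must be a positive integer"

    try:
        age = float(row["age"])
    except (TypeError, ValueError):
        return None, "age is not numeric"

    try:
        bools = {
            name: _as_bool(row[name], name)
            for name in ("arthrosis", "ppi_use", "antiaggregant_use", "anticoagulant_use")
        }
        is_case = _as_bool(row["is_case"], "is_case")
    except ValueError as exc:
        return None, str(exc)
    if is_case is None:
        return None, "is_case is missing"

    record = ParticipantRecord(
        participant_id=str(row["participant_id"]),
        is_case=is_case,
        stratum_id=str(row["stratum_id"]),
        hospital_id=str(row["hospital_id"]),
        period_id=str(row["period_id"]),
        age=age,
        sex=sex,
        arthrosis=bools["arthrosis"],
        h_pylori=hp,
        gi_history=gi,
        ppi_use=bools["ppi_use"],
        antiaggregant_use=bools["antiaggregant_use"],
        anticoagulant_use=bools["anticoagulant_use"],
        n_interviews=n_int,
        interview_reliability=reliability,
    )
    return record, None


def read_participants(
    path: str | Path,
    drugs_path: str | Path | None = None,
    schema: Mapping[str, str] | None = None,
) -> ParticipantReadResult:
    """Load and validate the participant table (plus optional drug records).

    ``schema`` optionally maps file column names onto the canonical names of
    :data:`PARTICIPANT_COLUMNS`.  Rows violating row-level invariants (zero
    reliability, invalid categories, ...) or stratum-level invariants (a
    stratum must hold exactly one case, all in the same hospital and period)
    are returned in the rejection report; every input row ends up either in
    ``records`` or in ``rejected``, never both.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "stratum_id": str,
                                  "hospital_id": str, "period_id": str})
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"participant table missing mandatory columns: {missing}")
    dupes = df["participant_id"][df["participant_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate participant_id values: {sorted(set(dupes))}")

    records: dict[str, ParticipantRecord] = {}
    row_of: dict[str, int] = {}
    rejected: list[RejectedRow] = []
    for idx, row in df.iterrows():
        record, reason = _validate_row(row)
        pid = str(row["participant_id"])
        if record is None:
            rejected.append(RejectedRow(int(idx), pid, reason or "invalid row"))
        else:
            records[pid] = record
            row_of[pid] = int(idx)

    if drugs_path is not None:
        _attach_drug_records(records, row_of, rejected, drugs_path)

    # stratum-level invariants, applied to rows that survived so far
    by_stratum: dict[str, list[ParticipantRecord]] = {}
    for rec in records.values():
        by_stratum.setdefault(rec.stratum_id, []).append(rec)
    bad_strata: dict[str, str] = {}
    for sid, members in by_stratum.items():
        n_cases = sum(m.is_case for m in members)
        if n_cases != 1:
            bad_strata[sid] = f"stratum {sid} has {n_cases} cases (expected exactly 1)"
        elif len({m.hospital_id for m in members}) != 1:
            bad_strata[sid] = f"stratum {sid} spans multiple hospitals"
        elif len({m.period_id for m in members}) != 1:
            bad_strata[sid] = f"stratum {sid} spans multiple recruitment periods"
    kept: list[ParticipantRecord] = []
    for rec in records.values():
        if rec.stratum_id in bad_strata:
            rejected.append(
                RejectedRow(row_of[rec.participant_id], rec.participant_id,
                            bad_strata[rec.stratum_id])
            )
        else:
            kept.append(rec)
    rejected.sort(key=lambda r: r.row_index)
    return ParticipantReadResult(records=kept, rejected=rejected, n_rows=len(df))


def _attach_drug_records(
    records: dict[str, ParticipantRecord],
    row_of: dict[str, int],
    rejected: list[RejectedRow],
    drugs_path: str | Path,
) -> None:
    drugs = pd.read_csv(drugs_path, dtype={"participant_id": str})
    missing = [c for c in DRUG_COLUMNS if c not in drugs.columns]
    if missing:
        raise DataFormatError(f"drug table missing mandatory columns: {missing}")
    bad: dict[str, str] = {}
    for _, row in drugs.iterrows():
        pid = str(row["participant_id"])
        if pid not in records:
            if pid not in row_of and pid not in {r.participant_id for r in rejected}:
                raise ValidationError(f"drug record for unknown participant {pid!r}")
            continue  # participant already rejected; drop its drug rows with it
        drug_class = str(row["drug_class"]).strip().lower()
        if drug_class not in DRUG_CLASSES:
            bad[pid] = f"invalid drug_class {row['drug_class']!r}"
            continue
        try:
            days = int(row["days_before_index"])
        except (TypeError, ValueError):
            bad[pid] = "days_before_index is not an integer"
            continue
        if days < 0:
            bad[pid] = "negative days_before_index"
            continue
        records[pid].drug_records.append(DrugRecord(drug_class, days))
    for pid, reason in bad.items():
        rejected.append(RejectedRow(row_of[pid], pid, reason))
        records.pop(pid, None)


def write_participants(
    records: Sequence[ParticipantRecord],
    path: str | Path,
    drugs_path: str | Path | None = None,
) -> None:
    """Write participant (and optionally drug) tables; inverse of the readers."""
    rows = []
    for rec in records:
        rows.append({
            "participant_id": rec.participant_id,
            "is_case": rec.is_case,
            "stratum_id": rec.stratum_id,
            "hospital_id": rec.hospital_id,
            "period_id": rec.period_id,
            "age": rec.age,
            "sex": rec.sex,
            "arthrosis": rec.arthrosis,
            "h_pylori": rec.h_pylori,
            "gi_history": rec.gi_history,
            "ppi_use": rec.ppi_use,
            "antiaggregant_use": rec.antiaggregant_use,
            "anticoagulant_use": rec.anticoagulant_use,
            "n_interviews": rec.n_interviews,
            "interview_reliability": rec.interview_reliability,
        })
    pd.DataFrame(rows, columns=list(PARTICIPANT_COLUMNS)).to_csv(path, index=False)
    if drugs_path is not None:
        drug_rows = [
            {"participant_id": rec.participant_id,
             "drug_class": dr.drug_class,
             "days_before_index": dr.days_before_index}
            for rec in records for dr in rec.drug_records
        ]
        pd.DataFrame(drug_rows, columns=list(DRUG_COLUMNS)).to_csv(drugs_path, index=False)


def read_genotypes(path: str | Path, panel: Sequence[SNPDefinition]) -> list[GenotypeCall]:
    """Read the wide genotype CSV; cells are normalized unordered allele pairs."""
    df = pd.read_csv(path, dtype=str)
    if "participant_id" not in df.columns:
        raise DataFormatError("genotype table missing participant_id column")
    by_rs = {snp.rs_id: snp for snp in panel}
    calls: list[GenotypeCall] = []
    for snp_id in df.columns:
        if snp_id == "participant_id":
            continue
        if snp_id not in by_rs:
            continue  # column for a SNP outside the requested panel: ignored
        snp = by_rs[snp_id]
        for _, row in df.iterrows():
            calls.append(GenotypeCall.from_cell(str(row["participant_id"]), snp, row[snp_id]))
    return calls


def write_genotypes(
    calls: Iterable[GenotypeCall], path: str | Path, panel: Sequence[SNPDefinition]
) -> None:
    cells: dict[str, dict[str, str]] = {}
    for call in calls:
        cells.setdefault(call.participant_id, {})[call.rs_id] = (
            "" if call.alleles is None else "".join(call.alleles)
        )
    rows = [{"participant_id": pid, **vals} for pid, vals in cells.items()]
    cols = ["participant_id"] + [snp.rs_id for snp in panel]
    pd.DataFrame(rows, columns=cols).fillna("").to_csv(path, index=False)


def read_genotypes_vcf(
    path: str | Path, panel: Sequence[SNPDefinition]
) -> list[GenotypeCall]:
    """Minimal VCF reader: GT field only, variants matched to the panel by ID.

    Requires cyvcf2 (``pip install gxepi[vcf]``).
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    by_rs = {snp.rs_id: snp for snp in panel}
    calls: list[GenotypeCall] = []
    seen: set[str] = set()
    for variant in vcf:
        snp = by_rs.get(variant.ID)
        if snp is None:
            continue
        seen.add(snp.rs_id)
        alleles = [variant.REF] + list(variant.ALT)
        for sample, gt in zip(samples, variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                calls.append(GenotypeCall(sample, snp.rs_id, None))
                continue
            pair = "".join(sorted((alleles[a], alleles[b])))
            calls.append(GenotypeCall.from_cell(sample, snp, pair))
    for snp in panel:
        if snp.rs_id not in seen:
            calls.extend(GenotypeCall(s, snp.rs_id, None) for s in samples)
    return calls


def read_panel(path: str | Path) -> list[SNPDefinition]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["snps"] if isinstance(doc, dict) else doc
    panel = []
    for entry in entries:
        panel.append(SNPDefinition(
            rs_id=str(entry["rs_id"]),
            wild_allele=str(entry["wild"]),
            variant_alleles=tuple(str(v) for v in entry["variants"]),
            gene=str(entry.get("gene", "")),
        ))
    if len({snp.rs_id for snp in panel}) != len(panel):
        raise ValidationError("panel contains duplicate rs ids")
    return panel


def write_panel(panel: Sequence[SNPDefinition], path: str | Path) -> None:
    doc = {"snps": [
        {"rs_id": snp.rs_id, "gene": snp.gene, "wild": snp.wild_allele,
         "variants": list(snp.variant_alleles)}
        for snp in panel
    ]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def participants_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Participants as a DataFrame (drug records stay on the dataclasses)."""
    df = pd.DataFrame([{
        "participant_id": r.participant_id,
        "is_case": r.is_case,
        "stratum_id": r.stratum_id,
        "hospital_id": r.hospital_id,
        "period_id": r.period_id,
        "age": r.age,
        "sex": r.sex,
        "arthrosis": r.arthrosis,
        "h_pylori": r.h_pylori,
        "gi_history": r.gi_history,
        "ppi_use": r.ppi_use,
        "antiaggregant_use": r.antiaggregant_use,
        "anticoagulant_use": r.anticoagulant_use,
        "n_interviews": r.n_interviews,
        "interview_reliability": r.interview_reliability,
    } for r in records])
    if not df.empty:
        df = df.set_index("participant_id", drop=False)
    return df
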