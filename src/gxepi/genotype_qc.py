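"""Per-SNP genotype quality control: call rate, exact Hardy-Weinberg test,
and a case/control genotype prevalence table.

Hardy-Weinberg equilibrium (HWE) is tested in controls only: under HWE the
genotype proportions are (p^2, 2pq, q^2) for allele frequencies (p, q), and a
departure in controls signals genotyping error or population stratification.
Two p-values are computed:

* the exact conditional test -- conditional on the observed allele counts, the
  heterozygote count follows a known discrete distribution, and the p-value is
  the total probability of all heterozygote counts whose conditional
  probability does not exceed that of the observed table;
* the 1-df chi-square test against Hardy-Weinberg expected counts.

The exact test is the primary one; both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .core_data import GenotypeCall, ParticipantRecord, SNPDefinition, ValidationError

__all__ = [
    "GenotypeCounts",
    "HWEResult",
    "call_rate",
    "genotype_counts",
    "hwe_exact",
    "prevalence_table",
    "qc_report",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one biallelic locus; AA is homozygous wild."""

    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_Aa, self.n_aa) < 0:
            raise ValidationError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa


@dataclass(frozen=True)
class HWEResult:
    p_exact: float
    p_chisq: float
    chisq_stat: float
    allele_freq_wild: float


def call_rate(calls: Iterable[GenotypeCall], n_participants: int,
              threshold: float = 0.98) -> tuple[float, bool]:
    """Fraction of participants with a non-missing call; pass iff >= threshold."""
    if n_participants <= 0:
        raise ValidationError("n_participants must be positive")
    n_called = sum(1 for c in calls if not c.is_missing)
    rate = n_called / n_participants
    return rate, rate >= threshold


def _het_log_probs(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities of every feasible heterozygote count.

    Conditional on ``n`` diploid subjects carrying ``n_a`` copies of the minor
    allele, the heterozygote count n_Aa ranges over values with the parity of
    ``n_a``; P(n_Aa) = n! 2^{n_Aa} / (n_AA! n_Aa! n_aa!) * (n_a! n_A! / (2n)!).
    """
    n_A = 2 * n - n_a
    hets = np.arange(n_a % 2, min(n_a, n_A) + 1, 2)
    n_aa = (n_a - hets) // 2
    n_AA = (n_A - hets) // 2
    logp = (
        gammaln(n + 1) - gammaln(n_AA + 1) - gammaln(hets + 1) - gammaln(n_aa + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1) + gammaln(n_A + 1) - gammaln(2 * n + 1)
    )
    return hets, logp


def hwe_exact(counts: GenotypeCounts) -> HWEResult:
    """Exact and chi-square Hardy-Weinberg tests for one locus.

    The exact p-value sums the conditional probabilities of all heterozygote
    counts at least as improbable as the observed one (two-sided by
    probability ordering).  Invariant to which homozygote is labelled wild.
    """
    n = counts.total
    if n == 0:
        raise ValidationError("cannot test HWE on all-zero genotype counts")
    n_a = 2 * counts.n_aa + counts.n_Aa  # variant allele copies
    hets, logp = _het_log_probs(n, n_a)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = int(np.flatnonzero(hets == counts.n_Aa)[0])
    p_exact = float(probs[probs <= probs[obs] * (1.0 + 1e-12)].sum())
    p_exact = min(p_exact, 1.0)

    p_wild = (2 * counts.n_AA + counts.n_Aa) / (2 * n)
    q = 1.0 - p_wild
    expected = np.array([p_wild ** 2, 2 * p_wild * q, q ** 2]) * n
    observed = np.array([counts.n_AA, counts.n_Aa, counts.n_aa], dtype=float)
    mask = expected > 0
    stat = float(((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    p_chisq = float(chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return HWEResult(p_exact=p_exact, p_chisq=p_chisq, chisq_stat=stat,
                     allele_freq_wild=float(p_wild))


def genotype_counts(
    calls: Iterable[GenotypeCall], snp: SNPDefinition
) -> GenotypeCounts:
    """Collapse calls at one SNP into (hom wild, het, hom/compound variant)."""
    n_AA = n_Aa = n_aa = 0
    for call in calls:
        if call.rs_id != snp.rs_id or call.alleles is None:
            continue
        n_var = sum(a in snp.variant_alleles for a in call.alleles)
        if n_var == 0:
            n_AA += 1
        elif n_var == 1:
            n_Aa += 1
        else:
            n_aa += 1
    return GenotypeCounts(n_AA, n_Aa, n_aa)


def prevalence_table(
    calls: Sequence[GenotypeCall],
    participants: Sequence[ParticipantRecord],
    panel: Sequence[SNPDefinition],
) -> pd.DataFrame:
    """Genotype prevalence by case status, with the control-only HWE p-value.

    One row per observed genotype per SNP; percentages use the full case and
    control group sizes as denominators (so missing calls leave the column
    summing below 100%).  The HWE p is marked not-applicable when controls
    show fewer than three genotype classes (including monovariant SNPs), the
    convention of the prevalence tables this mirrors.
    """
    case_ids = {p.participant_id for p in participants if p.is_case}
    control_ids = {p.participant_id for p in participants if not p.is_case}
    n_cases, n_controls = len(case_ids), len(control_ids)
    if n_controls == 0:
        raise ValidationError("prevalence table requires at least one control")

    rows = []
    for snp in panel:
        snp_calls = [c for c in calls if c.rs_id == snp.rs_id and c.alleles is not None]
        by_genotype: dict[str, list[GenotypeCall]] = {}
        for call in snp_calls:
            by_genotype.setdefault("".join(call.alleles), []).append(call)
        control_calls = [c for c in snp_calls if c.participant_id in control_ids]
        control_classes = {"".join(c.alleles) for c in control_calls}
        if len(control_classes) >= 3 and control_calls:
            hwe = hwe_exact(genotype_counts(control_calls, snp))
            p_exact, p_chisq = hwe.p_exact, hwe.p_chisq
            hwe_na = False
        else:
            p_exact = p_chisq = float("nan")
            hwe_na = True

        def genotype_order(g: str) -> tuple[int, str]:
            n_var = sum(a in snp.variant_alleles for a in g)
            return (n_var, g)

        for genotype in sorted(by_genotype, key=genotype_order):
            grp = by_genotype[genotype]
            nc = sum(1 for c in grp if c.participant_id in case_ids)
            nk = sum(1 for c in grp if c.participant_id in control_ids)
            rows.append({
                "gene": snp.gene,
                "rs_id": snp.rs_id,
                "genotype": genotype,
                "n_cases": nc,
                "pct_cases": 100.0 * nc / n_cases if n_cases else float("nan"),
                "n_controls": nk,
                "pct_controls": 100.0 * nk / n_controls,
                "hwe_p_exact": p_exact,
                "hwe_p_chisq": p_chisq,
                "hwe_not_applicable": hwe_na,
            })
    return pd.DataFrame(rows, columns=[
        "gene", "rs_id", "genotype", "n_cases", "pct_cases", "n_controls",
        "pct_controls", "hwe_p_exact", "hwe_p_chisq", "hwe_not_applicable",
    ])


def qc_report(
    calls: Sequence[GenotypeCall],
    participants: Sequence[ParticipantRecord],
    panel: Sequence[SNPDefinition],
    call_rate_threshold: float = 0.98,
    hwe_alpha: float = 0.001,
) -> pd.DataFrame:
    """One QC row per SNP: call rate, counts, HWE p-values and pass/fail flags.

    SNPs failing a check are flagged, never dropped here; the pipeline decides
    what to do with flagged SNPs.
    """
    control_ids = {p.participant_id for p in participants if not p.is_case}
    n_total = len(participants)
    rows = []
    for snp in panel:
        snp_calls = [c for c in calls if c.rs_id == snp.rs_id]
        rate, rate_ok = call_rate(snp_calls, n_total, call_rate_threshold)
        control_counts = genotype_counts(
            (c for c in snp_calls if c.participant_id in control_ids), snp
        )
        observed_classes = sum(
            1 for k in (control_counts.n_AA, control_counts.n_Aa, control_counts.n_aa)
            if k > 0
        )
        if observed_classes >= 3:
            hwe = hwe_exact(control_counts)
            p_exact, p_chisq, stat = hwe.p_exact, hwe.p_chisq, hwe.chisq_stat
            hwe_ok = p_exact >= hwe_alpha
            hwe_na = False
        else:
            p_exact = p_chisq = stat = float("nan")
            hwe_ok, hwe_na = True, True
        rows.append({
            "rs_id": snp.rs_id,
            "gene": snp.gene,
            "call_rate": rate,
            "call_rate_pass": rate_ok,
            "n_AA_controls": control_counts.n_AA,
            "n_Aa_controls": control_counts.n_Aa,
            "n_aa_controls": control_counts.n_aa,
            "hwe_p_exact": p_exact,
            "hwe_p_chisq": p_chisq,
            "hwe_chisq_stat": stat,
            "hwe_not_applicable": hwe_na,
            "hwe_pass": hwe_ok,
            "qc_pass": bool(rate_ok and hwe_ok),
        })
    return pd.DataFrame(rows)
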