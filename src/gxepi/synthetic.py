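"""Synthetic matched case-control studies with known gene-drug interaction.

The generator inverts the analysis model: a source population is organized
into small latent clusters (sharing hospital, sex and a narrow age band, each
with its own random intercept), genotypes are drawn in Hardy-Weinberg
proportions, drug exposure depends on covariates through a shared logistic
term (so confounding is real, not cosmetic), and case status follows

    logit P(case) = alpha + b10*G1 + b11*G2 + b01*G3 + gamma'x
                    + u_hospital + u_period + u_cluster

where (G1, G2, G3) are the drug(+)/wild, drug(+)/carrier and drug(-)/carrier
indicators for the focal SNP and drug class, and b.. are the logs of the
target odds ratios.  Each sampled case is then matched with ``controls_per_case``
controls from its own cluster, so every matched stratum shares hospital, sex,
an age gap within the matching tolerance, and the cluster random effect --
exactly the structure the nested random-intercept analysis assumes.  The true
additive-interaction summaries (RERI, S) implied by the target odds ratios
are stored in the truth record along with every parameter and realized random
effect; everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .core_data import (
    DrugRecord,
    GenotypeCall,
    ParticipantRecord,
    SNPDefinition,
    ValidationError,
)

__all__ = [
    "ConfounderSpec",
    "SimulationScenario",
    "SimulatedStudy",
    "MatchingInfeasibleError",
    "simulate_study",
    "make_fixture",
    "FIXTURE_NAMES",
]


class MatchingInfeasibleError(Exception):
    """Too few eligible clusters to form the requested matched strata."""


@dataclass(frozen=True)
class ConfounderSpec:
    """A binary covariate: prevalence, log-OR on outcome, log-OR on exposure."""

    prevalence: float
    log_or_outcome: float
    log_or_exposure: float


def _default_snps() -> tuple[tuple[SNPDefinition, float], ...]:
    # focal SNP emulates a common C>G variant (variant allele freq ~0.64,
    # carrier prevalence ~87%); the second SNP is a null A>G locus (~0.22)
    return (
        (SNPDefinition("rs_focal", "C", ("G",), gene="GSTA2_like"), 0.64),
        (SNPDefinition("rs_null", "A", ("G",), gene="CYP24A1_like"), 0.22),
    )


def _default_confounders() -> Mapping[str, ConfounderSpec]:
    # prevalences and outcome effects echo the descriptive table of the
    # emulated study (H. pylori OR ~2.5, anticoagulants OR ~3.1); the
    # exposure associations make change-in-estimate selection non-trivial
    return {
        "h_pylori": ConfounderSpec(0.77, math.log(2.5), 0.3),
        "anticoagulant_use": ConfounderSpec(0.05, math.log(3.1), 0.5),
        "arthrosis": ConfounderSpec(0.29, 0.0, 0.0),  # null covariate
    }


@dataclass
class SimulationScenario:
    """Generative parameters; defaults emulate the reported study design.

    326 cases recruited from 4 hospitals over 2 periods, ~1:2 matching on
    hospital/sex/age(+-5y), 74% male, ages 30-85, NSAID exposure in a 7-day
    pre-index window, and target group odds ratios on the focal drug class.
    """

    n_cases: int = 326
    controls_per_case: int = 2
    n_hospitals: int = 4
    n_periods: int = 2
    snps: tuple[tuple[SNPDefinition, float], ...] = field(default_factory=_default_snps)
    focal_rs_id: str = "rs_focal"
    focal_drug_class: str = "any_nsaid"
    p_exposed: Mapping[str, float] = field(
        default_factory=lambda: {"non_aspirin_nsaid": 0.13, "aspirin": 0.03}
    )
    or10: float = 3.17
    or01: float = 0.74
    or11: float = 7.30
    confounder_spec: Mapping[str, ConfounderSpec] = field(default_factory=_default_confounders)
    sd_stratum: float = 0.3
    sd_hospital: float = 0.3
    sd_period: float = 0.3
    baseline_odds: float = 0.25
    p_male: float = 0.74
    age_range: tuple[float, float] = (30.0, 85.0)
    exposure_window_days: int = 7
    missing_call_rate: float = 0.005
    cluster_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (("or10", self.or10), ("or01", self.or01), ("or11", self.or11)):
            if not value > 0:
                raise ValidationError(f"{name} must be positive")
        for snp, maf in self.snps:
            if not 0.0 <= maf <= 1.0:
                raise ValidationError(f"{snp.rs_id}: maf outside [0, 1]")
        for sd in (self.sd_stratum, self.sd_hospital, self.sd_period):
            if sd < 0:
                raise ValidationError("random-intercept SDs must be non-negative")

    @property
    def reri_true(self) -> float:
        return self.or11 - self.or10 - self.or01 + 1.0

    @property
    def s_true(self) -> float | None:
        denom = (self.or10 - 1.0) + (self.or01 - 1.0)
        return None if abs(denom) < 1e-12 else (self.or11 - 1.0) / denom


@dataclass
class SimulatedStudy:
    participants: list[ParticipantRecord]
    genotypes: list[GenotypeCall]
    panel: list[SNPDefinition]
    truth: dict


_CLASS_MEMBERS = {
    "any_nsaid": ("aspirin", "non_aspirin_nsaid"),
    "non_aspirin": ("non_aspirin_nsaid",),
    "aspirin": ("aspirin",),
}


def simulate_study(scenario: SimulationScenario) -> SimulatedStudy:
    """Generate one matched case-control study plus its truth record."""
    rng = np.random.default_rng(scenario.seed)
    m = scenario.controls_per_case
    cluster_size = scenario.cluster_size or max(8, m + 4)
    n_clusters = int(math.ceil(scenario.n_cases * 1.8))
    n_pop = n_clusters * cluster_size

    u_hospital = rng.normal(0.0, scenario.sd_hospital, scenario.n_hospitals)
    u_period = rng.normal(0.0, scenario.sd_period, scenario.n_periods)
    u_cluster = rng.normal(0.0, scenario.sd_stratum, n_clusters)

    cluster_hospital = rng.integers(0, scenario.n_hospitals, n_clusters)
    cluster_period = rng.integers(0, scenario.n_periods, n_clusters)
    cluster_sex = np.where(rng.random(n_clusters) < scenario.p_male, "male", "female")
    lo, hi = scenario.age_range
    cluster_age = rng.uniform(lo + 2.5, hi - 2.5, n_clusters)

    cluster_of = np.repeat(np.arange(n_clusters), cluster_size)
    age = cluster_age[cluster_of] + rng.uniform(-2.5, 2.5, n_pop)

    # covariates
    covar: dict[str, np.ndarray] = {}
    for name, spec in scenario.confounder_spec.items():
        covar[name] = (rng.random(n_pop) < spec.prevalence).astype(float)

    # exposure per recorded drug class, shifted by covariate associations
    exposure_shift = np.zeros(n_pop)
    for name, spec in scenario.confounder_spec.items():
        exposure_shift += spec.log_or_exposure * covar[name]
    exposed: dict[str, np.ndarray] = {}
    for drug, p0 in scenario.p_exposed.items():
        exposed[drug] = rng.random(n_pop) < expit(logit(p0) + exposure_shift)

    # genotypes in Hardy-Weinberg proportions
    genotype_nvar: dict[str, np.ndarray] = {}
    for snp, maf in scenario.snps:
        a1 = rng.random(n_pop) < maf
        a2 = rng.random(n_pop) < maf
        genotype_nvar[snp.rs_id] = a1.astype(int) + a2.astype(int)

    members = _CLASS_MEMBERS[scenario.focal_drug_class]
    focal_exposed = np.zeros(n_pop, dtype=bool)
    for drug in members:
        if drug in exposed:
            focal_exposed |= exposed[drug]
    carrier = genotype_nvar[scenario.focal_rs_id] >= 1
    g1 = focal_exposed & ~carrier
    g2 = focal_exposed & carrier
    g3 = ~focal_exposed & carrier

    eta = (
        math.log(scenario.baseline_odds)
        + math.log(scenario.or10) * g1
        + math.log(scenario.or11) * g2
        + math.log(scenario.or01) * g3
        + u_hospital[cluster_hospital[cluster_of]]
        + u_period[cluster_period[cluster_of]]
        + u_cluster[cluster_of]
    )
    for name, spec in scenario.confounder_spec.items():
        eta = eta + spec.log_or_outcome * covar[name]
    is_case_pop = rng.random(n_pop) < expit(eta)

    # Emulate consecutive enrolment: every incident case is eligible and forms
    # its own matched set; its controls are non-case members of its own
    # cluster (same hospital, sex, age band and cluster random effect), drawn
    # without replacement so no control serves two strata.
    participants: list[ParticipantRecord] = []
    genotype_rows: list[GenotypeCall] = []
    control_pool: dict[int, list[int]] = {}
    for c in range(n_clusters):
        idx = np.flatnonzero(cluster_of == c)
        pool = idx[~is_case_pop[idx]].tolist()
        rng.shuffle(pool)
        control_pool[c] = pool
    all_cases = np.flatnonzero(is_case_pop)
    order = rng.permutation(len(all_cases))
    chosen: list[tuple[int, int, list[int]]] = []
    for case in all_cases[order]:
        c = int(cluster_of[case])
        if len(control_pool[c]) >= m:
            ctrl = [control_pool[c].pop() for _ in range(m)]
            chosen.append((c, int(case), ctrl))
        if len(chosen) == scenario.n_cases:
            break
    if len(chosen) < scenario.n_cases:
        raise MatchingInfeasibleError(
            f"only {len(chosen)} of {scenario.n_cases} matched strata could be "
            f"formed; raise baseline_odds or the cluster count"
        )

    window = scenario.exposure_window_days
    for stratum_no, (c, case_idx, ctrl_idx) in enumerate(chosen):
        sid = f"S{stratum_no:05d}"
        for i in [case_idx, *ctrl_idx]:
            pid = f"P{i:06d}"
            records: list[DrugRecord] = []
            for drug in ("aspirin", "non_aspirin_nsaid"):
                if drug in exposed and exposed[drug][i]:
                    records.append(DrugRecord(drug, int(rng.integers(0, window + 1))))
                elif rng.random() < 0.10:  # out-of-window decoy record
                    records.append(DrugRecord(drug, int(rng.integers(window + 1, 31))))
            if rng.random() < 0.20:
                records.append(DrugRecord("other", int(rng.integers(0, 31))))
            gi_draw = rng.random()
            participants.append(ParticipantRecord(
                participant_id=pid,
                is_case=bool(is_case_pop[i]),
                stratum_id=sid,
                hospital_id=f"H{cluster_hospital[c]}",
                period_id=f"T{cluster_period[c]}",
                age=float(round(age[i], 1)),
                sex=str(cluster_sex[c]),
                arthrosis=bool(covar.get("arthrosis", np.zeros(n_pop))[i]),
                h_pylori="yes" if covar.get("h_pylori", np.zeros(n_pop))[i] else "no_or_uncertain",
                gi_history=("none_or_dyspepsia" if gi_draw < 0.86
                            else "ulcer" if gi_draw < 0.94 else "bleeding"),
                ppi_use=bool(covar.get("ppi_use", np.zeros(n_pop))[i]),
                antiaggregant_use=bool(covar.get("antiaggregant_use", np.zeros(n_pop))[i]),
                anticoagulant_use=bool(covar.get("anticoagulant_use", np.zeros(n_pop))[i]),
                n_interviews=int(1 + (rng.random() < 0.14)),
                interview_reliability=float(rng.integers(5, 11)),
                drug_records=records,
            ))
            for snp, _ in scenario.snps:
                if rng.random() < scenario.missing_call_rate:
                    genotype_rows.append(GenotypeCall(pid, snp.rs_id, None))
                    continue
                n_var = genotype_nvar[snp.rs_id][i]
                wild, var = snp.wild_allele, snp.variant_alleles[0]
                pair = tuple(sorted([wild, wild] if n_var == 0
                                    else [wild, var] if n_var == 1 else [var, var]))
                genotype_rows.append(GenotypeCall(pid, snp.rs_id, pair))

    sampled = [i for _, case, ctrl in chosen for i in [case, *ctrl]]
    truth = {
        "scenario": {
            **{k: v for k, v in asdict(scenario).items()
               if k not in ("snps", "confounder_spec", "p_exposed")},
            "p_exposed": dict(scenario.p_exposed),
            "confounder_spec": {k: asdict(v) for k, v in scenario.confounder_spec.items()},
            "snps": [{"rs_id": s.rs_id, "wild": s.wild_allele,
                      "variants": list(s.variant_alleles), "maf": maf}
                     for s, maf in scenario.snps],
        },
        "reri_true": scenario.reri_true,
        "s_true": scenario.s_true,
        "log_or": {"g1": math.log(scenario.or10), "g2": math.log(scenario.or11),
                   "g3": math.log(scenario.or01)},
        "n_population": int(n_pop),
        "n_population_cases": int(is_case_pop.sum()),
        "n_strata": len(chosen),
        "group_counts_sampled": {
            "g1": int(g1[sampled].sum()), "g2": int(g2[sampled].sum()),
            "g3": int(g3[sampled].sum()),
            "g4": int((~focal_exposed & ~carrier)[sampled].sum()),
        },
        "random_effects": {
            "hospital": u_hospital.tolist(),
            "period": u_period.tolist(),
            "stratum": [float(u_cluster[c]) for c, _, _ in chosen],
        },
        "seed": scenario.seed,
    }
    return SimulatedStudy(
        participants=participants,
        genotypes=genotype_rows,
        panel=[snp for snp, _ in scenario.snps],
        truth=truth,
    )


def _fixture_scenarios() -> dict[str, SimulationScenario]:
    base = dict(
        n_hospitals=2, n_periods=2, controls_per_case=2,
        sd_stratum=0.2, sd_hospital=0.2, sd_period=0.2,
        confounder_spec={
            "h_pylori": ConfounderSpec(0.5, math.log(2.0), 0.2),
            "arthrosis": ConfounderSpec(0.3, 0.0, 0.0),
        },
    )
    return {
        # or11 = or10*or01 and RERI = 0 simultaneously: null on both scales
        "tiny-null": SimulationScenario(
            n_cases=40, or10=2.0, or01=1.0, or11=2.0, seed=101, **base,
        ),
        "tiny-synergy": SimulationScenario(
            n_cases=60, or10=2.0, or01=1.5, or11=5.0, seed=102, **base,
        ),
        "tiny-monovariant": SimulationScenario(
            n_cases=40, or10=2.0, or01=1.5, or11=5.0, seed=103,
            snps=(
                (SNPDefinition("rs_focal", "C", ("G",), gene="GSTA2_like"), 0.5),
                # maf 0: every subject homozygous wild at this locus
                (SNPDefinition("rs_mono", "T", ("C",), gene="CYP2B6_like"), 0.0),
            ),
            missing_call_rate=0.0,
            **base,
        ),
    }


FIXTURE_NAMES = tuple(sorted(_fixture_scenarios()))


def make_fixture(name: str) -> SimulatedStudy:
    """Deterministic bundled test datasets (<=200 subjects, documented truth).

    * ``tiny-null``: no interaction on either scale (RERI=0, S=1 in truth);
    * ``tiny-synergy``: positive additive interaction (RERI=2.5, S=2.67);
    * ``tiny-monovariant``: includes a locus with a single observed genotype.
    """
    scenarios = _fixture_scenarios()
    if name not in scenarios:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(scenarios)}")
    return simulate_study(scenarios[name])
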