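# gxepi

Additive gene–drug interaction analysis for matched case-control studies.

`gxepi` is a biostatistics toolkit for candidate-SNP pharmacoepidemiology of
the kind used to ask: *does carrying a variant in a drug-metabolising gene
amplify the risk that a drug causes an adverse outcome?*  The motivating
setting is a multicenter matched case-control study of upper gastrointestinal
haemorrhage (UGIH) in users of non-steroidal anti-inflammatory drugs
(NSAIDs), but every stage is generic: genotype QC, exposure derivation,
four-group interaction coding, mixed-effects odds-ratio estimation, and
additive-scale interaction measures.

## The statistical core

Participants are cross-classified by drug exposure (any record of the drug
class within the 7 days before the index date) and variant carriage
(dominant model: ≥ 1 variant allele) into four groups, with the
doubly-unexposed group as reference:

| group | exposure | genotype |
|-------|----------|----------|
| G1    | drug(+)  | wild-type |
| G2    | drug(+)  | variant carrier |
| G3    | drug(−)  | variant carrier |
| G4    | drug(−)  | wild-type (reference) |

Group odds ratios OR₁₀ (G1), OR₁₁ (G2) and OR₀₁ (G3) are estimated by a
logistic regression with nested Gaussian random intercepts — matched stratum
within hospital within recruitment period — fitted by Laplace-approximate
maximum likelihood (the model family `lme4::glmer` fits; the implementation
is validated against it).  Covariates enter either as a forced adjustment
set or through a change-in-estimate rule (≥ 10 % shift in a group OR *and*
a BIC improvement).

Departure from additivity of odds-ratio excesses is summarised by

```
RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1          (0  = no additive interaction)
S    = (OR₁₁ − 1) / ((OR₁₀ − 1) + (OR₀₁ − 1))   (1 = no additive interaction)
```

with delta-method or parametric-bootstrap confidence intervals from the
fitted coefficient covariance.

Genotype QC reports the per-SNP call rate and an exact Hardy–Weinberg test
in controls (full conditional enumeration of the heterozygote count), plus
the 1-df chi-square test.

Because raw data from such studies are rarely redistributable, the package
includes a synthetic-study generator (`gxepi.synthetic`) that inverts the
analysis model: clustered source population, Hardy–Weinberg genotypes,
covariate-linked exposure, outcome risk with chosen group odds ratios and
random intercepts, and 1:m matching on hospital, sex and age ± 5 years.
Every dataset ships with a truth record, so the whole pipeline is testable
end to end.

## Worked example

Desk arithmetic — the interaction implied by three adjusted odds ratios
(here OR₁₀ = 3.17, OR₀₁ = 0.74, OR₁₁ = 7.30):

```python
>>> from gxepi import reri, synergism_index
>>> reri(7.30, 3.17, 0.74)
4.39
>>> synergism_index(7.30, 3.17, 0.74)[0]
3.2984293193717...
```

RERI = 4.39 means the joint exposure carries an excess odds of 4.39 beyond
the sum of the two separate excesses; S = 3.30 means the joint excess is
3.3 times that sum.

End to end on a synthetic study generated with those same effect sizes
(1000 cases, 1:2 matching, random-intercept SDs 0.3):

```python
from gxepi import AnalysisConfig, SimulationScenario, simulate_study, run_analysis

study = simulate_study(SimulationScenario(n_cases=1000, controls_per_case=2, seed=1))
bundle = run_analysis(AnalysisConfig(drug_strata=("any_nsaid",)),
                      study.participants, study.genotypes, study.panel)
row = bundle.results[bundle.results.rs_id == "rs_focal"].iloc[0]
```

which for seed 1 prints (truth: RERI = 4.39, S = 3.30):

```
OR10 = 3.39 (1.97, 5.85)
OR01 = 0.77 (0.59, 1.00)
OR11 = 6.10 (4.41, 8.44)
RERI = 2.94 (0.79, 5.09)
S    = 2.36 (1.03, 5.40)
n used: 2983
```

A single replicate scatters around the truth — the 95 % intervals cover the
generative RERI here, and across seeds the median estimate centres on it
(see `tests/test_acceptance.py`).

## Command line

```bash
gxe simulate --scenario scenario.yaml --out data/ --seed 7   # CSVs + truth.json
gxe qc  --participants data/participants.csv --drugs data/drugs.csv \
        --genotypes data/genotypes.csv --panel data/panel.yaml --out qc.csv
gxe run --config config.yaml --out results/ --seed 7
```

`config.yaml` points at the data files and sets the analysis options
(drug strata, exposure window, model, confounder selection, interaction CI
method, minimum cell count); `results/` receives `results.csv` (one row per
SNP × drug stratum), `descriptive.csv`, `qc_report.csv`, `skip_log.csv` and
`run.json` with full provenance.  Re-running with the same config and seed
reproduces the outputs byte for byte.

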