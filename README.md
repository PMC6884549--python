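# berquant

Quantification toolkit for assays linking **alkyladenine DNA glycosylase
(AAG)-initiated base excision repair (BER)** to transcription elongation.
It is written for bench scientists and computational biologists who have the
raw measurement tables — qPCR Ct values, flow-cytometry events,
differential-expression results, comet-assay intensities — and need the
downstream quantities those assays are designed to yield:

* **Damage qPCR** — region-specific AAG-substrate (lesion) frequencies from
  glycosylase/AP-endonuclease digestion Ct shifts. With lesions per
  amplicon ~ Poisson(λ) and per-cycle efficiency E, the intact fraction is
  e^(−λ), so ΔCt = Ct(+AAG+APE1) − Ct(APE1-only) = λ/ln E and
  λ̂ = max(ΔCt, 0)·ln E, reported relative to each gene's promoter.
* **ChIP-qPCR** — percent input,
  %input = 100·E^((Ct_input − log_E(1/f)) − Ct_IP) for input fraction f,
  and occupancy relative to the promoter region.
* **FM-HCR** — flow-cytometry host-cell reactivation repair scoring:
  F = N·MFI/S, F^O = F/F^E, %R.E. = 100·F^O_dam/F^O_un, after live-singlet
  gating.
* **DEG co-regulation** — Benjamini–Hochberg FDR, fold/FDR DEG calling,
  two-knockout Venn overlap and direction-quadrant classification.
* **Comet FLARE** — percent tail DNA = 100·tail/(head+tail), group means
  ± SEM, and the AAG-specific contrast (+enzyme − buffer arm).
* **Synthetic data** — seeded generators for every assay with a recorded
  `SimulationTruth`, used throughout the test suite for parameter-recovery
  checks.

Analyses are exposed as scikit-learn-style estimators
(`LesionFrequencyEstimator`, `ChipOccupancyEstimator`,
`RelativeExpressionEstimator`, `RepairCapacityEstimator`, `DegCaller`,
`CoregulationAnalyzer`, `CometGroupSummarizer`) with `fit`,
trailing-underscore results and `get_params`/`set_params`, plus thin
module-level functions and a `berquant` CLI
(`simulate`, `lesions`, `chip`, `expression`, `fmhcr`, `coreg`, `comet`,
`run`).

## Worked example

Simulate a gene with a planted 5× 3′-end lesion enrichment (promoter
λ = 0.1, end λ = 0.5) and recover the gradient:

```python
import pandas as pd
import berquant as bq

landscapes = bq.gen_lesion_landscape(["ALDH1A2"], base_lambda=0.1, end_enrichment=5.0)
wells, truth = bq.simulate_damage_qpcr(landscapes, ct_noise_sd=0.15, seed=7)
est = bq.LesionFrequencyEstimator().fit(wells)
print(est.estimates_.to_string(index=False))
```

```
sample_id    gene   region  delta_ct  lambda_hat  clamped  rel_to_promoter
       WT ALDH1A2      end  0.733959    0.508741    False         2.797025
       WT ALDH1A2   middle  0.356691    0.247240    False         1.359306
       WT ALDH1A2 promoter  0.262407    0.181887    False         1.000000
```

One noisy 3-replicate experiment: the end region's Ct shift of 0.73 cycles
converts to λ̂ ≈ 0.51 lesions/amplicon — right on the planted 0.5 — while
the low promoter signal (planted 0.1, estimated 0.18 here) makes the
single-experiment ratio (2.8) noisy; averaging λ̂ across repeated
experiments before ratioing converges to the planted 5× (see
`docs/methods.md` on ratio bias).

Score repair capacity from a simulated FM-HCR experiment with a planted
per-cell repair probability of 0.5:

```python
samples, _ = bq.simulate_flow_experiment(
    bq.FlowSimConfig(n_events=10_000, repair_prob=0.5, seed=7)
)
sheet = pd.DataFrame({
    "sample_id": ["damaged", "undamaged"], "condition": ["WT", "WT"],
    "damaged": [True, False], "replicate": [1, 1],
})
print(bq.RepairCapacityEstimator().fit(samples, sheet).capacities_)
```

```
condition  percent_re  sem  n_replicates
       WT   51.663336  0.0           1.0
```

%R.E. ≈ 51.7 against the expected 100·r = 50: the damaged reporter is
expressed in about half the transfected live singlets.

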