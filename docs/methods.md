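# Methods

`berquant` quantifies five assay readouts used to study how alkyladenine DNA
glycosylase (AAG)-initiated base excision repair (BER) interacts with
transcription elongation. This note records the models behind each module,
the parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the underlying assay
conventions leave room.

## Damage qPCR (lesion mapping)

Sheared genomic DNA (~200 bp fragments) is digested with AAG + APE1, which
converts every AAG-substrate base into a strand break; an APE1-only arm
serves as baseline. A break inside an amplicon blocks amplification, so with
lesions per amplicon ~ Poisson(λ) the intact template fraction is
p = exp(−λ) and, at per-cycle efficiency E,

    ΔCt = Ct(+AAG+APE1) − Ct(APE1-only) = λ / ln E,
    λ̂  = max(ΔCt, 0) · ln E.

Assumptions: a single lesion fully blocks amplification (no partial
read-through), lesions are Poisson-distributed, and the APE1-only arm is
lesion-free (pre-existing AP sites/nicks can be planted at a separate rate
in the simulator). The analytic intact fraction is cross-checked against a
brute-force Monte-Carlo that places Poisson lesions on 10⁵ fragments and
counts survivors; agreement is within 1% for λ ≤ 2 at that fragment count
(the binomial standard error itself approaches 1% near λ = 3).

Parameters: `efficiency` (E, default 2.0 — perfect doubling, the universal
qPCR convention; override per assay if a standard curve says otherwise);
`ct_noise_sd` (default 0.15 cycles, a typical technical-replicate spread);
`n_replicates` (default 3 technical replicates, averaged on the Ct scale
*before* ΔCt, matching standard practice).

Promoter-relative levels: `rel_to_promoter = λ̂(region)/λ̂(promoter)` by
default (the physically interpretable quantity); a ΔΔCt cycle-difference
mode is selectable because the field's "relative amount" arithmetic is not
standardised. A promoter λ̂ of exactly 0 receives a pseudocount (default
0.01 lesions/amplicon) with a logged warning — such ratios are flagged as
unreliable rather than silently infinite.

**Ratio bias and pooling.** When the promoter lesion load sits near the
noise floor (λ = 0.1 is ~1.2 noise SDs from zero at the default settings),
the per-experiment ratio λ̂_end/λ̂_prom is strongly right-biased: E[1/X]
exceeds 1/E[X], and clamp/pseudocount events add a heavy upper tail (median
≈ planted ratio, mean ≈ 2.5× it over 200 simulations). Replicate
*experiments* should therefore be combined by averaging the per-region
unclamped ΔCt first and ratioing the averages (the same average-then-ratio
principle used for technical replicates on the Ct scale; ΔCt is unbiased
whereas the zero-clamped λ̂ is not near the noise floor). That pooled
estimator is consistent, and it is what the recovery tests and the
acceptance script report, with a delta-method standard error.

## ChIP-qPCR occupancy

With an input aliquot fraction f (e.g. 0.01 for 1% input),

    %input = 100 · E^((Ct_input − log_E(1/f)) − Ct_IP),
    relative occupancy = %input(region) / %input(promoter).

The formula is invariant to adding a constant to both Ct values. f is a
required experiment-specific parameter — percent input is meaningless
without it. Relative occupancy at the promoter is exactly 1 by
construction; ratios of noisy percent-input values are log-normal with
negligible bias at the default noise (0.15 cycles).

## FM-HCR flow-cytometry repair scoring

Repair capacity is read from expression of a reporter plasmid carrying a
site-specific hypoxanthine lesion; an undamaged EGFP plasmid co-transfected
in every sample controls for transfection efficiency. After gating:

    F = N · MFI / S,   F_O = F / F_E,   %R.E. = 100 · F_O(dam) / F_O(un)

with N = reporter-positive live singlets, MFI their arithmetic mean
intensity on the linear scale, S = all live singlets, F_E the same F on the
EGFP channel. The common verbal definition of Eq. 1 conflates N and S; the
reading used here (N positive, S all gated) makes F a per-cell-normalised
total signal and %R.E. a repair fraction — with matched intensity
distributions between damaged and undamaged samples, E[%R.E.] = 100·r where
r is the per-cell repair probability.

Gating: scatter bounds remove debris; an FSC-H/FSC-A ratio band
(default 0.85–1.15) removes doublets; a viability-dye ceiling removes dead
cells. Gating is idempotent and relaxing any bound can only grow the gated
set. Positivity thresholds are per-channel constants (defaults sit between
the simulator's background and positive populations, one decade below the
positive median); when an untransfected background sample is available its
99.9th percentile is the recommended threshold. Spillover/compensation is
not modelled — channels are treated as already compensated.

Replicate handling: the damaged/undamaged ratio is computed per biological
replicate, then replicates are summarised as mean ± SEM (ratio-then-average,
not average-then-ratio — each replicate is a self-contained paired
experiment, unlike the within-experiment pooling above where arms are
unpaired).

## Two-knockout DEG overlap

DE tables (gene, log2FC, p, FDR) are consumed, never fitted — the DE model
itself (negative-binomial shrinkage etc.) is upstream, external tooling. A
gene is called at thresholds (min_fold, max_fdr) iff
|log2FC| ≥ log2(min_fold) and FDR ≤ max_fdr (both inclusive; log2FC = 0 is
never called). Missing FDR columns are derived from p-values by
Benjamini–Hochberg (step-up; implemented via statsmodels and verified
against a brute-force step-up oracle in the tests). Calling is monotone:
tightening either threshold never adds genes.

The two-table analysis computes the exact Venn decomposition by gene
identifier (genes absent from one table are treated as non-DE there and
excluded from the overlap) and assigns every co-regulated gene to one of
four direction quadrants; quadrant counts always partition the overlap.
Default thresholds differ per table (1.5-fold for A, 2-fold for B),
mirroring the two-knockout design the default simulation emulates.

## Comet FLARE

Per-cell percent tail DNA = 100 · tail/(head + tail) — the standard
tail-percent statistic (Olive-moment variants are out of scope). Groups
(condition × enzyme arm) are summarised as mean ± SEM, with SEM reported
both across cells and across replicate means; the replicate-level SEM is
the honest inferential unit when cells within a slide are correlated.
"AAG-specific" damage is defined as mean(+AAG arm) − mean(buffer arm)
within a condition: the enzyme converts AAG-substrate bases into strand
breaks, so the arm difference isolates them from pre-existing breaks.
Group comparisons use a one-way layout: ANOVA plus Dunnett many-to-one
contrasts (`berquant.io.compare_groups`).

## Synthetic-data generators

Every generator is a pure function of its configuration including the seed
and returns a `SimulationTruth` recording every planted parameter, so each
estimator's expected value is available in closed form.

* **Lesion landscapes** — promoter λ = base, 3′ end λ = base × enrichment,
  middle = geometric mean: a monotone 3′-rising gradient (defaults
  base 0.1, enrichment 5). Deterministic.
* **Damage qPCR** — Ct = baseline + λ/ln E + N(0, sd); both digestion arms.
* **ChIP** — planted occupancies converted to percent-input, then to IP and
  input Ct values that invert the percent-input formula exactly when
  noiseless.
* **Flow** — independent Bernoulli transfection (default rate 0.4), death
  (0.10) and doublet (0.05) labels; two-component log-normal intensities
  per channel (background 10^N(2,0.2), positive 10^N(4,0.25)); doublets get
  a depressed FSC-H/FSC-A ratio, dead cells a positive viability dye.
* **DE tables** — planted genes: log2FC = sign·(effect + |N(0, sd)|),
  p ∈ [10⁻¹², 10⁻⁶]; nulls: log2FC ~ N(0, sd), p ~ U(0,1); FDR by BH per
  table. The default configuration plants 1,045 / 489 affected genes with a
  113-gene overlap whose plurality quadrant is up-in-A/down-in-B, on a
  10,000-gene background (effect 2.0 log2 units, noise SD 0.25).
* **Comet** — per-cell tail fraction ~ Beta(mk, (1−m)k) with group mean m
  and concentration k = 30; four replicates of 50 cells per group; default
  means 5% (both buffer arms), 8% (+AAG, control condition), 14% (+AAG,
  elongation-inhibited condition), so enzyme-revealed damage rises under
  transcription inhibition while baseline breaks do not.

What the simulators do **not** emulate: instrument drift and plate effects
in qPCR; fluorescence spillover, autofluorescence tails and acquisition-time
effects in flow; correlation between log2FC and mean expression (no
mean–variance trend) in DE tables; within-slide correlation beyond the
replicate label in comet data. Recovery tests passing on these simulations
therefore validate the estimators' arithmetic and statistical behaviour
under the stated generative models, not robustness to those real-data
artefacts.

## Numerical choices and degenerate inputs

* Negative ΔCt is reported unclamped in `delta_ct` but clamped to 0 for λ̂,
  with a `clamped` flag.
* Empty gate results are a warning condition, not an error; downstream
  signal computation raises on S = 0.
* Zero transfection-control or undamaged-control signals raise named
  errors rather than returning infinities.
* All tables are tidy CSV (UTF-8, "." decimal); gene regions use BED
  0-based half-open coordinates with `gene|region` names; every simulated
  dataset carries a JSON truth sidecar; pipeline outputs carry a provenance
  record (config hash, seed, package version).
* Problem sizes in the test and acceptance runs: 10⁵ fragments for the
  digestion oracle, 10⁴ events × 50 replicates per repair probability for
  flow recovery, 200 simulated experiments for the qPCR/ChIP recoveries and
  the null-FDP check, 1,000 random vectors for the BH oracle — sizes at
  which binomial/standard-error bounds are tight enough to be informative.

## Known limitations

* Amplification efficiency is assumed constant across regions and arms;
  primer-specific efficiencies from standard curves are accepted as
  parameters but not estimated.
* No Ct calling from raw fluorescence, no FCS file parsing, no automated
  (cluster-based) gating, no comet image segmentation — all upstream of
  this package.
* The per-experiment promoter-relative lesion ratio is biased near the
  promoter noise floor (see above); single-experiment ratios at low
  promoter signal should be interpreted via the flagged pseudocount /
  pooled across experiments.
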