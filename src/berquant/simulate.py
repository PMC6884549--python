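"""Synthetic assay data with recorded ground truth.

Every generator here emulates one of the package's readouts — damage qPCR,
ChIP-qPCR, FM-HCR flow cytometry, two-knockout DE tables, comet FLARE — with
the statistical structure the corresponding analysis assumes, and returns a
:class:`~berquant.configs.SimulationTruth` holding every planted parameter.
Generators are pure functions of their arguments including the seed: the
same seed yields byte-identical tables.

Generative models
-----------------
* **Damage qPCR** — lesions per ~200 bp amplicon ~ Poisson(lambda); a single
  lesion blocks amplification, so the intact template fraction is
  exp(-lambda) and Ct = baseline + lambda/ln(E) + N(0, sd). The APE1-only
  control arm is lesion-free by default (pre-existing AP sites/nicks can be
  planted at a separate rate).
* **ChIP-qPCR** — planted relative occupancy is converted to percent-input
  values and then to IP/input Ct pairs that invert the percent-input formula
  exactly in the noiseless limit.
* **Flow** — independent Bernoulli structure for transfection, death and
  doublets; two-component log-normal intensities per channel; doublets show
  a depressed FSC-H/FSC-A ratio, dead cells a positive viability dye. Among
  transfected live singlets the damaged reporter is fluorescent with
  probability r, the undamaged reporter always.
* **DE tables** — planted genes get log2FC = sign*(effect + |N(0, sd)|) and
  tiny p-values; nulls get log2FC ~ N(0, sd) and uniform p-values; FDR is
  Benjamini-Hochberg over each table.
* **Comet** — per-cell tail fraction ~ Beta(m*k, (1-m)*k) around the planted
  group mean m with concentration k; head/tail intensities scale a
  log-normal total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .configs import (
    QUADRANTS,
    DeSimConfig,
    FlowSimConfig,
    InvalidParameterError,
    SimulationTruth,
)
from .coregulation import bh_adjust
from .qpcr import PROMOTER, TREATMENT_MINUS, TREATMENT_PLUS

REGIONS = (PROMOTER, "middle", "end")

__all__ = [
    "LesionLandscape",
    "gen_lesion_landscape",
    "simulate_damage_qpcr",
    "simulate_chip_qpcr",
    "simulate_flow_experiment",
    "simulate_de_tables",
    "simulate_comet_cells",
    "intact_fraction_mc",
]


@dataclass(frozen=True)
class LesionLandscape:
    """Planted mean lesion counts per amplicon for one gene's regions."""

    gene: str
    region_lambdas: Mapping[str, float]
    amplicon_len_bp: int = 200

    def __post_init__(self) -> None:
        if self.amplicon_len_bp <= 0:
            raise InvalidParameterError("amplicon_len_bp must be > 0")
        if any(lam < 0 for lam in self.region_lambdas.values()):
            raise InvalidParameterError("lesion rates must be >= 0")
        if len(set(self.region_lambdas)) != len(self.region_lambdas):
            raise InvalidParameterError("region labels must be unique")


def gen_lesion_landscape(
    genes: Sequence[str],
    base_lambda: float = 0.1,
    end_enrichment: float = 5.0,
    seed: int = 0,
) -> list[LesionLandscape]:
    """Three-region lesion landscapes with a 3'-end gradient.

    The promoter carries ``base_lambda`` lesions per amplicon, the 3' end
    ``base_lambda * end_enrichment``, and the gene middle their geometric
    mean — a monotone gradient rising toward the 3' end whenever
    end_enrichment > 1. Deterministic; the seed is carried along for
    provenance only.
    """
    if base_lambda < 0:
        raise InvalidParameterError(f"base_lambda must be >= 0, got {base_lambda}")
    if end_enrichment <= 0:
        raise InvalidParameterError(f"end_enrichment must be > 0, got {end_enrichment}")
    out = []
    for g in genes:
        lam_p = base_lambda
        lam_e = base_lambda * end_enrichment
        lam_m = math.sqrt(lam_p * lam_e)
        out.append(
            LesionLandscape(
                gene=str(g),
                region_lambdas={PROMOTER: lam_p, "middle": lam_m, "end": lam_e},
            )
        )
    return out


def intact_fraction_mc(lam: float, n_fragments: int = 100_000, seed: int = 0) -> float:
    """Brute-force digestion oracle: fraction of fragments with zero lesions.

    Draws Poisson(lam) lesions on each of ``n_fragments`` fragments and
    counts the fragments left intact; the analytic value is exp(-lam).
    """
    rng = np.random.default_rng(seed)
    lesions = rng.poisson(lam, size=n_fragments)
    return float((lesions == 0).mean())


def simulate_damage_qpcr(
    landscapes: LesionLandscape | Sequence[LesionLandscape],
    n_replicates: int = 3,
    efficiency: float = 2.0,
    ct_noise_sd: float = 0.15,
    baseline_ct: float = 25.0,
    control_lambda: float = 0.0,
    seed: int = 0,
    sample_id: str = "WT",
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate both digestion arms of the lesion assay for each landscape.

    The +AAG+APE1 arm amplifies the intact fraction exp(-lambda), shifting
    Ct by lambda/ln(E) over baseline; the APE1-only arm sees only
    ``control_lambda`` (pre-existing AP sites/strand breaks, zero by
    default). E[Ct(+) - Ct(-)] = (lambda - control_lambda)/ln(E).
    """
    if efficiency <= 1:
        raise InvalidParameterError(f"efficiency must be > 1, got {efficiency}")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    if ct_noise_sd < 0:
        raise InvalidParameterError("ct_noise_sd must be >= 0")
    if isinstance(landscapes, LesionLandscape):
        landscapes = [landscapes]
    rng = np.random.default_rng(seed)
    ln_e = math.log(efficiency)
    rows = []
    for ls in landscapes:
        for region, lam in ls.region_lambdas.items():
            for treatment, lam_arm in (
                (TREATMENT_PLUS, lam),
                (TREATMENT_MINUS, control_lambda),
            ):
                shift = lam_arm / ln_e
                noise = rng.normal(0.0, ct_noise_sd, size=n_replicates)
                for rep in range(n_replicates):
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "gene": ls.gene,
                            "region": region,
                            "treatment": treatment,
                            "replicate": rep + 1,
                            "ct": baseline_ct + shift + noise[rep],
                        }
                    )
    wells = pd.DataFrame(rows)
    truth = SimulationTruth(
        kind="damage_qpcr",
        seed=seed,
        params={
            "lambdas": {ls.gene: dict(ls.region_lambdas) for ls in landscapes},
            "control_lambda": control_lambda,
            "efficiency": efficiency,
            "ct_noise_sd": ct_noise_sd,
            "baseline_ct": baseline_ct,
            "n_replicates": n_replicates,
        },
    )
    return wells, truth


def simulate_chip_qpcr(
    occupancy: Mapping[str, float],
    input_fraction: float = 0.01,
    ct_noise_sd: float = 0.15,
    n_replicates: int = 3,
    seed: int = 0,
    gene: str = "GENE",
    sample_id: str = "WT",
    base_percent_input: float = 1.0,
    input_ct: float = 25.0,
    efficiency: float = 2.0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate IP and input Ct wells from a planted occupancy profile.

    The planted percent-input of each region is
    ``base_percent_input * occupancy[region]``; IP Ct values are constructed
    so that the percent-input formula recovers them exactly when
    ct_noise_sd = 0.
    """
    if any(v <= 0 for v in occupancy.values()):
        raise InvalidParameterError("occupancy levels must be > 0")
    if not (0 < input_fraction < 1):
        raise InvalidParameterError("input_fraction must be in (0, 1)")
    if efficiency <= 1:
        raise InvalidParameterError("efficiency must be > 1")
    rng = np.random.default_rng(seed)
    rows = []
    for region, occ in occupancy.items():
        pct = base_percent_input * occ
        # invert: pct = 100 * E**((input_ct - log_E(1/f)) - ct_ip)
        ct_ip = (
            input_ct
            - math.log(1.0 / input_fraction, efficiency)
            - math.log(pct / 100.0, efficiency)
        )
        for treatment, ct0 in (("IP", ct_ip), ("input", input_ct)):
            noise = rng.normal(0.0, ct_noise_sd, size=n_replicates)
            for rep in range(n_replicates):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "gene": gene,
                        "region": region,
                        "treatment": treatment,
                        "replicate": rep + 1,
                        "ct": ct0 + noise[rep],
                    }
                )
    wells = pd.DataFrame(rows)
    truth = SimulationTruth(
        kind="chip_qpcr",
        seed=seed,
        params={
            "occupancy": dict(occupancy),
            "input_fraction": input_fraction,
            "base_percent_input": base_percent_input,
            "efficiency": efficiency,
            "ct_noise_sd": ct_noise_sd,
            "n_replicates": n_replicates,
        },
    )
    return wells, truth


def _flow_channel(rng, positive: np.ndarray, model) -> np.ndarray:
    loc = np.where(positive, model.positive_loc, model.background_loc)
    scale = np.where(positive, model.positive_scale, model.background_scale)
    return 10.0 ** rng.normal(loc, scale)


def _flow_sample(rng, config: FlowSimConfig, reporter_on_prob: float) -> pd.DataFrame:
    n = config.n_events
    transfected = rng.random(n) < config.transfection_rate
    dead = rng.random(n) < config.dead_fraction
    doublet = rng.random(n) < config.doublet_fraction
    fsc_a = 10.0 ** rng.normal(4.0, 0.15, size=n)
    ratio = np.where(
        doublet, rng.normal(0.55, 0.05, size=n), rng.normal(1.0, 0.03, size=n)
    )
    ssc_a = 10.0 ** rng.normal(3.5, 0.2, size=n)
    viability = _flow_channel(rng, dead, config.viability_channel)
    egfp = _flow_channel(rng, transfected, config.egfp_channel)
    reporter_on = transfected & (rng.random(n) < reporter_on_prob)
    reporter = _flow_channel(rng, reporter_on, config.reporter_channel)
    return pd.DataFrame(
        {
            "fsc_a": fsc_a,
            "fsc_h": fsc_a * ratio,
            "ssc_a": ssc_a,
            "viability": viability,
            "ch_egfp": egfp,
            "ch_reporter": reporter,
        }
    )


def simulate_flow_experiment(
    config: FlowSimConfig,
) -> tuple[dict[str, pd.DataFrame], SimulationTruth]:
    """Simulate a damaged-reporter and an undamaged-reporter flow sample.

    Both samples share the EGFP transfection-control structure; on the
    damaged sample the reporter channel is positive with probability
    ``repair_prob`` among transfected cells, on the undamaged sample with
    probability 1. Expected downstream %R.E. is therefore
    100 * repair_prob.
    """
    rng = np.random.default_rng(config.seed)
    samples = {
        "damaged": _flow_sample(rng, config, config.repair_prob),
        "undamaged": _flow_sample(rng, config, 1.0),
    }
    truth = SimulationTruth(
        kind="flow",
        seed=config.seed,
        params={
            "repair_prob": config.repair_prob,
            "transfection_rate": config.transfection_rate,
            "dead_fraction": config.dead_fraction,
            "doublet_fraction": config.doublet_fraction,
            "n_events": config.n_events,
            "expected_percent_re": 100.0 * config.repair_prob,
        },
    )
    return samples, truth


def _planted_table(
    rng,
    genes: np.ndarray,
    planted: dict[str, int],
    effect: float,
    noise_sd: float,
) -> pd.DataFrame:
    """Build one DE table; ``planted`` maps gene -> +1/-1 sign (absent = null)."""
    n = len(genes)
    lfc = rng.normal(0.0, noise_sd, size=n)
    pvals = rng.uniform(0.0, 1.0, size=n)
    for i, g in enumerate(genes):
        s = planted.get(g)
        if s is not None:
            lfc[i] = s * (effect + abs(rng.normal(0.0, noise_sd)))
            pvals[i] = 10.0 ** (-rng.uniform(6.0, 12.0))
    fdr = bh_adjust(pvals)
    return pd.DataFrame({"gene": genes, "log2fc": lfc, "pvalue": pvals, "fdr": fdr})


def simulate_de_tables(
    config: DeSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Simulate paired knockout-vs-WT DE tables with a planted overlap.

    Planted genes carry |log2FC| >= effect_size with the assigned sign and
    p-values in [1e-12, 1e-6]; null genes get log2FC ~ N(0, noise_sd) and
    uniform p-values. The truth records every planted set and quadrant.
    """
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    perm = rng.permutation(config.n_genes)

    i = 0
    a_only = [genes[perm[j]] for j in range(i, i + config.n_a_only)]
    i += config.n_a_only
    b_only = [genes[perm[j]] for j in range(i, i + config.n_b_only)]
    i += config.n_b_only
    quad_genes: dict[str, list[str]] = {}
    for q in QUADRANTS:
        k = int(config.overlap_quadrants.get(q, 0))
        quad_genes[q] = [genes[perm[j]] for j in range(i, i + k)]
        i += k

    sign = {"up": 1, "down": -1}
    planted_a: dict[str, int] = {}
    planted_b: dict[str, int] = {}
    for g in a_only:
        planted_a[g] = 1 if rng.random() < config.a_only_up_fraction else -1
    for g in b_only:
        planted_b[g] = 1 if rng.random() < config.b_only_up_fraction else -1
    for q, gl in quad_genes.items():
        da, db = q.split("_")
        for g in gl:
            planted_a[g] = sign[da]
            planted_b[g] = sign[db]

    table_a = _planted_table(rng, genes, planted_a, config.effect_size, config.noise_sd)
    table_b = _planted_table(rng, genes, planted_b, config.effect_size, config.noise_sd)
    truth = SimulationTruth(
        kind="de_tables",
        seed=config.seed,
        params={
            "a_only": sorted(a_only),
            "b_only": sorted(b_only),
            "overlap_quadrants": {q: sorted(g) for q, g in quad_genes.items()},
            "n_overlap": config.n_overlap,
            "effect_size": config.effect_size,
            "noise_sd": config.noise_sd,
            "n_genes": config.n_genes,
        },
    )
    return table_a, table_b, truth


#: Default planted mean tail fractions per (condition, enzyme) group:
#: transcription inhibition (DRB) raises AAG-revealed damage but not the
#: buffer-arm baseline.
DEFAULT_COMET_MEANS: dict[tuple[str, str], float] = {
    ("DMSO", "buffer"): 0.05,
    ("DMSO", "AAG"): 0.08,
    ("DRB", "buffer"): 0.05,
    ("DRB", "AAG"): 0.14,
}


def simulate_comet_cells(
    n_cells: int = 50,
    mean_tail_fractions: Mapping[tuple[str, str], float] | None = None,
    dispersion: float = 30.0,
    seed: int = 0,
    n_replicates: int = 4,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate per-cell comet head/tail intensities for each group.

    ``n_cells`` cells per replicate, ``n_replicates`` replicates per
    (condition, enzyme) group. Per-cell tail fraction ~ Beta(m*k, (1-m)*k)
    with group mean m and concentration k = ``dispersion``; total comet
    intensity is log-normal.
    """
    means = dict(mean_tail_fractions or DEFAULT_COMET_MEANS)
    for grp, m in means.items():
        if not (0.0 < m < 1.0):
            raise InvalidParameterError(
                f"mean tail fraction for {grp} must be in (0, 1), got {m}"
            )
    if n_cells < 1 or n_replicates < 1 or dispersion <= 0:
        raise InvalidParameterError("n_cells, n_replicates >= 1 and dispersion > 0 required")
    rng = np.random.default_rng(seed)
    rows = []
    cid = 0
    for (cond, enz), m in means.items():
        for rep in range(1, n_replicates + 1):
            frac = rng.beta(m * dispersion, (1.0 - m) * dispersion, size=n_cells)
            total = 10.0 ** rng.normal(4.0, 0.1, size=n_cells)
            for j in range(n_cells):
                rows.append(
                    {
                        "cell_id": f"c{cid:06d}",
                        "condition": cond,
                        "enzyme": enz,
                        "replicate": rep,
                        "head_intensity": total[j] * (1.0 - frac[j]),
                        "tail_intensity": total[j] * frac[j],
                    }
                )
                cid += 1
    cells = pd.DataFrame(rows)
    truth = SimulationTruth(
        kind="comet",
        seed=seed,
        params={
            "mean_percent_tail": {f"{c}|{e}": 100.0 * m for (c, e), m in means.items()},
            "dispersion": dispersion,
            "n_cells_per_replicate": n_cells,
            "n_replicates": n_replicates,
        },
    )
    return cells, truth
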