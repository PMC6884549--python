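"""Ct-table quantification: lesion mapping, ChIP occupancy, relative expression.

Three assays share the same raw data shape — a tidy table of qPCR wells with
one Ct value per (sample, gene, region, treatment, replicate) — and the same
exponential amplification model with per-cycle efficiency E:

* **Lesion assay.** Genomic DNA is digested with a DNA glycosylase (AAG) plus
  AP endonuclease (APE1); every excised aberrant base becomes a strand break
  that blocks amplification of the covering amplicon. With lesions per
  amplicon ~ Poisson(lambda), the intact fraction is exp(-lambda) and the Ct
  shift against the APE1-only control arm is
  ``delta_ct = lambda / ln(E)``, inverted here as
  ``lambda_hat = max(delta_ct, 0) * ln(E)``.
* **ChIP.** Immunoprecipitated DNA is expressed as percent of the input
  aliquot, then as occupancy relative to the promoter region.
* **Expression.** Delta-delta-Ct fold change against a reference gene
  (GAPDH by default) and a calibrator sample.

Table-level estimators follow the scikit-learn convention: ``fit`` validates
and computes, results live in trailing-underscore attributes, ``transform``
re-applies the computation to a new table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .configs import InvalidParameterError, QpcrAssayConfig

logger = logging.getLogger(__name__)

TREATMENT_PLUS = "AAG+APE1"
TREATMENT_MINUS = "APE1-only"
PROMOTER = "promoter"

__all__ = [
    "GeneRegion",
    "MissingDataError",
    "aggregate_ct",
    "lesion_delta_ct",
    "lesion_frequency",
    "relative_lesions",
    "percent_input",
    "relative_occupancy",
    "relative_expression",
    "LesionFrequencyEstimator",
    "ChipOccupancyEstimator",
    "RelativeExpressionEstimator",
]


class MissingDataError(KeyError):
    """A required group (e.g. a promoter row or a treatment arm) is absent."""


@dataclass(frozen=True)
class GeneRegion:
    """A qPCR amplicon target in BED convention (0-based, half-open)."""

    gene: str
    region: str
    chrom: str
    start: int
    end: int
    amplicon_len_bp: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InvalidParameterError(
                f"region {self.gene}|{self.region}: start must be < end"
            )


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not np.isfinite(v):
            raise ValueError(f"{name}: non-finite Ct value {v!r}")


def aggregate_ct(
    wells: pd.DataFrame,
    by: Sequence[str] = ("sample_id", "gene", "region", "treatment"),
) -> pd.DataFrame:
    """Average technical replicates on the Ct scale.

    Returns one row per group with columns ``ct`` (arithmetic mean) and
    ``n_replicates``. Raises on an empty table or non-finite Ct values.
    """
    if len(wells) == 0:
        raise MissingDataError("empty well table: nothing to aggregate")
    ct = pd.to_numeric(wells["ct"], errors="coerce")
    if not np.isfinite(ct).all():
        bad = wells.loc[~np.isfinite(ct)]
        raise ValueError(f"non-finite Ct in {len(bad)} well(s), e.g. {bad.iloc[0].to_dict()}")
    keys = [k for k in by if k in wells.columns]
    out = (
        wells.assign(ct=ct)
        .groupby(list(keys), sort=True, observed=True)["ct"]
        .agg(ct="mean", n_replicates="size")
        .reset_index()
    )
    return out


def lesion_delta_ct(ct_plus: float, ct_minus: float) -> float:
    """Ct(+AAG+APE1) minus Ct(APE1-only) for one region.

    Negative values are allowed (they arise from technical noise at low
    lesion load) and are clamped only later, when converting to a frequency.
    """
    _require_finite("lesion_delta_ct", ct_plus, ct_minus)
    return float(ct_plus) - float(ct_minus)


def lesion_frequency(delta_ct: float, config: QpcrAssayConfig | None = None) -> float:
    """Poisson lesion frequency per amplicon from a Ct shift.

    Inverts the intact-fraction model p = exp(-lambda) = E**(-delta_ct):
    lambda_hat = max(delta_ct, 0) * ln(E). Negative shifts clamp to zero.
    """
    config = config or QpcrAssayConfig()
    _require_finite("lesion_frequency", delta_ct)
    if delta_ct < 0:
        logger.debug("negative delta_ct %.4f clamped to 0 for lambda_hat", delta_ct)
    return max(float(delta_ct), 0.0) * math.log(config.efficiency)


def relative_lesions(
    estimates: pd.DataFrame,
    promoter_region: str = PROMOTER,
    mode: str = "lambda_ratio",
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Fill ``rel_to_promoter`` per gene.

    ``mode="lambda_ratio"`` (default) reports lambda_hat(region) /
    lambda_hat(promoter); ``mode="ddct"`` reports the delta-delta-Ct
    difference delta_ct(region) - delta_ct(promoter) in cycles. A promoter
    lambda_hat of zero receives ``pseudocount`` (with a logged warning) so
    the ratio stays finite; the promoter row is exactly 1 in ratio mode and
    exactly 0 in ddct mode.
    """
    if mode not in ("lambda_ratio", "ddct"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    out = estimates.copy()
    rel = np.empty(len(out))
    for gene, idx in out.groupby("gene").groups.items():
        sub = out.loc[idx]
        prom = sub[sub["region"] == promoter_region]
        if prom.empty:
            raise MissingDataError(f"gene {gene!r}: no {promoter_region!r} row")
        if mode == "lambda_ratio":
            denom = float(prom["lambda_hat"].iloc[0])
            if denom == 0.0:
                logger.warning(
                    "gene %s: promoter lambda_hat = 0, applying pseudocount %g",
                    gene,
                    pseudocount,
                )
                denom = pseudocount
            vals = sub["lambda_hat"].to_numpy(dtype=float) / denom
            vals[sub["region"].to_numpy() == promoter_region] = 1.0
        else:
            base = float(prom["delta_ct"].iloc[0])
            vals = sub["delta_ct"].to_numpy(dtype=float) - base
            vals[sub["region"].to_numpy() == promoter_region] = 0.0
        rel[out.index.get_indexer(idx)] = vals
    out["rel_to_promoter"] = rel
    return out


def percent_input(
    ct_ip: float, ct_input: float, config: QpcrAssayConfig | None = None
) -> float:
    """ChIP signal as percent of total chromatin input.

    The measured input aliquot is first corrected to 100% of chromatin by
    subtracting log_E(1 / input_fraction) cycles, then
    percent = 100 * E**(adjusted_input_ct - ct_ip). Adding a constant to
    both Ct values leaves the result unchanged.
    """
    config = config or QpcrAssayConfig()
    _require_finite("percent_input", ct_ip, ct_input)
    e = config.efficiency
    adjusted = ct_input - math.log(1.0 / config.input_fraction, e)
    return 100.0 * e ** (adjusted - ct_ip)


def relative_occupancy(
    occupancies: pd.DataFrame, promoter_region: str = PROMOTER
) -> pd.DataFrame:
    """Fill ``relative_occupancy`` = percent_input(region) / percent_input(promoter)."""
    out = occupancies.copy()
    rel = np.empty(len(out))
    for gene, idx in out.groupby("gene").groups.items():
        sub = out.loc[idx]
        prom = sub[sub["region"] == promoter_region]
        if prom.empty:
            raise MissingDataError(f"gene {gene!r}: no {promoter_region!r} row")
        denom = float(prom["percent_input"].iloc[0])
        if denom <= 0:
            raise ZeroDivisionError(
                f"gene {gene!r}: promoter percent_input is {denom}, cannot normalise"
            )
        vals = sub["percent_input"].to_numpy(dtype=float) / denom
        vals[sub["region"].to_numpy() == promoter_region] = 1.0
        rel[out.index.get_indexer(idx)] = vals
    out["relative_occupancy"] = rel
    return out


def relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
    config: QpcrAssayConfig | None = None,
) -> float:
    """Delta-delta-Ct fold change of a target gene vs a calibrator sample.

    fold = E**(-[(Ct_t,s - Ct_ref,s) - (Ct_t,c - Ct_ref,c)]), with the
    reference gene (e.g. GAPDH) absorbing loading differences.
    """
    config = config or QpcrAssayConfig()
    _require_finite(
        "relative_expression",
        ct_target_sample,
        ct_ref_sample,
        ct_target_calibrator,
        ct_ref_calibrator,
    )
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return config.efficiency ** (-ddct)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


class _QpcrTableEstimator(BaseEstimator, TransformerMixin):
    """Shared fit/transform plumbing for stateless qPCR table transformers."""

    def fit(self, X: pd.DataFrame, y=None):
        self.estimates_ = self._compute(X)
        self.n_wells_in_ = int(len(X))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self._compute(X)

    def _compute(self, X: pd.DataFrame) -> pd.DataFrame:  # pragma: no cover
        raise NotImplementedError


class LesionFrequencyEstimator(_QpcrTableEstimator):
    """Region-specific glycosylase-substrate levels from a lesion-assay Ct table.

    Parameters
    ----------
    efficiency : float, default 2.0
        qPCR amplification factor per cycle.
    mode : {"lambda_ratio", "ddct"}, default "lambda_ratio"
        How the promoter-relative level is expressed.
    pseudocount : float, default 0.01
        Stand-in promoter lambda_hat when the promoter shows zero signal.
    promoter_region, treatment_plus, treatment_minus : str
        Labels identifying the normalising region and the two digestion arms.

    Attributes
    ----------
    estimates_ : DataFrame
        One row per (sample, gene, region) with ``delta_ct``, ``lambda_hat``,
        ``clamped`` and ``rel_to_promoter``.
    """

    def __init__(
        self,
        efficiency: float = 2.0,
        mode: str = "lambda_ratio",
        pseudocount: float = 0.01,
        promoter_region: str = PROMOTER,
        treatment_plus: str = TREATMENT_PLUS,
        treatment_minus: str = TREATMENT_MINUS,
    ):
        self.efficiency = efficiency
        self.mode = mode
        self.pseudocount = pseudocount
        self.promoter_region = promoter_region
        self.treatment_plus = treatment_plus
        self.treatment_minus = treatment_minus

    def _compute(self, wells: pd.DataFrame) -> pd.DataFrame:
        cfg = QpcrAssayConfig(efficiency=self.efficiency)
        agg = aggregate_ct(wells)
        keys = [k for k in ("sample_id", "gene", "region") if k in agg.columns]
        wide = agg.pivot_table(
            index=keys, columns="treatment", values="ct", observed=True
        )
        for arm in (self.treatment_plus, self.treatment_minus):
            if arm not in wide.columns:
                raise MissingDataError(f"treatment arm {arm!r} absent from well table")
        missing = wide[[self.treatment_plus, self.treatment_minus]].isna().any(axis=1)
        if missing.any():
            raise MissingDataError(
                f"{int(missing.sum())} group(s) lack one digestion arm, "
                f"e.g. {wide.index[missing][0]}"
            )
        out = wide.reset_index()
        out["delta_ct"] = out[self.treatment_plus] - out[self.treatment_minus]
        out["clamped"] = out["delta_ct"] < 0
        ln_e = math.log(cfg.efficiency)
        out["lambda_hat"] = np.maximum(out["delta_ct"], 0.0) * ln_e
        out = out[keys + ["delta_ct", "lambda_hat", "clamped"]]
        return relative_lesions(
            out,
            promoter_region=self.promoter_region,
            mode=self.mode,
            pseudocount=self.pseudocount,
        )


class ChipOccupancyEstimator(_QpcrTableEstimator):
    """Percent-input and promoter-relative occupancy from a ChIP-qPCR Ct table.

    Expects wells with ``treatment`` in {"IP", "input"}. The input aliquot
    fraction must be supplied; the assay cannot be normalised without it.

    Attributes
    ----------
    estimates_ : DataFrame
        One row per (sample, gene, region) with ``percent_input`` and
        ``relative_occupancy`` (promoter row exactly 1).
    """

    def __init__(
        self,
        input_fraction: float = 0.01,
        efficiency: float = 2.0,
        promoter_region: str = PROMOTER,
        ip_label: str = "IP",
        input_label: str = "input",
    ):
        self.input_fraction = input_fraction
        self.efficiency = efficiency
        self.promoter_region = promoter_region
        self.ip_label = ip_label
        self.input_label = input_label

    def _compute(self, wells: pd.DataFrame) -> pd.DataFrame:
        cfg = QpcrAssayConfig(
            efficiency=self.efficiency, input_fraction=self.input_fraction
        )
        agg = aggregate_ct(wells)
        keys = [k for k in ("sample_id", "gene", "region") if k in agg.columns]
        wide = agg.pivot_table(
            index=keys, columns="treatment", values="ct", observed=True
        )
        for arm in (self.ip_label, self.input_label):
            if arm not in wide.columns:
                raise MissingDataError(f"treatment arm {arm!r} absent from well table")
        out = wide.reset_index()
        adj = out[self.input_label] - math.log(
            1.0 / cfg.input_fraction, cfg.efficiency
        )
        out["percent_input"] = 100.0 * cfg.efficiency ** (adj - out[self.ip_label])
        out = out[keys + ["percent_input"]]
        return relative_occupancy(out, promoter_region=self.promoter_region)


class RelativeExpressionEstimator(_QpcrTableEstimator):
    """Delta-delta-Ct mRNA fold changes against a reference gene and calibrator.

    Expects RT-qPCR wells with one row per (sample, gene, replicate). Fold
    change of every non-reference gene is computed per sample, normalised to
    ``reference_gene`` and expressed relative to ``calibrator_sample``
    (which then sits at fold_change = 1 by construction).
    """

    def __init__(
        self,
        calibrator_sample: str = "WT",
        reference_gene: str = "GAPDH",
        efficiency: float = 2.0,
    ):
        self.calibrator_sample = calibrator_sample
        self.reference_gene = reference_gene
        self.efficiency = efficiency

    def _compute(self, wells: pd.DataFrame) -> pd.DataFrame:
        agg = aggregate_ct(wells, by=("sample_id", "gene"))
        wide = agg.pivot_table(
            index="sample_id", columns="gene", values="ct", observed=True
        )
        if self.reference_gene not in wide.columns:
            raise MissingDataError(
                f"reference gene {self.reference_gene!r} absent from well table"
            )
        if self.calibrator_sample not in wide.index:
            raise MissingDataError(
                f"calibrator sample {self.calibrator_sample!r} absent from well table"
            )
        dct = wide.sub(wide[self.reference_gene], axis=0)
        ddct = dct.sub(dct.loc[self.calibrator_sample], axis=1)
        fold = self.efficiency ** (-ddct)
        out = (
            fold.drop(columns=[self.reference_gene])
            .reset_index()
            .melt(id_vars="sample_id", var_name="gene", value_name="fold_change")
            .dropna(subset=["fold_change"])
            .sort_values(["gene", "sample_id"])
            .reset_index(drop=True)
        )
        return out
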