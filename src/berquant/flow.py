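"""FM-HCR repair-capacity scoring from flow-cytometry event tables.

Fluorescence-based host-cell reactivation (FM-HCR) infers base excision
repair capacity from a transfected reporter plasmid carrying a site-specific
lesion (hypoxanthine, an AAG substrate): transcriptional mutagenesis at the
unrepaired lesion yields a non-fluorescent protein, so reporter fluorescence
is proportional to repair. The quantification chain is

    F   = N * MFI / S          per-cell-normalised reporter signal
    F_O = F / F_E              normalised to the EGFP transfection control
    %R.E. = 100 * F_O_dam / F_O_un

where N is the number of reporter-positive live singlets, MFI their mean
fluorescence intensity (arithmetic, linear scale), S the number of all live
singlets, and F_E the same F computed on the EGFP control channel.

Events are gated on scatter bounds (debris/aggregates), an FSC-H/FSC-A
ratio band (doublets) and a viability-dye ceiling (dead cells) before any
signal is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .configs import GateConfig, InvalidParameterError

EVENT_COLUMNS = ("fsc_a", "fsc_h", "ssc_a", "viability", "ch_egfp", "ch_reporter")

__all__ = [
    "EmptySampleError",
    "PairingError",
    "ReporterResult",
    "gate_live_singlets",
    "reporter_signal",
    "normalize_to_transfection",
    "percent_reporter_expression",
    "analyze_experiment",
    "RepairCapacityEstimator",
]


class EmptySampleError(ValueError):
    """No events survive gating, or a control signal is zero."""


class PairingError(KeyError):
    """A condition/replicate lacks its damaged or undamaged counterpart."""


@dataclass(frozen=True)
class ReporterResult:
    """Per-sample, per-channel reporter quantities (N, MFI, S, F)."""

    n_positive: int
    mfi: float
    n_live: int
    f_signal: float


def gate_live_singlets(events: pd.DataFrame, config: GateConfig | None = None) -> pd.DataFrame:
    """Retain live singlet cells: inside scatter bounds, inside the
    FSC-H/FSC-A singlet band, below the viability-dye ceiling.

    Idempotent. An empty result is returned as-is (downstream signal
    computation then raises); it is not an error here.
    """
    config = config or GateConfig()
    if len(events) == 0:
        raise EmptySampleError("empty event table")
    fsc_a = events["fsc_a"].to_numpy(dtype=float)
    ratio = np.divide(
        events["fsc_h"].to_numpy(dtype=float),
        fsc_a,
        out=np.zeros(len(events)),
        where=fsc_a > 0,
    )
    lo, hi = config.fsc_a_range
    slo, shi = config.ssc_a_range
    blo, bhi = config.singlet_ratio_band
    keep = (
        (fsc_a >= lo)
        & (fsc_a <= hi)
        & (events["ssc_a"].to_numpy(dtype=float) >= slo)
        & (events["ssc_a"].to_numpy(dtype=float) <= shi)
        & (ratio >= blo)
        & (ratio <= bhi)
        & (events["viability"].to_numpy(dtype=float) <= config.viability_max)
    )
    return events.loc[keep]


def reporter_signal(
    gated: pd.DataFrame, channel: str, config: GateConfig | None = None
) -> ReporterResult:
    """Compute F = N * MFI / S on one fluorescence channel of a gated sample.

    N counts events above the channel's positivity threshold, MFI is their
    arithmetic mean intensity on the linear scale, S is the gated event
    count. With no positive events F = 0 and MFI is reported as 0.
    """
    config = config or GateConfig()
    s = len(gated)
    if s == 0:
        raise EmptySampleError("no live singlet events: cannot compute reporter signal")
    intens = gated[channel].to_numpy(dtype=float)
    pos = intens > config.threshold(channel)
    n = int(pos.sum())
    mfi = float(intens[pos].mean()) if n else 0.0
    return ReporterResult(n_positive=n, mfi=mfi, n_live=s, f_signal=n * mfi / s)


def normalize_to_transfection(f: float, f_e: float) -> float:
    """F_O = F / F_E, the reporter signal per unit transfection efficiency."""
    if f_e <= 0:
        raise EmptySampleError(
            f"EGFP transfection-control signal is {f_e}; cannot normalise"
        )
    return f / f_e


def percent_reporter_expression(f_o_dam: float, f_o_un: float) -> float:
    """%R.E. = 100 * F_O(damaged) / F_O(undamaged)."""
    if f_o_un <= 0:
        raise EmptySampleError(
            f"undamaged-control normalised signal is {f_o_un}; cannot compute %R.E."
        )
    return 100.0 * f_o_dam / f_o_un


def _sample_f_o(events: pd.DataFrame, config: GateConfig, reporter_channel: str,
                egfp_channel: str) -> float:
    gated = gate_live_singlets(events, config)
    f = reporter_signal(gated, reporter_channel, config).f_signal
    f_e = reporter_signal(gated, egfp_channel, config).f_signal
    return normalize_to_transfection(f, f_e)


def analyze_experiment(
    events_by_sample: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    config: GateConfig | None = None,
    reporter_channel: str = "ch_reporter",
    egfp_channel: str = "ch_egfp",
) -> pd.DataFrame:
    """Per-condition repair capacity from a set of paired flow samples.

    ``samples`` is a sample sheet with columns ``sample_id``, ``condition``,
    ``damaged`` (boolean) and ``replicate``. For each (condition, replicate)
    pair the damaged and undamaged F_O are ratioed into a %R.E.; replicate
    values are then summarised as mean +/- SEM per condition.
    """
    config = config or GateConfig()
    required = {"sample_id", "condition", "damaged", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise KeyError(f"sample sheet missing columns: {sorted(missing)}")

    f_o: dict[str, float] = {}
    for sid in samples["sample_id"]:
        if sid not in events_by_sample:
            raise PairingError(f"no event table for sample {sid!r}")
        f_o[sid] = _sample_f_o(
            events_by_sample[sid], config, reporter_channel, egfp_channel
        )

    rows = []
    for (cond, rep), grp in samples.groupby(["condition", "replicate"]):
        dam = grp[grp["damaged"].astype(bool)]
        und = grp[~grp["damaged"].astype(bool)]
        if len(dam) != 1 or len(und) != 1:
            raise PairingError(
                f"condition {cond!r} replicate {rep!r}: need exactly one damaged "
                f"and one undamaged sample, got {len(dam)}/{len(und)}"
            )
        pre = percent_reporter_expression(
            f_o[dam["sample_id"].iloc[0]], f_o[und["sample_id"].iloc[0]]
        )
        rows.append({"condition": cond, "replicate": rep, "percent_re": pre})
    per_rep = pd.DataFrame(rows)

    def _summ(g: pd.DataFrame) -> pd.Series:
        v = g["percent_re"].to_numpy(dtype=float)
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        return pd.Series(
            {"percent_re": float(v.mean()), "sem": sem, "n_replicates": len(v)}
        )

    summary = per_rep.groupby("condition").apply(_summ, include_groups=False).reset_index()
    summary.attrs["per_replicate"] = per_rep
    return summary


class RepairCapacityEstimator(BaseEstimator):
    """Scikit-learn-style wrapper around the full FM-HCR analysis.

    Parameters mirror :class:`~berquant.configs.GateConfig` as flat scalars
    so they work with ``get_params``/``set_params`` and grid search.

    ``fit(X, samples)`` takes a mapping sample_id -> event table and the
    sample sheet; fitted attributes are ``capacities_`` (per-condition
    %R.E. mean +/- SEM) and ``per_replicate_`` (the underlying ratios).
    """

    def __init__(
        self,
        fsc_a_min: float = 1e2,
        fsc_a_max: float = 1e7,
        ssc_a_min: float = 1e2,
        ssc_a_max: float = 1e7,
        singlet_ratio_min: float = 0.85,
        singlet_ratio_max: float = 1.15,
        viability_max: float = 1e3,
        egfp_threshold: float = 1e3,
        reporter_threshold: float = 1e3,
        reporter_channel: str = "ch_reporter",
        egfp_channel: str = "ch_egfp",
    ):
        self.fsc_a_min = fsc_a_min
        self.fsc_a_max = fsc_a_max
        self.ssc_a_min = ssc_a_min
        self.ssc_a_max = ssc_a_max
        self.singlet_ratio_min = singlet_ratio_min
        self.singlet_ratio_max = singlet_ratio_max
        self.viability_max = viability_max
        self.egfp_threshold = egfp_threshold
        self.reporter_threshold = reporter_threshold
        self.reporter_channel = reporter_channel
        self.egfp_channel = egfp_channel

    def gate_config(self) -> GateConfig:
        return GateConfig(
            fsc_a_range=(self.fsc_a_min, self.fsc_a_max),
            ssc_a_range=(self.ssc_a_min, self.ssc_a_max),
            singlet_ratio_band=(self.singlet_ratio_min, self.singlet_ratio_max),
            viability_max=self.viability_max,
            positivity_thresholds={
                self.egfp_channel: self.egfp_threshold,
                self.reporter_channel: self.reporter_threshold,
            },
        )

    def fit(self, X: dict[str, pd.DataFrame], samples: pd.DataFrame):
        summary = analyze_experiment(
            X,
            samples,
            config=self.gate_config(),
            reporter_channel=self.reporter_channel,
            egfp_channel=self.egfp_channel,
        )
        self.capacities_ = summary
        self.per_replicate_ = summary.attrs["per_replicate"]
        return self

    def fit_predict(self, X: dict[str, pd.DataFrame], samples: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X, samples).capacities_
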