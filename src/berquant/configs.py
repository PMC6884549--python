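"""Configuration and ground-truth containers shared across assay modules.

All containers are plain dataclasses with eager validation in
``__post_init__``: invalid parameters fail at construction time, before any
simulation or analysis runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping


class InvalidParameterError(ValueError):
    """A configuration value is outside its physically meaningful range."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise InvalidParameterError(f"{name} must be in [0, 1], got {value}")


@dataclass
class QpcrAssayConfig:
    """Parameters of the qPCR readout shared by lesion, ChIP and expression assays.

    Parameters
    ----------
    efficiency : float
        Amplification factor per cycle E. Perfect doubling (E = 2) is the
        universal qPCR convention and the default.
    input_fraction : float
        Fraction of chromatin kept aside as the ChIP "input" aliquot
        (e.g. 0.01 for a 1% input). Only used by percent-input arithmetic.
    ct_aggregation : str
        Rule for collapsing technical replicates; only "mean" is implemented.
    """

    efficiency: float = 2.0
    input_fraction: float = 0.01
    ct_aggregation: str = "mean"

    def __post_init__(self) -> None:
        if not self.efficiency > 1.0:
            raise InvalidParameterError(
                f"efficiency must be > 1, got {self.efficiency}"
            )
        if not (0.0 < self.input_fraction < 1.0):
            raise InvalidParameterError(
                f"input_fraction must be in (0, 1), got {self.input_fraction}"
            )
        if self.ct_aggregation != "mean":
            raise InvalidParameterError(
                f"unsupported ct_aggregation {self.ct_aggregation!r}"
            )


@dataclass
class GateConfig:
    """Flow-cytometry gating thresholds.

    Scatter bounds remove debris and aggregates, the FSC-H/FSC-A ratio band
    removes doublets, and the viability ceiling removes dye-positive dead
    cells. Positivity thresholds split each fluorescence channel into
    background and positive populations; by default they sit one decade
    below the positive-population median used by the simulator.
    """

    fsc_a_range: tuple[float, float] = (1e2, 1e7)
    ssc_a_range: tuple[float, float] = (1e2, 1e7)
    singlet_ratio_band: tuple[float, float] = (0.85, 1.15)
    viability_max: float = 1e3
    positivity_thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"ch_egfp": 1e3, "ch_reporter": 1e3}
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("fsc_a_range", self.fsc_a_range),
            ("ssc_a_range", self.ssc_a_range),
            ("singlet_ratio_band", self.singlet_ratio_band),
        ):
            if not lo < hi:
                raise InvalidParameterError(f"{name} interval is empty: {(lo, hi)}")
        if self.viability_max < 0:
            raise InvalidParameterError("viability_max must be >= 0")
        for ch, thr in self.positivity_thresholds.items():
            if thr < 0:
                raise InvalidParameterError(
                    f"positivity threshold for {ch} must be >= 0, got {thr}"
                )

    def threshold(self, channel: str) -> float:
        try:
            return float(self.positivity_thresholds[channel])
        except KeyError:
            raise InvalidParameterError(
                f"no positivity threshold configured for channel {channel!r}"
            ) from None


@dataclass
class DegThresholds:
    """Differential-expression cutoffs: minimum fold change and maximum FDR.

    A gene is called differentially expressed when |log2FC| >= log2(min_fold)
    and FDR <= max_fdr (both comparisons inclusive).
    """

    min_fold: float = 1.5
    max_fdr: float = 0.1

    def __post_init__(self) -> None:
        if self.min_fold < 1.0:
            raise InvalidParameterError(f"min_fold must be >= 1, got {self.min_fold}")
        if not (0.0 < self.max_fdr <= 1.0):
            raise InvalidParameterError(f"max_fdr must be in (0, 1], got {self.max_fdr}")

    @property
    def min_abs_log2fc(self) -> float:
        return math.log2(self.min_fold)


@dataclass
class ChannelModel:
    """Two-component log-normal intensity model for one fluorescence channel.

    Locations and scales are on the log10 scale; the background component
    models autofluorescence, the positive component the expressing population.
    """

    background_loc: float = 2.0
    background_scale: float = 0.2
    positive_loc: float = 4.0
    positive_scale: float = 0.25

    def __post_init__(self) -> None:
        if self.background_scale <= 0 or self.positive_scale <= 0:
            raise InvalidParameterError("channel scales must be > 0")


@dataclass
class FlowSimConfig:
    """Generative model of one FM-HCR flow experiment.

    ``repair_prob`` is the probability that a transfected cell repairs the
    lesion on the damaged reporter plasmid and therefore expresses the
    fluorescent reporter; the undamaged reporter expresses in every
    transfected cell. The expected downstream percent reporter expression is
    100 x repair_prob.
    """

    n_events: int = 10_000
    transfection_rate: float = 0.4
    repair_prob: float = 0.5
    dead_fraction: float = 0.10
    doublet_fraction: float = 0.05
    reporter_channel: ChannelModel = field(default_factory=ChannelModel)
    egfp_channel: ChannelModel = field(default_factory=ChannelModel)
    viability_channel: ChannelModel = field(default_factory=ChannelModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise InvalidParameterError(f"n_events must be > 0, got {self.n_events}")
        _check_prob("transfection_rate", self.transfection_rate)
        _check_prob("repair_prob", self.repair_prob)
        _check_prob("dead_fraction", self.dead_fraction)
        _check_prob("doublet_fraction", self.doublet_fraction)


#: Quadrant labels for co-regulated genes: direction in table A / table B.
QUADRANTS = ("up_up", "up_down", "down_up", "down_down")


@dataclass
class DeSimConfig:
    """Planted structure for a pair of knockout-vs-WT DE tables.

    Defaults emulate the two-knockout comparison the package targets:
    1,045 genes affected in table A and 489 in table B with a 113-gene
    overlap whose plurality quadrant is up-in-A / down-in-B, on a
    10,000-gene background.
    """

    n_genes: int = 10_000
    n_a_only: int = 932
    n_b_only: int = 376
    overlap_quadrants: Mapping[str, int] = field(
        default_factory=lambda: {
            "up_up": 20,
            "up_down": 70,
            "down_up": 8,
            "down_down": 15,
        }
    )
    a_only_up_fraction: float = 0.6
    b_only_up_fraction: float = 0.3
    effect_size: float = 2.0
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise InvalidParameterError("n_genes must be > 0")
        if self.effect_size <= 0:
            raise InvalidParameterError("effect_size must be > 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        _check_prob("a_only_up_fraction", self.a_only_up_fraction)
        _check_prob("b_only_up_fraction", self.b_only_up_fraction)
        unknown = set(self.overlap_quadrants) - set(QUADRANTS)
        if unknown:
            raise InvalidParameterError(f"unknown quadrant labels: {sorted(unknown)}")
        if any(v < 0 for v in self.overlap_quadrants.values()):
            raise InvalidParameterError("quadrant counts must be >= 0")
        if self.n_a_only < 0 or self.n_b_only < 0:
            raise InvalidParameterError("planted set sizes must be >= 0")
        if self.n_planted > self.n_genes:
            raise InvalidParameterError(
                f"planted counts ({self.n_planted}) exceed n_genes ({self.n_genes})"
            )

    @property
    def n_overlap(self) -> int:
        return int(sum(self.overlap_quadrants.values()))

    @property
    def n_planted(self) -> int:
        return self.n_a_only + self.n_b_only + self.n_overlap


@dataclass
class SimulationTruth:
    """Every planted parameter of one synthetic dataset, plus the seed.

    ``params`` holds the generator-specific ground truth (per-region lesion
    rates, repair probability, occupancy profile, planted gene sets and
    quadrants, comet group means) in JSON-serialisable form, sufficient to
    compute the expected value of each downstream estimator in closed form.
    """

    kind: str
    seed: int
    params: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        return cls(kind=d["kind"], seed=int(d["seed"]), params=d["params"])
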