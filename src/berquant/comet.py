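"""Comet-FLARE summarisation: per-cell percent tail DNA to group contrasts.

Single-cell gel electrophoresis with a lesion-specific glycosylase digestion
step (FLARE): incubating lysed comets with AAG converts its substrate bases
into strand breaks, so the extra tail DNA in the +enzyme arm over the buffer
arm reports AAG-specific lesions. Image segmentation happens upstream; this
module consumes per-cell head/tail intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = ["CometSummary", "percent_tail_dna", "summarize_groups", "CometGroupSummarizer"]


@dataclass
class CometSummary:
    """Group-level comet statistics.

    ``groups`` has one row per (condition, enzyme) with mean percent tail,
    SEM across cells, SEM across replicate means, and n. ``contrasts`` has
    one row per condition with the AAG-specific signal
    mean(+AAG) - mean(buffer).
    """

    groups: pd.DataFrame
    contrasts: pd.DataFrame


def percent_tail_dna(head: float, tail: float) -> float:
    """Percent of comet DNA in the tail: 100 * tail / (head + tail)."""
    if head < 0 or tail < 0:
        raise ValueError("intensities must be >= 0")
    total = head + tail
    if total == 0:
        raise ValueError("empty comet: head + tail intensity is 0")
    return 100.0 * tail / total


def summarize_groups(
    cells: pd.DataFrame, enzyme_arm: str = "AAG", buffer_arm: str = "buffer"
) -> CometSummary:
    """Summarise per-cell tail percentages into group means and enzyme contrasts.

    SEM is reported both across cells and across replicate means; the
    replicate-level SEM is the honest unit for inference when cells within a
    slide are correlated. Conditions missing a buffer arm get no contrast
    (logged warning), not an error.
    """
    if len(cells) == 0:
        raise ValueError("empty comet cell table")
    df = cells.copy()
    df["percent_tail"] = [
        percent_tail_dna(h, t)
        for h, t in zip(df["head_intensity"], df["tail_intensity"])
    ]

    rows = []
    for (cond, enz), grp in df.groupby(["condition", "enzyme"], sort=True):
        v = grp["percent_tail"].to_numpy(dtype=float)
        rep_means = grp.groupby("replicate")["percent_tail"].mean().to_numpy()
        rows.append(
            {
                "condition": cond,
                "enzyme": enz,
                "mean_percent_tail": float(v.mean()),
                "sem_cells": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
                "sem_replicates": float(
                    rep_means.std(ddof=1) / np.sqrt(len(rep_means))
                )
                if len(rep_means) > 1
                else 0.0,
                "n_cells": int(len(v)),
                "n_replicates": int(len(rep_means)),
            }
        )
    groups = pd.DataFrame(rows)

    crows = []
    for cond, grp in groups.groupby("condition"):
        arms = dict(zip(grp["enzyme"], grp["mean_percent_tail"]))
        if enzyme_arm not in arms or buffer_arm not in arms:
            logger.warning(
                "condition %r lacks a %s or %s arm; contrast omitted",
                cond,
                enzyme_arm,
                buffer_arm,
            )
            continue
        crows.append(
            {
                "condition": cond,
                "aag_specific_signal": arms[enzyme_arm] - arms[buffer_arm],
            }
        )
    contrasts = pd.DataFrame(crows, columns=["condition", "aag_specific_signal"])
    return CometSummary(groups=groups, contrasts=contrasts)


class CometGroupSummarizer(BaseEstimator):
    """Estimator wrapper over :func:`summarize_groups`.

    Fitted attributes: ``groups_`` and ``contrasts_`` DataFrames.
    """

    def __init__(self, enzyme_arm: str = "AAG", buffer_arm: str = "buffer"):
        self.enzyme_arm = enzyme_arm
        self.buffer_arm = buffer_arm

    def fit(self, X: pd.DataFrame, y=None):
        summary = summarize_groups(X, self.enzyme_arm, self.buffer_arm)
        self.groups_ = summary.groups
        self.contrasts_ = summary.contrasts
        return self

    def fit_predict(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).groups_
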