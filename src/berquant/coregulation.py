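"""Two-knockout DEG calling, overlap and direction-quadrant classification.

Consumes differential-expression result tables (gene, log2 fold change,
p-value, FDR) produced upstream by any DE fitter; no model fitting happens
here. Genes are called differentially expressed at a fold-change / FDR
cutoff, two knockout tables are intersected into a Venn layout, and each
co-regulated gene is classified into one of four direction quadrants
(up/up, up/down, down/up, down/down).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .configs import QUADRANTS, DegThresholds

__all__ = [
    "CoregulationSummary",
    "bh_adjust",
    "call_degs",
    "overlap_sets",
    "direction_quadrants",
    "DegCaller",
    "CoregulationAnalyzer",
]


@dataclass
class CoregulationSummary:
    """Venn counts and direction quadrants for two DEG sets."""

    n_a_only: int
    n_b_only: int
    n_overlap: int
    a_only: list[str] = field(default_factory=list)
    b_only: list[str] = field(default_factory=list)
    overlap: list[str] = field(default_factory=list)
    quadrant_counts: dict[str, int] = field(default_factory=dict)
    quadrant_genes: dict[str, list[str]] = field(default_factory=dict)

    @property
    def plurality_quadrant(self) -> str | None:
        if not self.quadrant_counts:
            return None
        return max(self.quadrant_counts, key=lambda q: self.quadrant_counts[q])

    def to_dict(self) -> dict:
        return {
            "n_a_only": self.n_a_only,
            "n_b_only": self.n_b_only,
            "n_overlap": self.n_overlap,
            "quadrant_counts": dict(self.quadrant_counts),
        }


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(records: pd.DataFrame, thresholds: DegThresholds | None = None) -> pd.Series:
    """Call differentially expressed genes at fold-change and FDR cutoffs.

    A gene is included iff |log2fc| >= log2(min_fold) and fdr <= max_fdr
    (a gene with log2fc exactly 0 is never included). If the table lacks an
    ``fdr`` column it is derived from ``pvalue`` by Benjamini-Hochberg.

    Returns a Series indexed by gene with values "up" / "down".
    """
    thresholds = thresholds or DegThresholds()
    df = records.copy()
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene identifier {dup!r} in DE table")
    if "fdr" not in df.columns or df["fdr"].isna().all():
        if "pvalue" not in df.columns:
            raise ValueError("DE table needs an 'fdr' or 'pvalue' column")
        df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    lfc = df["log2fc"].to_numpy(dtype=float)
    called = (
        (np.abs(lfc) >= thresholds.min_abs_log2fc)
        & (df["fdr"].to_numpy(dtype=float) <= thresholds.max_fdr)
        & (lfc != 0.0)
    )
    out = pd.Series(
        np.where(lfc[called] > 0, "up", "down"),
        index=pd.Index(df.loc[called, "gene"], name="gene"),
        name="direction",
    )
    return out


def overlap_sets(set_a: pd.Series, set_b: pd.Series) -> CoregulationSummary:
    """Exact Venn decomposition of two DEG sets by gene identifier."""
    a = set(set_a.index)
    b = set(set_b.index)
    a_only = sorted(a - b)
    b_only = sorted(b - a)
    inter = sorted(a & b)
    return CoregulationSummary(
        n_a_only=len(a_only),
        n_b_only=len(b_only),
        n_overlap=len(inter),
        a_only=a_only,
        b_only=b_only,
        overlap=inter,
    )


def direction_quadrants(
    summary: CoregulationSummary, set_a: pd.Series, set_b: pd.Series
) -> CoregulationSummary:
    """Assign each co-regulated gene to a direction quadrant.

    Quadrant labels are "<dirA>_<dirB>"; counts always partition the
    overlap.
    """
    counts = {q: 0 for q in QUADRANTS}
    genes: dict[str, list[str]] = {q: [] for q in QUADRANTS}
    for g in summary.overlap:
        try:
            q = f"{set_a.loc[g]}_{set_b.loc[g]}"
        except KeyError:
            raise ValueError(f"gene {g!r} in overlap lacks a direction") from None
        counts[q] += 1
        genes[q].append(g)
    assert sum(counts.values()) == summary.n_overlap
    summary.quadrant_counts = counts
    summary.quadrant_genes = genes
    return summary


class DegCaller(BaseEstimator):
    """Thresholding classifier for a DE result table.

    ``predict(X)`` returns a Series gene -> {"up", "down"} of called DEGs;
    ``fit`` records them in ``degs_``.
    """

    def __init__(self, min_fold: float = 1.5, max_fdr: float = 0.1):
        self.min_fold = min_fold
        self.max_fdr = max_fdr

    def _thresholds(self) -> DegThresholds:
        return DegThresholds(min_fold=self.min_fold, max_fdr=self.max_fdr)

    def fit(self, X: pd.DataFrame, y=None):
        self.degs_ = call_degs(X, self._thresholds())
        self.n_genes_in_ = int(len(X))
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        return call_degs(X, self._thresholds())


class CoregulationAnalyzer(BaseEstimator):
    """Two-table DEG overlap and directionality analysis.

    Thresholds may differ between tables (e.g. 1.5-fold for one knockout,
    2-fold for the other). ``fit((table_a, table_b))`` populates
    ``degs_a_``, ``degs_b_`` and ``summary_``.
    """

    def __init__(
        self,
        min_fold_a: float = 1.5,
        max_fdr_a: float = 0.1,
        min_fold_b: float = 2.0,
        max_fdr_b: float = 0.1,
    ):
        self.min_fold_a = min_fold_a
        self.max_fdr_a = max_fdr_a
        self.min_fold_b = min_fold_b
        self.max_fdr_b = max_fdr_b

    def fit(self, X: tuple[pd.DataFrame, pd.DataFrame], y=None):
        table_a, table_b = X
        self.degs_a_ = call_degs(
            table_a, DegThresholds(self.min_fold_a, self.max_fdr_a)
        )
        self.degs_b_ = call_degs(
            table_b, DegThresholds(self.min_fold_b, self.max_fdr_b)
        )
        summary = overlap_sets(self.degs_a_, self.degs_b_)
        self.summary_ = direction_quadrants(summary, self.degs_a_, self.degs_b_)
        return self

    def fit_predict(self, X: tuple[pd.DataFrame, pd.DataFrame]) -> CoregulationSummary:
        return self.fit(X).summary_
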