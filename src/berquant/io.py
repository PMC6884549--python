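"""Table schemas, validated I/O, group statistics and the pipeline runner.

Canonical on-disk formats: tidy CSV (UTF-8, header row, "." decimal) for all
tables, BED (0-based half-open, name encoded as ``gene|region``) for gene
regions, JSON for simulation truth and provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "TidyTableSchema",
    "SCHEMAS",
    "SchemaError",
    "validate_table",
    "load_table",
    "write_table",
    "read_regions_bed",
    "write_regions_bed",
    "mean_sem",
    "compare_groups",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


@dataclass(frozen=True)
class TidyTableSchema:
    """Column contract for one table kind."""

    name: str
    required: tuple[str, ...]
    numeric: tuple[str, ...] = ()
    finite: tuple[str, ...] = ()
    key: tuple[str, ...] = ()


SCHEMAS: dict[str, TidyTableSchema] = {
    s.name: s
    for s in (
        TidyTableSchema(
            name="qpcr_wells",
            required=("sample_id", "gene", "region", "treatment", "replicate", "ct"),
            numeric=("ct",),
            finite=("ct",),
            key=("sample_id", "gene", "region", "treatment", "replicate"),
        ),
        TidyTableSchema(
            name="flow_events",
            required=("fsc_a", "fsc_h", "ssc_a", "viability", "ch_egfp", "ch_reporter"),
            numeric=("fsc_a", "fsc_h", "ssc_a", "viability", "ch_egfp", "ch_reporter"),
            finite=("fsc_a", "fsc_h", "ssc_a", "viability", "ch_egfp", "ch_reporter"),
        ),
        TidyTableSchema(
            name="de_records",
            required=("gene", "log2fc", "pvalue", "fdr"),
            numeric=("log2fc", "pvalue", "fdr"),
            finite=("log2fc",),
            key=("gene",),
        ),
        TidyTableSchema(
            name="comet_cells",
            required=(
                "cell_id",
                "condition",
                "enzyme",
                "replicate",
                "head_intensity",
                "tail_intensity",
            ),
            numeric=("head_intensity", "tail_intensity"),
            finite=("head_intensity", "tail_intensity"),
            key=("cell_id",),
        ),
        TidyTableSchema(
            name="sample_sheet",
            required=("sample_id", "condition", "damaged", "replicate"),
            key=("sample_id",),
        ),
    )
}


def validate_table(df: pd.DataFrame, schema: TidyTableSchema) -> pd.DataFrame:
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema.name}: missing column(s) {missing}")
    for c in schema.numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in schema.finite:
        vals = df[c].to_numpy()
        if not np.isfinite(vals.astype(float)).all():
            raise SchemaError(f"{schema.name}: non-finite values in column {c!r}")
    if schema.key:
        dup = df.duplicated(subset=list(schema.key))
        if dup.any():
            raise SchemaError(
                f"{schema.name}: duplicated key {df.loc[dup, list(schema.key)].iloc[0].to_dict()}"
            )
    return df


def load_table(path: str | Path, schema: TidyTableSchema | str) -> pd.DataFrame:
    """Read a tidy CSV and validate it against its schema."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    df = pd.read_csv(path)
    df = validate_table(df, schema)
    logger.info("loaded %s: %d rows from %s", schema.name, len(df), path)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    """Read gene regions from BED: chrom, start, end, name = ``gene|region``."""
    rows = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        parts = ln.split("\t")
        if len(parts) < 4:
            raise SchemaError(f"BED line needs >= 4 fields: {ln!r}")
        chrom, start, end, name = parts[:4]
        if "|" not in name:
            raise SchemaError(f"BED name must be 'gene|region', got {name!r}")
        gene, region = name.split("|", 1)
        start_i, end_i = int(start), int(end)
        if not start_i < end_i:
            raise SchemaError(f"BED interval empty: {ln!r}")
        rows.append(
            {
                "gene": gene,
                "region": region,
                "chrom": chrom,
                "start": start_i,
                "end": end_i,
                "amplicon_len_bp": end_i - start_i,
            }
        )
    return pd.DataFrame(rows)


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}|{r.region}"
        for r in regions.itertuples()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


def mean_sem(values) -> tuple[float, float, int]:
    """Mean, standard error of the mean, and n."""
    v = np.asarray(values, dtype=float)
    n = v.size
    sem = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(v.mean()), sem, n


def compare_groups(
    groups: Mapping[str, Sequence[float]], control: str | None = None
) -> dict:
    """One-way layout: ANOVA F-test plus Dunnett's many-to-one comparisons.

    When ``control`` is given, each other group is compared against it with
    Dunnett's test; otherwise only the omnibus ANOVA is reported.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    f_stat, p = sps.f_oneway(*arrays)
    out = {"anova_F": float(f_stat), "anova_p": float(p)}
    if control is not None:
        if control not in groups:
            raise KeyError(f"control group {control!r} not present")
        others = [k for k in labels if k != control]
        res = sps.dunnett(
            *[np.asarray(groups[k], dtype=float) for k in others],
            control=np.asarray(groups[control], dtype=float),
        )
        out["dunnett"] = {k: float(pv) for k, pv in zip(others, res.pvalue)}
    return out


# ---------------------------------------------------------------------------
# Pipeline runner
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Which assays to simulate-and-analyse, with what parameters."""

    assays: tuple[str, ...] = ("damage-qpcr", "chip", "flow", "de", "comet")
    seed: int = 0
    out_dir: str | Path = "berquant_run"
    params: dict = field(default_factory=dict)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {
            "assays": list(config.assays),
            "seed": config.seed,
            "params": config.params,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Simulate every selected assay, analyse it, and write all outputs.

    Returns a dict of result objects; writes tidy CSVs, truth JSONs and a
    provenance record (config hash, seed, package version) under
    ``config.out_dir``. Deterministic: the same config reproduces identical
    numeric outputs.
    """
    from . import __version__, comet, coregulation, flow, qpcr, simulate
    from .configs import DeSimConfig, FlowSimConfig

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    p = config.params

    if "damage-qpcr" in config.assays:
        landscapes = simulate.gen_lesion_landscape(
            p.get("genes", ["GENE1"]),
            base_lambda=p.get("base_lambda", 0.1),
            end_enrichment=p.get("end_enrichment", 5.0),
            seed=config.seed,
        )
        wells, truth = simulate.simulate_damage_qpcr(landscapes, seed=config.seed)
        est = qpcr.LesionFrequencyEstimator().fit(wells)
        write_table(wells, out_dir / "damage_qpcr_wells.csv")
        write_table(est.estimates_, out_dir / "lesion_estimates.csv")
        truth.to_json(out_dir / "damage_qpcr_truth.json")
        results["damage-qpcr"] = est.estimates_

    if "chip" in config.assays:
        occupancy = p.get(
            "occupancy", {"promoter": 1.0, "middle": 2.0, "end": 4.0}
        )
        wells, truth = simulate.simulate_chip_qpcr(occupancy, seed=config.seed)
        est = qpcr.ChipOccupancyEstimator().fit(wells)
        write_table(wells, out_dir / "chip_wells.csv")
        write_table(est.estimates_, out_dir / "occupancy_estimates.csv")
        truth.to_json(out_dir / "chip_truth.json")
        results["chip"] = est.estimates_

    if "flow" in config.assays:
        fcfg = FlowSimConfig(seed=config.seed, **p.get("flow", {}))
        samples, truth = simulate.simulate_flow_experiment(fcfg)
        sheet = pd.DataFrame(
            {
                "sample_id": ["damaged", "undamaged"],
                "condition": ["WT", "WT"],
                "damaged": [True, False],
                "replicate": [1, 1],
            }
        )
        est = flow.RepairCapacityEstimator().fit(samples, sheet)
        for sid, ev in samples.items():
            write_table(ev, out_dir / f"flow_events_{sid}.csv")
        write_table(est.capacities_, out_dir / "repair_capacity.csv")
        truth.to_json(out_dir / "flow_truth.json")
        results["flow"] = est.capacities_

    if "de" in config.assays:
        dcfg = DeSimConfig(seed=config.seed, **p.get("de", {}))
        table_a, table_b, truth = simulate.simulate_de_tables(dcfg)
        analyzer = coregulation.CoregulationAnalyzer().fit((table_a, table_b))
        write_table(table_a, out_dir / "de_table_a.csv")
        write_table(table_b, out_dir / "de_table_b.csv")
        truth.to_json(out_dir / "de_truth.json")
        (out_dir / "coregulation_summary.json").write_text(
            json.dumps(analyzer.summary_.to_dict(), indent=2)
        )
        results["de"] = analyzer.summary_

    if "comet" in config.assays:
        cells, truth = simulate.simulate_comet_cells(seed=config.seed)
        summ = comet.CometGroupSummarizer().fit(cells)
        write_table(cells, out_dir / "comet_cells.csv")
        write_table(summ.groups_, out_dir / "comet_groups.csv")
        write_table(summ.contrasts_, out_dir / "comet_contrasts.csv")
        truth.to_json(out_dir / "comet_truth.json")
        results["comet"] = summ

    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "assays": list(config.assays),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    results["provenance"] = provenance
    return results
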