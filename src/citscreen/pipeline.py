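"""End-to-end orchestration: screen -> DE filter -> qPCR -> CIT, with reports.

The pipeline consumes tab-separated tables (CSV accepted by extension),
writes each stage's report as TSV with fixed column order (diplotype columns
ordered B/B, B/C, C/C), and records the configuration actually applied in a
JSON sidecar. Reports are written atomically and an existing completed
report is never overwritten unless explicitly allowed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import defilter, preprocess
from .cit import CODINGS, run_battery
from .diplotype import DIPLOTYPES
from .synthetic import SyntheticConfig, generate

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Raised when an input table violates the expected schema."""


@dataclass
class PipelineConfig:
    """Thresholds, coding and I/O paths for a pipeline run."""

    alpha: float = 0.05
    marginal_band: tuple[float, float] = preprocess.MARGINAL_BAND
    fpkm_floor: float = defilter.DEFAULT_FPKM_FLOOR
    lfc_threshold: float = defilter.DEFAULT_LFC_THRESHOLD
    coding: str = "categorical"
    target_region: tuple[int, int] = defilter.DEFAULT_TARGET_REGION
    seed: int = 0
    trait_table: str | None = None
    expression_table: str | None = None
    fpkm_table: str | None = None
    outdir: str = "citscreen_out"
    overwrite: bool = False
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fpkm_floor <= 0 or self.lfc_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(mapping)
        for key in ("marginal_band", "target_region"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)


def read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def validate_individual_table(frame: pd.DataFrame, path: str = "<table>") -> pd.DataFrame:
    """Check the individual-level schema and diplotype spelling."""
    required = {"individual_id", "litter", "diplotype"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    for i, value in frame["diplotype"].items():
        if value not in DIPLOTYPES:
            raise SchemaError(
                f"{path}: row {i + 2}, column 'diplotype': invalid value {value!r} "
                f"(expected one of {DIPLOTYPES})"
            )
    return frame


def write_report(frame: pd.DataFrame, path: str | Path, overwrite: bool = False) -> Path:
    """Atomically write a TSV report; refuse to clobber a completed report."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"report {path} already exists; pass overwrite to replace")
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        frame.to_csv(tmp, sep="\t", index=False)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)
    return path


def count_significant_traits(trait_screen: pd.DataFrame, alpha: float = 0.05) -> int:
    """Number of screened traits with ANOVA p below alpha."""
    return int((trait_screen["anova_p"] < alpha).sum())


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write all reports.

    Stages: (1) load or simulate the individual table; (2) litter
    residualization and diplotype trait screen; (3) FPKM DE screen over the
    target region when an FPKM table is supplied; (4) CIT battery of every
    expression column against every Test-1-passing trait. Returns a bundle
    with the in-memory frames and written paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "pipeline start: alpha=%g fpkm_floor=%g lfc=%g coding=%s seed=%d",
        config.alpha, config.fpkm_floor, config.lfc_threshold, config.coding, config.seed,
    )

    if config.trait_table:
        traits = validate_individual_table(read_table(config.trait_table), config.trait_table)
    else:
        syn_cfg = SyntheticConfig(seed=config.seed, **config.synthetic)
        dataset = generate(syn_cfg)
        traits = dataset.frame
        logger.info("simulated dataset: architecture=%s n=%d", syn_cfg.architecture, len(traits))

    if config.expression_table:
        expr = validate_individual_table(
            read_table(config.expression_table), config.expression_table
        )
        merged = traits.merge(
            expr.drop(columns=[c for c in ("litter", "set", "diplotype") if c in expr.columns]),
            on="individual_id",
        )
    else:
        merged = traits

    meta_cols = {"individual_id", "litter", "set", "diplotype"}
    trait_cols = [c for c in traits.columns if c not in meta_cols]
    gene_cols = [c for c in merged.columns if c not in meta_cols and c not in trait_cols]
    if not gene_cols:  # single-table input: treat expression-like columns by prefix
        gene_cols = [c for c in trait_cols if c.startswith(("expr", "gene", "indep", "null"))]
        trait_cols = [c for c in trait_cols if c not in gene_cols]

    screen = preprocess.screen_traits(merged, trait_cols, alpha=config.alpha)
    paths = {"screen": write_report(screen, outdir / "trait_screen.tsv", config.overwrite)}

    de_report = None
    if config.fpkm_table:
        records = defilter.read_fpkm_table(config.fpkm_table)
        region = defilter.TargetRegion(*config.target_region)
        in_region = [r for r in records if region.overlaps(r.start, r.end)]
        de_report = defilter.report_frame(
            in_region, fpkm_floor=config.fpkm_floor, lfc_threshold=config.lfc_threshold
        )
        paths["de"] = write_report(de_report, outdir / "de_screen.tsv", config.overwrite)

    passing = screen.loc[screen["anova_p"] < config.alpha, "trait"].tolist()
    if passing and gene_cols:
        cit = run_battery(
            merged,
            genes=gene_cols,
            traits=passing,
            alpha=config.alpha,
            coding=config.coding,
            marginal_band=config.marginal_band,
        )
    else:
        cit = pd.DataFrame(
            columns=["gene", "trait", "p1", "p2", "p3", "p4", "p2r", "p3r", "p4r", "label"]
        )
        logger.info("CIT stage: empty gene or trait list; emitting empty table")
    paths["cit"] = write_report(cit, outdir / "cit_results.tsv", config.overwrite)

    sidecar = outdir / "run_config.json"
    sidecar.write_text(
        json.dumps(
            {
                "alpha": config.alpha,
                "marginal_band": list(config.marginal_band),
                "fpkm_floor": config.fpkm_floor,
                "lfc_threshold": config.lfc_threshold,
                "coding": config.coding,
                "target_region": list(config.target_region),
                "seed": config.seed,
            },
            indent=2,
        )
    )
    paths["config"] = sidecar
    return {"screen": screen, "de": de_report, "cit": cit, "paths": paths}
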