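"""End-to-end orchestration: Cq input -> summary -> stability -> consensus -> RQ.

`run_pipeline` is the library entry point behind the ``refstab run`` command.
It reads (and aggregates) a Cq table, computes the descriptive summary, the
requested stability methods, the consensus ranking and, when a target gene
and calibrator are configured, the 2^-ddCt expression profile; everything is
written as CSV plus a JSON manifest.  On any stage failure the partial
outputs are removed and the stage is named in the log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .consensus import reffinder_consensus
from .efficiency import amplicon_efficiency
from .errors import RefstabError, ValidationError
from .io import (
    CqTable,
    aggregate_technical_replicates,
    cq_summary,
    read_cq_table,
    summaries_to_frame,
)
from .relquant import expression_profile
from .stability import METHODS, run_all_methods, scores_to_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one analysis run (CLI ``run`` maps YAML onto this)."""

    cq_path: str
    out_dir: str
    layout: str = "long"
    missing_token: str = "NA"
    decimal_comma: bool = False
    max_cycles: float = 40.0
    methods: tuple[str, ...] = METHODS
    group_by_condition: bool = False   # NormFinder grouped mode
    conditions: tuple[str, ...] | None = None  # optional sample filter
    efficiency_source: str = "default2"        # default2 | table | curves
    efficiency_table: str | None = None        # CSV: gene,efficiency
    curves_path: str | None = None             # CSV: well,gene,cycle,fluorescence
    target: str | None = None
    calibrator: str | None = None
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValidationError(f"unknown methods {sorted(unknown)}")
        if self.efficiency_source not in ("default2", "table", "curves"):
            raise ValidationError(
                f"unknown efficiency source {self.efficiency_source!r}"
            )
        if self.efficiency_source == "table" and not self.efficiency_table:
            raise ValidationError("efficiency_source=table needs efficiency_table")
        if self.efficiency_source == "curves" and not self.curves_path:
            raise ValidationError("efficiency_source=curves needs curves_path")
        if (self.target is None) != (self.calibrator is None):
            raise ValidationError("target and calibrator must be given together")


def read_curves_csv(path: str | Path):
    """Read per-well traces from a CSV with columns well,gene,cycle,fluorescence."""
    from .efficiency import AmplificationCurve

    df = pd.read_csv(path)
    need = {"well", "gene", "cycle", "fluorescence"}
    if not need <= set(df.columns):
        raise ValidationError(f"curves CSV must have columns {sorted(need)}")
    out = []
    for (well, gene), sub in df.groupby(["well", "gene"], sort=False):
        sub = sub.sort_values("cycle")
        out.append(AmplificationCurve(
            well_id=str(well), gene_id=str(gene),
            cycles=sub["cycle"].to_numpy(float),
            fluorescence=sub["fluorescence"].to_numpy(float),
        ))
    return out


def _efficiencies_for(config: RunConfig, table: CqTable,
                      written: list[Path], out_dir: Path,
                      ) -> Mapping[str, float] | None:
    if config.efficiency_source == "default2":
        return None
    if config.efficiency_source == "table":
        df = pd.read_csv(config.efficiency_table)
        if not {"gene", "efficiency"} <= set(df.columns):
            raise ValidationError("efficiency table needs gene,efficiency columns")
        return dict(zip(df["gene"].astype(str), df["efficiency"].astype(float)))
    curves = read_curves_csv(config.curves_path)
    by_gene: dict[str, list] = {}
    for c in curves:
        by_gene.setdefault(c.gene_id, []).append(c)
    rows, eff = [], {}
    for gene, wells in by_gene.items():
        est = amplicon_efficiency(wells, gene_id=gene)
        eff[gene] = est.mean_e
        rows.append({
            "gene": gene, "mean_e": est.mean_e, "sd_e": est.sd_e,
            "r": est.r, "n_wells": len(est.per_well),
            "quality_flag": est.quality_flag,
            "quality_reasons": "; ".join(est.quality_reasons),
        })
    path = out_dir / "efficiency.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written.append(path)
    return eff


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis; returns the manifest dictionary."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "read"
        table = read_cq_table(
            config.cq_path, layout=config.layout,
            missing_token=config.missing_token,
            decimal_comma=config.decimal_comma,
            max_cycles=config.max_cycles,
        )
        if config.conditions:
            table = table.subset_conditions(config.conditions)
        agg = aggregate_technical_replicates(table)

        stage = "efficiency"
        efficiencies = _efficiencies_for(config, agg, written, out_dir)

        stage = "summary"
        summary = summaries_to_frame(cq_summary(agg))
        path = out_dir / "cq_summary.csv"
        summary.to_csv(path, index=False)
        written.append(path)

        stage = "stability"
        groups = None
        if config.group_by_condition:
            groups = {s: cond for s, (cond, _) in agg.design.items()}
        scores = run_all_methods(agg, efficiencies=efficiencies,
                                 groups=groups, methods=config.methods)
        for method, sc in scores.items():
            path = out_dir / f"stability_{method}.csv"
            scores_to_frame(sc).to_csv(path, index=False)
            written.append(path)

        stage = "consensus"
        path = out_dir / "consensus.csv"
        if len(config.methods) >= 2:
            consensus = reffinder_consensus(scores)
            consensus.to_frame().to_csv(path, index=True, index_label="gene")
        else:
            # single method: its own ranking is the consensus
            consensus = None
            only = config.methods[0]
            frame = scores_to_frame(scores[only])[["gene", "value", "rank"]]
            frame.sort_values("rank", kind="stable").to_csv(path, index=False)
        written.append(path)

        stage = "quantify"
        if config.target is not None:
            if consensus is not None:
                ranking = consensus.ordered_genes()
            else:
                frame = scores_to_frame(scores[config.methods[0]])
                ranking = list(frame.sort_values("rank", kind="stable")["gene"])
            profile = expression_profile(
                agg, config.target,
                [g for g in ranking if g != config.target],
                config.calibrator,
            )
            path = out_dir / f"expression_{config.target}.csv"
            profile.to_csv(path, index=False)
            written.append(path)

        stage = "manifest"
        manifest = {
            "refstab_version": __version__,
            "seed": config.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in config.__dict__.items()},
            "n_records": int(len(table.data)),
            "n_samples": len(table.samples),
            "n_genes": len(table.genes),
            "outputs": [p.name for p in written] + ["manifest.json"],
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(path)
        return manifest
    except Exception:
        logger.error("pipeline failed at stage %r; removing partial outputs", stage)
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise
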