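"""Synthetic qPCR data with known ground truth.

The generator emulates a typical reference-gene validation design: a panel
of candidate genes measured over a control condition plus stress levels or
timepoints, with biological and technical replication.  The Cq model is

    Cq[sample, gene, rep] = baseline_g + effect[condition, g] + load_s + eps

where ``effect`` is zero for designed-stable genes and for every gene at the
control condition, ``load_s`` is a per-sample loading/pipetting shift shared
by all genes of that sample, and ``eps`` is technical noise.  Condition
effects are drawn once per run and held fixed across replicates — they are
the "instability" the stability statistics are meant to detect.  Noise is
normal on the Cq scale (log-scale of quantity), the standard qPCR error
model.

Defaults mirror a 9-candidate panel under 4 conditions (control + 3
stress levels) with 3 biological x 2 technical replicates, baseline Cq drawn
in 20-34 cycles and per-amplicon efficiencies in 1.90-2.07.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusRanking, reffinder_consensus
from .errors import ValidationError
from .io import LONG_COLUMNS, CqTable, aggregate_technical_replicates
from .efficiency import AmplificationCurve
from .stability import run_all_methods

DEFAULT_CONDITIONS = ("control", "6h", "12h", "24h")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic qPCR world.

    ``stable_genes`` have exactly zero condition effect; all SDs are in
    cycles.  ``baseline_cq``/``efficiencies`` may be given per gene or left
    None to be drawn uniformly from 20-34 cycles and 1.90-2.07 respectively.
    ``target_log2_fc`` (condition -> true log2 fold change) turns
    ``target_gene`` into a regulated target: its Cq effect is the negative
    of the true log2 fold change.
    """

    n_genes: int = 9
    stable_genes: tuple[str, ...] = ("G1", "G2")
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_bio: int = 3
    n_tech: int = 2
    baseline_cq: Mapping[str, float] | None = None
    sigma_tech: float = 0.15
    sigma_load: float = 0.5
    tau_effect: float = 1.0
    target_gene: str | None = None
    target_log2_fc: Mapping[str, float] | None = None
    efficiencies: Mapping[str, float] | None = None
    max_cycles: float = 40.0
    seed: int = 0

    @property
    def genes(self) -> list[str]:
        base = [f"G{i + 1}" for i in range(self.n_genes)]
        if self.target_gene and self.target_gene not in base:
            base.append(self.target_gene)
        return base

    def validate(self) -> None:
        genes = set(self.genes)
        if not set(self.stable_genes) <= genes:
            raise ValidationError(
                f"stable_genes {set(self.stable_genes) - genes} not in gene set"
            )
        for name in ("sigma_tech", "sigma_load", "tau_effect"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_genes < 1 or self.n_bio < 1 or self.n_tech < 1:
            raise ValidationError("need >= 1 gene and >= 1 replicate of each kind")
        if self.target_log2_fc and not self.target_gene:
            raise ValidationError("target_log2_fc given without target_gene")


@dataclass
class GroundTruth:
    """What the generator actually used: effects, loads, baselines, E."""

    effects: pd.DataFrame          # conditions x genes, cycles
    loads: pd.Series               # per sample, cycles
    baselines: pd.Series           # per gene, cycles
    efficiencies: pd.Series        # per gene


def _draw_gene_params(config: SimulationConfig, rng: np.random.Generator,
                      ) -> tuple[pd.Series, pd.Series]:
    genes = config.genes
    if config.baseline_cq is not None:
        base = pd.Series({g: float(config.baseline_cq[g]) for g in genes})
    else:
        base = pd.Series(rng.uniform(20.0, 34.0, len(genes)), index=genes)
    if config.efficiencies is not None:
        eff = pd.Series({g: float(config.efficiencies[g]) for g in genes})
    else:
        eff = pd.Series(rng.uniform(1.90, 2.07, len(genes)), index=genes)
    return base, eff


def simulate_cq(config: SimulationConfig) -> tuple[CqTable, GroundTruth]:
    """Draw one synthetic Cq table plus its ground truth.

    Deterministic given ``config.seed``.  Sample ids are
    ``{condition}_b{bio_rep}``; the control condition is the first entry of
    ``config.conditions`` and carries zero effect for every gene.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.genes
    base, eff = _draw_gene_params(config, rng)

    control = config.conditions[0]
    effects = pd.DataFrame(0.0, index=list(config.conditions), columns=genes)
    for cond in config.conditions[1:]:
        for g in genes:
            if g in config.stable_genes or g == config.target_gene:
                continue
            effects.loc[cond, g] = rng.normal(0.0, config.tau_effect)
    if config.target_gene and config.target_log2_fc:
        for cond, fc in config.target_log2_fc.items():
            if cond not in effects.index:
                raise ValidationError(f"unknown condition {cond!r} in target_log2_fc")
            effects.loc[cond, config.target_gene] = -float(fc)

    samples = [f"{cond}_b{b}" for cond in config.conditions
               for b in range(1, config.n_bio + 1)]
    loads = pd.Series(rng.normal(0.0, config.sigma_load, len(samples)),
                      index=samples)

    rows = []
    for cond in config.conditions:
        for b in range(1, config.n_bio + 1):
            s = f"{cond}_b{b}"
            for g in genes:
                for t in range(1, config.n_tech + 1):
                    cq = (base[g] + effects.loc[cond, g] + loads[s]
                          + rng.normal(0.0, config.sigma_tech))
                    cq = min(max(cq, 1e-6), config.max_cycles)
                    rows.append((s, g, cond, b, t, cq))
    table = CqTable(pd.DataFrame(rows, columns=LONG_COLUMNS),
                    max_cycles=config.max_cycles)
    truth = GroundTruth(effects=effects, loads=loads, baselines=base,
                        efficiencies=eff)
    return table, truth


def simulate_curves(
    config: SimulationConfig,
    f_threshold: float = 0.2,
    n_wells: int = 3,
    n_cycles: int = 40,
    baseline_f: float = 2.0,
    f_max: float = 2000.0,
    noise_sigma: float = 0.0,
    intended_cq: Mapping[str, float] | None = None,
) -> list[AmplificationCurve]:
    """Synthetic raw amplification curves, one set of wells per gene.

    Each well follows ``F(c) = baseline_f + A(c)`` with a saturating
    amplicon signal ``A(c) = F0 E^c / (1 + F0 E^c / f_max)`` and
    ``F0 = f_threshold / E^Cq`` so that the noise-free curve crosses
    ``f_threshold`` (above baseline) at the intended Cq.  Multiplicative
    noise of SD ``noise_sigma`` is applied to the amplicon signal only —
    SYBR signal noise scales with product amount while the background is
    comparatively stable.

    ``intended_cq`` defaults to each gene's baseline Cq from the config.
    """
    config.validate()
    if f_threshold <= 0:
        raise ValidationError("f_threshold must be positive")
    rng = np.random.default_rng(config.seed + 1)
    base, eff = _draw_gene_params(config, np.random.default_rng(config.seed))
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    out = []
    for g in config.genes:
        cq = float(intended_cq[g]) if intended_cq is not None else float(base[g])
        if not (1.0 <= cq <= n_cycles):
            raise ValidationError(
                f"intended Cq {cq} for gene {g} outside cycle range 1..{n_cycles}"
            )
        e = float(eff[g])
        f0 = f_threshold / e ** cq
        for w in range(1, n_wells + 1):
            amp = f0 * e ** cycles
            amp = amp / (1.0 + amp / f_max)
            if noise_sigma > 0:
                amp = amp * (1.0 + rng.normal(0.0, noise_sigma, len(cycles)))
            out.append(AmplificationCurve(
                well_id=f"{g}_w{w}", gene_id=g,
                cycles=cycles.copy(),
                fluorescence=baseline_f + np.clip(amp, 0.0, None),
            ))
    return out


@dataclass
class RecoverySummary:
    """Outcome of repeated simulate -> rank runs.

    ``per_method_topk``/``consensus_topk``: fraction of runs in which each
    designed-stable gene landed in the top k (columns k=1,2,3).
    ``all_stable_top_n``: fraction of runs in which the designed-stable
    genes filled the first ``len(stable_genes)`` consensus positions.
    ``rank_correlation``: mean Spearman correlation of consensus gene order
    between consecutive runs.
    """

    per_method_topk: dict[str, pd.DataFrame]
    consensus_topk: pd.DataFrame
    all_stable_top_n: float
    rank_correlation: float
    rankings: list[ConsensusRanking]


def recovery_experiment(
    config: SimulationConfig,
    n_runs: int = 200,
    top_k: Sequence[int] = (1, 2, 3),
) -> RecoverySummary:
    """Monte-Carlo check that designed-stable genes are recovered.

    Runs ``simulate_cq`` -> all four stability methods -> consensus
    ``n_runs`` times (seeds ``config.seed + run``), tallying how often each
    designed-stable gene reaches the top-k of each method and of the
    consensus.
    """
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    stable = list(config.stable_genes)
    methods = ("delta_ct", "genorm", "bestkeeper", "normfinder")
    hits = {m: pd.DataFrame(0.0, index=stable, columns=list(top_k))
            for m in methods}
    cons_hits = pd.DataFrame(0.0, index=stable, columns=list(top_k))
    all_top = 0
    rankings: list[ConsensusRanking] = []
    for run in range(n_runs):
        cfg = replace(config, seed=config.seed + run)
        table, _ = simulate_cq(cfg)
        agg = aggregate_technical_replicates(table)
        scores = run_all_methods(agg)
        for m in methods:
            ranks = {s.gene_id: s.rank for s in scores[m]}
            for g in stable:
                for k in top_k:
                    if ranks[g] <= k:
                        hits[m].loc[g, k] += 1
        consensus = reffinder_consensus(scores)
        rankings.append(consensus)
        for g in stable:
            for k in top_k:
                if consensus.final_rank[g] <= k:
                    cons_hits.loc[g, k] += 1
        if all(consensus.final_rank[g] <= len(stable) for g in stable):
            all_top += 1
    for m in methods:
        hits[m] /= n_runs
    cons_hits /= n_runs

    if len(rankings) > 1:
        corrs = []
        for a, b in zip(rankings[:-1], rankings[1:]):
            ra = a.final_rank
            rb = b.final_rank.reindex(ra.index)
            corrs.append(float(ra.corr(rb, method="spearman")))
        rank_corr = float(np.mean(corrs))
    else:
        rank_corr = math.nan
    return RecoverySummary(
        per_method_topk=hits,
        consensus_topk=cons_hits,
        all_stable_top_n=all_top / n_runs,
        rank_correlation=rank_corr,
        rankings=rankings,
    )
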