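"""Comprehensive (consensus) ranking by geometric mean of per-method ranks.

Given each candidate gene's rank under two or more stability methods, the
consensus score is the geometric mean of those ranks — the aggregation used
by the popular web consensus tools — and the final comprehensive order is
ascending in that score.  Ranks, not raw stability values, are aggregated:
the methods' values live on incompatible scales (cycles, log2 units,
model-based units) while ranks are directly comparable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


def rank_within_method(
    values: Mapping[str, float] | pd.Series,
    ascending: bool = True,
) -> pd.Series:
    """Rank genes by stability value; ties get the average of their positions.

    Genes with undefined (NaN) values are excluded with a warning and get a
    NaN rank.
    """
    s = pd.Series(values, dtype=float)
    nan = s.index[s.isna()]
    if len(nan):
        logger.warning("excluding genes with undefined values: %s", list(nan))
    return s.rank(method="average", ascending=ascending)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (matches table formatting conventions)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConsensusRanking:
    """Per-gene method ranks, their geometric mean, and the final order.

    ``geomean`` is full precision; ``geomean_2dp`` is the half-up 2-decimal
    display value.  ``final_rank`` is an integer permutation of 1..n_genes
    (geomean ties broken by mean method rank, then input gene order).
    """

    method_ranks: pd.DataFrame        # genes x methods
    geomean: pd.Series
    geomean_2dp: pd.Series
    final_rank: pd.Series
    methods: list[str]

    @property
    def genes(self) -> list[str]:
        return list(self.method_ranks.index)

    def ordered_genes(self) -> list[str]:
        return list(self.final_rank.sort_values(kind="stable").index)

    def to_frame(self) -> pd.DataFrame:
        out = self.method_ranks.copy()
        out.columns = [f"rank_{m}" for m in out.columns]
        out["geomean"] = self.geomean
        out["geomean_2dp"] = self.geomean_2dp
        out["final_rank"] = self.final_rank
        return out.sort_values("final_rank", kind="stable")


def _ranks_from_scores(scores) -> dict[str, dict[str, float]]:
    """Normalise accepted inputs to {method: {gene: rank}}."""
    if isinstance(scores, Mapping):
        mapped: dict[str, dict[str, float]] = {}
        for method, entry in scores.items():
            if isinstance(entry, Mapping):
                mapped[method] = {g: float(r) for g, r in dict(entry).items()}
            else:  # a list of StabilityScore-like objects
                mapped[method] = {s.gene_id: s.rank for s in entry}
        return mapped
    by_method: dict[str, dict[str, float]] = {}
    for s in scores:  # flat iterable of StabilityScore-like objects
        by_method.setdefault(s.method, {})[s.gene_id] = s.rank
    return by_method


def reffinder_consensus(scores) -> ConsensusRanking:
    """Geometric-mean consensus over per-method stability ranks.

    ``scores`` may be a flat iterable of StabilityScore objects, a mapping
    method -> list of scores, or a mapping method -> {gene: rank}.  At least
    two methods are required and every gene must carry a rank in every
    method (an undefined rank is an error naming the gene and method).
    """
    by_method = _ranks_from_scores(scores)
    if len(by_method) < 2:
        raise ValidationError("consensus needs ranks from >= 2 methods")
    methods = list(by_method)
    genes: list[str] = []
    for m in methods:
        for g in by_method[m]:
            if g not in genes:
                genes.append(g)
    for m in methods:
        for g in genes:
            r = by_method[m].get(g)
            if r is None or (isinstance(r, float) and math.isnan(r)):
                raise ValidationError(f"gene {g!r} has no rank under method {m!r}")
    ranks = pd.DataFrame({m: [by_method[m][g] for g in genes] for m in methods},
                         index=genes)
    geomean = np.exp(np.log(ranks).mean(axis=1))
    tie_break = ranks.mean(axis=1)
    order = sorted(range(len(genes)),
                   key=lambda i: (geomean.iloc[i], tie_break.iloc[i], i))
    final = pd.Series(0, index=genes, dtype=int)
    for pos, i in enumerate(order, start=1):
        final.iloc[i] = pos
    return ConsensusRanking(
        method_ranks=ranks,
        geomean=geomean,
        geomean_2dp=geomean.map(round_half_up),
        final_rank=final,
        methods=methods,
    )
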