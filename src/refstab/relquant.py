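"""Relative quantification of a target gene by the 2^-ΔΔCt method.

ΔCt = Cq(target) - Cq(reference) within each biological replicate;
ΔΔCt subtracts the mean ΔCt of the calibrator (untreated control) condition;
the fold change is RQ = 2^-ΔΔCt, assuming perfect doubling (E = 2).  RQ is
computed per biological replicate and then summarised as mean ± SE per
condition, so the calibrator's mean RQ is ~1 (exactly 1 only when its
replicates agree); a flag switches to exponentiating the mean ΔΔCt, which
pins the calibrator at exactly 1.

Multiple reference genes are combined by averaging their Cq values, i.e.
normalising to the geometric mean of their quantities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusRanking
from .errors import ValidationError
from .io import CqTable

logger = logging.getLogger(__name__)


@dataclass
class RelativeExpression:
    """Fold change of one target under one condition vs the calibrator."""

    target: str
    references: tuple[str, ...]
    condition: str
    bio_replicates: tuple[int, ...]
    delta_ct: tuple[float, ...]       # cycles, one per biological replicate
    delta_delta_ct: tuple[float, ...]
    rq: tuple[float, ...]             # fold change per replicate
    mean_rq: float
    se_rq: float

    @property
    def n(self) -> int:
        return len(self.rq)


def delta_delta_ct(
    table: CqTable,
    target: str,
    references: Sequence[str] | str,
    calibrator: str,
    efficiencies: Mapping[str, float] | None = None,
    average_before_exponentiation: bool = False,
) -> list[RelativeExpression]:
    """2^-ΔΔCt fold changes of ``target`` per condition.

    ``references`` is one gene or a list (multi-gene normalisation averages
    reference Cq values).  ``calibrator`` names the baseline condition whose
    mean ΔCt anchors ΔΔCt = 0.  When per-gene ``efficiencies`` are given,
    each gene's Cq is rescaled by log2(E) before differencing — a
    sensitivity analysis around the method's E = 2 assumption; by default
    the classical perfect-doubling form is used.

    Replicates missing the target or any reference are dropped with a
    warning.  Returns one record per condition in first-seen order.
    """
    if isinstance(references, str):
        references = [references]
    references = list(references)
    mat = table.cq_matrix()
    for g in [target] + references:
        if g not in mat.columns:
            raise ValidationError(f"gene {g!r} not in table")
    if target in references:
        raise ValidationError("target cannot also be a reference")
    design = table.design
    conditions = list(dict.fromkeys(c for c, _ in design.values()))
    if calibrator not in conditions:
        raise ValidationError(f"calibrator condition {calibrator!r} absent")

    if efficiencies is not None:
        scale = {g: math.log2(float(efficiencies.get(g, 2.0)))
                 for g in [target] + references}
    else:
        scale = {g: 1.0 for g in [target] + references}

    rows = []
    for sample in mat.index:
        cond, bio = design[sample]
        tq = mat.loc[sample, target]
        refs = mat.loc[sample, references]
        if pd.isna(tq) or refs.isna().any():
            logger.warning("dropping sample %s: missing target or reference Cq",
                           sample)
            continue
        ref_cq = float(np.mean([scale[g] * refs[g] for g in references]))
        rows.append((cond, bio, scale[target] * float(tq) - ref_cq))
    df = pd.DataFrame(rows, columns=["condition", "bio_rep", "delta_ct"])
    cal = df[df["condition"] == calibrator]
    if cal.empty:
        raise ValidationError(
            f"no usable replicate in calibrator condition {calibrator!r}"
        )
    cal_mean = float(cal["delta_ct"].mean())
    df["ddct"] = df["delta_ct"] - cal_mean
    df["rq"] = 2.0 ** (-df["ddct"])

    out = []
    for cond in conditions:
        sub = df[df["condition"] == cond]
        if sub.empty:
            continue
        rq = sub["rq"].to_numpy()
        if average_before_exponentiation:
            mean_rq = float(2.0 ** (-sub["ddct"].mean()))
        else:
            mean_rq = float(rq.mean())
        se = float(rq.std(ddof=1) / math.sqrt(len(rq))) if len(rq) > 1 else math.nan
        out.append(RelativeExpression(
            target=target,
            references=tuple(references),
            condition=cond,
            bio_replicates=tuple(int(b) for b in sub["bio_rep"]),
            delta_ct=tuple(float(v) for v in sub["delta_ct"]),
            delta_delta_ct=tuple(float(v) for v in sub["ddct"]),
            rq=tuple(float(v) for v in rq),
            mean_rq=mean_rq,
            se_rq=se,
        ))
    return out


def expression_profile(
    table: CqTable,
    target: str,
    ranking: ConsensusRanking | Sequence[str],
    calibrator: str,
    **kwargs,
) -> pd.DataFrame:
    """Fold-change profile of ``target`` under every candidate reference.

    Runs :func:`delta_delta_ct` once per reference gene, in consensus order
    (most stable first), and returns a long table indexed by
    (reference, condition) — the standard way to visualise how the choice of
    normaliser distorts the target's apparent response.
    """
    if isinstance(ranking, ConsensusRanking):
        refs = [g for g in ranking.ordered_genes() if g != target]
    else:
        refs = [g for g in ranking if g != target]
    rows = []
    for ref in refs:
        for rec in delta_delta_ct(table, target, [ref], calibrator, **kwargs):
            rows.append({
                "reference": ref, "condition": rec.condition,
                "mean_rq": rec.mean_rq, "se_rq": rec.se_rq, "n": rec.n,
            })
    return pd.DataFrame(rows)


def expression_to_frame(records: Sequence[RelativeExpression]) -> pd.DataFrame:
    return pd.DataFrame([
        {"target": r.target, "references": "+".join(r.references),
         "condition": r.condition, "mean_rq": r.mean_rq, "se_rq": r.se_rq,
         "n": r.n}
        for r in records
    ])
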