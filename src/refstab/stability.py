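"""Reference-gene stability statistics: comparative ΔCt, geNorm, BestKeeper, NormFinder.

All four score candidate reference genes from a samples × genes table of
quantification cycles; in every method a *lower* value means a *more stable*
gene.  ΔCt, geNorm and NormFinder operate on (log) relative quantities and
are invariant to per-sample loading shifts; BestKeeper works on raw Cq and
deliberately is not.

Missing Cq values are handled pairwise: each pairwise statistic uses the
samples where both genes are present, and NormFinder (a full two-way model)
drops incomplete samples with a warning.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .consensus import rank_within_method
from .errors import InsufficientDataError, ValidationError
from .io import CqTable

logger = logging.getLogger(__name__)

METHODS = ("delta_ct", "genorm", "bestkeeper", "normfinder")


@dataclass(frozen=True)
class StabilityScore:
    """One gene's stability under one method.

    ``value`` semantics by method: ΔCt — mean of the SDs (cycles) of this
    gene's pairwise Cq differences; geNorm — M, the mean SD of pairwise log2
    expression ratios; BestKeeper — SD [±CP], dispersion of raw Cq in
    cycles; NormFinder — model-based stability value on the log2 scale.
    ``rank`` is 1 for the most stable gene, ties averaged; None when the
    value is undefined.
    """

    gene_id: str
    method: str
    value: float
    rank: float | None
    extras: dict = field(default_factory=dict)


def scores_to_frame(scores: Sequence[StabilityScore]) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {"gene": s.gene_id, "method": s.method,
               "value": s.value, "rank": s.rank}
        row.update(s.extras)
        rows.append(row)
    return pd.DataFrame(rows)


def _make_scores(method: str, values: pd.Series,
                 extras: Mapping[str, Mapping[str, object]] | None = None,
                 ) -> list[StabilityScore]:
    ranks = rank_within_method(values, ascending=True)
    out = []
    for gene, val in values.items():
        rank = ranks.get(gene)
        extra = dict(extras.get(gene, {})) if extras else {}
        out.append(StabilityScore(gene, method, float(val),
                                  None if rank is None or pd.isna(rank)
                                  else float(rank), extra))
    return out


# ------------------------------------------------------------ quantities
@dataclass
class RelQuantityMatrix:
    """Samples × genes matrix of relative quantities Q = E^(Cq_min - Cq).

    Each gene's maximum Q is 1 (attained at its lowest Cq); log2(Q) is the
    log-quantity scale used by geNorm and NormFinder.
    """

    q: pd.DataFrame
    efficiencies: pd.Series
    transform: str = "Q = E^(Cq_min - Cq), per-gene Cq_min"

    @property
    def genes(self) -> list[str]:
        return list(self.q.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.q.index)

    def log2(self) -> pd.DataFrame:
        return np.log2(self.q)


def relative_quantities(
    table: CqTable,
    efficiencies: Mapping[str, float] | float | None = None,
) -> RelQuantityMatrix:
    """Convert aggregated Cq values to relative quantities.

    ``efficiencies`` may be a single E, a per-gene mapping, or None for the
    perfect-doubling default E = 2 (what the classical stability tools
    assume).  Every efficiency must exceed 1.
    """
    mat = table.cq_matrix()
    if efficiencies is None:
        eff = pd.Series(2.0, index=mat.columns)
    elif isinstance(efficiencies, (int, float)):
        eff = pd.Series(float(efficiencies), index=mat.columns)
    else:
        missing = [g for g in mat.columns if g not in efficiencies]
        if missing:
            raise ValidationError(f"no efficiency supplied for genes {missing}")
        eff = pd.Series({g: float(efficiencies[g]) for g in mat.columns})
    if (eff <= 1.0).any():
        bad = eff[eff <= 1.0].index.tolist()
        raise ValidationError(f"efficiency must be > 1 (got E<=1 for {bad})")
    q = eff ** (mat.min(axis=0) - mat)
    return RelQuantityMatrix(q=q[mat.columns], efficiencies=eff)


# ------------------------------------------------------- comparative ΔCt
def _pairwise_sd(x: pd.Series, y: pd.Series) -> float:
    """n-1 SD of (x - y) over samples where both are present."""
    d = (x - y).dropna()
    if len(d) < 2:
        return math.nan
    return float(d.std(ddof=1))


def delta_ct_stability(table: CqTable) -> list[StabilityScore]:
    """Comparative ΔCt stability.

    For every gene pair (j, k) compute the per-sample Cq difference and its
    n-1 SD; gene j's stability is the mean of SD_jk over all partners k.
    Pairs sharing fewer than two samples are excluded with a warning; a gene
    with no usable pair gets an undefined (NaN) value.
    """
    mat = table.cq_matrix()
    genes = list(mat.columns)
    if len(genes) < 2 or len(mat.index) < 2:
        raise InsufficientDataError("ΔCt needs >= 2 genes and >= 2 samples")
    values = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            sd = _pairwise_sd(mat[j], mat[k])
            if math.isnan(sd):
                logger.warning("ΔCt: pair (%s, %s) has <2 common samples", j, k)
            else:
                sds.append(sd)
        if not sds:
            logger.warning("ΔCt: gene %s has no usable pair", j)
            values[j] = math.nan
        else:
            values[j] = float(np.mean(sds))
    return _make_scores("delta_ct", pd.Series(values, index=genes))


# ----------------------------------------------------------------- geNorm
def genorm_m(matrix: RelQuantityMatrix, subset: Sequence[str] | None = None,
             ) -> pd.Series:
    """geNorm expression-stability measure M for each gene of ``subset``.

    M_j is the mean, over partner genes k, of the n-1 SD of the per-sample
    log2 expression ratio log2(Q_j / Q_k).
    """
    genes = list(subset) if subset is not None else matrix.genes
    if len(genes) < 2:
        raise InsufficientDataError("geNorm M needs >= 2 genes")
    y = matrix.log2()[genes]
    m = {}
    for j in genes:
        vs = []
        for k in genes:
            if k == j:
                continue
            v = _pairwise_sd(y[j], y[k])
            if not math.isnan(v):
                vs.append(v)
        m[j] = float(np.mean(vs)) if vs else math.nan
    return pd.Series(m, index=genes, name="M")


@dataclass
class GenormResult:
    """Stepwise geNorm output.

    ``exclusion_order`` lists genes worst-first; the two genes never
    excluded form ``final_pair`` and share tied rank 1.5.  ``m_at_step``
    holds each gene's M at the step it was excluded (final pair: M in the
    last 2-gene subset).  ``ranks`` is the overall geNorm ranking (reverse
    exclusion order); ``full_panel_m`` is M computed once on all genes.
    """

    exclusion_order: list[str]
    final_pair: tuple[str, str]
    m_at_step: dict[str, float]
    ranks: pd.Series
    full_panel_m: pd.Series

    def scores(self) -> list[StabilityScore]:
        out = []
        for gene in self.full_panel_m.index:
            out.append(StabilityScore(
                gene, "genorm", float(self.m_at_step[gene]),
                float(self.ranks[gene]),
                {"full_panel_m": float(self.full_panel_m[gene]),
                 "excluded_step": (self.exclusion_order.index(gene) + 1
                                   if gene in self.exclusion_order else None)},
            ))
        return out


def genorm_stepwise(matrix: RelQuantityMatrix) -> GenormResult:
    """Iterative geNorm ranking by stepwise exclusion of the least stable gene.

    At each step M is recomputed on the remaining subset and the gene with
    the highest M is removed, until two genes remain; those two cannot be
    distinguished by M (their M values are identical by construction) and
    are reported as the most stable pair with tied rank 1.5.  A tie at the
    maximum M is broken by excluding the gene that appears later in input
    order (logged).
    """
    genes = list(matrix.genes)
    if len(genes) < 3:
        raise InsufficientDataError("stepwise geNorm needs >= 3 genes")
    full_m = genorm_m(matrix)
    remaining = list(genes)
    exclusion: list[str] = []
    m_at_step: dict[str, float] = {}
    while len(remaining) > 2:
        m = genorm_m(matrix, remaining)
        mmax = m.max()
        worst_candidates = [g for g in remaining if m[g] >= mmax - 1e-12]
        if len(worst_candidates) > 1:
            logger.info("geNorm tie at M=%.6g among %s; excluding the later "
                        "gene in input order", mmax, worst_candidates)
        worst = worst_candidates[-1]  # later in input order
        m_at_step[worst] = float(m[worst])
        exclusion.append(worst)
        remaining.remove(worst)
    m_final = genorm_m(matrix, remaining)
    for g in remaining:
        m_at_step[g] = float(m_final[g])
    ranks = {g: 1.5 for g in remaining}
    for pos, g in enumerate(reversed(exclusion)):
        ranks[g] = 3.0 + pos
    return GenormResult(
        exclusion_order=exclusion,
        final_pair=(remaining[0], remaining[1]),
        m_at_step=m_at_step,
        ranks=pd.Series(ranks, index=genes, dtype=float),
        full_panel_m=full_m,
    )


def genorm_pairwise_variation(
    matrix: RelQuantityMatrix,
    ranking: Sequence[str] | GenormResult,
) -> pd.Series:
    """geNorm pairwise variation V_{n/n+1} for n = 2..n_genes-1.

    NF_n is the per-sample geometric mean of the top-n genes' quantities;
    V_{n/n+1} is the n-1 SD over samples of log2(NF_n / NF_{n+1}).  Low V
    means adding the (n+1)-th gene hardly changes the normalization factor.
    """
    if isinstance(ranking, GenormResult):
        order = list(ranking.ranks.sort_values(kind="stable").index)
    else:
        order = list(ranking)
    y = matrix.log2()[order]
    n_genes = len(order)
    if n_genes < 3:
        raise InsufficientDataError("pairwise variation needs >= 3 genes")
    out = {}
    for n in range(2, n_genes):
        log_nf_n = y[order[:n]].mean(axis=1)          # log2 geometric mean
        log_nf_n1 = y[order[: n + 1]].mean(axis=1)
        d = (log_nf_n - log_nf_n1).dropna()
        out[f"V{n}/{n + 1}"] = float(d.std(ddof=1))
    return pd.Series(out, name="V")


# ------------------------------------------------------------- BestKeeper
def bestkeeper(table: CqTable, use_classical_sd: bool = False,
               ) -> list[StabilityScore]:
    """BestKeeper descriptive index on raw Cq values.

    Per gene: geometric mean, arithmetic mean, min, max of Cq; SD [±CP] is
    the mean absolute deviation of Cq about the geometric mean (the original
    tool's convention; ``use_classical_sd`` switches to the n-1 SD about the
    arithmetic mean); CV [%CP] = 100·SD/arithmetic mean.  The stability
    value is SD [±CP].  Extras include each gene's Pearson r against the
    BestKeeper index (the per-sample geometric mean of Cq across genes).
    """
    mat = table.cq_matrix()
    if (mat.dropna(how="all") <= 0).any().any():
        raise ValidationError("BestKeeper requires positive Cq values")
    # index: per-sample geometric mean over genes present in that sample
    index = np.exp(np.log(mat).mean(axis=1, skipna=True))
    values, extras = {}, {}
    for gene in mat.columns:
        x = mat[gene].dropna()
        if len(x) < 2:
            values[gene] = math.nan
            extras[gene] = {}
            continue
        gm = float(np.exp(np.log(x).mean()))
        am = float(x.mean())
        if use_classical_sd:
            sd = float(x.std(ddof=1))
        else:
            sd = float(np.abs(x - gm).mean())
        r_idx = index.reindex(x.index)
        r = float(sps.pearsonr(x, r_idx)[0]) if x.nunique() > 1 else math.nan
        values[gene] = sd
        extras[gene] = {
            "geo_mean": gm, "arith_mean": am,
            "min_cq": float(x.min()), "max_cq": float(x.max()),
            "cv_percent": 100.0 * sd / am, "r_with_index": r,
        }
    return _make_scores("bestkeeper", pd.Series(values, index=mat.columns), extras)


def bestkeeper_index(table: CqTable) -> pd.Series:
    """Per-sample geometric mean of Cq across genes (the BestKeeper index)."""
    mat = table.cq_matrix()
    return np.exp(np.log(mat).mean(axis=1, skipna=True))


# ------------------------------------------------------------- NormFinder
def normfinder(
    matrix: RelQuantityMatrix,
    groups: Mapping[str, str] | None = None,
) -> list[StabilityScore]:
    """Model-based stability (Andersen-style variance decomposition).

    The log2 quantities are modelled as gene effect + sample effect +
    gene-specific noise.  Without groups, each gene's noise variance is
    estimated from sample-centred residuals with the small-panel k/(k-2)
    correction (k genes), floored at zero; the stability value is its square
    root.  With a sample→group mapping, per-group intragroup variances and
    shrunken intergroup differences combine into the grouped stability value
    ``mean_over_groups(|d_hat| + sqrt(var/n))``.

    Samples with any missing gene are dropped with a warning (the two-way
    model needs complete rows).
    """
    y = matrix.log2()
    k = y.shape[1]
    if k < 3:
        raise InsufficientDataError("NormFinder needs >= 3 genes")
    complete = y.dropna(axis=0)
    if len(complete) < len(y):
        logger.warning("NormFinder: dropping %d incomplete samples",
                       len(y) - len(complete))
    if len(complete) < 2:
        raise InsufficientDataError("NormFinder needs >= 2 complete samples")
    y = complete

    if groups is None:
        var_g = _normfinder_variances(y)
        stab = np.sqrt(var_g)
        extras = {g: {"intragroup_variance": float(var_g[g])} for g in y.columns}
        return _make_scores("normfinder", stab, extras)

    grp = pd.Series({s: groups[s] for s in y.index})
    counts = grp.value_counts()
    if (counts < 2).any():
        raise InsufficientDataError("each group needs >= 2 complete samples")
    z = y.sub(y.mean(axis=1), axis=0)                  # remove sample effects
    group_names = list(pd.unique(grp))
    n_groups = len(group_names)
    var_ag = pd.DataFrame(index=group_names, columns=y.columns, dtype=float)
    u_ag = pd.DataFrame(index=group_names, columns=y.columns, dtype=float)
    n_a = pd.Series({a: int(counts[a]) for a in group_names})
    for a in group_names:
        ya = y.loc[grp == a]
        var_ag.loc[a] = _normfinder_variances(ya)
        u_ag.loc[a] = z.loc[grp == a].mean(axis=0)
    if n_groups < 2:
        # one group degenerates to the ungrouped estimator
        stab = np.sqrt(var_ag.iloc[0].astype(float))
        extras = {g: {"intragroup_variance": float(var_ag.iloc[0][g])}
                  for g in y.columns}
        return _make_scores("normfinder", stab, extras)
    d_ag = u_ag.sub(u_ag.mean(axis=0), axis=1)         # centre across groups
    samp_var = var_ag.div(n_a, axis=0)
    gamma2 = max(0.0, float((d_ag ** 2).to_numpy().mean()
                            - samp_var.to_numpy().mean()))
    shrink = gamma2 / (gamma2 + samp_var) if gamma2 > 0 else samp_var * 0.0
    d_hat = d_ag * shrink
    stab_ag = d_hat.abs() + np.sqrt(samp_var.astype(float))
    stab = stab_ag.mean(axis=0)
    extras = {
        g: {
            "intragroup_variance": float(var_ag[g].mean()),
            "intergroup_difference": {a: float(d_hat.loc[a, g])
                                      for a in group_names},
        }
        for g in y.columns
    }
    return _make_scores("normfinder", stab, extras)


def _normfinder_variances(y: pd.DataFrame) -> pd.Series:
    """Per-gene noise variance in the additive model, floored at zero.

    With z the sample-centred log quantities and s2_g their per-gene n-1
    variance, E[s2_g] mixes sigma2_g with the panel average; solving the
    moment equations gives sigma2_g = k/(k-2) * (s2_g - S/k^2) where
    S = k/(k-1) * sum(s2) estimates the summed noise variance.
    """
    k = y.shape[1]
    z = y.sub(y.mean(axis=1), axis=0)
    s2 = z.var(axis=0, ddof=1)
    total = float(s2.sum()) * k / (k - 1)
    sigma2 = (s2 - total / k ** 2) * k / (k - 2)
    floored = sigma2.clip(lower=0.0)
    if (sigma2 < 0).any():
        logger.info("NormFinder: variance floored at 0 for %s",
                    list(sigma2.index[sigma2 < 0]))
    return floored


def run_all_methods(
    table: CqTable,
    efficiencies: Mapping[str, float] | float | None = None,
    groups: Mapping[str, str] | None = None,
    methods: Sequence[str] = METHODS,
) -> dict[str, list[StabilityScore]]:
    """Run the requested stability methods on an aggregated CqTable."""
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValidationError(f"unknown methods {sorted(unknown)}")
    out: dict[str, list[StabilityScore]] = {}
    matrix = None
    if {"genorm", "normfinder"} & set(methods):
        matrix = relative_quantities(table, efficiencies)
    for m in methods:
        if m == "delta_ct":
            out[m] = delta_ct_stability(table)
        elif m == "genorm":
            out[m] = genorm_stepwise(matrix).scores()
        elif m == "bestkeeper":
            out[m] = bestkeeper(table)
        elif m == "normfinder":
            out[m] = normfinder(matrix, groups=groups)
    return out
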