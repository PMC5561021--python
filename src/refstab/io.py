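"""Cq data model, CSV/RDML readers, replicate aggregation and descriptive summaries.

The central container is :class:`CqTable`, a validated tidy table of
quantification-cycle (Cq) measurements keyed by sample, gene, experimental
condition and biological/technical replicate.  Missing Cq values (wells that
never crossed the detection threshold) are carried explicitly as NaN and are
excluded pairwise by every downstream statistic.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("sample", "gene", "condition", "bio_rep", "tech_rep", "cq")
WIDE_META_COLUMNS = ("sample", "condition", "bio_rep")

DEFAULT_MAX_CYCLES = 40.0


@dataclass(frozen=True)
class CqRecord:
    """One Cq measurement for one well.

    ``cq`` is NaN for a non-amplifying well.  When present it must lie in
    ``(0, max_cycles]`` (the table enforces this).
    """

    sample_id: str
    gene_id: str
    condition: str
    bio_replicate: int
    tech_replicate: int
    cq: float


@dataclass
class CqTable:
    """Tidy collection of Cq measurements.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``sample, gene, condition, bio_rep, tech_rep, cq``; one row
        per well.  ``cq`` is float with NaN marking non-amplification.
    max_cycles : float
        Upper bound of the valid Cq range (the instrument's cycle count).

    Gene and sample order is first-seen order and is preserved by every
    operation in the package.
    """

    data: pd.DataFrame
    max_cycles: float = DEFAULT_MAX_CYCLES

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True).copy()
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"CqTable missing columns: {missing}")
        df = df.loc[:, list(LONG_COLUMNS)]
        df["sample"] = df["sample"].astype(str)
        df["gene"] = df["gene"].astype(str)
        df["condition"] = df["condition"].astype(str)
        df["bio_rep"] = df["bio_rep"].astype(int)
        df["tech_rep"] = df["tech_rep"].astype(int)
        df["cq"] = df["cq"].astype(float)
        if (df["bio_rep"] < 1).any() or (df["tech_rep"] < 1).any():
            raise ValidationError("bio_rep and tech_rep must be positive integers")
        bad = df["cq"].notna() & ~((df["cq"] > 0) & (df["cq"] <= self.max_cycles))
        if bad.any():
            row = df.loc[bad].iloc[0]
            raise ValidationError(
                f"cq={row['cq']} outside (0, {self.max_cycles}] for "
                f"sample={row['sample']!r} gene={row['gene']!r} "
                f"tech_rep={row['tech_rep']}"
            )
        dup = df.duplicated(subset=["sample", "gene", "tech_rep"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise ValidationError(
                "duplicate (sample, gene, tech_rep): "
                f"({row['sample']!r}, {row['gene']!r}, {row['tech_rep']})"
            )
        # each sample must map to a single (condition, bio_rep)
        meta = df.groupby("sample", sort=False)[["condition", "bio_rep"]].nunique()
        incons = meta[(meta["condition"] > 1) | (meta["bio_rep"] > 1)]
        if len(incons):
            raise ValidationError(
                f"sample {incons.index[0]!r} maps to more than one (condition, bio_rep)"
            )
        self.data = df

    # ------------------------------------------------------------------ views
    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.data["gene"]))

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.data["sample"]))

    @property
    def design(self) -> dict[str, tuple[str, int]]:
        """Mapping sample_id -> (condition, bio_replicate)."""
        sub = self.data.drop_duplicates("sample")
        return {
            r["sample"]: (r["condition"], int(r["bio_rep"]))
            for _, r in sub.iterrows()
        }

    @property
    def is_aggregated(self) -> bool:
        return not self.data.duplicated(subset=["sample", "gene"]).any()

    def records(self) -> list[CqRecord]:
        return [
            CqRecord(r["sample"], r["gene"], r["condition"],
                     int(r["bio_rep"]), int(r["tech_rep"]), float(r["cq"]))
            for _, r in self.data.iterrows()
        ]

    @classmethod
    def from_records(cls, records: Iterable[CqRecord],
                     max_cycles: float = DEFAULT_MAX_CYCLES) -> "CqTable":
        rows = [
            (r.sample_id, r.gene_id, r.condition, r.bio_replicate,
             r.tech_replicate, r.cq)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=LONG_COLUMNS)
        return cls(df, max_cycles=max_cycles)

    def cq_matrix(self) -> pd.DataFrame:
        """Samples x genes matrix of Cq values (requires aggregated table)."""
        if not self.is_aggregated:
            raise ValidationError(
                "table has multiple technical replicates; call "
                "aggregate_technical_replicates first"
            )
        mat = self.data.pivot(index="sample", columns="gene", values="cq")
        return mat.reindex(index=self.samples, columns=self.genes)

    def subset_conditions(self, conditions: Sequence[str]) -> "CqTable":
        keep = self.data["condition"].isin(list(conditions))
        if not keep.any():
            raise ValidationError(f"no samples in conditions {list(conditions)}")
        return CqTable(self.data.loc[keep], max_cycles=self.max_cycles)


@dataclass(frozen=True)
class CqSummary:
    """Per-gene descriptive statistics of aggregated Cq values.

    ``sd_cq``/``cv_percent`` are NaN when fewer than two values are present
    (SD uses the n-1 denominator; CV% = 100 * SD / mean).
    """

    gene_id: str
    n: int
    mean_cq: float
    min_cq: float
    max_cq: float
    sd_cq: float
    cv_percent: float


# ---------------------------------------------------------------------- I/O
def _parse_cq(token: str, missing_token: str, decimal_comma: bool) -> float:
    tok = token.strip()
    if tok == missing_token or tok == "":
        return math.nan
    if decimal_comma:
        tok = tok.replace(",", ".")
    return float(tok)


def read_cq_table(
    path: str | Path,
    layout: str = "long",
    missing_token: str = "NA",
    decimal_comma: bool = False,
    max_cycles: float = DEFAULT_MAX_CYCLES,
) -> CqTable:
    """Read a Cq table from CSV.

    ``layout='long'`` expects columns ``sample, gene, condition, bio_rep,
    tech_rep, cq``.  ``layout='wide'`` expects leading columns ``sample,
    condition, bio_rep`` followed by one column per gene (one row per sample,
    technical replicates already averaged).  Cells equal to ``missing_token``
    become explicit missing entries.  ``decimal_comma=True`` accepts comma
    decimal separators in the cq fields.
    """
    path = Path(path)
    if layout not in ("long", "wide"):
        raise ValueError(f"unknown layout {layout!r}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        rows = []
        if layout == "long":
            idx = {}
            for col in LONG_COLUMNS:
                if col not in header:
                    raise ParseError(f"{path}: long layout requires column {col!r}")
                idx[col] = header.index(col)
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                try:
                    rows.append((
                        row[idx["sample"]].strip(),
                        row[idx["gene"]].strip(),
                        row[idx["condition"]].strip(),
                        int(row[idx["bio_rep"]]),
                        int(row[idx["tech_rep"]]),
                        _parse_cq(row[idx["cq"]], missing_token, decimal_comma),
                    ))
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}: row {lineno}: {exc}") from exc
        else:
            for col in WIDE_META_COLUMNS:
                if col not in header[:3]:
                    raise ParseError(
                        f"{path}: wide layout requires leading columns "
                        f"{list(WIDE_META_COLUMNS)}"
                    )
            genes = header[3:]
            if not genes:
                raise ParseError(f"{path}: wide layout has no gene columns")
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                try:
                    sample, condition = row[0].strip(), row[1].strip()
                    bio_rep = int(row[2])
                    for g, cell in zip(genes, row[3:]):
                        rows.append((
                            sample, g, condition, bio_rep, 1,
                            _parse_cq(cell, missing_token, decimal_comma),
                        ))
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}: row {lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=LONG_COLUMNS)
    return CqTable(df, max_cycles=max_cycles)


def write_cq_table(
    table: CqTable,
    path: str | Path,
    layout: str = "long",
    missing_token: str = "NA",
) -> None:
    """Write a CqTable to CSV in long or wide layout (UTF-8, header row)."""
    path = Path(path)
    if layout == "long":
        out = table.data.copy()
        out["cq"] = out["cq"].map(
            lambda v: missing_token if pd.isna(v) else repr(float(v))
        )
        out.to_csv(path, index=False)
    elif layout == "wide":
        mat = table.cq_matrix()
        design = table.design
        with path.open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(list(WIDE_META_COLUMNS) + list(mat.columns))
            for sample in mat.index:
                cond, bio = design[sample]
                cells = [
                    missing_token if pd.isna(v) else repr(float(v))
                    for v in mat.loc[sample]
                ]
                w.writerow([sample, cond, bio] + cells)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_rdml(path: str | Path, max_cycles: float = DEFAULT_MAX_CYCLES) -> CqTable:
    """Import Cq values from an RDML v1.x XML document (import only).

    Maps each ``react`` element's sample reference and its ``data/tar``
    target references to CqRecords.  RDML carries no condition/replicate
    design, so condition defaults to the sample id, bio_rep to 1, and
    technical replicates are enumerated in document order.  A negative or
    absent ``cq`` element becomes a missing entry.
    """
    tree = ET.parse(Path(path))
    root = tree.getroot()

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    rows: list[tuple] = []
    counter: dict[tuple[str, str], int] = {}
    for react in root.iter():
        if local(react.tag) != "react":
            continue
        sample_id = react.get("id", "")
        for child in react:
            if local(child.tag) == "sample":
                sample_id = child.get("id", sample_id)
        for data in react:
            if local(data.tag) != "data":
                continue
            gene_id, cq = None, math.nan
            for el in data:
                if local(el.tag) == "tar":
                    gene_id = el.get("id")
                elif local(el.tag) == "cq" and el.text is not None:
                    try:
                        cq = float(el.text)
                    except ValueError:
                        cq = math.nan
            if gene_id is None:
                continue
            if not math.isnan(cq) and (cq <= 0 or cq > max_cycles):
                cq = math.nan  # RDML uses e.g. -1 for "no Cq"
            key = (sample_id, gene_id)
            counter[key] = counter.get(key, 0) + 1
            rows.append((sample_id, gene_id, sample_id, 1, counter[key], cq))
    if not rows:
        raise ParseError(f"{path}: no react/data/cq entries found")
    return CqTable(pd.DataFrame(rows, columns=LONG_COLUMNS), max_cycles=max_cycles)


# ------------------------------------------------------------- operations
def aggregate_technical_replicates(table: CqTable) -> CqTable:
    """Average technical replicates to one Cq per (sample, gene).

    The mean is taken over present values only; a (sample, gene) whose
    replicates are all missing stays missing.  Idempotent.
    """
    df = table.data
    agg = (
        df.groupby(["sample", "gene"], sort=False)
        .agg(condition=("condition", "first"), bio_rep=("bio_rep", "first"),
             cq=("cq", lambda s: s.mean()))   # pandas mean skips NaN
        .reset_index()
    )
    agg["tech_rep"] = 1
    agg = agg.loc[:, list(LONG_COLUMNS)]
    return CqTable(agg, max_cycles=table.max_cycles)


def cq_summary(table: CqTable) -> list[CqSummary]:
    """Per-gene mean/min/max/SD (n-1) and CV% over samples.

    Technical replicates must already be aggregated; missing entries are
    excluded.  Genes with fewer than two present values get NaN SD and CV.
    """
    if not table.is_aggregated:
        raise ValidationError("aggregate technical replicates before summarising")
    out = []
    mat = table.cq_matrix()
    for gene in table.genes:
        vals = mat[gene].dropna().to_numpy()
        n = len(vals)
        if n == 0:
            out.append(CqSummary(gene, 0, math.nan, math.nan, math.nan,
                                 math.nan, math.nan))
            continue
        mean = float(np.mean(vals))
        if n >= 2:
            sd = float(np.std(vals, ddof=1))
            cv = 100.0 * sd / mean
        else:
            sd = cv = math.nan
            logger.warning("gene %s has <2 Cq values; SD/CV undefined", gene)
        out.append(CqSummary(gene, n, mean, float(vals.min()),
                             float(vals.max()), sd, cv))
    return out


def summaries_to_frame(summaries: Sequence[CqSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def summaries_to_json(summaries: Sequence[CqSummary], path: str | Path) -> None:
    payload = [
        {k: (None if isinstance(v, float) and math.isnan(v) else v)
         for k, v in s.__dict__.items()}
        for s in summaries
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
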