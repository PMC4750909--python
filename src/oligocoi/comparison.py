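"""Sanger-vs-NGS community comparison: detection, skew, correlation.

Three views of how well read abundances recover the specimen-based truth:
(1) a per-(sample, OTU) detection matrix (detected on both bases, one, or
neither); (2) per-OTU over/under-estimation skew ratios, flagging OTUs
whose Sanger/NGS proportion ratio exceeds 2 in at least two samples; and
(3) Pearson correlation and least-squares regression between specimen and
read proportions, per sample and pooled across samples, before and after
applying correction factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correction import CorrectionFactor, apply_factors

__all__ = [
    "detection_matrix",
    "SkewRecord",
    "skew_ratios",
    "correlate",
    "CorrelationResult",
    "comparison_report",
]

_STATUSES = ("detected_both", "sanger_only", "ngs_only", "absent")


def detection_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Classify every (sample, OTU) cell by which basis detected it.

    Returns a DataFrame indexed by otu_id with one column per sample
    holding one of {detected_both, sanger_only, ngs_only, absent}, plus
    attrs ``summary`` with the sanger_only / ngs_only / detected_both
    totals.
    """
    for col in ("specimens", "mean_reads"):
        if col not in table.columns:
            raise ValueError(f"community table lacks column {col!r}")
    samples = sorted(table["sample_id"].unique())
    otus = sorted(table["otu_id"].unique())
    grid = pd.DataFrame("absent", index=otus, columns=samples)
    for row in table.itertuples():
        s = row.specimens > 0
        n = row.mean_reads > 0
        status = (
            "detected_both" if s and n else "sanger_only" if s else "ngs_only" if n else "absent"
        )
        grid.loc[row.otu_id, row.sample_id] = status
    grid.index.name = "otu_id"
    counts = grid.stack().value_counts()
    grid.attrs["summary"] = {st: int(counts.get(st, 0)) for st in _STATUSES}
    return grid


@dataclass(frozen=True)
class SkewRecord:
    """Per-OTU abundance skew between specimen and read proportions.

    ``ratios`` holds, per sample where the OTU is detected on both bases,
    max(pct_sanger/pct_ngs, pct_ngs/pct_sanger) (>= 1). Samples detected
    on a single basis appear in ``one_sided_samples`` and are excluded
    from the flag rule. ``direction`` is "over" when reads overestimate
    the OTU (mean log-ratio of NGS over Sanger positive), "under"
    otherwise; ``flagged`` is True iff the ratio exceeds 2 in at least
    two samples.
    """

    otu_id: str
    ratios: dict[str, float]
    direction: str | None
    flagged: bool
    one_sided_samples: tuple[str, ...] = ()


def skew_ratios(
    table: pd.DataFrame,
    *,
    ratio_threshold: float = 2.0,
    min_flag_samples: int = 2,
) -> list[SkewRecord]:
    """Compute per-OTU skew records from a proportioned community table."""
    for col in ("pct_specimens", "pct_reads"):
        if col not in table.columns:
            raise ValueError(
                f"table lacks {col!r}; run otus.add_proportions first"
            )
    records = []
    for otu, sub in table.groupby("otu_id", sort=True):
        ratios: dict[str, float] = {}
        log_ratios = []
        one_sided = []
        for row in sub.itertuples():
            ps, pn = row.pct_specimens, row.pct_reads
            if ps > 0 and pn > 0:
                ratios[row.sample_id] = max(ps / pn, pn / ps)
                log_ratios.append(math.log(pn / ps))
            elif ps > 0 or pn > 0:
                one_sided.append(row.sample_id)
        direction = None
        if log_ratios:
            direction = "over" if float(np.mean(log_ratios)) > 0 else "under"
        flagged = (
            sum(1 for r in ratios.values() if r > ratio_threshold)
            >= min_flag_samples
        )
        records.append(
            SkewRecord(
                otu_id=str(otu),
                ratios=ratios,
                direction=direction,
                flagged=flagged,
                one_sided_samples=tuple(one_sided),
            )
        )
    return records


class CorrelationResult(NamedTuple):
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    n: int


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation (two-sided p on n-2 df) and least-squares fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate (constant) input")
    lr = stats.linregress(x, y)
    return CorrelationResult(
        pearson_r=float(lr.rvalue),
        p_value=float(lr.pvalue),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        n=len(x),
    )


def _pairs(table: pd.DataFrame, ycol: str) -> pd.DataFrame:
    """(sample, OTU) cells entering a correlation: either percentage > 0."""
    sub = table.loc[(table["pct_specimens"] > 0) | (table[ycol] > 0)]
    return sub[["sample_id", "otu_id", "pct_specimens", ycol]]


def comparison_report(
    table: pd.DataFrame,
    factors: Mapping[str, CorrectionFactor] | Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sample and pooled correlations, raw and (optionally) corrected.

    Rows: one per (basis, sample) plus a pooled row per basis; columns:
    basis, sample_id, pearson_r, p_value, slope, intercept, n. Pooling
    concatenates every (sample, OTU) cell across samples, each table row
    used once; cells enter when either percentage is positive (absent
    OTUs carry a 0 on the other axis).
    """
    work = table.copy()
    bases = [("raw", "pct_reads")]
    if factors is not None:
        work = apply_factors(work, factors)
        bases.append(("corrected", "pct_corrected_reads"))
    rows = []
    for name, ycol in bases:
        pooled = []
        for sid, sub in work.groupby("sample_id", sort=True):
            cells = _pairs(sub, ycol)
            pooled.append(cells)
            try:
                res = correlate(cells["pct_specimens"], cells[ycol])
                rows.append({"basis": name, "sample_id": sid, **res._asdict()})
            except ValueError:
                rows.append(
                    {
                        "basis": name,
                        "sample_id": sid,
                        "pearson_r": np.nan,
                        "p_value": np.nan,
                        "slope": np.nan,
                        "intercept": np.nan,
                        "n": len(cells),
                    }
                )
        allcells = pd.concat(pooled, ignore_index=True)
        res = correlate(allcells["pct_specimens"], allcells[ycol])
        rows.append({"basis": name, "sample_id": "pooled", **res._asdict()})
    return pd.DataFrame(rows)
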