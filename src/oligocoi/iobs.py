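"""The IOBS oligochaete index of sediment bioindication.

IOBS = 10 * S / T, with S the total number of taxa (here OTUs) present in a
sample and T the percentage of tubificids with or without hair setae,
whichever group is dominant. Five quality classes partition the index
range: IOBS >= 6 very good; [3, 6) good; [2, 3) medium; [1, 2) poor; < 1
bad. The index can be computed from specimen counts (Sanger basis), mean
read counts (NGS basis) or bias-corrected read counts; T is always taken
from the same abundance basis as S.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

from .synthetic import ECO_GROUPS

__all__ = [
    "UndefinedIOBSError",
    "dominant_tubificid_pct",
    "iobs",
    "round_half_up",
    "quality_class",
    "IOBSResult",
    "iobs_report",
    "BASIS_COLUMNS",
]

#: Community-table abundance column backing each reporting basis.
BASIS_COLUMNS = {
    "sanger": "specimens",
    "ngs_uncorrected": "mean_reads",
    "ngs_corrected": "corrected_reads",
}

_CLASSES = (
    (6.0, "very_good"),
    (3.0, "good"),
    (2.0, "medium"),
    (1.0, "poor"),
)


class UndefinedIOBSError(ZeroDivisionError):
    """The index is undefined when no tubificids are present (T = 0)."""


def dominant_tubificid_pct(
    abundances: Mapping[str, float], eco_groups: Mapping[str, str]
) -> float:
    """Percentage of the dominant tubificid group (with vs without hair
    setae) in the sample's total abundance."""
    total = sum(abundances.values())
    if total <= 0:
        raise ValueError("zero total abundance")
    missing = [otu for otu in abundances if otu not in eco_groups]
    if missing:
        raise KeyError(f"OTUs without eco_group annotation: {sorted(missing)}")
    hair = sum(
        a for otu, a in abundances.items() if eco_groups[otu] == "tubificid_hair"
    )
    no_hair = sum(
        a for otu, a in abundances.items() if eco_groups[otu] == "tubificid_no_hair"
    )
    return 100.0 * max(hair, no_hair) / total


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero (display convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def iobs(n_taxa: int, pct_dominant: float) -> float:
    """Raw (unrounded) index value 10 * n_taxa / pct_dominant.

    Raises :class:`UndefinedIOBSError` when ``pct_dominant`` is zero; use
    :func:`round_half_up` for the conventional 2-decimal display value.
    """
    if n_taxa < 0:
        raise ValueError("n_taxa must be nonnegative")
    if not 0.0 <= pct_dominant <= 100.0:
        raise ValueError("pct_dominant must be a percentage in [0, 100]")
    if pct_dominant == 0.0:
        raise UndefinedIOBSError(
            "IOBS undefined: no tubificids in the sample (dominant % = 0)"
        )
    return 10.0 * n_taxa / pct_dominant


def quality_class(index: float) -> str:
    """Map an index value to its sediment-quality class."""
    if index < 0 or index != index:
        raise ValueError(f"index must be finite and nonnegative, got {index}")
    for bound, label in _CLASSES:
        if index >= bound:
            return label
    return "bad"


@dataclass(frozen=True)
class IOBSResult:
    sample_id: str
    basis: str
    n_taxa: int
    pct_dominant_tubificids: float
    index: float | None  # rounded to 2 decimals; None when undefined
    index_unrounded: float | None
    quality_class: str  # "undefined" when T = 0


def iobs_report(
    table: pd.DataFrame,
    eco_groups: Mapping[str, str],
    basis: str = "sanger",
) -> list[IOBSResult]:
    """Per-sample IOBS results from a community table on one basis.

    ``n_taxa`` counts OTUs with abundance > 0 on the chosen basis (no
    minimum-abundance cutoff — rare OTUs count). Samples without
    tubificids get an explicit ``"undefined"`` verdict rather than an
    infinite index. OTUs lacking an eco_group annotation abort the
    computation with the offending labels listed.
    """
    if basis not in BASIS_COLUMNS:
        raise ValueError(f"basis must be one of {sorted(BASIS_COLUMNS)}")
    col = BASIS_COLUMNS[basis]
    if col not in table.columns:
        raise ValueError(f"table lacks column {col!r} required for basis {basis!r}")
    bad_groups = {
        g for g in eco_groups.values() if g not in ECO_GROUPS
    }
    if bad_groups:
        raise ValueError(f"unknown eco_group values: {sorted(bad_groups)}")
    results = []
    for sid, sub in table.groupby("sample_id", sort=True):
        present = sub.loc[sub[col] > 0]
        abund = dict(zip(present["otu_id"], present[col].astype(float)))
        n_taxa = len(abund)
        if not abund:
            results.append(
                IOBSResult(sid, basis, 0, 0.0, None, None, "undefined")
            )
            continue
        pct = dominant_tubificid_pct(abund, eco_groups)
        try:
            raw = iobs(n_taxa, pct)
        except UndefinedIOBSError:
            results.append(
                IOBSResult(sid, basis, n_taxa, pct, None, None, "undefined")
            )
            continue
        results.append(
            IOBSResult(
                sid,
                basis,
                n_taxa,
                pct,
                round_half_up(raw, 2),
                raw,
                quality_class(raw),
            )
        )
    return results


def report_frame(results: list[IOBSResult]) -> pd.DataFrame:
    """Tabulate results in the three-row-per-basis layout (rows: number of
    OTUs, % tubificids, IOBS; columns: samples)."""
    df = pd.DataFrame([r.__dict__ for r in results])
    out = {}
    for sid, sub in df.groupby("sample_id"):
        col = {}
        for _, r in sub.iterrows():
            col[(r.basis, "n_otus")] = r.n_taxa
            col[(r.basis, "pct_tubificids")] = round_half_up(
                r.pct_dominant_tubificids, 2
            )
            col[(r.basis, "iobs")] = r["index"]
        out[sid] = col
    frame = pd.DataFrame(out)
    frame.index.names = ["basis", "quantity"]
    return frame
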