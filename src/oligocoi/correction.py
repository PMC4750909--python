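"""Empirical per-OTU correction factors for PCR amplification bias.

Read abundances in amplicon data over- or under-represent taxa whose COI
template amplifies more or less efficiently than average. When the skew of
an OTU is consistent in direction and magnitude across samples, it can be
offset by a single multiplicative correction factor fitted empirically: the
OTU's mean read count in every sample is multiplied by a candidate factor,
the resulting proportion recomputed (other OTUs' counts untouched), and the
factor retained is the one minimizing the mean absolute difference, in
percentage points, between the specimen-based (expected) and read-based
(observed) proportions across samples. Candidates come from a fixed grid:
0.10 to 1.00 in steps of 0.05, then 1 to 200 in steps of 1.

For final reporting all selected factors are applied jointly and the
per-sample percentages renormalized together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .otus import add_proportions

__all__ = [
    "correction_grid",
    "CorrectionFactor",
    "corrected_proportion",
    "objective",
    "optimize_factor",
    "optimize_factors",
    "objective_curve",
    "apply_factors",
    "paired_samples_for_otu",
]


def correction_grid(grid_max: float = 200.0) -> np.ndarray:
    """Candidate factors: {0.10, 0.15, ..., 1.00} U {1, 2, ..., grid_max},
    deduplicated at 1, ascending."""
    fine = np.round(np.arange(0.10, 1.0001, 0.05), 2)
    coarse = np.arange(1.0, grid_max + 0.5, 1.0)
    return np.unique(np.concatenate([fine, coarse]))


@dataclass(frozen=True)
class CorrectionFactor:
    """A fitted per-OTU factor and the achieved minimum objective."""

    otu_id: str
    factor: float
    min_avg_diff: float  # percentage points
    n_samples_used: int

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("factor must be positive")
        if self.min_avg_diff < 0:
            raise ValueError("min_avg_diff must be nonnegative")
        if self.n_samples_used < 1:
            raise ValueError("factor must be fitted on at least one sample")


#: One optimization data point: the focal OTU's expected percentage from
#: specimen counts, and the sample's per-OTU absolute mean read counts.
PairedSample = tuple[float, Mapping[str, float]]


def corrected_proportion(
    sample_counts: Mapping[str, float], focal_otu: str, factor: float
) -> float:
    """Percentage of the focal OTU after scaling only its own count.

    100 * f*c_focal / (f*c_focal + sum of other counts); the other OTUs'
    counts stay raw during optimization.
    """
    if focal_otu not in sample_counts:
        raise KeyError(f"focal OTU {focal_otu!r} absent from sample counts")
    if factor <= 0:
        raise ValueError("factor must be positive")
    if any(c < 0 for c in sample_counts.values()):
        raise ValueError("counts must be nonnegative")
    focal = factor * sample_counts[focal_otu]
    others = sum(c for otu, c in sample_counts.items() if otu != focal_otu)
    denom = focal + others
    if denom <= 0:
        raise ZeroDivisionError("all counts zero in sample")
    return 100.0 * focal / denom


def objective(
    focal_otu: str,
    factor: float,
    paired_samples: Sequence[PairedSample],
    *,
    mode: str = "absolute",
) -> float:
    """Mean per-sample discrepancy between expected and corrected observed
    proportions of the focal OTU, at the given factor.

    ``mode="absolute"`` (default): mean of |expected% - observed%| in
    percentage points. ``mode="relative"``: mean of the same difference
    divided by the expected percentage (samples with expected 0 excluded).
    """
    if not paired_samples:
        raise ValueError("no samples to evaluate")
    diffs = []
    for expected_pct, counts in paired_samples:
        obs = corrected_proportion(counts, focal_otu, factor)
        if mode == "absolute":
            diffs.append(abs(expected_pct - obs))
        elif mode == "relative":
            if expected_pct > 0:
                diffs.append(abs(expected_pct - obs) / expected_pct)
        else:
            raise ValueError(f"unknown objective mode {mode!r}")
    if not diffs:
        raise ValueError("no usable samples for relative objective")
    return float(np.mean(diffs))


def optimize_factor(
    focal_otu: str,
    paired_samples: Sequence[PairedSample],
    grid: np.ndarray | None = None,
    *,
    mode: str = "absolute",
) -> CorrectionFactor:
    """Grid-search the factor minimizing :func:`objective`.

    Ties are broken toward the candidate closest to 1 (no correction),
    then toward the smaller value.
    """
    if grid is None:
        grid = correction_grid()
    best: tuple[float, float, float] | None = None  # (obj, |log f|, f)
    for f in grid:
        val = objective(focal_otu, float(f), paired_samples, mode=mode)
        key = (val, abs(f - 1.0), f)
        if best is None or key < best:
            best = key
    return CorrectionFactor(
        otu_id=focal_otu,
        factor=float(best[2]),
        min_avg_diff=float(best[0]),
        n_samples_used=len(paired_samples),
    )


def objective_curve(
    focal_otu: str,
    paired_samples: Sequence[PairedSample],
    grid: np.ndarray | None = None,
    *,
    mode: str = "absolute",
) -> pd.DataFrame:
    """The full factor-vs-average-difference curve over the grid."""
    if grid is None:
        grid = correction_grid()
    return pd.DataFrame(
        {
            "factor": grid,
            "avg_diff": [
                objective(focal_otu, float(f), paired_samples, mode=mode)
                for f in grid
            ],
        }
    )


def paired_samples_for_otu(
    table: pd.DataFrame, focal_otu: str
) -> list[PairedSample]:
    """Extract the optimization inputs for one OTU from a community table.

    One entry per sample where the focal OTU is present on either basis
    (nonzero specimens OR nonzero mean reads); samples where it is absent
    from both carry no signal and are excluded.
    """
    out: list[PairedSample] = []
    for sid, sub in table.groupby("sample_id", sort=True):
        row = sub.loc[sub["otu_id"] == focal_otu]
        if row.empty:
            continue
        spec = float(row["specimens"].iloc[0])
        reads = float(row["mean_reads"].iloc[0])
        if spec <= 0 and reads <= 0:
            continue
        spec_total = float(sub["specimens"].sum())
        if spec_total <= 0:
            continue
        expected = 100.0 * spec / spec_total
        counts = dict(zip(sub["otu_id"], sub["mean_reads"].astype(float)))
        out.append((expected, counts))
    return out


def optimize_factors(
    table: pd.DataFrame,
    min_samples: int = 4,
    grid: np.ndarray | None = None,
    *,
    mode: str = "absolute",
) -> dict[str, CorrectionFactor]:
    """Fit factors for every OTU present in at least ``min_samples`` samples.

    Presence = nonzero specimens or mean reads in a sample. The default
    eligibility of 4 samples keeps the fit constrained by several
    independent communities.
    """
    out: dict[str, CorrectionFactor] = {}
    for otu in sorted(table["otu_id"].unique()):
        samples = paired_samples_for_otu(table, otu)
        if len(samples) < min_samples:
            continue
        out[otu] = optimize_factor(otu, samples, grid, mode=mode)
    return out


def apply_factors(
    table: pd.DataFrame,
    factors: Mapping[str, CorrectionFactor] | Mapping[str, float],
) -> pd.DataFrame:
    """Apply all selected factors jointly and renormalize per sample.

    Adds ``corrected_reads`` (= factor x mean_reads for corrected OTUs,
    mean_reads otherwise) and ``pct_corrected_reads`` recomputed per
    sample with every correction in effect; the uncorrected columns are
    retained. Factors naming OTUs absent from the table are ignored with
    a warning.

    Note the deliberate asymmetry with :func:`optimize_factor`: during
    optimization only the focal OTU is scaled; here the final table
    applies all factors at once.
    """
    import warnings

    table = table.copy()
    fvals: dict[str, float] = {}
    for otu, f in factors.items():
        fvals[otu] = f.factor if isinstance(f, CorrectionFactor) else float(f)
    unknown = set(fvals) - set(table["otu_id"])
    if unknown:
        warnings.warn(
            f"correction factors for OTUs absent from the table ignored: "
            f"{sorted(unknown)}",
            stacklevel=2,
        )
    table["corrected_reads"] = [
        row.mean_reads * fvals.get(row.otu_id, 1.0) for row in table.itertuples()
    ]
    return add_proportions(table)
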