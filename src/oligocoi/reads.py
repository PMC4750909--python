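"""Paired-read quality filtering, primer localization and dereplication.

The filtering cascade mirrors a strict amplicon protocol for non-overlapping
2x251 bp paired reads: (1) keep a pair only when BOTH mates have mean Phred
quality >= 30 and at most one base below Q30; (2) resolve orientation by
primer content — the reverse (HCO2198) primer is searched in R1 and, if
found, the forward (LCO1490) primer must be found in R2 (or vice versa);
pairs with zero or one primer are discarded; (3) trim the primer (and any
bases preceding it) and split reads into an LCO-end and an HCO-end dataset;
(4) dereplicate each dataset to unique sequences with counts.

Primer matching allows a configurable Levenshtein edit distance (default 1,
substitutions and indels) and is restricted, by default, to a prefix window
of len(primer) + max_edits bases, since amplicon reads begin at a primer.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import edlib
import pandas as pd

from .synthetic import HCO2198, LCO1490, reverse_complement

__all__ = [
    "FilterParams",
    "ReadPair",
    "PrimerMatch",
    "FilterAccounting",
    "read_passes_quality",
    "pair_passes_quality",
    "locate_primer",
    "resolve_orientation",
    "process_fastq",
    "dereplicate",
    "write_derep_fasta",
    "accounting_frame",
]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds and primers of the filtering cascade (defaults as above)."""

    q_mean_min: float = 30.0
    max_bases_below: int = 1
    q_base_threshold: int = 30
    primer_max_edits: int = 1
    lco_primer: str = LCO1490
    hco_primer: str = HCO2198
    #: None = window of len(primer) + max_edits; 0 = full-read scan.
    primer_window: int | None = None
    #: Also try the reverse complement of each mate when locating primers.
    try_reverse_complement: bool = False
    #: Treat IUPAC ambiguity codes in primers as matching their expansions.
    iupac_primers: bool = False

    def __post_init__(self) -> None:
        if self.q_mean_min < 0 or self.q_base_threshold < 0 or self.primer_max_edits < 0:
            raise ValueError("thresholds must be nonnegative")
        if not self.lco_primer or not self.hco_primer:
            raise ValueError("primers must be nonempty")


class ReadPair(NamedTuple):
    r1_seq: str
    r2_seq: str
    r1_qual: Sequence[int]
    r2_qual: Sequence[int]


class PrimerMatch(NamedTuple):
    start: int
    end: int  # exclusive
    edits: int


class OrientedPair(NamedTuple):
    """Primer-trimmed reads labeled by the amplicon end they sequence."""

    lco_read: str
    hco_read: str


def read_passes_quality(qual: Sequence[int], params: FilterParams = FilterParams()) -> bool:
    """True iff mean quality >= q_mean_min and at most ``max_bases_below``
    bases fall below ``q_base_threshold``."""
    if len(qual) == 0:
        raise ValueError("empty quality list")
    if sum(qual) / len(qual) < params.q_mean_min:
        return False
    return sum(1 for q in qual if q < params.q_base_threshold) <= params.max_bases_below


def pair_passes_quality(pair: ReadPair, params: FilterParams = FilterParams()) -> bool:
    """True iff both mates individually pass the read quality rule."""
    return read_passes_quality(pair.r1_qual, params) and read_passes_quality(
        pair.r2_qual, params
    )


_IUPAC = [("R", "AG"), ("Y", "CT"), ("S", "GC"), ("W", "AT"), ("K", "GT"),
          ("M", "AC"), ("B", "CGT"), ("D", "AGT"), ("H", "ACT"), ("V", "ACG"),
          ("N", "ACGT")]


def locate_primer(
    seq: str,
    primer: str,
    max_edits: int = 1,
    *,
    window: int | None = None,
    iupac: bool = False,
) -> PrimerMatch | None:
    """Best occurrence of ``primer`` within the read prefix window.

    Returns the lowest-edit (ties: leftmost) match with Levenshtein
    distance <= ``max_edits``, with an exclusive ``end``, or None. The
    window defaults to ``len(primer) + max_edits`` bases; pass ``window=0``
    to scan the whole read. With ``iupac=True`` degenerate primer bases
    match any of their expansions at zero cost.
    """
    if not primer:
        raise ValueError("empty primer")
    if max_edits < 0:
        raise ValueError("max_edits must be >= 0")
    if window is None:
        window = len(primer) + max_edits
    target = seq if window == 0 else seq[:window]
    if not target:
        return None
    extra = (
        {"additionalEqualities": [(a, b) for a, exp in _IUPAC for b in exp]}
        if iupac
        else {}
    )
    res = edlib.align(primer, target, mode="HW", task="locations", k=max_edits, **extra)
    if res["editDistance"] < 0:
        return None
    start, end = min(res["locations"], key=lambda loc: (loc[0] or 0, loc[1]))
    return PrimerMatch(start or 0, end + 1, res["editDistance"])


def _find_and_trim(
    seq: str, primer: str, params: FilterParams
) -> str | None:
    """Trim ``seq`` after the primer match, trying the reverse complement
    too when the params allow; returns None when the primer is absent."""
    m = locate_primer(
        seq,
        primer,
        params.primer_max_edits,
        window=params.primer_window,
        iupac=params.iupac_primers,
    )
    if m is None and params.try_reverse_complement:
        rc = reverse_complement(seq)
        m = locate_primer(
            rc,
            primer,
            params.primer_max_edits,
            window=params.primer_window,
            iupac=params.iupac_primers,
        )
        return rc[m.end :] if m is not None else None
    return seq[m.end :] if m is not None else None


def resolve_orientation(
    pair: ReadPair, params: FilterParams = FilterParams()
) -> OrientedPair | None:
    """Pairing rule: HCO (or LCO) must be in R1 and its counterpart in R2.

    The HCO primer is searched in R1 first; if present, LCO must be found
    in R2. Otherwise LCO is searched in R1 and HCO must be found in R2. Any
    other configuration (no primer, or only one of the two) discards the
    pair. Returned reads are primer-trimmed and labeled by amplicon end.
    """
    hco_in_r1 = _find_and_trim(pair.r1_seq, params.hco_primer, params)
    if hco_in_r1 is not None:
        lco_in_r2 = _find_and_trim(pair.r2_seq, params.lco_primer, params)
        if lco_in_r2 is not None:
            return OrientedPair(lco_read=lco_in_r2, hco_read=hco_in_r1)
        return None
    lco_in_r1 = _find_and_trim(pair.r1_seq, params.lco_primer, params)
    if lco_in_r1 is not None:
        hco_in_r2 = _find_and_trim(pair.r2_seq, params.hco_primer, params)
        if hco_in_r2 is not None:
            return OrientedPair(lco_read=lco_in_r1, hco_read=hco_in_r2)
    return None


@dataclass
class FilterAccounting:
    """Stage-by-stage pair tallies for one sequencing library.

    ``total_pairs >= quality_pass >= shared_pass >= primer_pass`` holds by
    construction; ``quality_pass`` is counted at pair level (both mates
    pass, hence equal to ``shared_pass``) and the per-mate tallies
    ``r1_quality_pass``/``r2_quality_pass`` mirror per-read reporting.
    """

    library_id: str
    total_pairs: int = 0
    r1_quality_pass: int = 0
    r2_quality_pass: int = 0
    quality_pass: int = 0
    shared_pass: int = 0
    primer_pass: int = 0
    unique_lco: int = 0
    unique_hco: int = 0
    otus_lco: int | None = None
    otus_hco: int | None = None


def _open_maybe_gz(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _fastq_records(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    from Bio import SeqIO

    with _open_maybe_gz(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper(), rec.letter_annotations[
                "phred_quality"
            ]


def process_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    params: FilterParams = FilterParams(),
    *,
    library_id: str | None = None,
) -> tuple[Counter, Counter, FilterAccounting]:
    """Run the full cascade on one paired FASTQ library.

    Returns the LCO and HCO datasets as sequence multisets
    (collections.Counter over primer-trimmed reads) and the stage
    accounting. Raises on mismatched record counts.
    """
    acc = FilterAccounting(library_id=library_id or Path(r1_path).stem)
    lco: Counter = Counter()
    hco: Counter = Counter()
    it1, it2 = _fastq_records(r1_path), _fastq_records(r2_path)
    paired = zip(it1, it2, strict=True)
    while True:
        try:
            rec1, rec2 = next(paired)
        except StopIteration:
            break
        except ValueError as exc:
            raise ValueError(
                f"FASTQ files have unequal record counts: {exc}"
            ) from None
        acc.total_pairs += 1
        pair = ReadPair(rec1[1], rec2[1], rec1[2], rec2[2])
        p1 = read_passes_quality(pair.r1_qual, params)
        p2 = read_passes_quality(pair.r2_qual, params)
        acc.r1_quality_pass += int(p1)
        acc.r2_quality_pass += int(p2)
        if not (p1 and p2):
            continue
        acc.quality_pass += 1
        acc.shared_pass += 1
        oriented = resolve_orientation(pair, params)
        if oriented is None:
            continue
        acc.primer_pass += 1
        lco[oriented.lco_read] += 1
        hco[oriented.hco_read] += 1
    acc.unique_lco = len(lco)
    acc.unique_hco = len(hco)
    return lco, hco, acc


def dereplicate(dataset: Iterable[str] | Counter) -> Counter:
    """Collapse a sequence multiset to unique sequences with counts."""
    if isinstance(dataset, Counter):
        return Counter(dataset)
    return Counter(dataset)


def write_derep_fasta(derep: Counter, path: str | Path, prefix: str = "uniq") -> None:
    """Write dereplicated sequences with ``;size=count`` annotations,
    most abundant first (ties by sequence for determinism)."""
    items = sorted(derep.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as fh:
        for i, (seq, cnt) in enumerate(items, start=1):
            fh.write(f">{prefix}{i};size={cnt}\n{seq}\n")


def accounting_frame(accounts: Iterable[FilterAccounting]) -> pd.DataFrame:
    """Tabulate accounting records, one library per row (library, total,
    per-mate quality, shared, primer, unique sequences and OTUs per end)."""
    rows = []
    for a in accounts:
        rows.append(
            {
                "library": a.library_id,
                "total_pairs": a.total_pairs,
                "quality_r1": a.r1_quality_pass,
                "quality_r2": a.r2_quality_pass,
                "shared": a.shared_pass,
                "primer": a.primer_pass,
                "unique_lco": a.unique_lco,
                "unique_hco": a.unique_hco,
                "otus_lco": a.otus_lco,
                "otus_hco": a.otus_hco,
            }
        )
    return pd.DataFrame(rows)
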