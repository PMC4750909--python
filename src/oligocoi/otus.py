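"""OTU inference from COI amplicon data.

Kimura two-parameter (K2P) distances, neighbor-joining tree construction,
divergence-threshold OTU delineation against a reference database, and
aggregation of dereplicated read counts into per-sample community tables.

Sequences are assumed position-homologous (equal length, gap-free or with
gaps/ambiguities handled by pairwise deletion); no alignment is performed
here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "K2PSaturationError",
    "k2p_distance",
    "DistanceMatrix",
    "distance_matrix",
    "TreeNode",
    "neighbor_joining",
    "tree_distances",
    "OTU_DIVERGENCE_THRESHOLD",
    "delineate_otus",
    "OTUAssignment",
    "end_reference",
    "count_reads_per_otu",
    "mean_reads",
    "community_table",
    "add_proportions",
]

#: Species-level COI divergence threshold for aquatic oligochaetes.
#: Queries strictly below this K2P distance from a reference join it;
#: at or above, they separate.
OTU_DIVERGENCE_THRESHOLD = 0.10

ENDS = ("LCO", "HCO")
REPLICATES = (1, 2)

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


class K2PSaturationError(ValueError):
    """Raised when the K2P logarithm argument is non-positive.

    This happens for highly divergent sequence pairs (the model cannot
    produce a finite distance); callers may opt into an infinite sentinel
    instead via ``on_saturation="inf"``.
    """


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _k2p_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """Return (n comparable sites, transitions, transversions)."""
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    diff = valid & (a != b)
    # purines A(0)/G(2) are even codes, pyrimidines C(1)/T(3) odd: a
    # substitution within the same parity class is a transition.
    transitions = int((diff & ((a & 1) == (b & 1))).sum())
    return n, transitions, int(diff.sum()) - transitions


def _k2p_from_pq(p: float, q: float, on_saturation: str) -> float:
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        if on_saturation == "inf":
            return math.inf
        raise K2PSaturationError(
            f"K2P distance undefined (saturated): P={p:.4f}, Q={q:.4f}"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(a: str, b: str, *, on_saturation: str = "raise") -> float:
    """Kimura two-parameter distance between two aligned DNA sequences.

    With P the transition and Q the transversion fraction over comparable
    sites, d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)). Sites where either
    sequence carries a non-ACGT character are excluded pairwise (the
    default behavior of the common distance tools).

    Parameters
    ----------
    a, b
        Equal-length nucleotide strings.
    on_saturation
        ``"raise"`` (default) raises :class:`K2PSaturationError` when the
        log argument is non-positive; ``"inf"`` returns ``math.inf``.
    """
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length: {len(a)} vs {len(b)}")
    n, ts, tv = _k2p_counts(_encode(a), _encode(b))
    if n == 0:
        raise ValueError("no comparable (both ACGT) sites between sequences")
    return _k2p_from_pq(ts / n, tv / n, on_saturation)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances with sequence labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(
    seqs: Sequence[str],
    labels: Sequence[str] | None = None,
    *,
    on_saturation: str = "raise",
) -> DistanceMatrix:
    """All-pairs K2P distances; symmetric with a zero diagonal."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if labels is None:
        labels = [f"seq{i}" for i in range(len(seqs))]
    if len(labels) != len(seqs):
        raise ValueError("labels/sequences length mismatch")
    enc = [_encode(s) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if len(enc[i]) != len(enc[j]):
                    raise ValueError(
                        f"sequences differ in length: {len(enc[i])} vs {len(enc[j])}"
                    )
                ns, ts, tv = _k2p_counts(enc[i], enc[j])
                if ns == 0:
                    raise ValueError("no comparable sites")
                dij = _k2p_from_pq(ts / ns, tv / ns, on_saturation)
            except (ValueError, K2PSaturationError) as exc:
                raise type(exc)(
                    f"pair ({labels[i]!r}, {labels[j]!r}): {exc}"
                ) from None
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(labels), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of an (unrooted, stored as rooted) phylogenetic tree.

    ``children`` holds (child, branch_length) pairs; leaves carry a name.
    """

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return f"{self._newick()};"

    def _newick(self) -> str:
        if self.is_leaf():
            return self.name or ""
        inner = ",".join(
            f"{child._newick()}:{blen:.10g}" for child, blen in self.children
        )
        return f"({inner}){self.name or ''}"


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining (Saitou & Nei) from a distance matrix.

    Joins are chosen by the Q criterion; branch lengths use the standard
    formulas. On an additive matrix the path lengths of the returned tree
    reproduce the input distances exactly (up to floating error). Ties in
    the Q matrix are broken toward the lowest (row, column) index pair, so
    output is deterministic for a given input order. Negative branch
    lengths, which NJ can produce on non-additive input, are retained.
    """
    if np.isinf(dm.values).any():
        raise ValueError(
            "distance matrix contains saturated (infinite) entries; "
            "resolve or cap them before tree building"
        )
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    d = dm.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode(children=[(nodes[active[i]], li), (nodes[active[j]], lj)])
        dnew = 0.5 * (sub[i, :] + sub[j, :] - dij)
        # grow the working matrix with the new node's distances
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for idx, a_idx in enumerate(active):
            d[k, a_idx] = d[a_idx, k] = dnew[idx]
        d[k, k] = 0.0
        nodes.append(parent)
        hi, lo = active[j], active[i]
        active.remove(hi)
        active.remove(lo)
        active.append(k)

    a, b = active
    rest = d[a, b]
    # attach the remaining pair; the internal node (created last) becomes root
    if not nodes[b].is_leaf():
        nodes[b].children.append((nodes[a], rest))
        return nodes[b]
    nodes[a].children.append((nodes[b], rest))
    return nodes[a]


def tree_distances(tree: TreeNode) -> dict[frozenset[str], float]:
    """Leaf-to-leaf path lengths of a tree, keyed by unordered name pairs."""
    # adjacency over all nodes
    adj: dict[int, list[tuple[TreeNode, float]]] = {}

    def walk(node: TreeNode) -> None:
        adj.setdefault(id(node), [])
        for child, blen in node.children:
            adj[id(node)].append((child, blen))
            adj.setdefault(id(child), []).append((node, blen))
            walk(child)

    walk(tree)
    leaves = tree.leaves()
    out: dict[frozenset[str], float] = {}
    nodes_by_id = {}

    def collect(node: TreeNode) -> None:
        nodes_by_id[id(node)] = node
        for child, _ in node.children:
            collect(child)

    collect(tree)
    for leaf in leaves:
        dist = {id(leaf): 0.0}
        stack = [leaf]
        while stack:
            cur = stack.pop()
            for nb, blen in adj[id(cur)]:
                if id(nb) not in dist:
                    dist[id(nb)] = dist[id(cur)] + blen
                    stack.append(nb)
        for other in leaves:
            if other is leaf:
                continue
            key = frozenset((leaf.name, other.name))
            out[key] = dist[id(other)]
    return out


# ---------------------------------------------------------------------------
# OTU delineation
# ---------------------------------------------------------------------------


@dataclass
class OTUAssignment:
    """Per-query OTU assignment.

    ``table`` has one row per query with columns ``query``, ``otu_id``,
    ``nearest_ref`` and ``nearest_ref_distance`` (NaN/inf-free where a
    finite distance exists; saturated pairs appear as +inf). ``new_otus``
    lists novel OTU labels in order of first appearance.
    """

    table: pd.DataFrame
    new_otus: list[str]

    def otu_of(self, query: str) -> str:
        row = self.table.loc[self.table["query"] == query]
        if row.empty:
            raise KeyError(query)
        return str(row["otu_id"].iloc[0])

    def as_mapping(self) -> dict[str, str]:
        return dict(zip(self.table["query"], self.table["otu_id"]))


def delineate_otus(
    query_seqs: Mapping[str, str],
    references: Mapping[str, str],
    threshold: float = OTU_DIVERGENCE_THRESHOLD,
    *,
    new_label_format: str = "({i})",
) -> OTUAssignment:
    """Assign query sequences to reference OTUs or new single-linkage OTUs.

    Each query joins its nearest reference OTU when the K2P distance is
    strictly below ``threshold``. Queries matching no reference are
    clustered among themselves by single linkage at the same threshold;
    each cluster becomes a new OTU, labeled in first-appearance order of
    its lowest-index member (``"(1)"``, ``"(2)"``, ... by default,
    the conventional notation for OTUs absent from the reference
    database).

    Saturated query-reference pairs are treated as infinitely distant.
    """
    if not query_seqs and not references:
        raise ValueError("no queries and no references")
    q_labels = list(query_seqs)
    q_enc = [_encode(query_seqs[lab]) for lab in q_labels]
    r_labels = list(references)
    r_enc = [_encode(references[lab]) for lab in r_labels]

    def pair_dist(a: np.ndarray, b: np.ndarray) -> float:
        if len(a) != len(b):
            raise ValueError("query/reference lengths differ; trim to a common end")
        ns, ts, tv = _k2p_counts(a, b)
        if ns == 0:
            return math.inf
        return _k2p_from_pq(ts / ns, tv / ns, "inf")

    assigned: dict[str, tuple[str, str | None, float]] = {}
    novel_idx: list[int] = []
    for qi, qlab in enumerate(q_labels):
        best_ref: str | None = None
        best_d = math.inf
        for rlab, renc in zip(r_labels, r_enc):
            dd = pair_dist(q_enc[qi], renc)
            if dd < best_d:
                best_d, best_ref = dd, rlab
        if best_ref is not None and best_d < threshold:
            assigned[qlab] = (best_ref, best_ref, best_d)
        else:
            assigned[qlab] = ("", best_ref, best_d)
            novel_idx.append(qi)

    # single-linkage clustering of novel queries at the threshold
    parent = {i: i for i in novel_idx}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a_pos, ia in enumerate(novel_idx):
        for ib in novel_idx[a_pos + 1 :]:
            if pair_dist(q_enc[ia], q_enc[ib]) < threshold:
                ra, rb = find(ia), find(ib)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    cluster_label: dict[int, str] = {}
    new_otus: list[str] = []
    for i in novel_idx:  # ascending input order => first-appearance numbering
        root = find(i)
        if root not in cluster_label:
            cluster_label[root] = new_label_format.format(i=len(new_otus) + 1)
            new_otus.append(cluster_label[root])
    for i in novel_idx:
        qlab = q_labels[i]
        _, ref, dd = assigned[qlab]
        assigned[qlab] = (cluster_label[find(i)], ref, dd)

    table = pd.DataFrame(
        {
            "query": q_labels,
            "otu_id": [assigned[q][0] for q in q_labels],
            "nearest_ref": [assigned[q][1] for q in q_labels],
            "nearest_ref_distance": [assigned[q][2] for q in q_labels],
        }
    )
    return OTUAssignment(table=table, new_otus=new_otus)


def end_reference(sequence: str, end: str, length: int) -> str:
    """Reference sub-sequence homologous to primer-trimmed reads of one end.

    LCO-end reads run 5'->3' from just after the forward primer; HCO-end
    reads are the reverse complement anchored at the reverse primer.
    """
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    if end == "LCO":
        return sequence[:length]
    if end == "HCO":
        return sequence.translate(comp)[::-1][:length]
    raise ValueError(f"unknown end {end!r} (expected 'LCO' or 'HCO')")


# ---------------------------------------------------------------------------
# Read-count aggregation
# ---------------------------------------------------------------------------


def count_reads_per_otu(
    datasets: Mapping[tuple[str, int], Mapping[str, int]],
    assignments: Mapping[str, Mapping[str, str]],
) -> tuple[pd.DataFrame, dict[tuple[str, int], int]]:
    """Sum dereplicated counts per OTU for each (end, replicate) dataset.

    Parameters
    ----------
    datasets
        ``{(end, replicate): {sequence: count}}`` dereplicated read maps,
        ends in {"LCO", "HCO"}.
    assignments
        ``{end: {sequence: otu_id}}`` — every sequence present in a
        dataset must be assigned for its end; a missing assignment is an
        error rather than a silent drop.

    Returns
    -------
    (counts, unassigned)
        ``counts`` indexed by otu_id with one column per (end, replicate)
        — OTUs absent from a dataset get an explicit 0 — and a tally of
        reads whose sequence was assigned the empty label (none by
        construction of :func:`delineate_otus`, which always labels).
    """
    cols = [(end, rep) for end in ENDS for rep in REPLICATES]
    rows: dict[str, dict[tuple[str, int], int]] = {}
    unassigned: dict[tuple[str, int], int] = {c: 0 for c in cols}
    for key, derep in datasets.items():
        if key not in cols:
            raise ValueError(f"unexpected dataset key {key!r}")
        end = key[0]
        amap = assignments.get(end, {})
        for seq, cnt in derep.items():
            if seq not in amap:
                raise KeyError(
                    f"sequence of length {len(seq)} in dataset {key} has no "
                    f"OTU assignment for end {end}"
                )
            otu = amap[seq]
            if not otu:
                unassigned[key] += int(cnt)
                continue
            rows.setdefault(otu, {c: 0 for c in cols})[key] += int(cnt)
    counts = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=pd.MultiIndex.from_tuples(cols, names=["end", "replicate"]),
        fill_value=0,
    )
    counts.index.name = "otu_id"
    return counts.fillna(0).astype(int).sort_index(), unassigned


def mean_reads(reads: Sequence[float]) -> float:
    """Arithmetic mean of the four per-dataset read counts (zeros included)."""
    if len(reads) != 4:
        raise ValueError(f"expected 4 read counts (2 ends x 2 replicates), got {len(reads)}")
    return float(sum(reads)) / 4.0


def community_table(
    specimen_counts: Mapping[str, int],
    read_counts: pd.DataFrame | Mapping[tuple[str, int], Mapping[str, int]] | None = None,
    sample_id: str = "S1",
) -> pd.DataFrame:
    """Combine Sanger specimen counts and per-dataset read counts per OTU.

    Returns one row per OTU with columns: sample_id, otu_id, specimens,
    reads_lco_1, reads_lco_2, reads_hco_1, reads_hco_2, mean_reads, plus
    pct_specimens / pct_reads (see :func:`add_proportions`).
    """
    if read_counts is None:
        read_counts = pd.DataFrame(
            columns=pd.MultiIndex.from_tuples(
                [(e, r) for e in ENDS for r in REPLICATES]
            )
        )
    if not isinstance(read_counts, pd.DataFrame):
        read_counts = pd.DataFrame.from_dict(
            {k: dict(v) for k, v in read_counts.items()}
        ).fillna(0)
        read_counts.columns = pd.MultiIndex.from_tuples(read_counts.columns)
    otus = sorted(set(specimen_counts) | set(read_counts.index))
    recs = []
    for otu in otus:
        r = {
            (end, rep): float(read_counts.loc[otu, (end, rep)])
            if otu in read_counts.index and (end, rep) in read_counts.columns
            else 0.0
            for end in ENDS
            for rep in REPLICATES
        }
        four = [r[("LCO", 1)], r[("LCO", 2)], r[("HCO", 1)], r[("HCO", 2)]]
        recs.append(
            {
                "sample_id": sample_id,
                "otu_id": otu,
                "specimens": int(specimen_counts.get(otu, 0)),
                "reads_lco_1": four[0],
                "reads_lco_2": four[1],
                "reads_hco_1": four[2],
                "reads_hco_2": four[3],
                "mean_reads": mean_reads(four),
            }
        )
    return add_proportions(pd.DataFrame(recs))


def add_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Add per-sample percentage columns for every abundance basis present.

    pct_specimens from ``specimens``, pct_reads from ``mean_reads`` and,
    when present, pct_corrected_reads from ``corrected_reads``. Sample
    totals of zero leave the percentage column as NaN for that sample.
    """
    table = table.copy()
    for src, dst in [
        ("specimens", "pct_specimens"),
        ("mean_reads", "pct_reads"),
        ("corrected_reads", "pct_corrected_reads"),
    ]:
        if src in table.columns:
            totals = table.groupby("sample_id")[src].transform("sum")
            with np.errstate(invalid="ignore", divide="ignore"):
                table[dst] = np.where(
                    totals > 0, 100.0 * table[src] / totals, np.nan
                )
    return table


def proportions(table: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    """Percentage columns for one sample (convenience view)."""
    sub = table.loc[table["sample_id"] == sample_id]
    if sub.empty:
        raise KeyError(sample_id)
    for basis in ("specimens", "mean_reads"):
        if basis in sub.columns and sub[basis].sum() <= 0:
            raise ValueError(f"sample {sample_id}: zero total on basis {basis!r}")
    cols = [c for c in sub.columns if c.startswith("pct_") or c in ("otu_id",)]
    return sub[cols].set_index("otu_id")
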