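"""Canonical k-mer counting and alignment-free shared-k-mer phylogeny.

Each sample is reduced to a table of canonical k-mers (lexicographic minimum
of a window and its reverse complement, so counting is strand-agnostic).
The evolutionary distance between two samples is derived from the proportion
of distinct k-mers they share,

    p = |K_a ∩ K_b| / min(|K_a|, |K_b|),      d = -ln(p) / k,

the alignment- and assembly-free (AAF) convention.  Trees are built from the
distance matrix by neighbor joining; column-bootstrap support and a
k-length congruence comparison are provided on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .records import PlastomeRecord, revcomp

logger = logging.getLogger(__name__)

DEFAULT_K = 31


# ---------------------------------------------------------------------------
# Counting

@dataclass
class KmerTable:
    sample_id: str
    k: int
    counts: dict[str, int]

    @property
    def n_kmers_total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_kmers_distinct(self) -> int:
        return len(self.counts)


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def count_kmers(record: PlastomeRecord, k: int = DEFAULT_K) -> KmerTable:
    """Count canonical k-mers over a record.

    Windows slide over the sequence, wrapping across the origin when the
    record is circular (a circular length-L sequence therefore yields exactly
    L windows, a linear one L - k + 1).  Windows containing N are skipped.
    """
    seq = record.sequence
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(seq):
        raise ValueError(f"k={k} exceeds sequence length {len(seq)} ({record.id})")
    if record.circular:
        seq = seq + seq[: k - 1]
    counts: dict[str, int] = {}
    has_n = "N" in seq
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if has_n and "N" in window:
            continue
        can = canonical(window)
        counts[can] = counts.get(can, 0) + 1
    return KmerTable(sample_id=record.id, k=k, counts=counts)


@dataclass
class FrequencyMatrix:
    """Samples x k-mers count matrix over the union of observed k-mers."""

    samples: list[str]
    kmers: list[str]
    counts: np.ndarray  # shape (n_samples, n_kmers), int

    @classmethod
    def from_tables(cls, tables: Sequence[KmerTable]) -> "FrequencyMatrix":
        ks = {t.k for t in tables}
        if len(ks) != 1:
            raise ValueError(f"mixed k values: {sorted(ks)}")
        union = sorted(set().union(*(t.counts.keys() for t in tables)))
        index = {km: j for j, km in enumerate(union)}
        mat = np.zeros((len(tables), len(union)), dtype=np.int64)
        for i, t in enumerate(tables):
            for km, c in t.counts.items():
                mat[i, index[km]] = c
        return cls(samples=[t.sample_id for t in tables], kmers=union, counts=mat)

    @property
    def k(self) -> int:
        return len(self.kmers[0]) if self.kmers else 0


# ---------------------------------------------------------------------------
# Distances

def shared_proportion(a: KmerTable, b: KmerTable) -> float:
    """Proportion of shared distinct k-mers, denominator = smaller table."""
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} vs {b.k}")
    small, large = (a.counts, b.counts) if len(a.counts) <= len(b.counts) else (b.counts, a.counts)
    if not small:
        raise ValueError("empty k-mer table")
    shared = sum(1 for km in small if km in large)
    return shared / len(small)


def aaf_distance(a: KmerTable, b: KmerTable, cap: float | None = None) -> tuple[float, bool]:
    """AAF distance d = -ln(p)/k; returns (distance, capped_flag).

    With no shared k-mers the distance is undefined: an error unless ``cap``
    is given, in which case the cap value is returned flagged.
    """
    p = shared_proportion(a, b)
    if p == 0.0:
        if cap is None:
            raise ValueError(
                f"no shared k-mers between {a.sample_id} and {b.sample_id}; "
                "pass cap= to assign a capped distance"
            )
        return cap, True
    return -np.log(p) / a.k, False


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    capped: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def distance_matrix(tables: Sequence[KmerTable], cap: float | None = None) -> DistanceMatrix:
    if len(tables) < 2:
        raise ValueError("need at least 2 samples")
    n = len(tables)
    mat = np.zeros((n, n))
    any_cap = False
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d, flagged = aaf_distance(tables[i], tables[j], cap=cap)
            except ValueError as exc:
                raise ValueError(
                    f"pair ({tables[i].sample_id}, {tables[j].sample_id}): {exc}"
                ) from exc
            mat[i, j] = mat[j, i] = d
            any_cap |= flagged
    return DistanceMatrix(labels=[t.sample_id for t in tables], values=mat, capped=any_cap)


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining on a distance matrix.

    Ties in the Q-criterion are broken by the lexicographically smallest
    (label_i, label_j) pair; negative branch lengths are clamped to zero
    with a log notice.  Returns an unrooted dendropy tree.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    taxa = dendropy.TaxonNamespace(dm.labels)
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lab)
        nodes.append(node)
    # sort key per active node: label of its lexicographically smallest leaf
    keys = list(dm.labels)
    d = dm.values.copy()

    def clamp(x: float, where: str) -> float:
        if x < 0:
            logger.info("clamping negative branch length %.4g at %s", x, where)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li = clamp(li, keys[i])
        lj = clamp(lj, keys[j])
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_row[keep]
        d = d2
        nodes = [nodes[x] for x in keep] + [parent]
        keys = [keys[x] for x in keep] + [min(keys[i], keys[j])]

    # terminal 3-node star: three-point formulas
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    root = dendropy.Node()
    lens = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, length in zip(nodes, lens):
        root.add_child(node)
        node.edge.length = clamp(length, "terminal star")

    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap support

def _splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree as leaf-label sets
    (each split keyed by the side not containing the alphabetically first leaf)."""
    leaves = sorted(t.label for t in tree.taxon_namespace)
    anchor = leaves[0]
    out: set[frozenset[str]] = set()
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        labs = {lf.taxon.label for lf in node.leaf_iter()}
        if 1 < len(labs) < len(leaves) - 1:
            side = labs if anchor not in labs else set(leaves) - labs
            out.add(frozenset(side))
    return out


def _distance_from_presence(presence: np.ndarray, labels: list[str], k: int,
                            cap: float = 5.0) -> DistanceMatrix:
    n = presence.shape[0]
    mat = np.zeros((n, n))
    totals = presence.sum(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(totals[i], totals[j])
            shared = int(np.minimum(presence[i], presence[j]).sum())
            p = shared / denom if denom else 0.0
            mat[i, j] = mat[j, i] = cap if p == 0 else -np.log(p) / k
    return DistanceMatrix(labels=labels, values=mat)


def bootstrap_support(freq: FrequencyMatrix, n_reps: int = 100,
                      seed: int = 0) -> dict[frozenset[str], float]:
    """Column-bootstrap split support for the NJ tree of a frequency matrix.

    Resamples k-mer columns with replacement, recomputes presence/absence ->
    distance -> NJ per replicate, and reports for each non-trivial split of
    the original tree the percentage of replicates containing it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    presence = (freq.counts > 0).astype(np.int64)
    k = freq.k
    base_tree = nj_tree(_distance_from_presence(presence, freq.samples, k))
    base_splits = _splits(base_tree)
    hits = {s: 0 for s in base_splits}
    ncols = presence.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep = presence[:, cols]
        rep_tree = nj_tree(_distance_from_presence(rep, freq.samples, k))
        rep_splits = _splits(rep_tree)
        for s in base_splits:
            if s in rep_splits:
                hits[s] += 1
    return {s: 100.0 * h / n_reps for s, h in hits.items()}


# ---------------------------------------------------------------------------
# k-length congruence

def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted Robinson–Foulds distance between two unrooted trees."""
    s1, s2 = _splits(t1), _splits(t2)
    return len(s1 ^ s2)


def compare_k(records: Sequence[PlastomeRecord], ks: Iterable[int] = (25, 31, 35),
              cap: float | None = None) -> dict:
    """Build one NJ tree per k and summarise pairwise topological congruence."""
    ks = list(ks)
    min_len = min(len(r) for r in records)
    for k in ks:
        if k > min_len:
            raise ValueError(f"k={k} exceeds shortest sequence ({min_len})")
    trees: dict[int, dendropy.Tree] = {}
    dms: dict[int, DistanceMatrix] = {}
    for k in ks:
        tables = [count_kmers(r, k) for r in records]
        dms[k] = distance_matrix(tables, cap=cap)
        trees[k] = nj_tree(dms[k])
    pairs = []
    for a in range(len(ks)):
        for b in range(a + 1, len(ks)):
            pairs.append({"k1": ks[a], "k2": ks[b],
                          "rf": rf_distance(trees[ks[a]], trees[ks[b]])})
    return {"ks": ks, "trees": trees, "distance_matrices": dms, "congruence": pairs}


__all__ = [
    "DEFAULT_K", "KmerTable", "FrequencyMatrix", "DistanceMatrix",
    "canonical", "count_kmers", "shared_proportion", "aaf_distance",
    "distance_matrix", "nj_tree", "bootstrap_support", "rf_distance",
    "compare_k",
]
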