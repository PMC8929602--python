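"""Hypervariable (H-disp) region discovery by k-mer frequency dispersion.

Each canonical k-mer is scored by the sample standard deviation (n-1
denominator) of its count vector across samples; a k-mer absent from a
sample counts 0 there, so presence/absence and copy-number differences both
contribute.  The highest-dispersion k-mers are selected, exactly mapped to a
reference plastome (both strands, wrapping across the origin when circular),
and overlapping hits are merged into contiguous H-disp regions.  Each region
is re-scanned against the reference so every exact copy is reported (the
diagnostic plastome repeats occur twice, once per inverted repeat), and
regions are labelled with their gene or intergenic context.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kmer import FrequencyMatrix
from .records import Feature, PlastomeRecord, revcomp


def majority_consensus(records: Sequence[PlastomeRecord],
                       id: str = "consensus") -> PlastomeRecord:
    """Majority-rule consensus over equal-length samples (ties: first sample).

    Mapping high-dispersion k-mers against a consensus rather than a single
    sample keeps ancestral k-mers mappable even where that sample is itself
    mutated; features are inherited from the first record.
    """
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError("consensus requires equal-length sequences")
    arrs = np.stack([np.frombuffer(r.sequence.encode(), dtype=np.uint8)
                     for r in records])
    out = arrs[0].copy()
    varying = np.nonzero((arrs != arrs[0]).any(axis=0))[0]
    for pos in varying:
        col = arrs[:, pos]
        counts = Counter(col.tolist())
        top = counts.most_common()
        best_n = top[0][1]
        if counts[int(arrs[0, pos])] < best_n:
            out[pos] = top[0][0]
    return PlastomeRecord(id=id, sequence=out.tobytes().decode(),
                          circular=records[0].circular,
                          features=list(records[0].features))


@dataclass
class DispersionRanking:
    """Per-k-mer dispersion scores, sorted descending (ties: lexicographic)."""

    k: int
    kmers: list[str]
    sd: np.ndarray
    counts: np.ndarray  # samples x kmers, aligned with kmers
    samples: list[str]

    def top(self, n: int) -> list[str]:
        return self.kmers[:n]


def dispersion_scores(freq: FrequencyMatrix, normalize: bool = False) -> DispersionRanking:
    """Score every k-mer by the across-sample standard deviation of its counts.

    ``normalize=True`` divides each sample's counts by its total k-mer count
    first (useful when genome sizes differ appreciably).
    """
    if len(freq.samples) < 2:
        raise ValueError("dispersion needs at least 2 samples")
    mat = freq.counts.astype(float)
    if normalize:
        totals = mat.sum(axis=1, keepdims=True)
        mat = mat / totals
    sd = np.std(mat, axis=0, ddof=1)
    order = sorted(range(len(freq.kmers)), key=lambda j: (-sd[j], freq.kmers[j]))
    return DispersionRanking(
        k=freq.k,
        kmers=[freq.kmers[j] for j in order],
        sd=sd[order],
        counts=freq.counts[:, order],
        samples=list(freq.samples),
    )


def select_high_dispersion(ranking: DispersionRanking, strategy: str = "top_q:0.01"
                           ) -> list[str]:
    """Select the highest-dispersion k-mers.

    Strategies: ``top_n:N`` (N largest), ``min_sd:t`` (sd > t strictly),
    ``top_q:q`` (top quantile q of the k-mers with sd > 0).
    """
    kind, _, arg = strategy.partition(":")
    if kind == "top_n":
        n = int(arg)
        return ranking.top(n)
    if kind == "min_sd":
        t = float(arg)
        return [km for km, s in zip(ranking.kmers, ranking.sd) if s > t]
    if kind == "top_q":
        q = float(arg)
        n_pos = int(np.sum(ranking.sd > 0))
        n = math.ceil(q * n_pos)
        return ranking.top(min(n, n_pos))
    raise ValueError(f"unknown selection strategy {strategy!r}")


def progressive_selection(ranking: DispersionRanking, start_n: int | None = None,
                          min_n: int = 10) -> list[list[str]]:
    """Nested subsets under a halving schedule, largest first — the
    progressive reduction of the k-mer set by dispersion contribution."""
    n_pos = int(np.sum(ranking.sd > 0))
    n = n_pos if start_n is None else min(start_n, n_pos)
    subsets = []
    while n >= min_n:
        subsets.append(ranking.top(n))
        n //= 2
    return subsets


# ---------------------------------------------------------------------------
# Mapping and merging

@dataclass(frozen=True)
class KmerHit:
    kmer: str
    position: int
    strand: str  # '+' if the k-mer matches forward, '-' if its revcomp does


def _position_index(reference: PlastomeRecord, k: int) -> dict[str, list[tuple[int, str]]]:
    seq = reference.sequence
    L = len(seq)
    if reference.circular:
        seq = seq + seq[: k - 1]
    index: dict[str, list[tuple[int, str]]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append((i % L, "+"))
    return index


def map_kmers_to_reference(kmers: Sequence[str], reference: PlastomeRecord
                           ) -> tuple[list[KmerHit], list[str]]:
    """Exact-match every k-mer (and its reverse complement) to the reference.

    All occurrences are reported; k-mers with no match are returned in the
    second element of the tuple.
    """
    if not kmers:
        return [], []
    k = len(kmers[0])
    if len(reference.sequence) < k:
        raise ValueError("reference shorter than k")
    index = _position_index(reference, k)
    hits: list[KmerHit] = []
    unmapped: list[str] = []
    for km in kmers:
        found = False
        for pos, _ in index.get(km, []):
            hits.append(KmerHit(kmer=km, position=pos, strand="+"))
            found = True
        rc = revcomp(km)
        if rc != km:
            for pos, _ in index.get(rc, []):
                hits.append(KmerHit(kmer=km, position=pos, strand="-"))
                found = True
        if not found:
            unmapped.append(km)
    hits.sort(key=lambda h: (h.position, h.strand, h.kmer))
    return hits, unmapped


@dataclass
class HDispRegion:
    reference_id: str
    start: int
    end: int
    sequence: str
    copies: list[tuple[int, str]]  # (position, strand) of every exact occurrence
    context_label: str = "unannotated"
    contributing_kmers: int = 0
    mean_sd: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


def _find_all_occurrences(pattern: str, reference: PlastomeRecord) -> list[tuple[int, str]]:
    seq = reference.sequence
    L = len(seq)
    text = seq + seq[: len(pattern) - 1] if reference.circular else seq
    out = []
    for probe, strand in ((pattern, "+"), (revcomp(pattern), "-")):
        if strand == "-" and probe == pattern:
            continue
        i = text.find(probe)
        while i != -1:
            out.append((i % L, strand))
            i = text.find(probe, i + 1)
    return sorted(set(out))


def merge_hits(hits: Sequence[KmerHit], reference: PlastomeRecord, k: int,
               max_gap: int = 0,
               sd_by_kmer: dict[str, float] | None = None) -> list[HDispRegion]:
    """Merge hit footprints [pos, pos+k) that overlap or are separated by at
    most ``max_gap`` into maximal H-disp regions.

    Each merged region's sequence is re-scanned against the reference so the
    reported copies cover every exact occurrence on either strand.
    """
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: h.position)
    clusters: list[list[KmerHit]] = [[hits[0]]]
    cur_end = hits[0].position + k
    for h in hits[1:]:
        if h.position <= cur_end + max_gap:
            clusters[-1].append(h)
            cur_end = max(cur_end, h.position + k)
        else:
            clusters.append([h])
            cur_end = h.position + k
    regions = []
    seen_seqs: set[str] = set()
    for cluster in clusters:
        start = cluster[0].position
        end = max(h.position + k for h in cluster)
        text = reference.sequence
        if end <= len(text):
            region_seq = text[start:end]
        else:  # wraps the origin of a circular reference
            region_seq = text[start:] + text[: end - len(text)]
        canon = min(region_seq, revcomp(region_seq))
        if canon in seen_seqs:
            continue  # same repeat already reported from its other copy
        seen_seqs.add(canon)
        copies = _find_all_occurrences(region_seq, reference)
        kmers = {h.kmer for h in cluster}
        mean_sd = (float(np.mean([sd_by_kmer[km] for km in kmers]))
                   if sd_by_kmer else 0.0)
        regions.append(HDispRegion(
            reference_id=reference.id, start=start, end=end, sequence=region_seq,
            copies=copies, contributing_kmers=len(kmers), mean_sd=mean_sd,
        ))
    return regions


# ---------------------------------------------------------------------------
# Annotation context

def _annotatable(features: Sequence[Feature]) -> list[Feature]:
    return sorted((f for f in features if f.type in ("gene", "tRNA", "rRNA")),
                  key=lambda f: f.start)


def _context_for_interval(start: int, end: int, feats: list[Feature]) -> str:
    inside = [f.name for f in feats if f.start <= start and end <= f.end]
    if inside:
        return "/".join(inside)
    overlapping = [f.name for f in feats if f.start < end and start < f.end]
    if overlapping:
        return "/".join(overlapping)
    left = [f for f in feats if f.end <= start]
    right = [f for f in feats if f.start >= end]
    lname = left[-1].name if left else (feats[-1].name if feats else "?")
    rname = right[0].name if right else (feats[0].name if feats else "?")
    return f"{lname}-{rname} intergenic"


def annotate_regions(regions: Sequence[HDispRegion],
                     features: Sequence[Feature]) -> list[HDispRegion]:
    """Attach a gene / intergenic context label to each region.

    A region inside a feature gets the feature name; between two features,
    "A-B intergenic"; spanning a boundary, the overlapping names joined.
    Without annotation every label is "unannotated".
    """
    feats = _annotatable(features)
    for region in regions:
        region.context_label = (
            _context_for_interval(region.start, region.end, feats)
            if feats else "unannotated"
        )
    return list(regions)


def rank_features_by_variability(ranking: DispersionRanking,
                                 reference: PlastomeRecord,
                                 selected: Sequence[str] | None = None
                                 ) -> list[dict]:
    """Per-feature variability: sum of sd over selected k-mers whose reference
    hit falls inside the feature, with the contributing k-mer count."""
    feats = _annotatable(reference.features)
    if not feats:
        return []
    kmers = list(selected) if selected is not None else list(ranking.kmers)
    sd_map = dict(zip(ranking.kmers, ranking.sd))
    hits, _ = map_kmers_to_reference(kmers, reference)
    totals: dict[str, float] = {}
    counts: dict[str, int] = {}
    for h in hits:
        for f in feats:
            if f.start <= h.position and h.position + ranking.k <= f.end:
                totals[f.name] = totals.get(f.name, 0.0) + sd_map.get(h.kmer, 0.0)
                counts[f.name] = counts.get(f.name, 0) + 1
    rows = [{"feature": name, "sum_sd": total, "n_kmers": counts[name]}
            for name, total in totals.items()]
    rows.sort(key=lambda r: (-r["sum_sd"], r["feature"]))
    return rows


def call_hdisp_regions(freq: FrequencyMatrix, reference: PlastomeRecord,
                       strategy: str = "top_q:0.01", max_gap: int = 0,
                       normalize: bool = False) -> tuple[list[HDispRegion], list[str]]:
    """End-to-end H-disp calling: score, select, map, merge, annotate."""
    ranking = dispersion_scores(freq, normalize=normalize)
    selected = select_high_dispersion(ranking, strategy)
    hits, unmapped = map_kmers_to_reference(selected, reference)
    sd_map = dict(zip(ranking.kmers, ranking.sd))
    regions = merge_hits(hits, reference, ranking.k, max_gap=max_gap, sd_by_kmer=sd_map)
    annotate_regions(regions, reference.features)
    regions.sort(key=lambda r: (r.start, r.end))
    return regions, unmapped


__all__ = [
    "DispersionRanking", "KmerHit", "HDispRegion",
    "dispersion_scores", "select_high_dispersion", "progressive_selection",
    "map_kmers_to_reference", "merge_hits", "annotate_regions",
    "rank_features_by_variability", "call_hdisp_regions",
]
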