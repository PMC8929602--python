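"""Simple sequence repeat (SSR) detection and cross-sample comparison.

Detects maximal perfect tandem runs of 2-6 bp motifs longer than 20 bp
(strict), reporting each run once under its smallest period, with the motif
in canonical form (lexicographic minimum over rotations of the motif and of
its reverse complement).  Loci are compared between samples by matching
identical flanking sequence; matched loci of unequal length are
length-polymorphic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .records import PlastomeRecord, revcomp


@dataclass(frozen=True)
class SSRRecord:
    reference_id: str
    start: int
    end: int
    motif: str       # canonical form
    raw_motif: str   # motif as it appears at the locus start
    copy_number: float

    @property
    def length(self) -> int:
        return self.end - self.start


def smallest_period(s: str) -> int:
    """Smallest period of a string via the KMP failure function."""
    n = len(s)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    p = n - fail[-1]
    return p


def canonical_motif(motif: str) -> str:
    """Lexicographic minimum over all rotations of the motif and of its
    reverse complement.  Homopolymer motifs (period 1) are rejected."""
    if not 2 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 2-6, got {motif!r}")
    if smallest_period(motif) == 1:
        raise ValueError(f"homopolymer motif {motif!r} excluded")
    rc = revcomp(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def find_ssrs(record: PlastomeRecord, motif_sizes: Sequence[int] = (2, 3, 4, 5, 6),
              min_len: int = 21) -> list[SSRRecord]:
    """Maximal perfect tandem runs of any 2-6 bp motif, length >= min_len.

    The default min_len=21 encodes the strict "more than 20 bp" rule.  Runs
    are reported once, under their smallest period; nested reports of the
    same run with a multiple period are suppressed.
    """
    seq = record.sequence
    n = len(seq)
    out: list[SSRRecord] = []
    for p in sorted(motif_sizes):
        i = 0
        while i + p <= n:
            # maximal run with period p starting at i
            j = i + p
            while j < n and seq[j] == seq[j - p]:
                j += 1
            run_len = j - i
            if run_len >= min_len and run_len >= 2 * p:
                motif = seq[i : i + p]
                # p must be the run's smallest period (nested-report rule);
                # the motif itself may have a smaller period (e.g. ACGTAC)
                if "N" not in motif and p == smallest_period(seq[i:j]):
                    out.append(SSRRecord(
                        reference_id=record.id, start=i, end=j,
                        motif=canonical_motif(motif), raw_motif=motif,
                        copy_number=round(run_len / p, 2),
                    ))
            i = j - p + 1 if run_len >= 2 * p else i + 1
    out.sort(key=lambda r: (r.start, r.end))
    # suppress intervals fully contained in another reported interval
    kept: list[SSRRecord] = []
    for r in out:
        if any(o.start <= r.start and r.end <= o.end and o is not r for o in out):
            continue
        kept.append(r)
    return kept


def find_ssrs_bruteforce(record: PlastomeRecord,
                         motif_sizes: Sequence[int] = (2, 3, 4, 5, 6),
                         min_len: int = 21) -> list[tuple[int, int, int]]:
    """Independent O(L * periods) oracle: (start, end, period) of every
    maximal run, smallest-period convention.  Test use only."""
    seq = record.sequence
    n = len(seq)
    found = set()
    for p in motif_sizes:
        for i in range(n - p):
            # extend maximal run at i (only record left-maximal starts)
            if i >= p and seq[i - 1] == seq[i + p - 1]:
                continue
            j = i + p
            while j < n and seq[j] == seq[j - p]:
                j += 1
            run_len = j - i
            if run_len >= min_len and run_len >= 2 * p and smallest_period(seq[i:j]) == p:
                found.add((i, j, p))
    # drop contained intervals
    out = []
    for iv in sorted(found):
        if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv for o in found):
            out.append(iv)
    return out


# ---------------------------------------------------------------------------
# Cross-sample comparison

@dataclass
class SSRComparison:
    shared: list[tuple[SSRRecord, SSRRecord]]
    polymorphic: list[tuple[SSRRecord, SSRRecord]]
    private_a: list[SSRRecord]
    private_b: list[SSRRecord]

    @property
    def n_polymorphic(self) -> int:
        return len(self.polymorphic)


def _flank_key(r: SSRRecord, seq: str, flank_len: int) -> tuple[str, str] | None:
    if r.start < flank_len or r.end + flank_len > len(seq):
        return None
    return seq[r.start - flank_len : r.start], seq[r.end : r.end + flank_len]


def compare_ssr_sets(a: Sequence[SSRRecord], b: Sequence[SSRRecord],
                     seq_a: str, seq_b: str, flank_len: int = 20) -> SSRComparison:
    """Match loci between two samples by identical flanking sequence.

    Loci with identical flank_len bp on both sides are the same locus:
    equal lengths -> shared, different -> length-polymorphic; unmatched loci
    are private to their sample.
    """
    keys_a = {}
    for r in a:
        key = _flank_key(r, seq_a, flank_len)
        if key is not None:
            keys_a[key] = r
    shared, polymorphic = [], []
    matched_a = set()
    private_b = []
    for r in b:
        key = _flank_key(r, seq_b, flank_len)
        ra = keys_a.get(key) if key is not None else None
        if ra is None:
            private_b.append(r)
            continue
        matched_a.add(id(ra))
        if ra.length == r.length:
            shared.append((ra, r))
        else:
            polymorphic.append((ra, r))
    private_a = [r for r in a if id(r) not in matched_a]
    return SSRComparison(shared=shared, polymorphic=polymorphic,
                         private_a=private_a, private_b=private_b)


__all__ = [
    "SSRRecord", "SSRComparison", "smallest_period", "canonical_motif",
    "find_ssrs", "find_ssrs_bruteforce", "compare_ssr_sets",
]
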