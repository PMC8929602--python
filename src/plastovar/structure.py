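"""Quadripartite plastome architecture: IR detection, canonical orientation,
per-region GC and junction context.

A plastome is modelled as a circle tiled by LSC, IRa, SSC and IRb, where one
IR is the (near-)exact reverse complement of the other.  Detection seeds on
exact 25-mers shared between the sequence and its reverse complement,
extends the best diagonals tolerating a bounded mismatch fraction, and keeps
the longest disjoint pair.  The longer inter-IR arc is the LSC.  Intervals
are 0-based half-open on the circle: ``end`` may exceed the sequence length,
meaning the interval wraps the origin (taken mod L); canonical orientation
removes all wrapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import Feature, PlastomeRecord, revcomp

logger = logging.getLogger(__name__)

SEED_LEN = 25


@dataclass
class QuadripartiteStructure:
    reference_id: str
    total_len: int
    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    n_mismatches_between_irs: int = 0
    degenerate_assignment: bool = False

    @property
    def ir_len(self) -> int:
        return self.ira[1] - self.ira[0]

    def regions(self) -> dict[str, tuple[int, int]]:
        return {"LSC": self.lsc, "IRa": self.ira, "SSC": self.ssc, "IRb": self.irb}

    def validate(self) -> None:
        """Assert the circular tiling and IR-length invariants."""
        covered = np.zeros(self.total_len, dtype=np.int8)
        for start, end in self.regions().values():
            if not (0 <= start < self.total_len) or end <= start:
                raise ValueError(f"bad interval ({start}, {end})")
            idx = np.arange(start, end) % self.total_len
            covered[idx] += 1
        if not np.all(covered == 1):
            raise ValueError("regions do not tile the circle exactly once")
        if (self.ira[1] - self.ira[0]) != (self.irb[1] - self.irb[0]):
            raise ValueError("IR copies differ in length")
        if (self.lsc[1] - self.lsc[0]) < (self.ssc[1] - self.ssc[0]):
            raise ValueError("LSC shorter than SSC")


# ---------------------------------------------------------------------------
# Detection

def _seed_diagonals(seq: str, rc: str) -> dict[int, list[tuple[int, int]]]:
    """Exact SEED_LEN-mer matches between seq and its reverse complement,
    grouped by diagonal (pos_in_seq - pos_in_rc is constant along an IR)."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - SEED_LEN + 1):
        index.setdefault(seq[i : i + SEED_LEN], []).append(i)
    diagonals: dict[int, list[tuple[int, int]]] = {}
    for j in range(len(rc) - SEED_LEN + 1):
        for i in index.get(rc[j : j + SEED_LEN], ()):
            diagonals.setdefault(i - j, []).append((i, j))
    return diagonals


_MISMATCH_PENALTY = 6
_XDROP = 18


def _extend_dir(seq: str, rc: str, i: int, j: int, step: int,
                exact: bool) -> tuple[int, int]:
    """X-drop extension in one direction from (i, j) exclusive.

    Scores +1/match, -6/mismatch, stops once the score drops _XDROP below
    its maximum; returns (bases extended to the max-score prefix, mismatches
    within that prefix).  Only a mismatch later recouped by matches is kept,
    so on exact inverted repeats this reproduces the maximal exact run.
    ``exact`` stops at the first mismatch instead.
    """
    score = best = 0
    ext = best_ext = 0
    mm = best_mm = 0
    while True:
        ni, nj = i + step * (ext + 1), j + step * (ext + 1)
        if not (0 <= ni < len(seq) and 0 <= nj < len(rc)):
            break
        if seq[ni] == rc[nj]:
            score += 1
        else:
            if exact:
                break
            score -= _MISMATCH_PENALTY
            mm += 1
        ext += 1
        if score > best:
            best, best_ext, best_mm = score, ext, mm
        if score <= best - _XDROP:
            break
    return best_ext, best_mm


def _extend(seq: str, rc: str, i0: int, j0: int, seed_len: int,
            exact: bool = False) -> tuple[int, int, int, int]:
    """Extend an exact seed in both directions; returns (i_start, j_start,
    length, n_mismatches)."""
    right_ext, right_mm = _extend_dir(seq, rc, i0 + seed_len - 1,
                                      j0 + seed_len - 1, +1, exact)
    left_ext, left_mm = _extend_dir(seq, rc, i0, j0, -1, exact)
    i_lo, j_lo = i0 - left_ext, j0 - left_ext
    length = left_ext + seed_len + right_ext
    return i_lo, j_lo, length, left_mm + right_mm


def _best_ir_pair(seq: str, max_mismatch_frac: float
                  ) -> tuple[int, int, int, int] | None:
    """Longest disjoint inverted-repeat pair as (startA, startB, length, mm),
    with startA < startB on the forward strand."""
    L = len(seq)
    rc = revcomp(seq)
    diagonals = _seed_diagonals(seq, rc)
    if not diagonals:
        return None
    ranked = sorted(diagonals.items(), key=lambda kv: -len(kv[1]))[:10]
    best = None
    exact = max_mismatch_frac == 0.0
    for _diag, seeds in ranked:
        i0, j0 = seeds[len(seeds) // 2]  # central seed of the diagonal
        i_lo, j_lo, length, mm = _extend(seq, rc, i0, j0, SEED_LEN, exact=exact)
        if mm > max_mismatch_frac * length:
            continue  # more diverged than an IR pair is allowed to be
        # map the rc interval back to forward coordinates
        b_start, b_end = L - (j_lo + length), L - j_lo
        a_start, a_end = i_lo, i_lo + length
        if a_start > b_start:
            a_start, a_end, b_start, b_end = b_start, b_end, a_start, a_end
        if b_start < a_end:  # overlapping: palindrome self-match, not an IR pair
            continue
        if best is None or length > best[2]:
            best = (a_start, b_start, length, mm)
    return best


def detect_quadripartite(record: PlastomeRecord, min_ir_len: int = 1000,
                         max_mismatch_frac: float = 0.001) -> QuadripartiteStructure:
    """Locate the IR pair and derive the four-region structure.

    For circular records a half-length rotation is also scanned so an IR
    spanning the sequence origin is still found; intervals are reported on
    the input coordinate system (mod-L wrapping allowed).
    """
    if min_ir_len < 100:
        raise ValueError("min_ir_len must be >= 100")
    L = len(record.sequence)
    candidates = []
    pair = _best_ir_pair(record.sequence, max_mismatch_frac)
    if pair:
        candidates.append((pair, 0))
    if record.circular:
        shift = L // 2
        rotated = record.sequence[shift:] + record.sequence[:shift]
        pair = _best_ir_pair(rotated, max_mismatch_frac)
        if pair:
            candidates.append((pair, shift))
    if not candidates:
        raise ValueError(f"{record.id}: no quadripartite structure "
                         f"(no inverted repeat >= {min_ir_len} bp)")
    (a_start, b_start, length, mm), shift = max(candidates, key=lambda c: c[0][2])
    if length < min_ir_len:
        raise ValueError(f"{record.id}: no quadripartite structure "
                         f"(longest inverted repeat {length} bp < {min_ir_len})")
    a_start = (a_start + shift) % L
    b_start = (b_start + shift) % L
    if a_start > b_start:
        a_start, b_start = b_start, a_start

    ir1 = (a_start, a_start + length)
    ir2 = (b_start, b_start + length)
    arc1 = (ir1[1], ir2[0])                    # between IR1 end and IR2 start
    arc2 = (ir2[1], ir1[0] + L)                # wraps through the origin
    len1 = arc1[1] - arc1[0]
    len2 = arc2[1] - arc2[0]
    degenerate = len1 == len2
    if degenerate:
        gc1 = _gc(_circ_slice(record.sequence, *arc1))
        gc2 = _gc(_circ_slice(record.sequence, *arc2))
        lsc, ssc = (arc1, arc2) if gc1 <= gc2 else (arc2, arc1)
        logger.warning("%s: equal arcs, LSC assigned by lower GC", record.id)
    elif len1 > len2:
        lsc, ssc = arc1, arc2
    else:
        lsc, ssc = arc2, arc1
    # orient so order around the circle is LSC -> IRa -> SSC -> IRb
    ira = ir2 if lsc == arc1 else ir1
    irb = ir1 if lsc == arc1 else ir2
    struct = QuadripartiteStructure(
        reference_id=record.id, total_len=L,
        lsc=(lsc[0] % L, lsc[0] % L + (lsc[1] - lsc[0])),
        ira=(ira[0] % L, ira[0] % L + length),
        ssc=(ssc[0] % L, ssc[0] % L + (ssc[1] - ssc[0])),
        irb=(irb[0] % L, irb[0] % L + length),
        n_mismatches_between_irs=mm,
        degenerate_assignment=degenerate,
    )
    struct.validate()
    return struct


def _circ_slice(seq: str, start: int, end: int) -> str:
    L = len(seq)
    start %= L
    span = end - start if end > start else end + L - start
    if start + span <= L:
        return seq[start : start + span]
    return seq[start:] + seq[: start + span - L]


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


# ---------------------------------------------------------------------------
# Oracle (exact repeats only; used by the test suite and acceptance checks)

def brute_force_ir(seq: str) -> tuple[int, int, int] | None:
    """Exhaustive longest exact disjoint inverted-repeat pair, O(L^2).

    Returns (startA, startB, length) with startA < startB, or None.
    Implemented as longest common substring between the sequence and its
    reverse complement via per-diagonal run lengths.
    """
    L = len(seq)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    r = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    best = None
    for diag in range(-(L - 1), L):
        if diag >= 0:
            a = s[diag:]
            b = r[: L - diag]
            i_off, j_off = diag, 0
        else:
            a = s[: L + diag]
            b = r[-diag:]
            i_off, j_off = 0, -diag
        eq = a == b
        # maximal runs of True
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for run_start, run_end in zip(idx[::2], idx[1::2]):
            run_len = run_end - run_start
            i = i_off + run_start
            j = j_off + run_start
            # forward coords of the rc-side match
            b_start, b_end = L - (j + run_len), L - j
            a_start, a_end = i, i + run_len
            if a_start > b_start:
                a_start, a_end, b_start, b_end = b_start, b_end, a_start, a_end
            if b_start < a_end:
                continue  # self-overlapping palindrome, not a disjoint pair
            if best is None or run_len > best[2]:
                best = (a_start, b_start, run_len)
    return best


# ---------------------------------------------------------------------------
# Canonical orientation

def _remap_features(features: Sequence[Feature], L: int, shift: int,
                    flip: bool, rc_start: int = 0) -> list[Feature]:
    out = []
    for f in features:
        ivs = []
        for s, e in f.intervals:
            span = e - s
            if not flip:
                ns = (s - shift) % L
            else:
                ns = (L - e - rc_start) % L
            if ns + span <= L:
                ivs.append((ns, ns + span))
            else:  # crosses the new origin: split
                ivs.append((ns, L))
                ivs.append((0, ns + span - L))
        strand = f.strand if not flip else ("-" if f.strand == "+" else "+")
        out.append(Feature(name=f.name, type=f.type, strand=strand,
                           intervals=tuple(sorted(ivs))))
    return out


def canonical_orientation(record: PlastomeRecord,
                          structure: QuadripartiteStructure
                          ) -> tuple[PlastomeRecord, QuadripartiteStructure]:
    """Rotate (and possibly flip) so the order is LSC, IRa, SSC, IRb with the
    LSC starting at coordinate 0.

    Both strands give a valid region order on a circle; the strand whose
    canonical sequence is lexicographically smaller is chosen, which makes
    the operation idempotent and invariant to rotation and reverse
    complement of the input.
    """
    L = structure.total_len
    seq = record.sequence

    def rotation(seq_: str, start: int) -> str:
        return seq_[start:] + seq_[:start]

    fwd = rotation(seq, structure.lsc[0] % L)
    # on the flipped strand the LSC also leads, starting where it ended
    rc_seq = revcomp(seq)
    lsc_end = structure.lsc[1] % L
    rc_start = (L - lsc_end) % L
    rev = rotation(rc_seq, rc_start)
    use_fwd = fwd <= rev
    new_seq = fwd if use_fwd else rev

    lsc_len = structure.lsc[1] - structure.lsc[0]
    ssc_len = structure.ssc[1] - structure.ssc[0]
    ir_len = structure.ir_len
    new_struct = QuadripartiteStructure(
        reference_id=record.id, total_len=L,
        lsc=(0, lsc_len),
        ira=(lsc_len, lsc_len + ir_len),
        ssc=(lsc_len + ir_len, lsc_len + ir_len + ssc_len),
        irb=(lsc_len + ir_len + ssc_len, L),
        n_mismatches_between_irs=structure.n_mismatches_between_irs,
        degenerate_assignment=structure.degenerate_assignment,
    )
    new_struct.validate()

    feats = _remap_features(record.features, L, shift=structure.lsc[0] % L,
                            flip=not use_fwd, rc_start=rc_start)
    new_rec = PlastomeRecord(id=record.id, sequence=new_seq,
                             circular=record.circular, features=feats)
    return new_rec, new_struct


# ---------------------------------------------------------------------------
# GC and junctions

def region_gc(record: PlastomeRecord, structure: QuadripartiteStructure
              ) -> dict[str, float]:
    """GC fraction per region plus the whole genome."""
    out = {}
    for name, (start, end) in structure.regions().items():
        out[name] = _gc(_circ_slice(record.sequence, start, end))
    out["genome"] = _gc(record.sequence)
    return out


JUNCTION_NAMES = ("LSC/IRa", "IRa/SSC", "SSC/IRb", "IRb/LSC")


def junction_context(structure: QuadripartiteStructure,
                     features: Sequence[Feature]) -> dict[str, dict]:
    """For each of the four junctions, the feature spanning it (with bp into
    each side) or the nearest features on both sides with distances."""
    L = structure.total_len
    boundaries = {
        "LSC/IRa": structure.lsc[1] % L,
        "IRa/SSC": structure.ira[1] % L,
        "SSC/IRb": structure.ssc[1] % L,
        "IRb/LSC": structure.irb[1] % L,
    }
    feats = sorted((f for f in features if f.type in ("gene", "tRNA", "rRNA")),
                   key=lambda f: f.start)
    report = {}
    for name, pos in boundaries.items():
        spanning = [f for f in feats if f.start < pos < f.end]
        if spanning:
            f = spanning[0]
            report[name] = {
                "kind": "spanning", "feature": f.name, "strand": f.strand,
                "bp_left": pos - f.start, "bp_right": f.end - pos,
            }
            continue
        if not feats:
            report[name] = {"kind": "none", "feature": "unannotated"}
            continue
        lefts = [(min((pos - f.end) % L, L), f) for f in feats]
        rights = [((f.start - pos) % L, f) for f in feats]
        dl, fl = min(lefts, key=lambda t: t[0])
        dr, fr = min(rights, key=lambda t: t[0])
        report[name] = {
            "kind": "between", "left_feature": fl.name, "left_distance": dl,
            "right_feature": fr.name, "right_distance": dr,
        }
    return report


def _junction_signature(report: dict[str, dict]) -> tuple:
    sig = []
    for name in JUNCTION_NAMES:
        entry = report[name]
        if entry["kind"] == "spanning":
            sig.append((name, "span", entry["feature"]))
        elif entry["kind"] == "between":
            sig.append((name, "between", entry["left_feature"], entry["right_feature"]))
        else:
            sig.append((name, "none"))
    return tuple(sig)


def compare_junctions(samples: Sequence[tuple[QuadripartiteStructure, Sequence[Feature]]]
                      ) -> list[list[str]]:
    """Group samples whose four junction contexts are identical."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to compare junctions")
    groups: dict[tuple, list[str]] = {}
    for structure, features in samples:
        sig = _junction_signature(junction_context(structure, features))
        groups.setdefault(sig, []).append(structure.reference_id)
    return [sorted(v) for v in sorted(groups.values(), key=lambda g: g[0])]


__all__ = [
    "QuadripartiteStructure", "detect_quadripartite", "brute_force_ir",
    "canonical_orientation", "region_gc", "junction_context",
    "compare_junctions", "JUNCTION_NAMES", "SEED_LEN",
]
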