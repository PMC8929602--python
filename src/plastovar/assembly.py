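"""Two-step selection of plastid contigs from a whole-genome assembly.

Chloroplast DNA is over-represented in total plant DNA extracts, so plastid
contigs show elevated depth of coverage (DP).  Step 1 keeps contigs with
coverage at or above the overall DP median; step 2 keeps those whose best
local alignment against a plastid reference panel reaches a minimum percent
identity (default 85%) over a minimum alignment length.  Alignment identity
is computed with edlib infix alignment against each panel sequence and its
reverse complement, gated by an exact k-mer seed prefilter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from .records import Contig, PlastomeRecord, revcomp

SEED_LEN = 15


@dataclass
class SelectionResult:
    kept: list[str]
    dropped_low_coverage: list[str]
    dropped_low_identity: list[str]
    dp_median: float
    min_identity: float
    min_aln_len: int
    identities: dict[str, float] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)

    def validate(self, input_ids: Sequence[str]) -> None:
        parts = self.kept + self.dropped_low_coverage + self.dropped_low_identity
        if sorted(parts) != sorted(input_ids):
            raise ValueError("selection lists do not partition the input contigs")


def coverage_cutoff(contigs: Sequence[Contig]) -> tuple[list[Contig], float]:
    """Keep contigs with coverage >= the DP median (even n: mean of the
    central pair)."""
    if not contigs:
        raise ValueError("no contigs given")
    dp_median = float(np.median([c.coverage for c in contigs]))
    kept = [c for c in contigs if c.coverage >= dp_median]
    return kept, dp_median


def _panel_seeds(panel: Sequence[PlastomeRecord]) -> set[str]:
    seeds: set[str] = set()
    for rec in panel:
        for text in (rec.sequence, revcomp(rec.sequence)):
            for i in range(0, len(text) - SEED_LEN + 1):
                seeds.add(text[i : i + SEED_LEN])
    return seeds


def _best_identity(contig: Contig, panel: Sequence[PlastomeRecord]) -> float:
    """Best percent identity of the contig against any panel sequence, via
    infix (contig-global, reference-local) edit-distance alignment."""
    best = 0.0
    q = contig.sequence
    for rec in panel:
        base = rec.sequence
        if rec.circular:  # allow hits spanning the origin
            base = base + base[: min(len(q), len(base))]
        for text in (base, revcomp(base)):
            res = edlib.align(q, text, mode="HW", task="distance")
            dist = res["editDistance"]
            if dist < 0:
                continue
            ident = 100.0 * (len(q) - dist) / len(q)
            best = max(best, ident)
    return best


def identity_filter(contigs: Sequence[Contig], panel: Sequence[PlastomeRecord],
                    min_identity: float = 85.0, min_aln_len: int = 100
                    ) -> tuple[list[Contig], list[Contig], dict[str, float], dict[str, str]]:
    """Classify contigs by best alignment identity against the panel.

    Returns (kept, dropped, identities, drop_reasons).  Contigs shorter than
    the seed length or the minimum alignment length are dropped with a
    reason; contigs sharing no exact seed with the panel skip alignment.
    """
    if not panel:
        raise ValueError("empty reference panel")
    seeds = _panel_seeds(panel)
    kept, dropped = [], []
    identities: dict[str, float] = {}
    reasons: dict[str, str] = {}
    for c in contigs:
        if len(c.sequence) < SEED_LEN:
            dropped.append(c)
            reasons[c.id] = f"shorter than seed length {SEED_LEN}"
            continue
        if len(c.sequence) < min_aln_len:
            dropped.append(c)
            reasons[c.id] = f"shorter than min alignment length {min_aln_len}"
            continue
        has_seed = any(c.sequence[i : i + SEED_LEN] in seeds
                       for i in range(0, len(c.sequence) - SEED_LEN + 1, SEED_LEN))
        if not has_seed:
            dropped.append(c)
            identities[c.id] = 0.0
            reasons[c.id] = "no exact seed match against panel"
            continue
        ident = _best_identity(c, panel)
        identities[c.id] = round(ident, 2)
        if ident >= min_identity:
            kept.append(c)
        else:
            dropped.append(c)
            reasons[c.id] = f"identity {ident:.1f}% < {min_identity}%"
    return kept, dropped, identities, reasons


def select_plastid_contigs(contigs: Sequence[Contig],
                           panel: Sequence[PlastomeRecord],
                           min_identity: float = 85.0,
                           min_aln_len: int = 100) -> SelectionResult:
    """Full two-step selection: DP-median coverage cutoff, then panel
    identity filter, with an audit trail."""
    high_dp, dp_median = coverage_cutoff(contigs)
    high_ids = {c.id for c in high_dp}
    dropped_cov = [c.id for c in contigs if c.id not in high_ids]
    kept, dropped_ident, identities, reasons = identity_filter(
        high_dp, panel, min_identity=min_identity, min_aln_len=min_aln_len)
    result = SelectionResult(
        kept=[c.id for c in kept],
        dropped_low_coverage=dropped_cov,
        dropped_low_identity=[c.id for c in dropped_ident],
        dp_median=dp_median,
        min_identity=min_identity,
        min_aln_len=min_aln_len,
        identities=identities,
        reasons=reasons,
    )
    result.validate([c.id for c in contigs])
    return result


__all__ = ["SelectionResult", "coverage_cutoff", "identity_filter",
           "select_plastid_contigs", "SEED_LEN"]
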