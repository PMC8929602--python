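"""Core in-memory containers shared across the package.

All coordinates in the package are 0-based half-open intervals on the
linearized plastome orientation LSC -> IRa -> SSC -> IRb.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """A named annotation: one or more 0-based half-open intervals on a record.

    ``type`` is one of ``gene``, ``tRNA``, ``rRNA``, ``region`` or ``other``;
    multi-interval features (e.g. two-exon genes) keep their intervals sorted.
    """

    name: str
    type: str = "gene"
    strand: str = "+"
    intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.name}: strand must be + or -")
        for start, end in self.intervals:
            if start < 0 or end <= start:
                raise ValueError(
                    f"feature {self.name}: invalid interval ({start}, {end})"
                )
        if list(self.intervals) != sorted(self.intervals):
            object.__setattr__(self, "intervals", tuple(sorted(self.intervals)))

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    def span(self) -> tuple[int, int]:
        """Outermost interval covered by the feature."""
        return self.start, self.end


@dataclass
class PlastomeRecord:
    """A named (optionally circular) DNA sequence with optional annotation."""

    id: str
    sequence: str
    circular: bool = False
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id}: non-IUPAC characters {sorted(bad)} "
                "(only A/C/G/T/N supported)"
            )
        self.sequence = seq
        for feat in self.features:
            if feat.end > len(seq):
                raise ValueError(
                    f"feature {feat.name} extends beyond record {self.id} "
                    f"(length {len(seq)})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def copy_with(self, **changes) -> "PlastomeRecord":
        data = {
            "id": self.id,
            "sequence": self.sequence,
            "circular": self.circular,
            "features": list(self.features),
        }
        data.update(changes)
        return PlastomeRecord(**data)


@dataclass
class Contig:
    """An assembly contig with its depth of coverage (DP, in x)."""

    id: str
    sequence: str
    coverage: float

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError(f"contig {self.id}: negative coverage")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


__all__ = ["DNA_ALPHABET", "revcomp", "Feature", "PlastomeRecord", "Contig", "replace"]
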