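"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Bio.SeqIO; feature annotation is accepted either as a
GFF-like TSV dialect or as a GenBank-style feature table, and is converted
to the package's 0-based half-open convention on ingestion.  Trees are
written as Newick, distance matrices as square PHYLIP, reports as TSV.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import Contig, Feature, PlastomeRecord


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, circular: bool = False) -> list[PlastomeRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(
                PlastomeRecord(id=rec.id, sequence=str(rec.seq), circular=circular)
            )
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[PlastomeRecord | Contig], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_contigs_fasta(path: str | Path, coverage_tsv: str | Path | None = None) -> list[Contig]:
    """Read contigs, taking coverage from assembler-style ``_cov_<x>`` headers
    or from a two-column (id, coverage) TSV."""
    cov_map: dict[str, float] = {}
    if coverage_tsv is not None:
        for line in Path(coverage_tsv).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            cid, cov = line.split("\t")[:2]
            if cid == "id":
                continue
            cov_map[cid] = float(cov)
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in cov_map:
            cov = cov_map[rec.id]
        else:
            m = re.search(r"_cov_([0-9.]+)", rec.id)
            if m is None:
                raise FormatError(
                    f"contig {rec.id}: no coverage in header and no TSV entry"
                )
            cov = float(m.group(1))
        contigs.append(Contig(id=rec.id, sequence=str(rec.seq), coverage=cov))
    return contigs


# ---------------------------------------------------------------------------
# Feature annotation

_GENBANK_LOC = re.compile(r"(complement\()?(join\()?([0-9.,<>\s]+)\)*")


def _parse_genbank_location(loc: str) -> tuple[str, list[tuple[int, int]]]:
    """Parse a GenBank location string into strand + 0-based intervals."""
    strand = "-" if "complement" in loc else "+"
    body = re.sub(r"complement\(|join\(|order\(|\)|<|>", "", loc)
    intervals = []
    for part in body.split(","):
        part = part.strip()
        if not part:
            continue
        if ".." in part:
            a, b = part.split("..")
        else:
            a = b = part
        start, end = int(a), int(b)
        if start < 1 or end < start:
            raise FormatError(f"invalid GenBank interval {part!r}")
        intervals.append((start - 1, end))  # 1-based inclusive -> 0-based half-open
    return strand, intervals


def read_features(path: str | Path, seq_length: int | None = None) -> list[Feature]:
    """Read annotation from a GFF-like TSV or a GenBank feature table.

    The dialect is sniffed per file: lines starting with ``FEATURES`` or a
    5-column INSDC feature-table layout select the GenBank parser, otherwise
    tab-separated ``seqid type name strand start end`` (1-based inclusive,
    GFF convention) is assumed.  Multi-interval features are merged into one
    :class:`Feature` with ordered intervals.
    """
    text = Path(path).read_text()
    if "FEATURES" in text or re.search(r"^\s{5}\S+\s+(complement|join|\d+\.\.)", text, re.M):
        feats = _read_genbank_table(text)
    else:
        feats = _read_gff_tsv(text)
    if seq_length is not None:
        for f in feats:
            if f.end > seq_length:
                raise FormatError(
                    f"feature {f.name} interval beyond sequence length {seq_length}"
                )
    return feats


_KNOWN_TYPES = {"gene", "tRNA", "rRNA", "region"}


def _read_gff_tsv(text: str) -> list[Feature]:
    grouped: dict[str, dict] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 6:
            raise FormatError(f"bad TSV feature line: {line!r}")
        _seqid, ftype, name, strand, start, end = cols[:6]
        if name == "name" and ftype == "type":
            continue  # header
        start_i, end_i = int(start), int(end)
        if start_i < 1 or end_i < start_i:
            raise FormatError(f"feature {name}: invalid coordinates {start}..{end}")
        iv = (start_i - 1, end_i)
        ftype = ftype if ftype in _KNOWN_TYPES else "other"
        entry = grouped.setdefault(name, {"type": ftype, "strand": strand, "ivs": []})
        entry["ivs"].append(iv)
    return [
        Feature(name=n, type=e["type"], strand=e["strand"], intervals=tuple(sorted(e["ivs"])))
        for n, e in grouped.items()
    ]


def _read_genbank_table(text: str) -> list[Feature]:
    feats: list[Feature] = []
    current: tuple[str, str] | None = None  # (type, location-so-far)
    pending_name: str | None = None

    def flush() -> None:
        nonlocal current, pending_name
        if current is None:
            return
        ftype, loc = current
        strand, ivs = _parse_genbank_location(loc)
        name = pending_name or f"{ftype}_{ivs[0][0]}"
        feats.append(
            Feature(
                name=name,
                type=ftype if ftype in _KNOWN_TYPES else "other",
                strand=strand,
                intervals=tuple(sorted(ivs)),
            )
        )
        current, pending_name = None, None

    for line in text.splitlines():
        m = re.match(r"^\s{2,8}(\S+)\s+((?:complement|join|order|[0-9<>]).*)$", line)
        if m and not line.strip().startswith("/"):
            flush()
            current = (m.group(1), m.group(2).strip())
            continue
        stripped = line.strip()
        if current is not None and stripped.startswith("/"):
            gm = re.match(r'/(?:gene|label|product)="?([^"]+)"?', stripped)
            if gm and pending_name is None:
                pending_name = gm.group(1)
        elif current is not None and stripped and not stripped.startswith("/"):
            if re.fullmatch(r"[0-9.,<>()a-z]+", stripped):
                current = (current[0], current[1] + stripped)
    flush()
    return feats


def write_features_tsv(features: Sequence[Feature], seqid: str, path: str | Path) -> None:
    """Write features in the package's GFF-like TSV dialect (1-based inclusive)."""
    lines = ["seqid\ttype\tname\tstrand\tstart\tend"]
    for f in features:
        for start, end in f.intervals:
            lines.append(f"{seqid}\t{f.type}\t{f.name}\t{f.strand}\t{start + 1}\t{end}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tree / matrix / report writers

def write_newick(tree, path: str | Path) -> None:
    """Write a dendropy tree as Newick with branch lengths."""
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def write_phylip_dist(labels: Sequence[str], matrix, path: str | Path,
                      cap: float | None = None) -> None:
    """Write a square PHYLIP distance matrix.

    Non-finite entries raise unless ``cap`` is given, in which case they are
    replaced by the cap value.
    """
    n = len(labels)
    lines = [f"{n}"]
    for i, lab in enumerate(labels):
        row = []
        for j in range(n):
            v = float(matrix[i][j])
            if not math.isfinite(v):
                if cap is None:
                    raise ValueError(
                        f"non-finite distance at ({labels[i]}, {labels[j]}); "
                        "pass cap= to write capped values"
                    )
                v = cap
            row.append(f"{v:.6f}")
        lines.append(f"{lab:<10s} " + " ".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_tsv_report(rows: Sequence[dict], path: str | Path,
                     columns: Sequence[str] | None = None) -> None:
    """Write a list of dict rows as TSV with a header line."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(str(row.get(c, "")) for c in columns))
    Path(path).write_text("\n".join(lines) + "\n")


__all__ = [
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_contigs_fasta",
    "read_features",
    "write_features_tsv",
    "write_newick",
    "write_phylip_dist",
    "write_tsv_report",
]
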