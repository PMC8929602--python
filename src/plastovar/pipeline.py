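"""End-to-end orchestration: simulate or load samples, then run structure,
k-mer distance/tree, H-disp, and SSR stages, writing a reproducible bundle.

All randomness flows from the single config seed; two runs with the same
inputs and seed produce byte-identical TSV bodies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .hdisp import call_hdisp_regions, dispersion_scores
from .io import read_fasta, write_fasta, write_newick, write_phylip_dist, write_tsv_report
from .kmer import FrequencyMatrix, count_kmers, distance_matrix, nj_tree
from .records import PlastomeRecord
from .repeats import find_ssrs
from .simulate import SimulationConfig, simulate_population, write_truth
from .structure import canonical_orientation, detect_quadripartite, region_gc

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "plastovar_out"
    seed: int = 0
    input_fasta: str | None = None      # if None, simulate
    simulation: SimulationConfig | None = None
    k: int = 31
    selection: str = "top_q:0.01"
    max_gap: int = 0
    reference: str | None = None        # sample id; default first sample
    min_ir_len: int = 1000
    ssr_min_len: int = 21
    distance_cap: float | None = 5.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = data.pop("simulation", None)
        cfg = cls(**data)
        if sim is not None:
            sim.setdefault("seed", cfg.seed)
            cfg.simulation = SimulationConfig(**{
                k: [tuple(x) if isinstance(x, list) else x for x in v]
                if isinstance(v, list) else v
                for k, v in sim.items()
            })
        return cfg


@dataclass
class Bundle:
    """Paths of the files a pipeline run produced."""

    outdir: Path
    files: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> Bundle:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    bundle = Bundle(outdir=outdir)

    # --- inputs
    if config.input_fasta is not None:
        path = Path(config.input_fasta)
        if not path.exists():
            raise FileNotFoundError(f"input_fasta: {path} does not exist")
        records = read_fasta(path, circular=True)
    else:
        sim = config.simulation or SimulationConfig(seed=config.seed)
        records, truth, _backbone = simulate_population(sim)
        write_fasta(records, outdir / "samples.fasta")
        write_truth(truth, outdir)
        bundle.files["samples"] = outdir / "samples.fasta"

    ref_id = config.reference or records[0].id
    try:
        reference = next(r for r in records if r.id == ref_id)
    except StopIteration:
        raise ValueError(f"reference {ref_id!r} not among sample ids") from None

    # --- structure stage
    try:
        rows = []
        gc_rows = []
        for rec in records:
            struct = detect_quadripartite(rec, min_ir_len=config.min_ir_len)
            canon, cstruct = canonical_orientation(rec, struct)
            gc = region_gc(canon, cstruct)
            rows.append({"sample": rec.id, **{
                f"{k.lower()}_{b}": v[i] for k, v in cstruct.regions().items()
                for i, b in enumerate(("start", "end"))
            }, "ir_mismatches": cstruct.n_mismatches_between_irs})
            gc_rows.append({"sample": rec.id,
                            **{k: round(v, 4) for k, v in gc.items()}})
        write_tsv_report(rows, outdir / "structure.tsv")
        write_tsv_report(gc_rows, outdir / "gc.tsv")
        bundle.files["structure"] = outdir / "structure.tsv"
        bundle.files["gc"] = outdir / "gc.tsv"
    except Exception as exc:
        raise RuntimeError(f"structure stage failed: {exc}") from exc

    # --- k-mer stage
    try:
        tables = [count_kmers(r, config.k) for r in records]
        dm = distance_matrix(tables, cap=config.distance_cap)
        write_phylip_dist(dm.labels, dm.values, outdir / "distances.phy",
                          cap=config.distance_cap)
        tree = nj_tree(dm)
        write_newick(tree, outdir / "tree.nwk")
        bundle.files["distances"] = outdir / "distances.phy"
        bundle.files["tree"] = outdir / "tree.nwk"
    except Exception as exc:
        raise RuntimeError(f"k-mer stage failed: {exc}") from exc

    # --- H-disp stage
    try:
        freq = FrequencyMatrix.from_tables(tables)
        regions, unmapped = call_hdisp_regions(
            freq, reference, strategy=config.selection, max_gap=config.max_gap)
        region_rows = [{
            "reference": r.reference_id, "start": r.start, "end": r.end,
            "length": r.length, "sequence": r.sequence, "n_copies": len(r.copies),
            "copies": ";".join(f"{p}{s}" for p, s in r.copies),
            "context": r.context_label, "contributing_kmers": r.contributing_kmers,
            "mean_sd": round(r.mean_sd, 4),
        } for r in regions]
        write_tsv_report(region_rows, outdir / "hdisp_regions.tsv", columns=[
            "reference", "start", "end", "length", "sequence", "n_copies",
            "copies", "context", "contributing_kmers", "mean_sd"])
        (outdir / "unmapped_kmers.txt").write_text("\n".join(unmapped) + "\n")
        bundle.files["hdisp"] = outdir / "hdisp_regions.tsv"
    except Exception as exc:
        raise RuntimeError(f"H-disp stage failed: {exc}") from exc

    # --- SSR stage
    try:
        ssr_rows = []
        for rec in records:
            for ssr in find_ssrs(rec, min_len=config.ssr_min_len):
                ssr_rows.append({
                    "sample": rec.id, "start": ssr.start, "end": ssr.end,
                    "length": ssr.length, "motif": ssr.motif,
                    "copy_number": ssr.copy_number,
                })
        write_tsv_report(ssr_rows, outdir / "ssrs.tsv", columns=[
            "sample", "start", "end", "length", "motif", "copy_number"])
        bundle.files["ssrs"] = outdir / "ssrs.tsv"
    except Exception as exc:
        raise RuntimeError(f"SSR stage failed: {exc}") from exc

    manifest = {
        "plastovar_version": __version__,
        "seed": config.seed,
        "k": config.k,
        "selection": config.selection,
        "max_gap": config.max_gap,
        "reference": ref_id,
        "min_ir_len": config.min_ir_len,
        "ssr_min_len": config.ssr_min_len,
        "n_samples": len(records),
        "files": {k: str(v.name) for k, v in bundle.files.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    bundle.files["manifest"] = outdir / "manifest.json"
    return bundle


def validate_outputs(bundle: Bundle) -> list[str]:
    """Schema / invariant / cross-file checks on a bundle.

    Returns a list of findings; empty means pass.
    """
    findings: list[str] = []
    outdir = bundle.outdir

    # distance matrix symmetric with zero diagonal
    dist_path = outdir / "distances.phy"
    labels = []
    if dist_path.exists():
        lines = dist_path.read_text().strip().splitlines()
        n = int(lines[0])
        mat = []
        for line in lines[1 : n + 1]:
            parts = line.split()
            labels.append(parts[0])
            mat.append([float(x) for x in parts[1:]])
        for i in range(n):
            if mat[i][i] != 0.0:
                findings.append(f"distance matrix: nonzero diagonal at {labels[i]}")
            for j in range(i + 1, n):
                if abs(mat[i][j] - mat[j][i]) > 1e-9:
                    findings.append(
                        f"distance matrix: asymmetry at ({labels[i]}, {labels[j]})")
    else:
        findings.append("missing distances.phy")

    # tree labels subset of sample ids
    tree_path = outdir / "tree.nwk"
    if tree_path.exists() and labels:
        import dendropy
        tree = dendropy.Tree.get(path=str(tree_path), schema="newick")
        tree_labels = {lf.taxon.label.replace(" ", "_") for lf in tree.leaf_node_iter()}
        unknown = tree_labels - {l.replace(" ", "_") for l in labels}
        if unknown:
            findings.append(f"tree labels not among samples: {sorted(unknown)}")
    elif not tree_path.exists():
        findings.append("missing tree.nwk")

    # structure tiling
    struct_path = outdir / "structure.tsv"
    if struct_path.exists():
        lines = struct_path.read_text().strip().splitlines()
        header = lines[0].split("\t")
        for line in lines[1:]:
            row = dict(zip(header, line.split("\t")))
            spans = [(int(row[f"{r}_start"]), int(row[f"{r}_end"]))
                     for r in ("lsc", "ira", "ssc", "irb")]
            total = sum(e - s for s, e in spans)
            ends = {e % total for _s, e in spans}
            starts = {s % total for s, _e in spans}
            if ends != starts:
                findings.append(f"structure: regions of {row['sample']} do not tile")
    else:
        findings.append("missing structure.tsv")

    # SSR perfection
    ssr_path = outdir / "ssrs.tsv"
    samples_path = outdir / "samples.fasta"
    if ssr_path.exists() and samples_path.exists():
        seqs = {r.id: r.sequence for r in read_fasta(samples_path)}
        lines = ssr_path.read_text().strip().splitlines()
        header = lines[0].split("\t")
        for line in lines[1:]:
            row = dict(zip(header, line.split("\t")))
            seq = seqs.get(row["sample"])
            if seq is None:
                findings.append(f"ssr: unknown sample {row['sample']}")
                continue
            s, e = int(row["start"]), int(row["end"])
            run = seq[s:e]
            p = len(run) // float(row["copy_number"]) if float(row["copy_number"]) else 0
            p = int(round(p))
            if p and any(run[i] != run[i - p] for i in range(p, len(run))):
                findings.append(f"ssr: imperfect run at {row['sample']}:{s}-{e}")
    return findings


__all__ = ["PipelineConfig", "Bundle", "run_pipeline", "validate_outputs"]
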