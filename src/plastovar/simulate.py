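"""Synthetic plastome populations with known ground truth.

Generates a circular quadripartite backbone (LSC + IRa + SSC + IRb, with IRb
the reverse complement of IRa), evolves a sample set along a guide tree under
a Jukes–Cantor-like substitution model with planted hypervariable windows,
plants length-polymorphic SSR loci, derives hybrid samples that copy a parent
plastome with a few private mutations, and simulates mixed plastid/nuclear
contig sets with distinct coverage distributions.  Every stochastic choice
flows from the config seed, so identical (config, seed) give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .io import write_fasta, write_tsv_report
from .records import Contig, Feature, PlastomeRecord, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B2I = {b: i for i, b in enumerate("ACGT")}

# Region labels on the linearized orientation; windows may be planted in any
# of the three mutable regions (IRb mirrors IRa).
MUTABLE_REGIONS = ("LSC", "SSC", "IRa")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_samples: int = 12
    guide_tree: str = "star"  # newick string or "star"
    lsc_len: int = 8700
    ir_len: int = 3000
    ssc_len: int = 1200
    background_rate: float = 0.005  # substitutions/site per unit branch length
    star_branch_length: float = 0.25
    # IR background substitution relative to single-copy regions; 0 models the
    # strong conservation of real plastid IRs (planted IRa windows still mutate)
    ir_rate_factor: float = 0.0
    # (region_label, length bp, rate multiplier)
    hypervariable_windows: list[tuple[str, int, float]] = field(default_factory=list)
    # (motif, base copy number, per-sample copy jitter)
    ssr_loci: list[tuple[str, int, int]] = field(default_factory=list)
    # (new_sample_id, parent_sample_id, n_private_mutations)
    hybrids: list[tuple[str, str, int]] = field(default_factory=list)
    gc_content: float = 0.37

    def __post_init__(self) -> None:
        if not (self.lsc_len > self.ssc_len > 0):
            raise ValueError("require lsc_len > ssc_len > 0")
        if self.ir_len <= 0:
            raise ValueError("ir_len must be positive")
        for label, length, mult in self.hypervariable_windows:
            if label not in MUTABLE_REGIONS:
                raise ValueError(f"window region {label!r} not in {MUTABLE_REGIONS}")
            if mult < 1:
                raise ValueError("rate_multiplier must be >= 1")
            if length > self.region_length(label):
                raise ValueError(
                    f"window of {length} bp does not fit in {label} "
                    f"({self.region_length(label)} bp)"
                )
        for _sid, _pid, n in self.hybrids:
            if n < 0:
                raise ValueError("n_private_mutations must be >= 0")

    @property
    def total_len(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len

    def region_length(self, label: str) -> int:
        return {"LSC": self.lsc_len, "IRa": self.ir_len,
                "SSC": self.ssc_len, "IRb": self.ir_len}[label]

    def region_interval(self, label: str) -> tuple[int, int]:
        lsc, ir, ssc = self.lsc_len, self.ir_len, self.ssc_len
        return {
            "LSC": (0, lsc),
            "IRa": (lsc, lsc + ir),
            "SSC": (lsc + ir, lsc + ir + ssc),
            "IRb": (lsc + ir + ssc, lsc + 2 * ir + ssc),
        }[label]


@dataclass
class SyntheticTruth:
    true_tree: dendropy.Tree | None
    planted_windows: list[tuple[int, int, float]]  # (start, end, multiplier) backbone coords
    ssr_truth: dict[str, list[tuple[int, str, int]]]  # sample -> (locus start on backbone, motif, copies)
    hybrid_parents: dict[str, str]


# ---------------------------------------------------------------------------
# Backbone

def _random_dna(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def _place_windows(rng: np.random.Generator, config: SimulationConfig
                   ) -> list[tuple[int, int, float]]:
    """Non-overlapping windows, each fully inside its host region."""
    placed: list[tuple[int, int, float]] = []
    for label, length, mult in config.hypervariable_windows:
        lo, hi = config.region_interval(label)
        for _attempt in range(1000):
            start = int(rng.integers(lo, hi - length + 1))
            iv = (start, start + length)
            if all(iv[1] <= s or iv[0] >= e for s, e, _ in placed):
                placed.append((iv[0], iv[1], mult))
                break
        else:
            raise ValueError(f"could not place window of {length} bp in {label}")
    return sorted(placed)


SSR_PAD = 24  # homopolymer pad after the longest possible array, > flank length


def _ssr_slot_len(motif: str, base_copies: int, jitter: int) -> int:
    return len(motif) * (base_copies + jitter) + SSR_PAD


def _pad_base(motif: str) -> str:
    """Homopolymer pad base differing from the motif's last character, so the
    tandem run terminates within one period and right flanks are shared."""
    for b in "ACGT":
        if b != motif[-1]:
            return b
    raise AssertionError("unreachable")


def _plant_ssrs(rng: np.random.Generator, seq: np.ndarray,
                config: SimulationConfig,
                windows: list[tuple[int, int, float]]) -> list[tuple[int, str, int]]:
    """Overwrite LSC stretches with perfect tandem arrays followed by a
    homopolymer pad; returns (slot start, motif, slot length).

    The pad keeps the bases after the array identical across samples no
    matter the per-sample copy number, so flank-based locus matching works.
    """
    loci = []
    lo, hi = config.region_interval("LSC")
    occupied: list[tuple[int, int]] = [(s, e) for s, e, _m in windows]
    for motif, base_copies, jitter in config.ssr_loci:
        slot = _ssr_slot_len(motif, base_copies, jitter)
        for _attempt in range(1000):
            start = int(rng.integers(lo, hi - slot))
            if all(start + slot + 25 <= s or start >= e + 25 for s, e in occupied):
                break
        else:
            raise ValueError(f"could not place SSR locus {motif}")
        occupied.append((start, start + slot))
        block = (motif * base_copies).ljust(slot, _pad_base(motif)).encode()
        seq[start : start + slot] = np.frombuffer(block, dtype=np.uint8)
        loci.append((start, motif, slot))
    return loci


_COMP = {65: 84, 67: 71, 71: 67, 84: 65}  # ord complements


def _junction_fixed_positions(config: SimulationConfig) -> list[int]:
    """The four bases adjacent to IR junctions, held fixed across samples so
    the quadripartite coordinates are exact ground truth."""
    lsc, ir, ssc = config.lsc_len, config.ir_len, config.ssc_len
    return [0, lsc - 1, lsc + ir, lsc + ir + ssc - 1]


def _break_junction_complementarity(seq: np.ndarray, config: SimulationConfig) -> None:
    """Ensure the bases flanking the IRs cannot extend the inverted repeat:
    a chance complementary pair at a junction would make the true maximal IR
    longer than the planted one."""
    lsc, ir, ssc = config.lsc_len, config.ir_len, config.ssc_len
    pairs = [(lsc - 1, 0), (lsc + ir, lsc + ir + ssc - 1)]
    for a, b in pairs:
        while seq[a] == _COMP[int(seq[b])]:
            seq[a] = BASES[(np.searchsorted(BASES, seq[a]) + 1) % 4]


def generate_backbone(config: SimulationConfig) -> tuple[PlastomeRecord, dict]:
    """Build the ancestral circular quadripartite plastome.

    Returns the record (with region and planted-window features) plus a
    layout dict holding window and SSR placements used by downstream steps.
    """
    rng = np.random.default_rng(config.seed)
    lsc = _random_dna(rng, config.lsc_len, config.gc_content)
    # IRs are GC-richer than single-copy regions in real plastomes
    ira = _random_dna(rng, config.ir_len, min(0.6, config.gc_content + 0.045))
    ssc = _random_dna(rng, config.ssc_len, config.gc_content)
    seq = np.concatenate([lsc, ira, ssc])
    _break_junction_complementarity(seq, config)
    windows = _place_windows(rng, config)
    ssr_slots = _plant_ssrs(rng, seq, config, windows)
    irb = np.frombuffer(
        revcomp(seq[config.lsc_len : config.lsc_len + config.ir_len]
                .tobytes().decode()).encode(),
        dtype=np.uint8,
    )
    full = np.concatenate([seq, irb])
    feats = [
        Feature(name=label, type="region",
                intervals=(config.region_interval(label),))
        for label in ("LSC", "IRa", "SSC", "IRb")
    ]
    feats += [
        Feature(name=f"window_{i}", type="other", intervals=((s, e),))
        for i, (s, e, _m) in enumerate(windows)
    ]
    record = PlastomeRecord(id="ancestor", sequence=full.tobytes().decode(),
                            circular=True, features=feats)
    return record, {"windows": windows, "ssr_slots": ssr_slots}


# ---------------------------------------------------------------------------
# Evolution along the guide tree

def _resolve_tree(config: SimulationConfig) -> dendropy.Tree:
    labels = [f"S{i + 1}" for i in range(config.n_samples)]
    if config.guide_tree == "star":
        taxa = dendropy.TaxonNamespace(labels)
        tree = dendropy.Tree(taxon_namespace=taxa)
        for lab in labels:
            node = dendropy.Node()
            node.taxon = taxa.get_taxon(lab)
            node.edge.length = config.star_branch_length
            tree.seed_node.add_child(node)
        return tree
    tree = dendropy.Tree.get(data=config.guide_tree, schema="newick")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) != config.n_samples:
        raise ValueError(
            f"guide tree has {len(leaves)} leaves, config says {config.n_samples}"
        )
    return tree


def _mutate(seq: np.ndarray, rng: np.random.Generator, p_site: np.ndarray) -> np.ndarray:
    """One branch of Jukes–Cantor-like evolution: substitute to one of the
    3 alternative bases wherever a uniform draw falls below the site rate."""
    hit = np.nonzero(rng.random(len(p_site)) < p_site)[0]
    if len(hit) == 0:
        return seq
    out = seq.copy()
    idx = np.searchsorted(BASES, out[hit])  # BASES is sorted (A<C<G<T)
    shift = rng.integers(1, 4, size=len(hit))
    out[hit] = BASES[(idx + shift) % 4]
    return out


def _mirror_ir(seq: np.ndarray, config: SimulationConfig) -> np.ndarray:
    a0, a1 = config.region_interval("IRa")
    b0, b1 = config.region_interval("IRb")
    ira = seq[a0:a1].tobytes().decode()
    out = seq.copy()
    out[b0:b1] = np.frombuffer(revcomp(ira).encode(), dtype=np.uint8)
    return out


def _ssr_jitter(seq: np.ndarray, rng: np.random.Generator,
                config: SimulationConfig, ssr_slots: list[tuple[int, str, int]]
                ) -> tuple[np.ndarray, list[tuple[int, str, int]]]:
    """Per-sample SSR copy-number jitter: rewrite each locus in place with
    base_copies + U{-jitter..jitter} copies, the homopolymer pad absorbing
    the slack so coordinates elsewhere are unchanged."""
    out = seq.copy()
    truth = []
    for (start, motif, slot), (m, base_copies, jitter) in zip(ssr_slots, config.ssr_loci):
        assert m == motif
        copies = base_copies + (int(rng.integers(-jitter, jitter + 1)) if jitter else 0)
        copies = max(copies, 1)
        block = (motif * copies).ljust(slot, _pad_base(motif)).encode()
        out[start : start + slot] = np.frombuffer(block, dtype=np.uint8)
        truth.append((start, motif, copies))
    return out, truth


def _protected_intervals(config: SimulationConfig,
                         ssr_slots: list[tuple[int, str, int]]) -> list[tuple[int, int]]:
    """SSR slots plus flanks, kept free of point mutations so copy number is
    the only signal at those loci."""
    return [(max(0, s - 25), s + slot + 5) for s, _m, slot in ssr_slots]


def evolve_population(backbone: PlastomeRecord, config: SimulationConfig,
                      layout: dict | None = None
                      ) -> tuple[list[PlastomeRecord], SyntheticTruth]:
    """Evolve samples from the backbone along the guide tree.

    Substitutions fall at ``background_rate`` per site per unit branch
    length, multiplied inside planted windows; IRa mutations are mirrored
    into IRb so the inverted-repeat identity is exact in every sample.
    Hybrids are then derived from their evolved parents.
    """
    if layout is None:
        layout = {"windows": [], "ssr_slots": []}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    tree = _resolve_tree(config)

    mut_end = config.region_interval("SSC")[1]  # LSC+IRa+SSC mutable, IRb mirrored
    p_site = np.full(mut_end, config.background_rate)
    a0, a1 = config.region_interval("IRa")
    p_site[a0:a1] *= config.ir_rate_factor
    for s, e, mult in layout["windows"]:
        p_site[s:e] = config.background_rate * mult
    for s, e in _protected_intervals(config, layout["ssr_slots"]):
        p_site[s:e] = 0.0
    p_site[_junction_fixed_positions(config)] = 0.0

    anc = np.frombuffer(backbone.sequence.encode(), dtype=np.uint8).copy()
    seqs: dict[str, np.ndarray] = {}

    def walk(node, state: np.ndarray) -> None:
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            child_state = _mutate(state, rng, np.minimum(p_site * bl, 0.75))
            if child.is_leaf():
                seqs[child.taxon.label] = child_state
            else:
                walk(child, child_state)

    walk(tree.seed_node, anc[:mut_end])

    records: list[PlastomeRecord] = []
    ssr_truth: dict[str, list[tuple[int, str, int]]] = {}
    for lab in sorted(seqs, key=lambda x: (len(x), x)):
        body, truth = _ssr_jitter(seqs[lab], rng, config, layout["ssr_slots"])
        full = np.concatenate([body, anc[mut_end:]])
        full = _mirror_ir(full, config)
        records.append(PlastomeRecord(id=lab, sequence=full.tobytes().decode(),
                                      circular=True, features=list(backbone.features)))
        ssr_truth[lab] = truth

    hybrid_parents: dict[str, str] = {}
    by_id = {r.id: r for r in records}
    sc_positions = _single_copy_positions(config)
    mask = np.ones(config.total_len, dtype=bool)
    for s, e in _protected_intervals(config, layout["ssr_slots"]):
        mask[s:e] = False
    mask[_junction_fixed_positions(config)] = False
    sc_positions = sc_positions[mask[sc_positions]]
    for hid, pid, n_priv in config.hybrids:
        if pid not in by_id:
            raise ValueError(f"hybrid parent {pid!r} not among samples")
        hseed = int(rng.integers(0, 2**31 - 1))
        hyb = make_hybrid(by_id[pid], n_priv, seed=hseed, positions=sc_positions)
        hyb = hyb.copy_with(id=hid)
        records.append(hyb)
        by_id[hid] = hyb
        hybrid_parents[hid] = pid
        ssr_truth[hid] = ssr_truth[pid]

    truth = SyntheticTruth(true_tree=tree, planted_windows=list(layout["windows"]),
                           ssr_truth=ssr_truth, hybrid_parents=hybrid_parents)
    return records, truth


def _single_copy_positions(config: SimulationConfig) -> np.ndarray:
    lsc = np.arange(*config.region_interval("LSC"))
    ssc = np.arange(*config.region_interval("SSC"))
    return np.concatenate([lsc, ssc])


def make_hybrid(parent: PlastomeRecord, n_private_mutations: int, seed: int,
                positions: np.ndarray | None = None) -> PlastomeRecord:
    """Copy a parent plastome with exactly n private substitutions at
    distinct positions (maternal-inheritance hybrid model).

    ``positions`` restricts the mutable coordinate set (the population
    simulator passes single-copy positions so the IR identity is preserved);
    by default the whole sequence is eligible.
    """
    if positions is None:
        positions = np.arange(len(parent.sequence))
    if n_private_mutations > len(positions):
        raise ValueError("n_private_mutations exceeds available positions")
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(parent.sequence.encode(), dtype=np.uint8).copy()
    chosen = rng.choice(positions, size=n_private_mutations, replace=False)
    idx = np.searchsorted(BASES, seq[chosen])
    shift = rng.integers(1, 4, size=len(chosen))
    seq[chosen] = BASES[(idx + shift) % 4]
    return PlastomeRecord(id=f"{parent.id}_hybrid", sequence=seq.tobytes().decode(),
                          circular=parent.circular, features=list(parent.features))


# ---------------------------------------------------------------------------
# Contig simulation

def simulate_contigs(plastome: PlastomeRecord, n_plastid: int, n_decoy: int,
                     seed: int, plastid_cov: tuple[float, float] = (500.0, 50.0),
                     decoy_cov: tuple[float, float] = (20.0, 5.0),
                     length_range: tuple[int, int] = (500, 3000),
                     ) -> tuple[list[Contig], dict[str, str]]:
    """Plastid contigs are substrings of the plastome with high-mean coverage;
    decoys are random sequence with low-mean coverage.  Returns (contigs,
    truth labels id -> 'plastid'|'decoy')."""
    if n_plastid < 0 or n_decoy < 0:
        raise ValueError("contig counts must be >= 0")
    rng = np.random.default_rng(seed)
    L = len(plastome.sequence)
    contigs: list[Contig] = []
    truth: dict[str, str] = {}
    for i in range(n_plastid):
        clen = int(rng.integers(length_range[0], length_range[1] + 1))
        clen = min(clen, L)
        start = int(rng.integers(0, L))
        sub = (plastome.sequence * 2)[start : start + clen]  # wrap the circle
        cov = max(1.0, float(rng.normal(*plastid_cov)))
        cid = f"plastid_{i}_cov_{cov:.1f}"
        contigs.append(Contig(id=cid, sequence=sub, coverage=cov))
        truth[cid] = "plastid"
    for i in range(n_decoy):
        clen = int(rng.integers(length_range[0], length_range[1] + 1))
        sub = _random_dna(rng, clen, 0.40).tobytes().decode()
        cov = max(0.1, float(rng.normal(*decoy_cov)))
        cid = f"decoy_{i}_cov_{cov:.1f}"
        contigs.append(Contig(id=cid, sequence=sub, coverage=cov))
        truth[cid] = "decoy"
    return contigs, truth


# ---------------------------------------------------------------------------
# Convenience: one-call simulation + optional writing

def simulate_population(config: SimulationConfig
                        ) -> tuple[list[PlastomeRecord], SyntheticTruth, PlastomeRecord]:
    backbone, layout = generate_backbone(config)
    records, truth = evolve_population(backbone, config, layout)
    return records, truth, backbone


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    rows = [{"start": s, "end": e, "rate_multiplier": m}
            for s, e, m in truth.planted_windows]
    write_tsv_report(rows, outdir / "truth_windows.tsv",
                     columns=["start", "end", "rate_multiplier"])
    ssr_rows = [{"sample": sid, "start": s, "motif": m, "copies": c}
                for sid, loci in sorted(truth.ssr_truth.items())
                for s, m, c in loci]
    write_tsv_report(ssr_rows, outdir / "truth_ssrs.tsv",
                     columns=["sample", "start", "motif", "copies"])
    hyb_rows = [{"hybrid": h, "parent": p} for h, p in sorted(truth.hybrid_parents.items())]
    write_tsv_report(hyb_rows, outdir / "truth_hybrids.tsv", columns=["hybrid", "parent"])
    if truth.true_tree is not None:
        truth.true_tree.write(path=str(outdir / "guide_tree.nwk"), schema="newick")


def default_hdisp_simulation(seed: int = 0) -> SimulationConfig:
    """The default H-disp recovery study: 12 samples on ~16 kb quadripartite
    genomes (a 1:10 scale model of a real plastome), three planted 60 bp
    hypervariable windows at 20x the background substitution rate."""
    return SimulationConfig(
        seed=seed, n_samples=12, lsc_len=8700, ir_len=3000, ssc_len=1200,
        hypervariable_windows=[("LSC", 60, 20.0), ("LSC", 60, 20.0),
                               ("SSC", 60, 20.0)],
    )


def write_population(records: list[PlastomeRecord], truth: SyntheticTruth,
                     outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(records, outdir / "samples.fasta")
    write_truth(truth, outdir)


__all__ = [
    "SimulationConfig", "SyntheticTruth", "generate_backbone",
    "evolve_population", "make_hybrid", "simulate_contigs",
    "simulate_population", "write_population",
]
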