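"""Synthetic 8-species alignments with known conserved / neutral / accelerated structure.

Columns evolve independently down a fixed species tree under JC69, with the
effective length of every branch scaled per segment class:

* ``neutral``   — branch lengths as given (rate multiplier 1);
* ``conserved`` — all branches scaled by ``conserved_rate`` (r_c <= 1);
* ``rapid``     — conserved background, but one chosen terminal branch is
  additionally multiplied by ``accel_multiplier`` (m >= 1), emulating a
  lineage-specific acceleration.

No indels are simulated: every row has equal ungapped length, so alignment
column *k* of a block maps to reference position ``block_start + k``.  A toy
gene-model fixture is laid out so that conserved and rapid segments fall
into known genomic-context categories (upstream 2 kb, 5'UTR, intron,
downstream 2 kb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .io import (
    AlignmentBlock,
    GeneModel,
    MafRow,
    SpeciesTree,
    read_newick,
    write_bed,
    write_maf,
)

__all__ = [
    "SegmentSpec",
    "SimConfig",
    "TruthSegment",
    "SimTruth",
    "oryza_tree",
    "simulate_blocks",
    "make_fixture_suite",
    "write_gff3",
]

_BASES = "ACGT"

SEGMENT_CLASSES = ("neutral", "conserved", "rapid")


def oryza_tree() -> SpeciesTree:
    """The packaged 8-taxon AA-genome *Oryza* tree (total length 0.057882)."""
    ref = resources.files("rapidcns.data").joinpath("oryza_aa8.nwk")
    return read_newick(ref.read_text())


@dataclass(frozen=True)
class SegmentSpec:
    """One segment of the per-block plan."""

    cls: str
    length: int
    conserved_rate: float = 0.2
    accel_species: str | None = None
    accel_multiplier: float = 1.0

    def __post_init__(self):
        if self.cls not in SEGMENT_CLASSES:
            raise ValueError(f"unknown segment class {self.cls!r}")
        if not (0.0 < self.conserved_rate <= 1.0):
            raise ValueError("conserved_rate must be in (0, 1]")
        if self.accel_multiplier < 1.0:
            raise ValueError("accel_multiplier must be >= 1")
        if self.cls == "rapid" and self.accel_species is None:
            raise ValueError("rapid segment needs an accel_species")


@dataclass
class SimConfig:
    tree: SpeciesTree
    n_blocks: int
    block_length: int
    segments: list[SegmentSpec]
    seed: int
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    reference: str = "SAT"
    rapid_block_period: int = 1  # rapid segments accelerated in every k-th block
    blocks_per_chrom: int = 20
    block_spacing: int = 1000

    def validate(self) -> None:
        if sum(s.length for s in self.segments) != self.block_length:
            raise ValueError("segment lengths must sum to block_length")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        if self.reference not in self.tree.leaf_index:
            raise ValueError(f"reference {self.reference!r} not a tree leaf")
        for s in self.segments:
            if s.accel_species is not None and s.accel_species not in self.tree.leaf_index:
                raise ValueError(f"unknown branch id {s.accel_species!r} in segment plan")


@dataclass
class TruthSegment:
    block_id: str
    chrom: str
    start: int  # reference coordinates, 0-based half-open
    end: int
    cls: str
    accel_species: str | None = None
    accel_multiplier: float = 1.0


@dataclass
class SimTruth:
    """Ground truth: segment tiling per block plus realized substitution counts.

    ``branch_counts[(block_id, seg_index)]`` maps tree-node index to the
    number of sites whose state changed along the edge above that node,
    within that segment.
    """

    segments: list[TruthSegment] = field(default_factory=list)
    branch_counts: dict[tuple[str, int], dict[int, int]] = field(default_factory=dict)

    def by_class(self, cls: str) -> list[TruthSegment]:
        return [s for s in self.segments if s.cls == cls]


def _block_coords(cfg: SimConfig, i: int) -> tuple[str, int]:
    chrom = f"chr{i // cfg.blocks_per_chrom + 1}"
    start = (i % cfg.blocks_per_chrom) * (cfg.block_length + cfg.block_spacing)
    return chrom, start


def _chrom_size(cfg: SimConfig) -> int:
    return cfg.blocks_per_chrom * (cfg.block_length + cfg.block_spacing) + 4000


def simulate_blocks(
    config: SimConfig,
) -> tuple[list[AlignmentBlock], SimTruth, list[GeneModel]]:
    """Simulate alignment blocks, ground truth, and a matching gene fixture."""
    config.validate()
    tree = config.tree
    rng = np.random.default_rng(config.seed)
    L = config.block_length
    comp = np.asarray(config.base_composition, dtype=float)

    # per-column base rate multiplier and per-column acceleration bookkeeping
    seg_bounds: list[tuple[int, int, SegmentSpec]] = []
    pos = 0
    for s in config.segments:
        seg_bounds.append((pos, pos + s.length, s))
        pos += s.length

    blocks: list[AlignmentBlock] = []
    truth = SimTruth()
    genes: list[GeneModel] = []

    order = np.argsort(-np.arange(tree.n_nodes))  # reverse postorder = parent first
    for bi in range(config.n_blocks):
        accelerate = (bi % config.rapid_block_period) == 0
        chrom, bstart = _block_coords(config, bi)
        block_id = f"block{bi + 1}"

        base_rate = np.ones(L)
        accel_edge_rate: dict[int, np.ndarray] = {}
        for a, b, s in seg_bounds:
            cls = s.cls
            if cls == "rapid" and (not accelerate or s.accel_multiplier == 1.0):
                cls = "conserved"
            if cls != "neutral":
                base_rate[a:b] = s.conserved_rate
            if cls == "rapid":
                leaf = tree.leaf_index[s.accel_species]
                node = next(
                    i for i in range(tree.n_nodes)
                    if tree.is_leaf[i] and tree.node_leaf[i] == s.accel_species
                )
                extra = accel_edge_rate.setdefault(node, np.ones(L))
                extra[a:b] = s.accel_multiplier
            truth.segments.append(
                TruthSegment(
                    block_id,
                    chrom,
                    bstart + a,
                    bstart + b,
                    cls,
                    s.accel_species if cls == "rapid" else None,
                    s.accel_multiplier if cls == "rapid" else 1.0,
                )
            )

        states = np.empty((tree.n_nodes, L), dtype=np.int8)
        states[tree.root] = rng.choice(4, size=L, p=comp)
        changed = np.zeros((tree.n_nodes, L), dtype=bool)
        for i in order:
            i = int(i)
            if tree.parent[i] < 0:
                continue
            t = tree.blen[i] * base_rate
            if i in accel_edge_rate:
                t = t * accel_edge_rate[i]
            p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            mut = rng.random(L) < p_change
            shift = rng.integers(1, 4, size=L, dtype=np.int8)
            states[i] = np.where(mut, (states[tree.parent[i]] + shift) % 4, states[tree.parent[i]])
            changed[i] = states[i] != states[tree.parent[i]]

        for si, (a, b, _) in enumerate(seg_bounds):
            truth.branch_counts[(block_id, si)] = {
                i: int(changed[i, a:b].sum())
                for i in range(tree.n_nodes)
                if tree.parent[i] >= 0
            }

        rows = []
        for sp in tree.leaves:
            node = next(
                i for i in range(tree.n_nodes)
                if tree.is_leaf[i] and tree.node_leaf[i] == sp
            )
            text = "".join(_BASES[c] for c in states[node])
            rows.append(MafRow(sp, chrom, bstart, L, "+", _chrom_size(config), text))
        block = AlignmentBlock(block_id=block_id, rows=rows)
        block.validate()
        blocks.append(block)

        gene = _toy_gene(config, bi, chrom, bstart, seg_bounds)
        if gene is not None:
            genes.append(gene)

    return blocks, truth, genes


def _toy_gene(cfg, bi, chrom, bstart, seg_bounds) -> GeneModel | None:
    """Place one toy gene per block so truth segments get known contexts.

    Even blocks: + strand gene whose upstream-2kb window contains the first
    conserved segment and whose 5'UTR contains the first rapid-slot segment.
    Odd blocks: - strand gene with the conserved segment in the downstream
    window and the rapid-slot segment in the intron.  CDS never overlaps
    either segment (CNS calling masks CDS columns).
    """
    cons = next(((a, b) for a, b, s in seg_bounds if s.cls == "conserved"), None)
    rapid = next(((a, b) for a, b, s in seg_bounds if s.cls == "rapid"), None)
    if cons is None or rapid is None:
        return None
    c0, c1 = cons
    r0, r1 = rapid
    L = cfg.block_length
    g0 = c1 + 600
    if not (g0 - 2000 <= c0 and g0 <= r0 and r1 + 1100 <= L):
        return None
    gid = f"gene_{chrom}_{bstart + g0}"
    if bi % 2 == 0:
        exons = [(g0, r1 + 100), (r1 + 600, r1 + 1100)]
        cds = [(r1 + 20, r1 + 100), (r1 + 600, r1 + 800)]
        utr5 = [(g0, r1 + 20)]
        utr3 = [(r1 + 800, r1 + 1100)]
        strand = "+"
    else:
        exons = [(g0, g0 + 300), (r1 + 100, r1 + 1100)]
        cds = [(g0 + 100, g0 + 300), (r1 + 100, r1 + 300)]
        utr3 = [(g0, g0 + 100)]
        utr5 = [(r1 + 300, r1 + 1100)]
        strand = "-"
    off = bstart
    shift = lambda ivs: [(s + off, e + off) for s, e in ivs]
    gene = GeneModel(gid, chrom, strand, shift(exons), shift(cds), shift(utr5), shift(utr3))
    gene.validate()
    return gene


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            def line(ftype, s, e, ident, parent=None):
                attrs = f"ID={ident}" if parent is None else f"ID={ident};Parent={parent}"
                fh.write(
                    f"{g.chrom}\ttoy\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )

            line("gene", g.start, g.end, g.gene_id)
            mrna = f"{g.gene_id}.1"
            line("mRNA", g.start, g.end, mrna, g.gene_id)
            for k, (s, e) in enumerate(g.exons, 1):
                line("exon", s, e, f"{mrna}.exon{k}", mrna)
            for k, (s, e) in enumerate(g.cds, 1):
                line("CDS", s, e, f"{mrna}.cds{k}", mrna)
            for k, (s, e) in enumerate(g.utr5, 1):
                line("five_prime_UTR", s, e, f"{mrna}.utr5.{k}", mrna)
            for k, (s, e) in enumerate(g.utr3, 1):
                line("three_prime_UTR", s, e, f"{mrna}.utr3.{k}", mrna)


def default_fixture_config(seed: int, n_blocks: int = 200, accel_species: str = "LON",
                           accel_multiplier: float = 5.0,
                           conserved_rate: float = 0.2) -> SimConfig:
    """The standard test-fixture layout: 5 kb blocks, ~20% constrained bases.

    Per block: 1.5 kb neutral, 0.5 kb conserved, 1 kb neutral, 0.5 kb
    rapid-slot, 1.5 kb neutral.  The rapid slot is accelerated in every 4th
    block (the others realize it as plain conserved), giving 50 truth-rapid
    and 350 truth-conserved segments at the default size.
    """
    tree = oryza_tree()
    segs = [
        SegmentSpec("neutral", 1500),
        SegmentSpec("conserved", 500, conserved_rate=conserved_rate),
        SegmentSpec("neutral", 1000),
        SegmentSpec(
            "rapid",
            500,
            conserved_rate=conserved_rate,
            accel_species=accel_species,
            accel_multiplier=accel_multiplier,
        ),
        SegmentSpec("neutral", 1500),
    ]
    return SimConfig(
        tree=tree,
        n_blocks=n_blocks,
        block_length=5000,
        segments=segs,
        seed=seed,
        rapid_block_period=4,
    )


def make_fixture_suite(out_dir: str | Path, seed: int, n_blocks: int = 200,
                       accel_multiplier: float = 5.0) -> dict[str, Path]:
    """Write the deterministic fixture set: MAF + GFF3 + Newick + truth BED."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = default_fixture_config(seed, n_blocks=n_blocks, accel_multiplier=accel_multiplier)
    blocks, truth, genes = simulate_blocks(cfg)
    paths = {
        "maf": out / "alignment.maf",
        "gff3": out / "genes.gff3",
        "newick": out / "tree.nwk",
        "truth_bed": out / "truth.bed",
    }
    write_maf(blocks, paths["maf"])
    write_gff3(genes, paths["gff3"])
    ref = resources.files("rapidcns.data").joinpath("oryza_aa8.nwk")
    paths["newick"].write_text(ref.read_text())

    @dataclass
    class _BedSeg:
        chrom: str
        start: int
        end: int
        name: str
        score: float = 0.0
        strand: str = "+"

    bed = [
        _BedSeg(
            s.chrom,
            s.start,
            s.end,
            s.cls if s.cls != "rapid" else f"rapid|{s.accel_species}|{s.accel_multiplier:g}",
        )
        for s in truth.segments
    ]
    write_bed(bed, paths["truth_bed"])
    return paths
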