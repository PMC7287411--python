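"""Readers and writers for the pipeline's file formats.

All coordinate-convention normalisation lives here: internally every
interval is 0-based, half-open.  GFF3 (1-based, closed) is converted at the
boundary; MAF and BED are already 0-based half-open and pass through
unchanged.  Writers produce byte-stable output: fixed number formatting and
a fixed sort order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import gffutils
import numpy as np

__all__ = [
    "MafRow",
    "AlignmentBlock",
    "SpeciesTree",
    "GeneModel",
    "MafParseError",
    "InvariantError",
    "read_maf",
    "write_maf",
    "read_newick",
    "read_gff3",
    "write_bed",
    "write_report",
]

_VALID_CHARS = frozenset("ACGTNacgtn-")


class MafParseError(ValueError):
    """Raised on malformed MAF input; message names the offending line."""


class InvariantError(ValueError):
    """Raised when parsed data violates a documented type invariant."""


# ---------------------------------------------------------------------------
# alignment blocks


@dataclass
class MafRow:
    """One ``s`` line of a MAF block.

    ``start`` and ``size`` follow MAF semantics: ``start`` is the 0-based
    offset on the given strand (for ``-`` rows it counts from the end of the
    source sequence) and ``size`` is the ungapped length of ``text``.
    """

    species: str
    chrom: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    @property
    def src(self) -> str:
        return f"{self.species}.{self.chrom}" if self.chrom else self.species


@dataclass
class AlignmentBlock:
    """One orthologous alignment segment: >=2 species rows of equal gapped length."""

    block_id: str
    rows: list[MafRow] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.rows) < 2:
            raise InvariantError(f"block {self.block_id}: needs >= 2 rows")
        lengths = {len(r.text) for r in self.rows}
        if len(lengths) != 1:
            raise InvariantError(
                f"block {self.block_id}: rows of unequal gapped length {sorted(lengths)}"
            )
        if len(self.rows[0].text) < 1:
            raise InvariantError(f"block {self.block_id}: empty alignment")
        seen = set()
        for r in self.rows:
            if r.species in seen:
                raise InvariantError(
                    f"block {self.block_id}: species {r.species!r} appears twice"
                )
            seen.add(r.species)
            ungapped = sum(1 for c in r.text if c != "-")
            if ungapped != r.size:
                raise InvariantError(
                    f"block {self.block_id}, row {r.src}: size field {r.size} "
                    f"!= {ungapped} non-gap characters"
                )
            bad = set(r.text) - _VALID_CHARS
            if bad:
                raise InvariantError(
                    f"block {self.block_id}, row {r.src}: invalid characters {sorted(bad)}"
                )
            if r.strand not in "+-":
                raise InvariantError(
                    f"block {self.block_id}, row {r.src}: bad strand {r.strand!r}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].text)

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.rows]

    def row_for(self, species: str) -> MafRow:
        for r in self.rows:
            if r.species == species:
                return r
        raise KeyError(f"species {species!r} not in block {self.block_id}")

    def matrix(self) -> np.ndarray:
        """Return the alignment as a (rows, columns) array of single bytes."""
        return np.frombuffer(
            "".join(r.text.upper() for r in self.rows).encode(), dtype="S1"
        ).reshape(len(self.rows), self.n_columns)


def _split_src(src: str) -> tuple[str, str]:
    # species identifier = token before the first "."
    if "." in src:
        sp, chrom = src.split(".", 1)
        return sp, chrom
    return src, ""


def read_maf(path: str | Path, species_map: dict[str, str] | None = None) -> list[AlignmentBlock]:
    """Parse a UCSC-dialect MAF file into validated :class:`AlignmentBlock` s.

    ``species_map`` optionally renames the parsed species identifiers (for
    inputs whose source tokens do not follow the ``species.chrom``
    convention).
    """
    blocks: list[AlignmentBlock] = []
    current: AlignmentBlock | None = None
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                if current is not None:
                    current.validate()
                    blocks.append(current)
                    current = None
                continue
            if line.startswith("#"):
                continue
            if line.startswith("a"):
                if current is not None:
                    current.validate()
                    blocks.append(current)
                n += 1
                block_id = f"block{n}"
                for tok in line.split()[1:]:
                    if tok.startswith("id="):
                        block_id = tok[3:]
                current = AlignmentBlock(block_id=block_id)
            elif line.startswith("s"):
                fields = line.split()
                if len(fields) != 7:
                    raise MafParseError(
                        f"line {lineno}: s-line has {len(fields)} fields, expected 7"
                    )
                if current is None:
                    raise MafParseError(f"line {lineno}: s-line outside of a block")
                _, src, start, size, strand, src_size, text = fields
                sp, chrom = _split_src(src)
                if species_map:
                    sp = species_map.get(sp, sp)
                try:
                    current.rows.append(
                        MafRow(sp, chrom, int(start), int(size), strand, int(src_size), text)
                    )
                except ValueError as exc:
                    raise MafParseError(f"line {lineno}: {exc}") from exc
            # other line types (i/e/q) are ignored
    if current is not None:
        current.validate()
        blocks.append(current)
    return blocks


def write_maf(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for b in blocks:
            fh.write(f"a id={b.block_id}\n")
            width = max((len(r.src) for r in b.rows), default=0)
            for r in b.rows:
                fh.write(
                    f"s {r.src:<{width}} {r.start} {r.size} {r.strand} {r.src_size} {r.text}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# species tree


class SpeciesTree:
    """Rooted binary phylogeny with branch lengths in substitutions/site.

    Wraps a :class:`dendropy.Tree` and exposes flat arrays convenient for
    column-wise computation: a postorder node ordering, per-node branch
    length (edge above the node; 0 for the root), children pairs, and for
    every node the bitmask of leaves below it.  Leaf *i* in ``leaves``
    carries bit ``1 << i``.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        self._tree = tree
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            dup = sorted({x for x in leaves if leaves.count(x) > 1})
            raise InvariantError(f"duplicate leaf label(s): {dup}")
        self.leaves: list[str] = leaves
        self.leaf_index: dict[str, int] = {s: i for i, s in enumerate(leaves)}

        nodes = list(tree.postorder_node_iter())
        self._nodes = nodes
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.n_nodes = n
        self.parent = np.full(n, -1, dtype=np.int64)
        self.blen = np.zeros(n, dtype=float)
        self.leafmask = np.zeros(n, dtype=np.int64)
        self.children: list[tuple[int, ...]] = [() for _ in range(n)]
        self.is_leaf = np.zeros(n, dtype=bool)
        self.node_leaf: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            kids = nd.child_nodes()
            if nd.parent_node is not None:
                self.parent[i] = idx[id(nd.parent_node)]
                if nd.edge.length is None:
                    lab = nd.taxon.label if nd.taxon else "(internal node)"
                    raise InvariantError(f"missing branch length above {lab}")
                if nd.edge.length < 0:
                    raise InvariantError("negative branch length")
                self.blen[i] = float(nd.edge.length)
            if kids:
                if len(kids) != 2:
                    raise InvariantError("tree must be binary (after rooting)")
                self.children[i] = tuple(idx[id(k)] for k in kids)
                self.leafmask[i] = int(
                    np.bitwise_or.reduce([self.leafmask[c] for c in self.children[i]])
                )
            else:
                self.is_leaf[i] = True
                self.node_leaf[i] = nd.taxon.label
                self.leafmask[i] = 1 << self.leaf_index[nd.taxon.label]
        self.root = n - 1  # postorder puts the root last
        self.full_mask = (1 << len(leaves)) - 1
        total = float(self.blen.sum())
        if not (np.isfinite(total) and total > 0):
            raise InvariantError("total tree length must be finite and > 0")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def total_length(self) -> float:
        return float(self.blen.sum())

    def mask_of(self, species: Iterable[str]) -> int:
        m = 0
        for s in species:
            m |= 1 << self.leaf_index[s]
        return m

    def restricted_length(self, mask: int) -> float:
        """Branch length of the subtree induced by the leaf subset ``mask``.

        An edge contributes iff it separates the subset into two non-empty
        parts, i.e. degree-<=1 paths hanging off the induced subtree are
        pruned (the root is suppressed if it becomes degree-1).
        """
        total = 0.0
        for i in range(self.n_nodes):
            if self.parent[i] < 0:
                continue
            below = self.leafmask[i] & mask
            if below != 0 and below != mask:
                total += self.blen[i]
        return total

    def restricted_length_table(self) -> np.ndarray:
        """``E``-lookup: restricted tree length for every leaf-subset bitmask."""
        size = 1 << self.n_leaves
        masks = np.arange(size, dtype=np.int64)
        table = np.zeros(size, dtype=float)
        for i in range(self.n_nodes):
            if self.parent[i] < 0:
                continue
            below = masks & self.leafmask[i]
            table += np.where((below != 0) & (below != masks), self.blen[i], 0.0)
        return table

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(path_or_string: str | Path) -> SpeciesTree:
    """Read a rooted Newick tree with branch lengths into a :class:`SpeciesTree`."""
    s = str(path_or_string)
    data = s if s.lstrip().startswith("(") else Path(s).read_text()
    try:
        tree = dendropy.Tree.get(
            data=data,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "Duplicate" in type(exc).__name__:
            raise InvariantError(f"duplicate leaf label: {exc}") from exc
        raise MafParseError(f"newick parse error: {exc}") from exc
    return SpeciesTree(tree)


# ---------------------------------------------------------------------------
# gene models


def _merge_intervals(ivs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class GeneModel:
    """A protein-coding gene with feature intervals in 0-based half-open coords.

    Multi-transcript genes store the union of each feature class across
    transcripts; exons are merged and non-overlapping.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]

    def validate(self) -> None:
        if self.strand not in "+-":
            raise MafParseError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.exons:
            raise InvariantError(f"gene {self.gene_id}: no exons")
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if prev[1] > nxt[0]:
                raise InvariantError(f"gene {self.gene_id}: overlapping exons")
        for kind, segs in (("CDS", self.cds), ("5'UTR", self.utr5), ("3'UTR", self.utr3)):
            for s, e in segs:
                if not any(xs <= s and e <= xe for xs, xe in self.exons):
                    raise InvariantError(
                        f"gene {self.gene_id}: {kind} [{s},{e}) not contained in any exon"
                    )


def _subtract(intervals: list[tuple[int, int]], minus: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s, e in intervals:
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
        if cur < e:
            out.append((cur, e))
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based closed in file -> half-open internally).

    Genes without explicit UTR features get UTRs inferred as the exonic
    complement of the CDS, assigned 5'/3' by strand.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons, cds, utr5, utr3 = [], [], [], []
        for ft in db.children(gene.id):
            iv = (ft.start - 1, ft.end)  # GFF3 1-based closed -> 0-based half-open
            if ft.featuretype == "exon":
                exons.append(iv)
            elif ft.featuretype == "CDS":
                cds.append(iv)
            elif ft.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif ft.featuretype == "three_prime_UTR":
                utr3.append(iv)
        exons = _merge_intervals(exons)
        cds = _merge_intervals(cds)
        utr5 = _merge_intervals(utr5)
        utr3 = _merge_intervals(utr3)
        if cds and not utr5 and not utr3:
            cds_lo, cds_hi = cds[0][0], cds[-1][1]
            left = _subtract(exons, [(cds_lo, max(cds_hi, exons[-1][1]))])
            right = _subtract(exons, [(min(cds_lo, exons[0][0]), cds_hi)])
            if gene.strand == "+":
                utr5, utr3 = left, right
            else:
                utr5, utr3 = right, left
        model = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=str(gene.strand),
            exons=exons,
            cds=cds,
            utr5=utr5,
            utr3=utr3,
        )
        model.validate()
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# BED / TSV writers


def write_bed(elements: Iterable, path: str | Path) -> None:
    """Write BED6 lines, sorted by (chrom, start).

    ``elements`` need ``chrom``, ``start``, ``end``, ``name`` (or
    ``element_id``) attributes; optional ``score`` (clamped to 0..1000) and
    ``strand``.
    """
    recs = []
    for el in elements:
        name = getattr(el, "name", None) or getattr(el, "element_id", ".")
        score = getattr(el, "score", 0)
        strand = getattr(el, "strand", "+")
        if el.end <= el.start:
            raise InvariantError(f"element {name}: end <= start")
        score = int(min(1000, max(0, round(score))))
        recs.append((el.chrom, int(el.start), int(el.end), str(name), score, strand))
    recs.sort(key=lambda r: (r[0], r[1], r[3]))
    with open(path, "w") as fh:
        for r in recs:
            fh.write("\t".join(map(str, r)) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, float, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]),
                        f[3] if len(f) > 3 else ".",
                        float(f[4]) if len(f) > 4 else 0.0,
                        f[5] if len(f) > 5 else "+"))
    return out


def _fmt(v) -> str:
    if isinstance(v, float):
        if v != v:  # NaN
            return "NA"
        return format(v, ".6g")
    if v is None:
        return "NA"
    return str(v)


def write_report(records: Sequence[dict], path: str | Path, columns: Sequence[str] | None = None,
                 sort_by: Sequence[str] | None = None) -> None:
    """Write a TSV report with a header row and >=6 significant digits.

    Row order is deterministic: explicitly via ``sort_by`` keys, otherwise
    input order is preserved.
    """
    if columns is None:
        columns = list(records[0].keys()) if records else []
    rows = list(records)
    if sort_by:
        rows.sort(key=lambda r: tuple(r[k] for k in sort_by))
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join(_fmt(r.get(c)) for c in columns) + "\n")


def read_report(path: str | Path):
    """Read a TSV report back into a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", na_values=["NA"])
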