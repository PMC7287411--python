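"""Conserved-element detection by rejected substitutions.

Each alignment column gets a score ``RS = E - O``: the substitutions
expected under the neutral tree for the species present in the column,
minus the substitutions observed (Fitch parsimony on the fixed topology).
Runs of constraint (positive RS / substitution depletion) outside coding
sequence are reported as conserved noncoding elements.

Observed counts use Fitch parsimony rather than a per-column rate fit: at
the branch lengths typical of congeneric plant panels (total tree length
well under 0.1 substitutions/site) multiple hits are negligible and the
parsimony count is a deterministic, exactly testable statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .io import AlignmentBlock, GeneModel, InvariantError, SpeciesTree

__all__ = [
    "NeutralModel",
    "ColumnScore",
    "ColumnScores",
    "CNSElement",
    "CallParams",
    "NeutralScaleError",
    "build_coding_mask",
    "estimate_neutral_scale",
    "score_column",
    "score_block",
    "call_elements",
    "detect_elements",
]

_CODE = np.zeros(256, dtype=np.uint8)
for b, v in zip(b"ACGT", (1, 2, 4, 8)):
    _CODE[b] = v
    _CODE[b + 32] = v  # lower case


class NeutralScaleError(ValueError):
    """Too little data to fit the neutral scale; pass an explicit lambda."""


@dataclass
class NeutralModel:
    """Neutral expectation: scaled branch lengths of the species tree.

    ``expected(mask)`` returns lambda times the length of the tree induced
    by the leaf subset ``mask`` (degree-<=1 paths pruned), which is the
    expected substitution count for a column in which exactly those species
    are present.
    """

    tree: SpeciesTree
    lam: float = 1.0
    _table: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if not (self.lam > 0):
            raise InvariantError("neutral scale lambda must be > 0")
        if self._table is None:
            self._table = self.tree.restricted_length_table()

    def expected(self, mask: int) -> float:
        return float(self.lam * self._table[mask])

    @property
    def table(self) -> np.ndarray:
        return self.lam * self._table


@dataclass
class ColumnScore:
    block_id: str
    column: int
    present: frozenset[str]
    observed: int
    expected: float
    rs: float
    usable: bool


@dataclass
class ColumnScores:
    """Vectorized per-column scores for one block."""

    block_id: str
    observed: np.ndarray  # int, Fitch parsimony count
    expected: np.ndarray  # float, lambda * restricted tree length
    rs: np.ndarray        # expected - observed where usable, else 0
    usable: np.ndarray    # bool
    present_count: np.ndarray
    present_mask: np.ndarray
    ref_pos: np.ndarray   # reference coordinate per column, -1 where ref gapped
    coding: np.ndarray    # bool, column overlaps the CDS mask

    def __len__(self) -> int:
        return self.observed.size


@dataclass
class CNSElement:
    element_id: str
    ref_species: str
    chrom: str
    start: int
    end: int
    n_columns: int
    sum_rs: float
    mean_rs: float
    block_id: str
    col_start: int
    col_end: int

    @property
    def score(self) -> float:
        # BED score column: mean RS x 100, integer-clamped 0..1000 by write_bed
        return self.mean_rs * 100.0

    @property
    def name(self) -> str:
        return self.element_id

    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------


def build_coding_mask(
    gene_models: Iterable[GeneModel], reference_species: str | None = None
) -> dict[str, list[tuple[int, int]]]:
    """Union of CDS intervals per chromosome (0-based half-open, merged).

    Only CDS is masked: conserved elements are allowed in UTRs and introns.
    ``reference_species`` is accepted for interface symmetry; gene models
    are already expressed in reference coordinates.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).extend(g.cds)
    out = {}
    for chrom, ivs in by_chrom.items():
        merged: list[tuple[int, int]] = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        out[chrom] = merged
    return out


def _mask_lookup(mask: dict[str, list[tuple[int, int]]], chrom: str, pos: np.ndarray) -> np.ndarray:
    """Boolean per position: inside a masked interval (pos may contain -1)."""
    ivs = mask.get(chrom, [])
    hit = np.zeros(pos.shape, dtype=bool)
    if not ivs:
        return hit
    starts = np.array([s for s, _ in ivs])
    ends = np.array([e for _, e in ivs])
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = (idx >= 0) & (pos >= 0)
    hit[ok] = pos[ok] < ends[idx[ok]]
    return hit


def _block_codes(block: AlignmentBlock, tree: SpeciesTree) -> np.ndarray:
    """(n_leaves, L) uint8 bitmask codes; 0 = gap/N/species absent from block."""
    L = block.n_columns
    codes = np.zeros((tree.n_leaves, L), dtype=np.uint8)
    for row in block.rows:
        if row.species not in tree.leaf_index:
            raise InvariantError(
                f"species {row.species!r} in block {block.block_id} absent from tree"
            )
        arr = np.frombuffer(row.text.encode(), dtype=np.uint8)
        codes[tree.leaf_index[row.species]] = _CODE[arr]
    return codes


def _fitch_counts(codes: np.ndarray, tree: SpeciesTree) -> np.ndarray:
    """Vectorized Fitch parsimony count per column on the induced subtree.

    Absent species carry state 0; an internal node whose children are both
    present combines them by set intersection (union plus one substitution
    when empty); otherwise states propagate through, which is exactly Fitch
    on the topology with degree-<=2 nodes suppressed.
    """
    L = codes.shape[1]
    states = np.zeros((tree.n_nodes, L), dtype=np.uint8)
    count = np.zeros(L, dtype=np.int64)
    for i in range(tree.n_nodes):
        if tree.is_leaf[i]:
            states[i] = codes[tree.leaf_index[tree.node_leaf[i]]]
        else:
            a, b = tree.children[i]
            sa, sb = states[a], states[b]
            inter = sa & sb
            both = (sa != 0) & (sb != 0)
            states[i] = np.where(both & (inter != 0), inter, sa | sb)
            count += (both & (inter == 0)).astype(np.int64)
    return count


def score_block(
    block: AlignmentBlock,
    model: NeutralModel,
    coding_mask: Mapping[str, list[tuple[int, int]]] | None = None,
    reference: str | None = None,
    min_species: int = 4,
) -> ColumnScores:
    """Score every column of a block: O (Fitch), E (scaled tree length), RS."""
    tree = model.tree
    codes = _block_codes(block, tree)
    observed = _fitch_counts(codes, tree)
    present = codes != 0
    weights = (1 << np.arange(tree.n_leaves, dtype=np.int64))[:, None]
    pmask = (present * weights).sum(axis=0)
    expected = model.table[pmask]
    pcount = present.sum(axis=0)

    if reference is not None:
        ref_row = block.row_for(reference)
        gapped = np.frombuffer(ref_row.text.encode(), dtype=np.uint8) == ord("-")
        ref_pos = np.full(len(gapped), -1, dtype=np.int64)
        ref_pos[~gapped] = ref_row.start + np.arange((~gapped).sum())
        chrom = ref_row.chrom
    else:
        ref_pos = np.arange(block.n_columns, dtype=np.int64)
        chrom = ""
    coding = (
        _mask_lookup(coding_mask, chrom, ref_pos)
        if coding_mask is not None
        else np.zeros(block.n_columns, dtype=bool)
    )
    usable = (pcount >= min_species) & ~coding
    rs = np.where(usable, expected - observed, 0.0)
    return ColumnScores(
        block_id=block.block_id,
        observed=observed,
        expected=expected,
        rs=rs,
        usable=usable,
        present_count=pcount,
        present_mask=pmask,
        ref_pos=ref_pos,
        coding=coding,
    )


def score_column(
    column: Mapping[str, str],
    model: NeutralModel,
    min_species: int = 4,
    block_id: str = "",
    column_index: int = 0,
    coding_masked: bool = False,
) -> ColumnScore:
    """Score a single column given as ``{species: base}`` (A/C/G/T/N/-)."""
    tree = model.tree
    codes = np.zeros((tree.n_leaves, 1), dtype=np.uint8)
    for sp, base in column.items():
        if sp not in tree.leaf_index:
            raise InvariantError(f"species {sp!r} absent from tree")
        codes[tree.leaf_index[sp], 0] = _CODE[ord(base)]
    observed = int(_fitch_counts(codes, tree)[0])
    present = frozenset(
        sp for sp in column if codes[tree.leaf_index[sp], 0] != 0
    )
    mask = tree.mask_of(present)
    expected = model.expected(mask)
    usable = len(present) >= min_species and not coding_masked
    rs = expected - observed if usable else 0.0
    return ColumnScore(block_id, column_index, present, observed, expected, rs, usable)


def estimate_neutral_scale(
    blocks: Iterable[AlignmentBlock],
    tree: SpeciesTree,
    coding_mask: Mapping[str, list[tuple[int, int]]] | None = None,
    reference: str | None = None,
    min_columns: int = 1000,
) -> float:
    """Fit lambda = mean Fitch substitutions per fully-present unmasked column,
    divided by the total tree length.

    Only columns where *all* tree leaves carry a base are used, so the
    parsimony-count / tree-length ratio is well defined.
    """
    base = NeutralModel(tree, lam=1.0)
    total_o = 0
    n_cols = 0
    for block in blocks:
        sc = score_block(block, base, coding_mask, reference, min_species=tree.n_leaves)
        full = (sc.present_count == tree.n_leaves) & ~sc.coding
        total_o += int(sc.observed[full].sum())
        n_cols += int(full.sum())
    if n_cols < min_columns:
        raise NeutralScaleError(
            f"only {n_cols} fully-present unmasked columns (< {min_columns}); "
            "pass an explicit lambda override (e.g. lambda = 1)"
        )
    lam = total_o / (n_cols * tree.total_length)
    if lam <= 0:
        raise NeutralScaleError(
            "all usable columns are invariant (lambda = 0); "
            "pass an explicit lambda override"
        )
    return lam


# ---------------------------------------------------------------------------
# element calling


@dataclass
class CallParams:
    """Element-calling parameters.

    ``mode='msp'`` (default): X-drop scan for maximal-scoring segments of
    cumulative RS, a one-sided Poisson substitution-depletion filter per
    candidate, and boundary refinement by the maximal log-likelihood-ratio
    subsegment (candidate substitution rate vs the neutral expectation).

    ``mode='runs'``: simple greedy runs of columns with RS above
    ``rs_floor``, tolerating interior runs of at most ``max_gap_run``
    non-positive/unusable columns; kept if the summed RS is positive.  At
    very shallow divergences almost every substitution-free column has the
    same small positive RS whatever its conservation class, so this mode
    cannot separate conserved from neutral sequence; it is retained as a
    transparent reference behaviour.
    """

    min_element_length: int = 10  # reference bases
    max_gap_run: int = 3
    rs_floor: float = 0.0
    mode: str = "msp"
    xdrop: float = 5.0
    alpha_element: float = 0.01


def _msp_candidates(x: np.ndarray, xdrop: float) -> list[tuple[int, int, float]]:
    """Local-alignment style scan: cumulative score resets at <= 0, a candidate
    closes on an X-drop from its running maximum, and its span is
    [reset point, argmax]."""
    segs: list[tuple[int, int, float]] = []
    L = len(x)
    j = 0
    s = 0.0
    best = 0.0
    start = 0
    bj = -1
    while j < L:
        s += x[j]
        if s > best:
            best = s
            bj = j
        if s <= 0:
            if best > 0:
                segs.append((start, bj + 1, best))
            s = 0.0
            best = 0.0
            start = j + 1
            bj = j
        elif best - s > xdrop:
            segs.append((start, bj + 1, best))
            j = bj  # resume just after the argmax
            s = 0.0
            best = 0.0
            start = j + 1
            bj = j
        j += 1
    if best > 0:
        segs.append((start, bj + 1, best))
    return segs


def _max_llr_subsegment(sub: np.ndarray, exp: np.ndarray, usable: np.ndarray) -> tuple[int, int]:
    """Kadane max-sum subarray of the per-column log-likelihood ratio between
    the candidate's own substitution rate and the neutral expectation.

    Columns without data (unusable) are charged the neutral-prior expected
    score, so runs of masked or gappy columns cannot act as free bridges
    into flanking neutral sequence.
    """
    e_tot = float(exp[usable].sum())
    o_tot = float(sub[usable].sum())
    n_use = int(usable.sum())
    if e_tot <= 0 or n_use == 0:
        return 0, len(sub)
    r0 = min(e_tot / n_use, 0.999)  # expected substitutions per usable column
    r1 = min(max(o_tot / n_use, 1.0 / (4 * n_use)), 0.999)
    pos = np.log((1 - r1) / (1 - r0))
    neg = np.log(r1 / r0)
    nodata = (1.0 - r0) * pos + r0 * neg
    y = np.where(usable, np.where(sub > 0, neg * np.maximum(sub, 1), pos), nodata)
    best = -np.inf
    s = 0.0
    start = 0
    ba, bb = 0, len(sub)
    for j, v in enumerate(y):
        if s <= 0:
            s = v
            start = j
        else:
            s += v
        if s > best:
            best = s
            ba, bb = start, j + 1
    return ba, bb


def call_elements(
    scores: ColumnScores,
    chrom: str,
    ref_species: str,
    params: CallParams | None = None,
    id_prefix: str = "CNS",
    id_start: int = 1,
) -> list[CNSElement]:
    """Call conserved elements from one block's column scores.

    Elements never cross block boundaries.  Coordinates are the reference
    positions of the first/last non-gap reference base in the column span.
    """
    params = params or CallParams()
    spans: list[tuple[int, int]] = []
    if params.mode == "runs":
        spans = _runs_spans(scores, params)
    elif params.mode == "msp":
        spans = _msp_spans(scores, params)
    else:
        raise ValueError(f"unknown calling mode {params.mode!r}")

    elements: list[CNSElement] = []
    k = id_start
    for a, b in spans:
        ref = scores.ref_pos[a:b]
        ref = ref[ref >= 0]
        if ref.size == 0:
            continue
        start, end = int(ref.min()), int(ref.max()) + 1
        if end - start < params.min_element_length:
            continue
        use = scores.usable[a:b]
        n_cols = int(use.sum())
        sum_rs = float(scores.rs[a:b][use].sum())
        if sum_rs <= 0 or n_cols == 0:
            continue
        elements.append(
            CNSElement(
                element_id=f"{id_prefix}_{k}",
                ref_species=ref_species,
                chrom=chrom,
                start=start,
                end=end,
                n_columns=n_cols,
                sum_rs=sum_rs,
                mean_rs=sum_rs / n_cols,
                block_id=scores.block_id,
                col_start=a,
                col_end=b,
            )
        )
        k += 1
    return elements


def _runs_spans(scores: ColumnScores, params: CallParams) -> list[tuple[int, int]]:
    good = scores.usable & (scores.rs > params.rs_floor)
    spans = []
    L = len(good)
    i = 0
    while i < L:
        if not good[i]:
            i += 1
            continue
        j = i
        last_good = i
        gap = 0
        while j + 1 < L:
            if good[j + 1]:
                j += 1
                last_good = j
                gap = 0
            elif gap < params.max_gap_run:
                j += 1
                gap += 1
            else:
                break
        spans.append((i, last_good + 1))
        i = last_good + 1
    return spans


def _msp_spans(scores: ColumnScores, params: CallParams) -> list[tuple[int, int]]:
    x = np.where(scores.usable, scores.rs, 0.0)
    sub = np.where(scores.usable, scores.observed, 0)
    spans = []
    for a, b, _ in _msp_candidates(x, params.xdrop):
        use = scores.usable[a:b]
        if int(use.sum()) == 0:
            continue
        o = float(sub[a:b][use].sum())
        e = float(scores.expected[a:b][use].sum())
        if e <= 0:
            continue
        # one-sided depletion: observed significantly below neutral expectation
        if _sps.poisson.cdf(o, e) > params.alpha_element:
            continue
        ca, cb = a, b
        for _ in range(4):  # iterate boundary refinement to a fixed point
            ta, tb = _max_llr_subsegment(
                sub[ca:cb], scores.expected[ca:cb], scores.usable[ca:cb]
            )
            na, nb = ca + ta, ca + tb
            if (na, nb) == (ca, cb):
                break
            ca, cb = na, nb
        if cb > ca:
            spans.append((ca, cb))
    return spans


def detect_elements(
    blocks: Sequence[AlignmentBlock],
    tree: SpeciesTree,
    gene_models: Iterable[GeneModel],
    reference: str,
    min_species: int = 4,
    params: CallParams | None = None,
    lam: float | None = None,
) -> tuple[list[CNSElement], NeutralModel, dict[str, ColumnScores]]:
    """End-to-end detection: mask CDS, fit lambda, score, call elements."""
    mask = build_coding_mask(gene_models, reference)
    if lam is None:
        lam = estimate_neutral_scale(blocks, tree, mask, reference)
    model = NeutralModel(tree, lam=lam)
    params = params or CallParams()
    elements: list[CNSElement] = []
    all_scores: dict[str, ColumnScores] = {}
    for block in blocks:
        sc = score_block(block, model, mask, reference, min_species)
        all_scores[block.block_id] = sc
        chrom = block.row_for(reference).chrom
        elements.extend(
            call_elements(sc, chrom, reference, params, id_start=len(elements) + 1)
        )
    return elements, model, all_scores
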