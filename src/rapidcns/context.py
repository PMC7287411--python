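"""Genomic-context classification of elements and term enrichment.

Five context categories relative to protein-coding gene models, all
strand-aware: the 2 kb window upstream of the gene span, 5'UTR, intron,
3'UTR, and the 2 kb window downstream.  An element carries every category
it overlaps by at least one base (no precedence collapse); a precedence
mode is available for single-label summaries.  Gene associations feed a
generic hypergeometric term-enrichment with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import GeneModel
from .stats import bh_adjust

__all__ = [
    "CATEGORIES",
    "PRECEDENCE",
    "ContextInterval",
    "RegionContext",
    "EnrichmentResult",
    "build_context_intervals",
    "classify_regions",
    "summarize_context_distribution",
    "enrich_terms",
]

CATEGORIES = (
    "upstream_2kb",
    "five_prime_utr",
    "intron",
    "three_prime_utr",
    "downstream_2kb",
)

# single-label mode: most gene-proximal regulatory class wins
PRECEDENCE = ("five_prime_utr", "three_prime_utr", "intron", "upstream_2kb", "downstream_2kb")


@dataclass(frozen=True)
class ContextInterval:
    chrom: str
    start: int
    end: int
    category: str
    gene_id: str


@dataclass
class RegionContext:
    element_id: str
    categories: set[str] = field(default_factory=set)
    associated_genes: dict[str, set[str]] = field(default_factory=dict)  # gene -> categories

    def single_label(self) -> str:
        for cat in PRECEDENCE:
            if cat in self.categories:
                return cat
        return "intergenic"


def build_context_intervals(
    gene_models: Iterable[GeneModel], flank: int = 2000
) -> list[ContextInterval]:
    """Labelled intervals per gene, strand-aware, clipped at position 0.

    The gene span used for the flanking windows is the full transcript
    extent (first to last exon), not the CDS extent.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    out: list[ContextInterval] = []
    for g in gene_models:
        up = (max(0, g.start - flank), g.start)
        down = (g.end, g.end + flank)
        if g.strand == "-":
            up, down = (g.end, g.end + flank), (max(0, g.start - flank), g.start)
        pairs = [
            ("upstream_2kb", [up]),
            ("downstream_2kb", [down]),
            ("five_prime_utr", g.utr5),
            ("three_prime_utr", g.utr3),
            ("intron", g.introns()),
        ]
        for cat, ivs in pairs:
            for s, e in ivs:
                if e > s:
                    out.append(ContextInterval(g.chrom, s, e, cat, g.gene_id))
    return out


def classify_regions(
    elements: Sequence, intervals: Sequence[ContextInterval]
) -> list[RegionContext]:
    """Assign every category whose interval overlaps an element by >= 1 base.

    ``elements`` need ``element_id``/``name``, ``chrom``, ``start``, ``end``.
    Elements on chromosomes absent from the interval set classify empty.
    """
    by_chrom: dict[str, list[ContextInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    index: dict[str, tuple[np.ndarray, np.ndarray, list[ContextInterval]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda v: (v.start, v.end))
        index[chrom] = (
            np.array([v.start for v in ivs]),
            np.maximum.accumulate(np.array([v.end for v in ivs])),
            ivs,
        )
    out = []
    for el in elements:
        eid = getattr(el, "element_id", None) or getattr(el, "name")
        ctx = RegionContext(element_id=eid)
        entry = index.get(el.chrom)
        if entry is not None:
            starts, cum_ends, ivs = entry
            hi = int(np.searchsorted(starts, el.end, side="left"))
            lo = int(np.searchsorted(cum_ends[:hi], el.start, side="right"))
            for iv in ivs[lo:hi]:
                if iv.start < el.end and el.start < iv.end:
                    ctx.categories.add(iv.category)
                    ctx.associated_genes.setdefault(iv.gene_id, set()).add(iv.category)
        out.append(ctx)
    return out


DEFAULT_LENGTH_BINS = (0, 100, 500, 1000, float("inf"))


def summarize_context_distribution(
    contexts: Sequence[RegionContext],
    lengths: Mapping[str, int],
    length_bins: Sequence[float] = DEFAULT_LENGTH_BINS,
    species_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Counts of regions per category x length bin (x species when given).

    A region with several categories contributes once to each category row
    (documented double-count); regions with no category count as
    ``intergenic``.
    """
    edges = list(length_bins)
    labels = [
        f"[{int(a)},{'inf' if b == float('inf') else int(b)})"
        for a, b in zip(edges, edges[1:])
    ]
    rows = []
    for ctx in contexts:
        ln = lengths[ctx.element_id]
        which = np.searchsorted(edges, ln, side="right") - 1
        which = min(max(which, 0), len(labels) - 1)
        cats = sorted(ctx.categories) or ["intergenic"]
        sp = species_of.get(ctx.element_id, "all") if species_of else "all"
        for cat in cats:
            rows.append((sp, cat, labels[which]))
    frame = pd.DataFrame(rows, columns=["species", "category", "length_bin"])
    cats = list(CATEGORIES) + ["intergenic"]
    table = (
        frame.groupby(["species", "category", "length_bin"], sort=True)
        .size()
        .unstack("length_bin", fill_value=0)
        .reindex(columns=labels, fill_value=0)
        .reset_index()
    )
    table["category"] = pd.Categorical(table["category"], categories=cats, ordered=True)
    return table.sort_values(["species", "category"], kind="stable").reset_index(drop=True)


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # study genes with the term
    K: int  # study size
    m: int  # background genes with the term
    M: int  # background size
    p: float
    p_adjusted: float = float("nan")


def enrich_terms(
    study_genes: Iterable[str],
    background_genes: Iterable[str],
    gene2term: pd.DataFrame | Sequence[tuple[str, str, str]],
) -> list[EnrichmentResult]:
    """Hypergeometric (upper-tail) term enrichment with BH adjustment.

    ``gene2term`` rows are (gene_id, term_id, term_name).  Terms with zero
    study hits are not reported; results are sorted by adjusted p, then
    term id.
    """
    study = set(study_genes)
    background = set(background_genes)
    extra = study - background
    if extra:
        raise ValueError(f"study genes not in background: {sorted(extra)}")
    if isinstance(gene2term, pd.DataFrame):
        triples = gene2term.iloc[:, :3].itertuples(index=False)
    else:
        triples = iter(gene2term)
    term_genes: dict[str, set[str]] = {}
    term_name: dict[str, str] = {}
    for gene, term, name in triples:
        if gene not in background:
            continue
        term_genes.setdefault(term, set()).add(gene)
        term_name[term] = name
    K = len(study)
    M = len(background)
    results = []
    for term, genes in term_genes.items():
        k = len(genes & study)
        if k == 0:
            continue
        m = len(genes)
        p = float(_sps.hypergeom.sf(k - 1, M, m, K))
        results.append(EnrichmentResult(term, term_name[term], k, K, m, M, p))
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    results.sort(key=lambda r: (r.p_adjusted, r.p, r.term_id))
    return results
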