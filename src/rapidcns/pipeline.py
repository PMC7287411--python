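"""End-to-end orchestration: detect -> stats -> annotate, with file contracts.

Each stage consumes and produces plain files (BED/TSV), so the chained
stages reproduce a single ``run`` exactly and intermediate results can be
inspected or swapped.  All analysis stages are deterministic; the only
randomness in the package lives in the simulator.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import context as ctx_mod
from . import detect as detect_mod
from . import stats as stats_mod
from .io import (
    read_bed,
    read_gff3,
    read_maf,
    read_newick,
    read_report,
    write_bed,
    write_report,
)

__all__ = ["RunConfig", "run_pipeline", "stage_detect", "stage_stats", "stage_annotate"]

log = logging.getLogger("rapidcns")

REPORT_VERSION = "1"


@dataclass
class RunConfig:
    maf: Path
    newick: Path
    gff3: Path
    out_dir: Path
    reference: str
    gene2term: Path | None = None
    min_species: int = 4
    min_element_length: int = 10
    max_gap_run: int = 3
    rs_floor: float = 0.0
    call_mode: str = "msp"
    xdrop: float = 5.0
    alpha_element: float = 0.01
    alpha: float = 0.001
    distance: str = "jc69"         # jc69 | raw
    baseline: str = "pooled"       # pooled | unweighted
    per_species_baseline: bool = True
    flank: int = 2000
    length_bins: tuple = ctx_mod.DEFAULT_LENGTH_BINS
    lam: float | None = None       # neutral scale override
    seed: int = 0                  # reserved for stochastic stages (none at present)

    def __post_init__(self):
        for name in ("maf", "newick", "gff3", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.gene2term is not None:
            self.gene2term = Path(self.gene2term)

    def check_inputs(self) -> None:
        for name in ("maf", "newick", "gff3"):
            p = getattr(self, name)
            if not p.exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
        if self.gene2term is not None and not self.gene2term.exists():
            raise FileNotFoundError(f"gene2term input not found: {self.gene2term}")

    def call_params(self) -> detect_mod.CallParams:
        return detect_mod.CallParams(
            min_element_length=self.min_element_length,
            max_gap_run=self.max_gap_run,
            rs_floor=self.rs_floor,
            mode=self.call_mode,
            xdrop=self.xdrop,
            alpha_element=self.alpha_element,
        )


ELEMENT_COLUMNS = [
    "element_id", "ref_species", "chrom", "start", "end", "length",
    "block_id", "col_start", "col_end", "n_columns", "sum_rs", "mean_rs",
]


def stage_detect(cfg: RunConfig) -> list[detect_mod.CNSElement]:
    """MAF + tree + GFF3 -> cns_elements.bed + element_stats.tsv."""
    blocks = read_maf(cfg.maf)
    tree = read_newick(cfg.newick)
    genes = read_gff3(cfg.gff3)
    elements, model, _ = detect_mod.detect_elements(
        blocks, tree, genes, cfg.reference,
        min_species=cfg.min_species, params=cfg.call_params(), lam=cfg.lam,
    )
    log.info("detect: %d blocks, lambda=%.6g, %d elements", len(blocks), model.lam, len(elements))
    out = cfg.out_dir
    write_bed(elements, out / "cns_elements.bed")
    recs = [
        {
            "element_id": e.element_id, "ref_species": e.ref_species,
            "chrom": e.chrom, "start": e.start, "end": e.end,
            "length": e.length, "block_id": e.block_id,
            "col_start": e.col_start, "col_end": e.col_end,
            "n_columns": e.n_columns, "sum_rs": e.sum_rs, "mean_rs": e.mean_rs,
        }
        for e in elements
    ]
    write_report(recs, out / "element_stats.tsv", columns=ELEMENT_COLUMNS,
                 sort_by=("chrom", "start", "element_id"))
    return elements


def _elements_from_report(path: Path) -> list[detect_mod.CNSElement]:
    df = read_report(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            detect_mod.CNSElement(
                element_id=row.element_id, ref_species=row.ref_species,
                chrom=row.chrom, start=int(row.start), end=int(row.end),
                n_columns=int(row.n_columns), sum_rs=float(row.sum_rs),
                mean_rs=float(row.mean_rs), block_id=row.block_id,
                col_start=int(row.col_start), col_end=int(row.col_end),
            )
        )
    return out


def stage_stats(cfg: RunConfig) -> list[stats_mod.RapidRegion]:
    """element_stats.tsv + MAF + tree -> rapid_regions.tsv, species_specific.tsv,
    group_contrasts.tsv."""
    out = cfg.out_dir
    elements = _elements_from_report(out / "element_stats.tsv")
    blocks = {b.block_id: b for b in read_maf(cfg.maf)}
    tree = read_newick(cfg.newick)

    profiles: dict[str, stats_mod.SubstitutionProfile] = {}
    meta: dict[str, detect_mod.CNSElement] = {}
    for el in elements:
        prof = stats_mod.element_profile(blocks[el.block_id], el, tree, cfg.distance)
        if prof.n < 2:
            log.warning("element %s has < 2 covered species; excluded", el.element_id)
            continue
        profiles[el.element_id] = prof
        meta[el.element_id] = el

    regions: list[stats_mod.RapidRegion] = []
    if profiles:
        baseline = stats_mod.compute_baseline(list(profiles.values()))
        p0 = baseline.p0 if cfg.baseline == "pooled" else baseline.unweighted_mean
        test_baseline = dataclasses.replace(baseline, p0=p0)
        log.info(
            "stats: %d profiled elements, pooled p0=%.6g, unweighted mean=%.6g",
            len(profiles), baseline.p0, baseline.unweighted_mean,
        )
        for eid, prof in profiles.items():
            regions.append(
                stats_mod.evaluate_element(
                    prof, test_baseline, cfg.alpha, cfg.per_species_baseline
                )
            )
        p_bh = stats_mod.bh_adjust([r.p for r in regions])
    else:
        log.warning("stats: no elements to evaluate")
        p_bh = np.array([])

    species = tree.leaves
    recs = []
    for r, adj in zip(regions, p_bh):
        el = meta[r.element_id]
        recs.append({
            "element_id": r.element_id, "chrom": el.chrom, "start": el.start,
            "end": el.end, "n_species": profiles[r.element_id].n,
            "mean_frequency": r.mean_frequency, "frequency": r.frequency,
            "d": r.d, "n_sites": r.n_sites, "chi2": r.chi2, "p": r.p,
            "p_bh": float(adj), "low_expected_count": int(r.low_expected_count),
            "is_rapid": int(r.is_rapid),
        })
    write_report(
        recs, out / "rapid_regions.tsv",
        columns=["element_id", "chrom", "start", "end", "n_species",
                 "mean_frequency", "frequency", "d", "n_sites", "chi2", "p",
                 "p_bh", "low_expected_count", "is_rapid"],
        sort_by=("chrom", "start", "element_id"),
    )

    sp_recs = []
    for r in regions:
        el = meta[r.element_id]
        for s in species:
            if s not in r.species_frequency:
                continue
            sp_recs.append({
                "element_id": r.element_id, "chrom": el.chrom, "start": el.start,
                "end": el.end, "species": s,
                "f_s": r.species_frequency[s],
                "chi2": r.species_chi2.get(s, float("nan")),
                "p": r.species_p.get(s, float("nan")),
                "species_specific": int(s in r.species_specific),
            })
    write_report(
        sp_recs, out / "species_specific.tsv",
        columns=["element_id", "chrom", "start", "end", "species", "f_s",
                 "chi2", "p", "species_specific"],
        sort_by=("chrom", "start", "element_id", "species"),
    )

    grp_recs = []
    if any(r.is_rapid for r in regions):
        for s in species:
            rest = [x for x in species if x != s]
            try:
                fa, fb, chi2, p = stats_mod.compare_group_frequencies(
                    regions, profiles, [s], rest
                )
            except ValueError:
                continue
            grp_recs.append({
                "contrast": f"{s}_vs_rest", "group_a": s, "group_b": ",".join(rest),
                "freq_a": fa, "freq_b": fb, "chi2": chi2, "p": p,
            })
    else:
        log.warning("stats: empty rapid set; group contrasts skipped")
    write_report(
        grp_recs, out / "group_contrasts.tsv",
        columns=["contrast", "group_a", "group_b", "freq_a", "freq_b", "chi2", "p"],
    )
    log.info("stats: %d rapid regions", sum(r.is_rapid for r in regions))
    return regions


@dataclass
class _BedElement:
    chrom: str
    start: int
    end: int
    element_id: str


def stage_annotate(cfg: RunConfig) -> None:
    """cns_elements.bed + rapid/species tables + GFF3 -> context tables
    (+ enrichment when a gene2term table is given)."""
    out = cfg.out_dir
    genes = read_gff3(cfg.gff3)
    intervals = ctx_mod.build_context_intervals(genes, cfg.flank)
    bed = read_bed(out / "cns_elements.bed")
    elements = [_BedElement(c, s, e, n) for c, s, e, n, _, _ in bed]
    contexts = ctx_mod.classify_regions(elements, intervals)
    lengths = {el.element_id: el.end - el.start for el in elements}

    recs = []
    for ctx in contexts:
        recs.append({
            "element_id": ctx.element_id,
            "categories": ",".join(sorted(ctx.categories)) or "intergenic",
            "single_label": ctx.single_label(),
            "genes": ",".join(sorted(ctx.associated_genes)) or "NA",
        })
    order = {el.element_id: (el.chrom, el.start, el.element_id) for el in elements}
    recs.sort(key=lambda r: order[r["element_id"]])
    write_report(recs, out / "context.tsv",
                 columns=["element_id", "categories", "single_label", "genes"])

    rapid_df = read_report(out / "rapid_regions.tsv")
    rapid_ids = set(rapid_df.loc[rapid_df["is_rapid"] == 1, "element_id"])
    sp_df = read_report(out / "species_specific.tsv")
    flagged = sp_df[sp_df["species_specific"] == 1]

    ctx_by_id = {c.element_id: c for c in contexts}
    strata: list[tuple[str, list[ctx_mod.RegionContext]]] = [
        ("all", contexts),
        ("rapid", [ctx_by_id[i] for i in sorted(rapid_ids) if i in ctx_by_id]),
    ]
    for s in sorted(set(flagged["species"])):
        ids = sorted(set(flagged.loc[flagged["species"] == s, "element_id"]))
        strata.append((s, [ctx_by_id[i] for i in ids if i in ctx_by_id]))
    tables = []
    for name, subset in strata:
        if not subset:
            continue
        t = ctx_mod.summarize_context_distribution(
            subset, lengths, cfg.length_bins, species_of={c.element_id: name for c in subset}
        )
        tables.append(t)
    summary = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=["species", "category"])
    )
    summary_recs = summary.astype(object).to_dict("records")
    write_report(summary_recs, out / "context_summary.tsv",
                 columns=list(summary.columns))

    if cfg.gene2term is not None:
        g2t = pd.read_csv(cfg.gene2term, sep="\t", header=None,
                          names=["gene_id", "term_id", "term_name"])
        background = [g.gene_id for g in genes]
        study = sorted({
            g
            for c in contexts
            if c.element_id in rapid_ids
            for g in c.associated_genes
        })
        results = ctx_mod.enrich_terms(study, background, g2t)
        enr = [{
            "term_id": r.term_id, "term_name": r.term_name, "k": r.k, "K": r.K,
            "m": r.m, "M": r.M, "p": r.p, "p_bh": r.p_adjusted,
        } for r in results]
        write_report(enr, out / "enrichment.tsv",
                     columns=["term_id", "term_name", "k", "K", "m", "M", "p", "p_bh"])
    log.info("annotate: %d contexts, %d rapid ids", len(contexts), len(rapid_ids))


def run_pipeline(cfg: RunConfig) -> Path:
    """Run detect -> stats -> annotate; returns the run directory.

    Re-running with identical inputs and config produces byte-identical
    data files.
    """
    cfg.check_inputs()
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(cfg.out_dir / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        eff = dataclasses.asdict(cfg)
        eff = {k: (str(v) if isinstance(v, Path) else v) for k, v in eff.items()}
        eff["report_version"] = REPORT_VERSION
        (cfg.out_dir / "config_effective.json").write_text(
            json.dumps(eff, indent=2, sort_keys=True, default=str) + "\n"
        )
        for stage, fn in (("detect", stage_detect), ("stats", stage_stats),
                          ("annotate", stage_annotate)):
            try:
                fn(cfg)
            except Exception as exc:
                log.error("stage %s failed: %s", stage, exc)
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return cfg.out_dir
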