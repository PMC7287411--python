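"""The core rate statistic and rapid-evolution tests.

For a region aligned across *n* species, the nucleotide substitution
frequency is the mean pairwise per-site distance

    f = 2 * sum_{i<j} d_ij / (n (n - 1)),

with d_ij a Jukes-Cantor-corrected (default) or raw mismatch proportion
over the columns where both species carry an unambiguous base.  Regions
whose pooled substitution counts significantly exceed the all-region
baseline (1-df chi-squared goodness of fit, one-sided by direction,
p < 0.001) are flagged as rapidly evolving; the same construction per
species against a per-species baseline flags species-specific acceleration.

The chi-squared treats the pooled per-pair counts as binomial.  Pairs that
share tree branches are correlated, so the test inherits the
pseudo-replication of the classic frequency-contrast approach it
implements; see the methods notes for calibration implications.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .detect import CNSElement, _block_codes
from .io import AlignmentBlock, SpeciesTree

__all__ = [
    "SubstitutionProfile",
    "GlobalBaseline",
    "RapidRegion",
    "pairwise_distance",
    "element_profile",
    "mean_pairwise_frequency",
    "compute_baseline",
    "chi_squared_rapid_test",
    "species_frequency",
    "species_specific_test",
    "evaluate_element",
    "compare_group_frequencies",
    "bh_adjust",
]

JC_SATURATION = 0.75


def jc69_distance(p: float) -> float:
    """JC69 correction d = -(3/4) ln(1 - 4p/3); saturates at p >= 0.75."""
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def pairwise_distance(
    row_i: str | np.ndarray,
    row_j: str | np.ndarray,
    correction: str = "jc69",
) -> tuple[float, int, int]:
    """(d_ij, sites_ij, diffs_ij) between two gapped sequences.

    Compared sites are columns where both rows carry an unambiguous base
    (not gap, not N).  With zero compared sites the distance is undefined
    and NaN is returned; callers treat the pair as missing.
    """
    a = _as_codes(row_i)
    b = _as_codes(row_j)
    if a.size != b.size:
        raise ValueError("rows must have equal gapped length")
    both = (a != 0) & (b != 0)
    sites = int(both.sum())
    diffs = int(((a != b) & both).sum())
    if sites == 0:
        return float("nan"), 0, 0
    p = diffs / sites
    if correction == "raw":
        return p, sites, diffs
    if correction != "jc69":
        raise ValueError(f"unknown correction {correction!r}")
    if p >= JC_SATURATION:
        warnings.warn(
            f"pairwise mismatch proportion {p:.3f} saturates the JC69 correction; "
            "falling back to the raw proportion",
            RuntimeWarning,
            stacklevel=2,
        )
        return p, sites, diffs
    return float(jc69_distance(p)), sites, diffs


def _as_codes(row) -> np.ndarray:
    if isinstance(row, np.ndarray):
        return row
    from .detect import _CODE

    return _CODE[np.frombuffer(row.encode(), dtype=np.uint8)]


@dataclass
class SubstitutionProfile:
    """Per-element pairwise distance matrices and the mean frequency."""

    element_id: str
    species: list[str]          # species with usable coverage (>=1 defined pair)
    d: np.ndarray               # (n, n) distances, NaN where the pair is missing
    sites: np.ndarray           # (n, n) int compared-site counts
    diffs: np.ndarray           # (n, n) int differing-site counts
    mean_frequency: float = float("nan")

    @property
    def n(self) -> int:
        return len(self.species)

    def pooled_counts(self) -> tuple[int, int]:
        """(D, N): diffs and sites summed over defined pairs (i < j)."""
        iu = np.triu_indices(self.n, k=1)
        defined = self.sites[iu] > 0
        return int(self.diffs[iu][defined].sum()), int(self.sites[iu][defined].sum())

    def species_counts(self, s: str) -> tuple[int, int]:
        i = self.species.index(s)
        defined = self.sites[i] > 0
        defined[i] = False
        return int(self.diffs[i][defined].sum()), int(self.sites[i][defined].sum())


def mean_pairwise_frequency(profile: SubstitutionProfile) -> float:
    """2 sum_{i<j} d_ij / (n(n-1)) over defined pairs.

    When some pairs are missing (zero overlap) the mean runs over the
    defined pairs only.  Undefined (NaN) when fewer than one defined pair.
    """
    n = profile.n
    if n < 2:
        return float("nan")
    iu = np.triu_indices(n, k=1)
    d = profile.d[iu]
    defined = ~np.isnan(d)
    n_pairs = int(defined.sum())
    if n_pairs == 0:
        return float("nan")
    if n_pairs == n * (n - 1) // 2:
        return float(2.0 * d[defined].sum() / (n * (n - 1)))
    return float(d[defined].mean())


def element_profile(
    block: AlignmentBlock,
    element: CNSElement,
    tree: SpeciesTree,
    correction: str = "jc69",
) -> SubstitutionProfile:
    """Build the pairwise profile for an element's column span."""
    codes = _block_codes(block, tree)[:, element.col_start : element.col_end]
    return profile_from_codes(element.element_id, codes, tree.leaves, correction)


def profile_from_codes(
    element_id: str,
    codes: np.ndarray,
    species: Sequence[str],
    correction: str = "jc69",
) -> SubstitutionProfile:
    present = codes != 0
    m = len(species)
    both = present[:, None, :] & present[None, :, :]
    sites = both.sum(axis=2)
    diffs = ((codes[:, None, :] != codes[None, :, :]) & both).sum(axis=2)
    np.fill_diagonal(sites, 0)
    np.fill_diagonal(diffs, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(sites > 0, diffs / np.maximum(sites, 1), np.nan)
        if correction == "jc69":
            d = np.where(p < JC_SATURATION, -0.75 * np.log1p(-4.0 * np.minimum(p, 0.74999) / 3.0), p)
        elif correction == "raw":
            d = p
        else:
            raise ValueError(f"unknown correction {correction!r}")
    np.fill_diagonal(d, 0.0)
    # species with usable coverage: at least one defined pair
    has_pair = (sites > 0).any(axis=1)
    keep = np.flatnonzero(has_pair)
    kept_species = [species[i] for i in keep]
    prof = SubstitutionProfile(
        element_id=element_id,
        species=kept_species,
        d=d[np.ix_(keep, keep)],
        sites=sites[np.ix_(keep, keep)].astype(np.int64),
        diffs=diffs[np.ix_(keep, keep)].astype(np.int64),
    )
    prof.mean_frequency = mean_pairwise_frequency(prof)
    return prof


@dataclass
class GlobalBaseline:
    """Pooled null frequencies across all elements.

    ``p0`` is the count-weighted pooled frequency sum(diffs)/sum(sites);
    ``unweighted_mean`` is the plain average of per-element mean
    frequencies; ``p0_species[s]`` pools the pairs involving species *s*.
    """

    p0: float
    unweighted_mean: float
    d_total: int
    n_total: int
    p0_species: dict[str, float] = field(default_factory=dict)
    d_species: dict[str, int] = field(default_factory=dict)
    n_species: dict[str, int] = field(default_factory=dict)


def compute_baseline(profiles: Sequence[SubstitutionProfile]) -> GlobalBaseline:
    d_tot = 0
    n_tot = 0
    means = []
    d_s: dict[str, int] = {}
    n_s: dict[str, int] = {}
    for prof in profiles:
        D, N = prof.pooled_counts()
        d_tot += D
        n_tot += N
        if not np.isnan(prof.mean_frequency):
            means.append(prof.mean_frequency)
        for s in prof.species:
            ds, ns = prof.species_counts(s)
            d_s[s] = d_s.get(s, 0) + ds
            n_s[s] = n_s.get(s, 0) + ns
    if n_tot == 0:
        raise ValueError("zero total compared sites; cannot form a baseline")
    return GlobalBaseline(
        p0=d_tot / n_tot,
        unweighted_mean=float(np.mean(means)) if means else float("nan"),
        d_total=d_tot,
        n_total=n_tot,
        p0_species={s: (d_s[s] / n_s[s] if n_s[s] else float("nan")) for s in n_s},
        d_species=d_s,
        n_species=n_s,
    )


def _gof_chi2(D: float, N: float, p0: float) -> tuple[float, float]:
    """1-df goodness of fit of D successes in N trials against rate p0."""
    e1 = p0 * N
    e0 = (1.0 - p0) * N
    chi2 = (D - e1) ** 2 / e1 + ((N - D) - e0) ** 2 / e0
    return float(chi2), float(_sps.chi2.sf(chi2, df=1))


@dataclass
class RapidRegion:
    element_id: str
    chi2: float
    p: float
    is_rapid: bool
    frequency: float                    # element pooled D/N
    mean_frequency: float               # the formula value
    d: int
    n_sites: int
    species_frequency: dict[str, float] = field(default_factory=dict)
    species_p: dict[str, float] = field(default_factory=dict)
    species_chi2: dict[str, float] = field(default_factory=dict)
    species_specific: set[str] = field(default_factory=set)
    low_expected_count: bool = False


def chi_squared_rapid_test(
    profile: SubstitutionProfile,
    baseline: GlobalBaseline,
    alpha: float = 0.001,
) -> RapidRegion:
    """Flag an element as rapidly evolving against the pooled baseline.

    One-sided by direction: significant *and* elevated (D/N > p0).
    """
    D, N = profile.pooled_counts()
    if N == 0:
        raise ValueError(f"element {profile.element_id}: no compared sites")
    p0 = baseline.p0
    if not (0.0 < p0 < 1.0):
        raise ValueError("baseline p0 must be in (0, 1)")
    chi2, p = _gof_chi2(D, N, p0)
    freq = D / N
    return RapidRegion(
        element_id=profile.element_id,
        chi2=chi2,
        p=p,
        is_rapid=bool(p < alpha and freq > p0),
        frequency=freq,
        mean_frequency=profile.mean_frequency,
        d=D,
        n_sites=N,
        low_expected_count=bool(p0 * N < 5),
    )


def species_frequency(profile: SubstitutionProfile, species: str) -> float:
    """Mean of d_sj over the defined pairs j != s; NaN if none defined."""
    if species not in profile.species:
        return float("nan")
    i = profile.species.index(species)
    defined = profile.sites[i] > 0
    defined[i] = False
    if not defined.any():
        return float("nan")
    return float(profile.d[i][defined].mean())


def species_specific_test(
    profile: SubstitutionProfile,
    baseline: GlobalBaseline,
    alpha: float = 0.001,
    per_species_baseline: bool = True,
) -> tuple[set[str], dict[str, float], dict[str, float]]:
    """Per-species goodness of fit of (D_s, N_s) against the species baseline.

    Returns (flagged set, per-species p, per-species chi2).  A species is
    flagged iff p < alpha and its element frequency exceeds its baseline.
    """
    flagged: set[str] = set()
    pvals: dict[str, float] = {}
    chis: dict[str, float] = {}
    for s in profile.species:
        Ds, Ns = profile.species_counts(s)
        if Ns == 0:
            continue
        p0s = baseline.p0_species.get(s) if per_species_baseline else baseline.p0
        if p0s is None or not (0.0 < p0s < 1.0):
            continue
        chi2, p = _gof_chi2(Ds, Ns, p0s)
        pvals[s] = p
        chis[s] = chi2
        if p < alpha and Ds / Ns > p0s:
            flagged.add(s)
    return flagged, pvals, chis


def evaluate_element(
    profile: SubstitutionProfile,
    baseline: GlobalBaseline,
    alpha: float = 0.001,
    per_species_baseline: bool = True,
) -> RapidRegion:
    """Full per-element evaluation: rapid flag, per-species frequencies and flags."""
    region = chi_squared_rapid_test(profile, baseline, alpha)
    region.species_frequency = {
        s: species_frequency(profile, s) for s in profile.species
    }
    flagged, pvals, chis = species_specific_test(
        profile, baseline, alpha, per_species_baseline
    )
    region.species_specific = flagged
    region.species_p = pvals
    region.species_chi2 = chis
    return region


def compare_group_frequencies(
    regions: Sequence[RapidRegion],
    profiles: Mapping[str, SubstitutionProfile],
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> tuple[float, float, float, float]:
    """Contrast pooled per-species frequencies between two species groups
    within the rapid-region set.

    Counts pool the per-species pairs (every pair involving a group member,
    from that member's side).  Returns (freq_A, freq_B, chi2, p) from a 2x2
    chi-squared without continuity correction.
    """
    ga = set(group_a)
    gb = set(group_b)
    if not ga or not gb or ga & gb:
        raise ValueError("groups must be disjoint and non-empty")
    rapid = [r for r in regions if r.is_rapid]
    if not rapid:
        raise ValueError("empty rapid set")
    DA = NA = DB = NB = 0
    for r in rapid:
        prof = profiles[r.element_id]
        for s in prof.species:
            ds, ns = prof.species_counts(s)
            if s in ga:
                DA += ds
                NA += ns
            elif s in gb:
                DB += ds
                NB += ns
    if NA == 0 or NB == 0:
        raise ValueError("a group has zero compared sites in the rapid set")
    table = np.array([[DA, NA - DA], [DB, NB - DB]], dtype=float)
    if DA + DB == 0 or (NA - DA) + (NB - DB) == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = _sps.chi2_contingency(table, correction=False)
    return DA / NA, DB / NB, float(chi2), float(p)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
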