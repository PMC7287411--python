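"""Pairwise distances, the mean-frequency formula, and the chi-squared tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from rapidcns.stats import (
    GlobalBaseline,
    SubstitutionProfile,
    bh_adjust,
    chi_squared_rapid_test,
    compare_group_frequencies,
    compute_baseline,
    evaluate_element,
    jc69_distance,
    mean_pairwise_frequency,
    pairwise_distance,
    profile_from_codes,
    species_frequency,
    species_specific_test,
)


class TestPairwiseDistance:
    def test_identical_overlap(self):
        d, sites, diffs = pairwise_distance("A" * 100, "A" * 100)
        assert (d, sites, diffs) == (0.0, 100, 0)

    def test_jc69_correction_value(self):
        d, sites, diffs = pairwise_distance("A" * 97 + "CCC", "A" * 97 + "GGG")
        assert sites == 100 and diffs == 3
        assert d == pytest.approx(0.030617, abs=1e-6)  # -0.75 ln(0.96)

    def test_raw_mode(self):
        d, _, _ = pairwise_distance("A" * 97 + "CCC", "A" * 97 + "GGG", correction="raw")
        assert d == pytest.approx(0.03)

    def test_zero_overlap_missing(self):
        d, sites, diffs = pairwise_distance("AAAA----", "----CCCC")
        assert np.isnan(d) and sites == 0 and diffs == 0

    def test_gaps_and_ns_excluded(self):
        d, sites, diffs = pairwise_distance("ACGTN-", "ACC-AA")
        assert sites == 3  # columns 0,1,2 only
        assert diffs == 1

    def test_saturated_distance_falls_back_to_raw(self):
        with pytest.warns(RuntimeWarning, match="saturat"):
            d, _, _ = pairwise_distance("ACGT" * 25, "CATG" * 25)
        assert d == pytest.approx(1.0)

    @given(st_h.floats(min_value=1e-6, max_value=0.7499))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_jc_correction_never_below_raw(self, p):
        assert jc69_distance(p) >= p


def _profile(d_vals, n=None, element_id="e"):
    """Fully-defined profile from the upper-triangle distances."""
    if n is None:
        n = int((1 + np.sqrt(1 + 8 * len(d_vals))) / 2)
    d = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    d[iu] = d_vals
    d = d + d.T
    sites = np.full((n, n), 1000, dtype=np.int64)
    np.fill_diagonal(sites, 0)
    diffs = np.rint(d * 1000).astype(np.int64)
    prof = SubstitutionProfile(element_id, [f"s{i}" for i in range(n)], d, sites, diffs)
    prof.mean_frequency = mean_pairwise_frequency(prof)
    return prof


class TestMeanFrequency:
    def test_two_species_reduces_to_single_distance(self):
        assert _profile([0.04]).mean_frequency == pytest.approx(0.04)

    def test_three_species_formula(self):
        # 2 * (0.01+0.02+0.03) / (3*2) = 0.02
        assert _profile([0.01, 0.02, 0.03]).mean_frequency == pytest.approx(0.02)

    def test_equal_distances_return_common_value(self):
        prof = _profile([0.013] * 28)
        assert prof.n == 8
        assert prof.mean_frequency == pytest.approx(0.013)

    def test_missing_pairs_use_defined_mean(self):
        prof = _profile([0.01, 0.02, 0.03])
        prof.sites[0, 2] = prof.sites[2, 0] = 0
        prof.d[0, 2] = prof.d[2, 0] = np.nan
        assert mean_pairwise_frequency(prof) == pytest.approx((0.01 + 0.03) / 2)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            vals = rng.uniform(0, 0.2, size=n * (n - 1) // 2)
            prof = _profile(vals, n=n)
            # independent oracle: explicit double loop over the formula
            acc = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    acc += prof.d[i, j]
            expected = 2.0 * acc / (n * (n - 1))
            assert abs(mean_pairwise_frequency(prof) - expected) <= 1e-12


class TestBaseline:
    def test_pooled_ratio(self):
        p1, p2 = _profile([0.001], n=2), _profile([0.003], n=2)
        p1.diffs[:] = np.array([[0, 1], [1, 0]])
        p1.sites[:] = np.array([[0, 100], [100, 0]])
        p2.diffs[:] = np.array([[0, 3], [3, 0]])
        p2.sites[:] = np.array([[0, 100], [100, 0]])
        base = compute_baseline([p1, p2])
        assert base.p0 == pytest.approx(4 / 200)

    def test_single_element(self):
        p = _profile([0.01, 0.02, 0.03])
        D, N = p.pooled_counts()
        assert compute_baseline([p]).p0 == pytest.approx(D / N)

    def test_uniform_frequency_invariant_to_weighting(self):
        profs = [_profile([0.02] * 28) for _ in range(3)]
        profs[1].sites *= 5
        profs[1].diffs *= 5
        base = compute_baseline(profs)
        assert base.p0 == pytest.approx(0.02)
        assert base.unweighted_mean == pytest.approx(0.02)

    def test_zero_sites_rejected(self):
        p = _profile([0.0], n=2)
        p.sites[:] = 0
        with pytest.raises(ValueError, match="zero total"):
            compute_baseline([p])


def _baseline(p0, species=None, p0_s=None):
    return GlobalBaseline(
        p0=p0, unweighted_mean=p0, d_total=0, n_total=0,
        p0_species=p0_s or {s: p0 for s in (species or [])},
    )


class TestRapidTest:
    def test_exact_null_not_flagged(self):
        prof = _profile([0.014] * 28)
        r = chi_squared_rapid_test(prof, _baseline(0.014))
        assert r.chi2 == pytest.approx(0.0, abs=1e-6)
        assert r.p == pytest.approx(1.0, abs=1e-6)
        assert not r.is_rapid

    def test_elevated_element_flagged(self):
        prof = _profile([0.035], n=2)
        # D=35, N=1000 against p0=0.0144: chi2 = 29.90, p = 4.55e-8
        r = chi_squared_rapid_test(prof, _baseline(0.0144))
        assert r.d == 35 and r.n_sites == 1000
        assert r.chi2 == pytest.approx(29.90, abs=0.005)
        assert r.p == pytest.approx(4.55e-8, rel=0.01)
        assert r.is_rapid

    def test_direction_filter_blocks_depleted_elements(self):
        prof = _profile([0.0], n=2)
        r = chi_squared_rapid_test(prof, _baseline(0.0144))
        assert r.chi2 > 0 and not r.is_rapid

    def test_low_expected_count_recorded(self):
        prof = _profile([0.01], n=2)
        r = chi_squared_rapid_test(prof, _baseline(0.001))
        assert r.low_expected_count

    def test_chi2_monotone_in_d_above_baseline(self):
        from rapidcns.stats import _gof_chi2

        p0 = 0.0144
        last = 0.0
        for D in range(15, 200, 7):
            chi2, _ = _gof_chi2(D, 1000, p0)
            assert chi2 >= last
            last = chi2


class TestSpeciesLevel:
    def test_species_frequency_mean_of_defined_pairs(self):
        prof = _profile([0.02] * 28)
        assert species_frequency(prof, "s0") == pytest.approx(0.02)
        prof.sites[0, 2:] = 0
        assert species_frequency(prof, "s0") == pytest.approx(prof.d[0, 1])

    def test_absent_species_undefined(self):
        prof = _profile([0.02] * 28)
        assert np.isnan(species_frequency(prof, "nope"))

    def test_all_at_baseline_flags_nothing(self):
        prof = _profile([0.014] * 28)
        flagged, pvals, _ = species_specific_test(prof, _baseline(0.014, prof.species))
        assert flagged == set()
        assert all(p > 0.9 for p in pvals.values())

    def test_direction_filter_at_species_level(self):
        prof = _profile([0.0] * 28)
        prof.sites *= 100  # huge N, zero diffs: tiny p but depleted
        flagged, _, _ = species_specific_test(prof, _baseline(0.0144, prof.species))
        assert flagged == set()

    def test_elevated_species_flagged(self):
        vals = np.full(28, 0.01)
        prof = _profile(vals)
        i = prof.species.index("s3")
        prof.d[i, :] = 0.02
        prof.d[:, i] = 0.02
        prof.d[i, i] = 0
        prof.diffs = np.rint(prof.d * 1000).astype(np.int64)
        flagged, _, _ = species_specific_test(prof, _baseline(0.01, prof.species))
        assert flagged == {"s3"}


class TestGroupContrast:
    def _regions(self, profs):
        base = compute_baseline(profs)
        # force everything rapid so the contrast pools all elements
        regions = []
        for p in profs:
            r = chi_squared_rapid_test(p, _baseline(1e-6))
            r.is_rapid = True
            regions.append(r)
        return regions, {p.element_id: p for p in profs}

    def test_identical_groups_give_null(self):
        profs = [_profile([0.02] * 28, element_id=f"e{i}") for i in range(2)]
        regions, by_id = self._regions(profs)
        fa, fb, chi2, p = compare_group_frequencies(regions, by_id, ["s0"], ["s1"])
        assert fa == pytest.approx(fb)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_two_by_two_value(self):
        # (D_A, N_A) = (50, 1000) vs (D_B, N_B) = (20, 1000):
        # pooled p = 0.035 -> chi2 = 2*(15^2/35) + 2*(15^2/965) = 13.3235
        prof = _profile([0.0], n=2, element_id="e")
        prof.diffs[:] = np.array([[0, 50], [20, 0]])  # asymmetric counts by side
        prof.sites[:] = np.array([[0, 1000], [1000, 0]])
        regions, by_id = self._regions([prof])
        fa, fb, chi2, p = compare_group_frequencies(regions, by_id, ["s0"], ["s1"])
        assert (fa, fb) == (pytest.approx(0.05), pytest.approx(0.02))
        expected = 2 * 15**2 / 35 + 2 * 15**2 / 965  # hand-computed 2x2 chi-squared
        assert chi2 == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(2.62e-4, rel=0.01)

    def test_bad_groups_rejected(self):
        profs = [_profile([0.02] * 28, element_id="e0")]
        regions, by_id = self._regions(profs)
        with pytest.raises(ValueError, match="disjoint"):
            compare_group_frequencies(regions, by_id, ["s0"], ["s0"])
        for r in regions:
            r.is_rapid = False
        with pytest.raises(ValueError, match="empty rapid"):
            compare_group_frequencies(regions, by_id, ["s0"], ["s1"])


class TestProfileFromCodes:
    def test_counts_match_pairwise_distance(self):
        rng = np.random.default_rng(3)
        codes = rng.choice([0, 1, 2, 4, 8], size=(4, 50), p=[0.1, 0.225, 0.225, 0.225, 0.225])
        prof = profile_from_codes("e", codes.astype(np.uint8), ["a", "b", "c", "d"])
        for i in range(4):
            for j in range(i + 1, 4):
                both = (codes[i] != 0) & (codes[j] != 0)
                assert prof.sites[i, j] == both.sum()
                assert prof.diffs[i, j] == ((codes[i] != codes[j]) & both).sum()

    def test_species_without_overlap_dropped(self):
        codes = np.array(
            [[1, 1, 1, 1], [1, 2, 1, 1], [0, 0, 0, 0]], dtype=np.uint8
        )
        prof = profile_from_codes("e", codes, ["a", "b", "c"])
        assert prof.species == ["a", "b"]
        assert prof.n == 2


def test_bh_adjustment_monotone_and_bounded():
    rng = np.random.default_rng(8)
    p = rng.uniform(0, 1, 40)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_evaluate_element_populates_species_fields():
    prof = _profile([0.02] * 28)
    region = evaluate_element(prof, _baseline(0.02, prof.species))
    assert set(region.species_frequency) == set(prof.species)
    assert region.species_specific == set()
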