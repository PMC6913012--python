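from __future__ import annotations

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from asmdiff.translocval import (
    F2Sample,
    Translocation,
    closeness_score,
    expected_copy_number,
    filter_translocations,
    normalize_marker_counts,
    simulate_f2_population,
    validate_translocations,
)
from asmdiff.translocval import test_absence as absence_test
from asmdiff.translocval import test_cluster as cluster_test
from asmdiff.translocval import test_copyfit as copyfit_test


def _sample(ga, gb, region=5.0, genome=5.0, counts=None, n_frac=0.0, sid="s"):
    counts = np.zeros((3, 2)) if counts is None else np.asarray(counts, dtype=float)
    return F2Sample(sid, ga, gb, region, genome, counts, n_frac)


class TestExpectedCopy:
    @pytest.mark.parametrize(
        "ga,gb,copies",
        [("AA", "BB", 4), ("BB", "AA", 0), ("AB", "AB", 2),
         ("AA", "AA", 2), ("AB", "BB", 3), ("BB", "AB", 1)],
    )
    def test_copy_table(self, ga, gb, copies):
        assert expected_copy_number(ga, gb) == copies

    def test_invalid_code_raises(self):
        with pytest.raises(ValueError):
            expected_copy_number("AC", "BB")


class TestFiltering:
    def test_small_translocation_dropped(self):
        tr = Translocation("t", "chr1", 1000, 1800)  # 801 bp
        assert filter_translocations([tr], {}) == []

    def test_centromeric_translocation_dropped(self):
        tr = Translocation("t", "chr1", 10_000, 15_000)
        assert filter_translocations([tr], {}, [("chr1", 14_000, 20_000)]) == []

    def test_n_heavy_translocation_dropped(self):
        tr = Translocation("t", "chr1", 10_000, 15_000)
        samples = {"t": [_sample("AA", "AA", n_frac=0.4), _sample("AB", "AB", n_frac=0.3)]}
        assert filter_translocations([tr], samples) == []

    def test_clean_translocation_kept(self):
        tr = Translocation("t", "chr1", 10_000, 15_000)
        samples = {"t": [_sample("AA", "AA")]}
        assert filter_translocations([tr], samples, [("chr2", 1, 100)]) == [tr]


class TestAbsence:
    def test_all_zero_copy_samples_quiet_validates(self):
        tr = Translocation("t", "chr1", 1, 10_000)
        zero = [_sample("BB", "AA", region=r) for r in (0.25, 0.0, 0.5)]  # ratios .05,0,.1
        assert absence_test(tr, zero + [_sample("AA", "BB")]) == "validated"

    def test_single_zero_copy_sample_is_not_applicable(self):
        tr = Translocation("t", "chr1", 1, 10_000)
        assert absence_test(tr, [_sample("BB", "AA", region=0.0)]) == "not_applicable"

    def test_reads_in_a_zero_copy_sample_fails(self):
        tr = Translocation("t", "chr1", 1, 10_000)
        zero = [_sample("BB", "AA", region=0.25), _sample("BB", "AA", region=2.5)]
        assert absence_test(tr, zero) == "failed"


class TestCopyFit:
    def _tr(self):
        return Translocation("t", "chr1", 1, 10_000)

    def test_perfect_dose_response_validates(self, rng):
        samples = []
        genotypes = [("BB", "AA"), ("BB", "AB"), ("AB", "BB"), ("AA", "AB"), ("AA", "BB")]
        for k in range(20):
            ga, gb = genotypes[k % len(genotypes)]
            c = expected_copy_number(ga, gb)
            samples.append(_sample(ga, gb, region=5.0 * c / 2.0 + rng.normal(0, 0.01)))
        res = copyfit_test([self._tr()], {"t": samples})
        slope, p, p_adj, status = res["t"]
        assert slope == pytest.approx(1.0, abs=0.05)
        assert status == "validated"

    def test_flat_response_fails(self):
        genotypes = [("BB", "AA"), ("AB", "BB"), ("AA", "BB")] * 5
        samples = [_sample(ga, gb, region=5.0) for ga, gb in genotypes]
        res = copyfit_test([self._tr()], {"t": samples})
        slope, _, _, status = res["t"]
        assert abs(slope) < 0.1 and status == "failed"

    def test_two_copy_levels_only_is_not_applicable(self):
        samples = [_sample("BB", "AB", region=2.5), _sample("AB", "BB", region=7.5)] * 3
        res = copyfit_test([self._tr()], {"t": samples})
        assert res["t"][3] == "not_applicable"

    def test_equal_genotype_samples_are_excluded(self):
        # only (AA,AA)/(AB,AB)/(BB,BB) samples -> nothing left to fit
        samples = [_sample(g, g, region=5.0) for g in ("AA", "AB", "BB")] * 3
        res = copyfit_test([self._tr()], {"t": samples})
        assert res["t"][3] == "not_applicable"


class TestClosenessScore:
    def test_identical_points_far_groups_score_zero(self):
        g1 = np.tile([[10.0, 0.0]], (3, 1))
        g2 = np.tile([[0.0, 10.0]], (3, 1))
        assert closeness_score({"a": g1, "b": g2}) == 0.0

    def test_hand_computed_two_group_fixture(self):
        """Two groups of three with unit spread, computed directly from the
        definition on the six points."""
        g1 = np.array([[10.0, 0.0], [11.0, 0.0], [10.0, 1.0]])
        g2 = np.array([[0.0, 10.0], [1.0, 10.0], [0.0, 11.0]])
        expected = 0.0
        for g, other in ((g1, g2), (g2, g1)):
            within = np.mean(
                [np.linalg.norm(g[i] - g[j]) for i in range(3) for j in range(i + 1, 3)]
            )
            between = np.mean([np.linalg.norm(a - b) for a in g for b in other])
            expected += within / between
        assert closeness_score({"a": g1, "b": g2}) == pytest.approx(expected)

    def test_label_permutation_increases_score(self, rng):
        pts = np.vstack([rng.normal(0, 1, (6, 4)), rng.normal(20, 1, (6, 4))])
        true_score = closeness_score({"a": pts[:6], "b": pts[6:]})
        worse = 0
        for _ in range(100):
            perm = rng.permutation(12)
            s = closeness_score({"a": pts[perm[:6]], "b": pts[perm[6:]]})
            worse += s >= true_score
        assert worse >= 95

    def test_scaling_invariance_after_normalization(self, rng):
        counts = rng.poisson(8.0, size=(12, 5, 2)).astype(float)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        n1 = normalize_marker_counts(counts)
        n2 = normalize_marker_counts(counts * 7.0)
        s1 = closeness_score({k: n1[labels == k] for k in "ab"})
        s2 = closeness_score({k: n2[labels == k] for k in "ab"})
        assert s1 == pytest.approx(s2)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            closeness_score({"a": np.zeros((3, 2))})


class TestClusterTest:
    def _tr(self):
        return Translocation("t", "chr1", 1, 10_000)

    def test_single_genotype_class_not_applicable(self, rng):
        samples = [
            _sample("AA", "BB", counts=rng.poisson(5, (5, 2)), sid=f"s{i}") for i in range(6)
        ]
        _, _, status = cluster_test(self._tr(), samples, n_sim=50, seed=1)
        assert status == "not_applicable"

    def test_too_few_markers_not_applicable(self, rng):
        samples = [
            _sample(["AA", "BB"][i % 2], "AB", counts=rng.poisson(5, (2, 2)), sid=f"s{i}")
            for i in range(8)
        ]
        _, _, status = cluster_test(self._tr(), samples, n_sim=50, seed=1)
        assert status == "not_applicable"

    def test_invariant_alt_counts_filtered(self):
        samples = [
            _sample(["AA", "BB"][i % 2], "AB", counts=np.full((4, 2), 3.0), sid=f"s{i}")
            for i in range(8)
        ]
        _, _, status = cluster_test(self._tr(), samples, n_sim=50, seed=1)
        assert status == "not_applicable"

    def test_separated_genotype_clusters_get_low_p(self):
        tr = Translocation("t1", "chr1", 100_000, 104_999)
        samples = {"t1": simulate_f2_population(50, 5.0, tr, seed=9)}
        res = validate_translocations([tr], samples, n_sim=500, seed=10)
        assert res[0].cluster == "validated"


class TestF2Simulation:
    def test_genotype_frequencies_are_mendelian(self):
        samples = simulate_f2_population(10_000, 5.0, seed=1)
        from collections import Counter
        freq = Counter(s.genotype_a for s in samples)
        assert abs(freq["AA"] / 10_000 - 0.25) < 0.02
        assert abs(freq["AB"] / 10_000 - 0.50) < 0.02
        assert abs(freq["BB"] / 10_000 - 0.25) < 0.02

    def test_four_copy_samples_double_their_coverage_ratio(self):
        samples = simulate_f2_population(4000, 10.0, seed=2)
        four = [s.coverage_ratio for s in samples if (s.genotype_a, s.genotype_b) == ("AA", "BB")]
        assert np.mean(four) == pytest.approx(2.0, abs=0.05)

    def test_full_pipeline_recovers_unit_slope(self):
        tr = Translocation("t1", "chr1", 100_000, 104_999)
        samples = {"t1": simulate_f2_population(50, 5.0, tr, seed=9)}
        res = validate_translocations([tr], samples, n_sim=500, seed=10)
        assert 0.9 <= res[0].slope <= 1.1
        assert res[0].copyfit == "validated"
        assert res[0].confirmed


def test_bh_adjustment_is_monotone_and_never_decreases_p(rng):
    p = rng.uniform(0, 1, 40)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    assert np.all(p_adj >= p - 1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(p_adj[order]) >= -1e-12)
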