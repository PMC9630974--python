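import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuemix.decomposition import (
    VERDICT_NON_PGE,
    VERDICT_PGE,
    decompose_depth_pairs,
    decompose_heterozygous,
    expected_misassignment,
    pge_test,
)
from tissuemix.formats import AlleleDepthRecord


def het_records(pairs, chrom="autosome"):
    return [
        AlleleDepthRecord("s", i + 1, "heterozygous", a, b, 30.0, chrom)
        for i, (a, b) in enumerate(pairs)
    ]


class TestDecompose:
    def test_major_minor_by_definition(self):
        major, minor = decompose_heterozygous(het_records([(10, 5), (3, 9), (7, 7)]))
        assert major.tolist() == [10, 9, 7]
        assert minor.tolist() == [5, 3, 7]

    def test_ties_contribute_to_both(self):
        major, minor = decompose_heterozygous(het_records([(4, 4), (6, 6)]))
        assert major.tolist() == minor.tolist() == [4, 6]

    def test_non_autosomal_records_ignored(self):
        records = het_records([(10, 5)]) + het_records([(50, 40)], chrom="X")
        major, _ = decompose_heterozygous(records)
        assert major.tolist() == [10]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no heterozygous"):
            decompose_heterozygous([])

    @given(
        st.lists(
            st.tuples(st.integers(1, 200), st.integers(1, 200)), min_size=1, max_size=50
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_invariant_to_ref_alt_swap(self, pairs):
        fwd = decompose_heterozygous(het_records(pairs))
        swapped = decompose_heterozygous(het_records([(b, a) for a, b in pairs]))
        assert fwd[0].tolist() == swapped[0].tolist()
        assert fwd[1].tolist() == swapped[1].tolist()


class TestExpectedMisassignment:
    def test_equal_means_is_half_by_symmetry(self):
        assert expected_misassignment(14.0, 14.0, 15.0) == pytest.approx(0.5, abs=1e-9)

    def test_vanishing_paternal_coverage(self):
        assert expected_misassignment(17.44, 1e-4, 15.0) < 1e-3

    def test_monotone_in_coverage_ratio(self):
        vals = [expected_misassignment(17.44, c, 15.0) for c in (5.0, 9.0, 13.0, 17.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_monotone_in_overdispersion(self):
        vals = [expected_misassignment(17.44, 11.29, s) for s in (5.0, 15.0, 50.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_matches_monte_carlo(self, rng):
        n = 200_000
        mat = rng.negative_binomial(15, 15 / (15 + 17.44), n)
        pat = rng.negative_binomial(15, 15 / (15 + 11.29), n)
        mc = np.mean(pat > mat) + 0.5 * np.mean(pat == mat)
        se = np.sqrt(mc * (1 - mc) / n)
        assert expected_misassignment(17.44, 11.29, 15.0) == pytest.approx(mc, abs=3 * se)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            expected_misassignment(10.0, 12.0, 15.0)
        with pytest.raises(ValueError):
            expected_misassignment(10.0, 5.0, 0.0)


class TestPgeTestToy:
    def test_x_matching_major_is_pge_like(self, rng):
        major = rng.negative_binomial(15, 15 / (15 + 17.44), 3000)
        minor = rng.negative_binomial(15, 15 / (15 + 11.29), 3000)
        xhom = rng.negative_binomial(15, 15 / (15 + 17.44), 2000)
        res = pge_test(np.maximum(major, minor), np.minimum(major, minor), xhom)
        assert res.position_index <= 0.25
        assert res.verdict == VERDICT_PGE
        assert res.d_major_x < res.d_minor_x

    def test_x_midway_is_non_pge_like(self, rng):
        # X0 male: both alleles from one distribution, X at its centre
        a = rng.negative_binomial(15, 15 / (15 + 14.35), 5000)
        b = rng.negative_binomial(15, 15 / (15 + 14.35), 5000)
        xhom = rng.negative_binomial(15, 15 / (15 + 14.35), 2000)
        res = pge_test(np.maximum(a, b), np.minimum(a, b), xhom)
        assert res.position_index == pytest.approx(0.5, abs=0.15)
        assert res.verdict == VERDICT_NON_PGE

    def test_identical_medians_is_non_pge(self):
        depths = np.full(500, 20)
        res = pge_test(depths, depths, depths)
        assert res.position_index is None
        assert res.verdict == VERDICT_NON_PGE

    def test_undersized_samples_rejected(self):
        small = np.full(50, 20)
        with pytest.raises(ValueError, match="fewer"):
            pge_test(small, small, np.full(500, 20))


class TestSimulatedVerdicts:
    def test_pge_fixture_is_pge_like(self, pge_sample):
        major, minor = decompose_heterozygous(pge_sample.records)
        xhom = [
            r.depth_alt
            for r in pge_sample.records
            if r.genotype_class == "homozygous_alt" and r.chrom_class == "X"
        ]
        res = pge_test(major, minor, xhom)
        assert res.verdict == VERDICT_PGE
        assert res.position_index <= 0.25

    def test_x0_fixture_is_non_pge_like(self, x0_sample):
        major, minor = decompose_heterozygous(x0_sample.records)
        xhom = [
            r.depth_alt
            for r in x0_sample.records
            if r.genotype_class == "homozygous_alt" and r.chrom_class == "X"
        ]
        res = pge_test(major, minor, xhom)
        assert res.verdict == VERDICT_NON_PGE
        assert res.position_index >= 0.4
        # in an X0 male the decomposition misassigns ~half the sites
        assert res.expected_misassignment == pytest.approx(0.5, abs=0.02)

    def test_x0_truth_misassignment_is_half(self, x0_sample):
        """Ground truth: paternal draw beats maternal at ~50% of sites."""
        mat, pat = x0_sample.maternal_depths, x0_sample.paternal_depths
        assert mat.size >= 10_000
        frac = np.mean(pat > mat) + 0.5 * np.mean(pat == mat)
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_pge_truth_misassignment_matches_model(self, pge_sample):
        """Observed flip rate in the simulation equals the NB model prediction."""
        mat, pat = pge_sample.maternal_depths, pge_sample.paternal_depths
        frac = np.mean(pat > mat) + 0.5 * np.mean(pat == mat)
        cfg = pge_sample.config
        model = expected_misassignment(cfg.c_maternal, cfg.c_paternal, cfg.nb_size)
        se = np.sqrt(model * (1 - model) / mat.size)
        assert frac == pytest.approx(model, abs=4 * se)
        assert np.mean(decompose_depth_pairs(mat, pat)[0]) > np.mean(pat)

    def test_verdicts_stable_under_bootstrap(self, pge_sample, x0_sample, rng):
        for sample, expected in ((pge_sample, VERDICT_PGE), (x0_sample, VERDICT_NON_PGE)):
            major, minor = decompose_heterozygous(sample.records)
            xhom = np.array(
                [
                    r.depth_alt
                    for r in sample.records
                    if r.genotype_class == "homozygous_alt" and r.chrom_class == "X"
                ]
            )
            agree = 0
            n_boot = 100
            for _ in range(n_boot):
                idx = rng.integers(0, major.size, major.size)
                xidx = rng.integers(0, xhom.size, xhom.size)
                res = pge_test(major[idx], minor[idx], xhom[xidx])
                agree += res.verdict == expected
            assert agree >= 0.9 * n_boot
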