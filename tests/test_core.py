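"""HAC distances, distributions, the variance estimator and Svd."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hacsweep.core import (
    HaplotypeWindow,
    MalformedInputError,
    ReferenceHaplotype,
    SiteAnnotation,
    build_marh,
    encode_window,
    extract_centered_window,
    hac_distance,
    hac_distribution,
    hac_variance,
    split_by_allele,
    svd_at_site,
    vd_at_site,
)


def brute_variance(values, ddof=1):
    """Independent two-pass oracle for the sample variance."""
    values = [float(v) for v in values]
    mean = sum(values) / len(values)
    return sum((v - mean) ** 2 for v in values) / (len(values) - ddof)


class TestHacVariance:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([2, 2, 2, 2], 0.0),
            ([0, 1, 2, 3], 5.0 / 3.0),
            ([0, 10], 50.0),
            ([1, 3, 5], 4.0),
        ],
    )
    def test_known_values(self, values, expected):
        assert hac_variance(values) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.integers(min_value=0, max_value=200), min_size=2, max_size=60))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_matches_brute_force_oracle(self, values):
        assert hac_variance(values) == pytest.approx(
            brute_variance(values), rel=1e-12, abs=1e-12
        )

    def test_denominator_switch(self):
        vals = [0, 1, 2, 3]
        assert hac_variance(vals, ddof=0) == pytest.approx(brute_variance(vals, ddof=0))

    def test_undefined_below_two(self):
        with pytest.raises(ValueError):
            hac_variance([3])


class TestHacDistance:
    def test_identity_symmetry_bounds(self, random_window_factory):
        win = random_window_factory(n=10, S=15)
        ref = build_marh(win)
        assert hac_distance(ref.alleles, ref) == 0
        for row in win.alleles:
            d = hac_distance(row, ref)
            assert 0 <= d <= win.S
            assert d == hac_distance(ref.alleles, ReferenceHaplotype(row))

    def test_full_complement_is_maximal(self):
        ref = ReferenceHaplotype(np.zeros(51, dtype=np.uint8))
        assert hac_distance(np.ones(51, dtype=np.uint8), ref) == 51

    def test_count_of_differences(self):
        ref = ReferenceHaplotype(np.zeros(8, dtype=np.uint8))
        hap = np.zeros(8, dtype=np.uint8)
        hap[[1, 4, 6]] = 1
        assert hac_distance(hap, ref) == 3

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hac_distance(np.zeros(3, np.uint8), ReferenceHaplotype(np.zeros(4, np.uint8)))


class TestHacDistribution:
    def test_copies_of_reference(self):
        ref = ReferenceHaplotype(np.array([0, 1, 0], dtype=np.uint8))
        rows = np.tile(ref.alleles, (5, 1))
        dist = hac_distribution(rows, ref)
        assert dist.counts[0] == 5 and dist.counts.sum() == 5
        assert dist.mean == 0.0 and dist.variance == 0.0

    def test_mean_and_unbiased_variance(self):
        # HAC multiset {1, 3, 5} against the all-zero reference
        ref = ReferenceHaplotype(np.zeros(6, dtype=np.uint8))
        rows = np.zeros((3, 6), dtype=np.uint8)
        rows[0, :1] = 1
        rows[1, :3] = 1
        rows[2, :5] = 1
        dist = hac_distribution(rows, ref)
        assert dist.mean == pytest.approx(3.0)
        assert dist.variance == pytest.approx(4.0)

    def test_single_haplotype_variance_undefined(self):
        ref = ReferenceHaplotype(np.zeros(4, dtype=np.uint8))
        dist = hac_distribution(np.ones((1, 4), dtype=np.uint8), ref)
        assert dist.mean == 4.0 and dist.variance is None

    def test_empty_rejected(self):
        ref = ReferenceHaplotype(np.zeros(4, dtype=np.uint8))
        with pytest.raises(ValueError):
            hac_distribution(np.zeros((0, 4), dtype=np.uint8), ref)

    def test_subsample_counts_conserve_window_distribution(self, random_window_factory):
        win = random_window_factory()
        ref = build_marh(win)
        full = hac_distribution(win.alleles, ref)
        for k in range(win.S):
            major, minor = split_by_allele(win, k, ref)
            counts = np.zeros_like(full.counts)
            for rows in (major, minor):
                if rows.shape[0]:
                    counts += hac_distribution(rows, ref).counts
            assert np.array_equal(counts, full.counts)


class TestMarh:
    def test_majority_allele_and_tie_rule(self, toy_window):
        ref = build_marh(toy_window)
        # derived freqs: 1/3, 2/3, 1/6, 1/2, 5/6 -> major: anc, der, anc, tie->anc, der
        assert ref.alleles.tolist() == [0, 1, 0, 0, 1]
        assert ref.tie_sites == {3}

    def test_below_majority_site_carries_ancestral(self):
        alleles = np.array([[1], [1], [1], [0], [0], [0], [0], [0], [0], [0]], np.uint8)
        win = HaplotypeWindow(alleles=alleles, positions=np.array([0.0]))
        assert build_marh(win).alleles[0] == 0  # derived_freq 0.3

    def test_empty_window_rejected(self):
        with pytest.raises(MalformedInputError):
            build_marh(HaplotypeWindow(np.zeros((0, 0), np.uint8), np.array([])))


class TestEncodeWindow:
    def ann(self, i, anc="A", der="G"):
        return SiteAnnotation(f"s{i}", float(i), anc, der, derived_freq=0.0)

    def test_recode_and_frequencies(self):
        win = encode_window(
            [["A", "G"], ["G", "G"], ["A", "G"], ["A", "A"]],
            [self.ann(0), self.ann(1)],
        )
        assert win.alleles[:, 0].tolist() == [0, 1, 0, 0]
        assert win.derived_freq().tolist() == [0.25, 0.75]

    def test_two_by_one(self):
        win = encode_window([["A"], ["G"]], [self.ann(0)])
        assert win.alleles.ravel().tolist() == [0, 1]
        assert win.derived_freq()[0] == 0.5

    def test_non_segregating_rejected(self):
        with pytest.raises(MalformedInputError, match="not segregating"):
            encode_window([["A"], ["A"]], [self.ann(0)])

    def test_unknown_symbol_names_site(self):
        with pytest.raises(MalformedInputError, match="s0"):
            encode_window([["T"], ["G"]], [self.ann(0)])


class TestSplitAndSvd:
    def test_split_partition(self, toy_window):
        ref = build_marh(toy_window)
        for k in range(toy_window.S):
            major, minor = split_by_allele(toy_window, k, ref)
            assert major.shape[0] + minor.shape[0] == toy_window.n
            assert major.shape[0] >= minor.shape[0] or k in ref.tie_sites

    def test_major_count_matches_frequency(self):
        # derived at 0.75 and on the MARH: |R_k| = 0.75 n
        alleles = np.zeros((8, 3), dtype=np.uint8)
        alleles[:6, 1] = 1
        alleles[0, 0] = 1
        alleles[1, 2] = 1
        win = HaplotypeWindow(alleles=alleles, positions=np.arange(3.0))
        ref = build_marh(win)
        major, minor = split_by_allele(win, 1, ref)
        assert major.shape[0] == 6 and minor.shape[0] == 2

    def _constructed_window(self):
        """n=12, S=51: site k=25 derived in 9 rows (f_d = 0.75).

        The 9 derived carriers equal the MARH exactly (HAC 0); the other 3
        rows carry the ancestral allele at k plus 0/2/4 extra minor alleles,
        i.e. HACs {1, 3, 5}.
        """
        n, S, k = 12, 51, 25
        alleles = np.zeros((n, S), dtype=np.uint8)
        alleles[:9, k] = 1  # derived major at the evaluated site
        alleles[10, [0, 1]] = 1
        alleles[11, [2, 3, 4, 5]] = 1
        return HaplotypeWindow(alleles=alleles, positions=np.arange(S, dtype=float)), k

    def test_vd_from_constructed_classes(self):
        win, k = self._constructed_window()
        res = vd_at_site(win, k)
        assert res.defined
        assert res.n_major == 9 and res.n_minor == 3
        assert res.var_major == pytest.approx(0.0)
        assert res.var_minor == pytest.approx(4.0)  # brute force over {1,3,5}
        assert res.vd == pytest.approx(4.0)

    def test_svd_weighting_and_normalisation(self):
        win, k = self._constructed_window()
        res = svd_at_site(win, k)
        assert res.svd == pytest.approx(0.75 * 4.0 / 51.0)  # ~0.05882
        assert res.svd == pytest.approx(0.0588235294, abs=1e-9)

    def test_identical_multisets_give_zero(self):
        alleles = np.zeros((8, 5), dtype=np.uint8)
        alleles[:4, 0] = 1  # tie at evaluated site -> R carries ancestral
        alleles[[0, 4], 2] = 1  # one extra minor allele in each class
        win = HaplotypeWindow(alleles=alleles, positions=np.arange(5.0))
        res = vd_at_site(win, 0)
        assert res.defined and res.vd == pytest.approx(0.0)

    def test_small_class_flagged_undefined(self):
        alleles = np.zeros((8, 4), dtype=np.uint8)
        alleles[0, 1] = 1  # singleton at evaluated site
        alleles[:, 2] = [1, 1, 1, 1, 1, 0, 0, 0]
        win = HaplotypeWindow(alleles=alleles, positions=np.arange(4.0))
        res = svd_at_site(win, 1)
        assert not res.defined and res.svd is None and res.vd is None

    def test_zero_vd_gives_zero_svd_any_freq(self):
        alleles = np.zeros((8, 5), dtype=np.uint8)
        alleles[:4, 0] = 1
        alleles[[0, 4], 2] = 1
        win = HaplotypeWindow(alleles=alleles, positions=np.arange(5.0))
        assert svd_at_site(win, 0).svd == pytest.approx(0.0)

    def test_full_brute_force_agreement_on_random_windows(self, random_window_factory):
        for _ in range(20):
            win = random_window_factory(n=14, S=12)
            ref = build_marh(win)
            for k in range(win.S):
                res = svd_at_site(win, k, ref)
                h = np.count_nonzero(win.alleles != ref.alleles[None, :], axis=1)
                in_major = win.alleles[:, k] == ref.alleles[k]
                if in_major.sum() < 2 or (~in_major).sum() < 2:
                    assert not res.defined
                    continue
                vd = brute_variance(h[~in_major]) - brute_variance(h[in_major])
                f_d = win.alleles[:, k].mean()
                assert res.vd == pytest.approx(vd, abs=1e-9)
                assert res.svd == pytest.approx(f_d * vd / win.S, abs=1e-9)

    def test_coding_swap_of_non_evaluated_site_invariant(self, random_window_factory):
        """Flipping 0<->1 at a non-evaluated site (a relabelling of which
        allele is called derived there) must not move vd or the HACs, since
        the majority allele is unchanged as a physical object."""
        for _ in range(10):
            win = random_window_factory(n=14, S=10)
            k = 4
            base = vd_at_site(win, k)
            j = 7
            if win.alleles[:, j].sum() * 2 == win.n:
                continue  # a tie would legitimately change the tie-rule call
            flipped = win.alleles.copy()
            flipped[:, j] ^= 1
            win2 = HaplotypeWindow(alleles=flipped, positions=win.positions)
            other = vd_at_site(win2, k)
            assert base.defined == other.defined
            if base.defined:
                assert base.vd == pytest.approx(other.vd, abs=1e-9)

    def test_include_evaluated_flag(self):
        win, k = self._constructed_window()
        with_site = svd_at_site(win, k, include_evaluated=True)
        without = svd_at_site(win, k, include_evaluated=False)
        # excluding the evaluated column removes exactly one difference from
        # every minor-class haplotype: variance of {0,2,4} instead of {1,3,5}
        assert without.vd == pytest.approx(with_site.vd)
        assert without.svd == pytest.approx(0.75 * 4.0 / 51.0)


class TestWindowExtraction:
    def test_centering(self):
        win = HaplotypeWindow(
            alleles=np.zeros((4, 11), np.uint8) ^ np.eye(4, 11, dtype=np.uint8),
            positions=np.arange(11.0),
            evaluated_index=5,
        )
        sub = extract_centered_window(win, 5)
        assert sub.S == 5 and sub.evaluated_index == 2
        assert sub.positions.tolist() == [3.0, 4.0, 5.0, 6.0, 7.0]

    def test_even_window_center_convention(self):
        win = HaplotypeWindow(
            alleles=np.eye(4, 10, dtype=np.uint8),
            positions=np.arange(10.0),
            evaluated_index=5,
        )
        sub = extract_centered_window(win, 4)
        assert sub.evaluated_index == 2 and sub.S == 4

    def test_insufficient_flank_raises(self):
        win = HaplotypeWindow(
            alleles=np.eye(4, 7, dtype=np.uint8),
            positions=np.arange(7.0),
            evaluated_index=1,
        )
        with pytest.raises(ValueError):
            extract_centered_window(win, 5)


class TestHacScaling:
    def test_neutral_mean_svd_not_positive(self, neutral_reps):
        """Under neutrality the HAC variance difference centres at or below
        zero (the major class is bigger, hence if anything more diverse)."""
        vals = []
        for rep in neutral_reps.replicates:
            win = extract_centered_window(rep, 51)
            res = svd_at_site(win, win.evaluated_index)
            if res.defined:
                vals.append(res.svd)
        vals = np.asarray(vals)
        assert vals.size > 100
        mc_se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert vals.mean() <= 3 * mc_se

    def test_hac_variance_growth_tamed_by_normalisation(self, neutral_reps):
        """Dividing vd by S must remove most of the window-size dependence.

        Without recombination a window shares one genealogy, so minor-allele
        indicators stay correlated at any distance and the HAC variance
        grows faster than linearly in S (close to S² in the worst case);
        linkage decay only brings it towards O(S).  The usable property is
        that growth is clearly sub-quadratic, so var/S (the Svd scale) moves
        far less across S = 26..201 than the raw variance does.
        """
        mean_var = {}
        for S in (26, 51, 201):
            vs = []
            for rep in neutral_reps.replicates:
                win = extract_centered_window(rep, S)
                ref = build_marh(win)
                h = np.count_nonzero(win.alleles != ref.alleles[None, :], axis=1)
                vs.append(np.var(h, ddof=1))
            mean_var[S] = np.mean(vs)
        assert mean_var[26] < mean_var[51] < mean_var[201]
        slope = np.polyfit(
            np.log([26, 51, 201]), np.log([mean_var[S] for S in (26, 51, 201)]), 1
        )[0]
        assert slope < 2.0
        raw_spread = mean_var[201] / mean_var[26]
        norm_spread = (mean_var[201] / 201) / (mean_var[26] / 26)
        assert norm_spread < raw_spread / 2
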