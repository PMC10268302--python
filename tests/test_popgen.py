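"""Diversity/divergence statistics against brute-force pairwise oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clonintro.core_io import MISSING, make_windows
from clonintro.popgen_stats import (
    dxy_difference,
    pairwise_pi_hat,
    pbs,
    sample_heterozygosity,
    window_dxy,
    window_fst,
    window_pi,
)
from conftest import make_gm


# ---------------------------------------------------------------------------
# independent oracles: enumerate haplotype pairs explicitly
# ---------------------------------------------------------------------------

def haplotype_multiset(dosages):
    """Expand non-missing diploid dosages into a 0/1 haplotype list."""
    haps = []
    for d in dosages:
        if d == MISSING:
            continue
        haps.extend([1] * d + [0] * (2 - d))
    return haps


def brute_pi_site(dosages):
    haps = haplotype_multiset(dosages)
    if len(haps) < 2:
        return np.nan
    pairs = list(itertools.combinations(range(len(haps)), 2))
    return sum(haps[i] != haps[j] for i, j in pairs) / len(pairs)


def brute_dxy_site(dos_a, dos_b):
    ha, hb = haplotype_multiset(dos_a), haplotype_multiset(dos_b)
    if not ha or not hb:
        return np.nan
    return sum(x != y for x in ha for y in hb) / (len(ha) * len(hb))


def brute_hudson_site(dos_a, dos_b):
    """Hudson numerator/denominator from pairwise heterozygosities."""
    hb = brute_dxy_site(dos_a, dos_b)
    hwa, hwb = brute_pi_site(dos_a), brute_pi_site(dos_b)
    if np.isnan(hb) or np.isnan(hwa) or np.isnan(hwb):
        return np.nan, np.nan
    return hb - (hwa + hwb) / 2.0, hb


def random_toy_gm(rng, n_sites=20, n_samples=8, p_missing=0.1):
    dos = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    dos[rng.random((n_sites, n_samples)) < p_missing] = MISSING
    return make_gm(dos, pos=np.arange(1, n_sites + 1) * 40)


WINDOWS_1K = {"chr1": 1000}


class TestHeterozygosity:
    def test_fraction_of_all_snps(self):
        dos = np.zeros((10, 2), dtype=np.int8)
        dos[:3, 0] = 1
        dos[3, 0] = 2
        het = sample_heterozygosity(make_gm(dos))
        assert het["s0"] == pytest.approx(0.3)
        assert het["s1"] == 0.0

    def test_called_denominator_excludes_missing(self):
        dos = np.array([[1], [1], [MISSING], [0]], dtype=np.int8)
        gm = make_gm(dos)
        assert sample_heterozygosity(gm, "all_sites")["s0"] == pytest.approx(0.5)
        assert sample_heterozygosity(gm, "called")["s0"] == pytest.approx(2 / 3)

    def test_invariant_to_site_order(self):
        rng = np.random.default_rng(0)
        gm = random_toy_gm(rng)
        perm = rng.permutation(gm.n_sites)
        shuffled = make_gm(gm.dosage[perm], pos=np.arange(1, gm.n_sites + 1) * 40)
        pd.testing.assert_series_equal(sample_heterozygosity(gm),
                                       sample_heterozygosity(shuffled))

    def test_zero_sites_errors(self):
        gm = make_gm(np.zeros((0, 1)), pos=np.array([], dtype=int),
                     chrom=np.array([], dtype=object))
        with pytest.raises(ValueError):
            sample_heterozygosity(gm)


class TestWindowPi:
    def test_two_diploid_example(self):
        # one site, derived count 2 of 4 haplotypes, 1000-bp window
        gm = make_gm([[1, 1]], pos=[500])
        win = make_windows(WINDOWS_1K, 1000, 1, gm)
        res = window_pi(gm, np.array([0, 1]), win)
        assert res["pi"][0] == pytest.approx(2 * 0.5 * 0.5 * (4 / 3) / 1000)
        assert res["pi"][0] == pytest.approx(brute_pi_site([1, 1]) / 1000)

    def test_monomorphic_window_is_zero(self):
        gm = make_gm([[2, 2], [0, 0]], pos=[10, 20])
        win = make_windows(WINDOWS_1K, 1000, 1, gm)
        assert window_pi(gm, np.array([0, 1]), win)["pi"][0] == 0.0

    def test_per_bp_normalization_halves_with_doubled_length(self):
        gm = make_gm([[1, 1]], pos=[500])
        win1 = make_windows({"chr1": 1000}, 1000, 1, gm)
        win2 = make_windows({"chr1": 2000}, 2000, 1, gm)
        pi1 = window_pi(gm, np.array([0, 1]), win1)["pi"][0]
        pi2 = window_pi(gm, np.array([0, 1]), win2)["pi"][0]
        assert pi2 == pytest.approx(pi1 / 2)

    def test_matches_brute_force_with_missing_data(self):
        rng = np.random.default_rng(1)
        gm = random_toy_gm(rng)
        win = make_windows(WINDOWS_1K, 1000, 1, gm)
        res = window_pi(gm, np.arange(8), win)
        expected = np.nansum([brute_pi_site(gm.dosage[i]) for i in range(gm.n_sites)])
        assert res["pi"][0] == pytest.approx(expected / 1000)


class TestWindowDxy:
    def test_fixed_difference(self):
        gm = make_gm([[0, 0, 2, 2]], pos=[50])
        win = make_windows({"chr1": 100}, 100, 1, gm)
        res = window_dxy(gm, np.array([0, 1]), np.array([2, 3]), win)
        assert res["dxy"][0] == pytest.approx(0.01)

    def test_group_against_itself_equals_2pq(self):
        gm = make_gm([[1, 1]], pos=[500])
        win = make_windows(WINDOWS_1K, 1000, 1, gm)
        res = window_dxy(gm, np.array([0, 1]), np.array([0, 1]), win)
        assert res["dxy"][0] == pytest.approx(2 * 0.5 * 0.5 / 1000)

    def test_difference_zero_when_identical_and_subtracts(self):
        gm = random_toy_gm(np.random.default_rng(2), p_missing=0.0)
        win = make_windows(WINDOWS_1K, 1000, 1, gm)
        a = window_dxy(gm, np.arange(4), np.array([4, 5, 6, 7]), win)
        diff = dxy_difference(a, a)
        assert diff["dxy_difference"][0] == 0.0
        b = a.copy()
        b["dxy"] = a["dxy"] + 0.002
        assert dxy_difference(a, b)["dxy_difference"][0] == pytest.approx(-0.002)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        gm = random_toy_gm(rng)
        win = make_windows(WINDOWS_1K, 1000, 1, gm)
        ia, ib = np.arange(4), np.arange(4, 8)
        res = window_dxy(gm, ia, ib, win)
        expected = np.nansum([brute_dxy_site(gm.dosage[i, ia], gm.dosage[i, ib])
                              for i in range(gm.n_sites)])
        assert res["dxy"][0] == pytest.approx(expected / 1000)

    def test_mismatched_windows_error(self):
        gm = random_toy_gm(np.random.default_rng(4))
        win = make_windows(WINDOWS_1K, 1000, 1, gm)
        a = window_dxy(gm, np.arange(4), np.arange(4, 8), win)
        b = a.copy()
        b["start"] += 1
        with pytest.raises(ValueError):
            dxy_difference(a, b)


class TestHudsonFst:
    def test_hand_evaluated_single_site(self):
        # pA=0.8, pB=0.2, nA=nB=10 haplotypes
        dos_a = [2, 2, 2, 1, 1]   # 8/10 derived
        dos_b = [1, 1, 0, 0, 0]   # 2/10 derived
        gm = make_gm([dos_a + dos_b], pos=[500])
        win = make_windows(WINDOWS_1K, 1000, 1, gm)
        res = window_fst(gm, np.arange(5), np.arange(5, 10), win)
        num = 0.36 - 0.16 / 9 - 0.16 / 9
        assert res["fst"][0] == pytest.approx(num / 0.68)
        assert res["fst"][0] == pytest.approx(0.4771, abs=1e-4)

    def test_equal_intermediate_freqs_give_small_negative(self):
        dos = [1, 1, 1, 1, 1]
        gm = make_gm([dos + dos], pos=[500])
        win = make_windows(WINDOWS_1K, 1000, 1, gm)
        res = window_fst(gm, np.arange(5), np.arange(5, 10), win)
        expected = (0.0 - 0.25 / 9 - 0.25 / 9) / 0.5
        assert res["fst"][0] == pytest.approx(expected)
        assert res["fst"][0] < 0

    def test_fixed_difference_approaches_one(self):
        gm = make_gm([[2] * 10 + [0] * 10], pos=[500])
        win = make_windows(WINDOWS_1K, 1000, 1, gm)
        res = window_fst(gm, np.arange(10), np.arange(10, 20), win)
        assert res["fst"][0] == pytest.approx(1.0)

    def test_ratio_of_sums_matches_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        gm = random_toy_gm(rng)
        win = make_windows(WINDOWS_1K, 1000, 1, gm)
        ia, ib = np.arange(4), np.arange(4, 8)
        res = window_fst(gm, ia, ib, win)
        nums, dens = [], []
        for i in range(gm.n_sites):
            n, d = brute_hudson_site(gm.dosage[i, ia], gm.dosage[i, ib])
            if np.isfinite(n):
                nums.append(n)
                dens.append(d)
        assert res["fst"][0] == pytest.approx(sum(nums) / sum(dens))

    def test_zero_denominator_is_nan(self):
        gm = make_gm([[0, 0, 0, 0]], pos=[500])
        win = make_windows(WINDOWS_1K, 1000, 1, gm)
        res = window_fst(gm, np.array([0, 1]), np.array([2, 3]), win)
        assert np.isnan(res["fst"][0])


def fst_frame(values):
    df = pd.DataFrame({"chrom": "c", "start": np.arange(len(values)) * 10,
                       "end": (np.arange(len(values)) + 1) * 10})
    df["fst"] = values
    return df


class TestPbs:
    def test_formula_example(self):
        res = pbs(fst_frame([0.1]), fst_frame([0.1]), fst_frame([0.0]))
        assert res["pbs"][0] == pytest.approx((2 * -np.log(0.9)) / 2)
        assert res["pbs"][0] == pytest.approx(0.10536, abs=1e-5)

    def test_all_zero(self):
        res = pbs(fst_frame([0.0]), fst_frame([0.0]), fst_frame([0.0]))
        assert res["pbs"][0] == 0.0

    def test_symmetric_in_non_focal_branches(self):
        a, b, c = fst_frame([0.3]), fst_frame([0.1]), fst_frame([0.05])
        assert pbs(a, b, c)["pbs"][0] == pytest.approx(pbs(b, a, c)["pbs"][0])

    def test_star_topology_identical_for_every_focal_choice(self):
        f = fst_frame([0.2])
        vals = {pbs(f, f, f)["pbs"][0] for _ in range(3)}
        assert len(vals) == 1

    def test_fst_one_flagged(self):
        res = pbs(fst_frame([1.0]), fst_frame([0.1]), fst_frame([0.1]))
        assert not np.isfinite(res["pbs"][0])
        assert res["flagged"][0]


class TestPiHat:
    @staticmethod
    def cohort(rng, n_ind=40, n_sites=3000):
        p = rng.uniform(0.1, 0.9, n_sites)
        dos = rng.binomial(2, p[:, None], size=(n_sites, n_ind)).astype(np.int8)
        return p, dos

    def test_duplicated_sample_is_one(self):
        rng = np.random.default_rng(6)
        _, dos = self.cohort(rng, n_ind=20, n_sites=500)
        dos = np.column_stack([dos, dos[:, 0]])
        gm = make_gm(dos, pos=np.arange(1, 501) * 7)
        (res,) = pairwise_pi_hat(gm, [("s0", "s20")])
        assert res.pi_hat == pytest.approx(1.0, abs=1e-6)

    def test_unrelated_near_zero(self):
        rng = np.random.default_rng(7)
        _, dos = self.cohort(rng)
        gm = make_gm(dos, pos=np.arange(1, 3001) * 7)
        (res,) = pairwise_pi_hat(gm, [("s0", "s1")])
        assert res.pi_hat == pytest.approx(0.0, abs=0.05)

    def test_parent_offspring_near_half(self):
        rng = np.random.default_rng(8)
        p, dos = self.cohort(rng)
        transmitted = rng.binomial(1, dos[:, 0] / 2.0)
        other = rng.binomial(1, p)
        dos = np.column_stack([dos, (transmitted + other).astype(np.int8)])
        gm = make_gm(dos, pos=np.arange(1, 3001) * 7)
        (res,) = pairwise_pi_hat(gm, [("s0", "s40")])
        assert res.pi_hat == pytest.approx(0.5, abs=0.05)

    def test_low_confidence_flag(self):
        rng = np.random.default_rng(9)
        _, dos = self.cohort(rng, n_ind=10, n_sites=30)
        gm = make_gm(dos, pos=np.arange(1, 31) * 7)
        (res,) = pairwise_pi_hat(gm, [("s0", "s1")])
        assert res.low_confidence
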