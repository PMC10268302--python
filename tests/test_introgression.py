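"""ABBA-BABA family statistics against per-site loop oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonintro.core_io import PopulationMap, RegionSet, make_windows
from clonintro.intro_stats import (
    SiteFreqs,
    d_jackknife,
    f4_admixture_ratio,
    fbranch,
    genes_per_fd_bin,
    top_quantile_regions,
    trio_site_freqs,
    window_abba_baba,
)
from conftest import make_gm


def freqs_from_arrays(p1, p2, p3, p4=None, spacing=40):
    n = len(p1)
    if p4 is None:
        p4 = np.zeros(n)
    return SiteFreqs(chrom=np.asarray(["chr1"] * n, dtype=object),
                     pos=np.arange(1, n + 1) * spacing,
                     p1=np.asarray(p1, float), p2=np.asarray(p2, float),
                     p3=np.asarray(p3, float), p4=np.asarray(p4, float))


def brute_window_stats(freqs):
    """Per-site python-loop evaluation of D, fd, fdM sums."""
    s_abba = s_baba = s_fd = s_fdm = 0.0
    for p1, p2, p3, p4 in zip(freqs.p1, freqs.p2, freqs.p3, freqs.p4):
        abba = (1 - p1) * p2 * p3 * (1 - p4)
        baba = p1 * (1 - p2) * p3 * (1 - p4)
        s_abba += abba
        s_baba += baba
        pd_ = max(p2, p3)
        s_fd += (1 - p1) * pd_ * pd_ * (1 - p4) - p1 * (1 - pd_) * pd_ * (1 - p4)
        if p2 >= p1:
            dm = max(p2, p3)
            s_fdm += (1 - p1) * dm * dm * (1 - p4) - p1 * (1 - dm) * dm * (1 - p4)
        else:
            dm = max(p1, p3)
            s_fdm -= (1 - dm) * p2 * dm * (1 - p4) - dm * (1 - p2) * dm * (1 - p4)
    num = s_abba - s_baba
    d = num / (s_abba + s_baba) if s_abba + s_baba > 0 else np.nan
    fd = num / s_fd if num > 0 and s_fd > 0 else np.nan
    fdm = num / s_fdm if s_fdm > 0 else np.nan
    return d, fd, fdm


ONE_KB = {"chr1": 1000}


class TestTrioSiteFreqs:
    def test_frequency_counting(self):
        # columns: P1 x2, P2 x2, P3 x1, O x1
        gm = make_gm([[0, 0, 1, 2, 2, 0]], pos=[100],
                     sample_ids=["a1", "a2", "b1", "b2", "c1", "o1"])
        pm = PopulationMap({"a1": "P1", "a2": "P1", "b1": "P2", "b2": "P2",
                            "c1": "P3", "o1": "O"})
        fr = trio_site_freqs(gm, pm, ("P1", "P2", "P3", "O"))
        assert fr.p1[0] == 0.0
        assert fr.p2[0] == pytest.approx(0.75)
        assert fr.p3[0] == 1.0
        assert fr.p4[0] == 0.0

    def test_fully_missing_group_excluded(self):
        gm = make_gm([[0, -1, 1, 0], [1, 1, 1, 0]], pos=[100, 200],
                     sample_ids=["a1", "b1", "c1", "o1"])
        pm = PopulationMap({"a1": "P1", "b1": "P2", "c1": "P3", "o1": "O"})
        fr = trio_site_freqs(gm, pm, ("P1", "P2", "P3", "O"))
        assert list(fr.pos) == [200]

    def test_unpolarized_matrix_rejected(self):
        gm = make_gm([[0, 1, 1, 0]], coded="alt",
                     sample_ids=["a1", "b1", "c1", "o1"])
        pm = PopulationMap({"a1": "P1", "b1": "P2", "c1": "P3", "o1": "O"})
        with pytest.raises(ValueError):
            trio_site_freqs(gm, pm, ("P1", "P2", "P3", "O"))


class TestWindowAbbaBaba:
    def test_single_site_hand_sums(self):
        fr = freqs_from_arrays([0.0], [0.5], [0.5])
        win = make_windows(ONE_KB, 1000, 0)
        res = window_abba_baba(fr, win)
        assert res["sum_abba"][0] == pytest.approx(0.25)
        assert res["sum_baba"][0] == 0.0
        assert res["D"][0] == pytest.approx(1.0)
        assert res["fd"][0] == pytest.approx(1.0)

    def test_p1_equals_p2_gives_zero(self):
        p = np.array([0.2, 0.5, 0.8])
        fr = freqs_from_arrays(p, p, [0.3, 0.6, 0.9])
        res = window_abba_baba(fr, make_windows(ONE_KB, 1000, 0))
        assert res["D"][0] == pytest.approx(0.0)
        assert res["fdM"][0] == pytest.approx(0.0)

    def test_excess_baba_fd_nan_d_negative(self):
        fr = freqs_from_arrays([0.9], [0.0], [0.9])
        res = window_abba_baba(fr, make_windows(ONE_KB, 1000, 0))
        assert np.isnan(res["fd"][0])
        assert res["D"][0] < 0
        assert res["fdM"][0] < 0

    def test_matches_per_site_loop_oracle(self):
        rng = np.random.default_rng(10)
        fr = freqs_from_arrays(rng.random(25), rng.random(25), rng.random(25),
                               rng.random(25) * 0.1)
        res = window_abba_baba(fr, make_windows(ONE_KB, 1000, 0))
        d, fd, fdm = brute_window_stats(fr)
        assert res["D"][0] == pytest.approx(d)
        assert res["fd"][0] == pytest.approx(fd, nan_ok=True)
        assert res["fdM"][0] == pytest.approx(fdm)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_fdm_sign_matches_d_sign(self, seed):
        rng = np.random.default_rng(seed)
        fr = freqs_from_arrays(rng.random(15), rng.random(15), rng.random(15))
        res = window_abba_baba(fr, make_windows(ONE_KB, 1000, 0))
        d, fdm = res["D"][0], res["fdM"][0]
        if np.isfinite(d) and np.isfinite(fdm) and d != 0:
            assert np.sign(fdm) == np.sign(d)

    def test_fd_denominator_uses_larger_of_p2_p3(self):
        # p3 > p2: denominator must substitute p3 into both donor slots
        fr = freqs_from_arrays([0.0], [0.2], [0.8])
        res = window_abba_baba(fr, make_windows(ONE_KB, 1000, 0))
        num = (1 - 0) * 0.2 * 0.8
        den = 0.8 * 0.8
        assert res["fd"][0] == pytest.approx(num / den)

    def test_invalid_window_is_nan(self):
        fr = freqs_from_arrays([0.0], [0.5], [0.5])
        win = make_windows(ONE_KB, 1000, min_snps=100)
        res = window_abba_baba(fr, win)
        assert np.isnan(res["D"][0])

    def test_jackknife_on_many_windows(self):
        rng = np.random.default_rng(11)
        n = 200
        fr = SiteFreqs(chrom=np.asarray(["chr1"] * n, dtype=object),
                       pos=np.arange(1, n + 1) * 100,
                       p1=rng.random(n) * 0.3, p2=rng.random(n),
                       p3=rng.random(n), p4=np.zeros(n))
        win = make_windows({"chr1": 20_000}, 1000, 0)
        res = window_abba_baba(fr, win)
        d, se, z = d_jackknife(res)
        assert np.isfinite(d) and se > 0 and np.isfinite(z)


class TestTopQuantile:
    @staticmethod
    def frame(fd_values):
        n = len(fd_values)
        return pd.DataFrame({"chrom": "c", "start": np.arange(n) * 10,
                             "end": (np.arange(n) + 1) * 10, "fd": fd_values,
                             "valid": np.isfinite(fd_values)})

    def test_five_of_hundred(self):
        vals = np.linspace(0, 1, 100)
        rs = top_quantile_regions(self.frame(vals), 0.05)
        assert len(rs) == 5

    def test_ties_at_threshold_included(self):
        vals = np.array([0.1] * 90 + [0.9] * 10)
        rs = top_quantile_regions(self.frame(vals), 0.05)
        assert len(rs) == 10  # all tied top values come along

    def test_all_nan_errors(self):
        with pytest.raises(ValueError):
            top_quantile_regions(self.frame(np.array([np.nan, np.nan])), 0.05)

    def test_q_out_of_range_errors(self):
        with pytest.raises(ValueError):
            top_quantile_regions(self.frame(np.array([0.5])), 1.5)


class TestGenesPerBin:
    def test_gene_counting_and_straddling(self):
        windows = pd.DataFrame({"chrom": "c", "start": [0, 1000],
                                "end": [1000, 2000], "fd": [0.1, 0.9]})
        genes = RegionSet.from_records(
            [("c", 10, 50, "g1"), ("c", 60, 90, "g2"), ("c", 900, 1100, "g3")])
        res = genes_per_fd_bin(windows, genes, [0.0, 0.5, 1.0])
        assert res["mean_genes"][0] == 3.0  # g1, g2 and straddling g3
        assert res["mean_genes"][1] == 1.0  # g3 counts again in window 2

    def test_empty_bin_is_nan(self):
        windows = pd.DataFrame({"chrom": "c", "start": [0], "end": [1000],
                                "fd": [0.1]})
        genes = RegionSet.from_records([("c", 10, 50, "g")])
        res = genes_per_fd_bin(windows, genes, [0.0, 0.5, 1.0])
        assert np.isnan(res["mean_genes"][1])
        assert res["n_windows"][1] == 0


class TestFbranch:
    def test_donor_in_descendants_is_nan(self, scenario_dataset):
        ds = scenario_dataset
        fb = fbranch(ds["tree"], ds["gm"], ds["popmap"], "OUT")
        assert np.isnan(fb.loc["wine", "wine"])
        assert np.isnan(fb.loc["(table,wine)", "wine"])
        assert np.isnan(fb.loc["(table,wine)", "table"])

    def test_pulse_recipient_branch_carries_signal(self, scenario_dataset):
        ds = scenario_dataset
        fb = fbranch(ds["tree"], ds["gm"], ds["popmap"], "OUT")
        assert fb.loc["wine", "EU"] > 0.05
        assert fb.loc["wine", "EU"] > fb.loc["table", "EU"]

    def test_tree_popmap_mismatch_errors(self, scenario_dataset):
        ds = scenario_dataset
        with pytest.raises(ValueError):
            fbranch("(EU,(ME1,(ME9,(table,wine))));", ds["gm"], ds["popmap"], "OUT")

    def test_f4_ratio_complete_admixture_is_one(self):
        # P2 identical to P3 -> f = 1 by construction
        rng = np.random.default_rng(12)
        p3 = rng.random(30)
        fr = freqs_from_arrays(rng.random(30) * 0.2, p3, p3)
        assert f4_admixture_ratio(fr) == pytest.approx(1.0)
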