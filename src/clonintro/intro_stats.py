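"""ABBA-BABA family introgression statistics.

For an ordered trio (P1, P2, P3) with outgroup O and per-site derived
allele frequencies p1..p4:

    ABBA = (1-p1) p2 p3 (1-p4)        BABA = p1 (1-p2) p3 (1-p4)
    D    = sum(ABBA-BABA) / sum(ABBA+BABA)

fd replaces P2 and P3 by the "donor" population with the higher derived
frequency in the denominator, estimating the admixture fraction for
windows with excess ABBA; it is undefined (NaN) when the numerator sum
is not positive.  fdM uses the same numerator but a denominator that
switches between P2<->P3 sharing (p2 >= p1) and P1<->P3 sharing
(p1 > p2, negated), making the statistic symmetric about zero with
sign(fdM) = sign(D).  Positive fdM means donor sharing with P2.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from Bio import Phylo

from .core_io import GenotypeMatrix, PopulationMap, RegionSet, assign_sites_to_windows


@dataclass
class SiteFreqs:
    """Per-site derived-allele frequencies for an ordered (P1,P2,P3,O) trio."""

    chrom: np.ndarray
    pos: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p4: np.ndarray


def trio_site_freqs(gm: GenotypeMatrix, popmap: PopulationMap,
                    trio: tuple[str, str, str, str]) -> SiteFreqs:
    """Derived-allele frequencies per site for the four trio roles.

    Requires a polarized matrix.  Sites where any role group has zero
    non-missing calls are excluded.
    """
    if gm.coded != "derived":
        raise ValueError("matrix must be polarized (coded='derived') for trio statistics")
    if len(trio) != 4:
        raise ValueError("trio must name four groups: (P1, P2, P3, O)")
    freqs, keep = [], np.ones(gm.n_sites, dtype=bool)
    for group in trio:
        idx = gm.sample_indices(popmap.samples(group))
        p, n = gm.group_freqs(idx)
        keep &= n > 0
        freqs.append(p)
    return SiteFreqs(gm.chrom[keep], gm.pos[keep],
                     *(f[keep] for f in freqs))


def _site_patterns(p1, p2, p3, p4):
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def _fd_denominator(p1, p2, p3, p4):
    pd_ = np.maximum(p2, p3)
    a, b = _site_patterns(p1, pd_, pd_, p4)
    return a - b


def _fdm_denominator(p1, p2, p3, p4):
    d23 = np.maximum(p2, p3)
    a23, b23 = _site_patterns(p1, d23, d23, p4)
    d13 = np.maximum(p1, p3)
    a13, b13 = _site_patterns(d13, p2, d13, p4)
    return np.where(p2 >= p1, a23 - b23, -(a13 - b13))


def window_abba_baba(freqs: SiteFreqs, windows: RegionSet) -> pd.DataFrame:
    """Per-window D, fd and fdM with site-pattern sums.

    Invalid windows and zero-denominator windows report NaN; fd is NaN
    whenever its numerator sum is non-positive.
    """
    widx = assign_sites_to_windows(windows, freqs.chrom, freqs.pos)
    nw = len(windows)
    abba, baba = _site_patterns(freqs.p1, freqs.p2, freqs.p3, freqs.p4)
    num = abba - baba
    fd_den = _fd_denominator(freqs.p1, freqs.p2, freqs.p3, freqs.p4)
    fdm_den = _fdm_denominator(freqs.p1, freqs.p2, freqs.p3, freqs.p4)

    inwin = widx >= 0
    def wsum(v):
        return np.bincount(widx[inwin], weights=v[inwin], minlength=nw)

    s_abba, s_baba = wsum(abba), wsum(baba)
    s_num, s_fd_den, s_fdm_den = wsum(num), wsum(fd_den), wsum(fdm_den)
    n_sites = np.bincount(widx[inwin], minlength=nw)

    valid = windows.df["valid"].to_numpy() if "valid" in windows.df.columns \
        else np.ones(nw, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(s_abba + s_baba > 0, s_num / (s_abba + s_baba), np.nan)
        fd = np.where((s_num > 0) & (s_fd_den > 0), s_num / s_fd_den, np.nan)
        fdm = np.where(s_fdm_den > 0, s_num / s_fdm_den, np.nan)
    out = windows.df[["chrom", "start", "end"]].copy()
    out["n_sites"] = n_sites
    out["sum_abba"], out["sum_baba"] = s_abba, s_baba
    out["D"] = np.where(valid, d, np.nan)
    out["fd"] = np.where(valid, fd, np.nan)
    out["fdM"] = np.where(valid, fdm, np.nan)
    out["valid"] = valid & (n_sites > 0)
    return out


def d_jackknife(trio_results: pd.DataFrame) -> tuple[float, float, float]:
    """Genome-wide D with block-jackknife (block = window) SE and Z."""
    sub = trio_results[trio_results["valid"]]
    sa, sb = sub["sum_abba"].to_numpy(), sub["sum_baba"].to_numpy()
    tot_a, tot_b = sa.sum(), sb.sum()
    if tot_a + tot_b <= 0:
        return np.nan, np.nan, np.nan
    d_all = (tot_a - tot_b) / (tot_a + tot_b)
    n = len(sub)
    if n < 2:
        return d_all, np.nan, np.nan
    loo_a, loo_b = tot_a - sa, tot_b - sb
    with np.errstate(invalid="ignore", divide="ignore"):
        d_loo = (loo_a - loo_b) / (loo_a + loo_b)
    se = float(np.sqrt((n - 1) / n * np.nansum((d_loo - np.nanmean(d_loo)) ** 2)))
    z = d_all / se if se > 0 else np.nan
    return float(d_all), se, float(z)


# ---------------------------------------------------------------------------
# f-branch
# ---------------------------------------------------------------------------

def f4_admixture_ratio(freqs: SiteFreqs) -> float:
    """f estimate for (A=P1, B=P2, C=P3; O): gene flow C -> B.

    Numerator is the D numerator; the denominator substitutes C for B,
    i.e. the expected numerator under complete admixture.
    """
    abba, baba = _site_patterns(freqs.p1, freqs.p2, freqs.p3, freqs.p4)
    a_cc, b_cc = _site_patterns(freqs.p1, freqs.p3, freqs.p3, freqs.p4)
    den = (a_cc - b_cc).sum()
    if den == 0:
        return np.nan
    return float((abba - baba).sum() / den)


class _TreeIndex:
    """Rooted population tree with tip-set and MRCA-depth helpers."""

    def __init__(self, newick: str):
        self.tree = Phylo.read(StringIO(newick), "newick")
        self.tips = [t.name for t in self.tree.get_terminals()]
        self.clades = [c for c in self.tree.find_clades()
                       if c is not self.tree.root]
        self._depths = self.tree.depths(unit_branch_lengths=True)
        self._tipsets = {id(c): frozenset(t.name for t in c.get_terminals())
                         for c in self.tree.find_clades()}
        # depth of the MRCA for every tip pair
        self._mrca_depth = {}
        for i, a in enumerate(self.tips):
            for b in self.tips[i + 1:]:
                m = self.tree.common_ancestor(a, b)
                self._mrca_depth[frozenset((a, b))] = self._depths[m]

    def tipset(self, clade) -> frozenset:
        return self._tipsets[id(clade)]

    def mrca_depth(self, a: str, b: str) -> float:
        return self._mrca_depth[frozenset((a, b))]

    def branch_name(self, clade) -> str:
        tips = sorted(self.tipset(clade))
        return tips[0] if len(tips) == 1 else "(" + ",".join(tips) + ")"


def fbranch(newick: str, gm: GenotypeMatrix, popmap: PopulationMap,
            outgroup: str) -> pd.DataFrame:
    """f-branch matrix: branches (rows) x candidate donors (columns).

    For branch ``b`` and donor ``C``: fb(b, C) = median over valid A of
    [min over B in descendants(b) of f(A, B, C)], with negative values
    floored at zero.  A trio (A, B, C) is valid when the tree topology is
    ((A, B), C).  Cells with no valid trio are NaN.
    """
    ti = _TreeIndex(newick)
    groups = set(popmap.groups())
    missing = [t for t in ti.tips if t not in groups]
    if missing:
        raise ValueError(f"tree tips not in population map: {missing}")
    if outgroup not in groups:
        raise ValueError(f"outgroup {outgroup!r} not in population map")

    cache: dict[tuple[str, str, str], float] = {}

    def f(a: str, b: str, c: str) -> float:
        key = (a, b, c)
        if key not in cache:
            freqs = trio_site_freqs(gm, popmap, (a, b, c, outgroup))
            cache[key] = f4_admixture_ratio(freqs)
        return cache[key]

    rows = []
    donors = list(ti.tips)
    for clade in ti.clades:
        desc = ti.tipset(clade)
        row: dict[str, float] = {}
        for c in donors:
            if c in desc:
                row[c] = np.nan
                continue
            b0 = next(iter(desc))
            valid_a = [a for a in ti.tips
                       if a not in desc and a != c
                       and ti.mrca_depth(a, b0) > ti.mrca_depth(c, b0)]
            if not valid_a:
                row[c] = np.nan
                continue
            vals = [min(f(a, b, c) for b in desc) for a in valid_a]
            row[c] = max(0.0, float(np.median(vals)))
        rows.append(pd.Series(row, name=ti.branch_name(clade)))
    out = pd.DataFrame(rows)
    out.index.name = "branch"
    return out


# ---------------------------------------------------------------------------
# region extraction / annotation
# ---------------------------------------------------------------------------

def top_quantile_regions(trio_results: pd.DataFrame, q: float = 0.05,
                         stat: str = "fd") -> RegionSet:
    """Windows in the top ``q`` fraction of the statistic, ties included."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    vals = trio_results[stat].to_numpy()
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError(f"no valid windows with finite {stat}")
    thresh = np.quantile(vals[ok], 1.0 - q)
    sel = trio_results[ok & (vals >= thresh)]
    df = sel[["chrom", "start", "end"]].copy()
    df["label"] = f"top_{stat}"
    df["value"] = sel[stat].to_numpy()
    return RegionSet(df)


def genes_per_fd_bin(trio_results: pd.DataFrame, genes: RegionSet,
                     bin_edges, stat: str = "fd") -> pd.DataFrame:
    """Mean gene count per statistic bin.

    A gene counts toward a window if it overlaps it by at least 1 bp, so
    a gene straddling two windows counts once in each.
    """
    vals = trio_results[stat].to_numpy()
    ok = np.isfinite(vals)
    counts = np.zeros(len(trio_results), dtype=np.int64)
    gdf = genes.df
    for i, (c, s, e) in enumerate(zip(trio_results["chrom"],
                                      trio_results["start"],
                                      trio_results["end"])):
        sub = gdf[gdf["chrom"] == c]
        counts[i] = int(((sub["start"] < e) & (sub["end"] > s)).sum())
    bins = np.asarray(bin_edges, dtype=float)
    which = np.digitize(vals, bins) - 1
    rows = []
    for b in range(len(bins) - 1):
        in_bin = ok & (which == b)
        rows.append({
            "bin_low": bins[b], "bin_high": bins[b + 1],
            "n_windows": int(in_bin.sum()),
            "mean_genes": float(counts[in_bin].mean()) if in_bin.any() else np.nan,
        })
    return pd.DataFrame(rows)
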