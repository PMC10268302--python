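"""Windowed diversity and divergence statistics.

Per-bp statistics (pi, Dxy) normalize by the full window length in base
pairs, treating positions absent from the SNP matrix as invariant; this
is the convention of SNP-only resequencing pipelines and keeps values on
the familiar 1e-3 scale.  Windows flagged invalid get NaN so downstream
quantile selection skips them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix, RegionSet, assign_sites_to_windows


# ---------------------------------------------------------------------------
# per-sample heterozygosity
# ---------------------------------------------------------------------------

def sample_heterozygosity(gm: GenotypeMatrix, denominator: str = "all_sites") -> pd.Series:
    """Heterozygous-site fraction per sample.

    ``denominator="all_sites"`` divides by every retained SNP site (the
    number of all SNPs); ``"called"`` divides by that sample's non-missing
    sites.
    """
    if gm.n_sites == 0:
        raise ValueError("genotype matrix has no sites")
    n_het = (gm.dosage == 1).sum(axis=0)
    if denominator == "all_sites":
        denom = np.full(gm.n_samples, gm.n_sites, dtype=float)
    elif denominator == "called":
        denom = (gm.dosage != MISSING).sum(axis=0).astype(float)
    else:
        raise ValueError("denominator must be 'all_sites' or 'called'")
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(denom > 0, n_het / denom, np.nan)
    return pd.Series(het, index=gm.sample_ids, name="heterozygosity")


# ---------------------------------------------------------------------------
# per-site building blocks
# ---------------------------------------------------------------------------

def _site_pi(p: np.ndarray, n_hap: np.ndarray) -> np.ndarray:
    """Mean pairwise difference per site: 2p(1-p) * n/(n-1); NaN when n < 2."""
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 2.0 * p * (1.0 - p) * n_hap / (n_hap - 1.0)
    out = np.where(n_hap >= 2, out, np.nan)
    return out


def _window_sum(values: np.ndarray, widx: np.ndarray, n_windows: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum of finite per-site values and count of contributing sites per window."""
    ok = np.isfinite(values) & (widx >= 0)
    sums = np.bincount(widx[ok], weights=values[ok], minlength=n_windows)
    counts = np.bincount(widx[ok], minlength=n_windows)
    return sums, counts


def _finish(windows: RegionSet, sums: np.ndarray, counts: np.ndarray,
            name: str) -> pd.DataFrame:
    df = windows.df[["chrom", "start", "end"]].copy()
    span = (df["end"] - df["start"]).to_numpy().astype(float)
    vals = sums / span
    valid = windows.df["valid"].to_numpy() if "valid" in windows.df.columns \
        else np.ones(len(df), dtype=bool)
    vals = np.where(valid, vals, np.nan)
    df["n_sites"] = counts
    df[name] = vals
    return df


def window_pi(gm: GenotypeMatrix, group_idx: np.ndarray, windows: RegionSet) -> pd.DataFrame:
    """Nucleotide diversity per bp within one group, per window."""
    p, n = gm.group_freqs(group_idx)
    site = _site_pi(p, n)
    widx = assign_sites_to_windows(windows, gm.chrom, gm.pos)
    sums, counts = _window_sum(site, widx, len(windows))
    return _finish(windows, sums, counts, "pi")


def window_dxy(gm: GenotypeMatrix, idx_a: np.ndarray, idx_b: np.ndarray,
               windows: RegionSet) -> pd.DataFrame:
    """Absolute divergence per bp between two groups, per window."""
    pa, na = gm.group_freqs(idx_a)
    pb, nb = gm.group_freqs(idx_b)
    site = pa * (1 - pb) + pb * (1 - pa)
    site = np.where((na >= 1) & (nb >= 1), site, np.nan)
    widx = assign_sites_to_windows(windows, gm.chrom, gm.pos)
    sums, counts = _window_sum(site, widx, len(windows))
    return _finish(windows, sums, counts, "dxy")


def dxy_difference(dxy_a: pd.DataFrame, dxy_b: pd.DataFrame) -> pd.DataFrame:
    """Elementwise dxy_a - dxy_b over identical window sets.

    The study's introgression contrast: Dxy(wine,EU) - Dxy(table,EU) per
    window, negative where the first pair is more similar.
    """
    keys = ["chrom", "start", "end"]
    if not dxy_a[keys].equals(dxy_b[keys]):
        raise ValueError("window sets differ between the two dxy tables")
    out = dxy_a[keys].copy()
    out["dxy_difference"] = dxy_a["dxy"].to_numpy() - dxy_b["dxy"].to_numpy()
    return out


def hudson_fst_components(pa, na, pb, nb) -> tuple[np.ndarray, np.ndarray]:
    """Per-site numerator/denominator of the Hudson FST estimator."""
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((pa - pb) ** 2
               - pa * (1 - pa) / (na - 1.0)
               - pb * (1 - pb) / (nb - 1.0))
    den = pa * (1 - pb) + pb * (1 - pa)
    ok = (na >= 2) & (nb >= 2)
    return np.where(ok, num, np.nan), np.where(ok, den, np.nan)


def window_fst(gm: GenotypeMatrix, idx_a: np.ndarray, idx_b: np.ndarray,
               windows: RegionSet) -> pd.DataFrame:
    """Hudson FST (ratio of sums) per window; NaN when the denominator is 0."""
    pa, na = gm.group_freqs(idx_a)
    pb, nb = gm.group_freqs(idx_b)
    num, den = hudson_fst_components(pa, na, pb, nb)
    widx = assign_sites_to_windows(windows, gm.chrom, gm.pos)
    ok = np.isfinite(num) & np.isfinite(den) & (widx >= 0)
    nsum = np.bincount(widx[ok], weights=num[ok], minlength=len(windows))
    dsum = np.bincount(widx[ok], weights=den[ok], minlength=len(windows))
    counts = np.bincount(widx[ok], minlength=len(windows))
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(dsum > 0, nsum / np.where(dsum > 0, dsum, 1.0), np.nan)
    valid = windows.df["valid"].to_numpy() if "valid" in windows.df.columns \
        else np.ones(len(windows), dtype=bool)
    df = windows.df[["chrom", "start", "end"]].copy()
    df["n_sites"] = counts
    df["fst"] = np.where(valid, fst, np.nan)
    return df


# ---------------------------------------------------------------------------
# population branch statistic
# ---------------------------------------------------------------------------

def pbs(fst_focal_b: pd.DataFrame, fst_focal_c: pd.DataFrame,
        fst_b_c: pd.DataFrame) -> pd.DataFrame:
    """Population branch statistic for the focal group of a trio.

    ``T = -log(1 - FST)`` per pair; ``PBS = (T_fb + T_fc - T_bc) / 2``.
    Windows where any pairwise FST >= 1 yield infinite T and are flagged.
    """
    keys = ["chrom", "start", "end"]
    for other in (fst_focal_c, fst_b_c):
        if not fst_focal_b[keys].equals(other[keys]):
            raise ValueError("window sets differ between FST tables")

    def t(col: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return -np.log1p(-col)

    tfb = t(fst_focal_b["fst"].to_numpy())
    tfc = t(fst_focal_c["fst"].to_numpy())
    tbc = t(fst_b_c["fst"].to_numpy())
    out = fst_focal_b[keys].copy()
    out["T_fb"], out["T_fc"], out["T_bc"] = tfb, tfc, tbc
    out["pbs"] = (tfb + tfc - tbc) / 2.0
    out["flagged"] = ~np.isfinite(out["pbs"].to_numpy()) & (
        np.isfinite(tfb) | np.isfinite(tfc) | np.isfinite(tbc))
    return out


# ---------------------------------------------------------------------------
# PLINK-style method-of-moments IBD
# ---------------------------------------------------------------------------

@dataclass
class RelatednessResult:
    sample_a: str
    sample_b: str
    p_ibd0: float
    p_ibd1: float
    p_ibd2: float
    pi_hat: float
    n_sites: int
    low_confidence: bool


def _ibs_given_ibd(x: np.ndarray, y: np.ndarray):
    """Conditional IBS-state probabilities given IBD state.

    Finite-sample corrections arise naturally from drawing the non-shared
    alleles *without replacement* from the cohort pool of ``x`` coded and
    ``y`` alternate allele copies (the PLINK --genome moment estimator's
    correction).  Returns arrays for P(IBS=0|IBD=0), P(IBS=1|IBD=0),
    P(IBS=2|IBD=0), P(IBS=1|IBD=1), P(IBS=2|IBD=1).
    """
    t = x + y

    def ff(a, k):  # falling factorial a(a-1)...(a-k+1)
        out = np.ones_like(a, dtype=float)
        for i in range(k):
            out = out * (a - i)
        return out

    t4 = ff(t, 4)
    # IBD=0: four independent draws; individual 1 = draws 1,2, individual 2 = 3,4
    p0_ibs0 = 2.0 * ff(x, 2) * ff(y, 2) / t4
    p0_ibs2 = (ff(x, 4) + ff(y, 4) + 4.0 * ff(x, 2) * ff(y, 2)) / t4
    p0_ibs1 = 1.0 - p0_ibs0 - p0_ibs2
    # IBD=1: shared allele S plus one extra draw per individual
    t3 = (t - 1.0) * (t - 2.0)
    p1_ibs2 = (x / t * ((x - 1) * (x - 2) + y * (y - 1)) / t3
               + y / t * ((y - 1) * (y - 2) + x * (x - 1)) / t3)
    p1_ibs1 = 1.0 - p1_ibs2
    return p0_ibs0, p0_ibs1, p0_ibs2, p1_ibs1, p1_ibs2


def pairwise_pi_hat(gm: GenotypeMatrix, pairs: list[tuple[str, str]],
                    min_sites: int = 50) -> list[RelatednessResult]:
    """Method-of-moments IBD sharing (PI_HAT) for sample pairs.

    Cohort allele frequencies come from all samples in the matrix.  Sites
    need at least 4 coded and 4 alternate allele copies in the cohort so
    the without-replacement probabilities are defined.
    """
    d = gm.dosage
    called_all = d != MISSING
    x = np.where(called_all, d, 0).sum(axis=1).astype(float)       # coded copies
    n_hap = 2.0 * called_all.sum(axis=1)
    y = n_hap - x
    informative = (x >= 4) & (y >= 4)

    results = []
    for sa, sb in pairs:
        ia, ib = gm.sample_indices([sa, sb])
        da, db = d[:, ia], d[:, ib]
        use = informative & (da != MISSING) & (db != MISSING)
        n = int(use.sum())
        if n == 0:
            results.append(RelatednessResult(sa, sb, np.nan, np.nan, np.nan,
                                             np.nan, 0, True))
            continue
        xa, ya = x[use], y[use]
        ibs = 2 - np.abs(da[use].astype(int) - db[use].astype(int))
        # both het counts as IBS 2; opposite homozygotes give |diff| 2 -> IBS 0
        n0 = float((ibs == 0).sum())
        n1 = float((ibs == 1).sum())
        n2 = float((ibs == 2).sum())
        e00, e10, e20, e11, e21 = _ibs_given_ibd(xa, ya)
        s00, s10, s20 = e00.sum(), e10.sum(), e20.sum()
        s11, s21 = e11.sum(), e21.sum()
        p0 = n0 / s00 if s00 > 0 else 0.0
        p1 = (n1 - p0 * s10) / s11 if s11 > 0 else 0.0
        p2 = (n2 - p0 * s20 - p1 * s21) / n
        probs = np.clip([p0, p1, p2], 0.0, None)
        total = probs.sum()
        probs = probs / total if total > 0 else np.array([1.0, 0.0, 0.0])
        pi_hat = float(np.clip(probs[1] / 2.0 + probs[2], 0.0, 1.0))
        results.append(RelatednessResult(sa, sb, *map(float, probs), pi_hat,
                                         n, n < min_sites))
    return results


def relatedness_table(results: list[RelatednessResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
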