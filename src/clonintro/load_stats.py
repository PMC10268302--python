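"""Deleterious-load accounting stratified by genomic region class.

Load models per individual, counting derived alleles at putatively
deleterious sites (dSNPs):

* heterozygous load — number of heterozygous dSNP genotypes;
* recessive load    — number of homozygous-derived dSNP genotypes;
* additive load     — het + 2 x hom, i.e. the derived allele count.

Synonymous SNPs (sSNPs) serve as the neutral yardstick; the per-individual
dSNP/sSNP ratio uses additive allele counts by default (site counts behind
a flag).  Random same-length region placements provide the negative
control for density comparisons.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, GenotypeMatrix, RegionSet

EFFECT_CLASSES = ("dSNP", "sSNP", "SV")


def read_effects(path) -> pd.DataFrame:
    """Effect-class table: chrom, pos (1-based), class in {dSNP, sSNP, SV}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "class"],
                     dtype={"chrom": str, "pos": np.int64, "class": str},
                     comment="#")
    bad = ~df["class"].isin(EFFECT_CLASSES)
    if bad.any():
        raise ValueError(f"unknown effect classes: {sorted(df['class'][bad].unique())}")
    if df.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate (chrom, pos) keys in effect table")
    return df


def write_effects(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "class"]].to_csv(path, sep="\t", header=False, index=False)


def effect_mask(gm: GenotypeMatrix, effects: pd.DataFrame, klass: str) -> np.ndarray:
    """Boolean site mask for one effect class."""
    keys = set(zip(effects.loc[effects["class"] == klass, "chrom"],
                   effects.loc[effects["class"] == klass, "pos"]))
    return np.fromiter(((c, p) in keys for c, p in zip(gm.chrom, gm.pos)),
                       dtype=bool, count=gm.n_sites)


def load_per_individual(gm: GenotypeMatrix, effects: pd.DataFrame,
                        strata: dict[str, RegionSet],
                        ratio_on: str = "alleles") -> pd.DataFrame:
    """Per-individual load counts and densities for each region stratum.

    ``ratio_on="alleles"`` computes the dSNP/sSNP ratio on additive allele
    counts; ``"sites"`` uses the number of carrier sites (het + hom).
    """
    if ratio_on not in ("alleles", "sites"):
        raise ValueError("ratio_on must be 'alleles' or 'sites'")
    d_mask = effect_mask(gm, effects, "dSNP")
    s_mask = effect_mask(gm, effects, "sSNP")
    rows = []
    for name, rs in strata.items():
        in_region = rs.site_mask(gm.chrom, gm.pos)
        length = rs.total_length()
        dm, sm = d_mask & in_region, s_mask & in_region
        if not dm.any() and not sm.any():
            warnings.warn(f"stratum {name!r} contains no classified sites")
        for j, sample in enumerate(gm.sample_ids):
            dos = gm.dosage[:, j]
            n_het_d = int(((dos == 1) & dm).sum())
            n_hom_d = int(((dos == 2) & dm).sum())
            n_het_s = int(((dos == 1) & sm).sum())
            n_hom_s = int(((dos == 2) & sm).sum())
            additive_d = n_het_d + 2 * n_hom_d
            additive_s = n_het_s + 2 * n_hom_s
            if ratio_on == "alleles":
                num, den = additive_d, additive_s
            else:
                num, den = n_het_d + n_hom_d, n_het_s + n_hom_s
            rows.append({
                "sample": sample, "stratum": name,
                "n_het_d": n_het_d, "n_hom_d": n_hom_d,
                "n_het_s": n_het_s, "n_hom_s": n_hom_s,
                "het_load": n_het_d, "recessive_load": n_hom_d,
                "additive_load": additive_d,
                "ratio_ds": num / den if den > 0 else np.nan,
                "stratum_bp": length,
                "het_density": n_het_d / length if dm.any() else np.nan,
                "recessive_density": n_hom_d / length if dm.any() else np.nan,
                "additive_density": additive_d / length if dm.any() else np.nan,
            })
    return pd.DataFrame(rows)


def random_control_regions(contig_lengths: dict[str, int], template: RegionSet,
                           n_reps: int, seed: int,
                           max_tries: int = 1000) -> list[RegionSet]:
    """Random same-length, non-overlapping placements of the template regions.

    Each template region is placed uniformly over valid start positions
    genome-wide (contigs weighted by the number of admissible starts) and
    re-drawn on collision with already placed regions in the same
    replicate.  Fully seed-reproducible.
    """
    rng = np.random.default_rng(seed)
    lengths = template.lengths()
    contigs = list(contig_lengths)
    too_long = lengths.max() if len(lengths) else 0
    if any(too_long > contig_lengths[c] for c in contigs) and \
            all(too_long > contig_lengths[c] for c in contigs):
        raise ValueError("a template region is longer than every contig")
    out = []
    for _ in range(n_reps):
        placed: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
        rows = []
        for ln in lengths:
            n_starts = np.array([max(contig_lengths[c] - ln + 1, 0) for c in contigs],
                                dtype=float)
            probs = n_starts / n_starts.sum()
            for attempt in range(max_tries):
                c = contigs[rng.choice(len(contigs), p=probs)]
                s = int(rng.integers(0, contig_lengths[c] - ln + 1))
                e = s + int(ln)
                if all(e <= ps or s >= pe for ps, pe in placed[c]):
                    placed[c].append((s, e))
                    rows.append({"chrom": c, "start": s, "end": e,
                                 "label": "control"})
                    break
            else:
                raise RuntimeError(
                    f"could not place a {ln}-bp control region without overlap "
                    f"after {max_tries} tries")
        out.append(RegionSet(pd.DataFrame(rows)))
    return out


# ---------------------------------------------------------------------------
# site frequency spectra
# ---------------------------------------------------------------------------

def sfs_by_class(gm: GenotypeMatrix, effects: pd.DataFrame, klass: str,
                 stratum: RegionSet | None, group_idx: np.ndarray) -> pd.Series:
    """Unfolded SFS (normalized) of one effect class within a stratum.

    Bins are derived-allele counts 1..n_hap-1 among the group's
    haplotypes; with missing data the count is the rounded frequency
    scaled to the full haplotype number.  Requires a polarized matrix
    and at least two segregating sites.
    """
    if gm.coded != "derived":
        raise ValueError("SFS requires a polarized matrix")
    mask = effect_mask(gm, effects, klass)
    if stratum is not None:
        mask &= stratum.site_mask(gm.chrom, gm.pos)
    p, n = gm.group_freqs(group_idx)
    n_hap = 2 * len(group_idx)
    with np.errstate(invalid="ignore"):
        count = np.rint(p * n_hap).astype(int)
    seg = mask & (n > 0) & (count >= 1) & (count <= n_hap - 1)
    if seg.sum() < 2:
        raise ValueError(f"fewer than 2 segregating {klass} sites in stratum")
    hist = np.bincount(count[seg], minlength=n_hap)[1:n_hap]
    spec = hist / hist.sum()
    return pd.Series(spec, index=np.arange(1, n_hap), name=f"sfs_{klass}")


def compare_sfs(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test over matched frequency bins.

    Returns (signed rank statistic W, p-value).  W is the sum of signed
    ranks of (a - b): negative when mass in ``a`` sits at lower bins than
    in ``b`` in the upper tail — i.e. a leftward (rare-shifted) spectrum
    gives negative W when comparing upper-bin masses.  Identical spectra
    give (0, 1) exactly.
    """
    if len(a) != len(b):
        raise ValueError("spectra must share bin structure")
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    nz = diff[diff != 0]
    if len(nz) == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(nz))
    w_signed = float(np.sum(np.sign(nz) * ranks))
    res = stats.wilcoxon(nz)
    return w_signed, float(res.pvalue)


# ---------------------------------------------------------------------------
# introgressed-allele spectra
# ---------------------------------------------------------------------------

def introgressed_allele_spectrum(gm: GenotypeMatrix, popmap, donor_group: str,
                                 reference_groups: list[str],
                                 recipient_group: str, regions: RegionSet,
                                 donor_min: float = 0.2,
                                 ref_max: float = 0.0) -> pd.DataFrame:
    """Frequency behaviour of donor-diagnostic alleles in the recipient.

    An introgressed-candidate allele is a derived allele inside an
    introgressed region with donor frequency >= ``donor_min`` and
    frequency <= ``ref_max`` in every reference group.  For each
    candidate: recipient allele frequency, fraction of recipient
    individuals carrying >= 1 copy, and the heterozygous share among
    carriers.
    """
    in_region = regions.site_mask(gm.chrom, gm.pos)
    pdon, ndon = gm.group_freqs(gm.sample_indices(popmap.samples(donor_group)))
    cand = in_region & (ndon > 0) & (pdon >= donor_min)
    for ref in reference_groups:
        pr, nr = gm.group_freqs(gm.sample_indices(popmap.samples(ref)))
        cand &= (nr > 0) & (pr <= ref_max)
    ridx = gm.sample_indices(popmap.samples(recipient_group))
    if not cand.any():
        warnings.warn("no introgressed-candidate alleles found")
        return pd.DataFrame(columns=["chrom", "pos", "donor_freq",
                                     "recipient_freq", "carrier_fraction",
                                     "het_share"])
    rows = []
    for i in np.flatnonzero(cand):
        dos = gm.dosage[i, ridx]
        called = dos != MISSING
        n_ind = int(called.sum())
        if n_ind == 0:
            continue
        carriers = (dos >= 1) & called
        n_car = int(carriers.sum())
        n_het = int(((dos == 1) & called).sum())
        rows.append({
            "chrom": gm.chrom[i], "pos": int(gm.pos[i]),
            "donor_freq": float(pdon[i]),
            "recipient_freq": float(np.where(called, dos, 0).sum() / (2 * n_ind)),
            "carrier_fraction": n_car / n_ind,
            "het_share": n_het / n_car if n_car else np.nan,
        })
    return pd.DataFrame(rows)


def bin_allele_spectrum(table: pd.DataFrame, edges=None) -> pd.DataFrame:
    """Bin candidate alleles by recipient allele AND carrier frequency.

    Both views are emitted because edge bins differ between allele and
    carrier ("individual") frequencies; each row carries the mean
    heterozygous share of alleles in the bin.
    """
    if edges is None:
        edges = np.linspace(0.0, 1.0, 11)
    edges = np.asarray(edges, dtype=float)
    rows = []
    for col in ("recipient_freq", "carrier_fraction"):
        vals = table[col].to_numpy() if len(table) else np.empty(0)
        which = np.clip(np.digitize(vals, edges) - 1, 0, len(edges) - 2)
        for b in range(len(edges) - 1):
            sel = which == b if len(table) else np.empty(0, dtype=bool)
            n = int(sel.sum())
            rows.append({
                "measure": col, "bin_low": edges[b], "bin_high": edges[b + 1],
                "proportion": n / len(table) if len(table) else np.nan,
                "mean_het_share": float(table["het_share"][sel].mean()) if n else np.nan,
            })
    return pd.DataFrame(rows)


def region_overlap_summary(a: RegionSet, b: RegionSet) -> dict:
    """How much of region set ``a`` is covered by set ``b``.

    Returns the number of a-regions overlapping >= 1 b-region by >= 1 bp,
    total shared base pairs, and the fraction of a-regions overlapped.
    """
    bdf = b.sort().df
    n_overlap = 0
    shared = 0
    for c, s, e in zip(a.df["chrom"], a.df["start"], a.df["end"]):
        sub = bdf[bdf["chrom"] == c]
        lo = np.maximum(sub["start"].to_numpy(), s)
        hi = np.minimum(sub["end"].to_numpy(), e)
        ov = np.clip(hi - lo, 0, None)
        if (ov > 0).any():
            n_overlap += 1
        shared += int(ov.sum())
    return {
        "n_a": len(a), "n_b": len(b),
        "n_a_overlapping": n_overlap,
        "shared_bp": shared,
        "fraction_a_overlapping": n_overlap / len(a) if len(a) else np.nan,
    }
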