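"""Genotype and region data model plus readers/writers for VCF, BED and TSV.

Coordinate conventions
----------------------
VCF positions are 1-based on input and output.  All internal region
arithmetic (windows, introgressed calls, genes) is 0-based half-open,
i.e. the BED convention.  A VCF site at ``pos`` falls in the region
``[start, end)`` iff ``start < pos <= end`` equivalently
``start <= pos - 1 < end``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger("clonintro")

#: dosage code for a missing diploid genotype
MISSING: int = -1

REGION_COLUMNS = ["chrom", "start", "end", "label"]


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic-SNP dosage matrix (sites x samples).

    ``dosage[i, j]`` counts copies of the coded allele for sample ``j`` at
    site ``i`` and takes values in ``{0, 1, 2, MISSING}``.  ``coded`` is
    ``"alt"`` straight from a VCF and ``"derived"`` after outgroup
    polarization.
    """

    chrom: np.ndarray          # (n_sites,) str
    pos: np.ndarray            # (n_sites,) int64, 1-based
    ref_allele: np.ndarray     # (n_sites,) str
    alt_allele: np.ndarray     # (n_sites,) str
    dosage: np.ndarray         # (n_sites, n_samples) int8
    sample_ids: list[str]
    coded: str = "alt"

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.dosage.shape != (len(self.pos), len(self.sample_ids)):
            raise ValueError("dosage shape does not match sites x samples")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,MISSING}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_indices(self, samples: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.asarray([lookup[s] for s in samples], dtype=np.intp)

    def take_sites(self, mask_or_idx) -> "GenotypeMatrix":
        return replace(
            self,
            chrom=self.chrom[mask_or_idx],
            pos=self.pos[mask_or_idx],
            ref_allele=self.ref_allele[mask_or_idx],
            alt_allele=self.alt_allele[mask_or_idx],
            dosage=self.dosage[mask_or_idx],
        )

    def take_samples(self, samples: list[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(samples)
        return replace(self, dosage=self.dosage[:, idx], sample_ids=list(samples))

    def contigs(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def group_freqs(self, sample_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-site coded-allele frequency and non-missing haplotype count."""
        d = self.dosage[:, sample_idx]
        called = d != MISSING
        n_hap = 2 * called.sum(axis=1)
        derived = np.where(called, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_hap > 0, derived / np.maximum(n_hap, 1), np.nan)
        return p, n_hap


@dataclass
class PopulationMap:
    """sample -> group assignment with optional trio-role bindings."""

    assignments: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)  # role (P1..O) -> group

    @classmethod
    def read(cls, path) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"],
                         dtype=str, comment="#")
        return cls(dict(zip(df["sample"], df["group"])))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for s, g in self.assignments.items():
                fh.write(f"{s}\t{g}\n")

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignments.values():
            seen.setdefault(g, None)
        return list(seen)

    def samples(self, group: str) -> list[str]:
        out = [s for s, g in self.assignments.items() if g == group]
        if not out:
            raise KeyError(f"group {group!r} has no samples")
        return out


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

@dataclass
class RegionSet:
    """Labeled genomic intervals, 0-based half-open, with interval algebra.

    Backed by a DataFrame with at least chrom/start/end/label columns;
    extra columns (``value``, ``n_snps``, ``valid`` ...) ride along.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "label" not in df.columns:
            df["label"] = "."
        missing = [c for c in REGION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"region table lacks columns {missing}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            raise ValueError("regions must satisfy start < end")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records, label: str = ".") -> "RegionSet":
        rows = []
        for rec in records:
            if len(rec) == 2:
                raise ValueError("records need (chrom, start, end)")
            chrom, start, end, *rest = rec
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "label": rest[0] if rest else label})
        return cls(pd.DataFrame(rows, columns=REGION_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def sort(self) -> "RegionSet":
        df = self.df.sort_values(["chrom", "start", "end"], kind="mergesort")
        return RegionSet(df.reset_index(drop=True))

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def total_length(self) -> int:
        return int(self.lengths().sum())

    def with_values(self, values, name: str = "value") -> "RegionSet":
        df = self.df.copy()
        df[name] = values
        return RegionSet(df)

    def site_mask(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean mask of 1-based sites falling inside any region."""
        mask = np.zeros(len(pos), dtype=bool)
        p0 = np.asarray(pos) - 1  # to 0-based
        for c, sub in self.df.groupby("chrom", sort=False):
            on = np.asarray(chrom) == c
            if not on.any():
                continue
            for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
                mask |= on & (p0 >= s) & (p0 < e)
        return mask


def read_bed(path, label_default: str = ".") -> RegionSet:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return RegionSet(pd.DataFrame(columns=REGION_COLUMNS)
                         .astype({"start": np.int64, "end": np.int64}))
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = REGION_COLUMNS[: df.shape[1]]
    if "label" not in df.columns:
        df["label"] = label_default
    if df.shape[1] > 3:
        df["label"] = df["label"].astype(str)
    return RegionSet(df)


def write_bed(rs: RegionSet, path, extra_columns: list[str] | None = None) -> None:
    cols = REGION_COLUMNS + [c for c in (extra_columns or []) if c in rs.df.columns]
    rs.df[cols].to_csv(path, sep="\t", header=False, index=False)


def merge_regions(rs: RegionSet, max_gap: int) -> RegionSet:
    """Union same-chromosome regions separated by a gap smaller than ``max_gap``.

    Overlapping regions are always unioned; with ``max_gap`` 0 only true
    overlaps collapse, matching the gap < max_gap rule.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = []
    srt = rs.sort().df
    for chrom, sub in srt.groupby("chrom", sort=False):
        cur_s = cur_e = None
        label = sub["label"].iloc[0]
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s - cur_e < max_gap or s < cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e, label))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e, label))
    return RegionSet(pd.DataFrame(out, columns=REGION_COLUMNS))


def make_windows(contig_lengths: dict[str, int], size: int, min_snps: int,
                 gm: GenotypeMatrix | None = None) -> RegionSet:
    """Tile contigs into nonoverlapping windows annotated with SNP counts.

    The trailing partial tile is kept and flagged ``partial`` so that
    genome fractions computed downstream are exact.  A window is ``valid``
    when it contains at least ``min_snps`` biallelic SNPs.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if gm is not None:
        unknown = set(gm.contigs()) - set(contig_lengths)
        if unknown:
            raise ValueError(f"contigs in genotype matrix missing from lengths: {sorted(unknown)}")
    rows = []
    for chrom, length in contig_lengths.items():
        starts = np.arange(0, length, size, dtype=np.int64)
        for s in starts:
            e = min(s + size, length)
            rows.append({"chrom": chrom, "start": int(s), "end": int(e),
                         "label": "window", "partial": bool(e - s < size)})
    df = pd.DataFrame(rows)
    n_snps = np.zeros(len(df), dtype=np.int64)
    if gm is not None and gm.n_sites:
        for i, row in df.iterrows():
            on = (gm.chrom == row["chrom"]) & (gm.pos - 1 >= row["start"]) & (gm.pos - 1 < row["end"])
            n_snps[i] = int(on.sum())
    df["n_snps"] = n_snps
    df["valid"] = df["n_snps"] >= min_snps
    return RegionSet(df)


def assign_sites_to_windows(windows: RegionSet, chrom: np.ndarray,
                            pos: np.ndarray) -> np.ndarray:
    """Window index per site (-1 when outside every window).

    Assumes nonoverlapping windows sorted within chromosome, as produced
    by :func:`make_windows`.
    """
    idx = np.full(len(pos), -1, dtype=np.int64)
    p0 = np.asarray(pos) - 1
    for c, sub in windows.df.groupby("chrom", sort=False):
        on = np.asarray(chrom) == c
        if not on.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        k = np.searchsorted(starts, p0[on], side="right") - 1
        ok = (k >= 0) & (p0[on] < ends[np.clip(k, 0, len(ends) - 1)])
        loc = np.flatnonzero(on)
        idx[loc[ok]] = sub.index.to_numpy()[k[ok]]
    return idx


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SNP_ALLELES = frozenset("ACGT")


def read_vcf(path, keep_samples: list[str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Multiallelic records, indels and SVs are skipped; missing genotypes
    become :data:`MISSING`.  Dosage counts ALT copies (``coded="alt"``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    if keep_samples is not None:
        vcf.set_samples(keep_samples)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        if rec.REF not in _SNP_ALLELES or rec.ALT[0] not in _SNP_ALLELES:
            continue
        gt = rec.genotype.array()  # (n, ploidy+1), -1 = missing allele
        alleles = gt[:, :2]
        miss = (alleles < 0).any(axis=1)
        dos = alleles.clip(min=0).sum(axis=1).astype(np.int8)
        dos[miss] = MISSING
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(dos)
    if not rows:
        warnings.warn("no biallelic SNPs found; returning empty matrix")
        dosage = np.zeros((0, len(samples)), dtype=np.int8)
    else:
        dosage = np.vstack(rows)
    return GenotypeMatrix(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref_allele=np.asarray(refs, dtype=object),
        alt_allele=np.asarray(alts, dtype=object),
        dosage=dosage,
        sample_ids=samples,
        coded="alt",
    )


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write the matrix as a minimal GT-only VCF (text, version 4.2)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clonintro\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for i in range(gm.n_sites):
            gts = "\t".join(_GT_CODE[int(d)] for d in gm.dosage[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref_allele[i]}\t"
                     f"{gm.alt_allele[i]}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

def polarize_by_outgroup(gm: GenotypeMatrix, outgroup_samples: list[str]) -> GenotypeMatrix:
    """Recode dosages to count derived alleles using outgroup homozygosity.

    A site is kept only when every non-missing outgroup genotype is
    homozygous for the same allele, which is then taken as ancestral.
    Sites with heterozygous, conflicting, or entirely missing outgroup
    calls are dropped — fd/fdM and the unfolded SFS need clean polarity.
    Idempotent: an already polarized matrix passes through unchanged.
    """
    if not outgroup_samples:
        raise ValueError("outgroup_samples must be non-empty")
    oidx = gm.sample_indices(outgroup_samples)
    od = gm.dosage[:, oidx]
    called = od != MISSING
    any_called = called.any(axis=1)
    has_het = ((od == 1) & called).any(axis=1)
    all_ref = np.where(called, od == 0, True).all(axis=1)
    all_alt = np.where(called, od == 2, True).all(axis=1)
    keep = any_called & ~has_het & (all_ref | all_alt)
    flip = keep & all_alt & ~all_ref

    dosage = gm.dosage.copy()
    fl = np.flatnonzero(flip)
    sub = dosage[fl]
    sub = np.where(sub == MISSING, MISSING, 2 - sub).astype(np.int8)
    dosage[fl] = sub

    ref = gm.ref_allele.copy()
    alt = gm.alt_allele.copy()
    ref[fl], alt[fl] = gm.alt_allele[fl], gm.ref_allele[fl]

    out = replace(gm, dosage=dosage, ref_allele=ref, alt_allele=alt)
    out = out.take_sites(keep)
    out.coded = "derived"
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("polarization dropped %d/%d sites", n_drop, gm.n_sites)
    return out
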