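"""Five-population synthetic scenario with known introgression truth.

The generator mirrors the structure of a grapevine-style study system at
desk scale: a western wild donor lineage (``EU``) that split deeply and
drifted at reduced size (hence reduced diversity), two eastern wild
groups (``ME1``, ``ME2``), and two cultivated analogs (``table``,
``wine``) derived from ME2.  A recent hybridization pulse from EU into
the cultivated analogs is ~5x stronger into wine than into table,
followed by ten generations of outcrossing and a short clonal phase for
the cultivated analogs.  Outgroup samples are emitted fixed for the
ancestral allele, so outgroup polarization is exact.

Truth tracts are maximal runs of introgressed-origin sites per sampled
haplotype; tract bounds extend midpoint-to-midpoint between flanking
native sites (boundaries between markers are unobservable, so a
convention is fixed).  Tracts containing no emitted variant site are
dropped — invisible truth would be untestable.

Absolute times and population sizes are deliberately small; the tree
topology and the 5:1 pulse-rate ratio are the emulated quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import forward_sim as fs
from .core_io import GenotypeMatrix, PopulationMap, RegionSet, merge_regions, write_bed, write_vcf
from .load_stats import write_effects

SCENARIO_TREE = "(EU,(ME1,(ME2,(table,wine))));"


@dataclass
class ScenarioConfig:
    """Desk-scale study scenario; defaults define the standard conditions."""

    contigs: dict[str, int] = field(
        default_factory=lambda: {"chr1": 500_000, "chr2": 500_000})
    n_sites: int = 3000
    n_ancestral: int = 200
    n_eu: int = 80
    n_me1: int = 150
    n_me2: int = 150
    n_table: int = 100
    n_wine: int = 100
    gens_ancestral: int = 40
    gens_post_eu_split: int = 120
    gens_post_me_split: int = 50
    gens_pre_pulse: int = 15          # cultivated drift before the pulse
    outcross_generations_after_pulse: int = 10
    clonal_generations: int = 5       # recent clonality of cultivated analogs
    m_wine: float = 0.25              # pulse hybrid fraction into wine
    m_table: float = 0.05             # ~5x weaker into table
    mu: float = 1e-8
    recomb_rate: float = 1e-6
    samples_per_group: int = 12
    outgroup_samples: int = 4
    effect_probs: dict[str, float] = field(
        default_factory=lambda: {"sSNP": 0.35, "dSNP": 0.25, "SV": 0.05})
    seed: int = 0

    def validate(self) -> None:
        for name in ("gens_ancestral", "gens_post_eu_split", "gens_post_me_split",
                     "gens_pre_pulse"):
            if getattr(self, name) <= 0:
                raise ValueError(f"degenerate schedule: {name} must be positive")
        if not (0 <= self.m_wine < 1 and 0 <= self.m_table < 1):
            raise ValueError("pulse fractions must be in [0, 1)")
        if self.n_sites < len(self.contigs):
            raise ValueError("need at least one site per contig")


def _site_coordinates(cfg: ScenarioConfig, rng: np.random.Generator):
    """Per-site (chrom, 1-based pos), global bp coordinate, contig breaks."""
    names = list(cfg.contigs)
    per = np.full(len(names), cfg.n_sites // len(names))
    per[: cfg.n_sites - per.sum()] += 1
    chroms, pos1, global_pos, breaks = [], [], [], []
    offset = 0.0
    total = 0
    for name, k in zip(names, per):
        length = cfg.contigs[name]
        p = np.sort(rng.choice(length, size=k, replace=False))
        chroms.extend([name] * k)
        pos1.extend((p + 1).tolist())
        global_pos.extend((offset + p).tolist())
        offset += length
        total += k
        if total < cfg.n_sites:
            breaks.append(total - 1)  # interval index between contigs
    return (np.asarray(chroms, dtype=object), np.asarray(pos1, dtype=np.int64),
            np.asarray(global_pos, dtype=float), np.asarray(breaks, dtype=np.intp))


def _founders(rng: np.random.Generator, source: fs.SimState, n_new: int) -> fs.SimState:
    """New population founded by 2*n_new recombinant gametes from the source."""
    parents = rng.integers(0, source.n_ind, 2 * n_new)
    gam, gorig = fs.make_gametes(rng, source, parents)
    new = source.copy()
    new.hap, new.origin = gam, gorig
    return new


def _truth_tracts(cfg: ScenarioConfig, origin_rows: np.ndarray, labels: list[str],
                  chroms: np.ndarray, pos1: np.ndarray) -> RegionSet:
    rows = []
    contig_names = list(cfg.contigs)
    for hap_row, label in zip(origin_rows, labels):
        for cname in contig_names:
            on = chroms == cname
            flags = hap_row[on]
            p0 = pos1[on] - 1
            if not flags.any():
                continue
            length = cfg.contigs[cname]
            # midpoints between adjacent sites; contig edges at the ends
            left = np.empty(len(p0), dtype=np.int64)
            right = np.empty(len(p0), dtype=np.int64)
            mid = (p0[:-1] + p0[1:]) // 2
            left[0], left[1:] = 0, mid + 1
            right[-1], right[:-1] = length, mid + 1
            idx = np.flatnonzero(flags)
            splits = np.flatnonzero(np.diff(idx) > 1)
            for run in np.split(idx, splits + 1):
                rows.append({"chrom": cname, "start": int(left[run[0]]),
                             "end": int(right[run[-1]]), "label": label})
    if not rows:
        return RegionSet(pd.DataFrame(columns=["chrom", "start", "end", "label"])
                         .astype({"start": np.int64, "end": np.int64}))
    return RegionSet(pd.DataFrame(rows))


def generate_dataset(cfg: ScenarioConfig) -> dict:
    """Run the scenario and return the genotype matrix with its truth.

    Returns a dict with keys ``gm`` (polarity: dosage counts derived
    alleles, ``coded="derived"``), ``popmap``, ``truth`` (per-haplotype
    tract RegionSet), ``truth_regions`` (union of tracts), ``effects``
    (site-class table) and ``config``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chroms, pos1, gpos, breaks = _site_coordinates(cfg, rng)

    anc = fs.build_state(rng, cfg.n_ancestral, cfg.n_sites,
                         float(sum(cfg.contigs.values())), cfg.mu,
                         cfg.recomb_rate,
                         init_freqs=fs.neutral_sfs_freqs(rng, cfg.n_sites,
                                                         cfg.n_ancestral),
                         pos=gpos)
    anc.p_switch = fs.haldane_switch_probs(gpos, cfg.recomb_rate, breaks)

    def run(pops, gens, clonal=()):
        for _ in range(gens):
            for name, st in pops.items():
                (fs.step_clonal if name in clonal else fs.step_outcrossing)(rng, st)

    run({"anc": anc}, cfg.gens_ancestral)
    eu = _founders(rng, anc, cfg.n_eu)
    me_anc = _founders(rng, anc, cfg.n_ancestral)
    run({"EU": eu, "me_anc": me_anc}, cfg.gens_post_eu_split)
    me1 = _founders(rng, me_anc, cfg.n_me1)
    me2 = _founders(rng, me_anc, cfg.n_me2)
    run({"EU": eu, "ME1": me1, "ME2": me2}, cfg.gens_post_me_split)
    table = _founders(rng, me2, cfg.n_table)
    wine = _founders(rng, me2, cfg.n_wine)
    pops = {"EU": eu, "ME1": me1, "ME2": me2, "table": table, "wine": wine}
    run(pops, cfg.gens_pre_pulse)

    if cfg.m_wine > 0:
        pops["wine"] = fs.hybridize(wine, eu, cfg.m_wine, rng)
    if cfg.m_table > 0:
        pops["table"] = fs.hybridize(table, eu, cfg.m_table, rng)
    run(pops, cfg.outcross_generations_after_pulse)
    run(pops, cfg.clonal_generations, clonal=("table", "wine"))

    # --- emission ---------------------------------------------------------
    sample_rows, dosage_cols, origin_rows, hap_labels = [], [], [], []
    assignments: dict[str, str] = {}
    for group in ("ME1", "ME2", "EU", "table", "wine"):
        st = pops[group]
        picked = np.sort(rng.choice(st.n_ind, cfg.samples_per_group, replace=False))
        for k, ind in enumerate(picked):
            sid = f"{group}{k:02d}"
            assignments[sid] = group
            dos = st.hap[2 * ind].astype(np.int8) + st.hap[2 * ind + 1]
            dosage_cols.append(dos)
            for hap in (0, 1):
                if group in ("table", "wine"):
                    origin_rows.append(st.origin[2 * ind + hap])
                    hap_labels.append(f"{sid}_hap{hap}")
    for k in range(cfg.outgroup_samples):
        sid = f"OUT{k:02d}"
        assignments[sid] = "OUT"
        dosage_cols.append(np.zeros(cfg.n_sites, dtype=np.int8))

    dosage = np.column_stack(dosage_cols)
    ingroup = dosage[:, : -cfg.outgroup_samples] if cfg.outgroup_samples else dosage
    keep = ingroup.sum(axis=1) > 0  # variable among emitted ingroup samples
    gm = GenotypeMatrix(
        chrom=chroms[keep], pos=pos1[keep],
        ref_allele=np.asarray(["A"] * int(keep.sum()), dtype=object),
        alt_allele=np.asarray(["T"] * int(keep.sum()), dtype=object),
        dosage=dosage[keep], sample_ids=list(assignments), coded="derived")

    origin_rows = np.asarray(origin_rows)
    truth = _truth_tracts(cfg, origin_rows, hap_labels, chroms, pos1)
    if len(truth):
        visible = [bool(truth_row_has_site(r, gm)) for r in truth.df.itertuples()]
        truth = RegionSet(truth.df[visible])
    # population-level region calls: runs of sites where donor-ancestry
    # frequency among wine-analog haplotypes is at least twice the pulse
    # expectation — the object a region classifier would call introgressed
    wine_rows = np.asarray([l.startswith("wine") for l in hap_labels])
    anc_freq = origin_rows[wine_rows].mean(axis=0) if wine_rows.any() else \
        np.zeros(cfg.n_sites)
    # top-decile ancestry call (with an absolute floor), echoing how
    # region scans take the top quantile of a signal; robust to drift of
    # the overall pulse ancestry
    thresh = max(float(np.quantile(anc_freq, 0.9)), 0.05)
    enriched = anc_freq >= thresh
    truth_regions = _truth_tracts(cfg, enriched[None, :], ["introgressed"],
                                  chroms, pos1)
    if len(truth_regions):
        truth_regions = merge_regions(truth_regions, 0)

    classes = np.asarray(list(cfg.effect_probs), dtype=object)
    probs = np.asarray(list(cfg.effect_probs.values()))
    draw = rng.random(gm.n_sites)
    edges = np.cumsum(probs)
    which = np.searchsorted(edges, draw)
    labeled = which < len(classes)
    effects = pd.DataFrame({"chrom": gm.chrom[labeled], "pos": gm.pos[labeled],
                            "class": classes[which[labeled]]})

    return {"gm": gm, "popmap": PopulationMap(assignments), "truth": truth,
            "truth_regions": truth_regions, "effects": effects, "config": cfg,
            "tree": SCENARIO_TREE}


def truth_row_has_site(row, gm: GenotypeMatrix) -> bool:
    on = (gm.chrom == row.chrom) & (gm.pos - 1 >= row.start) & (gm.pos - 1 < row.end)
    return bool(on.any())


def spike_load(dataset: dict, enrichment: float, seed: int,
               recipient_group: str = "wine") -> dict:
    """Relabel dSNPs so heterozygous-dSNP density inside truth tracts is
    ``enrichment`` x the outside density.

    Uses rejection-style greedy assignment over candidate (non-SV) sites;
    the realized enrichment is recorded in the returned dict.
    """
    gm: GenotypeMatrix = dataset["gm"]
    truth_regions: RegionSet = dataset["truth_regions"]
    if len(truth_regions) == 0:
        raise ValueError("dataset has no truth tracts to enrich")
    rng = np.random.default_rng(seed)
    ridx = gm.sample_indices(dataset["popmap"].samples(recipient_group))
    het = (gm.dosage[:, ridx] == 1).sum(axis=1).astype(float)

    effects = dataset["effects"]
    sv_keys = set(zip(effects.loc[effects["class"] == "SV", "chrom"],
                      effects.loc[effects["class"] == "SV", "pos"]))
    candidate = np.fromiter(((c, p) not in sv_keys
                             for c, p in zip(gm.chrom, gm.pos)),
                            dtype=bool, count=gm.n_sites)
    inside = truth_regions.site_mask(gm.chrom, gm.pos)
    genome_bp = int(effects_genome_length(dataset))
    l_in = truth_regions.total_length()
    l_out = genome_bp - l_in
    out_sites = np.flatnonzero(candidate & ~inside & (het > 0))
    in_sites = np.flatnonzero(candidate & inside & (het > 0))
    if len(out_sites) == 0 or len(in_sites) == 0:
        raise ValueError("no heterozygous candidate sites to label as dSNP")

    # outside-dSNP budget: at most a third of candidates, capped so the
    # inside het mass can actually meet the enrichment target
    order = rng.permutation(in_sites)
    cum = np.cumsum(het[order])
    mean_het_out = het[out_sites].mean()
    feasible = int(0.8 * cum[-1] * l_out / (enrichment * l_in * mean_het_out))
    n_out_d = min(max(len(out_sites) // 3, 1), max(feasible, 0))
    if n_out_d < 1:
        raise ValueError(
            f"tracts too small to realize enrichment {enrichment}: inside "
            f"heterozygote mass {cum[-1]:.1f} cannot match even one outside dSNP")
    chosen_out = rng.choice(out_sites, n_out_d, replace=False)
    # drop highest-het outside picks until the inside mass can match
    chosen_out = chosen_out[np.argsort(het[chosen_out])]
    while len(chosen_out) > 1 and \
            enrichment * het[chosen_out].sum() / l_out * l_in > cum[-1]:
        chosen_out = chosen_out[:-1]
    d_out = het[chosen_out].sum() / l_out
    target_in = enrichment * d_out * l_in
    if cum[-1] < target_in:
        raise ValueError(
            f"tracts too small to realize enrichment {enrichment}: "
            f"need heterozygote mass >= {target_in:.1f}, have {cum[-1]:.1f}")
    n_in_d = int(np.searchsorted(cum, target_in) + 1)
    if n_in_d > 1 and abs(cum[n_in_d - 2] - target_in) < abs(cum[n_in_d - 1] - target_in):
        n_in_d -= 1  # the smaller set lands nearer the target
    chosen_in = order[:n_in_d]
    d_in = het[chosen_in].sum() / l_in
    realized = d_in / d_out

    dsnp = np.zeros(gm.n_sites, dtype=bool)
    dsnp[chosen_out] = True
    dsnp[chosen_in] = True
    keep = effects[effects["class"] != "dSNP"]
    keep_keys = set(zip(keep["chrom"], keep["pos"]))
    rows = [{"chrom": c, "pos": p, "class": "dSNP"}
            for c, p in zip(gm.chrom[dsnp], gm.pos[dsnp])
            if (c, p) not in keep_keys]
    new_effects = (pd.concat([keep, pd.DataFrame(rows)], ignore_index=True)
                   .sort_values(["chrom", "pos"], kind="mergesort")
                   .reset_index(drop=True))
    out = dict(dataset)
    out["effects"] = new_effects
    out["realized_enrichment"] = float(realized)
    return out


def effects_genome_length(dataset: dict) -> int:
    return int(sum(dataset["config"].contigs.values()))


def write_dataset(dataset: dict, outdir) -> dict[str, str]:
    """Write VCF, popmap, truth BEDs, effects TSV and a config echo."""
    import pathlib

    import yaml

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg: ScenarioConfig = dataset["config"]
    paths = {
        "vcf": str(outdir / "synthetic.vcf"),
        "popmap": str(outdir / "popmap.tsv"),
        "truth_bed": str(outdir / "truth_tracts.bed"),
        "truth_regions_bed": str(outdir / "truth_regions.bed"),
        "effects": str(outdir / "effects.tsv"),
        "config": str(outdir / "scenario.yaml"),
        "tree": str(outdir / "populations.nwk"),
    }
    write_vcf(dataset["gm"], paths["vcf"], cfg.contigs)
    dataset["popmap"].write(paths["popmap"])
    write_bed(dataset["truth"], paths["truth_bed"])
    write_bed(dataset["truth_regions"], paths["truth_regions_bed"])
    write_effects(dataset["effects"], paths["effects"])
    with open(paths["tree"], "w") as fh:
        fh.write(dataset["tree"] + "\n")
    echo = {k: (dict(v) if isinstance(v, dict) else v)
            for k, v in cfg.__dict__.items()}
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=True)
    return paths
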