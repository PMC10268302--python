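"""Diploid Wright-Fisher forward simulator with clonal propagation.

The engine tracks a fixed panel of polymorphic sites on a genome of
``genome_length`` bp.  Fitness is multiplicative across sites,
``w = prod (1+s)^hom (1+h s)^het``.  Reproduction is either outcrossing
(two fitness-weighted parents, gametes formed with recombination) or
clonal (one fitness-weighted parent copied exactly).  Recombination uses
the Haldane map between adjacent tracked sites — switch probability
``0.5 (1 - exp(-2 r d))`` for an inter-site distance of ``d`` bp — which
delivers Poisson(r * L) crossovers per gamete in aggregate and free
reassortment of distant sites.  Mutation is Poisson(mu * L) per gamete;
under clonality each of the two haplotypes of the copied offspring
mutates at the same Poisson(mu * L) rate, so the per-genome mutation
input matches the outcrossing mode and heterozygosity can accumulate
(the mechanism behind the clonal heterozygosity rise).

Every allele copy carries an origin flag (native / introgressed) that is
transmitted through reproduction and never relabeled, so the fate of a
hybridization pulse can be followed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class NonviablePopulationError(RuntimeError):
    """All individuals have zero fitness."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class DFEConfig:
    """Distribution of fitness effects for donor/pulse and new mutations.

    Beneficial s ~ Exponential(mean ``s_beneficial_mean``); deleterious
    s ~ -Gamma(shape, mean |``s_deleterious_mean``|).  A site is
    beneficial with probability ``p_beneficial``, otherwise deleterious;
    set both means to 0 for a neutral model.
    """

    p_beneficial: float = 0.5
    s_beneficial_mean: float = 0.01
    s_deleterious_mean: float = -0.01
    s_deleterious_shape: float = 0.3

    def draw(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Selection coefficients and classes (+1 beneficial, -1 deleterious, 0 neutral)."""
        ben = rng.random(n) < self.p_beneficial
        s = np.zeros(n)
        klass = np.zeros(n, dtype=np.int8)
        if self.s_beneficial_mean > 0:
            s[ben] = rng.exponential(self.s_beneficial_mean, ben.sum())
            klass[ben] = 1
        mean_del = abs(self.s_deleterious_mean)
        if mean_del > 0:
            shape = self.s_deleterious_shape
            s[~ben] = -rng.gamma(shape, mean_del / shape, (~ben).sum())
            klass[~ben] = -1
        return s, klass


@dataclass
class SimConfig:
    """Forward-simulation parameters (desk-scale defaults)."""

    n_recipient: int = 200
    n_donor: int = 100
    genome_length: float = 1_000_000.0
    n_sites: int = 1000
    n_donor_sites: int = 200           # donor-fixed differential sites in the pulse
    mu: float = 5e-8                   # per bp per generation
    recomb_rate: float = 1e-6          # per bp per generation
    dfe: DFEConfig = field(default_factory=DFEConfig)
    h: float = 0.5                     # dominance, beneficial sites
    h_deleterious: float | None = None  # override for deleterious sites
    hybrid_fraction: float = 0.1
    outcross_generations_after_pulse: int = 10
    total_generations: int = 2000
    propagation_mode: str = "clonal"   # mode after the post-pulse outcrossing phase
    record_every: int = 25
    snapshot_generations: tuple[int, ...] = ()
    replicates: int = 1
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_recipient, self.n_donor, self.n_sites) <= 0:
            raise ValueError("population sizes and site counts must be positive")
        if not 0.0 <= self.hybrid_fraction <= 1.0:
            raise ValueError("hybrid_fraction must be in [0, 1]")
        if self.mu < 0 or self.recomb_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.propagation_mode not in ("clonal", "outcrossing"):
            raise ValueError("propagation_mode must be 'clonal' or 'outcrossing'")
        if any(g > self.total_generations for g in self.snapshot_generations):
            raise ValueError("snapshot generation beyond total_generations")


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

@dataclass
class SimState:
    """Diploid population: haplotype rows 2i, 2i+1 belong to individual i."""

    hap: np.ndarray        # (2N, S) uint8 alleles
    origin: np.ndarray     # (2N, S) bool, True = introgressed ancestry
    s: np.ndarray          # (S,) selection coefficient per site
    h: np.ndarray          # (S,) dominance per site
    pos: np.ndarray        # (S,) bp positions, strictly increasing
    p_switch: np.ndarray   # (S-1,) inter-site recombination probabilities
    site_class: np.ndarray  # (S,) int8: +1 beneficial, -1 deleterious, 0 neutral
    mu_genome: float       # mu * L, expected new mutations per gamete

    @property
    def n_ind(self) -> int:
        return self.hap.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.hap.shape[1]

    def copy(self) -> "SimState":
        return SimState(self.hap.copy(), self.origin.copy(), self.s.copy(),
                        self.h.copy(), self.pos.copy(), self.p_switch.copy(),
                        self.site_class.copy(), self.mu_genome)

    def dosage(self) -> np.ndarray:
        return self.hap[0::2].astype(np.int16) + self.hap[1::2]

    def mean_heterozygosity(self) -> float:
        """Mean over individuals of the per-site heterozygous fraction."""
        return float((self.dosage() == 1).mean())


def haldane_switch_probs(pos: np.ndarray, r: float,
                         contig_breaks: np.ndarray | None = None) -> np.ndarray:
    d = np.diff(pos)
    p = 0.5 * (1.0 - np.exp(-2.0 * r * d))
    if contig_breaks is not None and len(contig_breaks):
        p[contig_breaks] = 0.5  # free reassortment across contigs
    return p


def build_state(rng: np.random.Generator, n_ind: int, n_sites: int,
                genome_length: float, mu: float, r: float,
                init_freqs: np.ndarray | None = None,
                pos: np.ndarray | None = None) -> SimState:
    """Neutral population, optionally with standing variation.

    ``init_freqs`` gives per-site starting derived frequencies; haplotypes
    are independent Bernoulli draws (linkage equilibrium start).
    """
    if pos is None:
        pos = np.sort(rng.random(n_sites)) * genome_length
    hap = np.zeros((2 * n_ind, n_sites), dtype=np.uint8)
    if init_freqs is not None:
        hap[:] = rng.random((2 * n_ind, n_sites)) < init_freqs
    return SimState(
        hap=hap,
        origin=np.zeros_like(hap, dtype=bool),
        s=np.zeros(n_sites),
        h=np.full(n_sites, 0.5),
        pos=pos,
        p_switch=haldane_switch_probs(pos, r),
        site_class=np.zeros(n_sites, dtype=np.int8),
        mu_genome=mu * genome_length,
    )


def neutral_sfs_freqs(rng: np.random.Generator, n_sites: int, n_anc: int) -> np.ndarray:
    """Starting frequencies drawn from the neutral 1/i spectrum of a 2N pool."""
    counts = np.arange(1, 2 * n_anc)
    w = 1.0 / counts
    return counts[rng.choice(len(counts), n_sites, p=w / w.sum())] / (2.0 * n_anc)


# ---------------------------------------------------------------------------
# generation kernels
# ---------------------------------------------------------------------------

def _fitness(state: SimState) -> np.ndarray:
    sel = np.flatnonzero(state.s != 0.0)
    n = state.n_ind
    if len(sel) == 0:
        return np.ones(n)
    d = state.hap[0::2][:, sel].astype(np.float64) + state.hap[1::2][:, sel]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_het = np.log1p(state.h[sel] * state.s[sel])
        log_hom = np.log1p(state.s[sel])
    logw = (d == 1.0) @ log_het + (d == 2.0) @ log_hom
    logw = np.where(np.isnan(logw), -np.inf, logw)
    top = logw.max()
    if not np.isfinite(top):
        raise NonviablePopulationError("all individuals have zero fitness")
    return np.exp(logw - top)


def _sample_parents(rng: np.random.Generator, w: np.ndarray, size: int) -> np.ndarray:
    if np.all(w == w[0]):
        return rng.integers(0, len(w), size)
    total = w.sum()
    if total <= 0:
        raise NonviablePopulationError("all individuals have zero fitness")
    return rng.choice(len(w), size=size, p=w / total)


def make_gametes(rng: np.random.Generator, state: SimState,
                 parents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One recombinant gamete (alleles, origins) per entry of ``parents``."""
    g = len(parents)
    s_count = state.n_sites
    h0 = state.hap[2 * parents]
    h1 = state.hap[2 * parents + 1]
    choice = np.empty((g, s_count), dtype=bool)
    choice[:, 0] = rng.integers(0, 2, g, dtype=np.int8).astype(bool)
    if s_count > 1:
        switches = rng.random((g, s_count - 1)) < state.p_switch
        parity = np.cumsum(switches, axis=1, dtype=np.int32) & 1
        choice[:, 1:] = choice[:, [0]] ^ parity.astype(bool)
    gam = np.where(choice, h1, h0)
    o0 = state.origin[2 * parents]
    o1 = state.origin[2 * parents + 1]
    gorig = np.where(choice, o1, o0)
    return gam, gorig


def _mutate(rng: np.random.Generator, hap: np.ndarray, mu_genome: float) -> None:
    """Poisson(mu*L) mutations per haplotype row, flipping the current allele."""
    n_mut = rng.poisson(mu_genome * hap.shape[0])
    if n_mut:
        rows = rng.integers(0, hap.shape[0], n_mut)
        cols = rng.integers(0, hap.shape[1], n_mut)
        hap[rows, cols] ^= 1


def step_outcrossing(rng: np.random.Generator, state: SimState) -> None:
    w = _fitness(state)
    n = state.n_ind
    mothers = _sample_parents(rng, w, n)
    fathers = _sample_parents(rng, w, n)
    parents = np.empty(2 * n, dtype=np.intp)
    parents[0::2] = mothers
    parents[1::2] = fathers
    gam, gorig = make_gametes(rng, state, parents)
    state.hap = gam
    state.origin = gorig
    _mutate(rng, state.hap, state.mu_genome)


def step_clonal(rng: np.random.Generator, state: SimState) -> None:
    w = _fitness(state)
    parents = _sample_parents(rng, w, state.n_ind)
    rows = np.empty(2 * state.n_ind, dtype=np.intp)
    rows[0::2] = 2 * parents
    rows[1::2] = 2 * parents + 1
    state.hap = state.hap[rows].copy()
    state.origin = state.origin[rows].copy()
    _mutate(rng, state.hap, state.mu_genome)


STEPS = {"outcrossing": step_outcrossing, "clonal": step_clonal}


def hybridize(state: SimState, donor: SimState, hybrid_fraction: float,
              rng: np.random.Generator) -> SimState:
    """Replace floor(f*N) recipient individuals with recipient x donor F1s.

    Each F1 receives one recombinant gamete from a random recipient parent
    and one from a random donor parent; every allele copy on the donor
    gamete is flagged introgressed.
    """
    if not 0.0 <= hybrid_fraction <= 1.0:
        raise ValueError("hybrid_fraction must be in [0, 1]")
    n_f1 = int(hybrid_fraction * state.n_ind)
    if n_f1 == 0:
        return state
    out = state.copy()
    slots = rng.choice(state.n_ind, n_f1, replace=False)
    rec_parents = rng.integers(0, state.n_ind, n_f1)
    don_parents = rng.integers(0, donor.n_ind, n_f1)
    rec_gam, rec_orig = make_gametes(rng, state, rec_parents)
    don_gam, _ = make_gametes(rng, donor, don_parents)
    out.hap[2 * slots] = rec_gam
    out.origin[2 * slots] = rec_orig
    out.hap[2 * slots + 1] = don_gam
    out.origin[2 * slots + 1] = True
    return out


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryRecord:
    generation: int
    total_introgressed_copies: int
    segregating_introgressed_sites: int
    segregating_beneficial: int
    segregating_deleterious: int
    mean_heterozygosity: float


def introgressed_copy_counts(state: SimState, site_idx: np.ndarray) -> np.ndarray:
    """Derived, introgressed-origin allele copies per tracked site."""
    sub = (state.hap[:, site_idx] == 1) & state.origin[:, site_idx]
    return sub.sum(axis=0)


def record_state(state: SimState, site_idx: np.ndarray, gen: int) -> TrajectoryRecord:
    counts = introgressed_copy_counts(state, site_idx)
    two_n = state.hap.shape[0]
    seg = (counts > 0) & (counts < two_n)
    klass = state.site_class[site_idx]
    return TrajectoryRecord(
        generation=gen,
        total_introgressed_copies=int(counts.sum()),
        segregating_introgressed_sites=int(seg.sum()),
        segregating_beneficial=int((seg & (klass == 1)).sum()),
        segregating_deleterious=int((seg & (klass == -1)).sum()),
        mean_heterozygosity=state.mean_heterozygosity(),
    )


def plateau_generation(generations: np.ndarray, totals: np.ndarray,
                       window: int = 50, tol: float = 0.01,
                       confirm: int = 3) -> int | None:
    """First generation where the ``window``-generation sliding mean of the
    total-copy trajectory changes by < ``tol`` (relative), sustained for
    ``confirm`` consecutive records.  None when no plateau is reached."""
    generations = np.asarray(generations)
    totals = np.asarray(totals, dtype=float)
    if len(totals) < 2:
        return None
    step = max(int(np.median(np.diff(generations))), 1)
    k = max(window // step, 1)
    if len(totals) <= k:
        return None
    sliding = np.convolve(totals, np.ones(k) / k, mode="valid")
    gens = generations[k - 1:]
    ok_run = 0
    for i in range(1, len(sliding)):
        prev = sliding[i - 1]
        change = abs(sliding[i] - prev) / prev if prev > 0 else 0.0
        ok_run = ok_run + 1 if change < tol else 0
        if ok_run >= confirm:
            return int(gens[i - confirm + 1])
    return None


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _replicate_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))
            for k in range(n)]


def _build_pulse_states(cfg: SimConfig, rng: np.random.Generator
                        ) -> tuple[SimState, SimState, np.ndarray]:
    """Recipient + donor populations sharing background standing variation;
    donor fixed derived at the donor-differential sites."""
    n_sites = cfg.n_sites
    donor_idx = np.sort(rng.choice(n_sites, min(cfg.n_donor_sites, n_sites),
                                   replace=False))
    background = np.setdiff1d(np.arange(n_sites), donor_idx)
    freqs = np.zeros(n_sites)
    if len(background):
        freqs[background] = neutral_sfs_freqs(rng, len(background), cfg.n_recipient)
    pos = np.sort(rng.random(n_sites)) * cfg.genome_length
    recipient = build_state(rng, cfg.n_recipient, n_sites, cfg.genome_length,
                            cfg.mu, cfg.recomb_rate, init_freqs=freqs, pos=pos)
    donor = build_state(rng, cfg.n_donor, n_sites, cfg.genome_length,
                        cfg.mu, cfg.recomb_rate, init_freqs=freqs, pos=pos)
    donor.hap[:, donor_idx] = 1
    donor.origin[:] = True
    s, klass = cfg.dfe.draw(rng, len(donor_idx))
    for st in (recipient, donor):
        st.s[donor_idx] = s
        st.site_class[donor_idx] = klass
        if cfg.h_deleterious is not None:
            st.h[donor_idx[klass == -1]] = cfg.h_deleterious
        st.h[donor_idx[klass == 1]] = cfg.h
    return recipient, donor, donor_idx


def run_forward(cfg: SimConfig) -> list[dict]:
    """Run the hybridization-pulse experiment for each replicate.

    Schedule: pulse at generation 0, ``outcross_generations_after_pulse``
    generations of outcrossing, then ``propagation_mode`` for the rest.
    Returns one dict per replicate with the trajectory (list of
    :class:`TrajectoryRecord`), snapshots (generation -> dict with
    introgressed-allele frequencies and surviving-allele ``s`` values),
    and the final state.
    """
    cfg.validate()
    results = []
    for rng in _replicate_rngs(cfg.seed, cfg.replicates):
        recipient, donor, donor_idx = _build_pulse_states(cfg, rng)
        state = hybridize(recipient, donor, cfg.hybrid_fraction, rng)
        traj = [record_state(state, donor_idx, 0)]
        snapshots: dict[int, dict] = {}
        for gen in range(1, cfg.total_generations + 1):
            mode = ("outcrossing" if gen <= cfg.outcross_generations_after_pulse
                    else cfg.propagation_mode)
            STEPS[mode](rng, state)
            if gen % cfg.record_every == 0 or gen == cfg.total_generations:
                traj.append(record_state(state, donor_idx, gen))
            if gen in cfg.snapshot_generations:
                snapshots[gen] = snapshot(state, donor_idx)
        results.append({"trajectory": traj, "snapshots": snapshots,
                        "state": state, "donor_site_idx": donor_idx})
    return results


def snapshot(state: SimState, donor_idx: np.ndarray) -> dict:
    """Frequencies and fitness effects of surviving introgressed alleles."""
    counts = introgressed_copy_counts(state, donor_idx)
    two_n = state.hap.shape[0]
    alive = counts > 0
    seg = alive & (counts < two_n)
    return {
        "freq": counts[seg] / two_n,
        "freq_all_surviving": counts[alive] / two_n,
        "s": state.s[donor_idx][alive],
        "class": state.site_class[donor_idx][alive],
    }


def heterozygosity_experiment(cfg: SimConfig) -> dict[str, list[list[TrajectoryRecord]]]:
    """Outcrossing vs clonal heterozygosity trajectories from identical
    starting populations (no pulse, mutation on)."""
    cfg.validate()
    out: dict[str, list] = {"outcrossing": [], "clonal": []}
    for rng in _replicate_rngs(cfg.seed, cfg.replicates):
        base = build_state(rng, cfg.n_recipient, cfg.n_sites, cfg.genome_length,
                           cfg.mu, cfg.recomb_rate)
        empty = np.arange(cfg.n_sites)
        child = rng.spawn(2)
        for mode, r in zip(("outcrossing", "clonal"), child):
            state = base.copy()
            traj = [record_state(state, empty, 0)]
            for gen in range(1, cfg.total_generations + 1):
                STEPS[mode](r, state)
                if gen % cfg.record_every == 0 or gen == cfg.total_generations:
                    traj.append(record_state(state, empty, gen))
            out[mode].append(traj)
    return out


def default_pulse_config(seed: int = 0, **overrides) -> SimConfig:
    """Standard conditions for the hybridization-pulse experiments.

    Weak per-site selection spread over many donor sites: selection then
    acts on whole-clone load under clonality (fast takeover) but
    site-by-site under outcrossing (slow, drift-limited fixation) — the
    regime in which introgressed alleles establish and the clonal arm
    equilibrates much earlier than the outcrossing arm.  Mutation is off
    so trajectories reflect only the fate of the pulse alleles.
    """
    base = dict(
        n_recipient=150, n_donor=80, n_sites=400, n_donor_sites=150,
        mu=0.0,
        dfe=DFEConfig(p_beneficial=0.5, s_beneficial_mean=0.01,
                      s_deleterious_mean=-0.004, s_deleterious_shape=0.5),
        hybrid_fraction=0.1, outcross_generations_after_pulse=10,
        total_generations=2000, record_every=25, replicates=20, seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def introgression_experiment(cfg: SimConfig) -> dict[str, list[dict]]:
    """Both arms of the pulse experiment: clonal-after-pulse vs outcrossing
    throughout, with identical per-replicate seeds."""
    arms = {}
    for mode in ("clonal", "outcrossing"):
        arm_cfg = SimConfig(**{**cfg.__dict__, "propagation_mode": mode})
        arms[mode] = run_forward(arm_cfg)
    return arms


def trajectory_frame(traj: list[TrajectoryRecord]):
    import pandas as pd

    return pd.DataFrame([t.__dict__ for t in traj])
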