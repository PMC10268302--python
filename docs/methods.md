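# Methods

## Data model and conventions

Genotypes live in a sites × samples dosage matrix restricted to biallelic
SNPs; dosage counts copies of the coded allele with −1 for a missing
genotype. VCF positions are 1-based; all internal region arithmetic
(windows, introgressed calls, genes, truth tracts) is 0-based half-open.
Outgroup polarization keeps a site only when every non-missing outgroup
genotype is homozygous for the same allele; that allele becomes ancestral
and dosages are flipped where needed. Sites with heterozygous, conflicting
or entirely missing outgroup calls are dropped rather than folded, because
fd/fdM and the unfolded SFS require derived-allele polarity. Polarization
is idempotent.

Windows tile each contig; the trailing partial tile is kept and flagged so
genome fractions remain exact. A window is valid when it holds at least
`min_snps` biallelic SNPs (default 100 per 50 kb, the rule of thumb for
fd-style scans on resequencing data; the synthetic scenario uses 20 at its
smaller scale). Invalid windows propagate NaN — never 0 — so quantile-based
region extraction skips them.

## Statistics

Per site with derived frequency *p* and *n* non-missing haplotypes:
π site = 2p(1−p)·n/(n−1); D<sub>xy</sub> site = p₁(1−p₂)+p₂(1−p₁). Window
values divide the per-site sums by the full window length in bp, treating
unobserved positions as invariant — the convention that puts SNP-only input
on the familiar per-bp scale (~10⁻³). F<sub>ST</sub> is the Hudson
estimator aggregated as a ratio of sums, chosen for robustness to unequal
sample sizes; slightly negative estimates near zero differentiation are
reported as computed. PBS uses T = −log(1−F<sub>ST</sub>); windows with any
pairwise F<sub>ST</sub> ≥ 1 are flagged non-finite.

ABBA-BABA statistics follow the frequency formulation: ABBA =
(1−p₁)p₂p₃(1−p₄), BABA = p₁(1−p₂)p₃(1−p₄). fd substitutes the larger of
(p₂, p₃) into both donor slots of the denominator and is reported NaN for
windows whose numerator sum is not positive — the statistic is defined only
for excess ABBA, and density plots need honest missingness rather than
zeros. fdM switches the denominator between P2↔P3 sharing (p₂ ≥ p₁) and
negated P1↔P3 sharing (p₁ > p₂); positive fdM means donor sharing with P2.
Block-jackknife (block = window) standard errors accompany genome-wide D,
but region extraction is quantile-based, not significance-gated. The
f-branch matrix computes f4-admixture ratios f(A,B,C) = Σ(ABBA−BABA) /
Σ(ABBA−BABA with C substituted for B) for every tree-consistent trio and
aggregates fb(b, C) = median over valid A of [min over B descendants of b],
negatives floored at zero. At desk scale, cells whose donor is the
immediate sister of the focal clade carry an inflated null from shared
drift on the short internal branch — a known caveat of f-branch — so null
calibration should be read from the donor column of interest (the EU-like
donor in the bundled scenario).

PI_HAT inverts observed IBS counts to IBD probabilities by the method of
moments. The conditional IBS-given-IBD probabilities are derived by drawing
the non-shared alleles without replacement from the cohort allele pool,
which reproduces the finite-sample corrections of the classic PLINK
`--genome` estimator; negative intermediate probabilities are clamped to
zero before renormalization, and pairs with fewer than 50 informative sites
are flagged low-confidence.

Load models per individual and region stratum: heterozygous load = het
dSNP genotypes, recessive load = hom-derived dSNP genotypes, additive =
het + 2·hom. The dSNP/sSNP ratio uses additive allele counts by default
(per-individual burden framing); a site-count variant sits behind a flag.
Effect classes are consumed as input — no variant-effect prediction is
performed — and the synthetic generator labels sites itself. Random control
regions preserve template lengths exactly, are placed uniformly over
admissible starts genome-wide, and are re-drawn on collision within a
replicate; placement is seed-reproducible. Introgressed-candidate alleles
are a declared convention: derived alleles inside a region call with donor
frequency ≥ 0.2 and reference-group frequency ≤ 0 by default, both
configurable. Spectra comparisons use the Wilcoxon signed-rank test over
matched normalized bins, reporting a signed rank sum (negative = mass
shifted toward rare bins) alongside the p-value; identical spectra return
(0, 1) exactly.

## Forward simulator

Diploid Wright–Fisher with multiplicative fitness
w = Π (1+s)^hom (1+hs)^het over selected sites. Outcrossing samples two
fitness-weighted parents per offspring and builds each gamete by switching
between parental haplotypes with the Haldane probability
0.5(1−e^(−2rd)) per inter-site interval (0.5 across contig boundaries),
which yields Poisson(r·L) crossovers in aggregate and free reassortment of
distant sites. Clonal reproduction samples one fitness-weighted parent and
copies the diploid genotype exactly. Mutation is Poisson(μ·L) per gamete;
under clonality each haplotype of the copy mutates at the same rate, so the
per-genome mutational input matches the outcrossing mode and heterozygosity
can accumulate — the mechanism behind the clonal heterozygosity rise.
Mutations flip the current allele, so long-run neutral equilibrium follows
the symmetric biallelic model; at the small per-site θ used in tests
(≤ 0.05) its expected heterozygosity is within a few percent of the
infinite-alleles form 4Nμ′/(1+4Nμ′).

Hybridization replaces ⌊f·N⌋ recipients with F1s (one recombinant gamete
from each population); every allele copy on the donor gamete is flagged
introgressed, and flags are transmitted through reproduction but never
relabeled. "Equilibrium" is operationalized as the first generation where a
50-generation sliding mean of total introgressed copies changes by < 1%
for three consecutive records.

### Pulse-experiment conditions

The standard pulse experiment (`default_pulse_config`) uses N = 150
recipients (200 in the acceptance run), 150–200 donor-fixed sites, pulse
fraction 0.1, ten outcrossing generations, then 2,000 generations in the
scheduled mode, with weak per-site selection: beneficial s ~ Exp(0.01),
deleterious s ~ −Gamma(shape 0.5, mean 0.004), h = 0.5, and mutation off so
trajectories reflect only the fate of the pulse alleles. The regime is
chosen for its mechanism: with many weakly selected sites, clonality makes
selection act on whole-clone load — takeover is fast and the copy total
plateaus within a few hundred generations — while outcrossing decouples
sites and resolves them one by one on the drift timescale, plateauing much
later. A net-adaptive pulse is required for the copy total to rise to a
plateau at all; a net-deleterious pulse is simply purged. Under strict
clonality the winning clone preserves its heterozygous introgressed sites
indefinitely, so surviving segregating alleles sit at exactly 50%
frequency — the quantity the acceptance script reports.

## Synthetic scenario

The generator runs the engine over a split schedule: an ancestral
population seeded with standing variation drawn from the neutral 1/i
spectrum; a deep split producing a low-diversity donor lineage (EU-like,
N = 80) and an eastern wild ancestor; splits into two wild groups (ME-like,
N = 150 each); and two cultivated analogs (N = 100) founded from one of
them. Fifteen generations before sampling, the donor pulses into both
cultivated analogs with hybrid fractions 0.25 (wine analog) and 0.05
(table analog) — the 5:1 ratio is the emulated quantity, not the absolute
rate — followed by ten outcrossing generations and five clonal generations
for the cultivated analogs. Outgroup samples are emitted fixed ancestral,
so polarization is exact. The desk genome is two 500-kb contigs carrying
3,000 tracked sites, giving ~50 emitted SNPs per 50-kb window — windowed
fd needs adequate per-window SNP counts to be meaningful, and sparser
desk genomes violate the method's own applicability.

Truth comes in two forms. Per-haplotype tracts are maximal runs of
introgressed-origin sites, with bounds extended midpoint-to-midpoint
between flanking native sites (tract edges between markers are
unobservable, so a convention must be fixed); tracts containing no emitted
variant are dropped. Region-level calls are runs of sites whose
donor-ancestry frequency among sampled wine-analog haplotypes falls in the
top decile (absolute floor 5%), echoing top-quantile region extraction;
a disabled pulse yields no calls. `spike_load` relabels dSNPs so the
heterozygous-dSNP density inside region calls is a chosen multiple of the
outside density, by greedy seeded assignment against the realized
heterozygote mass; the realized enrichment is recorded, making the spike a
recoverable ground truth for the load pipeline.

What the generator does not emulate: realistic recombination maps,
mutation-rate heterogeneity, linked-selection background, SV mechanism
(SVs are presence/absence labels), phasing, or sequencing error and
coverage-driven missingness. Passing tests therefore demonstrate the
correctness and internal consistency of the estimators under drift,
admixture and selection — not robustness to real-data artefacts.

## Numerical choices and limitations

All randomness flows from a single root seed through per-replicate spawned
streams; identical config + seed gives byte-identical outputs. Statistics
return NaN rather than raising on empty denominators; errors are reserved
for contract violations (unknown groups, unpolarized input, impossible
placements). The simulator holds a fixed site panel rather than an
infinite-sites genome: recurrent mutation can re-create an allele at a
tracked site, which is why pulse-fate experiments run with mutation off.
Populations are panmictic with discrete generations and no selfing; clonal
mode has no somatic structure. f-branch and fd behave as expected for the
five-population topology shipped here; very short internal branches or
donors nested inside the focal clade need larger simulated genomes than the
desk scale used in the test suite.
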