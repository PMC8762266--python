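# Methods

## Source-population simulator

Each site draws an ancestral frequency `q ~ Uniform(0.02, 0.98)`; each
population k draws its frequency from the Balding–Nichols distribution
`Beta(q(1−F_k)/F_k, (1−q)(1−F_k)/F_k)`, so `F_k` acts as an F_ST-like
differentiation coefficient. A population's `n_founders` founder
haplotypes sample alleles independently at these frequencies; every sample
haplotype is a founder mosaic whose switch points are Poisson with
`founder_switch_rate` per Morgan, plus independent per-site allele flips
at `mutation_flip_rate` (private-mutation noise). Sites monomorphic across
all populations combined are dropped and redrawn (at most 10× the
requested count, then an error). This gives each population block-wise
haplotype sharing — the structure a copying HMM exploits — at a
controllable effective diversity, without a coalescent dependency; any
generator producing the same `(HaplotypeSet, AncestryTracks)` contract can
be swapped in upstream.

What the generator does **not** emulate: a coalescent site-frequency
spectrum (rare variants at desk scale are mostly cohort singletons),
allele age–frequency correlation beyond founder structure, recurrent
mutation, genotyping error, phase error (targets are truth-phased), or
realistic recombination maps (uniform by default; piecewise-linear maps
are supported). Passing tests therefore demonstrate the *evaluation
machinery* and the *relative* panel-composition effects, not absolute
real-data accuracy values.

## Admixture model

A single pulse `g` generations ago: per haplotype, ancestry-switch points
are Poisson with rate `g` per Morgan along the genetic map; each segment's
ancestry is an independent draw from the admixture proportions (a switch
may redraw the same ancestry, so realized ancestry-change points thin to
rate `g·(1 − Σ p_k²)`), and each segment is copied verbatim from one
uniformly chosen donor haplotype of that ancestry — one donor per segment,
preserving within-ancestry LD. Truth tracts are emitted exactly and
normalized (adjacent same-ancestry tracts merged). Coordinates are
0-based half-open; VCF export converts to 1-based.

In the experiment the donor haplotypes are **disjoint** from all panel
members: targets are never mosaics of haplotypes present in the reference,
so imputation accuracy reflects founder-level sharing, as in a real cohort,
rather than trivial self-copying.

## Array ascertainment

`M = round(length_bp / target_mean_spacing_bp)` sites are chosen to match
a B-bin MAF histogram computed in the ascertainment population (default
EUR). Quotas per bin follow largest-remainder rounding with proportional
redistribution of shortfalls; within a bin, candidates are drawn uniformly
with a spacing-aware rejection step (reject draws closer than a quarter of
the target spacing to an already-chosen site, up to 50 attempts, then
accept unconditionally). Sites monomorphic in the ascertainment population
are ineligible. The default histogram (10/15/20/25/30 % across five equal
MAF bins) up-weights common variants, reproducing the European-discovery
bias of commercial arrays; an empirical histogram can be supplied. The
default target spacing of 1,700 bp matches the genome-wide density of a
~1.8 M-marker array; the desk-scale experiment uses 25 kb so that 2,000 of
8,000 simulated sites are typed.

## Imputation engine

Haploid Li–Stephens copying HMM per target haplotype over the `H`
reference haplotypes, uniform initial distribution, transitions between
adjacent typed sites

    s_j = max(min_switch, 1 − exp(−4 · Ne_eff · d_j / H)),

with `d_j` the genetic distance in Morgans; staying probability
`(1 − s_j) + s_j/H`, each other state `s_j/H`. Emissions are `1 − λ` on
allele match and `λ` on mismatch (`miscopy_lambda`); missing observations
emit 1 (site skipped). Scaled forward–backward recursions keep every row
normalized (no underflow up to at least 1e5 sites); the whole batch of
target haplotypes is advanced jointly, with posterior buffers chunked to
bound memory.

At untyped sites the state posterior is interpolated linearly in genetic
distance between the flanking typed sites and renormalized; beyond the
outermost typed sites the nearest typed posterior is used. Haploid
allele-1 probability is `λ + (1 − 2λ) · Σ_h γ(h)·allele_h`; the two
haplotypes of an individual combine independently into
`(P(AA), P(Aa), P(aa))`. Per site over N individuals, with
`e_i = P_i(Aa) + 2P_i(aa)`, `f_i = P_i(Aa) + 4P_i(aa)` and
`θ = Σe_i / 2N`:

    INFO = 1 − Σ(f_i − e_i²) / (2N·θ·(1−θ)),

defined as 1 when θ is 0 or 1 and clipped to [0, 1].

Panel merging supports `intersect` (common sites, stacked haplotypes) and
`cross_impute` (site union; sites absent from one panel are imputed for
that panel's haplotypes against the other and hard-called at 0.5, ties to
allele 0 — reference panels must stay binary, and the hard call makes the
uncertainty introduced by merging explicit). Leave-one-out evaluation
removes the target's two haplotypes from the panel before imputing it.

Parameter defaults: `Ne_eff = 1e4` (standard Li–Stephens effective size),
`miscopy_lambda = 1e-3`, `min_switch = 1e-8`. All are exposed in the YAML
config. No state-subsetting or chunking heuristics are applied — the full
panel is the state space, which is exact and affordable at desk scale.

## Stratification and accuracy

Every (individual, held-out site) observation gets (a) the unordered pair
of truth-tract ancestries of the individual's two haplotypes at the site
(AFR < EUR < NAT normalization; half-open interval lookup, so a position
on a tract boundary belongs to the tract starting there) and (b) a MAF
class from the truth MAF in the full admixed cohort (panel members and
targets; truth, not imputed, frequencies). Classes are `[lower, upper)`
with the top class closed at 0.5, so a MAF exactly on a breakpoint belongs
to the class above (0.05 is "common"); MAF below the lowest breakpoint
(default 0.003) is excluded. The class grid is configurable — the gap
analysis uses a 2 % split, finer rare-variant grids are possible.

Accuracy is squared Pearson correlation between imputed and true dosages.
The default pools all (individual, site) pairs within a stratum, which is
stable for sparse rare-variant strata; a per-individual-then-average mode
is available and recorded in the run manifest. Before pooling, dosages are
oriented to the cohort **minor** allele per site (`d → 2 − d` where the
alternate allele is the major one): pooled correlations on raw
alternate-allele dosages are dominated by between-site mean structure
(a stratum mixing mostly-0 and mostly-2 sites scores r² ≈ 1 regardless of
the panel), whereas folded correlations measure recovery of the minor
allele — the quantity imputation is actually used for. Strata with fewer
than two distinct truth values or zero variance are reported as missing
(never 0) and excluded from monotonicity summaries. GWAS-quality counts
use MAF ≥ 0.01 (inclusive) and INFO > 0.3 (strict); per-individual counts
for paired panel comparisons use INFO computed from that individual's own
genotype probabilities (N = 1) so that the two-tailed paired t-test is a
genuine per-individual pairing.

## Incremental-panel experiment

The base panel mirrors a 1KGP-like composition — AFR : EUR : admixed
individuals at 661 : 503 : 347, scaled (0.1× → 66 : 50 : 35) — plus
nested, growing subsets of NAT reference individuals (first 2s haplotypes
of the simulated NAT reference pool, fixed order per seed, so panels are
nested). Targets are a separate set of admixed individuals (30 at 0.1×)
imputed directly against each panel; truth MAF for binning comes from the
full 65-individual admixed cohort. The gap analysis reports, per frequency
class, the smallest addition at which NAT_NAT r² ≥ EUR_EUR r², plus the
improvement-over-baseline curve Δr²(s) = r²(s) − r²(0).

### Desk-scale study conditions

All shipped tests and the acceptance script use the 0.1-scale
configuration: 50 Mb chromosome at 1 cM/Mb, 8,000 segregating sites,
2,000 typed, additions 0/20/50/100, five seeds. Generator settings:
40 founders per population, founder switch rate 30/Morgan (≈3 cM founder
blocks, comfortably longer than the 0.025 cM marker spacing), flip rate
5e-4 (a handful of unimputable private singletons per haplotype),
`F` = 0.08/0.06/0.12 for AFR/EUR/NAT (continental-scale differentiation,
extra drift for the NAT founder bottleneck), and 80 donor haplotypes per
ancestry. With these conditions the full experiment runs in roughly ten
seconds per seed on one CPU; full-scale runs (3,000 additions, hundreds of
megabases) are configurable but are not what the shipped tests assert.

## Known limitations

- Cohort rare variants at 0.1 scale are singletons (130 cohort
  haplotypes), so the rare bin is thin; absolute rare-bin r² values are
  noisy across seeds even though the qualitative ordering is stable.
- The simulated gap-closing sizes depend on the founder diversity and the
  scale factor; they are an analogue of the full-scale projection, not a
  calibrated estimate of it.
- Local ancestry is truth (simulation) or user-supplied (files); ancestry
  inference error is never modeled.
- Biallelic SNPs only; no multi-pulse admixture, sex chromosomes, phasing,
  genotyping error, or imputation-server protocols.
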