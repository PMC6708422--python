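# Methods

## Population model

The simulator is a discrete-generation, individual-based Wright–Fisher model
with partial self-fertilization. Each of `N` offspring per generation is
produced by selfing one uniformly chosen parent with probability `1 − s_out`,
otherwise by crossing two distinct uniformly chosen parents. Every
transmitted chromosome is an independent recombinant gamete: Poisson(`λ`)
crossover points (no interference) placed uniformly on the locus index
range, with a random start phase alternating the two parental strands. After
transmission each allele flips with probability `μ` (symmetric, biallelic,
recurrent mutation). Under partial selfing the equilibrium inbreeding
coefficient is `F = (1 − s_out)/(1 + s_out)` and the drift-effective size is
`Ne = N / (1 + F)`; at wheat's `s_out = 0.033`, `F ≈ 0.936` and
`Ne ≈ N/1.94`.

Allopolyploids are built by amphiploidy: one gamete from a random individual
of each parent taxon, chromosome-doubled, giving a fully homozygous founder
carrying the disjoint union of the parental subgenomes. Inheritance is
strictly disomic — chromosomes pair within their subgenome and alleles never
move between subgenomes, so differences fixed between parent taxa persist as
homoeologous (between-subgenome) divergence. New taxa grow from a single
founder by geometric doubling capped at `N` (target reached well inside the
scheduled 100 growth generations; the growth phase runs for the full
schedule either way).

**Genetic map embedding.** Loci are evenly spaced and Poisson(1) crossovers
per meiosis define a 100 cM chromosome: locus `i` of `n` sits at
`100·i/n` cM, and 1 cM is identified with 1 Mb so that the physical grid of
the cross-population scan is defined. This is the simplest embedding
consistent with λ = 1; no interference and no map heterogeneity are modelled.

**Initialization.** Besides a monomorphic start (for burn-in runs), a
stationary initializer draws per-locus allele frequencies from the symmetric
mutation–drift stationary distribution Beta(θ, θ), θ = 4·Ne·μ, and samples
genotypes at inbreeding equilibrium `F`. It replaces the 25,000-generation
burn-in in scaled-down work; loci start in linkage equilibrium, so analyses
that depend on LD structure must run enough generations afterwards
(~2·Ne) for haplotype structure to build up.

## Demography scenario

The full profile mirrors the study design: a 500-individual diploid ancestor
(7 chromosomes × 100k loci, μ = 1e-5); A, B, D taxa founded at generations
6,000 / 6,200 / 11,000; AB tetraploid by hybridization at 12,000; the
482-individual ABD hexaploid at 18,000; end of neutral evolution at 25,000.
The hexaploid is split uniformly at random into Pre70 (259) and Post70 (223)
cohorts, which then evolve with restricted gene flow while genome-wide
F<sub>ST</sub> is tracked each generation; the run stops at the first
generation with F<sub>ST</sub> ≥ 0.13.

**F<sub>ST</sub> tracking estimator.** The stopping rule uses the
Hudson-style ratio of averages, `Σ(p₁−p₂)² / Σ[p₁(1−p₂)+p₂(1−p₁)]`, whose
expectation is the drift differentiation `f(t) = 1 − exp(−t/2Ne)`. The
per-locus *scan* statistic (below) is a different, population-drift moment
form whose two-population expectation is ≈ f/2; using it as the stopping
tracker would roughly double the differentiation time. The Hudson tracker
reproduces both the closed form `t ≈ −2N·ln(1 − F_target)` in random-mating
checks and the study's reported ~35 generations at the real cohort sizes;
the two estimators serve different purposes and are deliberately not
unified.

**Gene flow during differentiation.** The magnitude of the "restricted" gene
flow is a free parameter. A fraction `m` of each cohort's offspring draws
one parent from the other cohort. At the study's cohort sizes, `m = 0.005`
would stretch differentiation to ~58 generations, while `m = 0` gives ~38
and `m = 0.001` ~35 — matching the reported 35.2 ± 4.7. The package default
is therefore `m = 0.001`; it is configurable and recorded in outputs.

**Ascertainment.** Chip development is emulated by drawing a 19-individual
discovery panel from the Post70 cohort (optionally plus tetraploid
accessions, which in the study made no difference and defaults to off),
keeping only loci polymorphic within the panel, and sampling the study's
SNP count uniformly from them; all individuals are then restricted to the
retained loci. This shifts the folded site-frequency spectrum toward common
alleles, as on the real chip.

**Outcrossing calibration.** `fit_outcrossing_rate` matches simulated to
target LD-decay curves (mean r² binned by cM distance, 0–50 cM, mean squared
difference) over a coarse grid 0.01–0.10 (step 0.01) and a fine grid (step
0.001) spanning the coarse argmin's neighbours. Replicates use common random
numbers across grid points so the objective surface is smooth in the rate.
The calibration forward model runs at `N = 150`, one chromosome of 3,000
loci, `μ = 2e-4`, 350 generations from stationary start, with rare variants
(MAF < 0.05) excluded from the curve. The mutation rate matters here: under
strong selfing the effective recombination between loci 1 cM apart is
~`0.01·(1−F) ≈ 1e-3` per meiosis, so a mutation rate of order 1e-3 would
dominate short-range LD and erase the outcrossing signal; 2e-4 keeps LD
recombination-limited while still yielding a few hundred usable SNPs.

## Scan statistics

**Windowed F<sub>ST</sub>.** Per locus,
`F̂ = (1/K) Σ_j (p_j − p̄)² / (p̄(1−p̄))` with the unweighted mean `p̄` over
the K populations — a moment form of the population-specific drift model
(the original formulation is Bayesian; no estimator details are published
for the study, so the moment form is used and validated by rank agreement,
ρ > 0.99, with the Hudson estimator). Loci with `p̄ ∈ {0,1}` are undefined.
Windows average 15 consecutive per-locus values with step 1 and are reported
at the window-center SNP with the count of contributing (non-missing) loci.

**iHS.** EHH for the carriers of an allele is the probability that two
random carrier haplotypes are identical by state from the core SNP out to a
given position. iHH integrates EHH over genetic distance (trapezoid between
adjacent SNPs) in both directions until EHH < 0.05. Raw
iHS = `ln(iHH_major/iHH_minor)`: chip data lack ancestral states, so
polarization is by the major allele in the combined sample and scores are
standardized to mean 0 / variance 1 within minor-allele-frequency bins of
width 0.025 (bins with fewer than 5 scores yield missing). A SNP is missing
when extension hits the chromosome edge before truncation or would cross an
inter-SNP gap > 2 cM. One addition is required in a 96.7%-selfing
population: a few percent of haplotype pairs are recent clones, so EHH has a
floor above any practical cutoff and would hit the edge at every core.
Integration is therefore censored at a maximum extension distance
(`max_extend_cm`, default 20 cM), the same device as the 1 Mb default
extension limit in standard haplotype-scan software. MAF floor 0.05.

**nSL.** The pair statistic is the number of consecutive segregating sites
of the maximal interval containing the core on which two carrier haplotypes
are identical (censored at chromosome ends); per-allele scores are the mean
over carrier pairs, raw nSL the log ratio (major/minor), standardized in the
same frequency bins. No genetic map is needed.

**XPCLR.** Evaluation points every 1 Mb; per point, SNPs within 0.5 cM with
the reference population polymorphic; LD pruning keeps one random SNP of
each pair with r² > 0.95; at most 50 SNPs per window by seeded uniform
thinning. Given reference frequency `p₁`, the objective frequency after
drift is modelled as Normal(`p₁`, `ω·p₁(1−p₁)`) truncated to (0,1) with the
tail mass placed at the boundaries; `ω` is the genome-wide moment estimate
`mean[(p₂−p₁)²/(p₁(1−p₁))]` (floored at 1e-4 for degenerate inputs). The
sweep model applies the star-like hitchhiking transform to the drifted
frequency `p`: with probability `p` the linked variant rides to
`1 − c + c·p`, else to `c·p`, where `c = 1 − exp(−r·ln(2N)/s)` is the
escape probability of a lineage at recombination distance `r` (Morgans) from
a sweep of intensity `s` (c → 1 recovers neutrality). The per-SNP
likelihood of the binomial allele count marginalizes over the drift density
by fixed Gauss–Legendre quadrature (24 nodes); the score is
`2·(max_s CLL(s) − CLL(neutral))` over a fixed logarithmic grid of 20
intensities from 1e-5 to 1e-1. This is a composite likelihood: scores are
used only relative to their own neutral distribution, never as χ² values.

## Thresholds, calling, merging

Thresholds are empirical quantiles (linear interpolation between order
statistics) of statistic values pooled across neutral replicates: the 99th
percentile for XPCLR, iHS and nSL, the 99.9th for windowed F<sub>ST</sub>
(whose window overlap gives it much higher variance). iHS and nSL are
two-sided and thresholded on |score|; F<sub>ST</sub> and XPCLR one-sided.
Significance is strict `>`. Adjacent significant points on a chromosome
merge into one signature when the mean r² between their contributing SNPs
exceeds the background-LD 99th percentile — "strong LD" is not quantified in
the source analysis, so the background percentile is reused for internal
consistency with the inter-region criterion. Overlapping intervals from
different methods/populations are unioned transitively (closed intervals;
methods and population sets union).

## Inter-region LD criterion

Pairwise r² follows Hill–Robertson: `D²/(p_A(1−p_A)p_B(1−p_B))` from
haplotype counts, computed for inbred cultivars on one haplotype per
homozygous individual (heterozygous calls treated as missing for that
locus — chip heterozygote calls are unreliable in hexaploid wheat). Two
regions on different chromosomes (or ≥50 cM apart) are "in LD" when strictly
more than half of the retained SNPs in each region have inter-region LD
above the background 99th percentile (0.161 when no panel is supplied). A
SNP's inter-region LD is its *median* r² against the other region's SNPs — a
max-based summary would be dominated by exactly the mapping-error outliers
the criterion excludes — and SNPs more than 3 MADs above the region-pair
median are excluded as not following the general pattern. Both choices are
configurable; regions with fewer than 5 SNPs are ineligible. The reported
value per pair is the maximum r² among retained SNPs, and in-LD pairs are
clustered by graph connectivity.

## Desk profile and what the tests show

The published experiment (100 replicates, 25,000 generations, 700k loci) is
cluster-scale. The shipped desk profile is `N = 200`, one chromosome per
subgenome, 2,000 loci per chromosome, stationary initialization, a
compressed event schedule, and `μ = 5e-4` — the mutation rate is raised so
the reduced locus count still yields chip-like SNP density after
ascertainment (~2,500 panel-polymorphic loci, of which 800 are retained).
Neutral calibration replicates for testing skip the taxon schedule: they
equilibrate a stationary hexaploid for 200 generations, split, differentiate
to F<sub>ST</sub> 0.13 and ascertain; the full schedule is exercised by a
separate end-to-end run. The calibration check derives thresholds from nine
of ten replicates and measures the flagged fraction on the held-out one,
aggregated over all leave-one-out folds; because scores within a replicate
are positively correlated (F<sub>ST</sub> windows share 14 of 15 SNPs), the
aggregate is compared to a wide (99.9%) binomial band. Passing these tests
shows the machinery is internally calibrated at desk scale under the stated
model; it does not certify power or error rates on real wheat data, where
map heterogeneity, genotyping error and non-equilibrium breeding structure
are all outside the generator.

## Numerical and degenerate-input conventions

Quantiles everywhere use linear interpolation between order statistics.
Monomorphic loci give missing r²/F̂ values and are dropped with the drop
reported in contributing-SNP counts — nothing is imputed silently. Ties at
exact 50/50 allele frequency polarize to allele 0; the sign of iHS/nSL is
undefined there and only |score| is meaningful (significance uses |score|).
`drift_until_fst` with target 0 returns immediately (0 generations);
exceeding `max_gen` raises an error carrying the F<sub>ST</sub> trajectory.
Simulations are deterministic given parameters and seed; every stochastic
step (panel draws, LD pruning, thinning, pair sampling) takes an explicit
seed or generator that is recorded in outputs.

## Known limitations

No crossover interference, gene conversion, polysomic inheritance, or
homoeologous exchange; selection is absent from all calibration runs (the
null is strictly neutral). The even-spacing 1 cM ≡ 1 Mb map is a modelling
convention, not wheat's real map. The Nicholson-style moment form and the
iHS/nSL default parameters are documented interpretations where the source
analysis left the estimator or tool settings unstated; both are
configurable. The desk profile's raised mutation rate trades mutation-drift
realism for SNP density and is not used where that matters (the outcrossing
calibration uses its own lower-μ forward model).
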