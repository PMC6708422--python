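"""Forward-time individual-based simulator for selfing di-/allopolyploids.

The model is a discrete-generation Wright-Fisher population of ``N``
individuals with partial self-fertilization: each offspring is produced by
selfing one uniformly chosen parent with probability ``1 - s_out``, otherwise
by crossing two distinct uniformly chosen parents.  Each transmitted
chromosome is a recombinant gamete with Poisson(``lambda_xo``) crossovers (no
interference) placed uniformly on the locus index range, independently for
every chromosome of every subgenome: inheritance is strictly disomic, so
alleles never move between subgenomes.  After transmission every allele flips
with probability ``mu`` (symmetric biallelic mutation, recurrent mutation
allowed).

Allopolyploids are built by amphiploidy: one gamete from each parent taxon,
chromosome-doubled, giving a fully homozygous founder that carries the union
of the parental subgenomes.  New taxa grow from a single founder to the
target size by geometric doubling capped at ``N``.

Genetic map embedding: loci are evenly spaced; Poisson(1) crossovers per
meiosis defines a 100 cM chromosome, so locus ``i`` of ``n`` maps to
``100*i/n`` cM and 1 cM is identified with 1 Mb of physical position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import HaplotypeSet

# ---------------------------------------------------------------------------
# Parameters and state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimParams:
    """Population-genetic parameters of one simulated taxon.

    Parameters
    ----------
    N : target population size (individuals)
    mu : per-locus per-generation symmetric mutation rate
    lambda_xo : mean crossovers per chromosome per meiosis
    s_out : per-offspring outcrossing probability (wheat ~ 0.033)
    n_chrom : chromosomes per subgenome
    n_loci : loci per chromosome
    seed : seed for convenience wrappers that do not take an explicit rng
    """

    N: int = 500
    mu: float = 1e-5
    lambda_xo: float = 1.0
    s_out: float = 0.033
    n_chrom: int = 7
    n_loci: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0,1]")
        if self.lambda_xo < 0:
            raise ValueError("lambda_xo must be >= 0")
        if not 0.0 <= self.s_out <= 1.0:
            raise ValueError("s_out must be in [0,1]")

    @property
    def inbreeding_equilibrium(self) -> float:
        """Equilibrium inbreeding coefficient F = (1-s)/(1+s) under partial
        selfing with outcrossing probability s."""
        return (1.0 - self.s_out) / (1.0 + self.s_out)

    @property
    def effective_size(self) -> float:
        """Drift-effective size N/(1+F) under partial selfing."""
        return self.N / (1.0 + self.inbreeding_equilibrium)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class Population:
    """Haplotype state of one taxon.

    ``haps`` is a uint8 array of shape (N, 2, L) where L concatenates all
    chromosomes of all subgenomes in the order of ``chrom_names``;
    ``chrom_offsets`` holds the L+1 block boundaries.
    """

    label: str
    subgenomes: list[str]
    chrom_names: list[str]
    chrom_offsets: np.ndarray
    haps: np.ndarray
    generation: int = 0

    @property
    def size(self) -> int:
        return self.haps.shape[0]

    @property
    def n_loci_total(self) -> int:
        return self.haps.shape[2]

    def copy(self) -> "Population":
        return replace(self, haps=self.haps.copy(),
                       subgenomes=list(self.subgenomes),
                       chrom_names=list(self.chrom_names),
                       chrom_offsets=self.chrom_offsets.copy())


def _chrom_structure(subgenomes: list[str], n_chrom: int, n_loci: int):
    names = [f"{i + 1}{sg}" for sg in subgenomes for i in range(n_chrom)]
    offsets = np.arange(len(names) + 1) * n_loci
    return names, offsets


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def initialize_population(params: SimParams, init: str = "monomorphic",
                          subgenomes: list[str] | None = None,
                          label: str = "ancestor",
                          rng: np.random.Generator | None = None) -> Population:
    """Create a population, either monomorphic (all alleles 0) or at the
    symmetric mutation-drift stationary distribution.

    The stationary initializer draws per-locus allele frequencies from
    Beta(theta, theta) with theta = 4*Ne*mu (Ne the selfing-adjusted
    effective size) and then samples genotypes at the selfing-outcrossing
    equilibrium inbreeding coefficient F = (1-s)/(1+s).
    """
    rng = params.rng() if rng is None else rng
    subgenomes = subgenomes if subgenomes is not None else ["A"]
    names, offsets = _chrom_structure(subgenomes, params.n_chrom, params.n_loci)
    L = offsets[-1]
    if init == "monomorphic":
        haps = np.zeros((params.N, 2, L), dtype=np.uint8)
    elif init == "stationary":
        theta = 4.0 * params.effective_size * params.mu
        p = rng.beta(theta, theta, size=L) if theta > 0 else \
            rng.integers(0, 2, size=L).astype(float)
        f_eq = params.inbreeding_equilibrium
        a0 = (rng.random((params.N, L)) < p).astype(np.uint8)
        a_ind = (rng.random((params.N, L)) < p).astype(np.uint8)
        ibd = rng.random((params.N, L)) < f_eq
        a1 = np.where(ibd, a0, a_ind).astype(np.uint8)
        haps = np.stack([a0, a1], axis=1)
    else:
        raise ValueError(f"unknown init {init!r}")
    return Population(label=label, subgenomes=list(subgenomes),
                      chrom_names=names, chrom_offsets=offsets, haps=haps)


# ---------------------------------------------------------------------------
# Reproduction
# ---------------------------------------------------------------------------

def make_gametes(parent_haps: np.ndarray, chrom_offsets: np.ndarray,
                 lambda_xo: float, rng: np.random.Generator) -> np.ndarray:
    """Recombinant gametes from (n, 2, L) parental haplotypes -> (n, L).

    Per chromosome: Poisson(lambda_xo) crossover points uniform on the locus
    index range, a random start phase, and alternation of parental strands at
    the crossover points.
    """
    n, _, L = parent_haps.shape
    out = np.empty((n, L), dtype=np.uint8)
    for c in range(len(chrom_offsets) - 1):
        a, b = int(chrom_offsets[c]), int(chrom_offsets[c + 1])
        Lc = b - a
        phase = rng.integers(0, 2, size=n).astype(np.int64)
        if Lc > 1 and lambda_xo > 0:
            k = rng.poisson(lambda_xo, size=n)
            total = int(k.sum())
            if total:
                B = np.zeros((n, Lc), dtype=np.int64)
                gi = np.repeat(np.arange(n), k)
                pos = rng.integers(1, Lc, size=total)
                np.add.at(B, (gi, pos), 1)
                strand = (phase[:, None] + np.cumsum(B, axis=1)) % 2
            else:
                strand = np.broadcast_to(phase[:, None] % 2, (n, Lc))
        else:
            strand = np.broadcast_to(phase[:, None] % 2, (n, Lc))
        blk0 = parent_haps[:, 0, a:b]
        blk1 = parent_haps[:, 1, a:b]
        out[:, a:b] = np.where(strand == 0, blk0, blk1)
    return out


def _mutate_inplace(haps: np.ndarray, mu: float, rng: np.random.Generator) -> None:
    if mu <= 0:
        return
    M = haps.size
    k = int(rng.binomial(M, mu))
    if k == 0:
        return
    pos = np.unique(rng.integers(0, M, size=k))
    flat = haps.reshape(-1)
    flat[pos] ^= 1


def _reproduce(pop: Population, n_offspring: int, params: SimParams,
               rng: np.random.Generator) -> Population:
    n_par = pop.size
    selfed = rng.random(n_offspring) >= params.s_out
    p1 = rng.integers(0, n_par, size=n_offspring)
    p2 = rng.integers(0, n_par, size=n_offspring)
    if n_par > 1:
        clash = (~selfed) & (p2 == p1)
        while clash.any():
            p2[clash] = rng.integers(0, n_par, size=int(clash.sum()))
            clash = (~selfed) & (p2 == p1)
    other = np.where(selfed, p1, p2)
    g1 = make_gametes(pop.haps[p1], pop.chrom_offsets, params.lambda_xo, rng)
    g2 = make_gametes(pop.haps[other], pop.chrom_offsets, params.lambda_xo, rng)
    haps = np.stack([g1, g2], axis=1)
    _mutate_inplace(haps, params.mu, rng)
    return replace(pop, haps=haps, generation=pop.generation + 1)


def step_generation(pop: Population, params: SimParams,
                    rng: np.random.Generator | None = None) -> Population:
    """Advance one non-overlapping generation at size ``params.N``."""
    if pop.size == 0:
        raise ValueError("cannot reproduce an empty population")
    rng = params.rng() if rng is None else rng
    return _reproduce(pop, params.N, params, rng)


def _grow_from_founder(founder: Population, params: SimParams,
                       growth_generations: int,
                       rng: np.random.Generator) -> Population:
    """Geometric-doubling growth schedule, capped at N, run for exactly
    ``growth_generations`` generations."""
    if growth_generations < 1:
        raise ValueError("growth_generations must be >= 1")
    pop = founder
    size = founder.size
    for _ in range(growth_generations):
        size = min(params.N, 2 * size)
        pop = _reproduce(pop, size, params, rng)
    return pop


def found_taxon(src: Population, params: SimParams,
                growth_generations: int = 100,
                label: str | None = None,
                rng: np.random.Generator | None = None) -> Population:
    """Found a new taxon from one uniformly chosen individual of ``src`` and
    grow it to ``params.N`` within ``growth_generations`` generations."""
    if src.size == 0:
        raise ValueError("source population is empty")
    rng = params.rng() if rng is None else rng
    idx = int(rng.integers(0, src.size))
    founder = replace(src, haps=src.haps[idx:idx + 1].copy(), generation=0,
                      label=label or f"{src.label}_daughter")
    return _grow_from_founder(founder, params, growth_generations, rng)


def polyploidize(popA: Population, popB: Population, params: SimParams,
                 growth_generations: int = 100,
                 label: str | None = None,
                 rng: np.random.Generator | None = None) -> Population:
    """Amphiploid founder from one gamete of each parent taxon, chromosome
    doubled (fully homozygous within every subgenome), grown to ``params.N``.

    Subgenomes are inherited disomically thereafter; fixed differences
    between the parents become homoeologous (between-subgenome) differences.
    """
    if set(popA.subgenomes) & set(popB.subgenomes):
        raise ValueError("subgenome label sets must be disjoint")
    nA = len(popA.chrom_names) // len(popA.subgenomes)
    nB = len(popB.chrom_names) // len(popB.subgenomes)
    if nA != nB or popA.haps.shape[2] // len(popA.chrom_names) != \
            popB.haps.shape[2] // len(popB.chrom_names):
        raise ValueError("incompatible chromosome structure")
    rng = params.rng() if rng is None else rng
    iA = int(rng.integers(0, popA.size))
    iB = int(rng.integers(0, popB.size))
    gA = make_gametes(popA.haps[iA:iA + 1], popA.chrom_offsets,
                      params.lambda_xo, rng)[0]
    gB = make_gametes(popB.haps[iB:iB + 1], popB.chrom_offsets,
                      params.lambda_xo, rng)[0]
    gam = np.concatenate([gA, gB])
    haps = np.stack([gam, gam])[None, :, :]  # doubled -> homozygous founder
    subgenomes = list(popA.subgenomes) + list(popB.subgenomes)
    names = list(popA.chrom_names) + list(popB.chrom_names)
    offsets = np.concatenate([popA.chrom_offsets,
                              popB.chrom_offsets[1:] + popA.chrom_offsets[-1]])
    founder = Population(label=label or f"{popA.label}x{popB.label}",
                         subgenomes=subgenomes, chrom_names=names,
                         chrom_offsets=offsets, haps=haps.astype(np.uint8))
    return _grow_from_founder(founder, params, growth_generations, rng)


def split_population(pop: Population, n1: int, n2: int,
                     rng: np.random.Generator | int | None = None
                     ) -> tuple[Population, Population]:
    """Disjoint uniform random partition into subpopulations of exactly
    ``n1`` and ``n2`` individuals."""
    if n1 + n2 > pop.size:
        raise ValueError(f"n1+n2={n1 + n2} exceeds population size {pop.size}")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    perm = rng.permutation(pop.size)
    a = replace(pop, haps=pop.haps[perm[:n1]].copy(), label=f"{pop.label}_1")
    b = replace(pop, haps=pop.haps[perm[n1:n1 + n2]].copy(), label=f"{pop.label}_2")
    return a, b


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def allele_frequencies(pop: Population) -> np.ndarray:
    """Per-locus frequency of allele 1 over all 2N haplotypes."""
    return pop.haps.mean(axis=(0, 1))


def observed_heterozygosity(pop: Population) -> float:
    """Fraction of heterozygous (individual, locus) genotype calls, averaged
    over loci polymorphic in the population; 0 if no locus is polymorphic."""
    if pop.size == 0:
        raise ValueError("empty population")
    p = allele_frequencies(pop)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        return 0.0
    het = pop.haps[:, 0, poly] != pop.haps[:, 1, poly]
    return float(het.mean())


def to_haplotype_set(pops: dict[str, Population],
                     ploidy_note: int | None = None) -> HaplotypeSet:
    """Export one or more same-structure populations as a HaplotypeSet with
    cohort labels, using the even-spacing map embedding (100 cM chromosomes,
    1 cM == 1 Mb)."""
    first = next(iter(pops.values()))
    n_per = first.haps.shape[2] // len(first.chrom_names)
    loci_rows = []
    for c, name in enumerate(first.chrom_names):
        for i in range(n_per):
            cm = 100.0 * i / n_per
            loci_rows.append((f"{name}_{i}", name, cm, int(round(cm * 1e6)) + 1))
    loci = pd.DataFrame(loci_rows, columns=["locus", "chrom", "cM", "bp"])
    individuals, groups, mats = [], {}, []
    for lab, pop in pops.items():
        if pop.chrom_names != first.chrom_names:
            raise ValueError("populations differ in chromosome structure")
        ids = [f"{lab}_{i}" for i in range(pop.size)]
        individuals.extend(ids)
        groups.update({s: lab for s in ids})
        mats.append(pop.haps.reshape(2 * pop.size, -1))
    hs = HaplotypeSet(
        individuals=individuals, loci=loci,
        alleles=np.concatenate(mats, axis=0).astype(np.int8),
        ploidy_note=ploidy_note or len(first.subgenomes),
        sample_groups=groups)
    hs.validate()
    return hs
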