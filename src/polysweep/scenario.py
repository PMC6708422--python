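"""The Australian-wheat demography scenario, end to end.

Timeline of the full profile (generations): a diploid ancestor of 500
individuals (7 chromosomes, 100k loci each) evolves from generation 0; the A
genome taxon is founded at 6,000, B at 6,200 and D at 11,000 (500 individuals
each, grown from a single founder within 100 generations); the AB tetraploid
forms by amphiploidy at 12,000 and the hexaploid ABD population of 482
individuals at 18,000; the run ends at 25,000.  The hexaploid is then split
at random into Pre70 (259) and Post70 (223) cohorts which differentiate with
restricted gene flow until their genome-wide Fst reaches the empirical value
0.13.  SNP-chip ascertainment bias is emulated by keeping only loci
polymorphic in a random 19-individual Post70 discovery panel (optionally plus
tetraploid accessions) and drawing the study's panel size at random from
them.

The desk profile is a scaled-down configuration for laptop-speed testing:
N=200, one chromosome per subgenome, 2,000 loci per chromosome, stationary
initialization in place of the long burn-in, and a compressed event schedule.
Its mutation rate is raised to 5e-4 so that the reduced locus count still
yields a realistic SNP density after ascertainment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import HaplotypeSet
from .ldtools import ld_decay_curve
from .popsim import (Population, SimParams, _reproduce, allele_frequencies,
                     found_taxon, initialize_population, make_gametes,
                     polyploidize, split_population, to_haplotype_set)
from .sweepstats import hudson_fst_mean

FULL_PARAMS = SimParams(N=500, mu=1e-5, lambda_xo=1.0, s_out=0.033,
                        n_chrom=7, n_loci=100_000)
DESK_PARAMS = SimParams(N=200, mu=5e-4, lambda_xo=1.0, s_out=0.033,
                        n_chrom=1, n_loci=2_000)


class DriftTimeoutError(RuntimeError):
    """Raised when drift_until_fst exhausts max_gen; carries the trajectory."""

    def __init__(self, msg, trajectory):
        super().__init__(msg)
        self.trajectory = np.asarray(trajectory)


@dataclass(frozen=True)
class DemographyScript:
    """Timed event schedule plus global simulation parameters."""

    params: SimParams = FULL_PARAMS
    init: str = "monomorphic"
    gen_a: int = 6_000
    gen_b: int = 6_200
    gen_d: int = 11_000
    gen_ab: int = 12_000
    gen_abd: int = 18_000
    end_gen: int = 25_000
    growth_generations: int = 100
    n_hexaploid: int = 482
    n_pre: int = 259
    n_post: int = 223
    target_fst: float = 0.13
    migration: float = 0.001
    max_drift_gen: int = 5_000

    def __post_init__(self):
        gens = [self.gen_a, self.gen_b, self.gen_d, self.gen_ab,
                self.gen_abd, self.end_gen]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("event generations must be strictly increasing")
        if not 0 < self.target_fst < 1:
            raise ValueError("target_fst must be in (0,1)")
        if not 0 <= self.migration < 1:
            raise ValueError("migration must be in [0,1)")

    @classmethod
    def full_profile(cls, seed: int = 0) -> "DemographyScript":
        return cls(params=replace(FULL_PARAMS, seed=seed))

    @classmethod
    def desk_profile(cls, seed: int = 0) -> "DemographyScript":
        return cls(params=replace(DESK_PARAMS, seed=seed), init="stationary",
                   gen_a=10, gen_b=20, gen_d=60, gen_ab=80, gen_abd=160,
                   end_gen=280, growth_generations=20,
                   n_hexaploid=200, n_pre=107, n_post=93)


@dataclass(frozen=True)
class AscertainmentSpec:
    """SNP discovery panel emulating chip development: loci kept iff
    polymorphic in a small random panel of the modern cohort."""

    panel_size: int = 19
    tetraploid_panel: int = 0  # set to 18 to mimic the durum-inclusive panel
    n_loci: int = 9_858
    seed: int = 0


@dataclass
class SimulatedDataset:
    """Pre70/Post70 hexaploid cohorts plus the retained tetraploid taxon."""

    pre: Population
    post: Population
    tetraploid: Population | None
    params: SimParams
    drift_generations: int = 0
    fst: float = float("nan")

    def to_haplotype_set(self) -> HaplotypeSet:
        return to_haplotype_set({"Pre70": self.pre, "Post70": self.post})


@dataclass
class CalibrationResult:
    fitted_rate: float
    objectives: pd.DataFrame  # rate, objective, stage
    target_curve: pd.DataFrame
    curves: dict = field(default_factory=dict)
    generations_to_fst: list = field(default_factory=list)


@dataclass
class StateSubsample:
    state: Population
    rest: Population
    generations: int
    fst: float


# ---------------------------------------------------------------------------
# Differentiation under restricted gene flow
# ---------------------------------------------------------------------------

def _reproduce_with_migration(pop: Population, other: Population,
                              params: SimParams, m: float,
                              rng: np.random.Generator) -> Population:
    """One generation of ``pop``; a fraction m of offspring draw their second
    parent from ``other`` (forced outcross), the rest reproduce normally."""
    nxt = _reproduce(pop, params.N, params, rng)
    if m <= 0:
        return nxt
    n_mig = rng.binomial(params.N, m)
    if n_mig == 0:
        return nxt
    slots = rng.choice(params.N, size=n_mig, replace=False)
    p_local = rng.integers(0, pop.size, size=n_mig)
    p_away = rng.integers(0, other.size, size=n_mig)
    g1 = make_gametes(pop.haps[p_local], pop.chrom_offsets,
                      params.lambda_xo, rng)
    g2 = make_gametes(other.haps[p_away], other.chrom_offsets,
                      params.lambda_xo, rng)
    nxt.haps[slots] = np.stack([g1, g2], axis=1)
    return nxt


@dataclass
class DriftResult:
    generations: int
    fst: float
    trajectory: np.ndarray
    pop_x: Population
    pop_y: Population


def drift_until_fst(pop_x: Population, pop_y: Population, params: SimParams,
                    target_fst: float, m: float = 0.0, max_gen: int = 5_000,
                    rng: np.random.Generator | None = None) -> DriftResult:
    """Run both populations with restricted gene flow m until their
    genome-wide Fst (Hudson ratio-of-averages over all loci) first reaches
    ``target_fst``; returns the generation count and achieved value.

    Raises :class:`DriftTimeoutError` (carrying the Fst trajectory) when
    ``max_gen`` is reached first.
    """
    if not 0 <= target_fst < 1:
        raise ValueError("target_fst must be in [0,1)")
    if not 0 <= m < 1:
        raise ValueError("m must be in [0,1)")
    rng = params.rng() if rng is None else rng
    fst = hudson_fst_mean(allele_frequencies(pop_x), allele_frequencies(pop_y))
    traj = [fst]
    g = 0
    px = replace(params, N=pop_x.size)
    py = replace(params, N=pop_y.size)
    while fst < target_fst:
        if g >= max_gen:
            raise DriftTimeoutError(
                f"Fst {fst:.4f} below target {target_fst} after {max_gen} "
                "generations", traj)
        new_x = _reproduce_with_migration(pop_x, pop_y, px, m, rng)
        new_y = _reproduce_with_migration(pop_y, pop_x, py, m, rng)
        pop_x, pop_y = new_x, new_y
        g += 1
        fst = hudson_fst_mean(allele_frequencies(pop_x),
                              allele_frequencies(pop_y))
        traj.append(fst)
    return DriftResult(g, float(fst), np.asarray(traj), pop_x, pop_y)


# ---------------------------------------------------------------------------
# Scenario driver
# ---------------------------------------------------------------------------

def run_wheat_scenario(script: DemographyScript,
                       rng: np.random.Generator | None = None
                       ) -> SimulatedDataset:
    """Execute the demography script and return the differentiated
    Pre70/Post70 hexaploid dataset plus the retained tetraploid taxon."""
    rng = script.params.rng() if rng is None else rng
    p = script.params
    stage = "burn-in"
    try:
        anc = initialize_population(p, script.init, subgenomes=["anc"],
                                    label="ancestor", rng=rng)
        for _ in range(script.gen_a):
            anc = _reproduce(anc, p.N, p, rng)

        def relabel(pop, sg):
            pop.subgenomes = [sg]
            pop.chrom_names = [f"{i + 1}{sg}" for i in range(p.n_chrom)]
            return pop

        stage = "found A"
        tax_a = relabel(found_taxon(anc, p, script.growth_generations,
                                    label="A", rng=rng), "A")
        stage = "ancestor to B founding"
        for _ in range(script.gen_b - script.gen_a):
            anc = _reproduce(anc, p.N, p, rng)
        stage = "found B"
        tax_b = relabel(found_taxon(anc, p, script.growth_generations,
                                    label="B", rng=rng), "B")
        stage = "ancestor to D founding"
        for _ in range(script.gen_d - script.gen_b):
            anc = _reproduce(anc, p.N, p, rng)
        stage = "found D"
        tax_d = relabel(found_taxon(anc, p, script.growth_generations,
                                    label="D", rng=rng), "D")

        stage = "A/B to tetraploid event"
        for _ in range(script.gen_ab - script.gen_a - script.growth_generations):
            tax_a = _reproduce(tax_a, p.N, p, rng)
        for _ in range(script.gen_ab - script.gen_b - script.growth_generations):
            tax_b = _reproduce(tax_b, p.N, p, rng)
        stage = "tetraploidization (AB)"
        tet = polyploidize(tax_a, tax_b, p, script.growth_generations,
                           label="AB", rng=rng)

        stage = "AB/D to hexaploid event"
        for _ in range(script.gen_abd - script.gen_ab - script.growth_generations):
            tet = _reproduce(tet, p.N, p, rng)
        for _ in range(script.gen_abd - script.gen_d - script.growth_generations):
            tax_d = _reproduce(tax_d, p.N, p, rng)
        stage = "hexaploidization (ABD)"
        p_hex = replace(p, N=script.n_hexaploid)
        hexa = polyploidize(tet, tax_d, p_hex, script.growth_generations,
                            label="ABD", rng=rng)

        stage = "run to end of simulation"
        for _ in range(script.end_gen - script.gen_abd - script.growth_generations):
            hexa = _reproduce(hexa, p_hex.N, p_hex, rng)
            tet = _reproduce(tet, p.N, p, rng)

        stage = "cohort split"
        pre, post = split_population(hexa, script.n_pre, script.n_post, rng)
        pre.label, post.label = "Pre70", "Post70"
        stage = "differentiation to target Fst"
        res = drift_until_fst(pre, post, p, script.target_fst,
                              m=script.migration,
                              max_gen=script.max_drift_gen, rng=rng)
    except Exception as exc:
        raise RuntimeError(f"scenario failed at stage {stage!r}: {exc}") from exc
    res.pop_x.label, res.pop_y.label = "Pre70", "Post70"
    return SimulatedDataset(pre=res.pop_x, post=res.pop_y, tetraploid=tet,
                            params=p, drift_generations=res.generations,
                            fst=res.fst)


# ---------------------------------------------------------------------------
# Ascertainment
# ---------------------------------------------------------------------------

def ascertain_snp_panel(dataset: SimulatedDataset, spec: AscertainmentSpec,
                        rng: np.random.Generator | None = None
                        ) -> HaplotypeSet:
    """Emulate SNP-chip ascertainment: keep exactly ``spec.n_loci`` loci
    drawn uniformly (without replacement) from those polymorphic within a
    random ``spec.panel_size``-individual Post70 discovery panel (optionally
    augmented with tetraploid accessions), then restrict every individual's
    genotypes to the retained loci."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    post = dataset.post
    if spec.panel_size > post.size:
        raise ValueError("panel larger than Post70 cohort")
    panel = rng.choice(post.size, size=spec.panel_size, replace=False)
    hap = post.haps[panel].reshape(2 * spec.panel_size, -1)
    count1 = hap.sum(axis=0).astype(np.int64)
    total = np.full(hap.shape[1], hap.shape[0], dtype=np.int64)
    if spec.tetraploid_panel and dataset.tetraploid is not None:
        tet = dataset.tetraploid
        tpanel = rng.choice(tet.size, size=spec.tetraploid_panel, replace=False)
        thap = tet.haps[tpanel].reshape(2 * spec.tetraploid_panel, -1)
        n_shared = thap.shape[1]  # A+B subgenome loci lead the hexaploid layout
        count1[:n_shared] += thap.sum(axis=0).astype(np.int64)
        total[:n_shared] += thap.shape[0]
    poly = np.flatnonzero((count1 > 0) & (count1 < total))
    if poly.size < spec.n_loci:
        raise ValueError(
            f"only {poly.size} loci polymorphic in the discovery panel; "
            f"{spec.n_loci} requested")
    keep = np.sort(rng.choice(poly, size=spec.n_loci, replace=False))
    hs = dataset.to_haplotype_set()
    return hs.restrict_loci(keep)


def ascertain_haplotype_set(hs: HaplotypeSet, spec: AscertainmentSpec,
                            panel_group: str = "Post70",
                            rng: np.random.Generator | None = None
                            ) -> HaplotypeSet:
    """Ascertainment on a labelled HaplotypeSet (file-based workflows): the
    discovery panel is drawn from ``panel_group`` individuals."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    cand = hs.group_indices(panel_group)
    if spec.panel_size > cand.size:
        raise ValueError("panel larger than the panel group")
    panel = rng.choice(cand, size=spec.panel_size, replace=False)
    rows = hs.haplotype_rows(panel)
    a = hs.alleles[rows]
    nn = (a != -1).sum(axis=0)
    k1 = (a == 1).sum(axis=0)
    poly = np.flatnonzero((k1 > 0) & (k1 < nn))
    if poly.size < spec.n_loci:
        raise ValueError(
            f"only {poly.size} loci polymorphic in the discovery panel; "
            f"{spec.n_loci} requested")
    keep = np.sort(rng.choice(poly, size=spec.n_loci, replace=False))
    return hs.restrict_loci(keep)


# ---------------------------------------------------------------------------
# Outcrossing-rate calibration
# ---------------------------------------------------------------------------

#: forward-model scale for outcrossing-rate calibration: mutation low enough
#: that LD below ~2 cM is recombination- (not mutation-) limited under
#: selfing, and enough loci for stable binned curves.
CALIBRATION_PARAMS = SimParams(N=150, mu=2e-4, lambda_xo=1.0, s_out=0.033,
                               n_chrom=1, n_loci=3_000)


def simulate_ld_curve(params: SimParams, generations: int,
                      seed: int, bin_width_cm: float = 2.0,
                      max_cm: float = 50.0, maf_floor: float = 0.05,
                      subgenomes: list[str] | None = None) -> pd.DataFrame:
    """LD-decay curve of a stationary-initialized population evolved for
    ``generations`` generations (the calibration forward model)."""
    rng = np.random.default_rng(seed)
    pop = initialize_population(params, "stationary",
                                subgenomes=subgenomes or ["A"], rng=rng)
    for _ in range(generations):
        pop = _reproduce(pop, params.N, params, rng)
    hs = to_haplotype_set({"pop": pop})
    return ld_decay_curve(hs, bin_width_cm=bin_width_cm, max_cm=max_cm,
                          maf_floor=maf_floor)


def _curve_mse(sim: pd.DataFrame, target: pd.DataFrame) -> float:
    merged = target.merge(sim, on="bin_mid_cM", suffixes=("_t", "_s"))
    ok = np.isfinite(merged["mean_r2_t"]) & np.isfinite(merged["mean_r2_s"])
    if not ok.any():
        return float("nan")
    d = merged.loc[ok, "mean_r2_t"] - merged.loc[ok, "mean_r2_s"]
    return float((d ** 2).mean())


def fit_outcrossing_rate(target_curve: pd.DataFrame,
                         params: SimParams = CALIBRATION_PARAMS,
                         coarse_grid: np.ndarray | None = None,
                         fine_step: float = 0.001,
                         replicates: int = 3,
                         generations: int = 350,
                         bin_width_cm: float = 2.0,
                         seed: int = 0) -> CalibrationResult:
    """Two-stage grid search for the outcrossing rate whose simulated
    LD-decay curve best matches ``target_curve`` (mean squared difference of
    binned r2 over 0-50 cM).

    The coarse pass (default 0.01..0.10, step 0.01) selects the bracketing
    interval around its argmin; the fine pass (step ``fine_step``) returns
    the argmin.  Replicates use common random numbers across grid points, so
    the objective surface is smooth in the rate.
    """
    if not np.isfinite(target_curve["mean_r2"]).any():
        raise ValueError("degenerate target curve: all bins missing")
    coarse = np.round(np.arange(0.01, 0.1001, 0.01), 10) \
        if coarse_grid is None else np.asarray(coarse_grid, float)

    def objective(rate: float) -> float:
        vals = []
        for r in range(replicates):
            sim = simulate_ld_curve(replace(params, s_out=float(rate)),
                                    generations, seed=seed + 7919 * (r + 1),
                                    bin_width_cm=bin_width_cm)
            vals.append(_curve_mse(sim, target_curve))
        return float(np.nanmean(vals))

    rows = [(float(r), objective(r), "coarse") for r in coarse]
    coarse_obj = np.array([o for _, o, _ in rows])
    b = int(np.nanargmin(coarse_obj))
    lo = coarse[max(0, b - 1)]
    hi = coarse[min(len(coarse) - 1, b + 1)]
    fine = np.round(np.arange(lo, hi + fine_step / 2, fine_step), 10)
    fine_rows = [(float(r), objective(r), "fine") for r in fine]
    rows.extend(fine_rows)
    fine_obj = np.array([o for _, o, _ in fine_rows])
    fitted = float(fine[int(np.nanargmin(fine_obj))])
    return CalibrationResult(
        fitted_rate=fitted,
        objectives=pd.DataFrame(rows, columns=["rate", "objective", "stage"]),
        target_curve=target_curve)


# ---------------------------------------------------------------------------
# State-level subsampling
# ---------------------------------------------------------------------------

def _merge_populations(a: Population, b: Population, label: str) -> Population:
    return Population(label=label, subgenomes=list(a.subgenomes),
                      chrom_names=list(a.chrom_names),
                      chrom_offsets=a.chrom_offsets.copy(),
                      haps=np.concatenate([a.haps, b.haps], axis=0))


def subsample_state(dataset: SimulatedDataset, n_pre_state: int,
                    n_post_state: int, target_fst_state: float,
                    m: float = 0.001, max_gen: int = 5_000,
                    rng: np.random.Generator | None = None) -> StateSubsample:
    """Draw a state cohort (n_pre_state Pre70 + n_post_state Post70
    individuals) against the remaining individuals and differentiate the
    state/rest pair to the state's empirical Fst."""
    rng = np.random.default_rng(dataset.params.seed) if rng is None else rng
    if n_pre_state > dataset.pre.size or n_post_state > dataset.post.size:
        raise ValueError("requested state cohort exceeds available cohort")
    s_pre, r_pre = split_population(dataset.pre, n_pre_state,
                                    dataset.pre.size - n_pre_state, rng)
    s_post, r_post = split_population(dataset.post, n_post_state,
                                      dataset.post.size - n_post_state, rng)
    state = _merge_populations(s_pre, s_post, "state")
    rest = _merge_populations(r_pre, r_post, "rest")
    res = drift_until_fst(state, rest, dataset.params, target_fst_state,
                          m=m, max_gen=max_gen, rng=rng)
    res.pop_x.label, res.pop_y.label = "state", "rest"
    return StateSubsample(res.pop_x, res.pop_y, res.generations, res.fst)


# ---------------------------------------------------------------------------
# Neutral null replicates (desk calibration)
# ---------------------------------------------------------------------------

def simulate_null_replicate(params: SimParams = DESK_PARAMS,
                            n_pre: int = 107, n_post: int = 93,
                            target_fst: float = 0.13, m: float = 0.001,
                            equilibration: int = 200,
                            panel_size: int = 19, n_snps: int = 800,
                            seed: int = 0) -> HaplotypeSet:
    """One neutral replicate at desk scale: stationary-initialized hexaploid,
    equilibrated, split into cohorts, differentiated to the target Fst, and
    chip-ascertained.  Returns a labelled HaplotypeSet."""
    rng = np.random.default_rng(seed)
    pop = initialize_population(params, "stationary",
                                subgenomes=["A", "B", "D"], label="hex",
                                rng=rng)
    for _ in range(equilibration):
        pop = _reproduce(pop, params.N, params, rng)
    pre, post = split_population(pop, n_pre, n_post, rng)
    res = drift_until_fst(pre, post, params, target_fst, m=m, rng=rng)
    res.pop_x.label, res.pop_y.label = "Pre70", "Post70"
    ds = SimulatedDataset(pre=res.pop_x, post=res.pop_y, tetraploid=None,
                          params=params, drift_generations=res.generations,
                          fst=res.fst)
    spec = AscertainmentSpec(panel_size=panel_size, n_loci=n_snps,
                             seed=seed + 1)
    return ascertain_snp_panel(ds, spec, rng=rng)
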