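"""End-to-end orchestration and the summary statistics of the sweep table.

`summarize_sweep_table` reproduces the headline counts of the published
region table: regions per detection method and per population, methods'
exclusive and pairwise-overlap counts, region-length statistics, and the
number of regions found in multiple populations.  `run_pipeline` wires the
whole method together at a configurable scale: neutral replicates ->
thresholds -> scans on an "observed" replicate -> significant-window calling
-> LD-based merging -> combination across methods.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ldtools, sweepcall, sweepstats
from .dataio import (ALL_METHODS, ALL_POPULATIONS, LDMatrixFixture,
                     SweepTable, load_ld_matrix_fixture,
                     load_sweep_table_fixture)
from .popsim import SimParams
from .scenario import DESK_PARAMS, simulate_null_replicate


@dataclass
class SummaryReport:
    method_counts: dict
    population_counts: dict
    method_exclusive_counts: dict
    method_exclusive_by_population: dict
    pairwise_method_overlap: dict
    lengths_cm: list
    max_length_cm: float
    mean_length_cm: float
    multi_population_count: int
    region_lengths: dict

    def to_json(self) -> str:
        d = asdict(self)
        d["pairwise_method_overlap"] = {
            "|".join(k): v for k, v in self.pairwise_method_overlap.items()}
        return json.dumps(d, indent=2)


def summarize_sweep_table(t: SweepTable) -> SummaryReport:
    """Counts and lengths from a sweep table (with expansion rules already
    applied by the loader).  Lengths are end - start in cM; pairwise method
    overlap counts rows whose method set contains both members."""
    rows = t.rows
    method_counts = {m: int(sum(m in ms for ms in rows["methods"]))
                     for m in ALL_METHODS}
    population_counts = {p: int(sum(p in ps for ps in rows["pops"]))
                         for p in ALL_POPULATIONS}
    excl = {m: int(sum(ms == frozenset({m}) for ms in rows["methods"]))
            for m in ALL_METHODS}
    excl_by_pop = {
        m: {p: int(sum(ms == frozenset({m}) and p in ps
                       for ms, ps in zip(rows["methods"], rows["pops"])))
            for p in ALL_POPULATIONS}
        for m in ALL_METHODS}
    overlap = {}
    for i, m1 in enumerate(ALL_METHODS):
        for m2 in ALL_METHODS[i + 1:]:
            overlap[(m1, m2)] = int(sum(m1 in ms and m2 in ms
                                        for ms in rows["methods"]))
    lengths = (rows["end_cm"].astype(float)
               - rows["start_cm"].astype(float)).round(10).tolist()
    multi = int(sum(len(ps) > 1 for ps in rows["pops"]))
    return SummaryReport(
        method_counts=method_counts,
        population_counts=population_counts,
        method_exclusive_counts=excl,
        method_exclusive_by_population=excl_by_pop,
        pairwise_method_overlap=overlap,
        lengths_cm=lengths,
        max_length_cm=float(max(lengths)) if lengths else 0.0,
        mean_length_cm=float(np.mean(lengths)) if lengths else 0.0,
        multi_population_count=multi,
        region_lengths=dict(zip(rows["region"], lengths)),
    )


def mean_offdiag(m: LDMatrixFixture) -> tuple[float, float]:
    """Arithmetic mean of all non-missing off-diagonal cells: (rounded to two
    decimals for reporting, unrounded)."""
    n = len(m.labels)
    if m.values.shape != (n, n):
        raise ValueError("matrix not square")
    off = m.values[~np.eye(n, dtype=bool)]
    off = off[np.isfinite(off)]
    if off.size == 0:
        raise ValueError("all off-diagonal cells missing")
    raw = float(off.mean())
    return round(raw, 2), raw


def selfing_het(g: int) -> float:
    """Expected heterozygosity at a polymorphic locus after g generations of
    selfing, counting the fully heterozygous founder as generation 1:
    1 / 2^(g-1).  g=6 gives 3.125%."""
    if not isinstance(g, (int, np.integer)) or g < 1:
        raise ValueError("g must be an integer >= 1")
    return 1.0 / 2 ** (g - 1)


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Scale and seeds for one end-to-end run.

    ``profile`` names a bundled scale: ``desk`` (N=200, 2k loci/chromosome)
    or ``mini`` (N=60, 500 loci; smoke-test scale).  Thresholds use the 99th
    percentile (99.9th for windowed Fst, which has much higher variance).
    """

    profile: str = "desk"
    n_null_replicates: int = 10
    seed: int = 0
    fst_percentile: float = 0.999
    other_percentile: float = 0.99
    outdir: str | None = None
    params: SimParams | None = None
    n_snps: int | None = None
    equilibration: int | None = None

    def resolve(self) -> tuple[SimParams, int, int, int, int,
                               "sweepstats.ScanConfig"]:
        # scan geometry follows marker density: the mini profile's sparse
        # panel needs wider gap tolerance and a shorter EHH extension
        if self.profile == "desk":
            base, n_snps, equil, n_pre, n_post = DESK_PARAMS, 800, 200, 107, 93
            scan = sweepstats.ScanConfig(seed=self.seed)
        elif self.profile == "mini":
            base = replace(DESK_PARAMS, N=60, n_loci=500, mu=1e-3)
            n_snps, equil, n_pre, n_post = 150, 60, 32, 28
            scan = sweepstats.ScanConfig(seed=self.seed, max_gap_cm=8.0,
                                         max_extend_cm=8.0, min_bin_count=3)
        else:
            raise ValueError(f"unknown profile {self.profile!r}")
        params = self.params or base
        params = replace(params, seed=self.seed)
        return (params, self.n_snps or n_snps,
                self.equilibration if self.equilibration is not None else equil,
                n_pre, n_post, scan)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "params" in d and d["params"] is not None:
            d["params"] = SimParams(**d["params"])
        return cls(**d)


def _scan_replicate(hs, cfg_scan, rng):
    """All four statistic tracks for one labelled Pre70/Post70 replicate."""
    pre_idx = hs.group_indices("Pre70")
    post_idx = hs.group_indices("Post70")
    sub_post = _subset(hs, post_idx)
    sub_pre = _subset(hs, pre_idx)
    return {
        "FST": sweepstats.fst_scan(hs, cfg=cfg_scan),
        "IHS": sweepstats.ihs_scan(sub_post, cfg=cfg_scan),
        "NSL": sweepstats.nsl_scan(sub_post, cfg=cfg_scan),
        "XPCLR": sweepstats.xpclr_scan(sub_post, sub_pre, cfg=cfg_scan,
                                       rng=rng),
    }


def _subset(hs, individuals):
    from .dataio import HaplotypeSet
    rows = hs.haplotype_rows(individuals)
    return HaplotypeSet(
        individuals=[hs.individuals[i] for i in individuals],
        loci=hs.loci, alleles=hs.alleles[rows],
        ploidy_note=hs.ploidy_note,
        sample_groups={hs.individuals[i]:
                       hs.sample_groups[hs.individuals[i]]
                       for i in individuals} if hs.sample_groups else None)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """simulate -> thresholds -> scan -> call -> merge -> combine -> report.

    Simulates ``n_null_replicates`` neutral replicates plus one "observed"
    replicate, derives per-statistic thresholds from the nulls, calls and
    merges significant windows on the observed replicate, and combines the
    per-method tables.  Under neutrality the observed replicate is itself
    null, so the flagged fraction estimates the nominal percentile tail.
    """
    params, n_snps, equil, n_pre, n_post, cfg_scan = cfg.resolve()
    stage = "simulate"
    log = {"stages": []}
    try:
        nulls = {m: [] for m in ALL_METHODS}
        for r in range(cfg.n_null_replicates):
            hs = simulate_null_replicate(
                params, n_pre=n_pre, n_post=n_post, equilibration=equil,
                n_snps=n_snps, seed=cfg.seed + 1009 * (r + 1))
            tracks = _scan_replicate(
                hs, cfg_scan, np.random.default_rng(cfg.seed + r))
            for m, tr in tracks.items():
                s = tr.scores()
                nulls[m].append(s[np.isfinite(s)])
            log["stages"].append({"stage": f"null replicate {r}",
                                  "n_snps": int(hs.n_loci)})
        stage = "thresholds"
        thresholds = {}
        for m in ALL_METHODS:
            null = sweepcall.NullDistribution(m, np.concatenate(nulls[m]),
                                              provenance=[f"replicate {i}" for
                                                          i in range(cfg.n_null_replicates)])
            pct = cfg.fst_percentile if m == "FST" else cfg.other_percentile
            thresholds[m] = sweepcall.derive_threshold(null, pct)
        stage = "observed replicate"
        hs_obs = simulate_null_replicate(
            params, n_pre=n_pre, n_post=n_post, equilibration=equil,
            n_snps=n_snps, seed=cfg.seed + 999_331)
        tracks = _scan_replicate(hs_obs, cfg_scan,
                                 np.random.default_rng(cfg.seed + 77))
        stage = "call and merge"
        bg = ldtools.background_ld_percentile(
            hs_obs, q=0.99, n_pairs=20_000,
            rng=np.random.default_rng(cfg.seed + 5))
        tables, flagged = [], {}
        for m, tr in tracks.items():
            pts = sweepcall.call_significant_windows(tr, thresholds[m])
            n_finite = int(np.isfinite(tr.scores()).sum())
            flagged[m] = {"n_significant": int(len(pts)),
                          "n_points": n_finite,
                          "fraction": len(pts) / n_finite if n_finite else np.nan}
            tables.append(sweepcall.merge_regions(
                pts, hs_obs, ld_threshold=bg, statistic=m,
                population="Post70"))
        stage = "combine"
        combined = sweepcall.combine_scans(tables)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    result = {"thresholds": thresholds, "flagged": flagged,
              "sweeps": combined, "background_r2_p99": bg,
              "tracks": tracks, "log": log,
              "config_hash": hashlib.sha256(
                  repr(cfg).encode()).hexdigest()[:12]}
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        combined.to_tsv(out / "sweeps.tsv")
        sweepcall.thresholds_to_json(list(thresholds.values()),
                                     out / "thresholds.json")
        for m, tr in tracks.items():
            tr.data.to_csv(out / f"track_{m.lower()}.tsv", sep="\t",
                           index=False)
        (out / "report.json").write_text(json.dumps(
            {"flagged": flagged, "background_r2_p99": bg,
             "config_hash": result["config_hash"],
             "seed": cfg.seed}, indent=2))
    return result


def fixture_report() -> dict:
    """Summary numbers derived from the packaged fixtures (instant)."""
    t = load_sweep_table_fixture()
    rep = summarize_sweep_table(t)
    m = load_ld_matrix_fixture()
    rounded, raw = mean_offdiag(m)
    return {"summary": rep, "mean_offdiag_rounded": rounded,
            "mean_offdiag_raw": raw, "n_regions": len(t)}
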