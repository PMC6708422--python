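"""Significance thresholds from neutral null distributions and region calling.

Thresholds are empirical quantiles of statistic values pooled over neutral
simulation replicates (99th percentile; 99.9th for the high-variance windowed
Fst).  Scores strictly above the threshold are significant; iHS and nSL are
two-sided, so thresholds and calls use absolute values.  Adjacent significant
points on a chromosome are merged into a single sweep signature when their
contributing SNPs are in strong LD, operationalized as mean inter-point r2
above the background-LD 99th percentile.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import HaplotypeSet, SweepTable
from .ldtools import mean_inter_r2
from .sweepstats import TWO_SIDED_STATISTICS, ScoreTrack


@dataclass
class NullDistribution:
    """Pooled statistic values from neutral replicates."""

    statistic: str
    values: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError("empty null distribution")
        self.values = v


@dataclass(frozen=True)
class Threshold:
    statistic: str
    percentile: float
    value: float

    def to_json(self) -> dict:
        return {"statistic": self.statistic, "percentile": self.percentile,
                "value": self.value}


def derive_threshold(null: NullDistribution, percentile: float,
                     two_sided: bool | None = None) -> Threshold:
    """Empirical quantile of the null by linear interpolation between order
    statistics.  Two-sided statistics (iHS, nSL) are thresholded on absolute
    values; the default is inferred from the statistic name."""
    if not 0 < percentile < 1:
        raise ValueError("percentile must be in (0,1)")
    if two_sided is None:
        two_sided = null.statistic.upper() in TWO_SIDED_STATISTICS
    vals = np.abs(null.values) if two_sided else null.values
    rec = 1.0 / (1.0 - percentile)
    if vals.size < rec:
        warnings.warn(
            f"null has {vals.size} values; >= {rec:.0f} recommended for the "
            f"{percentile:.3f} quantile", stacklevel=2)
    value = float(np.quantile(vals, percentile, method="linear"))
    return Threshold(null.statistic, percentile, value)


def call_significant_windows(track: ScoreTrack, thr: Threshold) -> pd.DataFrame:
    """Points of the track with score strictly above the threshold (absolute
    score for two-sided statistics), order preserved."""
    if track.statistic != thr.statistic:
        raise ValueError(
            f"statistic mismatch: track {track.statistic!r} vs "
            f"threshold {thr.statistic!r}")
    s = track.scores()
    if track.statistic.upper() in TWO_SIDED_STATISTICS:
        s = np.abs(s)
    keep = np.isfinite(s) & (s > thr.value)
    return track.data.loc[keep].reset_index(drop=True)


def merge_regions(points: pd.DataFrame, hs: HaplotypeSet,
                  ld_threshold: float,
                  snp_sets: list[np.ndarray] | None = None,
                  statistic: str = "", population: str = "") -> SweepTable:
    """Merge consecutive significant points into sweep regions.

    Adjacent points on the same chromosome join one region iff the mean r2
    between their contributing SNP sets exceeds ``ld_threshold``.  When
    ``snp_sets`` is not given, each point contributes its nearest locus.
    Singleton points become zero-length regions (start == end).
    """
    pts = points.reset_index(drop=True)
    if snp_sets is None:
        snp_sets = []
        cm = hs.loci["cM"].to_numpy(float)
        for _, row in pts.iterrows():
            idx = hs.chrom_slice(row["chrom"])
            j = idx[np.argmin(np.abs(cm[idx] - row["pos_cM"]))]
            snp_sets.append(np.array([j]))
    regions = []
    current: list[int] = []

    def flush():
        if not current:
            return
        sub = pts.iloc[current]
        start, end = float(sub["pos_cM"].min()), float(sub["pos_cM"].max())
        chrom = sub["chrom"].iloc[0]
        regions.append({
            "region": f"{chrom}-{start:g}:{end:g}",
            "chrom": chrom, "start_cm": start, "end_cm": end,
            "pops": frozenset({population}) if population else frozenset({"?"}),
            "methods": frozenset({statistic}) if statistic else frozenset({"?"}),
            "annotation": "-",
        })

    for i in range(len(pts)):
        if not current:
            current = [i]
            continue
        prev = current[-1]
        same_chrom = pts["chrom"].iloc[i] == pts["chrom"].iloc[prev]
        joined = False
        if same_chrom:
            r2 = mean_inter_r2(hs, snp_sets[prev], snp_sets[i])
            joined = np.isfinite(r2) and r2 > ld_threshold
        if joined:
            current.append(i)
        else:
            flush()
            current = [i]
    flush()
    return SweepTable(pd.DataFrame(
        regions, columns=["region", "chrom", "start_cm", "end_cm",
                          "pops", "methods", "annotation"]))


def combine_scans(tables: list[SweepTable]) -> SweepTable:
    """Union overlapping intervals across methods/populations.

    Intervals are closed; any cM overlap on the same chromosome chains
    regions together (transitively) into one row whose method and population
    sets are the unions and whose interval is the union span.
    """
    rows = pd.concat([t.rows for t in tables if len(t)], ignore_index=True) \
        if any(len(t) for t in tables) else pd.DataFrame(
            columns=["region", "chrom", "start_cm", "end_cm", "pops",
                     "methods", "annotation"])
    out = []
    for chrom, sub in rows.groupby("chrom", sort=True):
        sub = sub.sort_values(["start_cm", "end_cm"]).reset_index(drop=True)
        cur = None
        for _, r in sub.iterrows():
            if cur is None:
                cur = dict(r)
                cur["pops"] = frozenset(r["pops"])
                cur["methods"] = frozenset(r["methods"])
                continue
            if r["start_cm"] <= cur["end_cm"]:  # closed-interval overlap
                cur["end_cm"] = max(cur["end_cm"], r["end_cm"])
                cur["pops"] = cur["pops"] | r["pops"]
                cur["methods"] = cur["methods"] | r["methods"]
            else:
                out.append(cur)
                cur = dict(r)
                cur["pops"] = frozenset(r["pops"])
                cur["methods"] = frozenset(r["methods"])
        if cur is not None:
            out.append(cur)
    for r in out:
        r["region"] = f"{r['chrom']}-{r['start_cm']:g}:{r['end_cm']:g}"
        r["annotation"] = r.get("annotation", "-")
    return SweepTable(pd.DataFrame(
        out, columns=["region", "chrom", "start_cm", "end_cm", "pops",
                      "methods", "annotation"]))


def thresholds_to_json(thresholds: list[Threshold], path: str | Path) -> None:
    Path(path).write_text(json.dumps([t.to_json() for t in thresholds],
                                     indent=2))
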