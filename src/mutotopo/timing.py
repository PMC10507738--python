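"""Replication-timing decile analysis.

The wavelet-smoothed Repli-seq signal (higher = earlier replication) is
sorted in descending order and partitioned into ten deciles each holding
as close to 10% of the total signal as whole segments allow (segments
are atomic). Mutation densities per decile are counts divided by
attributable (non-N) bases, normalized so the densest decile equals 1.
A signature's trend across deciles is INCREASING/DECREASING only when
the OLS slope differs significantly from flat AND the normalized
densities are monotone (non-strict); otherwise FLAT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSequence
from .io import SignalTrack

N_DECILES = 10

INCREASING = "INCREASING"
DECREASING = "DECREASING"
FLAT = "FLAT"


@dataclass
class DecileSet:
    """Ten interval groups ordered earliest to latest replication."""

    frames: list  # list of DataFrames (chrom, start, end, value)
    signal_share: np.ndarray  # fraction of total signal per decile
    _locator: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for d, frame in enumerate(self.frames):
            for rec in frame.itertuples(index=False):
                self._locator.setdefault(rec.chrom, []).append((rec.start, rec.end, d))
        self._index = {}
        for chrom, triples in self._locator.items():
            triples.sort()
            arr = np.asarray(triples, dtype=np.int64)
            self._index[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])

    def locate(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Decile index (0 = earliest) per position; -1 outside coverage."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        out = np.full(pos.size, -1, dtype=np.int64)
        if chrom not in self._index:
            return out
        starts, ends, dec = self._index[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        ok = (i >= 0) & (pos < ends[np.clip(i, 0, None)])
        out[ok] = dec[i[ok]]
        return out

    def attributable_bases(self, genome: GenomeSequence) -> np.ndarray:
        bases = np.zeros(N_DECILES, dtype=np.int64)
        for d, frame in enumerate(self.frames):
            for rec in frame.itertuples(index=False):
                bases[d] += genome.attributable_bases(rec.chrom, rec.start, rec.end)
        return bases


def split_deciles(signal: SignalTrack, chrom_order: list | None = None) -> DecileSet:
    """Sort segments by signal value descending and fill ten deciles with
    whole segments, each targeting 10% of total signal mass (adaptive
    target = remaining mass / remaining deciles, so every decile is
    non-empty). Ties broken by genomic order."""
    seg = signal.segments_frame()
    if len(seg) < N_DECILES:
        raise ValueError(f"need at least {N_DECILES} signal segments, got {len(seg)}")
    order = chrom_order or sorted(seg["chrom"].unique())
    chrom_rank = {c: i for i, c in enumerate(order)}
    seg = seg.assign(_rank=seg["chrom"].map(chrom_rank))
    seg = seg.sort_values(
        by=["value", "_rank", "start"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    mass = (seg["value"] * (seg["end"] - seg["start"])).to_numpy(dtype=float)
    total = float(mass.sum())
    if total <= 0:
        raise ValueError("signal track has non-positive total mass")
    frames = [[] for _ in range(N_DECILES)]
    shares = np.zeros(N_DECILES)
    d = 0
    acc = 0.0
    remaining = total
    n_left = len(seg)
    for i in range(len(seg)):
        target = remaining / (N_DECILES - d)
        frames[d].append(i)
        acc += mass[i]
        n_left -= 1
        if acc >= target - 1e-12 and d < N_DECILES - 1 and n_left >= (N_DECILES - 1 - d):
            shares[d] = acc / total
            remaining -= acc
            acc = 0.0
            d += 1
    shares[d] = acc / total
    out_frames = [
        seg.iloc[rows][["chrom", "start", "end", "value"]].reset_index(drop=True)
        for rows in frames
    ]
    return DecileSet(frames=out_frames, signal_share=shares)


@dataclass
class DecileDensityVector:
    """Normalized mutation densities per decile (max = 1)."""

    x: np.ndarray
    raw_counts: np.ndarray
    attributable_bases: np.ndarray
    n_excluded: int = 0


def decile_density(
    df: pd.DataFrame, deciles: DecileSet, genome: GenomeSequence
) -> DecileDensityVector:
    """Normalized density vector for a mutation frame: per-decile counts
    divided by attributable bases, scaled to max 1. Mutations outside
    decile coverage are excluded and counted."""
    counts = np.zeros(N_DECILES, dtype=np.int64)
    excluded = 0
    for chrom, grp in df.groupby("chrom", sort=False):
        d = deciles.locate(chrom, grp["pos"].to_numpy(dtype=np.int64))
        excluded += int((d < 0).sum())
        inside = d[d >= 0]
        np.add.at(counts, inside, 1)
    bases = deciles.attributable_bases(genome)
    if np.any(bases == 0):
        raise ValueError("decile with zero attributable bases: density undefined")
    dens = counts / bases
    peak = dens.max()
    x = dens / peak if peak > 0 else dens.astype(float)
    return DecileDensityVector(x=x, raw_counts=counts, attributable_bases=bases, n_excluded=excluded)


@dataclass
class SimulatedDensityEnsemble:
    """Per-decile mean/sd/95% CI over replicate density vectors."""

    matrix: np.ndarray  # n_reps x 10
    mean: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


def ensemble_stats(replicate_vectors: list) -> SimulatedDensityEnsemble:
    """Mean, sd (ddof=1) and normal-approximation 95% CI of the replicate
    ensemble (CI = mean +/- 1.96 sd / sqrt(n_reps))."""
    if len(replicate_vectors) < 2:
        raise ValueError("need >= 2 replicates")
    rows = [
        v.x if isinstance(v, DecileDensityVector) else np.asarray(v, dtype=float)
        for v in replicate_vectors
    ]
    mat = np.vstack(rows)
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    half = 1.96 * sd / np.sqrt(mat.shape[0])
    return SimulatedDensityEnsemble(
        matrix=mat, mean=mean, sd=sd, ci_low=mean - half, ci_high=mean + half
    )


@dataclass
class TimingTrend:
    trend: str
    slope: float
    p: float


def classify_trend(x, alpha: float = 0.05, atol: float = 0.0) -> TimingTrend:
    """OLS of density against decile index 1..10; INCREASING/DECREASING
    require a significant slope and (non-strict) monotone densities."""
    x = x.x if isinstance(x, DecileDensityVector) else np.asarray(x, dtype=float)
    if x.size != N_DECILES or not np.all(np.isfinite(x)):
        raise ValueError("need 10 finite densities")
    if np.all(x == x[0]):
        return TimingTrend(trend=FLAT, slope=0.0, p=1.0)
    res = stats.linregress(np.arange(1, N_DECILES + 1), x)
    slope, p = float(res.slope), float(res.pvalue)
    diffs = np.diff(x)
    if p <= alpha and slope > 0 and np.all(diffs >= -atol):
        return TimingTrend(trend=INCREASING, slope=slope, p=p)
    if p <= alpha and slope < 0 and np.all(diffs <= atol):
        return TimingTrend(trend=DECREASING, slope=slope, p=p)
    return TimingTrend(trend=FLAT, slope=slope, p=p)


def aggregate_densities(vectors: list) -> np.ndarray:
    """Unweighted average of normalized density vectors across cohorts
    (the cross-cancer-type summary operation)."""
    mat = np.vstack([v.x if isinstance(v, DecileDensityVector) else v for v in vectors])
    return mat.mean(axis=0)
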