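"""Occupancy and abundance analysis of topographical features.

Occupancy: the average signal of a feature (nucleosomes, CTCF, histone
marks) in a 2,001 bp window centered on each mutation (1,000 bp 5' to
1,000 bp 3'), averaged in two rounds — over mutations within each
dataset (K vectors) and then unweighted over datasets/cohorts (M
vectors) — for real and simulated catalogs alike. Cancer-type profiles
are compared to the global profile by Pearson correlation over the
central +/-500 bp.

Abundance: the mean signal over +/-50 bp (101 positions) around real
mutations, s_real, versus the same quantity per simulated replicate; a
z-test against the replicate ensemble, Fisher's method across datasets
of one cohort, BH correction, and calls ENRICHED (fold >= 1.05) or
DEPLETED (fold <= 0.95) at q <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SignalTrack

WINDOW_HALF = 1000
SIMILARITY_HALF = 500
ABUNDANCE_HALF = 50
FOLD_MIN = 1.05

ENRICHED = "ENRICHED"
DEPLETED = "DEPLETED"
NONE_CALL = "NONE"


def window_signal(
    track: SignalTrack, chrom: str, pos: int, half: int = WINDOW_HALF
) -> np.ndarray:
    """Per-base signal vector of length 2*half+1 centered at ``pos``
    (offset 0 = the mutation start position)."""
    return track.values_array(chrom, pos - half, pos + half + 1)


def mean_window_signal(
    track: SignalTrack,
    df: pd.DataFrame,
    half: int = WINDOW_HALF,
    chrom_lengths: dict | None = None,
) -> tuple[np.ndarray, int]:
    """Average window vector over a mutation frame (round 1 of the
    occupancy averaging). Mutations whose window does not fit inside the
    chromosome are skipped and counted. Returns (vector, n_used)."""
    width = 2 * half + 1
    acc = np.zeros(width)
    n = 0
    for chrom, grp in df.groupby("chrom", sort=False):
        limit = chrom_lengths.get(chrom) if chrom_lengths else None
        dense = track.dense(chrom, length=limit)
        for pos in grp["pos"].to_numpy(dtype=np.int64):
            if pos - half < 0 or pos + half + 1 > dense.size:
                continue
            acc += dense[pos - half : pos + half + 1]
            n += 1
    if n == 0:
        raise ValueError("no usable mutations for occupancy profile")
    return acc / n, n


def mean_abundance_signal(
    track: SignalTrack,
    df: pd.DataFrame,
    half: int = ABUNDANCE_HALF,
    window_half: int = WINDOW_HALF,
    chrom_lengths: dict | None = None,
) -> float:
    """Mean over mutations of the +/-``half`` bp mean signal — equal to
    ``abundance_windows(mean_window_signal(...))`` when every window
    fits, computed in O(1) per mutation via prefix sums. Mutations whose
    full occupancy window does not fit are skipped, mirroring
    :func:`mean_window_signal`."""
    total = 0.0
    n = 0
    width = 2 * half + 1
    for chrom, grp in df.groupby("chrom", sort=False):
        limit = chrom_lengths.get(chrom) if chrom_lengths else None
        cs = track.dense_cumsum(chrom, length=limit)
        size = cs.size - 1
        pos = grp["pos"].to_numpy(dtype=np.int64)
        ok = (pos - window_half >= 0) & (pos + window_half + 1 <= size)
        pos = pos[ok]
        total += float((cs[pos + half + 1] - cs[pos - half]).sum()) / width
        n += pos.size
    if n == 0:
        raise ValueError("no usable mutations for abundance analysis")
    return total / n


@dataclass
class OccupancyProfile:
    """K (per-dataset) and M (dataset-averaged) occupancy vectors for the
    real catalog and the simulation-averaged counterparts."""

    k_real: list  # one 2,001-vector per dataset
    m_real: np.ndarray
    k_sims: list
    m_sims: np.ndarray
    n_mutations: int


def average_occupancy(
    real: pd.DataFrame,
    sims: list,
    tracks: list,
    half: int = WINDOW_HALF,
    chrom_lengths: dict | None = None,
) -> OccupancyProfile:
    """Two-round averaging over mutations then datasets, identically for
    the real catalog and each simulated replicate (replicates averaged
    into K_sims/M_sims)."""
    k_real = []
    n_used = 0
    for track in tracks:
        vec, n = mean_window_signal(track, real, half, chrom_lengths)
        k_real.append(vec)
        n_used = max(n_used, n)
    m_real = np.mean(k_real, axis=0)
    k_sims = []
    for track in tracks:
        per_rep = [mean_window_signal(track, s, half, chrom_lengths)[0] for s in sims]
        k_sims.append(np.mean(per_rep, axis=0))
    m_sims = np.mean(k_sims, axis=0)
    return OccupancyProfile(
        k_real=k_real, m_real=m_real, k_sims=k_sims, m_sims=m_sims, n_mutations=n_used
    )


def pearson_fisher_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson r with a Fisher z-transform two-sided p value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    n = a.size
    if abs(r) >= 1.0:
        return r, 0.0
    z = np.arctanh(r) * np.sqrt(n - 3)
    return r, float(2 * stats.norm.sf(abs(z)))


def occupancy_similarity(
    k_real: np.ndarray,
    m_real: np.ndarray,
    half: int = SIMILARITY_HALF,
    r_min: float = 0.5,
) -> dict:
    """Correlate a cohort profile with the global profile over the
    central +/-``half`` offsets. ``similar`` additionally requires the
    BH-adjusted p (filled in by the caller across the family) <= 0.05;
    here the raw p is returned with a provisional flag."""
    center = (len(k_real) - 1) // 2
    lo, hi = center - half, center + half + 1
    r, p = pearson_fisher_z(k_real[lo:hi], m_real[lo:hi])
    flagged = np.isnan(r)
    return {
        "r": r,
        "p": p,
        "similar": (not flagged) and r >= r_min,
        "degenerate": bool(flagged),
    }


def abundance_windows(vec_2001: np.ndarray, half: int = ABUNDANCE_HALF) -> float:
    """Mean signal over the +/-``half`` bp window (101 positions
    including offset 0) of a 2,001-position occupancy vector."""
    center = (len(vec_2001) - 1) // 2
    return float(np.mean(vec_2001[center - half : center + half + 1]))


@dataclass
class AbundanceResult:
    s_real: float
    sim_mean: float
    sim_sd: float
    fold_change: float
    z: float
    p: float
    q: float = float("nan")
    call: str = NONE_CALL
    degenerate: bool = False


def abundance_test_dataset(s_real: float, s_sims: np.ndarray) -> AbundanceResult:
    """z-test of the real +/-50 bp mean signal against the simulated
    replicate ensemble for one dataset."""
    s_sims = np.asarray(s_sims, dtype=float)
    if s_sims.size < 2:
        raise ValueError("need >= 2 replicates")
    mean, sd = s_sims.mean(), s_sims.std(ddof=1)
    fold = s_real / mean if mean != 0 else float("nan")
    if sd == 0:
        z = 0.0 if s_real == mean else np.inf * np.sign(s_real - mean)
        p = 1.0 if s_real == mean else 0.0
        return AbundanceResult(s_real, mean, sd, fold, z, p, degenerate=True)
    z = (s_real - mean) / sd
    p = float(2 * stats.norm.sf(abs(z)))
    return AbundanceResult(s_real, mean, sd, fold, z, p)


def combine_abundance(results: list) -> tuple[float, float]:
    """Fisher's method across the per-dataset p values of one cohort and
    the average of the per-dataset fold changes."""
    ps = [r.p for r in results]
    folds = [r.fold_change for r in results]
    if len(ps) == 1:
        return ps[0], folds[0]
    stat = -2 * np.sum(np.log(np.clip(ps, 1e-300, 1.0)))
    combined = float(stats.chi2.sf(stat, df=2 * len(ps)))
    return combined, float(np.mean(folds))


def call_abundance(fold: float, q: float, fold_min: float = FOLD_MIN, q_max: float = 0.05) -> str:
    """ENRICHED / DEPLETED / NONE per the fold and BH-adjusted p rule
    (at least 5% enrichment or depletion)."""
    if np.isnan(fold) or np.isnan(q) or q > q_max:
        return NONE_CALL
    if fold >= fold_min:
        return ENRICHED
    if fold <= 2 - fold_min:  # 0.95 for the default 1.05
        return DEPLETED
    return NONE_CALL


def abundance_analysis(
    real: pd.DataFrame,
    sims: list,
    tracks: list,
    half_window: int = WINDOW_HALF,
    half_abundance: int = ABUNDANCE_HALF,
    chrom_lengths: dict | None = None,
) -> dict:
    """Full abundance pipeline for one (signature, feature, cohort):
    per-dataset z-tests, Fisher combination, averaged fold. The caller
    applies BH across cohorts/features and then :func:`call_abundance`."""
    per_dataset = []
    for track in tracks:
        s_real = mean_abundance_signal(track, real, half_abundance, half_window, chrom_lengths)
        s_sims = np.array(
            [
                mean_abundance_signal(track, s, half_abundance, half_window, chrom_lengths)
                for s in sims
            ]
        )
        per_dataset.append(abundance_test_dataset(s_real, s_sims))
    combined_p, avg_fold = combine_abundance(per_dataset)
    return {"per_dataset": per_dataset, "p": combined_p, "fold": avg_fold}
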