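"""Transcription- and replication-strand annotation.

Transcription: a mutation inside a single-strand gene region is
TRANSCRIBED when its pyrimidine base lies on the gene's template strand,
UNTRANSCRIBED when on the coding strand; bidirectionally transcribed
regions are excluded, everything outside genes is NONTRANSCRIBED.

Replication: a Repli-seq wavelet profile with printed initiation peaks
and termination valleys is converted into leading/lagging regions on the
+ strand (positive slope between valley and peak = leading), with
monotone stretches shorter than ``min_len`` dropped and ``term_trim``
bases flanking each termination valley removed. A mutation's label then
follows from its pyrimidine strand: pyrimidine on + in a leading-plus
region is LEADING, on - it is LAGGING, and symmetrically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSequence, Mutation, pyrimidine_strand
from .io import IntervalSet, SignalTrack

TRANSCRIBED = "TRANSCRIBED"
UNTRANSCRIBED = "UNTRANSCRIBED"
NONTRANSCRIBED = "NONTRANSCRIBED"
EXCLUDED_BIDIRECTIONAL = "EXCLUDED_BIDIRECTIONAL"

LEADING = "LEADING"
LAGGING = "LAGGING"
UNASSIGNED_STRAND = "UNASSIGNED"

LEADING_PLUS = "LEADING_PLUS"
LAGGING_PLUS = "LAGGING_PLUS"


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def _covered(starts: np.ndarray, ends: np.ndarray, pos: np.ndarray) -> np.ndarray:
    if starts.size == 0:
        return np.zeros(pos.size, dtype=bool)
    i = np.searchsorted(starts, pos, side="right") - 1
    ok = i >= 0
    out = np.zeros(pos.size, dtype=bool)
    out[ok] = pos[ok] < ends[i[ok]]
    return out


class GeneIndex:
    """Merged +/- strand gene coverage for fast strand lookups."""

    def __init__(self, genes: pd.DataFrame):
        self.plus: dict[str, tuple] = {}
        self.minus: dict[str, tuple] = {}
        for chrom, grp in genes.groupby("chrom", sort=True):
            for strand, store in (("+", self.plus), ("-", self.minus)):
                sub = grp[grp["strand"] == strand]
                store[chrom] = _merge_intervals(
                    sub["start"].to_numpy(dtype=np.int64),
                    sub["end"].to_numpy(dtype=np.int64),
                )

    def strand_coverage(self, chrom: str, pos: np.ndarray):
        empty = (np.zeros(0, dtype=np.int64),) * 2
        on_plus = _covered(*self.plus.get(chrom, empty), pos)
        on_minus = _covered(*self.minus.get(chrom, empty), pos)
        return on_plus, on_minus


def transcription_labels(
    chrom_arr: np.ndarray, pos_arr: np.ndarray, pyr_arr: np.ndarray, genes: GeneIndex
) -> np.ndarray:
    """Vectorized transcription labels for a classified catalog."""
    labels = np.full(chrom_arr.size, NONTRANSCRIBED, dtype=object)
    frame = pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr})
    for chrom, grp in frame.groupby("chrom", sort=False):
        rows = grp.index.to_numpy()
        pos = grp["pos"].to_numpy(dtype=np.int64)
        on_plus, on_minus = genes.strand_coverage(chrom, pos)
        both = on_plus & on_minus
        only_plus = on_plus & ~on_minus
        only_minus = on_minus & ~on_plus
        pyr = pyr_arr[rows]
        lab = np.full(rows.size, NONTRANSCRIBED, dtype=object)
        lab[both] = EXCLUDED_BIDIRECTIONAL
        # pyrimidine on template strand (opposite the gene) => TRANSCRIBED
        lab[only_plus & (pyr == "-")] = TRANSCRIBED
        lab[only_plus & (pyr == "+")] = UNTRANSCRIBED
        lab[only_minus & (pyr == "+")] = TRANSCRIBED
        lab[only_minus & (pyr == "-")] = UNTRANSCRIBED
        labels[rows] = lab
    return labels


def annotate_transcription(mut: Mutation, genes: GeneIndex, genome: GenomeSequence) -> str:
    """Single-mutation transcription label (see module docstring)."""
    pyr = pyrimidine_strand(mut)
    return transcription_labels(
        np.array([mut.chrom], dtype=object),
        np.array([mut.pos], dtype=np.int64),
        np.array([pyr], dtype=object),
        genes,
    )[0]


# ---------------------------------------------------------------------------
# replication

@dataclass
class RepliSeqProfile:
    """Wavelet-smoothed replication timing (higher = earlier) with printed
    initiation peaks and termination valleys."""

    signal: SignalTrack
    peaks: IntervalSet
    valleys: IntervalSet


@dataclass
class ReplicationStrandMap:
    """Disjoint intervals labeled LEADING_PLUS / LAGGING_PLUS per
    chromosome (the - strand labels are the complement)."""

    starts: dict
    ends: dict
    labels: dict  # arrays of 0 (LEADING_PLUS) / 1 (LAGGING_PLUS)

    def total_bases(self, label: str) -> int:
        want = 0 if label == LEADING_PLUS else 1
        total = 0
        for chrom in self.starts:
            mask = self.labels[chrom] == want
            total += int((self.ends[chrom][mask] - self.starts[chrom][mask]).sum())
        return total


def derive_replication_strand_map(
    profile: RepliSeqProfile,
    min_len: int = 10000,
    term_trim: int = 25000,
    trim_mode: str = "both",
) -> ReplicationStrandMap:
    """Label monotone stretches between adjacent peak/valley anchors.

    Valley-to-peak stretches have positive timing slope (leading on +),
    peak-to-valley negative slope (lagging on +). Stretches shorter than
    ``min_len`` are dropped; ``term_trim`` bases adjacent to each valley
    midpoint are removed (on both sides, or only the earlier-replicated
    5' side with ``trim_mode='left'``). Chromosomes without both peaks
    and valleys are left unannotated with a warning.
    """
    if trim_mode not in ("both", "left"):
        raise ValueError("trim_mode must be 'both' or 'left'")
    starts, ends, labels = {}, {}, {}
    chroms = set(profile.peaks.chroms) | set(profile.valleys.chroms)
    for chrom in sorted(chroms):
        if chrom not in profile.peaks.starts or chrom not in profile.valleys.starts:
            warnings.warn(f"no peaks or no valleys on {chrom}; left unannotated")
            continue
        p_mid = profile.peaks.midpoints(chrom)
        v_mid = profile.valleys.midpoints(chrom)
        anchors = np.concatenate([p_mid, v_mid])
        kinds = np.concatenate([np.zeros(p_mid.size), np.ones(v_mid.size)])  # 1=valley
        order = np.argsort(anchors, kind="stable")
        anchors, kinds = anchors[order], kinds[order]
        if np.any(kinds[1:] == kinds[:-1]):
            raise ValueError(f"peaks and valleys do not alternate on {chrom}")
        seg_s, seg_e, seg_l = [], [], []
        for a, b, ka, kb in zip(anchors[:-1], anchors[1:], kinds[:-1], kinds[1:]):
            if b - a < min_len:
                continue
            # valley -> peak: signal rises (later to earlier): +slope, leading on +
            label = 0 if ka == 1 else 1
            s, e = int(a), int(b)
            if ka == 1 and trim_mode == "both":
                # left anchor is a termination valley: trim its right flank
                s += term_trim
            if kb == 1:
                # approaching a termination valley: trim the 25 kb
                # replicated last (trimmed in both modes)
                e -= term_trim
            if e > s:
                seg_s.append(s)
                seg_e.append(e)
                seg_l.append(label)
        starts[chrom] = np.asarray(seg_s, dtype=np.int64)
        ends[chrom] = np.asarray(seg_e, dtype=np.int64)
        labels[chrom] = np.asarray(seg_l, dtype=np.int64)
    return ReplicationStrandMap(starts=starts, ends=ends, labels=labels)


def replication_labels(
    chrom_arr: np.ndarray,
    pos_arr: np.ndarray,
    pyr_arr: np.ndarray,
    repmap: ReplicationStrandMap,
) -> np.ndarray:
    """Vectorized LEADING/LAGGING/UNASSIGNED labels."""
    labels = np.full(chrom_arr.size, UNASSIGNED_STRAND, dtype=object)
    frame = pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr})
    for chrom, grp in frame.groupby("chrom", sort=False):
        if chrom not in repmap.starts or repmap.starts[chrom].size == 0:
            continue
        rows = grp.index.to_numpy()
        pos = grp["pos"].to_numpy(dtype=np.int64)
        i = np.searchsorted(repmap.starts[chrom], pos, side="right") - 1
        inside = (i >= 0) & (pos < repmap.ends[chrom][np.clip(i, 0, None)])
        region = repmap.labels[chrom][np.clip(i, 0, None)]  # 0 leading+, 1 lagging+
        pyr_plus = pyr_arr[rows] == "+"
        lab = np.full(rows.size, UNASSIGNED_STRAND, dtype=object)
        lead = inside & (((region == 0) & pyr_plus) | ((region == 1) & ~pyr_plus))
        lagg = inside & (((region == 0) & ~pyr_plus) | ((region == 1) & pyr_plus))
        lab[lead] = LEADING
        lab[lagg] = LAGGING
        labels[rows] = lab
    return labels


def annotate_replication(mut: Mutation, repmap: ReplicationStrandMap) -> str:
    pyr = pyrimidine_strand(mut)
    return replication_labels(
        np.array([mut.chrom], dtype=object),
        np.array([mut.pos], dtype=np.int64),
        np.array([pyr], dtype=object),
        repmap,
    )[0]


def annotate_catalog_strands(
    df: pd.DataFrame,
    genes: GeneIndex | None = None,
    repmap: ReplicationStrandMap | None = None,
) -> pd.DataFrame:
    """Add ``tx_label`` and/or ``rep_label`` columns to a classified
    catalog (requires ``pyr_strand`` from classify_catalog)."""
    df = df.reset_index(drop=True).copy()
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(dtype=np.int64)
    pyr = df["pyr_strand"].to_numpy()
    if genes is not None:
        df["tx_label"] = transcription_labels(chrom, pos, pyr, genes)
    if repmap is not None:
        df["rep_label"] = replication_labels(chrom, pos, pyr, repmap)
    return df


def genic_labels(tx_labels: np.ndarray) -> np.ndarray:
    """Genic/intergenic stratum from transcription labels: every gene hit
    (including bidirectional exclusions) is genic, NONTRANSCRIBED is
    intergenic."""
    return np.where(tx_labels == NONTRANSCRIBED, "INTERGENIC", "GENIC")
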