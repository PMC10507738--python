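"""Strand-coordinated mutagenesis (SCM).

Runs of consecutive single base substitutions within one sample that
share the six-class channel, the reference strand carrying the mutated
pyrimidine, and the attributed signature, with every consecutive pair
closer than the inter-mutational distance threshold (default 10,000 bp,
strict), are collected as SCM groups. Singletons are discarded. Observed
group-length counts per signature are tested against the per-replicate
counts from simulated catalogs with a z-test and BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .asymmetry import bh_adjust

IMD_DEFAULT = 10000
PROB_CUTOFF_DEFAULT = 0.5


@dataclass(frozen=True)
class SCMGroup:
    sample_id: str
    signature: str
    channel: str  # six-class
    strand: str  # pyrimidine reference strand
    chrom: str
    start: int
    end: int
    length: int


def _retained(df: pd.DataFrame, prob_cutoff: float, context: str) -> pd.DataFrame:
    from .genome import UNASSIGNED

    sub = df[
        (df["mut_type"] == "SBS")
        & (df["signature"] != UNASSIGNED)
        & (df["probability"] >= prob_cutoff)
    ].copy()
    sub["scm_ctx"] = sub["sbs6"] if context == "sbs6" else sub["channel"]
    return sub.sort_values(["sample", "chrom", "pos"], kind="stable").reset_index(drop=True)


def find_scm_groups(
    df: pd.DataFrame,
    imd: int = IMD_DEFAULT,
    prob_cutoff: float = PROB_CUTOFF_DEFAULT,
    context: str = "sbs6",
) -> list[SCMGroup]:
    """Maximal same-context, same-strand, same-signature runs with
    consecutive gaps < ``imd`` within each sample; length >= 2.

    Distances are measured between retained mutations only (those with an
    assigned signature at probability >= ``prob_cutoff``); ``context``
    chooses six-class (default) or SBS-96 strictness.
    """
    sub = _retained(df, prob_cutoff, context)
    groups: list[SCMGroup] = []
    run: list = []

    def flush():
        if len(run) >= 2:
            first, last = run[0], run[-1]
            groups.append(
                SCMGroup(
                    sample_id=first.sample,
                    signature=first.signature,
                    channel=first.scm_ctx,
                    strand=first.pyr_strand,
                    chrom=first.chrom,
                    start=int(first.pos),
                    end=int(last.pos) + 1,
                    length=len(run),
                )
            )

    prev = None
    for rec in sub.itertuples(index=False):
        if prev is not None and (
            rec.sample == prev.sample
            and rec.chrom == prev.chrom
            and rec.scm_ctx == prev.scm_ctx
            and rec.pyr_strand == prev.pyr_strand
            and rec.signature == prev.signature
            and rec.pos - prev.pos < imd
        ):
            run.append(rec)
        else:
            flush()
            run = [rec]
        prev = rec
    flush()
    return groups


def group_length_histogram(groups) -> pd.Series:
    """Counts per (signature, length)."""
    if not groups:
        return pd.Series(dtype=int)
    frame = pd.DataFrame([(g.signature, g.length) for g in groups], columns=["signature", "length"])
    return frame.groupby(["signature", "length"]).size()


def test_scm_lengths(
    real_hist: pd.Series, sim_hists: list, q_max: float = 0.05
) -> pd.DataFrame:
    """z-test of the observed group count per (signature, length) against
    the simulated replicate counts (mean/sd with ddof=1); BH across all
    cells. Cells with zero simulated variance are flagged degenerate:
    p = 1 when the observation equals the common simulated value, else a
    zero-p sentinel."""
    if len(sim_hists) < 2:
        raise ValueError("need >= 2 simulated replicates")
    keys = set(real_hist.index)
    for h in sim_hists:
        keys |= set(h.index)
    keys = sorted(keys)
    rows = []
    for sig, length in keys:
        obs = int(real_hist.get((sig, length), 0))
        sims = np.array([float(h.get((sig, length), 0)) for h in sim_hists])
        mean, sd = sims.mean(), sims.std(ddof=1)
        degenerate = sd == 0
        if degenerate:
            z = 0.0 if obs == mean else np.inf * np.sign(obs - mean)
            p = 1.0 if obs == mean else 0.0
        else:
            z = (obs - mean) / sd
            p = 2 * stats.norm.sf(abs(z))
        rows.append((sig, int(length), obs, mean, sd, z, p, degenerate))
    out = pd.DataFrame(
        rows,
        columns=["signature", "length", "observed", "sim_mean", "sim_sd", "z", "p", "degenerate"],
    )
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["reported"] = out["q"] <= q_max
    return out
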