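"""Catalog-level classification: attach channels, pyrimidine strand and
signature attributions to a mutation DataFrame.

The DataFrame produced by :func:`mutotopo.io.read_mutations` is the
working container for whole-catalog operations; scalar dataclass APIs in
:mod:`mutotopo.genome` serve single-mutation use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import genome as gm
from .channels import sbs6_of_sbs96
from .genome import GenomeSequence, UNASSIGNED
from .io import SignatureProbabilityTable


def classify_catalog(df: pd.DataFrame, genome: GenomeSequence) -> pd.DataFrame:
    """Add ``channel`` (scheme label), ``sbs6`` (six-class channel, empty
    for DBS/ID) and ``pyr_strand`` columns; unclassifiable mutations
    (N context, chromosome-edge overruns) are dropped and counted in
    ``result.attrs['n_unclassifiable']``.
    """
    df = df.reset_index(drop=True).copy()
    channel = np.full(len(df), "", dtype=object)
    sbs6 = np.full(len(df), "", dtype=object)
    pyr = np.full(len(df), "", dtype=object)
    keep = np.ones(len(df), dtype=bool)

    is_sbs = (df["mut_type"] == "SBS").to_numpy()
    # SBS: vectorized per chromosome
    sbs_df = df[is_sbs]
    for chrom, grp in sbs_df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        alt_codes = gm.encode_sequence("".join(grp["alt"])).astype(np.int64)
        ref_codes = gm.encode_sequence("".join(grp["ref"])).astype(np.int64)
        codes = genome.codes(chrom)
        inside = (pos >= 0) & (pos < codes.size)
        if not inside.all():
            raise ValueError(f"mutation position outside {chrom}")
        mismatch = codes[pos].astype(np.int64) != ref_codes
        if np.any(mismatch & (codes[pos] < 4)):
            bad = pos[mismatch & (codes[pos] < 4)][0]
            raise ValueError(f"ref mismatch with genome at {chrom}:{bad}")
        idx96, valid = gm.sbs96_indices(genome, chrom, pos, alt_codes)
        rows = grp.index.to_numpy()
        labels = gm.sbs96_labels_array(idx96)
        channel[rows] = labels
        sbs6[rows[valid]] = [sbs6_of_sbs96(l) for l in labels[valid]]
        pyr[rows] = np.where((codes[pos] == 1) | (codes[pos] == 3), "+", "-")
        keep[rows] &= valid

    # DBS / ID: scalar path (catalogs are SBS-dominated)
    for i, rec in df[~is_sbs].iterrows():
        mut = gm.Mutation(rec["sample"], rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"], rec["mut_type"])
        try:
            channel[i] = gm.classify(mut, genome)
            pyr[i] = gm.pyrimidine_strand(mut)
        except gm.UnclassifiableMutation:
            keep[i] = False

    df["channel"] = channel
    df["sbs6"] = sbs6
    df["pyr_strand"] = pyr
    out = df[keep].reset_index(drop=True)
    out.attrs["n_unclassifiable"] = int((~keep).sum())
    return out


def attach_signatures(
    df: pd.DataFrame, probabilities: SignatureProbabilityTable, cutoff: float = 0.5
) -> pd.DataFrame:
    """Add ``signature``/``probability`` columns by the argmax-with-cutoff
    rule; mutations missing from the table raise KeyError (every mutation
    passed downstream with an attribution must appear in the table)."""
    df = df.copy()
    sigs = []
    probs = []
    for rec in df.itertuples(index=False):
        row = probabilities.row(rec.sample, rec.chrom, int(rec.pos))
        name = gm.assign_signature(row, cutoff)
        sigs.append(name)
        probs.append(row[name] if name != UNASSIGNED else max(row.values()))
    df["signature"] = sigs
    df["probability"] = probs
    return df


def filter_signatures(df: pd.DataFrame, min_count: int = 1000) -> pd.DataFrame:
    """Keep only mutations of signatures with at least ``min_count``
    attributed mutations (and drop UNASSIGNED)."""
    counts = gm.signature_mutation_counts(df["signature"], min_count=min_count)
    return df[df["signature"].isin(counts)].reset_index(drop=True)
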