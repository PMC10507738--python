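"""Strand and genic/intergenic asymmetry tests.

For each (signature, six-class channel) the real mutation counts on two
strata (transcribed/untranscribed, lagging/leading, genic/intergenic)
are compared against the simulated counts via the odds ratio

    OR = (real_a / real_b) / (sim_a / sim_b)

with a two-sided Fisher exact p on the 2x2 table, Benjamini-Hochberg
correction across one analysis family, and the reporting rule
q <= 0.05 with OR strictly above 1.10 in either direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .channels import SBS6_CHANNELS

OR_MIN = 1.10
Q_MAX = 0.05


def strand_odds_ratio(real_a: int, real_b: int, sim_a: int, sim_b: int):
    """(odds ratio, two-sided Fisher exact p) for the 2x2 table
    [[real_a, real_b], [sim_a, sim_b]]. Zero denominators yield inf/0
    odds ratios; the exact test is still defined."""
    if (real_a + real_b == 0) or (sim_a + sim_b == 0):
        return float("nan"), float("nan")
    num = real_a * sim_b
    den = real_b * sim_a
    if den == 0:
        ratio = float("nan") if num == 0 else float("inf")
    else:
        ratio = num / den
    p = float(stats.fisher_exact([[real_a, real_b], [sim_a, sim_b]])[1])
    return ratio, p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, order-preserving."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def aggregate_sim_counts(per_replicate_counts, how: str = "mean") -> int:
    """Collapse per-replicate counts into the simulated cell of the 2x2
    table: per-replicate mean rounded to nearest integer (default) or the
    raw sum across replicates."""
    arr = np.asarray(per_replicate_counts, dtype=float)
    if how == "mean":
        return int(np.rint(arr.mean())) if arr.size else 0
    if how == "sum":
        return int(arr.sum())
    raise ValueError("how must be 'mean' or 'sum'")


def build_strand_count_table(
    real: pd.DataFrame,
    sims: list,
    stratum_col: str,
    stratum_a: str,
    stratum_b: str,
    sim_agg: str = "mean",
) -> pd.DataFrame:
    """Per (signature, six-class channel) counts on two strata for the
    real catalog and the simulated replicates (aggregated per
    ``aggregate_sim_counts``). Frames must carry ``signature`` and
    ``sbs6`` columns (SBS-level analysis)."""

    def _counts(df: pd.DataFrame) -> pd.Series:
        sub = df[df[stratum_col].isin([stratum_a, stratum_b])]
        return sub.groupby(["signature", "sbs6", stratum_col], observed=True).size()

    real_counts = _counts(real)
    sim_counts = [_counts(s) for s in sims]
    keys = sorted(
        {(sig, ch) for sig, ch, _ in real_counts.index}
        | {(sig, ch) for sc in sim_counts for sig, ch, _ in sc.index}
    )
    rows = []
    for sig, ch in keys:
        ra = int(real_counts.get((sig, ch, stratum_a), 0))
        rb = int(real_counts.get((sig, ch, stratum_b), 0))
        sa = aggregate_sim_counts([sc.get((sig, ch, stratum_a), 0) for sc in sim_counts], sim_agg)
        sb = aggregate_sim_counts([sc.get((sig, ch, stratum_b), 0) for sc in sim_counts], sim_agg)
        rows.append((sig, ch, stratum_a, stratum_b, ra, rb, sa, sb))
    return pd.DataFrame(
        rows,
        columns=[
            "signature",
            "channel",
            "stratum_a",
            "stratum_b",
            "real_a",
            "real_b",
            "sim_a",
            "sim_b",
        ],
    )


def detect_asymmetries(
    counts: pd.DataFrame, or_min: float = OR_MIN, q_max: float = Q_MAX
) -> pd.DataFrame:
    """Apply the OR/Fisher machinery to a strand count table and flag
    reported cells (BH across all rows of the table = one family)."""
    out = counts.copy()
    ors, ps, directions = [], [], []
    for rec in counts.itertuples(index=False):
        ratio, p = strand_odds_ratio(rec.real_a, rec.real_b, rec.sim_a, rec.sim_b)
        ors.append(ratio)
        ps.append(p)
        real_share = rec.real_a / (rec.real_a + rec.real_b) if rec.real_a + rec.real_b else np.nan
        sim_share = rec.sim_a / (rec.sim_a + rec.sim_b) if rec.sim_a + rec.sim_b else np.nan
        directions.append(rec.stratum_a if real_share >= sim_share else rec.stratum_b)
    out["odds_ratio"] = ors
    out["p"] = ps
    testable = ~np.isnan(out["p"].to_numpy())
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable] = bh_adjust(out.loc[testable, "p"].to_numpy())
    out["q"] = q
    out["direction"] = directions
    with np.errstate(divide="ignore"):
        effect = np.where(
            np.asarray(ors) >= 1.0, np.asarray(ors), 1.0 / np.asarray(ors)
        )
    out["reported"] = testable & (out["q"].to_numpy() <= q_max) & (effect > or_min)
    return out


def corrected_genic_counts(transcribed: int, untranscribed: int) -> int:
    """Strand-asymmetry-corrected genic count: both strands set to the
    larger of the two, i.e. 2 * max(transcribed, untranscribed)."""
    return 2 * max(transcribed, untranscribed)


def genic_intergenic_fold(
    real_genic: int,
    real_intergenic: int,
    sim_genic: int,
    sim_intergenic: int,
):
    """Genic vs intergenic enrichment via the same OR/Fisher machinery.

    Apply :func:`corrected_genic_counts` to the genic counts beforehand
    for the asymmetry-corrected variant.
    """
    return strand_odds_ratio(real_genic, real_intergenic, sim_genic, sim_intergenic)


def six_channel_table_template() -> pd.DataFrame:
    return pd.DataFrame({"channel": list(SBS6_CHANNELS)})
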