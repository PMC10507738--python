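"""Sample stratification and group comparisons.

APOBEC3 presence is scored per sample as

    ratio = ln(n mutations attributed to SBS2 or SBS13)
          / ln(n mutations attributed to anything else)

with HIGH at ratio >= 0.90, MID strictly between 0.75 and 0.90 (MID
samples are dropped from downstream group re-analyses), LOW at
ratio <= 0.75. Arbitrary annotation-driven groups (e.g. POLE-/POLE+,
heavy/light drinkers) are plain sample columns; group burdens are
compared by median fold change with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

APOBEC_SIGNATURES = ("SBS2", "SBS13")
HIGH_THRESHOLD = 0.90
LOW_THRESHOLD = 0.75

HIGH, MID, LOW = "HIGH", "MID", "LOW"


class UnclassifiableSample(ValueError):
    """Sample has too few mutations for a defined log ratio."""


def apobec_ratio(n_apobec: int, n_other: int) -> float:
    """ln(n_apobec) / ln(n_other); requires n_apobec >= 1 and
    n_other >= 2 so the denominator log is positive."""
    if n_apobec < 1 or n_other < 2:
        raise UnclassifiableSample(
            f"need n_apobec >= 1 and n_other >= 2, got ({n_apobec}, {n_other})"
        )
    return float(np.log(n_apobec) / np.log(n_other))


def classify_ratio(ratio: float) -> str:
    if ratio >= HIGH_THRESHOLD:
        return HIGH
    if ratio > LOW_THRESHOLD:
        return MID
    return LOW


@dataclass(frozen=True)
class ApobecClassification:
    sample_id: str
    ratio: float
    apobec_class: str


def classify_apobec(df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample APOBEC3 classification from an attributed catalog
    (columns ``sample`` and ``signature``). Samples with undefined
    ratios are flagged UNCLASSIFIABLE. MID samples are excluded from
    downstream group runs by :func:`split_by_class`."""
    rows = []
    for sample, grp in df.groupby("sample", sort=True):
        n_ap = int(grp["signature"].isin(APOBEC_SIGNATURES).sum())
        n_other = int(len(grp) - n_ap)
        try:
            ratio = apobec_ratio(n_ap, n_other)
            cls = classify_ratio(ratio)
        except UnclassifiableSample:
            ratio, cls = float("nan"), "UNCLASSIFIABLE"
        rows.append((sample, ratio, cls))
    return pd.DataFrame(rows, columns=["sample", "ratio", "apobec_class"])


def split_by_class(df: pd.DataFrame, classification: pd.DataFrame) -> dict:
    """Split an attributed catalog into LOW and HIGH APOBEC3 groups
    (MID and unclassifiable samples dropped)."""
    by = classification.set_index("sample")["apobec_class"]
    out = {}
    for cls in (LOW, HIGH):
        samples = by[by == cls].index
        out[cls] = df[df["sample"].isin(samples)].reset_index(drop=True)
    return out


def compare_group_burden(group_a, group_b) -> tuple[float, float]:
    """(median fold change a/b, two-sided Mann-Whitney U p) between two
    per-sample burden vectors."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    med_b = np.median(b)
    fold = float(np.median(a) / med_b) if med_b != 0 else float("nan")
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return fold, p


def group_burdens(df: pd.DataFrame, signature: str | None = None) -> pd.Series:
    """Per-sample mutation counts, optionally restricted to a signature."""
    sub = df if signature is None else df[df["signature"] == signature]
    return sub.groupby("sample").size()
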