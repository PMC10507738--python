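"""Strand-coordinated mutagenesis: run finding vs an O(n^2) oracle,
threshold strictness, partition invariants and the length z-test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mutotopo.scm import find_scm_groups, group_length_histogram
from mutotopo.scm import test_scm_lengths as scm_length_test


def attributed(rows):
    """rows: (sample, chrom, pos, sbs6, strand, signature, probability)"""
    return pd.DataFrame(
        [
            {
                "sample": s,
                "chrom": c,
                "pos": p,
                "ref": "C",
                "alt": "T",
                "mut_type": "SBS",
                "channel": f"A[{ch}]A",
                "sbs6": ch,
                "pyr_strand": strand,
                "signature": sig,
                "probability": prob,
            }
            for s, c, p, ch, strand, sig, prob in rows
        ]
    )


def oracle_groups(df, imd=10_000):
    """Independent O(n^2) run finder: check every candidate window of the
    sorted retained list for being a valid, maximal chain."""
    sub = df[(df["signature"] != "UNASSIGNED") & (df["probability"] >= 0.5)]
    sub = sub.sort_values(["sample", "chrom", "pos"]).reset_index(drop=True)
    keys = list(
        zip(sub["sample"], sub["chrom"], sub["sbs6"], sub["pyr_strand"], sub["signature"])
    )
    pos = sub["pos"].tolist()
    n = len(sub)

    def linked(i, j):
        return keys[i] == keys[j] and 0 < pos[j] - pos[i] < imd

    found = []
    for i in range(n):
        for j in range(i + 1, n):
            window = list(range(i, j + 1))
            ok = all(linked(a, b) for a, b in zip(window[:-1], window[1:]))
            if not ok:
                continue
            left_ext = i > 0 and linked(i - 1, i)
            right_ext = j < n - 1 and linked(j, j + 1)
            if not left_ext and not right_ext:
                found.append((keys[i], tuple(pos[i : j + 1])))
    return sorted(found)


class TestFindGroups:
    def test_simple_run(self):
        df = attributed(
            [("s", "chr1", p, "C>T", "+", "SBS1", 0.9) for p in (100, 5000, 9000)]
        )
        groups = find_scm_groups(df)
        assert len(groups) == 1 and groups[0].length == 3

    def test_imd_threshold_strict(self):
        """A 10,000 bp gap does not chain (threshold is strictly less)."""
        df = attributed(
            [("s", "chr1", 100, "C>T", "+", "SBS1", 0.9), ("s", "chr1", 10_100, "C>T", "+", "SBS1", 0.9)]
        )
        assert find_scm_groups(df) == []
        df2 = attributed(
            [("s", "chr1", 100, "C>T", "+", "SBS1", 0.9), ("s", "chr1", 10_099, "C>T", "+", "SBS1", 0.9)]
        )
        assert len(find_scm_groups(df2)) == 1

    def test_strand_change_breaks_run(self):
        df = attributed(
            [
                ("s", "chr1", 100, "C>T", "+", "SBS1", 0.9),
                ("s", "chr1", 5000, "C>T", "+", "SBS1", 0.9),
                ("s", "chr1", 6000, "C>T", "-", "SBS1", 0.9),
            ]
        )
        groups = find_scm_groups(df)
        assert len(groups) == 1 and groups[0].length == 2

    def test_probability_filter_and_gap_measurement(self):
        """A removed low-probability mutation does not merge two runs
        whose retained flanking gap reaches the threshold, but distances
        are measured between retained mutations only."""
        df = attributed(
            [
                ("s", "chr1", 100, "C>T", "+", "SBS1", 0.9),
                ("s", "chr1", 5_000, "C>T", "+", "SBS1", 0.4),  # filtered out
                ("s", "chr1", 9_900, "C>T", "+", "SBS1", 0.9),
            ]
        )
        groups = find_scm_groups(df)
        assert len(groups) == 1 and groups[0].length == 2

    def test_sample_boundary(self):
        df = attributed(
            [("a", "chr1", 100, "C>T", "+", "SBS1", 0.9), ("b", "chr1", 200, "C>T", "+", "SBS1", 0.9)]
        )
        assert find_scm_groups(df) == []

    def test_oracle_equivalence_random_catalogs(self):
        rng = np.random.default_rng(12)
        for trial in range(8):
            n = int(rng.integers(50, 400))
            rows = []
            for _ in range(n):
                rows.append(
                    (
                        rng.choice(["a", "b"]),
                        rng.choice(["chr1", "chr2"]),
                        int(rng.integers(0, 300_000)),
                        rng.choice(["C>T", "T>G"]),
                        rng.choice(["+", "-"]),
                        rng.choice(["SBS1", "SBS5"]),
                        float(rng.choice([0.9, 0.4])),
                    )
                )
            df = attributed(rows).drop_duplicates(subset=["sample", "chrom", "pos"])
            got = sorted(
                (
                    (g.sample_id, g.chrom, g.channel, g.strand, g.signature),
                    tuple(
                        df[
                            (df["sample"] == g.sample_id)
                            & (df["chrom"] == g.chrom)
                            & (df["pos"] >= g.start)
                            & (df["pos"] < g.end)
                            & (df["sbs6"] == g.channel)
                            & (df["pyr_strand"] == g.strand)
                            & (df["probability"] >= 0.5)
                        ]["pos"]
                        .sort_values()
                        .tolist()
                    ),
                )
                for g in find_scm_groups(df)
            )
            want = sorted(
                ((k[0], k[1], k[2], k[3], k[4]), p) for k, p in oracle_groups(df)
            )
            assert [g[1] for g in got] == [w[1] for w in want]

    def test_partition_invariant(self):
        """Group lengths plus discarded singletons account for every
        retained mutation in each partition cell."""
        rng = np.random.default_rng(3)
        rows = [
            ("s", "chr1", int(p), "C>T", "+", "SBS1", 0.9)
            for p in sorted(rng.choice(200_000, 150, replace=False))
        ]
        df = attributed(rows)
        groups = find_scm_groups(df)
        in_groups = sum(g.length for g in groups)
        # reconstruct singleton count from the chain structure
        pos = df["pos"].sort_values().to_numpy()
        links = np.diff(pos) < 10_000
        runs = np.split(pos, np.flatnonzero(~links) + 1)
        singles = sum(1 for r in runs if len(r) == 1)
        assert in_groups + singles == len(df)

    def test_maximality(self):
        rng = np.random.default_rng(9)
        rows = [
            ("s", "chr1", int(p), "C>T", "+", "SBS1", 0.9)
            for p in sorted(rng.choice(150_000, 120, replace=False))
        ]
        df = attributed(rows)
        pos_set = df["pos"].to_numpy()
        for g in find_scm_groups(df):
            before = pos_set[(pos_set < g.start)]
            after = pos_set[(pos_set >= g.end)]
            if before.size:
                assert g.start - before.max() >= 10_000
            if after.size:
                assert after.min() - (g.end - 1) >= 10_000


class TestLengthTest:
    def _hist(self, counts):
        return pd.Series(counts)

    def test_observed_equals_mean(self):
        real = self._hist({("S1", 2): 5})
        sims = [self._hist({("S1", 2): 4}), self._hist({("S1", 2): 6})]
        res = scm_length_test(real, sims)
        row = res.iloc[0]
        assert row.z == 0 and row.p == 1.0

    def test_closed_form_z(self):
        rng = np.random.default_rng(0)
        sims = [self._hist({("S1", 2): int(v)}) for v in rng.normal(2, 1, 100).round()]
        real = self._hist({("S1", 2): 10})
        res = scm_length_test(real, sims)
        row = res.iloc[0]
        vals = np.array([float(s.iloc[0]) for s in sims])
        want_z = (10 - vals.mean()) / vals.std(ddof=1)
        assert row.z == pytest.approx(want_z)
        assert row.p == pytest.approx(2 * norm.sf(abs(want_z)))

    def test_degenerate_sd(self):
        sims = [self._hist({("S1", 6): 0}) for _ in range(5)]
        real = self._hist({("S1", 6): 5})
        res = scm_length_test(real, sims)
        row = res.iloc[0]
        assert row.degenerate and row.p == 0.0 and row.reported

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            scm_length_test(self._hist({("S1", 2): 1}), [self._hist({})])


def test_histogram_lengths_at_least_two():
    from mutotopo.scm import SCMGroup

    groups = [
        SCMGroup("s", "SBS1", "C>T", "+", "chr1", 0, 10, 2),
        SCMGroup("s", "SBS1", "C>T", "+", "chr1", 20, 40, 3),
    ]
    hist = group_length_histogram(groups)
    assert hist.min() >= 1 and set(l for _, l in hist.index) == {2, 3}
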