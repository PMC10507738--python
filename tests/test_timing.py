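"""Decile construction, density normalization, replicate ensembles and
trend classification."""

import numpy as np
import pandas as pd
import pytest

from mutotopo.genome import GenomeSequence
from mutotopo.io import SignalTrack
from mutotopo.timing import (
    DecileDensityVector,
    aggregate_densities,
    classify_trend,
    decile_density,
    ensemble_stats,
    split_deciles,
)


def equal_track(n_segments=1000, width=100, value=1.0):
    starts = np.arange(0, n_segments * width, width, dtype=np.int64)
    return SignalTrack({"chr1": (starts, starts + width, np.full(n_segments, value))})


class TestSplitDeciles:
    def test_equal_segments_exact_tenths(self):
        deciles = split_deciles(equal_track())
        assert np.allclose(deciles.signal_share, 0.1)
        assert all(len(f) == 100 for f in deciles.frames)

    def test_descending_values_one_per_decile(self):
        starts = np.arange(0, 100, 10, dtype=np.int64)
        values = np.arange(10, 0, -1, dtype=float)  # 10, 9, ..., 1
        track = SignalTrack({"chr1": (starts, starts + 10, values)})
        deciles = split_deciles(track)
        for k, frame in enumerate(deciles.frames):
            assert len(frame) == 1
            assert frame.loc[0, "value"] == 10 - k  # decile k holds value 11-(k+1)

    def test_signal_conserved(self):
        rng = np.random.default_rng(1)
        starts = np.arange(0, 5_000, 100, dtype=np.int64)
        track = SignalTrack({"chr1": (starts, starts + 100, rng.random(50) * 10)})
        deciles = split_deciles(track)
        assert deciles.signal_share.sum() == pytest.approx(1.0)
        assert all(len(f) > 0 for f in deciles.frames)

    def test_earliest_decile_has_highest_values(self):
        rng = np.random.default_rng(2)
        starts = np.arange(0, 10_000, 100, dtype=np.int64)
        track = SignalTrack({"chr1": (starts, starts + 100, rng.random(100) * 10)})
        deciles = split_deciles(track)
        assert deciles.frames[0]["value"].min() >= deciles.frames[-1]["value"].max()

    def test_too_few_segments_error(self):
        with pytest.raises(ValueError, match="10"):
            split_deciles(equal_track(n_segments=9))


@pytest.fixture(scope="module")
def flat_genome():
    return GenomeSequence({"chr1": "ACGT" * 25_000})  # 100 kb, no N


class TestDecileDensity:

    def test_uniform_density_all_ones(self, flat_genome):
        deciles = split_deciles(equal_track())
        rng = np.random.default_rng(0)
        # two mutations in every decile by construction
        rows = []
        for frame in deciles.frames:
            for rec in frame.head(2).itertuples(index=False):
                rows.append(("s", "chr1", int(rec.start) + 1, "", "", "SBS"))
        df = pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt", "mut_type"])
        v = decile_density(df, deciles, flat_genome)
        assert np.allclose(v.x, 1.0)

    def test_single_loaded_decile(self, flat_genome):
        deciles = split_deciles(equal_track())
        target = deciles.frames[9].iloc[0]
        df = pd.DataFrame(
            [("s", "chr1", int(target.start) + 3, "", "", "SBS")] * 50,
            columns=["sample", "chrom", "pos", "ref", "alt", "mut_type"],
        )
        v = decile_density(df, deciles, flat_genome)
        assert v.x[9] == 1.0 and np.all(v.x[:9] == 0.0)

    def test_outside_coverage_counted(self, flat_genome):
        deciles = split_deciles(equal_track(n_segments=100, width=100))  # covers 10 kb
        df = pd.DataFrame(
            [("s", "chr1", 50_000, "", "", "SBS"), ("s", "chr1", 55, "", "", "SBS")],
            columns=["sample", "chrom", "pos", "ref", "alt", "mut_type"],
        )
        v = decile_density(df, deciles, flat_genome)
        assert v.n_excluded == 1 and v.raw_counts.sum() == 1

    def test_order_invariant(self, flat_genome):
        deciles = split_deciles(equal_track())
        rng = np.random.default_rng(5)
        pos = rng.integers(0, 100_000, 500)
        df = pd.DataFrame(
            [("s", "chr1", int(p), "", "", "SBS") for p in pos],
            columns=["sample", "chrom", "pos", "ref", "alt", "mut_type"],
        )
        a = decile_density(df, deciles, flat_genome)
        b = decile_density(df.iloc[::-1].reset_index(drop=True), deciles, flat_genome)
        assert np.array_equal(a.raw_counts, b.raw_counts)

    def test_zero_attributable_decile_error(self):
        genome = GenomeSequence({"chr1": "N" * 50_000 + "ACGT" * 12_500})
        deciles = split_deciles(equal_track())
        df = pd.DataFrame(
            [("s", "chr1", 60_000, "", "", "SBS")],
            columns=["sample", "chrom", "pos", "ref", "alt", "mut_type"],
        )
        with pytest.raises(ValueError, match="attributable"):
            decile_density(df, deciles, genome)


class TestEnsemble:
    def test_identical_replicates_zero_sd(self):
        v = np.linspace(0.1, 1.0, 10)
        ens = ensemble_stats([v, v, v])
        assert np.allclose(ens.sd, 0) and np.allclose(ens.ci_low, ens.ci_high)

    def test_two_replicate_closed_form(self):
        a = np.zeros(10)
        b = np.zeros(10)
        a[0], b[0] = 0.0, 2.0
        ens = ensemble_stats([a, b])
        assert ens.mean[0] == 1.0
        assert ens.sd[0] == pytest.approx(np.sqrt(2))

    def test_ci_coverage_gaussian(self):
        """~95% of per-decile means of fresh replicate draws fall inside
        the normal-approximation CI computed from the ensemble."""
        rng = np.random.default_rng(11)
        hits = 0
        trials = 400
        for _ in range(trials):
            mat = rng.normal(0.5, 0.1, size=(30, 10))
            ens = ensemble_stats(list(mat))
            # the CI targets the ensemble mean of the generating process
            hits += int(ens.ci_low[0] <= 0.5 <= ens.ci_high[0])
        assert 0.90 <= hits / trials <= 0.99


class TestTrend:
    def test_perfect_line_increasing(self):
        v = np.linspace(0.1, 1.0, 10)
        assert classify_trend(v).trend == "INCREASING"
        assert classify_trend(v[::-1]).trend == "DECREASING"

    def test_constant_flat(self):
        t = classify_trend(np.ones(10))
        assert t.trend == "FLAT" and t.p == 1.0

    def test_significant_slope_but_nonmonotone_is_flat(self):
        v = np.array([0.05, 0.3, 0.1, 0.45, 0.3, 0.6, 0.5, 0.8, 0.7, 1.0])
        t = classify_trend(v)
        assert t.p <= 0.05  # the slope alone is clearly significant
        assert t.trend == "FLAT"  # ...but monotonicity fails

    def test_plateau_still_increasing(self):
        v = np.array([0.1, 0.1, 0.2, 0.3, 0.3, 0.5, 0.6, 0.8, 0.9, 1.0])
        assert classify_trend(v).trend == "INCREASING"


def test_aggregate_densities_mean():
    a = DecileDensityVector(np.full(10, 0.2), np.zeros(10, int), np.ones(10, int))
    b = DecileDensityVector(np.full(10, 0.8), np.zeros(10, int), np.ones(10, int))
    assert np.allclose(aggregate_densities([a, b]), 0.5)
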