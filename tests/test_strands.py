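"""Transcription and replication strand annotation, including the
sawtooth replication map derivation and strand-flip symmetry."""

import numpy as np
import pandas as pd
import pytest

from mutotopo.catalog import classify_catalog
from mutotopo.genome import GenomeSequence, Mutation
from mutotopo.io import IntervalSet, SignalTrack
from mutotopo.strands import (
    EXCLUDED_BIDIRECTIONAL,
    GeneIndex,
    LAGGING,
    LAGGING_PLUS,
    LEADING,
    LEADING_PLUS,
    NONTRANSCRIBED,
    TRANSCRIBED,
    UNASSIGNED_STRAND,
    UNTRANSCRIBED,
    RepliSeqProfile,
    annotate_catalog_strands,
    annotate_replication,
    annotate_transcription,
    derive_replication_strand_map,
)


def _genes(rows):
    return GeneIndex(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "score", "strand"])
    )


@pytest.fixture(scope="module")
def ct_genome():
    # position 150 carries a C; 350 carries a G
    seq = list("A" * 500)
    seq[150] = "C"
    seq[350] = "G"
    return GenomeSequence({"chr1": "".join(seq)})


class TestTranscription:
    def test_four_strand_combinations(self, ct_genome):
        """Enumerate pyrimidine strand x gene strand under the convention
        that the pyrimidine on the template strand means TRANSCRIBED."""
        plus_gene = _genes([("chr1", 100, 200, "g", 0, "+"), ("chr1", 300, 400, "h", 0, "+")])
        minus_gene = _genes([("chr1", 100, 200, "g", 0, "-"), ("chr1", 300, 400, "h", 0, "-")])
        c_mut = Mutation("s", "chr1", 150, "C", "T")  # pyrimidine on +
        g_mut = Mutation("s", "chr1", 350, "G", "A")  # pyrimidine on -
        assert annotate_transcription(c_mut, plus_gene, ct_genome) == UNTRANSCRIBED
        assert annotate_transcription(c_mut, minus_gene, ct_genome) == TRANSCRIBED
        assert annotate_transcription(g_mut, plus_gene, ct_genome) == TRANSCRIBED
        assert annotate_transcription(g_mut, minus_gene, ct_genome) == UNTRANSCRIBED

    def test_outside_genes_nontranscribed(self, ct_genome):
        genes = _genes([("chr1", 300, 400, "g", 0, "+")])
        mut = Mutation("s", "chr1", 150, "C", "T")
        assert annotate_transcription(mut, genes, ct_genome) == NONTRANSCRIBED

    def test_bidirectional_excluded(self, ct_genome):
        genes = _genes([("chr1", 100, 200, "g", 0, "+"), ("chr1", 120, 180, "h", 0, "-")])
        mut = Mutation("s", "chr1", 150, "C", "T")
        assert annotate_transcription(mut, genes, ct_genome) == EXCLUDED_BIDIRECTIONAL

    def test_labels_partition(self, random_genome):
        rng = np.random.default_rng(0)
        genes = _genes(
            [("chr1", 0, 20_000, "a", 0, "+"), ("chr1", 30_000, 40_000, "b", 0, "-"),
             ("chr1", 32_000, 38_000, "c", 0, "+")]
        )
        seq = random_genome.sequence("chr1")
        rows = []
        for p in rng.integers(1, 59_999, 400):
            ref = seq[p]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append(("s", "chr1", int(p), ref, alt, "SBS"))
        df = classify_catalog(
            pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt", "mut_type"]),
            random_genome,
        )
        ann = annotate_catalog_strands(df, genes)
        counts = ann["tx_label"].value_counts()
        assert counts.sum() == len(ann)
        assert set(counts.index) <= {
            TRANSCRIBED, UNTRANSCRIBED, NONTRANSCRIBED, EXCLUDED_BIDIRECTIONAL
        }


def sawtooth_profile(n=200_000, period=200_000, amp=100.0):
    """One peak at 0, valley at period/2, peak at period."""
    starts = np.arange(0, n, 1000, dtype=np.int64)
    mid = starts + 500
    phase = (mid % period) / period
    tri = 1.0 - 2.0 * np.abs(phase - np.where(phase < 0.5, 0.0, 1.0))
    track = SignalTrack({"chr1": (starts, starts + 1000, amp * tri)})
    peaks = IntervalSet.from_frame(
        pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, n - 2], "end": [2, n]})
    )
    valleys = IntervalSet.from_frame(
        pd.DataFrame({"chrom": ["chr1"], "start": [n // 2 - 1], "end": [n // 2 + 1]})
    )
    return RepliSeqProfile(signal=track, peaks=peaks, valleys=valleys)


class TestReplicationMap:
    def test_sawtooth_segments_and_trim(self):
        """Peak at 0, valley at 100 kb, peak at 200 kb: lagging on
        [0, 75 kb), leading on [125 kb, 200 kb) after the 25 kb trim,
        matching a per-base slope oracle."""
        profile = sawtooth_profile()
        repmap = derive_replication_strand_map(profile)
        starts, ends, labels = (
            repmap.starts["chr1"],
            repmap.ends["chr1"],
            repmap.labels["chr1"],
        )
        assert starts.tolist() == [1, 125_000]
        assert ends.tolist() == [75_000, 199_999]
        assert labels.tolist() == [1, 0]  # lagging+, leading+
        # per-base slope oracle on the untrimmed halves
        dense = profile.signal.dense("chr1", length=200_000)
        diffs = np.diff(dense[500::1000].astype(float))
        assert np.all(diffs[:99] <= 0) and np.all(diffs[100:] >= 0)

    def test_short_stretch_dropped(self):
        profile = sawtooth_profile(n=18_000, period=18_000)
        # 9 kb monotone halves: below the 10 kb minimum -> nothing labeled
        repmap = derive_replication_strand_map(profile)
        assert repmap.starts.get("chr1", np.array([])).size == 0

    def test_flat_signal_no_labels(self):
        # flat signal prints no valleys: the chromosome stays unannotated
        starts = np.arange(0, 100_000, 1000, dtype=np.int64)
        track = SignalTrack({"chr1": (starts, starts + 1000, np.ones(starts.size))})
        peaks = IntervalSet.from_frame(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2]}))
        valleys = IntervalSet()
        profile = RepliSeqProfile(signal=track, peaks=peaks, valleys=valleys)
        with pytest.warns(UserWarning, match="unannotated"):
            repmap = derive_replication_strand_map(profile)
        assert "chr1" not in repmap.starts

    def test_symmetric_base_totals(self):
        profile = sawtooth_profile(n=400_000, period=200_000)
        repmap = derive_replication_strand_map(profile)
        assert repmap.total_bases(LEADING_PLUS) == repmap.total_bases(LAGGING_PLUS)


@pytest.fixture(scope="module")
def repmap():
    return derive_replication_strand_map(sawtooth_profile())


class TestAnnotateReplication:

    def test_strand_cases(self, repmap):
        lead_region_pos = 150_000  # leading+ region
        lag_region_pos = 30_000  # lagging+ region
        c = lambda p: Mutation("s", "chr1", p, "C", "T")  # pyr on +
        g = lambda p: Mutation("s", "chr1", p, "G", "A")  # pyr on -
        assert annotate_replication(c(lead_region_pos), repmap) == LEADING
        assert annotate_replication(g(lead_region_pos), repmap) == LAGGING
        assert annotate_replication(c(lag_region_pos), repmap) == LAGGING
        assert annotate_replication(g(lag_region_pos), repmap) == LEADING

    def test_trimmed_zone_unassigned(self, repmap):
        mut = Mutation("s", "chr1", 90_000, "C", "T")  # inside the 25 kb trim
        assert annotate_replication(mut, repmap) == UNASSIGNED_STRAND


def test_strand_flip_symmetry(random_genome):
    """Reverse complementing all reported alleles swaps
    TRANSCRIBED<->UNTRANSCRIBED and LEADING<->LAGGING exactly and leaves
    NONTRANSCRIBED/UNASSIGNED fixed."""
    rng = np.random.default_rng(3)
    seq = random_genome.sequence("chr1")
    rows = []
    for p in rng.integers(1, 59_999, 500):
        ref = seq[p]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        rows.append(("s", "chr1", int(p), ref, alt, "SBS"))
    df = pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt", "mut_type"])
    genes = _genes([("chr1", 5_000, 25_000, "a", 0, "+"), ("chr1", 35_000, 55_000, "b", 0, "-")])
    profile = sawtooth_profile(n=60_000, period=60_000)
    repmap = derive_replication_strand_map(profile, min_len=10_000, term_trim=5_000)

    fwd = annotate_catalog_strands(classify_catalog(df, random_genome), genes, repmap)
    # reverse complementing the reported alleles flips the strand that
    # carries the pyrimidine while the locus (and channel) stay fixed
    flipped = fwd.copy()
    flipped["pyr_strand"] = np.where(fwd["pyr_strand"] == "+", "-", "+")
    rev = annotate_catalog_strands(flipped, genes, repmap)
    swap_tx = {
        TRANSCRIBED: UNTRANSCRIBED,
        UNTRANSCRIBED: TRANSCRIBED,
        NONTRANSCRIBED: NONTRANSCRIBED,
        EXCLUDED_BIDIRECTIONAL: EXCLUDED_BIDIRECTIONAL,
    }
    swap_rep = {LEADING: LAGGING, LAGGING: LEADING, UNASSIGNED_STRAND: UNASSIGNED_STRAND}
    assert [swap_tx[t] for t in fwd["tx_label"]] == rev["tx_label"].tolist()
    assert [swap_rep[t] for t in fwd["rep_label"]] == rev["rep_label"].tolist()
    # the physical channel is unchanged by re-reporting the strand
    assert fwd["channel"].tolist() == rev["channel"].tolist()
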