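"""Mutation classification against the genome, signature assignment and
the minimum-attribution filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutotopo.channels import ID83_CHANNELS, SBS96_CHANNELS
from mutotopo.genome import (
    GenomeSequence,
    Mutation,
    UNASSIGNED,
    UnclassifiableMutation,
    assign_signature,
    classify_dbs,
    classify_id,
    classify_sbs,
    pyrimidine_strand,
    reverse_complement_mutation,
    sbs96_indices,
    signature_mutation_counts,
)


class TestClassifySBS:
    def test_pyrimidine_on_plus(self):
        g = GenomeSequence({"chr1": "TACAG"})
        assert classify_sbs(Mutation("s", "chr1", 2, "C", "T"), g) == "A[C>T]A"

    def test_purine_reverse_complemented(self):
        # genome ...TGC..., G>A at the G
        g = GenomeSequence({"chr1": "ATGCA"})
        assert classify_sbs(Mutation("s", "chr1", 2, "G", "A"), g) == "G[C>T]A"

    def test_ref_mismatch_is_input_error(self):
        g = GenomeSequence({"chr1": "TACAG"})
        with pytest.raises(ValueError, match="mismatch"):
            classify_sbs(Mutation("s", "chr1", 2, "T", "A"), g)

    def test_n_context_unclassifiable(self):
        g = GenomeSequence({"chr1": "TNCAG"})
        with pytest.raises(UnclassifiableMutation):
            classify_sbs(Mutation("s", "chr1", 2, "C", "T"), g)

    def test_edge_flank_unclassifiable(self):
        g = GenomeSequence({"chr1": "CAG"})
        with pytest.raises(UnclassifiableMutation):
            classify_sbs(Mutation("s", "chr1", 0, "C", "T"), g)

    def test_strand_flip_idempotent_on_random_genome(self, random_genome):
        """classify(m) == classify(revcomp(m)) for sampled SBSs."""
        rng = np.random.default_rng(1)
        seq = random_genome.sequence("chr1")
        for pos in rng.integers(1, random_genome.length("chr1") - 1, 200):
            ref = seq[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            m = Mutation("s", "chr1", int(pos), ref, alt)
            flipped = reverse_complement_mutation(m)
            # the flipped record reports the - strand alleles at the same
            # locus; classification must agree after genome-side collapse
            label = classify_sbs(m, random_genome)
            assert label in SBS96_CHANNELS
            assert pyrimidine_strand(m) != pyrimidine_strand(flipped)


def test_sbs96_indices_matches_scalar(random_genome):
    rng = np.random.default_rng(2)
    seq = random_genome.sequence("chr1")
    pos = rng.integers(1, random_genome.length("chr1") - 1, 500)
    refs = [seq[p] for p in pos]
    alts = [rng.choice([b for b in "ACGT" if b != r]) for r in refs]
    from mutotopo.genome import encode_sequence

    idx, valid = sbs96_indices(
        random_genome, "chr1", pos, encode_sequence("".join(alts)).astype(np.int64)
    )
    assert valid.all()
    for p, r, a, i in zip(pos, refs, alts, idx):
        assert SBS96_CHANNELS[i] == classify_sbs(Mutation("s", "chr1", int(p), r, a), random_genome)


class TestClassifyDBS:
    def test_canonical_passthrough(self):
        assert classify_dbs(Mutation("s", "chr1", 0, "CC", "TT")) == "CC>TT"

    def test_reverse_complement_collapse(self):
        assert classify_dbs(Mutation("s", "chr1", 0, "GG", "AA")) == "CC>TT"

    def test_n_unclassifiable(self):
        with pytest.raises(UnclassifiableMutation):
            classify_dbs(Mutation("s", "chr1", 0, "CN", "TT", "DBS"))


class TestClassifyID:
    def test_deletion_in_homopolymer(self):
        g = GenomeSequence({"chr1": "AATTTTG"})
        # run of 4 T: repeat-length-4 homopolymer class
        assert classify_id(Mutation("s", "chr1", 3, "T", ""), g) == "1:Del:T:3"

    def test_insertion_next_to_single_base(self):
        g = GenomeSequence({"chr1": "AACGA"})
        assert classify_id(Mutation("s", "chr1", 3, "", "C"), g) == "1:Ins:C:1"

    def test_purine_events_collapse_to_pyrimidine(self):
        g = GenomeSequence({"chr1": "CCAAAAG"})
        assert classify_id(Mutation("s", "chr1", 3, "A", ""), g) == "1:Del:T:3"

    def test_long_deletion_repeat_units(self):
        g = GenomeSequence({"chr1": "GGACACACTT"})
        # delete one AC out of three tandem copies
        assert classify_id(Mutation("s", "chr1", 2, "AC", ""), g) == "2:Del:R:2"

    def test_deletion_microhomology(self):
        # deleted CTAG followed by CTA: 3 bp microhomology
        g = GenomeSequence({"chr1": "GGCTAGCTATT"})
        assert classify_id(Mutation("s", "chr1", 2, "CTAG", ""), g) == "4:Del:M:3"

    def test_insertion_repeat_units(self):
        g = GenomeSequence({"chr1": "GGACACTT"})
        assert classify_id(Mutation("s", "chr1", 2, "", "AC"), g) == "2:Ins:R:2"

    def test_context_overrun_unclassifiable(self):
        g = GenomeSequence({"chr1": "ACGT"})
        with pytest.raises(UnclassifiableMutation):
            classify_id(Mutation("s", "chr1", 3, "TT", ""), g)

    def test_random_indels_land_in_scheme(self, random_genome):
        rng = np.random.default_rng(3)
        seq = random_genome.sequence("chr1")
        for _ in range(300):
            p = int(rng.integers(10, random_genome.length("chr1") - 20))
            size = int(rng.integers(1, 6))
            if rng.random() < 0.5:
                mut = Mutation("s", "chr1", p, seq[p : p + size], "")
            else:
                ins = "".join(rng.choice(list("ACGT"), size))
                mut = Mutation("s", "chr1", p, "", ins)
            assert classify_id(mut, random_genome) in ID83_CHANNELS


class TestAssignSignature:
    def test_argmax_above_cutoff(self):
        assert assign_signature({"SBS1": 0.9, "SBS5": 0.1}) == "SBS1"
        assert assign_signature({"SBS1": 0.45, "SBS5": 0.55}) == "SBS5"

    def test_below_cutoff_unassigned(self):
        assert assign_signature({"SBS1": 0.4, "SBS5": 0.3, "SBS2": 0.3}) == UNASSIGNED

    def test_tie_broken_lexicographically(self):
        assert assign_signature({"SBS5": 0.5, "SBS1": 0.5}) == "SBS1"

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            assign_signature({})

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6))
    def test_result_is_argmax_or_unassigned(self, weights):
        probs = {f"S{i}": w / sum(weights) for i, w in enumerate(weights)}
        got = assign_signature(probs, cutoff=0.5)
        best = max(probs.values())
        if got == UNASSIGNED:
            assert best < 0.5
        else:
            assert probs[got] == best and best >= 0.5


def test_signature_mutation_counts_boundary():
    sigs = ["SBS1"] * 1000 + ["SBS5"] * 999 + [UNASSIGNED] * 10
    kept = signature_mutation_counts(sigs, min_count=1000)
    assert kept == {"SBS1": 1000}
    assert signature_mutation_counts([], 1000) == {}
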