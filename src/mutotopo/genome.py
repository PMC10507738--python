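"""Core domain types: genome, mutations, and per-mutation classification.

Coordinates are 0-based half-open throughout; readers convert from 1-based
formats at the boundary. Insertions/deletions are stored anchor-free: a
deletion carries the deleted sequence in ``ref`` with an empty ``alt``, an
insertion the inserted sequence in ``alt`` with an empty ``ref``; ``pos``
is the first deleted base, respectively the base the insertion precedes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import (
    PYRIMIDINES,
    SBS96_CHANNELS,
    complement,
    dbs78_is_flipped,
    dbs78_label,
    revcomp,
    sbs96_label,
)

# base encoding used for all vectorized paths
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

UNASSIGNED = "UNASSIGNED"


class UnclassifiableMutation(Exception):
    """Raised when required sequence context contains N or overruns a
    chromosome end; such mutations are excluded downstream and counted."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an uppercase DNA string as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


class GenomeSequence:
    """In-memory reference genome over {A,C,G,T,N}.

    Stores each chromosome as a uint8 code array; exposes string slices,
    per-base lookups and attributable (non-N) base counting.
    """

    def __init__(self, sequences: dict[str, str]):
        self.chrom_names: list[str] = list(sequences)
        self._codes: dict[str, np.ndarray] = {}
        for chrom, seq in sequences.items():
            if len(seq) < 1:
                raise ValueError(f"chromosome {chrom!r} is empty")
            self._codes[chrom] = encode_sequence(seq.upper())
        self._nonn_cumsum: dict[str, np.ndarray] = {}

    @classmethod
    def from_codes(cls, codes: dict[str, np.ndarray]) -> "GenomeSequence":
        obj = cls.__new__(cls)
        obj.chrom_names = list(codes)
        obj._codes = {c: np.asarray(a, dtype=np.uint8) for c, a in codes.items()}
        for chrom, arr in obj._codes.items():
            if arr.size < 1:
                raise ValueError(f"chromosome {chrom!r} is empty")
        obj._nonn_cumsum = {}
        return obj

    def codes(self, chrom: str) -> np.ndarray:
        return self._codes[chrom]

    def length(self, chrom: str) -> int:
        return int(self._codes[chrom].size)

    def sequence(self, chrom: str) -> str:
        return decode_sequence(self._codes[chrom])

    def slice(self, chrom: str, start: int, end: int) -> str:
        if start < 0 or end > self.length(chrom) or start > end:
            raise IndexError(f"[{start}, {end}) outside {chrom}")
        return decode_sequence(self._codes[chrom][start:end])

    def base(self, chrom: str, pos: int) -> str:
        if pos < 0 or pos >= self.length(chrom):
            raise IndexError(f"position {pos} outside {chrom}")
        return decode_sequence(self._codes[chrom][pos : pos + 1])

    def attributable_bases(self, chrom: str, start: int, end: int) -> int:
        """Count of A/C/G/T bases (never N) in [start, end)."""
        if chrom not in self._nonn_cumsum:
            nonn = (self._codes[chrom] != 4).astype(np.int64)
            self._nonn_cumsum[chrom] = np.concatenate([[0], np.cumsum(nonn)])
        cs = self._nonn_cumsum[chrom]
        start = max(0, start)
        end = min(self.length(chrom), end)
        if end <= start:
            return 0
        return int(cs[end] - cs[start])


@dataclass(frozen=True)
class Mutation:
    """One somatic event. ``pos`` is the 0-based reference position of the
    first changed base (first deleted base / insertion point for IDs)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mut_type: str = field(default="")

    def __post_init__(self):
        mut_type = self.mut_type or infer_mut_type(self.ref, self.alt)
        object.__setattr__(self, "mut_type", mut_type)


def infer_mut_type(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1 and ref != alt:
        return "SBS"
    if len(ref) == 2 and len(alt) == 2 and ref[0] != alt[0] and ref[1] != alt[1]:
        return "DBS"
    if len(ref) != len(alt) and (len(ref) == 0 or len(alt) == 0):
        return "ID"
    raise ValueError(f"unsupported allele pair {ref!r}>{alt!r}")


# ---------------------------------------------------------------------------
# classification

def classify_sbs(mut: Mutation, genome: GenomeSequence) -> str:
    """SBS-96 channel of a single base substitution.

    The mutated base and both flanks are read from the genome; purine
    references are reverse complemented to the pyrimidine frame.
    """
    if mut.mut_type != "SBS":
        raise ValueError("classify_sbs requires an SBS mutation")
    if mut.pos - 1 < 0 or mut.pos + 2 > genome.length(mut.chrom):
        raise UnclassifiableMutation(f"flank outside chromosome at {mut.chrom}:{mut.pos}")
    tri = genome.slice(mut.chrom, mut.pos - 1, mut.pos + 2)
    if "N" in tri or "N" in mut.alt:
        raise UnclassifiableMutation(f"N in context at {mut.chrom}:{mut.pos}")
    if tri[1] != mut.ref:
        raise ValueError(
            f"ref mismatch at {mut.chrom}:{mut.pos}: genome {tri[1]} vs {mut.ref}"
        )
    return sbs96_label(tri[0], tri[1], mut.alt, tri[2])


def classify_dbs(mut: Mutation) -> str:
    """DBS-78 channel (maximum pyrimidine collapse)."""
    if mut.mut_type != "DBS":
        raise ValueError("classify_dbs requires a DBS mutation")
    if "N" in mut.ref or "N" in mut.alt:
        raise UnclassifiableMutation("N in doublet alleles")
    return dbs78_label(mut.ref, mut.alt)


def _homopolymer_run(codes: np.ndarray, pos: int, base_code: int) -> int:
    """Length of the run of ``base_code`` containing/adjacent to ``pos``
    scanning left from pos-1 and right from pos inclusive."""
    n = codes.size
    right = pos
    while right < n and codes[right] == base_code:
        right += 1
    left = pos - 1
    while left >= 0 and codes[left] == base_code:
        left -= 1
    return right - (left + 1)


def _count_copies(codes: np.ndarray, seq: np.ndarray, start: int, direction: int) -> int:
    """Number of adjacent full copies of ``seq`` in ``codes`` going right
    from ``start`` (direction=+1) or left ending at ``start`` (direction=-1)."""
    L = seq.size
    n = codes.size
    count = 0
    if direction > 0:
        p = start
        while p + L <= n and np.array_equal(codes[p : p + L], seq):
            count += 1
            p += L
    else:
        p = start
        while p - L >= 0 and np.array_equal(codes[p - L : p], seq):
            count += 1
            p -= L
    return count


def classify_id(mut: Mutation, genome: GenomeSequence) -> str:
    """ID-83 channel combining event size, base/length class, surrounding
    repeat length and (for non-repeat deletions) microhomology."""
    if mut.mut_type != "ID":
        raise ValueError("classify_id requires an ID mutation")
    is_del = len(mut.alt) == 0
    seq_str = mut.ref if is_del else mut.alt
    if "N" in seq_str or not seq_str:
        raise UnclassifiableMutation("N or empty sequence in ID event")
    codes = genome.codes(mut.chrom)
    n = codes.size
    L = len(seq_str)
    size_class = min(L, 5)
    seq = encode_sequence(seq_str)
    pos = mut.pos
    if pos < 0 or pos > n or (is_del and pos + L > n):
        raise UnclassifiableMutation("ID context overruns chromosome end")
    if is_del and not np.array_equal(codes[pos : pos + L], seq):
        raise ValueError(f"deleted sequence mismatch at {mut.chrom}:{pos}")

    if L == 1:
        base = seq_str
        canon = base if base in PYRIMIDINES else complement(base)
        if is_del:
            run = _homopolymer_run(codes, pos, seq[0])
            # the deleted base itself is one unit of the homopolymer
            return f"1:Del:{canon}:{min(run - 1, 5)}"
        run = _homopolymer_run(codes, pos, seq[0])
        return f"1:Ins:{canon}:{min(run, 5)}"

    if is_del:
        right = _count_copies(codes, seq, pos + L, +1)
        left = _count_copies(codes, seq, pos, -1)
        repeats = right + left
        if repeats >= 1:
            return f"{size_class}:Del:R:{min(repeats, 5)}"
        # microhomology: partial overlap of the deleted sequence with flanks
        mh = 0
        for k in range(min(L - 1, 5), 0, -1):
            if pos + L + k <= n and np.array_equal(codes[pos + L : pos + L + k], seq[:k]):
                mh = k
                break
            if pos - k >= 0 and np.array_equal(codes[pos - k : pos], seq[L - k :]):
                mh = k
                break
        if mh >= 1:
            cap = 5 if size_class == 5 else size_class - 1
            return f"{size_class}:Del:M:{min(mh, cap)}"
        return f"{size_class}:Del:R:0"

    right = _count_copies(codes, seq, pos, +1)
    left = _count_copies(codes, seq, pos, -1)
    return f"{size_class}:Ins:R:{min(right + left, 5)}"


def classify(mut: Mutation, genome: GenomeSequence) -> str:
    """Dispatch to the scheme matching the mutation type."""
    if mut.mut_type == "SBS":
        return classify_sbs(mut, genome)
    if mut.mut_type == "DBS":
        return classify_dbs(mut)
    return classify_id(mut, genome)


def pyrimidine_strand(mut: Mutation) -> str:
    """Reference strand carrying the mutated pyrimidine: '+' when the
    reference allele is pyrimidine-oriented as written, '-' otherwise.

    For DBSs the canonical-label orientation decides; for IDs the first
    base of the event sequence is used (package convention).
    """
    if mut.mut_type == "SBS":
        return "+" if mut.ref in PYRIMIDINES else "-"
    if mut.mut_type == "DBS":
        return "-" if dbs78_is_flipped(mut.ref, mut.alt) else "+"
    seq = mut.ref if mut.ref else mut.alt
    return "+" if seq[0] in PYRIMIDINES else "-"


def reverse_complement_mutation(mut: Mutation) -> Mutation:
    """The same physical event reported on the opposite reference strand."""
    return Mutation(
        sample_id=mut.sample_id,
        chrom=mut.chrom,
        pos=mut.pos,
        ref=revcomp(mut.ref),
        alt=revcomp(mut.alt),
        mut_type=mut.mut_type,
    )


# ---------------------------------------------------------------------------
# vectorized SBS-96 classification

_SUB_INDEX = np.full((4, 4), -1, dtype=np.int64)
for _ri, _ai, _k in ((1, 0, 0), (1, 2, 1), (1, 3, 2), (3, 0, 3), (3, 1, 4), (3, 2, 5)):
    _SUB_INDEX[_ri, _ai] = _k


def sbs96_indices(
    genome: GenomeSequence, chrom: str, pos: np.ndarray, alt_codes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized SBS-96 channel indices (into ``SBS96_CHANNELS``).

    Returns (idx, valid); idx is -1 where the context is unclassifiable
    (N in the trinucleotide or flank outside the chromosome).
    """
    codes = genome.codes(chrom)
    n = codes.size
    pos = np.asarray(pos, dtype=np.int64)
    alt_codes = np.asarray(alt_codes, dtype=np.int64)
    inside = (pos >= 1) & (pos + 1 < n)
    safe = np.where(inside, pos, 1)
    left = codes[safe - 1].astype(np.int64)
    center = codes[safe].astype(np.int64)
    right = codes[safe + 1].astype(np.int64)
    valid = inside & (left < 4) & (center < 4) & (right < 4) & (alt_codes < 4)
    is_pyr = (center == 1) | (center == 3)
    l5 = np.where(is_pyr, left, 3 - right)
    c = np.where(is_pyr, center, 3 - center)
    a = np.where(is_pyr, alt_codes, 3 - alt_codes)
    r3 = np.where(is_pyr, right, 3 - left)
    sub = _SUB_INDEX[np.clip(c, 0, 3), np.clip(a, 0, 3)]
    valid &= sub >= 0
    idx = np.where(valid, sub * 16 + l5 * 4 + r3, -1)
    return idx, valid


def sbs96_labels_array(idx: np.ndarray) -> np.ndarray:
    """Map channel indices to labels (object dtype; '' for -1)."""
    table = np.array(SBS96_CHANNELS + ("",), dtype=object)
    return table[np.where(idx >= 0, idx, len(SBS96_CHANNELS))]


# ---------------------------------------------------------------------------
# signature assignment

def assign_signature(probabilities: dict[str, float], cutoff: float = 0.5) -> str:
    """Argmax signature if its probability reaches ``cutoff``, else
    UNASSIGNED. Ties broken by lexicographically smallest name."""
    if not probabilities:
        raise ValueError("empty probability row")
    best = min(probabilities.items(), key=lambda kv: (-kv[1], kv[0]))
    return best[0] if best[1] >= cutoff else UNASSIGNED


def signature_mutation_counts(signatures, min_count: int = 1000) -> dict[str, int]:
    """Per-signature counts passing the minimum-attribution filter.

    Signatures with fewer than ``min_count`` attributed mutations are
    excluded from all downstream per-signature analyses.
    """
    counts: dict[str, int] = {}
    for sig in signatures:
        if sig == UNASSIGNED:
            continue
        counts[sig] = counts.get(sig, 0) + 1
    return {s: c for s, c in counts.items() if c >= min_count}
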