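"""Mutation classification schemas.

Somatic mutations are binned into the standard COSMIC-style channel sets:

* SBS-6   — single base substitutions by mutated pyrimidine (C>A ... T>G);
* SBS-96  — SBS-6 expanded with the immediate 5' and 3' flanking bases;
* DBS-78  — doublet base substitutions collapsed to the maximum pyrimidine
  context of the Watson-Crick pair;
* ID-83   — small insertions/deletions by event size, base (for 1 bp
  events), surrounding repeat length, and deletion microhomology.

All labels follow the SigProfilerMatrixGenerator conventions, e.g.
``A[C>T]G``, ``CC>TT``, ``1:Del:T:3``.
"""

from __future__ import annotations

import itertools

BASES = "ACGT"
PYRIMIDINES = "CT"
PURINES = "AG"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# SBS-6 / SBS-96

SBS6_CHANNELS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

SBS96_CHANNELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SBS6_CHANNELS
    for five in BASES
    for three in BASES
)


def sbs96_label(fivep: str, ref: str, alt: str, threep: str) -> str:
    """Canonical SBS-96 label for a stranded trinucleotide substitution.

    When the mutated reference base is a purine the whole context is
    reverse complemented so the label is always pyrimidine-centered.
    """
    if ref in PURINES:
        fivep, ref, alt, threep = (
            complement(threep),
            complement(ref),
            complement(alt),
            complement(fivep),
        )
    return f"{fivep}[{ref}>{alt}]{threep}"


def sbs6_of_sbs96(label: str) -> str:
    """Collapse an SBS-96 label to its SBS-6 channel."""
    return label[2:5]


# ---------------------------------------------------------------------------
# DBS-78

_DBS78_ALTS = {
    "AC": ("CA", "CG", "CT", "GA", "GG", "GT", "TA", "TG", "TT"),
    "AT": ("CA", "CC", "CG", "GA", "GC", "TA"),
    "CC": ("AA", "AG", "AT", "GA", "GG", "GT", "TA", "TG", "TT"),
    "CG": ("AT", "GC", "GT", "TA", "TC", "TT"),
    "CT": ("AA", "AC", "AG", "GA", "GC", "GG", "TA", "TC", "TG"),
    "GC": ("AA", "AG", "AT", "CA", "CG", "TA"),
    "TA": ("AT", "CG", "CT", "GC", "GG", "GT"),
    "TC": ("AA", "AG", "AT", "CA", "CG", "CT", "GA", "GG", "GT"),
    "TG": ("AA", "AC", "AT", "CA", "CC", "CT", "GA", "GC", "GT"),
    "TT": ("AA", "AC", "AG", "CA", "CC", "CG", "GA", "GC", "GG"),
}

DBS78_CHANNELS = tuple(
    f"{ref}>{alt}" for ref in sorted(_DBS78_ALTS) for alt in _DBS78_ALTS[ref]
)

_DBS78_SET = frozenset(DBS78_CHANNELS)


def dbs78_label(ref: str, alt: str) -> str:
    """Canonical DBS-78 label, collapsing a doublet and its reverse
    complement to the canonical (maximum pyrimidine) member."""
    direct = f"{ref}>{alt}"
    if direct in _DBS78_SET:
        return direct
    flipped = f"{revcomp(ref)}>{revcomp(alt)}"
    if flipped in _DBS78_SET:
        return flipped
    raise ValueError(f"not a valid doublet substitution: {ref}>{alt}")


def dbs78_is_flipped(ref: str, alt: str) -> bool:
    """True when the canonical DBS-78 label is on the opposite strand."""
    return f"{ref}>{alt}" not in _DBS78_SET


# ---------------------------------------------------------------------------
# ID-83

def _id83_enumerate() -> tuple:
    labels = []
    for base in ("C", "T"):
        labels += [f"1:Del:{base}:{k}" for k in range(6)]
    for base in ("C", "T"):
        labels += [f"1:Ins:{base}:{k}" for k in range(6)]
    for size in range(2, 6):
        labels += [f"{size}:Del:R:{k}" for k in range(6)]
    for size in range(2, 6):
        labels += [f"{size}:Ins:R:{k}" for k in range(6)]
    labels += ["2:Del:M:1"]
    labels += [f"3:Del:M:{k}" for k in (1, 2)]
    labels += [f"4:Del:M:{k}" for k in (1, 2, 3)]
    labels += [f"5:Del:M:{k}" for k in (1, 2, 3, 4, 5)]
    return tuple(labels)


ID83_CHANNELS = _id83_enumerate()

SCHEME_CHANNELS = {
    "SBS6": SBS6_CHANNELS,
    "SBS96": SBS96_CHANNELS,
    "DBS78": DBS78_CHANNELS,
    "ID83": ID83_CHANNELS,
}


class ChannelScheme:
    """One of the four classification schemas with its ordered channels."""

    def __init__(self, name: str):
        if name not in SCHEME_CHANNELS:
            raise ValueError(f"unknown scheme {name!r}")
        self.name = name
        self.channels = SCHEME_CHANNELS[name]
        self.index = {c: i for i, c in enumerate(self.channels)}

    def __len__(self) -> int:
        return len(self.channels)

    def __repr__(self) -> str:
        return f"ChannelScheme({self.name}, {len(self)} channels)"


def all_stranded_sbs_contexts():
    """Yield every stranded (5', ref, alt, 3') SBS context (192 of them)."""
    for ref in BASES:
        for alt in BASES:
            if alt == ref:
                continue
            for five, three in itertools.product(BASES, BASES):
                yield five, ref, alt, three
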