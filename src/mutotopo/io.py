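"""Readers and writers for the external formats the pipeline touches.

Every reader validates its input and converts to internal 0-based
half-open coordinates at the boundary: VCF POS and wig starts are 1-based
in the files, BED and bedGraph already 0-based. Readers reject, never
silently repair, coordinate disorder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .genome import GenomeSequence, Mutation

# IUPAC ambiguity codes are legal FASTA content; anything ambiguous is
# stored as N (only A/C/G/T are attributable downstream).
_IUPAC = set("ACGTNRYSWKMBDHV")
_AMBIGUOUS = str.maketrans({c: "N" for c in "RYSWKMBDHV"})

MUTATION_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "mut_type"]


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


def read_fasta(path) -> GenomeSequence:
    """Load a FASTA file into memory, uppercased, ambiguity codes as N."""
    fasta = Fasta(str(path), sequence_always_upper=True, rebuild=True)
    sequences = {}
    for name in fasta.keys():
        seq = str(fasta[name][:])
        bad = set(seq) - _IUPAC
        if bad:
            raise FormatError(f"non-IUPAC character(s) {sorted(bad)} in {name}")
        sequences[name] = seq.translate(_AMBIGUOUS)
    if not sequences:
        raise FormatError(f"no sequences in {path}")
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# mutation catalogs

def _normalize_alleles(pos: int, ref: str, alt: str):
    """Strip the shared prefix of an anchored VCF allele pair, returning
    the anchor-free (pos, ref, alt) representation."""
    k = 0
    while k < len(ref) and k < len(alt) and ref[k] == alt[k]:
        k += 1
    return pos + k, ref[k:], alt[k:]


def _typed_record(sample, chrom, pos, ref, alt):
    ref, alt = ref.upper(), alt.upper()
    if len(ref) == 1 and len(alt) == 1 and ref != alt:
        return (sample, chrom, pos, ref, alt, "SBS")
    if len(ref) == 2 and len(alt) == 2 and ref[0] != alt[0] and ref[1] != alt[1]:
        return (sample, chrom, pos, ref, alt, "DBS")
    if len(ref) != len(alt) and (len(ref) == 0 or len(alt) == 0):
        return (sample, chrom, pos, ref, alt, "ID")
    return None


def read_mutations(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a mutation catalog into the canonical DataFrame
    (sample, chrom, pos, ref, alt, mut_type), sorted by (chrom, pos).

    ``dialect='vcf'`` expects one sample name in the VCF header (or uses
    the file stem); ``'tsv'`` expects columns SAMPLE CHROM POS REF ALT
    with 1-based POS. Unsupported allele pairs (multi-base substitutions
    longer than 2, complex indels) are skipped with a warning.
    """
    records = []
    skipped = 0
    if dialect == "vcf":
        with pysam.VariantFile(str(path)) as vf:
            sample = list(vf.header.samples)[0] if vf.header.samples else _stem(path)
            for rec in vf:
                for alt in rec.alts or ():
                    pos0, ref, a = _normalize_alleles(rec.pos - 1, rec.ref, alt)
                    typed = _typed_record(sample, rec.chrom, pos0, ref, a)
                    if typed is None:
                        skipped += 1
                    else:
                        records.append(typed)
    elif dialect == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["SAMPLE", "CHROM", "POS", "REF", "ALT"])
        df.columns = [c.upper() for c in df.columns]
        required = {"SAMPLE", "CHROM", "POS", "REF", "ALT"}
        if not required.issubset(df.columns):
            raise FormatError(f"mutation TSV must have columns {sorted(required)}")
        for row in df.itertuples(index=False):
            ref = "" if pd.isna(row.REF) or row.REF == "-" else row.REF
            alt = "" if pd.isna(row.ALT) or row.ALT == "-" else row.ALT
            pos0, ref, alt = _normalize_alleles(int(row.POS) - 1, ref, alt)
            typed = _typed_record(row.SAMPLE, row.CHROM, pos0, ref, alt)
            if typed is None:
                skipped += 1
            else:
                records.append(typed)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if skipped:
        warnings.warn(f"skipped {skipped} unsupported record(s) in {path}")
    out = pd.DataFrame(records, columns=MUTATION_COLUMNS)
    if out.empty:
        warnings.warn(f"no mutations read from {path}")
    return out.sort_values(["chrom", "pos", "sample"], kind="stable").reset_index(drop=True)


def write_mutations(df: pd.DataFrame, path) -> None:
    """Write the canonical mutation frame as the TSV dialect (1-based POS,
    '-' for empty indel alleles)."""
    out = pd.DataFrame(
        {
            "SAMPLE": df["sample"],
            "CHROM": df["chrom"],
            "POS": df["pos"].astype(int) + 1,
            "REF": df["ref"].replace("", "-"),
            "ALT": df["alt"].replace("", "-"),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def mutations_to_objects(df: pd.DataFrame) -> list[Mutation]:
    return [
        Mutation(r.sample, r.chrom, int(r.pos), r.ref, r.alt, r.mut_type)
        for r in df.itertuples(index=False)
    ]


def mutations_from_objects(muts) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.sample_id, m.chrom, m.pos, m.ref, m.alt, m.mut_type) for m in muts],
        columns=MUTATION_COLUMNS,
    )


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


# ---------------------------------------------------------------------------
# signal tracks

class SignalTrack:
    """Per-chromosome sorted, non-overlapping (start, end, value) segments.

    Queries outside covered segments return ``missing_value`` (default
    0.0) and increment :attr:`coverage_gaps`.
    """

    def __init__(self, segments: dict[str, tuple], missing_value: float = 0.0):
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        self.values: dict[str, np.ndarray] = {}
        self.missing_value = float(missing_value)
        self.coverage_gaps = 0
        for chrom, (starts, ends, values) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (starts.size == ends.size == values.size):
                raise FormatError(f"ragged segment arrays for {chrom}")
            if np.any(starts >= ends):
                raise FormatError(f"empty or inverted segment on {chrom}")
            if starts.size > 1 and np.any(np.diff(starts) < 0):
                raise FormatError(f"segments out of order on {chrom}")
            if starts.size > 1 and np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"overlapping segments on {chrom}")
            self.starts[chrom] = starts
            self.ends[chrom] = ends
            self.values[chrom] = values

    @property
    def chroms(self) -> list[str]:
        return list(self.starts)

    def query(self, chrom: str, pos: int) -> float:
        if chrom not in self.starts:
            self.coverage_gaps += 1
            return self.missing_value
        starts = self.starts[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < self.ends[chrom][i]:
            return float(self.values[chrom][i])
        self.coverage_gaps += 1
        return self.missing_value

    def values_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal over [start, end); uncovered bases get the
        missing value."""
        out = np.full(end - start, self.missing_value, dtype=np.float64)
        if chrom not in self.starts:
            return out
        starts, ends, values = self.starts[chrom], self.ends[chrom], self.values[chrom]
        lo = max(0, int(np.searchsorted(ends, start, side="right")))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            if b > a:
                out[a:b] = values[i]
        return out

    def dense(self, chrom: str, length: int | None = None) -> np.ndarray:
        """Cached per-base signal array for a chromosome (uncovered bases
        hold the missing value). ``length`` pads/limits to a chromosome
        length; otherwise the last covered base ends the array."""
        if not hasattr(self, "_dense"):
            self._dense: dict = {}
        n = int(length) if length is not None else int(self.ends[chrom][-1]) if chrom in self.ends else 0
        key = (chrom, n)
        if key not in self._dense:
            arr = np.full(n, self.missing_value, dtype=np.float64)
            if chrom in self.starts:
                for s, e, v in zip(self.starts[chrom], self.ends[chrom], self.values[chrom]):
                    if s >= n:
                        break
                    arr[s : min(e, n)] = v
            self._dense[key] = arr
        return self._dense[key]

    def dense_cumsum(self, chrom: str, length: int | None = None) -> np.ndarray:
        """Cached prefix sums of the dense array (leading 0), for O(1)
        window means."""
        if not hasattr(self, "_dense_cs"):
            self._dense_cs: dict = {}
        dense = self.dense(chrom, length)
        key = (chrom, dense.size)
        if key not in self._dense_cs:
            self._dense_cs[key] = np.concatenate([[0.0], np.cumsum(dense)])
        return self._dense_cs[key]

    def segments_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.starts:
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": self.starts[chrom],
                        "end": self.ends[chrom],
                        "value": self.values[chrom],
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end", "value"])
        return pd.concat(rows, ignore_index=True)


def _finalize_track(chunks: dict[str, list]) -> SignalTrack:
    segments = {}
    for chrom, triples in chunks.items():
        arr = np.asarray(triples, dtype=np.float64)
        order = np.argsort(arr[:, 0], kind="stable")
        if not np.array_equal(order, np.arange(arr.shape[0])):
            raise FormatError(f"segments out of order on {chrom}")
        segments[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    return SignalTrack(segments)


def read_signal_track(path, dialect: str | None = None) -> SignalTrack:
    """Parse a wig (fixedStep / variableStep) or bedGraph file.

    The dialect is auto-detected from the first declaration line when not
    given. wig coordinates are 1-based in the file and converted here.
    """
    chunks: dict[str, list] = {}
    mode = None
    chrom = None
    step = span = 1
    nxt = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                mode = "fixedStep"
                chrom = fields["chrom"]
                nxt = int(fields["start"]) - 1
                step = int(fields.get("step", 1))
                span = int(fields.get("span", step))
                chunks.setdefault(chrom, [])
                continue
            if line.startswith("variableStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                mode = "variableStep"
                chrom = fields["chrom"]
                span = int(fields.get("span", 1))
                chunks.setdefault(chrom, [])
                continue
            parts = line.split()
            if mode == "fixedStep" and len(parts) == 1:
                chunks[chrom].append((nxt, nxt + span, float(parts[0])))
                nxt += step
            elif mode == "variableStep" and len(parts) == 2:
                start = int(parts[0]) - 1
                chunks[chrom].append((start, start + span, float(parts[1])))
            elif len(parts) == 4:
                mode = "bedGraph"
                chunks.setdefault(parts[0], []).append(
                    (int(parts[1]), int(parts[2]), float(parts[3]))
                )
            else:
                raise FormatError(f"cannot parse line {line!r} in {path}")
    if dialect is not None:
        expected = {"wig-fixedStep": "fixedStep", "wig-variableStep": "variableStep", "bedGraph": "bedGraph"}
        if dialect not in expected:
            raise ValueError(f"unknown dialect {dialect!r}")
        if mode is not None and mode != expected[dialect]:
            raise FormatError(f"declared dialect {dialect} but content is {mode}")
    if not chunks:
        raise FormatError(f"no signal segments in {path}")
    return _finalize_track(chunks)


def write_signal_track_wig(track: SignalTrack, path) -> None:
    """Write as fixedStep wig where steps are uniform, bedGraph otherwise."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.starts[chrom], track.ends[chrom], track.values[chrom]
            widths = ends - starts
            uniform = (
                starts.size > 0
                and np.all(widths == widths[0])
                and (starts.size == 1 or np.all(np.diff(starts) == widths[0]))
            )
            if uniform:
                fh.write(
                    f"fixedStep chrom={chrom} start={starts[0] + 1} "
                    f"step={widths[0]} span={widths[0]}\n"
                )
                fh.write("\n".join(f"{v:.6g}" for v in values) + "\n")
            else:
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# intervals and genes

@dataclass
class IntervalSet:
    """Per-chromosome sorted intervals with optional labels."""

    starts: dict[str, np.ndarray] = field(default_factory=dict)
    ends: dict[str, np.ndarray] = field(default_factory=dict)
    labels: dict[str, list] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntervalSet":
        obj = cls()
        for chrom, grp in df.groupby("chrom", sort=True):
            grp = grp.sort_values("start", kind="stable")
            starts = grp["start"].to_numpy(dtype=np.int64)
            ends = grp["end"].to_numpy(dtype=np.int64)
            if np.any(starts >= ends):
                raise FormatError(f"empty or inverted interval on {chrom}")
            obj.starts[chrom] = starts
            obj.ends[chrom] = ends
            obj.labels[chrom] = (
                grp["name"].tolist() if "name" in grp.columns else [""] * len(grp)
            )
        return obj

    @property
    def chroms(self) -> list[str]:
        return list(self.starts)

    def midpoints(self, chrom: str) -> np.ndarray:
        return (self.starts[chrom] + self.ends[chrom]) // 2

    def total_length(self) -> int:
        return int(sum((self.ends[c] - self.starts[c]).sum() for c in self.starts))


def read_intervals(path) -> IntervalSet:
    """BED3(+name): 0-based half-open, no coordinate conversion."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name"})
    return IntervalSet.from_frame(df)


def write_intervals(intervals: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for chrom in intervals.chroms:
            for s, e, name in zip(
                intervals.starts[chrom], intervals.ends[chrom], intervals.labels[chrom]
            ):
                fh.write(f"{chrom}\t{s}\t{e}" + (f"\t{name}" if name else "") + "\n")


def read_genes(path) -> pd.DataFrame:
    """BED6 protein-coding gene annotations; strand is mandatory."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise FormatError("gene file must be BED6 (strand column required)")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "gene_id", "score", "strand"]
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError("gene strand must be '+' or '-'")
    if (df["start"] >= df["end"]).any():
        raise FormatError("gene start must be < end")
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_genes(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "gene_id", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# signature probabilities

class SignatureProbabilityTable:
    """Per-mutation signature probabilities keyed by (sample, chrom, pos).

    Each row's probabilities must sum to 1 within 1e-6.
    """

    META = ["sample", "chrom", "pos", "channel"]

    def __init__(self, df: pd.DataFrame):
        self.signatures = [c for c in df.columns if c not in self.META]
        if not self.signatures:
            raise FormatError("probability table has no signature columns")
        sums = df[self.signatures].sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-6
        if bad.any():
            raise FormatError(
                f"{int(bad.sum())} probability row(s) do not sum to 1 (first sum {sums[bad].iloc[0]:.6f})"
            )
        self.frame = df.reset_index(drop=True)
        self._lookup = {
            (r.sample, r.chrom, int(r.pos)): i
            for i, r in enumerate(df[["sample", "chrom", "pos"]].itertuples(index=False))
        }

    def row(self, sample: str, chrom: str, pos: int) -> dict[str, float]:
        i = self._lookup[(sample, chrom, pos)]
        rec = self.frame.iloc[i]
        return {s: float(rec[s]) for s in self.signatures}

    def __len__(self) -> int:
        return len(self.frame)


def read_probabilities(path) -> SignatureProbabilityTable:
    """TSV with columns sample, chrom, pos (1-based), channel, then one
    column per signature."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() if c.lower() in SignatureProbabilityTable.META else c for c in df.columns]
    missing = set(SignatureProbabilityTable.META) - set(df.columns)
    if missing:
        raise FormatError(f"probability table missing columns {sorted(missing)}")
    df["pos"] = df["pos"].astype(int) - 1
    return SignatureProbabilityTable(df)


def write_probabilities(table: SignatureProbabilityTable, path) -> None:
    out = table.frame.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic TSV output with header."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
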