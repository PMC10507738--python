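"""Context-preserving background simulation.

Each replicate catalog keeps, for every (sample, chromosome, channel),
exactly the real catalog's mutation count, while drawing new positions
uniformly from same-chromosome loci whose reference context yields the
same channel: SBSs match the canonical pyrimidine-centered trinucleotide
(32 contexts), DBSs the canonical reference doublet, IDs the ID-83 class
of the locus. Replicates are reproducible from (seed, replicate): each
uses an independent RNG stream keyed by that pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genome as gm
from .channels import revcomp
from .genome import GenomeSequence, Mutation

DEFAULT_N_REPS = 100

_CANON_DOUBLETS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")
_DOUBLET_INDEX = {}
for _i, _d in enumerate(_CANON_DOUBLETS):
    _DOUBLET_INDEX[_d] = (_i, False)
    _rc = revcomp(_d)
    if _rc not in _DOUBLET_INDEX:
        _DOUBLET_INDEX[_rc] = (_i, True)

# canonical alt code for each SBS-96 sub index (C>A,C>G,C>T,T>A,T>C,T>G)
_SUB_ALT = np.array([0, 2, 3, 0, 1, 2], dtype=np.int64)


class ContextCoverageError(RuntimeError):
    """A chromosome has zero loci matching a required mutational context."""


def _run_lengths(codes: np.ndarray) -> np.ndarray:
    """Per-position length of the maximal equal-base run containing it."""
    n = codes.size
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    boundaries = np.flatnonzero(codes[1:] != codes[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [n]])
    lengths = ends - starts
    return np.repeat(lengths, lengths)


class ContextIndex:
    """Per-chromosome maps from mutational context to eligible loci."""

    def __init__(self, genome: GenomeSequence):
        self.genome = genome
        self._sbs: dict[str, list] = {}
        self._dbs: dict[str, list] = {}
        self._runlen: dict[str, np.ndarray] = {}
        self._id_cache: dict[tuple, tuple] = {}

    # -- SBS ---------------------------------------------------------------
    @staticmethod
    def sbs_context_code(left: int, center: int, right: int) -> int:
        """Canonical 0..31 code for a trinucleotide (center A/C/G/T)."""
        if center in (1, 3):
            l5, c, r3 = left, center, right
        else:
            l5, c, r3 = 3 - right, 3 - center, 3 - left
        return (16 if c == 3 else 0) + l5 * 4 + r3

    def sbs_positions(self, chrom: str) -> list:
        """Positions of each canonical trinucleotide context (list of 32
        arrays indexed by context code); N-containing contexts excluded."""
        if chrom not in self._sbs:
            codes = self.genome.codes(chrom).astype(np.int64)
            n = codes.size
            buckets = [np.zeros(0, dtype=np.int64)] * 32
            if n >= 3:
                left, center, right = codes[:-2], codes[1:-1], codes[2:]
                valid = (left < 4) & (center < 4) & (right < 4)
                is_pyr = (center == 1) | (center == 3)
                l5 = np.where(is_pyr, left, 3 - right)
                c = np.where(is_pyr, center, 3 - center)
                r3 = np.where(is_pyr, right, 3 - left)
                ctx = np.where(c == 3, 16, 0) + l5 * 4 + r3
                pos = np.arange(1, n - 1, dtype=np.int64)
                order = np.argsort(ctx[valid], kind="stable")
                sorted_ctx = ctx[valid][order]
                sorted_pos = pos[valid][order]
                cuts = np.searchsorted(sorted_ctx, np.arange(33))
                buckets = [sorted_pos[cuts[k] : cuts[k + 1]] for k in range(32)]
            self._sbs[chrom] = buckets
        return self._sbs[chrom]

    def context_positions(self, chrom: str, trinucleotide: str) -> np.ndarray:
        """Loci of a 3-mer context (either strand orientation accepted)."""
        t = gm.encode_sequence(trinucleotide).astype(int)
        code = self.sbs_context_code(t[0], t[1], t[2])
        return self.sbs_positions(chrom)[code]

    # -- DBS ---------------------------------------------------------------
    def dbs_positions(self, chrom: str) -> list:
        if chrom not in self._dbs:
            codes = self.genome.codes(chrom).astype(np.int64)
            buckets = [np.zeros(0, dtype=np.int64)] * 10
            if codes.size >= 2:
                c0, c1 = codes[:-1], codes[1:]
                valid = (c0 < 4) & (c1 < 4)
                pair = c0 * 4 + c1
                canon = np.full(16, -1, dtype=np.int64)
                for d, (i, _f) in _DOUBLET_INDEX.items():
                    dc = gm.encode_sequence(d).astype(int)
                    canon[dc[0] * 4 + dc[1]] = i
                ci = canon[np.clip(pair, 0, 15)]
                pos = np.arange(codes.size - 1, dtype=np.int64)
                for i in range(10):
                    buckets[i] = pos[valid & (ci == i)]
            self._dbs[chrom] = buckets
        return self._dbs[chrom]

    # -- ID ----------------------------------------------------------------
    def _runlens(self, chrom: str) -> np.ndarray:
        if chrom not in self._runlen:
            self._runlen[chrom] = _run_lengths(self.genome.codes(chrom))
        return self._runlen[chrom]

    def _id_1bp_loci(self, chrom: str, label: str) -> tuple:
        """(positions, insert_base_codes|None) for a 1 bp indel label."""
        key = (chrom, label)
        if key in self._id_cache:
            return self._id_cache[key]
        _, kind, base, k = label.split(":")
        k = int(k)
        codes = self.genome.codes(chrom).astype(np.int64)
        runlen = self._runlens(chrom)
        b = int(gm.encode_sequence(base)[0])
        comp_b = 3 - b
        if kind == "Del":
            eligible = []
            for bc in (b, comp_b):
                cls = np.minimum(runlen - 1, 5)
                mask = (codes == bc) & (cls == k)
                eligible.append(np.flatnonzero(mask))
            pos = np.concatenate(eligible)
            pos.sort()
            result = (pos, None)
        else:
            pos_list, base_list = [], []
            for bc in (b, comp_b):
                here = codes == bc
                # run of bc touching insertion point p: codes[p]==bc or codes[p-1]==bc
                count = np.zeros(codes.size, dtype=np.int64)
                count[here] = runlen[here]
                prev = np.zeros(codes.size, dtype=bool)
                prev[1:] = here[:-1] & ~here[1:]
                count[prev] = runlen[np.flatnonzero(prev) - 1]
                mask = np.minimum(count, 5) == k
                p = np.flatnonzero(mask)
                pos_list.append(p)
                base_list.append(np.full(p.size, bc, dtype=np.int64))
            pos = np.concatenate(pos_list)
            bases = np.concatenate(base_list)
            order = np.argsort(pos, kind="stable")
            result = (pos[order], bases[order])
        self._id_cache[key] = result
        return result

    def sample_id_event(self, chrom: str, real: Mutation, label: str, rng) -> tuple:
        """Draw one (pos, ref, alt) on ``chrom`` classifying to ``label``."""
        is_del = len(real.alt) == 0
        seq = real.ref if is_del else real.alt
        if len(seq) == 1:
            pos, bases = self._id_1bp_loci(chrom, label)
            if pos.size == 0:
                raise ContextCoverageError(f"no loci for context {label} on {chrom}")
            j = int(rng.integers(0, pos.size))
            p = int(pos[j])
            if is_del:
                return p, self.genome.base(chrom, p), ""
            return p, "", gm.decode_sequence(np.array([bases[j]], dtype=np.uint8))
        return self._sample_id_rejection(chrom, seq, is_del, label, rng)

    def _sample_id_rejection(self, chrom: str, seq: str, is_del: bool, label: str, rng):
        n = self.genome.length(chrom)
        L = len(seq)
        seqs = (seq, revcomp(seq))
        for _ in range(200000):
            p = int(rng.integers(1, max(2, n - L - 1)))
            ev = self._try_id_event(chrom, p, seqs, is_del, label)
            if ev is not None:
                return ev
        # exhaustive fallback (cached) for rare context classes
        key = (chrom, label, seq, is_del)
        if key not in self._id_cache:
            loci = []
            for p in range(1, n - L - 1):
                ev = self._try_id_event(chrom, p, seqs, is_del, label)
                if ev is not None:
                    loci.append(ev)
            self._id_cache[key] = (loci, None)
        loci, _ = self._id_cache[key]
        if not loci:
            raise ContextCoverageError(f"no loci for context {label} on {chrom}")
        return loci[int(rng.integers(0, len(loci)))]

    def _try_id_event(self, chrom, p, seqs, is_del, label):
        if is_del:
            candidate = self.genome.slice(chrom, p, p + len(seqs[0]))
            if candidate not in seqs or "N" in candidate:
                return None
            mut = Mutation("_", chrom, p, candidate, "", "ID")
            try:
                if gm.classify_id(mut, self.genome) == label:
                    return p, candidate, ""
            except gm.UnclassifiableMutation:
                return None
            return None
        for s in seqs:
            mut = Mutation("_", chrom, p, "", s, "ID")
            try:
                if gm.classify_id(mut, self.genome) == label:
                    return p, "", s
            except gm.UnclassifiableMutation:
                continue
        return None


@dataclass
class SimulatedCatalogSet:
    """Ordered replicate catalogs (mutation DataFrames) with their seed."""

    replicates: list
    n_reps: int
    seed: int


def simulate_catalog(
    real: pd.DataFrame,
    genome: GenomeSequence,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    index: ContextIndex | None = None,
    allow_collisions: bool = True,
) -> SimulatedCatalogSet:
    """Generate ``n_reps`` context-preserving replicate catalogs.

    ``real`` is the canonical mutation frame (see :mod:`mutotopo.io`);
    every mutation must be classifiable on ``genome``. With
    ``allow_collisions=False`` positions within one (chromosome, context)
    group of a replicate are drawn without replacement.
    """
    index = index or ContextIndex(genome)
    real = real.reset_index(drop=True)
    plan = _build_plan(real, genome, index)
    replicates = []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        replicates.append(_simulate_once(real, genome, index, plan, rng, allow_collisions))
    return SimulatedCatalogSet(replicates=replicates, n_reps=n_reps, seed=seed)


def _build_plan(real: pd.DataFrame, genome: GenomeSequence, index: ContextIndex):
    """Precompute per-mutation context keys so each replicate only draws."""
    n = len(real)
    kind = np.zeros(n, dtype=np.int64)  # 0 SBS, 1 DBS, 2 ID
    ctx = np.full(n, -1, dtype=np.int64)
    alt_canon = np.full(n, -1, dtype=np.int64)
    id_labels = {}
    mut_type = real["mut_type"].to_numpy()
    for chrom, grp in real.groupby("chrom", sort=False):
        if chrom not in genome.chrom_names:
            raise ValueError(f"catalog chromosome {chrom!r} absent from genome")
        sbs_rows = grp.index[mut_type[grp.index] == "SBS"].to_numpy()
        if sbs_rows.size:
            pos = real.loc[sbs_rows, "pos"].to_numpy(dtype=np.int64)
            alts = gm.encode_sequence("".join(real.loc[sbs_rows, "alt"])).astype(np.int64)
            idx96, valid = gm.sbs96_indices(genome, chrom, pos, alts)
            if not valid.all():
                bad = sbs_rows[~valid][0]
                raise ValueError(f"unclassifiable SBS in real catalog at row {bad}")
            sub = idx96 // 16
            ctx[sbs_rows] = np.where(sub >= 3, 16, 0) + (idx96 % 16)
            alt_canon[sbs_rows] = _SUB_ALT[sub]
    for i in np.flatnonzero(mut_type == "DBS"):
        rec = real.iloc[i]
        kind[i] = 1
        di, flipped = _DOUBLET_INDEX[rec["ref"]]
        ctx[i] = di
        alt_canon[i] = 0
        id_labels[i] = rec["alt"] if not flipped else revcomp(rec["alt"])
    for i in np.flatnonzero(mut_type == "ID"):
        rec = real.iloc[i]
        kind[i] = 2
        mut = Mutation(rec["sample"], rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"], "ID")
        id_labels[i] = gm.classify_id(mut, genome)
    return kind, ctx, alt_canon, id_labels


def _simulate_once(real, genome, index, plan, rng, allow_collisions):
    kind, ctx, alt_canon, id_labels = plan
    n = len(real)
    new_pos = np.zeros(n, dtype=np.int64)
    new_ref = np.empty(n, dtype=object)
    new_alt = np.empty(n, dtype=object)
    chrom_arr = real["chrom"].to_numpy()
    keyframe = pd.DataFrame({"chrom": chrom_arr, "kind": kind, "ctx": ctx})
    for (chrom, k, c), grp in keyframe.groupby(["chrom", "kind", "ctx"], sort=True):
        rows = grp.index.to_numpy()
        codes = genome.codes(chrom)
        if k == 0:
            loci = index.sbs_positions(chrom)[c]
            if loci.size == 0:
                raise ContextCoverageError(f"no loci for SBS context code {c} on {chrom}")
            draws = _draw(loci, rows.size, rng, allow_collisions)
            new_pos[rows] = draws
            center = codes[draws].astype(np.int64)
            is_pyr = (center == 1) | (center == 3)
            for j, row in enumerate(rows):
                a = alt_canon[row] if is_pyr[j] else 3 - alt_canon[row]
                new_ref[row] = "ACGT"[center[j]]
                new_alt[row] = "ACGT"[a]
        elif k == 1:
            loci = index.dbs_positions(chrom)[c]
            if loci.size == 0:
                raise ContextCoverageError(
                    f"no loci for doublet {_CANON_DOUBLETS[c]} on {chrom}"
                )
            draws = _draw(loci, rows.size, rng, allow_collisions)
            new_pos[rows] = draws
            for j, row in enumerate(rows):
                p = int(draws[j])
                ref2 = genome.slice(chrom, p, p + 2)
                alt2 = id_labels[row] if ref2 == _CANON_DOUBLETS[c] else revcomp(id_labels[row])
                new_ref[row] = ref2
                new_alt[row] = alt2
        else:
            for row in rows:
                rec = real.iloc[row]
                mut = Mutation(rec["sample"], chrom, int(rec["pos"]), rec["ref"], rec["alt"], "ID")
                p, r, a = index.sample_id_event(chrom, mut, id_labels[row], rng)
                new_pos[row] = p
                new_ref[row] = r
                new_alt[row] = a
    out = real.copy()
    out["pos"] = new_pos
    out["ref"] = new_ref
    out["alt"] = new_alt
    return out.sort_values(["chrom", "pos", "sample"], kind="stable").reset_index(drop=True)


def _draw(loci: np.ndarray, size: int, rng, allow_collisions: bool) -> np.ndarray:
    if allow_collisions or size > loci.size:
        return loci[rng.integers(0, loci.size, size)]
    return rng.choice(loci, size=size, replace=False)
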