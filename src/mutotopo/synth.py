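"""Seeded synthetic-data generation.

Produces toy genomes, gene annotations, sawtooth replication-timing
profiles, periodic/blocky/peaked feature tracks and mutation catalogs
with planted, parameterized topographical structure (strand odds
ratios, timing gradients, occupancy preference, clustered same-strand
runs), so every analysis stage is testable without external downloads.
Everything derives from a single spec seed through named substreams; a
manifest records every planted effect for recovery tests.

These fixtures are statistical stand-ins at desk scale, not biological
simulations of human chromatin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as mio
from .genome import GenomeSequence
from .io import IntervalSet, SignalTrack
from .simulate import ContextIndex
from .strands import GeneIndex, transcription_labels, replication_labels
from .timing import DecileSet

_SUBSTREAM = {"genome": 1, "genes": 2, "repliseq": 3, "feature": 4, "catalog": 5}


def _rng(seed: int, stream: str, extra: int = 0):
    return np.random.default_rng([int(seed), _SUBSTREAM[stream], extra])


@dataclass
class SignatureSpec:
    """One planted mutational process.

    Effects are optional and independent: ``tx_or`` enriches the
    transcribed strand by the given odds, ``rep_or`` the lagging strand,
    ``timing_weights`` gives relative decile placement weights (earliest
    to latest), ``occupancy`` targets a +/-50 bp signal fold on a blocks
    track, ``phase_lock`` pins positions to a track period, ``scm_runs``
    inserts same-strand runs [(length, count), ...].
    """

    name: str
    n_mutations: int = 1000
    mut_type: str = "SBS"
    channel_weights: dict = field(default_factory=lambda: {"C>T": 1.0})
    doublet: str = "CC>TT"
    id_label: str = "1:Del:T:3"
    n_samples: int = 4
    prob_sharpness: float = 0.9
    tx_or: float | None = None
    rep_or: float | None = None
    timing_weights: tuple | None = None
    occupancy: dict | None = None
    phase_lock: dict | None = None
    scm_runs: list | None = None
    scm_channel: str = "C>T"


def default_signatures() -> list:
    """The default planted catalog: one signature per analysis axis."""
    return [
        SignatureSpec(name="SBS91", n_mutations=3000, channel_weights={"C>T": 1.0}, tx_or=2.0),
        SignatureSpec(name="SBS92", n_mutations=3000, channel_weights={"C>A": 1.0}, rep_or=2.0),
        SignatureSpec(
            name="SBS93",
            n_mutations=3000,
            channel_weights={"T>C": 1.0},
            timing_weights=tuple(range(1, 11)),
        ),
        SignatureSpec(name="SBS94", n_mutations=2000, channel_weights={"C>G": 1.0}),
        SignatureSpec(
            name="SBS95",
            n_mutations=300,
            channel_weights={"T>G": 1.0},
            scm_runs=[(6, 5)],
            scm_channel="T>G",
        ),
        SignatureSpec(name="DBS91", n_mutations=300, mut_type="DBS", doublet="CC>TT"),
        SignatureSpec(name="ID91", n_mutations=300, mut_type="ID", id_label="1:Del:T:3"),
    ]


@dataclass
class FixtureSpec:
    """Toy-scale study conditions: genome, annotation and track shapes,
    plus the planted mutational processes."""

    seed: int = 0
    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}
    )
    gene_length: int = 20_000
    gene_spacing: int = 50_000
    bidirectional_every: int = 12
    repliseq_period: int = 200_000
    repliseq_amplitude: float = 100.0
    repliseq_step: int = 1_000
    feature_step: int = 10
    min_context_coverage: int = 50
    signatures: list = field(default_factory=default_signatures)


# ---------------------------------------------------------------------------
# genome, genes, tracks

def make_genome(spec: FixtureSpec) -> GenomeSequence:
    """Uniform-random ACGT chromosomes; retried with doubled lengths (then
    an error) if any canonical trinucleotide context is rarer than
    ``min_context_coverage`` per chromosome."""
    sizes = dict(spec.chrom_sizes)
    for attempt in range(3):
        rng = _rng(spec.seed, "genome", attempt)
        codes = {c: rng.integers(0, 4, size=n).astype(np.uint8) for c, n in sizes.items()}
        genome = GenomeSequence.from_codes(codes)
        index = ContextIndex(genome)
        ok = all(
            min(len(b) for b in index.sbs_positions(chrom)) >= spec.min_context_coverage
            for chrom in genome.chrom_names
        )
        if ok:
            return genome
        sizes = {c: 2 * n for c, n in sizes.items()}
    raise RuntimeError("could not satisfy context coverage; chromosomes too short")


def make_genes(spec: FixtureSpec, genome: GenomeSequence) -> pd.DataFrame:
    """Tile genes along each chromosome with alternating strands; every
    ``bidirectional_every``-th gene gets an overlapping opposite-strand
    partner (a bidirectionally transcribed region)."""
    rows = []
    k = 0
    for chrom in genome.chrom_names:
        n = genome.length(chrom)
        start = spec.gene_spacing // 2
        while start + spec.gene_length < n:
            strand = "+" if k % 2 == 0 else "-"
            rows.append((chrom, start, start + spec.gene_length, f"gene{k}", 0, strand))
            if spec.bidirectional_every and (k % spec.bidirectional_every) == spec.bidirectional_every - 1:
                rows.append(
                    (
                        chrom,
                        start + spec.gene_length // 4,
                        start + 3 * spec.gene_length // 4,
                        f"gene{k}b",
                        0,
                        "-" if strand == "+" else "+",
                    )
                )
            k += 1
            start += spec.gene_spacing
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "score", "strand"])


def make_repliseq(spec: FixtureSpec, genome: GenomeSequence):
    """Sawtooth wavelet-like profile: peaks (initiation, early/high
    signal) at multiples of the period, valleys (termination, late/low)
    half a period later. Returns (signal, peaks, valleys)."""
    segments = {}
    peak_rows, valley_rows = [], []
    period, amp, step = spec.repliseq_period, spec.repliseq_amplitude, spec.repliseq_step
    for chrom in genome.chrom_names:
        n = genome.length(chrom)
        starts = np.arange(0, n - step + 1, step, dtype=np.int64)
        mid = starts + step // 2
        phase = (mid % period) / period  # 0 at peak, 0.5 at valley
        tri = 1.0 - 2.0 * np.abs(phase - np.where(phase < 0.5, 0.0, 1.0))
        values = amp * tri
        segments[chrom] = (starts, starts + step, values)
        for p in range(0, n + 1, period):
            lo, hi = max(0, p - step), min(n, p + step)
            if lo < hi:
                peak_rows.append((chrom, lo, hi))
            v = p + period // 2
            if v < n:
                valley_rows.append((chrom, max(0, v - step), min(n, v + step)))
    signal = SignalTrack(segments)
    peaks = IntervalSet.from_frame(pd.DataFrame(peak_rows, columns=["chrom", "start", "end"]))
    valleys = IntervalSet.from_frame(pd.DataFrame(valley_rows, columns=["chrom", "start", "end"]))
    return signal, peaks, valleys


def make_feature_track(spec: FixtureSpec, genome: GenomeSequence, kind: str, **params) -> SignalTrack:
    """Deterministic feature tracks: 'constant' (value), 'cosine'
    (baseline, amplitude, period, phase), 'blocks' (low, high,
    block_width), 'peaked' (baseline, height, site_spacing, width)."""
    step = params.get("step", spec.feature_step)
    segments = {}
    for chrom in genome.chrom_names:
        n = genome.length(chrom)
        starts = np.arange(0, n - step + 1, step, dtype=np.int64)
        mid = starts + step // 2
        if kind == "constant":
            values = np.full(starts.size, float(params.get("value", 1.0)))
        elif kind == "cosine":
            period = params.get("period", 200)
            values = params.get("baseline", 2.0) + params.get("amplitude", 1.0) * np.cos(
                2 * np.pi * (mid - params.get("phase", 0)) / period
            )
        elif kind == "blocks":
            width = params.get("block_width", 2000)
            high = (mid // width) % 2 == 1
            values = np.where(high, params.get("high", 3.0), params.get("low", 1.0))
        elif kind == "peaked":
            spacing = params.get("site_spacing", 5000)
            width = params.get("width", 150)
            offset = np.abs((mid % spacing) - spacing // 2)
            values = params.get("baseline", 0.5) + params.get("height", 4.0) * np.exp(
                -0.5 * ((offset - 0) / width) ** 2
            )
        else:
            raise ValueError(f"unknown track kind {kind!r}")
        segments[chrom] = (starts, starts + step, values)
    return SignalTrack(segments)


# ---------------------------------------------------------------------------
# catalog

def _eligible_sbs_loci(genome: GenomeSequence, chrom: str, pyr_ref: str) -> np.ndarray:
    """Positions whose base is the pyrimidine ref or its complement,
    with full flanks inside the chromosome."""
    codes = genome.codes(chrom)
    want = {"C": (1, 2), "T": (3, 0)}[pyr_ref]
    mask = (codes == want[0]) | (codes == want[1])
    mask[0] = mask[-1] = False
    return np.flatnonzero(mask)


def _acceptance_weights(
    spec_sig: SignatureSpec,
    genome: GenomeSequence,
    chrom: str,
    pos: np.ndarray,
    genes: GeneIndex | None,
    repmap,
    deciles: DecileSet | None,
    occupancy_ctx: dict | None,
):
    """Per-locus stratum codes and per-stratum weights for the planted
    effects. Strata distinguish every effect level (e.g. untranscribed
    vs nontranscribed) so allocation is exact within each level, not
    merely within equal-weight pools."""
    codes = genome.codes(chrom)
    pyr = np.where((codes[pos] == 1) | (codes[pos] == 3), "+", "-")
    strata = np.zeros(pos.size, dtype=np.int64)
    weights = np.ones(1)

    def extend(level_codes, level_weights):
        nonlocal strata, weights
        k = len(level_weights)
        strata = strata * k + level_codes
        weights = np.repeat(weights, k) * np.tile(np.asarray(level_weights, float), weights.size)

    if spec_sig.tx_or is not None:
        if genes is None:
            raise ValueError("tx_or planted but no genes provided")
        lab = transcription_labels(np.full(pos.size, chrom, dtype=object), pos, pyr, genes)
        level = np.select(
            [lab == "TRANSCRIBED", lab == "UNTRANSCRIBED"], [0, 1], default=2
        )
        extend(level, [spec_sig.tx_or, 1.0, 1.0])
    if spec_sig.rep_or is not None:
        if repmap is None:
            raise ValueError("rep_or planted but no replication map provided")
        lab = replication_labels(np.full(pos.size, chrom, dtype=object), pos, pyr, repmap)
        level = np.select([lab == "LAGGING", lab == "LEADING"], [0, 1], default=2)
        extend(level, [spec_sig.rep_or, 1.0, 1.0])
    if spec_sig.timing_weights is not None:
        if deciles is None:
            raise ValueError("timing_weights planted but no deciles provided")
        tw = [float(w) for w in spec_sig.timing_weights]
        d = deciles.locate(chrom, pos)
        extend(np.where(d >= 0, d, 10), tw + [float(np.mean(tw))])
    if spec_sig.occupancy is not None:
        level, level_weights = occupancy_ctx[chrom]["strata_fn"](pos)
        extend(level, level_weights)
    if spec_sig.phase_lock is not None:
        period = spec_sig.phase_lock["period"]
        phase = spec_sig.phase_lock.get("phase", 0)
        tol = spec_sig.phase_lock.get("tol", 5)
        level = (((pos - phase) % period) >= tol).astype(np.int64)
        extend(level, [1.0, 0.0])
    return strata, weights


def _occupancy_context(occ: dict, genome: GenomeSequence) -> dict:
    """Per-chromosome acceptance-weight function hitting a target
    +/-50 bp fold on a 'blocks' track: with high/low block values h/l
    covering fraction f each, placing a fraction p_high of mutations in
    high blocks gives fold (p*h + (1-p)*l) / (f*h + (1-f)*l)."""
    track: SignalTrack = occ["track"]
    h, l = occ.get("high", 3.0), occ.get("low", 1.0)
    width = occ.get("block_width", 2000)
    margin = occ.get("margin", 60)
    f = 0.5
    mean = f * h + (1 - f) * l
    target = occ["target_fold"] * mean
    p_high = float(np.clip((target - l) / (h - l), 0.0, 1.0))
    ctx = {}
    for chrom in genome.chrom_names:
        def strata_fn(pos, width=width, margin=margin, p_high=p_high):
            offset = pos % width
            interior = (offset >= margin) & (offset < width - margin)
            high = (pos // width) % 2 == 1
            level = np.select(
                [interior & high, interior & ~high], [0, 1], default=2
            ).astype(np.int64)
            # weights proportional to target share / stratum availability
            return level, [p_high / f, (1 - p_high) / (1 - f), 0.0]

        ctx[chrom] = {"strata_fn": strata_fn}
    return ctx


def _weighted_sample(
    loci: np.ndarray, strata_codes: np.ndarray, code_weights: np.ndarray, n: int, rng
) -> np.ndarray:
    """Draw n distinct loci realizing the weighting by exact stratified
    allocation: each stratum receives round(n * weight * size / total)
    draws (largest-remainder rounding) and loci are drawn uniformly
    without replacement within strata. This plants effect sizes at their
    nominal value instead of a binomial realization around it."""
    values = np.asarray([code_weights[c] for c in np.unique(strata_codes)], dtype=float)
    strata = [loci[strata_codes == c] for c in np.unique(strata_codes)]
    keep = values > 0
    strata = [s for s, k in zip(strata, keep) if k]
    values = values[keep]
    if sum(s.size for s in strata) < n:
        raise ValueError("requested effect unachievable: too few weighted loci")
    sizes = np.array([s.size for s in strata], dtype=float)
    masses = values * sizes
    exact = n * masses / masses.sum()
    alloc = np.floor(exact).astype(int)
    shortfall = n - alloc.sum()
    order = np.argsort(-(exact - alloc), kind="stable")
    alloc[order[:shortfall]] += 1
    # cap at stratum size and spill any excess into strata with room
    for _ in range(len(strata)):
        over = alloc - sizes.astype(int)
        if (over <= 0).all():
            break
        spill = int(over[over > 0].sum())
        alloc = np.minimum(alloc, sizes.astype(int))
        room = sizes.astype(int) - alloc
        for i in np.argsort(-room):
            take = min(spill, int(room[i]))
            alloc[i] += take
            spill -= take
            if spill == 0:
                break
    draws = [
        rng.choice(s, size=int(k), replace=False) for s, k in zip(strata, alloc) if k > 0
    ]
    out = np.concatenate(draws)
    return out[rng.permutation(out.size)]


_ALT_CHOICES = {"C>A": "A", "C>G": "G", "C>T": "T", "T>A": "A", "T>C": "C", "T>G": "G"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def make_catalog(
    spec: FixtureSpec,
    genome: GenomeSequence,
    genes: pd.DataFrame | None = None,
    repmap=None,
    deciles: DecileSet | None = None,
):
    """Generate (mutations frame, probability table, manifest) with every
    planted effect from ``spec.signatures`` realized by weighted
    placement; the manifest records the true effects for recovery tests."""
    rng = _rng(spec.seed, "catalog")
    gene_index = GeneIndex(genes) if genes is not None else None
    index = ContextIndex(genome)
    chroms = genome.chrom_names
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    all_rows = []
    sig_names = [s.name for s in spec.signatures]
    manifest = {"seed": spec.seed, "signatures": {}}

    for sig in spec.signatures:
        occupancy_ctx = _occupancy_context(sig.occupancy, genome) if sig.occupancy else None
        rows = []
        if sig.mut_type == "SBS":
            per_chrom = rng.multinomial(sig.n_mutations, chrom_p)
            for chrom, n_c in zip(chroms, per_chrom):
                if n_c == 0:
                    continue
                channels = list(sig.channel_weights)
                cw = np.array([sig.channel_weights[c] for c in channels], dtype=float)
                per_channel = rng.multinomial(n_c, cw / cw.sum())
                for ch, n_ch in zip(channels, per_channel):
                    if n_ch == 0:
                        continue
                    pyr_ref = ch[0]
                    loci = _eligible_sbs_loci(genome, chrom, pyr_ref)
                    codes_s, w = _acceptance_weights(
                        sig, genome, chrom, loci, gene_index, repmap, deciles, occupancy_ctx
                    )
                    pos = _weighted_sample(loci, codes_s, w, n_ch, rng)
                    codes = genome.codes(chrom)[pos]
                    alt_pyr = _ALT_CHOICES[ch]
                    for p, code in zip(pos, codes):
                        ref = "ACGT"[code]
                        alt = alt_pyr if ref in "CT" else _COMP[alt_pyr]
                        rows.append((chrom, int(p), ref, alt, "SBS"))
            if sig.scm_runs:
                rows += _plant_scm_runs(sig, genome, rng)
        elif sig.mut_type == "DBS":
            ref2, alt2 = sig.doublet.split(">")
            per_chrom = rng.multinomial(sig.n_mutations, chrom_p)
            for chrom, n_c in zip(chroms, per_chrom):
                from .simulate import _CANON_DOUBLETS, _DOUBLET_INDEX

                di, _ = _DOUBLET_INDEX[ref2]
                loci = index.dbs_positions(chrom)[di]
                pos = loci[rng.integers(0, loci.size, n_c)]
                for p in np.unique(pos)[:n_c]:
                    r = genome.slice(chrom, int(p), int(p) + 2)
                    a = alt2 if r == _CANON_DOUBLETS[di] else _revcomp2(alt2)
                    rows.append((chrom, int(p), r, a, "DBS"))
        elif sig.mut_type == "ID":
            per_chrom = rng.multinomial(sig.n_mutations, chrom_p)
            for chrom, n_c in zip(chroms, per_chrom):
                loci, bases = index._id_1bp_loci(chrom, sig.id_label)
                is_del = ":Del:" in sig.id_label
                picks = loci[rng.integers(0, loci.size, n_c)]
                for j, p in enumerate(np.unique(picks)[:n_c]):
                    if is_del:
                        rows.append((chrom, int(p), genome.base(chrom, int(p)), "", "ID"))
                    else:
                        jj = int(np.searchsorted(loci, p))
                        rows.append((chrom, int(p), "", "ACGT"[bases[jj]], "ID"))
        else:
            raise ValueError(f"unknown mut_type {sig.mut_type!r}")

        samples = [f"S{(i % sig.n_samples) + 1}" for i in range(len(rows))]
        rng.shuffle(samples)
        for (chrom, p, r, a, t), sample in zip(rows, samples):
            all_rows.append((sample, chrom, p, r, a, t, sig.name))
        manifest["signatures"][sig.name] = {
            "n_mutations": len(rows),
            "mut_type": sig.mut_type,
            "tx_or": sig.tx_or,
            "rep_or": sig.rep_or,
            "timing_weights": list(sig.timing_weights) if sig.timing_weights else None,
            "occupancy_fold": sig.occupancy["target_fold"] if sig.occupancy else None,
            "phase_lock": sig.phase_lock,
            "scm_runs": sig.scm_runs,
            "prob_sharpness": sig.prob_sharpness,
        }

    muts = pd.DataFrame(
        all_rows, columns=["sample", "chrom", "pos", "ref", "alt", "mut_type", "true_signature"]
    ).sort_values(["chrom", "pos", "sample"], kind="stable").reset_index(drop=True)
    probs = _probability_table(muts, spec, sig_names)
    catalog = muts[["sample", "chrom", "pos", "ref", "alt", "mut_type"]].copy()
    return catalog, probs, manifest


def _revcomp2(s: str) -> str:
    return _COMP[s[1]] + _COMP[s[0]]


def _plant_scm_runs(sig: SignatureSpec, genome: GenomeSequence, rng) -> list:
    """Insert same-channel, same-strand runs: consecutive pyrimidine loci
    of the run channel's reference base on the + strand, subsampled so
    member spacing is ~100 bp (well under the 10 kb threshold)."""
    pyr_ref = sig.scm_channel[0]
    alt = _ALT_CHOICES[sig.scm_channel]
    rows = []
    chroms = genome.chrom_names
    for length, count in sig.scm_runs:
        for _ in range(count):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            codes = genome.codes(chrom)
            base_code = {"C": 1, "T": 3}[pyr_ref]
            loci = np.flatnonzero(codes == base_code)
            loci = loci[(loci > 0) & (loci < codes.size - 1)]
            stride = max(1, 100 // 4)
            loci = loci[::stride]
            start_idx = int(rng.integers(0, loci.size - length))
            members = loci[start_idx : start_idx + length]
            for p in members:
                rows.append((chrom, int(p), pyr_ref, alt, "SBS"))
    return rows


def _probability_table(muts: pd.DataFrame, spec: FixtureSpec, sig_names: list):
    """Sharp per-mutation probability rows: the generating signature gets
    its spec's sharpness, the rest is split evenly over the others."""
    sharp = {s.name: s.prob_sharpness for s in spec.signatures}
    columns = sig_names if len(sig_names) > 1 else sig_names + ["SBS_OTHER"]
    data = np.zeros((len(muts), len(columns)))
    col_index = {c: i for i, c in enumerate(columns)}
    for i, (true_sig) in enumerate(muts["true_signature"]):
        p = sharp[true_sig]
        rest = (1.0 - p) / (len(columns) - 1)
        data[i, :] = rest
        data[i, col_index[true_sig]] = p
    frame = pd.DataFrame(
        {
            "sample": muts["sample"],
            "chrom": muts["chrom"],
            "pos": muts["pos"].astype(int),
            "channel": "",
        }
    )
    for c in columns:
        frame[c] = data[:, col_index[c]]
    return mio.SignatureProbabilityTable(frame)


# ---------------------------------------------------------------------------
# file emission

def write_fixture_set(spec: FixtureSpec, outdir) -> dict:
    """Generate the full fixture set and write every file format the
    pipeline reads. Returns the manifest (also written as JSON)."""
    import os

    from .strands import derive_replication_strand_map, RepliSeqProfile
    from .timing import split_deciles

    os.makedirs(outdir, exist_ok=True)
    genome = make_genome(spec)
    genes = make_genes(spec, genome)
    signal, peaks, valleys = make_repliseq(spec, genome)
    profile = RepliSeqProfile(signal=signal, peaks=peaks, valleys=valleys)
    repmap = derive_replication_strand_map(profile)
    deciles = split_deciles(signal)
    catalog, probs, manifest = make_catalog(spec, genome, genes, repmap, deciles)

    mio.write_fasta(genome, os.path.join(outdir, "genome.fa"))
    mio.write_genes(genes, os.path.join(outdir, "genes.bed"))
    mio.write_signal_track_wig(signal, os.path.join(outdir, "repliseq.wig"))
    mio.write_intervals(peaks, os.path.join(outdir, "repliseq_peaks.bed"))
    mio.write_intervals(valleys, os.path.join(outdir, "repliseq_valleys.bed"))
    nucleosome = make_feature_track(spec, genome, "cosine", period=200, step=spec.feature_step)
    ctcf = make_feature_track(spec, genome, "peaked", step=spec.feature_step)
    mio.write_signal_track_wig(nucleosome, os.path.join(outdir, "nucleosome.wig"))
    mio.write_signal_track_wig(ctcf, os.path.join(outdir, "ctcf.wig"))
    mio.write_mutations(catalog, os.path.join(outdir, "mutations.tsv"))
    mio.write_probabilities(probs, os.path.join(outdir, "probabilities.tsv"))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
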