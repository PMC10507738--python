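"""End-to-end orchestration of the topography analyses.

The stages mirror the analysis workflow: classify and attribute the real
catalog, simulate context-preserving backgrounds, annotate strands,
then run the asymmetry, strand-coordinated mutagenesis, replication
timing, occupancy/abundance and stratification analyses, writing one
TSV per analysis family. All thresholds default to the published
values and are recorded in a resolved-config echo next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import asymmetry as asym
from . import io as mio
from . import occupancy as occ
from . import scm as scm_mod
from . import timing as timing_mod
from .catalog import attach_signatures, classify_catalog, filter_signatures
from .cohorts import classify_apobec
from .genome import GenomeSequence
from .simulate import simulate_catalog
from .strands import (
    GeneIndex,
    RepliSeqProfile,
    annotate_catalog_strands,
    derive_replication_strand_map,
    genic_labels,
)
from .timing import split_deciles


@dataclass
class RunConfig:
    """Paths and thresholds of one run; defaults are the published
    method constants."""

    genome: str = ""
    mutations: str = ""
    probabilities: str = ""
    genes: str = ""
    repliseq_wig: str = ""
    repliseq_peaks: str = ""
    repliseq_valleys: str = ""
    feature_tracks: dict = field(default_factory=dict)  # name -> [paths] (datasets)
    out: str = "results"
    seed: int = 0
    n_reps: int = 100
    or_min: float = 1.10
    q_max: float = 0.05
    imd: int = 10000
    prob_cutoff: float = 0.5
    min_mutations: int = 1000
    occupancy_half: int = 1000
    similarity_half: int = 500
    abundance_half: int = 50
    abundance_fold: float = 0.05
    term_trim: int = 25000
    min_stretch: int = 10000

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def echo(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


@dataclass
class LoadedInputs:
    genome: GenomeSequence
    catalog: pd.DataFrame
    probabilities: mio.SignatureProbabilityTable
    genes: pd.DataFrame | None
    gene_index: GeneIndex | None
    repmap: object | None
    deciles: object | None
    tracks: dict
    chrom_lengths: dict


def load_inputs(config: RunConfig) -> LoadedInputs:
    genome = mio.read_fasta(config.genome)
    catalog = mio.read_mutations(config.mutations, dialect="tsv")
    probabilities = mio.read_probabilities(config.probabilities)
    genes = gene_index = repmap = deciles = None
    if config.genes:
        genes = mio.read_genes(config.genes)
        gene_index = GeneIndex(genes)
    if config.repliseq_wig:
        signal = mio.read_signal_track(config.repliseq_wig)
        peaks = mio.read_intervals(config.repliseq_peaks)
        valleys = mio.read_intervals(config.repliseq_valleys)
        profile = RepliSeqProfile(signal=signal, peaks=peaks, valleys=valleys)
        repmap = derive_replication_strand_map(
            profile, min_len=config.min_stretch, term_trim=config.term_trim
        )
        deciles = split_deciles(signal, chrom_order=genome.chrom_names)
    tracks = {
        name: [mio.read_signal_track(p) for p in paths]
        for name, paths in config.feature_tracks.items()
    }
    chrom_lengths = {c: genome.length(c) for c in genome.chrom_names}
    return LoadedInputs(
        genome=genome,
        catalog=catalog,
        probabilities=probabilities,
        genes=genes,
        gene_index=gene_index,
        repmap=repmap,
        deciles=deciles,
        tracks=tracks,
        chrom_lengths=chrom_lengths,
    )


def annotate_all(inputs: LoadedInputs, config: RunConfig):
    """Classified, attributed, strand-annotated real catalog plus the
    simulated replicates annotated the same way (replicates keep the
    real catalog's signature attributions, mutation for mutation)."""
    attributed = classify_catalog(inputs.catalog, inputs.genome)
    attributed = attach_signatures(attributed, inputs.probabilities, cutoff=config.prob_cutoff)
    real = annotate_catalog_strands(attributed, inputs.gene_index, inputs.repmap)

    # simulate from the attributed frame: each replicate row is the same
    # physical mutation re-positioned, so signature/probability columns
    # carry through and only position-dependent columns are recomputed
    sims = simulate_catalog(
        attributed, inputs.genome, n_reps=config.n_reps, seed=config.seed
    )
    sim_annotated = []
    for rep in sims.replicates:
        ann = classify_catalog(rep, inputs.genome)
        ann = annotate_catalog_strands(ann, inputs.gene_index, inputs.repmap)
        sim_annotated.append(ann)
    return real, sim_annotated


def run_asymmetry(real, sims, config: RunConfig, outdir: str) -> dict:
    """Transcription, replication and genic/intergenic families."""
    os.makedirs(outdir, exist_ok=True)
    results = {}
    fam = [
        ("transcription", "tx_label", "TRANSCRIBED", "UNTRANSCRIBED"),
        ("replication", "rep_label", "LAGGING", "LEADING"),
    ]
    real_f = filter_signatures(real, config.min_mutations)
    keep = set(real_f["signature"].unique())
    sims_f = [s[s["signature"].isin(keep)] for s in sims]
    for name, col, a, b in fam:
        if col not in real.columns:
            continue
        table = asym.build_strand_count_table(real_f, sims_f, col, a, b)
        res = asym.detect_asymmetries(table, or_min=config.or_min, q_max=config.q_max)
        mio.write_table(res, os.path.join(outdir, f"asymmetry_{name}.tsv"))
        results[name] = res
    if "tx_label" in real.columns:
        real_g = real_f.copy()
        real_g["region"] = genic_labels(real_g["tx_label"].to_numpy())
        sims_g = []
        for s in sims_f:
            s = s.copy()
            s["region"] = genic_labels(s["tx_label"].to_numpy())
            sims_g.append(s)
        table = asym.build_strand_count_table(real_g, sims_g, "region", "GENIC", "INTERGENIC")
        res = asym.detect_asymmetries(table, or_min=config.or_min, q_max=config.q_max)
        mio.write_table(res, os.path.join(outdir, "asymmetry_genic_intergenic.tsv"))
        results["genic_intergenic"] = res
    return results


def run_scm(real, sims, config: RunConfig, outdir: str) -> pd.DataFrame:
    os.makedirs(outdir, exist_ok=True)
    real_groups = scm_mod.find_scm_groups(real, imd=config.imd, prob_cutoff=config.prob_cutoff)
    real_hist = scm_mod.group_length_histogram(real_groups)
    sim_hists = [
        scm_mod.group_length_histogram(
            scm_mod.find_scm_groups(s, imd=config.imd, prob_cutoff=config.prob_cutoff)
        )
        for s in sims
    ]
    res = scm_mod.test_scm_lengths(real_hist, sim_hists, q_max=config.q_max)
    mio.write_table(res, os.path.join(outdir, "scm.tsv"))
    return res


def run_timing(real, sims, inputs: LoadedInputs, config: RunConfig, outdir: str) -> pd.DataFrame:
    os.makedirs(outdir, exist_ok=True)
    if inputs.deciles is None:
        raise ValueError("timing analysis requires a Repli-seq profile")
    rows = []
    real_f = filter_signatures(real, config.min_mutations)
    for sig, grp in real_f.groupby("signature", sort=True):
        x_real = timing_mod.decile_density(grp, inputs.deciles, inputs.genome)
        rep_vectors = []
        for s in sims:
            sub = s[s["signature"] == sig]
            if len(sub):
                rep_vectors.append(
                    timing_mod.decile_density(sub, inputs.deciles, inputs.genome)
                )
        trend = timing_mod.classify_trend(x_real)
        ens = timing_mod.ensemble_stats(rep_vectors) if len(rep_vectors) >= 2 else None
        row = {"signature": sig, "trend": trend.trend, "slope": trend.slope, "p": trend.p}
        for d in range(10):
            row[f"x{d + 1}"] = x_real.x[d]
        if ens is not None:
            for d in range(10):
                row[f"sim_mean{d + 1}"] = ens.mean[d]
                row[f"sim_sd{d + 1}"] = ens.sd[d]
        rows.append(row)
    res = pd.DataFrame(rows)
    mio.write_table(res, os.path.join(outdir, "timing.tsv"))
    return res


def run_occupancy_abundance(real, sims, inputs: LoadedInputs, config: RunConfig, outdir: str) -> pd.DataFrame:
    os.makedirs(outdir, exist_ok=True)
    rows = []
    real_f = filter_signatures(real, config.min_mutations)
    fold_lo = 1.0 - config.abundance_fold
    fold_hi = 1.0 + config.abundance_fold
    for sig, grp in real_f.groupby("signature", sort=True):
        sim_subs = [s[s["signature"] == sig] for s in sims]
        sim_subs = [s for s in sim_subs if len(s)]
        if len(sim_subs) < 2:
            continue
        for feature, tracks in inputs.tracks.items():
            profile = occ.average_occupancy(
                grp, sim_subs, tracks, half=config.occupancy_half, chrom_lengths=inputs.chrom_lengths
            )
            sim_res = occ.abundance_analysis(
                grp,
                sim_subs,
                tracks,
                half_window=config.occupancy_half,
                half_abundance=config.abundance_half,
                chrom_lengths=inputs.chrom_lengths,
            )
            similarity = occ.occupancy_similarity(
                profile.k_real[0], profile.m_real, half=config.similarity_half
            )
            rows.append(
                {
                    "signature": sig,
                    "feature": feature,
                    "n_mutations": profile.n_mutations,
                    "fold": sim_res["fold"],
                    "p": sim_res["p"],
                    "r": similarity["r"],
                    "r_p": similarity["p"],
                }
            )
    res = pd.DataFrame(rows)
    if len(res):
        res["q"] = asym.bh_adjust(res["p"].to_numpy())
        res["call"] = [
            occ.call_abundance(f, q, fold_min=fold_hi, q_max=config.q_max)
            for f, q in zip(res["fold"], res["q"])
        ]
        res["r_q"] = asym.bh_adjust(res["r_p"].fillna(1.0).to_numpy())
        res["similar"] = (res["r"] >= 0.5) & (res["r_q"] <= config.q_max)
    mio.write_table(res, os.path.join(outdir, "occupancy_abundance.tsv"))
    return res


def run_stratify(real, config: RunConfig, outdir: str) -> pd.DataFrame:
    os.makedirs(outdir, exist_ok=True)
    res = classify_apobec(real)
    mio.write_table(res, os.path.join(outdir, "apobec_classification.tsv"))
    return res


def run_all(config: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the result
    frames and writes the resolved config echo."""
    os.makedirs(config.out, exist_ok=True)
    inputs = load_inputs(config)
    real, sims = annotate_all(inputs, config)
    mio.write_table(real, os.path.join(config.out, "annotated_mutations.tsv"))
    results = {"asymmetry": run_asymmetry(real, sims, config, config.out)}
    results["scm"] = run_scm(real, sims, config, config.out)
    if inputs.deciles is not None:
        results["timing"] = run_timing(real, sims, inputs, config, config.out)
    if inputs.tracks:
        results["occupancy"] = run_occupancy_abundance(real, sims, inputs, config, config.out)
    results["stratification"] = run_stratify(real, config, config.out)
    config.echo(os.path.join(config.out, "resolved_config.json"))
    return results
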