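"""Occupancy profiles and abundance fold changes around mutations.

Plants a 1.5x signal preference within a blocky feature track, then
measures the +/-50 bp abundance fold of real mutations against
simulated backgrounds and the 2,001 bp occupancy profile.
"""

from mutotopo import occupancy as occ
from mutotopo.catalog import attach_signatures, classify_catalog
from mutotopo.simulate import simulate_catalog
from mutotopo.synth import FixtureSpec, SignatureSpec, make_catalog, make_feature_track, make_genome

spec = FixtureSpec(seed=5, chrom_sizes={"chr1": 400_000})
genome = make_genome(spec)
track = make_feature_track(spec, genome, "blocks", low=1.0, high=3.0, block_width=2000, step=10)
spec.signatures = [
    SignatureSpec(
        name="SBS96X",
        n_mutations=1500,
        occupancy={"track": track, "target_fold": 1.5, "high": 3.0, "low": 1.0,
                   "block_width": 2000, "margin": 60},
    )
]
catalog, probs, _ = make_catalog(spec, genome)
real = attach_signatures(classify_catalog(catalog, genome), probs, 0.5)
sims = simulate_catalog(real, genome, n_reps=10, seed=6)
sim_ann = [classify_catalog(r, genome) for r in sims.replicates]

lens = {"chr1": genome.length("chr1")}
res = occ.abundance_analysis(real, sim_ann, [track], chrom_lengths=lens)
call = occ.call_abundance(res["fold"], res["p"])
profile = occ.average_occupancy(real, sim_ann, [track], chrom_lengths=lens)

print(f"abundance fold (real vs simulated +/-50 bp signal): {res['fold']:.3f}")
print(f"z-test p: {res['p']:.3g}  ->  call: {call}")
print(f"occupancy window length: {len(profile.m_real)} positions")
print(f"real center signal {profile.m_real[1000]:.2f} vs simulated {profile.m_sims[1000]:.2f}")
print()
print("A fold >= 1.05 at q <= 0.05 is called ENRICHED (<= 0.95 DEPLETED):")
print("real mutations sit in high-signal blocks 1.5x more than chance.")
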