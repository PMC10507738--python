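"""Strand-coordinated mutagenesis: same-strand mutation runs.

Plants five runs of six consecutive same-channel, same-strand
substitutions within 10 kb spacing, then tests observed run-length
counts against simulated backgrounds.
"""

from mutotopo import scm
from mutotopo.catalog import attach_signatures, classify_catalog
from mutotopo.simulate import simulate_catalog
from mutotopo.synth import FixtureSpec, SignatureSpec, make_catalog, make_genome

spec = FixtureSpec(
    seed=8,
    chrom_sizes={"chr1": 2_000_000},
    signatures=[
        SignatureSpec(
            name="SBS95", n_mutations=100, channel_weights={"T>G": 1.0},
            scm_runs=[(6, 5)], scm_channel="T>G", n_samples=1,
        )
    ],
)
genome = make_genome(spec)
catalog, probs, _ = make_catalog(spec, genome)
real = attach_signatures(classify_catalog(catalog, genome), probs, 0.5)

groups = scm.find_scm_groups(real)
real_hist = scm.group_length_histogram(groups)
print("observed run-length histogram:", dict(real_hist))

sims = simulate_catalog(real, genome, n_reps=10, seed=9)
sim_hists = [
    scm.group_length_histogram(scm.find_scm_groups(classify_catalog(r, genome)))
    for r in sims.replicates
]
res = scm.test_scm_lengths(real_hist, sim_hists)
print(res[res["length"] >= 5][["length", "observed", "sim_mean", "z", "q", "reported"]].to_string(index=False))
print()
print("Runs of length >= 6 appear far more often than in simulations")
print("(large z, q <= 0.05): the footprint of processive single-strand")
print("DNA damage, invisible to per-mutation statistics.")
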