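"""Classify single mutations into SBS-96 / DBS-78 / ID-83 channels.

Builds a toy genome, classifies a few events and prints their channel
labels — the pyrimidine-oriented trinucleotide class for substitutions,
the canonical doublet for DBSs, and the size/repeat/microhomology class
for indels.
"""

from mutotopo import GenomeSequence, Mutation, classify_sbs, classify_dbs, classify_id

genome = GenomeSequence({"chr1": "TTACAGGAATTTTGCC"})

sbs = Mutation("sample1", "chr1", 3, "C", "T")      # context ACA
sbs_purine = Mutation("sample1", "chr1", 5, "G", "A")  # purine ref: flipped
dbs = Mutation("sample1", "chr1", 5, "GG", "AA")
deletion = Mutation("sample1", "chr1", 10, "T", "")  # inside a TTTT run

print("SBS  C>T in ACA          ->", classify_sbs(sbs, genome))
print("SBS  G>A (purine ref)    ->", classify_sbs(sbs_purine, genome))
print("DBS  GG>AA               ->", classify_dbs(dbs))
print("ID   1 bp T deletion     ->", classify_id(deletion, genome))
print()
print("The SBS labels are pyrimidine-centered (purine references are")
print("reverse complemented); the ID label 1:Del:T:3 means a 1 bp T")
print("deletion inside a homopolymer of four T (the deleted base plus")
print("three remaining copies).")
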