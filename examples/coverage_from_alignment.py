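"""Build a coverage matrix from a partitioned alignment.

A toy six-taxon, two-locus nucleotide alignment is scanned against a
RAxML-style partition definition: a locus counts as sampled for a taxon as
soon as one of its sites holds a non-missing character.  The resulting 0/1
matrix drives the density, comprehensive-taxon, and triple-coverage
diagnostics that the terrace and decisiveness machinery consume.
"""

from phyloterrace import (
    comprehensive_taxa,
    coverage_from_alignment,
    decisiveness_conditions,
    parse_raxml_partitions,
    triple_coverage_fraction,
)

alignment = {
    "t1": "ACGTACGTAAAA",
    "t2": "ACGTACGT----",
    "t3": "ACGT----AAAA",
    "t4": "NNNNNNNNTTTT",
    "t5": "ACGTACGTCCCC",
    "t6": "--------GGGG",
}
scheme = parse_raxml_partitions(
    "DNA, locus1 = 1-8\n"
    "DNA, locus2 = 9-12\n"
)

matrix = coverage_from_alignment(alignment, scheme, missing_chars="-?Nn")
print("presence matrix (taxa x loci):")
for taxon, row in zip(matrix.taxa, matrix.presence):
    print(f"   {taxon}: {row.astype(int).tolist()}")
print(f"coverage density d = {matrix.density:.3f}")
print("comprehensive taxa:", comprehensive_taxa(matrix))

triples = triple_coverage_fraction(matrix, mode="exact")
print(f"taxon-triple coverage: {triples.fraction:.3f}")
sufficient, necessary = decisiveness_conditions(matrix)
print(f"fully sampled locus present: {sufficient}")
print(f"all triples covered (necessary condition): {necessary}")

# What the numbers mean: t4's all-N locus1 stretch counts as absent, so t4
# is only sampled for locus2.  No locus samples every taxon and some taxon
# triples are never seen together, so this pattern cannot guarantee a
# unique optimal tree — trees differing in how the never-co-sampled taxa
# arrange can tie.
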