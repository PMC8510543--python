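"""Classify genes of a circular genome by replichore and orientation.

Builds a 100 kb toy genome replicated bidirectionally from position 1
(terminus at 50,001) and shows how strand and replichore combine into the
codirectional (CD) / head-on (HO) call and the transcribed-strand template.
"""

from oriconflict import Gene, GenomeAnnotation, classify_orientation, partition_counts

genome = GenomeAnnotation(
    genome_id="toy",
    length=100_000,
    origin_pos=1,
    sequence="ACGT" * 25_000,
)
print(f"origin at {genome.origin_pos}, terminus at {genome.terminus_pos}\n")

genes = [
    Gene("dnaE_like", 10_000, 13_000, "forward"),   # right replichore
    Gene("mutL_like", 20_000, 22_000, "reverse"),   # right replichore
    Gene("rpoB_like", 70_000, 74_000, "forward"),   # left replichore
    Gene("gyrA_like", 80_000, 82_500, "reverse"),   # left replichore
]
genome.genes.extend(genes)

print(f"{'gene':<10} {'strand':<8} {'replichore':<11} {'orientation':<12} template")
for g in genes:
    call = classify_orientation(g, genome)
    print(f"{g.gene_id:<10} {g.strand:<8} {call.replichore:<11} "
          f"{call.orientation:<12} {call.transcribed_strand_template}")

n_cd, n_ho = partition_counts(genome)
print(f"\n{n_cd} CD and {n_ho} HO genes.")
print("CD genes are transcribed off the leading-strand template (LDST);")
print("HO genes off the lagging-strand template (LGST) — the geometric fact")
print("that lets a replication strand bias masquerade as an orientation bias.")
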