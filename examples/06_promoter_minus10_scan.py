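"""Scan promoters for transitions at the 3' T of a -10 element.

Constructs a promoter whose sense strand carries a perfect TATAAT hexamer
ending 7 nt upstream of the TSS (the classic T-7 position) and checks
whether an A:T transition at that T is called as a -10 element hit.
"""

from oriconflict import GenomeAnnotation, Mutation, Promoter, scan_minus10

seq = list("G" * 200)
seq[118:124] = list("TATAAT")       # sense hexamer, 3' T at position 124
genome = GenomeAnnotation(
    "toy", 200, 1, "".join(seq),
    promoters=[Promoter("pX", tss_pos=131, strand="forward")],
)

transition = Mutation("m1", "exp", "L1", 124, "BPS", "T", "C")
control = Mutation("m2", "exp", "L1", 95, "BPS", "G", "A")  # G:C, ignored

hits = scan_minus10(genome.promoters, [transition, control], genome)
for h in hits:
    print(f"promoter {h.promoter_id} ({h.orientation}): hexamer {h.hexamer} "
          f"({h.matches}/6 match to TATAAT), mutated T {h.distance_to_tss} nt "
          f"upstream of the TSS, T-7 position: {h.is_t_minus7}")

print("\nA hit at T-7 is the signature previously attributed to head-on")
print("replication-transcription collisions in promoters; the scanner")
print("reports each candidate with its promoter's CD/HO orientation.")
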