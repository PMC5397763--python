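"""Detect a planted co-evolving column pair in a two-domain alignment.

Builds two per-domain alignments of 100 sequences in which column 8 of
domain A and column 15 of domain B (concatenated column 40) are coupled
through a fixed residue-to-residue mapping in 90% of the rows, with 5%
gaps sprinkled in.  The mutual-information pipeline (gap filter ->
concatenation -> pseudocounted MI -> average-product correction) should
rank exactly that pair first.
"""

from interlock import predict_coevolving_pairs
from interlock.synthetic_data import CouplingSpec, generate_coupled_msa

msa_a, msa_b, truth = generate_coupled_msa(
    n_seqs=100,
    length_a=25,
    length_b=25,
    couplings=[CouplingSpec(column_pair=(8, 40), strength=0.9)],
    gap_fraction=0.05,
    seed=3,
)

result = predict_coevolving_pairs(msa_a, msa_b, top_n=5)

print("rank  i    j    MI      MIp     class")
for p in result.pairs:
    print(f"{p.rank:<5d} {p.i:<4d} {p.j:<4d} {p.mi:.4f}  {p.mip:+.4f}  {p.pair_class}")
print()
print(f"planted pair: {truth.couplings[0].column_pair}")
# MI is shared background + coupling signal; MIp subtracts the background,
# so the planted pair should stand clear of the noise floor at rank 1.
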