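"""Genome-level vs gene-level ANI on a simulated pair.

Builds an indel-free 200 kb genome pair at 3% per-site divergence, estimates
genome ANI with the fragment-seeded engine, and counts gene-level differences
directly on a 1 kb slice.
"""

from markerani import gene_pair_diff, genome_ani
from markerani.simulate import simulate_genome_pair

a, b, realized = simulate_genome_pair(length=200_000, divergence=0.03, seed=42)
truth = 100 * (1 - realized)

res = genome_ani(a, b)
print(f"true ANI           : {truth:.2f}%")
print(f"fragment-engine ANI: {res.ani:.2f}%  "
      f"(aligned fraction {res.aligned_fraction:.2f}, {res.n_fragments_used} fragments)")

stat = gene_pair_diff(a[:1000], b[:1000])
print(f"gene-style count   : {stat.diffs} diffs / {stat.sites} sites -> ANIg {stat.ani:.2f}%")

# The engine should land within ~0.1 points of the realized divergence; the
# gene-level count is exact by construction on aligned, indel-free input.
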