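"""Generate a reproducible synthetic multi-organism PPI dataset.

The generator emulates the shape of host-pathogen datasets: organism
blocks, sparse within-organism edges, rarer cross-organism edges, and
patchy per-source evidence.  Fixed seed, identical files every run.
"""

from pinetviz import GeneratorSpec, generate, load_dataset

spec = GeneratorSpec(
    n_proteins=50,
    organisms=[("HS", 0.6), ("MTB", 0.4)],
    edge_probability=0.1,
    cross_organism_probability=0.02,
    seed=2024,
)
interactions_tsv, features_tsv, expression_tsv = generate(spec)
dataset = load_dataset(interactions_tsv, features_tsv, expression_tsv)

cross = sum(
    1 for rec in dataset.interactions
    if dataset.proteins[rec.endpoint_a].organism != dataset.proteins[rec.endpoint_b].organism
)
print(f"{len(dataset.proteins)} proteins, {len(dataset.interactions)} interactions "
      f"({cross} host-pathogen), warnings: {len(dataset.warnings)}")
print("first interaction lines:")
print("\n".join(interactions_tsv.splitlines()[:4]))
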