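"""Full inverse-mapping pipeline: impression -> co-clustered spectra.

Latent codes feed a hexagonal self-organizing map; each neuron is
labeled with the union of its member molecules' odor descriptors.
Querying an impression inverse-maps the matching neurons back to
molecules whose spectra cluster there.
"""

from scentmap import (
    AEConfig, GeneratorConfig, SOMConfig, sample_dataset, write_fixture,
)
from scentmap.pipeline import PipelineConfig, run_pipeline, run_query

dataset = sample_dataset(GeneratorConfig(n_molecules=120, n_archetypes=8, seed=3))
paths = write_fixture(dataset, "scratch/example_pipeline/fixture")

config = PipelineConfig(
    spectra_path=paths["spectra"],
    descriptors_path=paths["descriptors"],
    output_dir="scratch/example_pipeline/run",
    ae=AEConfig(epochs=150),
    som=SOMConfig(width=8, height=6, iterations=2000),
    seed=3,
)
result = run_pipeline(config, resume=False)
print(f"map 8x6: quantization error {result.quantization_error:.4f}, "
      f"{result.empty_neurons} empty neurons")

impression = dataset.archetypes[0].descriptors[0]
print(f"\nquery: desired scent impression {impression!r}")
for r in run_query(result, descriptor=impression):
    print(f"  neuron (H={r.neuron[0]}, V={r.neuron[1]}): "
          f"{len(r.member_ids)} co-clustered molecules")
    for m in r.member_ids[:5]:
        print(f"    {m}  descriptors={sorted(r.member_descriptors[m])}")
# Molecules listed under one neuron share similar fragment patterns, so
# any of them is a candidate carrier of the queried impression.
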