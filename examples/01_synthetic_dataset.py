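"""Generate a synthetic odorant dataset and write it as MSP + CSV.

Each molecule descends from a "functional-group archetype": a template
fragment ladder (peaks every 14 m/z, like a CH2 homologous series) plus
2-4 odor descriptors that overlap between neighboring archetypes.
"""

from scentmap import GeneratorConfig, sample_dataset, write_fixture

config = GeneratorConfig(n_molecules=60, n_archetypes=6, seed=42)
dataset = sample_dataset(config)
paths = write_fixture(dataset, "scratch/example_fixture")

print(f"molecules: {len(dataset.spectra)}")
print(f"descriptor vocabulary: {dataset.table.descriptor_names}")
for arch in dataset.archetypes:
    mzs = [mz for mz, _ in arch.template]
    print(f"archetype {arch.archetype_id}: ladder {mzs[0]}..{mzs[-1]} "
          f"step 14, descriptors {arch.descriptors}")
print(f"files: {sorted(paths.values())}")
# The first descriptor of each archetype is its signature impression;
# later examples query it to recover the archetype's molecules.
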