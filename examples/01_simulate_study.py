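"""Generate a small synthetic study and look at what it contains.

The generator builds a labelled single-cell reference, renders toy H&E-like
patches with known nucleus counts, and creates spot labels as the IE prior
plus a morphology-linked signal plus gene noise.
"""

import numpy as np

from scist.simulate import SimConfig, generate_study, save_study

cfg = SimConfig(n_genes=30, n_sections=2, spots_per_section=50,
                patch_size=64, seed=11)
study = generate_study(cfg)
ds = study.dataset

print(f"sections: {ds.sections}")
print(f"spots: {len(ds)}, genes: {len(ds.genes)}, "
      f"patches: {ds.patches.shape}")
print(f"reference cell types: {list(study.refs.cell_types)}")
first = ds.counts[0]
print(f"first spot {first.patch_id!r} nucleus counts: {first.counts}")
print(f"label vs IE mean abs difference: "
      f"{np.abs(ds.labels - ds.ie).mean():.3f} "
      f"(morphology signal + noise on the log1p scale)")

save_study(study, "scratch/example_study")
print("study written to scratch/example_study/ "
      "(spots.tsv, MTX counts, PNG patches, segmentation.tsv, reference)")
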