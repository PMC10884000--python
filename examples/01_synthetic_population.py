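"""Generate a synthetic fetal-face cohort and inspect its ground truth.

The generator draws open face-like surface meshes whose size follows a
quadratic growth curve over 24-34 gestational weeks, whose shape varies along
two smooth latent momenta modes, and whose momenta drift linearly with age.
"""

import numpy as np

import fetalmorph as fm

spec = fm.SyntheticPopulationSpec(n_subjects=30, seed=7, group_fraction=0.15)
sample = fm.sample_population(spec)

print(sample.metadata.head())
print()
sizes = np.array([fm.face_size(m) for m in sample.meshes])
print(f"surrogate size range: {sizes.min():.1f} - {sizes.max():.1f} mm")
print(f"correlation with recorded truth: {np.corrcoef(sizes, sample.metadata.true_size)[0, 1]:.4f}")
n_fgr = (sample.metadata.group == "FGR").sum()
print(f"{n_fgr} growth-restricted subjects out of {spec.n_subjects}")

# The size range spans the growth between 24 and 34 weeks (~50 to ~70 mm of
# surrogate size); the near-unit correlation shows the generator's recorded
# true size is exactly what the size surrogate measures on the meshes.
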