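"""Estimate a shape atlas on a small cohort and inspect its principal modes.

The atlas alternates varifold-metric registrations of the template to each
subject with a template update; statistics then live in the momenta
parameterisation (3 vectors per control point).
"""

import numpy as np

import fetalmorph as fm
from fetalmorph.atlas import (
    estimate_atlas, filter_control_points, init_control_points, reconstruction_error,
)
from fetalmorph.stats import mode_visualization_meshes, pca_momenta

sample = fm.sample_population(
    fm.SyntheticPopulationSpec(n_subjects=6, seed=2, template_resolution=(16, 18))
)
config = fm.KernelConfig(lambda_V=10.0, lambda_W=7.0)
cps = init_control_points(sample.meshes, 15.0)
template, _ = fm.make_template_face(16, 18)

atlas = estimate_atlas(sample.meshes, cps, config, template, n_outer_iters=3)
print("outer-iteration energies:", [f"{e:.0f}" for e in atlas.energy_trace])
atlas = filter_control_points(atlas)
print(f"{len(atlas.cps)} control points kept -> D = {3 * len(atlas.cps)} shape parameters")

errors, summary = reconstruction_error(atlas, sample.meshes)
print(f"reconstruction error: mean {summary['mean']:.2f} mm, max {summary['max']:.2f} mm")

pca = pca_momenta(atlas.momenta_matrix(), n_modes=3)
print("explained variance fractions:", np.round(pca.explained_fractions, 3))
minus, plus = mode_visualization_meshes(atlas, pca, 0, sd_multiples=[-2, 2])
span = np.linalg.norm(plus.vertices - minus.vertices, axis=1).max()
print(f"mode 1 at +/-2 SD moves vertices by up to {span:.1f} mm")

# Energies decrease monotonically (the estimation converges); the mean
# reconstruction error sits near the generator's 0.2 mm vertex noise, and the
# leading PCA mode carries most of the induced shape variance.
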