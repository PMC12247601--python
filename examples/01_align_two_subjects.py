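"""Align one subject's voxel space to another's using shared stimuli.

Generates a synthetic subject pair whose responses differ by a hidden
scaled rotation, fits all three alignment models on the common stimuli,
and reports how well each one maps the source onto the target.
"""

import numpy as np

from brainalign import (
    SyntheticConfig,
    apply_alignment,
    fit_anatomical,
    fit_procrustes,
    fit_ridge_alignment,
    generate_multisubject,
    match_common,
)

ds = generate_multisubject(
    SyntheticConfig(n_stimuli=600, n_common=200, k=8, v=40,
                    noise_sd=0.2, mode="orthogonal", seed=0)
)
pair = match_common(ds.source, ds.target)
print(f"{pair.n_stimuli} common stimuli, {pair.source.n_voxels} voxels per subject\n")

models = {
    "anatomical": fit_anatomical(pair),
    "procrustes": fit_procrustes(pair),
    "ridge": fit_ridge_alignment(pair, seed=0),
}
print("relative alignment error on the common set (|aligned - target| / |target|):")
for name, model in models.items():
    aligned = apply_alignment(model, pair.source)
    err = np.linalg.norm(aligned.betas - pair.target.betas) / np.linalg.norm(
        pair.target.betas
    )
    extra = ""
    if name == "procrustes":
        extra = f"  (recovered scale c = {model.c:.3f}; planted c0 = 1.7)"
    if name == "ridge":
        extra = f"  (cross-validated alpha = {model.alpha:g})"
    print(f"  {name:<11} {err:.4f}{extra}")

print(
    "\nThe identity baseline cannot undo the rotation (error near 1), while"
    "\nboth functional methods recover the map up to the noise floor."
)
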