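"""Decode a second subject's brain activity with a decoder it never saw.

Trains a linear decoder on the target subject's unique stimuli, aligns
the source subject into the target's voxel space with ridge regression,
and scores the decoded embeddings and rendered images of the source.
"""

from brainalign import (
    SyntheticConfig,
    apply_alignment,
    fit_linear_decoder,
    fit_ridge_alignment,
    generate_multisubject,
    match_common,
    predict_embeddings,
    render_images,
    evaluate_reconstruction,
)

import numpy as np

ds = generate_multisubject(SyntheticConfig(seed=1))  # 400 common, 60 voxels, noise 0.5
common = ds.common_ids
decoder_train = np.setdiff1d(ds.target.stimulus_ids, common)

decoder = fit_linear_decoder(
    ds.target.subset(decoder_train), ds.embeddings.subset(decoder_train), alpha=10.0
)
print(f"decoder trained on {len(decoder_train)} target-unique stimuli")

pair = match_common(ds.source, ds.target)
model = fit_ridge_alignment(pair, seed=0)
print(f"ridge alignment fitted on {pair.n_stimuli} common stimuli (alpha={model.alpha:g})")

aligned = apply_alignment(model, ds.source.subset(common))
pred = predict_embeddings(decoder, aligned)
report = evaluate_reconstruction(
    render_images(pred, ds.renderer),
    render_images(ds.embeddings.subset(common), ds.renderer),
    pred_embeddings=pred.E,
    true_embeddings=ds.embeddings.subset(common).E,
)
for name, value in report.as_dict().items():
    print(f"  {name:<16} {value:.4f}")
print(
    "\nPixCorr/SSIM compare rendered images pixel-wise; the 2-way scores are"
    "\nthe fraction of pairwise trials where a decoded stimulus is closer to"
    "\nits own ground truth than to a distractor (0.5 = chance, 1.0 = perfect)."
)
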