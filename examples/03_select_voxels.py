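"""Rank voxels by class-aware Laplacian score on a phantom cohort.

Each survival class's subjects form their own similarity graph; voxels whose
intensities vary smoothly over that graph (low Laplacian score) are retained.
Planted lesion voxels carry a per-subject severity gradient, so they are the
locality-preserving features and should dominate the top of the ranking.
"""

import numpy as np

from petsurv import assemble_features, class_aware_ranking, gaussian_smooth, normalize_whole_brain
from petsurv.synthetic import default_phantom_config, generate_cohort, generate_phantom_volumes

config = default_phantom_config()
cohort = generate_cohort("clustered", n=config.n_subjects, seed=config.seed)
phantom = generate_phantom_volumes(config, cohort)
volumes = [
    normalize_whole_brain(gaussian_smooth(v, 10.0, mask=phantom.mask), phantom.mask)
    for v in phantom.volumes
]
features = assemble_features(volumes, phantom.mask)
labels = cohort["true_class"].to_numpy()

for c in (1, 2, 3):
    ranking = class_aware_ranking(features, labels, c, m=400)
    truth = np.flatnonzero(phantom.class_lesion_masks[c][phantom.mask.data])
    selected = set(ranking.selected.tolist())
    recall = np.mean([v in selected for v in truth])
    print(
        f"class {c}: {truth.size:4d} planted voxels, "
        f"recall in top-400 = {recall:.2f}, "
        f"best score = {ranking.scores[ranking.order[0]]:.4f}"
    )
# Recall near 1 means the unsupervised ranking rediscovers the planted
# class-specific lesions without ever seeing the ground truth.
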