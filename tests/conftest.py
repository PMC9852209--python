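import sys
import warnings
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from petsurv.laplacian import class_aware_ranking
from petsurv.preproc import assemble_features, gaussian_smooth, normalize_whole_brain
from petsurv.synthetic import (
    default_phantom_config,
    generate_cohort,
    generate_phantom_volumes,
)


@pytest.fixture(scope="session")
def default_phantom():
    """The default phantom cohort, preprocessed once for the whole session.

    Volumes are smoothed with the standard 10-mm kernel and normalized to the
    whole-brain mean before the feature matrix is assembled, mirroring the
    pipeline's preprocessing order.
    """
    cfg = default_phantom_config()
    cohort = generate_cohort("clustered", n=cfg.n_subjects, seed=cfg.seed)
    result = generate_phantom_volumes(cfg, cohort)
    volumes = [
        normalize_whole_brain(gaussian_smooth(v, 10.0, mask=result.mask), result.mask)
        for v in result.volumes
    ]
    fm = assemble_features(volumes, result.mask)
    return SimpleNamespace(
        config=cfg,
        cohort=cohort,
        result=result,
        volumes=volumes,
        fm=fm,
        labels=cohort["true_class"].to_numpy(),
    )


@pytest.fixture(scope="session")
def phantom_rankings(default_phantom):
    """Class-aware top-400 rankings on the full phantom cohort."""
    ph = default_phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            c: class_aware_ranking(ph.fm, ph.labels, c, m=400) for c in (1, 2, 3)
        }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
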