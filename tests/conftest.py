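import numpy as np
import pytest

import mi_esi as m


@pytest.fixture(scope="session")
def montage():
    return m.default_montage()


@pytest.fixture(scope="session")
def atlas():
    return m.default_atlas()


@pytest.fixture(scope="session")
def forward(montage, atlas):
    """Shared small forward model: 4 sources/patch + 30 background sources."""
    positions, labels, atlas_m = m.place_sources(atlas, sources_per_patch=4,
                                                 n_background=30, seed=42)
    lf = m.build_spherical_leadfield(montage, positions, labels)
    return montage, atlas_m, lf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_epochs(rng, n_per_class=20, n_ch=6, n_samples=60, scale=None):
    """Two-class random-covariance epochs for CSP/classifier tests."""
    if scale is None:
        d = np.array([2.0, 1.5, 1.0, 0.7, 0.45, 0.25])
        scale = (np.diag(d), np.diag(d[::-1]))
    trials = []
    for cls, A in zip((m.RIGHT_HAND, m.RIGHT_FOOT), scale):
        for _ in range(n_per_class):
            D = A[:n_ch, :n_ch] @ rng.standard_normal((n_ch, n_samples))
            trials.append(m.Trial(D, cls, 100.0, [f"ch{i}" for i in range(n_ch)]))
    split = np.array([True] * n_per_class + [True] * n_per_class)
    return m.EpochSet(trials, split)
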