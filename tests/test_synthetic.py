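"""Spherical lead field and the synthetic ERD generator."""

import numpy as np
import pytest

import mi_esi as m
from mi_esi.preprocess import bandpass
from mi_esi.synthetic import _dipole_potential_series


def symmetric_montage(n_ring=8):
    """A left/right mirror-symmetric montage for symmetry oracles."""
    pos = [(0.0, 0.0, 1.0)]
    for z in (0.2, 0.6):
        r = np.sqrt(1 - z**2)
        for k in range(n_ring):
            th = 2 * np.pi * k / n_ring + np.pi / n_ring  # no electrode on x=0
            pos.append((r * np.cos(th), r * np.sin(th), z))
    pos = np.array(pos)
    names = [f"e{i}" for i in range(len(pos))]
    return m.Montage(names, pos)


class TestLeadField:
    def test_center_source_not_singular(self):
        mont = symmetric_montage()
        lf = m.build_spherical_leadfield(mont, np.zeros((1, 3)))
        assert np.all(np.isfinite(lf.gain))
        # center limit is the uniform-field solution, oriented +z
        expected = 3 / (4 * np.pi) * mont.positions[:, 2]
        assert np.allclose(lf.gain[:, 0], expected / np.linalg.norm(expected), atol=1e-12)

    def test_mirror_symmetric_sources(self):
        mont = symmetric_montage()
        src = np.array([[0.3, 0.2, 0.5], [-0.3, 0.2, 0.5]])
        lf = m.build_spherical_leadfield(mont, src)
        # mirror each electrode across x=0 and compare gain columns
        mirrored = mont.positions * np.array([-1.0, 1.0, 1.0])
        perm = [int(np.argmin(np.linalg.norm(mont.positions - p, axis=1)))
                for p in mirrored]
        assert np.allclose(lf.gain[perm, 0], lf.gain[:, 1], atol=1e-9)

    def test_source_on_or_outside_sphere_rejected(self):
        mont = symmetric_montage()
        with pytest.raises(m.GeometryError):
            m.build_spherical_leadfield(mont, np.array([[0.0, 0.0, 1.0]]))
        with pytest.raises(m.GeometryError):
            m.build_spherical_leadfield(mont, np.array([[0.0, 0.0, 1.5]]))

    def test_off_sphere_montage_rejected(self):
        mont = symmetric_montage()
        scaled = m.Montage(mont.electrode_names, mont.positions)  # copy
        scaled.positions = mont.positions * 2.0  # bypass montage validation
        with pytest.raises(m.GeometryError):
            m.build_spherical_leadfield(scaled, np.zeros((1, 3)))

    def test_series_converged(self):
        mont = symmetric_montage()
        src = np.array([[0.3, 0.2, 0.75]])  # radius ~0.85, the atlas depth
        a = _dipole_potential_series(mont.positions, src[0], src[0] / np.linalg.norm(src[0]), 60)
        b = _dipole_potential_series(mont.positions, src[0], src[0] / np.linalg.norm(src[0]), 150)
        assert np.max(np.abs(a - b)) / np.max(np.abs(b)) < 1e-3

    def test_unit_norm_columns_and_roi_lookup(self, forward):
        _, atlas, lf = forward
        assert np.allclose(np.linalg.norm(lf.gain, axis=0), 1.0, atol=1e-12)
        assert len(lf.sources_in("M1HL")) == 4
        assert len(lf.sources_in("background")) == 30
        assert lf.n_sensors == 118

    def test_membership_covers_all_patches(self, forward):
        _, atlas, lf = forward
        for region in atlas.names:
            idx = atlas.sources_of(region)
            assert np.all(np.asarray(lf.source_roi[idx]) == region)


def small_forward(montage, atlas, n_background=10):
    pos, labels, atlas_m = m.place_sources(atlas, sources_per_patch=2,
                                           n_background=n_background, seed=7)
    return m.build_spherical_leadfield(montage, pos, labels), atlas_m


class TestGenerator:
    def test_same_seed_bit_identical(self, montage, atlas):
        lf, _ = small_forward(montage, atlas)
        cfg = m.GeneratorConfig(n_trials_per_class=3, seed=99)
        a, _ = m.generate_epochs(cfg, lf)
        b, _ = m.generate_epochs(cfg, lf)
        for ta, tb in zip(a.trials, b.trials):
            assert np.array_equal(ta.data, tb.data)

    def test_trial_geometry_and_labels(self, montage, atlas):
        lf, _ = small_forward(montage, atlas)
        cfg = m.GeneratorConfig(n_trials_per_class=4, seed=1)
        eps, truth = m.generate_epochs(cfg, lf)
        assert len(eps) == 8
        assert eps.trials[0].data.shape == (118, 350)
        assert eps.labels.count(m.RIGHT_HAND) == 4
        assert truth.active_patch == ["M1HL" if l == m.RIGHT_HAND else "M1FL"
                                      for l in eps.labels]

    def test_no_effect_null_band_power(self, montage, atlas):
        """erd_attenuation = 1: class-conditional mu band power of the
        hand-patch sensor projection is equal across classes."""
        lf, _ = small_forward(montage, atlas)
        cfg = m.GeneratorConfig(n_trials_per_class=30, erd_attenuation=1.0,
                                snr=10.0, seed=3)
        eps, _ = m.generate_epochs(cfg, lf)
        w = lf.gain[:, lf.sources_in("M1HL")].mean(axis=1)
        w /= np.linalg.norm(w)
        powers = {c: [] for c in (m.RIGHT_HAND, m.RIGHT_FOOT)}
        for t in eps.trials:
            proj = bandpass(w @ t.data[None].squeeze(0), t.fs)[50:250]
            powers[t.label].append(np.mean(proj**2))
        ratio = np.mean(powers[m.RIGHT_HAND]) / np.mean(powers[m.RIGHT_FOOT])
        assert ratio == pytest.approx(1.0, rel=0.15)

    def test_attenuation_squared_power_ratio(self, montage, atlas):
        """Oracle on the generated ground-truth sources: the imagery-window
        band-power ratio between classes in the hand patch is attenuation^2."""
        lf, _ = small_forward(montage, atlas)
        att = 0.3
        cfg = m.GeneratorConfig(n_trials_per_class=50, erd_attenuation=att,
                                snr=10.0, seed=4)
        eps, truth = m.generate_epochs(cfg, lf, store_sources=True)
        hand = lf.sources_in("M1HL")
        win = slice(60, 240)  # inside the imagery interval, past the ramps
        p = {c: [] for c in (m.RIGHT_HAND, m.RIGHT_FOOT)}
        for i, t in enumerate(eps.trials):
            p[t.label].append(np.mean(truth.source_tc[i][hand][:, win] ** 2))
        ratio = np.mean(p[m.RIGHT_HAND]) / np.mean(p[m.RIGHT_FOOT])
        assert ratio == pytest.approx(att**2, rel=0.2)

    def test_snr_power_ratio(self, montage, atlas):
        lf, _ = small_forward(montage, atlas)
        cfg = m.GeneratorConfig(n_trials_per_class=50, snr=5.0, seed=5)
        eps, truth = m.generate_epochs(cfg, lf, store_clean=True)
        data = eps.data_array()
        noise = data - truth.clean_sensor
        ratio = np.mean(noise**2) / np.mean(truth.clean_sensor**2)
        assert ratio == pytest.approx(1.0 / 5.0, rel=0.05)

    def test_missing_base_patch_rejected(self, montage):
        pos = np.array([[0.1, 0.0, 0.5], [0.0, 0.1, 0.5]])
        lf = m.build_spherical_leadfield(montage, pos, ["background", "background"])
        with pytest.raises(m.ConfigurationError):
            m.generate_epochs(m.GeneratorConfig(n_trials_per_class=2), lf)

    def test_invalid_config_rejected(self):
        with pytest.raises(m.ConfigurationError):
            m.GeneratorConfig(erd_attenuation=1.5)
        with pytest.raises(m.ConfigurationError):
            m.GeneratorConfig(snr=0.0)


class TestSplits:
    @pytest.mark.parametrize("subject,n_train,n_test",
                             [("aa", 168, 112), ("al", 224, 56), ("av", 84, 196),
                              ("aw", 56, 224), ("ay", 28, 252)])
    def test_per_subject_counts(self, subject, n_train, n_test):
        trials = [m.Trial(np.zeros((2, 4)), m.RIGHT_HAND if i % 2 == 0 else m.RIGHT_FOOT,
                          100.0, ["a", "b"]) for i in range(280)]
        eps = m.EpochSet(trials, np.zeros(280, bool))
        out = m.make_table1_splits(eps, subject)
        assert int(out.split.sum()) == n_train
        assert int((~out.split).sum()) == n_test
        assert len(out) == 280
        # class-balanced as far as parity allows
        train_labels = [t.label for t, s in zip(out.trials, out.split) if s]
        assert abs(train_labels.count(m.RIGHT_HAND)
                   - train_labels.count(m.RIGHT_FOOT)) <= 1

    def test_unknown_subject_rejected(self):
        trials = [m.Trial(np.zeros((2, 4)), m.RIGHT_HAND, 100.0, ["a", "b"])
                  for _ in range(280)]
        with pytest.raises(m.ConfigurationError):
            m.make_table1_splits(m.EpochSet(trials, np.zeros(280, bool)), "zz")

    def test_too_few_trials_rejected(self):
        trials = [m.Trial(np.zeros((2, 4)), m.RIGHT_HAND, 100.0, ["a", "b"])
                  for _ in range(10)]
        with pytest.raises(m.ConfigurationError):
            m.make_table1_splits(m.EpochSet(trials, np.zeros(10, bool)), "aa")
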