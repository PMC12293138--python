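"""Synthetic source-space motor-imagery EEG with known ground truth.

The generator emulates two-class (right hand vs right foot) cued motor
imagery recorded by a spherical-head EEG montage. Event-related
desynchronization (ERD) is modeled as amplitude attenuation of a mu-band
oscillation in the contralateral primary motor patch during the imagery
interval: hand imagery attenuates the left hand motor area (M1HL), foot
imagery the left foot motor area (M1FL), while the other patch keeps its
baseline amplitude. All remaining cortical patches and a set of free
background sources carry 1/f-shaped noise, and white sensor noise is added
at a configured signal-to-noise power ratio. Every draw flows from one seed,
so a fixed seed reproduces the dataset bit for bit.

The forward model is the classical Legendre-series potential of a current
dipole inside a homogeneous conducting unit sphere; gain columns are scaled
to unit norm, so absolute source units are arbitrary and only amplitude
ratios matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import eval_legendre, lpmv

from .core_io import (RIGHT_FOOT, RIGHT_HAND, ConfigurationError, EpochSet,
                      Montage, Trial)
from .roi import RoiAtlas


class GeometryError(ValueError):
    """Source/sensor geometry violates the spherical head model."""


# ---------------------------------------------------------------------------
# lead field


@dataclass
class LeadField:
    """Sensors x sources gain matrix with per-source ROI membership."""

    gain: np.ndarray
    source_positions: np.ndarray  # n_sources x 3, strictly inside unit sphere
    source_roi: np.ndarray  # region name or "background" per source
    source_orientations: np.ndarray | None = None
    electrode_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.source_positions = np.asarray(self.source_positions, dtype=float)
        self.source_roi = np.asarray(self.source_roi, dtype=object)
        if self.gain.shape[1] != self.source_positions.shape[0]:
            raise ValueError("gain column count must equal the number of sources")
        if self.gain.shape[1] != self.source_roi.shape[0]:
            raise ValueError("one ROI label per source required")
        if np.any(np.linalg.norm(self.gain, axis=0) == 0):
            raise ValueError("lead field contains an all-zero column")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]

    def sources_in(self, roi: str) -> np.ndarray:
        return np.flatnonzero(self.source_roi == roi)

    def restrict(self, sensor_indices: np.ndarray, names: list[str] | None = None) -> "LeadField":
        """Lead field seen by a sensor subset (plain row selection, so the
        physics stays consistent with data generated at the full montage)."""
        idx = np.asarray(sensor_indices, dtype=int)
        return LeadField(self.gain[idx], self.source_positions, self.source_roi,
                         self.source_orientations, names or
                         [self.electrode_names[i] for i in idx] if self.electrode_names else [])


def _dipole_potential_series(electrodes: np.ndarray, position: np.ndarray,
                             orientation: np.ndarray, n_terms: int) -> np.ndarray:
    """Surface potential of a current dipole in a homogeneous unit sphere.

    Classical expansion in Legendre polynomials: for a dipole at distance b
    from the center with radial moment m_r and tangential moment m_t (in the
    plane spanned by the dipole position and the observation point),

        phi = (1/4*pi*sigma) * sum_n ((2n+1)/n) * b^(n-1)
              * [ n*m_r*P_n(u) + m_t*P_n^1(u) ]

    with u the cosine of the angle between dipole position and electrode and
    P_n^1 the associated Legendre function without the Condon-Shortley phase.
    The b -> 0 limit is the uniform-field solution 3*(q . r)/(4*pi*sigma),
    so a source at the center is not singular.
    """
    q = np.asarray(orientation, dtype=float)
    b = float(np.linalg.norm(position))
    const = 1.0 / (4.0 * np.pi)
    if b < 1e-12:
        return 3.0 * const * (electrodes @ q)
    bhat = position / b
    u = np.clip(electrodes @ bhat, -1.0, 1.0)
    m_r = float(q @ bhat)
    t_full = q - m_r * bhat
    # unit tangential direction from the dipole axis toward each electrode
    t_dir = electrodes - u[:, None] * bhat
    t_norm = np.linalg.norm(t_dir, axis=1)
    safe = t_norm > 1e-12
    t_dir[safe] /= t_norm[safe, None]
    t_dir[~safe] = 0.0
    m_t = t_dir @ t_full

    phi = np.zeros(len(electrodes))
    for n in range(1, n_terms + 1):
        cn = (2 * n + 1) / n * b ** (n - 1)
        pn = eval_legendre(n, u)
        pn1 = -lpmv(1, n, u)  # strip the Condon-Shortley phase
        phi += cn * (n * m_r * pn + m_t * pn1)
    return const * phi


def build_spherical_leadfield(montage: Montage, source_positions: np.ndarray,
                              source_roi: Sequence[str] | None = None,
                              orientations: np.ndarray | None = None,
                              n_terms: int = 60) -> LeadField:
    """Analytic single-shell gain matrix for sources inside the unit sphere.

    Orientation defaults to radial (outward) per source; a source at the
    center gets the +z orientation. Columns are scaled to unit norm.
    """
    electrodes = np.asarray(montage.positions, dtype=float)
    if not np.allclose(np.linalg.norm(electrodes, axis=1), 1.0, atol=1e-6):
        raise GeometryError("montage positions must lie on the unit sphere")
    pos = np.atleast_2d(np.asarray(source_positions, dtype=float))
    radii = np.linalg.norm(pos, axis=1)
    if np.any(radii >= 1.0 - 1e-9):
        bad = np.flatnonzero(radii >= 1.0 - 1e-9)
        raise GeometryError(f"sources must be strictly inside the unit sphere: indices {bad.tolist()}")
    if orientations is None:
        orientations = np.where(radii[:, None] > 1e-12,
                                pos / np.maximum(radii[:, None], 1e-12),
                                np.array([0.0, 0.0, 1.0]))
    orientations = np.atleast_2d(np.asarray(orientations, dtype=float))
    orientations = orientations / np.linalg.norm(orientations, axis=1, keepdims=True)

    gain = np.empty((len(electrodes), len(pos)))
    for j in range(len(pos)):
        gain[:, j] = _dipole_potential_series(electrodes, pos[j], orientations[j], n_terms)
    norms = np.linalg.norm(gain, axis=0)
    if np.any(norms == 0):
        raise GeometryError("a source produced an all-zero gain column")
    gain /= norms
    roi = np.asarray(source_roi if source_roi is not None else ["background"] * len(pos),
                     dtype=object)
    return LeadField(gain, pos, roi, orientations, list(montage.electrode_names))


def place_sources(atlas: RoiAtlas, sources_per_patch: int = 6,
                  n_background: int = 50, patch_radius: float = 0.1,
                  seed: int = 0) -> tuple[np.ndarray, list[str], RoiAtlas]:
    """Place dipole sources on the atlas patches plus free background sources.

    Each patch gets ``sources_per_patch`` dipoles on a small spherical cap
    around its center (deterministic ring layout); background sources are
    drawn at random directions and depths from the seed. Returns positions,
    per-source labels, and a copy of the atlas with membership filled in.
    """
    positions: list[np.ndarray] = []
    labels: list[str] = []
    membership: dict[str, np.ndarray] = {}
    for region in atlas.regions:
        c = region.center
        r = np.linalg.norm(c)
        d = c / r
        # tangent basis at the patch center
        ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(d, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        idx0 = len(positions)
        for k in range(sources_per_patch):
            if k == 0:
                direction = d
            else:
                theta = 2.0 * np.pi * (k - 1) / max(sources_per_patch - 1, 1)
                direction = (d * np.cos(patch_radius)
                             + (e1 * np.cos(theta) + e2 * np.sin(theta)) * np.sin(patch_radius))
            positions.append(direction / np.linalg.norm(direction) * r)
            labels.append(region.name)
        membership[region.name] = np.arange(idx0, len(positions))

    rng = np.random.default_rng(seed)
    for _ in range(n_background):
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        positions.append(v * rng.uniform(0.3, 0.8))
        labels.append("background")
    atlas_with_members = RoiAtlas(list(atlas.regions), membership)
    return np.asarray(positions), labels, atlas_with_members


# ---------------------------------------------------------------------------
# generator


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic subject.

    280 trials (140 per class) at 100 Hz match the real recordings' per-subject
    totals; trials are 3.5 s long with the cue at t = 0 and the imagery
    interval covering 0.5-2.5 s. ``erd_attenuation`` multiplies the mu
    amplitude of the class-relevant patch during imagery (1 = no effect,
    0 = complete desynchronization); ``snr`` is the sensor-level
    signal-to-noise power ratio.
    """

    n_trials_per_class: int = 140
    fs: float = 100.0
    trial_length: float = 3.5
    mu_freq: float = 10.0
    erd_attenuation: float = 0.4
    snr: float = 5.0
    n_background_sources: int = 50
    background_rms: float = 0.5  # background-source RMS relative to mu amplitude 1
    imagery_window: tuple[float, float] = (0.5, 2.5)
    sensor_scale_uv: float = 10.0  # nominal sensor amplitude scale, µV
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_attenuation <= 1.0:
            raise ConfigurationError("erd_attenuation must be in [0, 1]")
        if not self.snr > 0:
            raise ConfigurationError("snr must be positive")
        if not self.fs > 0:
            raise ConfigurationError("fs must be positive")


@dataclass
class GroundTruth:
    """Per-trial generative state returned alongside the epochs."""

    active_patch: list[str]  # the patch attenuated in each trial
    mu_phases: np.ndarray  # n_trials x n_mu_sources
    source_tc: np.ndarray | None = None  # n_trials x n_sources x n_samples
    clean_sensor: np.ndarray | None = None  # noise-free sensor data


def _one_over_f_noise(rng: np.random.Generator, n_series: int, n_samples: int,
                      fs: float, rms: float) -> np.ndarray:
    """1/f-power-shaped noise via spectral shaping of white noise."""
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(freqs, 1.0))  # flat below 1 Hz
    shape[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * shape, n=n_samples, axis=-1)
    cur = shaped.std(axis=-1, keepdims=True)
    cur[cur == 0] = 1.0
    return shaped * (rms / cur)


def _erd_envelope(t: np.ndarray, window: tuple[float, float],
                  attenuation: float, ramp: float = 0.1) -> np.ndarray:
    """Amplitude envelope: 1 at baseline, ``attenuation`` during imagery,
    raised-cosine ramps of ``ramp`` seconds at the transitions."""
    w = np.zeros_like(t)
    lo, hi = window
    inside = (t >= lo + ramp) & (t <= hi - ramp)
    w[inside] = 1.0
    rise = (t >= lo) & (t < lo + ramp)
    w[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - lo) / ramp))
    fall = (t > hi - ramp) & (t <= hi)
    w[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - (hi - ramp)) / ramp))
    return 1.0 - (1.0 - attenuation) * w


def generate_epochs(config: GeneratorConfig, leadfield: LeadField,
                    store_sources: bool = False,
                    store_clean: bool = False) -> tuple[EpochSet, GroundTruth]:
    """Generate a two-class synthetic epoch set from the lead field.

    Hand trials attenuate the mu oscillation of the M1HL sources during the
    imagery window while M1FL stays at baseline, and vice versa for foot
    trials; all other labeled patches and the background sources carry
    1/f-shaped noise. Sensor data are gain x sources plus white sensor noise
    whose power is signal power / snr. Deterministic under a fixed seed.
    """
    hand_idx = leadfield.sources_in("M1HL")
    foot_idx = leadfield.sources_in("M1FL")
    if len(hand_idx) == 0 or len(foot_idx) == 0:
        raise ConfigurationError("lead field must contain sources labeled M1HL and M1FL")
    mu_idx = np.concatenate([hand_idx, foot_idx])
    noise_idx = np.setdiff1d(np.arange(leadfield.n_sources), mu_idx)

    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.trial_length * config.fs))
    t = np.arange(n_samples) / config.fs
    n_trials = 2 * config.n_trials_per_class
    labels = [RIGHT_HAND if i % 2 == 0 else RIGHT_FOOT for i in range(n_trials)]

    env_att = _erd_envelope(t, config.imagery_window, config.erd_attenuation)
    omega = 2.0 * np.pi * config.mu_freq

    trials: list[Trial] = []
    active: list[str] = []
    all_phases = np.empty((n_trials, len(mu_idx)))
    src_store = (np.empty((n_trials, leadfield.n_sources, n_samples))
                 if store_sources else None)
    clean_store = (np.empty((n_trials, leadfield.n_sensors, n_samples))
                   if store_clean else None)

    for i, label in enumerate(labels):
        S = np.zeros((leadfield.n_sources, n_samples))
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(mu_idx))
        all_phases[i] = phases
        osc = np.sin(omega * t[None, :] + phases[:, None])
        n_hand = len(hand_idx)
        osc_hand, osc_foot = osc[:n_hand], osc[n_hand:]
        if label == RIGHT_HAND:
            S[hand_idx] = osc_hand * env_att[None, :]
            S[foot_idx] = osc_foot
        else:
            S[hand_idx] = osc_hand
            S[foot_idx] = osc_foot * env_att[None, :]
        if len(noise_idx):
            S[noise_idx] = _one_over_f_noise(rng, len(noise_idx), n_samples,
                                             config.fs, config.background_rms)
        clean = config.sensor_scale_uv * (leadfield.gain @ S)
        p_signal = float(np.mean(clean ** 2))
        sigma = np.sqrt(p_signal / config.snr)
        data = clean + rng.normal(0.0, sigma, size=clean.shape)
        trials.append(Trial(data, label, config.fs, list(leadfield.electrode_names)
                            or [f"ch{k}" for k in range(leadfield.n_sensors)]))
        active.append("M1HL" if label == RIGHT_HAND else "M1FL")
        if store_sources:
            src_store[i] = S
        if store_clean:
            clean_store[i] = clean

    epochs = EpochSet(trials, np.ones(n_trials, bool))
    return epochs, GroundTruth(active, all_phases, src_store, clean_store)


# ---------------------------------------------------------------------------
# train/test splits

#: per-subject (train, test) counts of the real competition recordings
TABLE1_SPLITS = {
    "aa": (168, 112),
    "al": (224, 56),
    "av": (84, 196),
    "aw": (56, 224),
    "ay": (28, 252),
}


def make_even_split(epochs: EpochSet, n_train: int) -> EpochSet:
    """Assign train/test flags, class-balanced as far as parity allows.

    The first ceil(n_train/2) trials of the first class and floor(n_train/2)
    of the second (in trial order) are flagged train; everything else test.
    """
    labels = epochs.labels
    classes = sorted(set(labels) - {"unknown"})
    if n_train > len(epochs):
        raise ConfigurationError(f"cannot assign {n_train} training trials to {len(epochs)}")
    per_class = {c: n_train // len(classes) for c in classes}
    for c in classes[: n_train % len(classes)]:
        per_class[c] += 1
    counts = dict.fromkeys(classes, 0)
    split = np.zeros(len(epochs), dtype=bool)
    taken = 0
    for i, lab in enumerate(labels):
        if lab in counts and counts[lab] < per_class[lab]:
            split[i] = True
            counts[lab] += 1
            taken += 1
    if taken < n_train:  # class imbalance: fill from whatever remains
        for i, lab in enumerate(labels):
            if taken == n_train:
                break
            if not split[i] and lab != "unknown":
                split[i] = True
                taken += 1
    return EpochSet(epochs.trials, split, epochs.subject_id)


def make_table1_splits(epochs: EpochSet, subject_id: str) -> EpochSet:
    """Assign the per-subject train/test counts of the real dataset.

    Requires at least 280 trials; the first 280 (in order) are used and any
    extras dropped, reproducing the real recordings' fixed trial budget.
    """
    if subject_id not in TABLE1_SPLITS:
        raise ConfigurationError(
            f"unknown subject {subject_id!r}; known: {sorted(TABLE1_SPLITS)}")
    if len(epochs) < 280:
        raise ConfigurationError(f"need >= 280 trials, got {len(epochs)}")
    n_train, n_test = TABLE1_SPLITS[subject_id]
    assert n_train + n_test == 280
    sub = EpochSet(epochs.trials[:280], np.zeros(280, bool), subject_id)
    return make_even_split(sub, n_train)


def subject_config(base: GeneratorConfig, master_seed: int, subject_id: str) -> GeneratorConfig:
    """Per-subject generator config with an independent seed substream."""
    subjects = sorted(TABLE1_SPLITS)
    idx = subjects.index(subject_id) if subject_id in subjects else abs(hash(subject_id)) % 1000
    child = np.random.SeedSequence([int(master_seed) % (2**31), idx]).generate_state(1)[0]
    return replace(base, seed=int(child % (2**31)))
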