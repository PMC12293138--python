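"""Sensorimotor ROI atlas, patch time-series extraction, and combination search.

The analysis works on 24 labeled cortical patches (12 per hemisphere:
somatosensory association cortex, foot/hand primary somatosensory areas,
secondary somatosensory area, cingulate motor area, foot/hand/lip primary
motor areas, SMA, pre-SMA, and dorsal/ventral premotor cortex). Right-hand
and right-foot imagery are driven by the contralateral (left) hand and foot
primary motor areas, so M1HL and M1FL form the fixed base of every region
combination; the search enumerates all 4-subsets of a 16-region candidate
pool on top of that base (C(16,4) = 1820 combinations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations as _combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ConfigurationError

#: fixed base of every combination: left-hemisphere hand and foot motor areas
BASE_REGIONS = ("M1HL", "M1FL")

#: region label order within one hemisphere (ids 1-12 left, 13-24 right)
HEMI_LABELS = ("SAC", "S1F", "S1H", "S2", "CMA", "M1F", "M1H", "M1L",
               "SMA", "pSMA", "PMd", "PMv")


class AtlasError(ValueError):
    """An atlas region is missing, empty, or inconsistently defined."""


@dataclass(frozen=True)
class Region:
    id: int
    name: str
    hemisphere: str
    center: np.ndarray  # 3-D patch center, inside the unit sphere
    surface: bool  # False for the cingulate motor area (interior)


@dataclass
class RoiAtlas:
    """24 labeled patches plus per-region source membership.

    ``membership`` maps region name to the indices of the lead-field sources
    belonging to that patch; it is filled when sources are placed on the
    atlas (see :func:`mi_esi.synthetic.place_sources`).
    """

    regions: list[Region]
    membership: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.regions) != 24:
            raise AtlasError(f"atlas must define exactly 24 regions, got {len(self.regions)}")
        by_name = {r.name: r for r in self.regions}
        if len(by_name) != 24:
            raise AtlasError("duplicate region names")
        for r in self.regions:
            lab = r.name[:-1]
            mate = lab + ("R" if r.hemisphere == "L" else "L")
            if mate not in by_name or abs(by_name[mate].id - r.id) != 12:
                raise AtlasError(f"left/right counterpart ids of {r.name} must differ by 12")

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise AtlasError(f"unknown region {name!r}")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def id_of(self, name: str) -> int:
        return self[name].id

    def sources_of(self, name: str) -> np.ndarray:
        self[name]  # validates the name
        members = self.membership.get(name)
        if members is None or len(members) == 0:
            raise AtlasError(f"region {name!r} has no member sources")
        return np.asarray(members, dtype=int)

    def averaging_matrix(self, n_sources: int, order: list[str] | None = None) -> np.ndarray:
        """Rows average member sources of each region (rows x n_sources)."""
        order = order or self.names
        A = np.zeros((len(order), n_sources))
        for i, name in enumerate(order):
            idx = self.sources_of(name)
            A[i, idx] = 1.0 / len(idx)
        return A


def default_atlas(path: str | Path | None = None) -> RoiAtlas:
    """Load the shipped (or a user-edited) atlas coordinate file."""
    if path is None:
        data = resources.files("mi_esi.data")
        with resources.as_file(data / "atlas_24.csv") as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    regions = [
        Region(int(r.id), str(r.name), str(r.hemisphere),
               np.array([r.x, r.y, r.z], dtype=float), bool(r.surface))
        for r in df.itertuples()
    ]
    return RoiAtlas(regions)


def default_pool(atlas: RoiAtlas) -> list[str]:
    """The 16-region candidate pool for the combination search.

    Excluded from the 24: the two base regions, both cingulate motor areas
    (interior, not on the cortical surface), the right-hemisphere hand/foot
    motor areas (ipsilateral to the imagined limbs) and both lip motor areas
    (task-irrelevant) — the only exclusion set of size 8 that leaves the
    quoted 16 candidates. Ordered by region id.
    """
    excluded = set(BASE_REGIONS) | {"CMAL", "CMAR", "M1HR", "M1FR", "M1LL", "M1LR"}
    pool = [r.name for r in sorted(atlas.regions, key=lambda r: r.id) if r.name not in excluded]
    assert len(pool) == 16
    return pool


@dataclass(frozen=True)
class RoiCombination:
    """A 6-region set: the fixed 2-region base plus 4 extra regions."""

    base: tuple[str, ...]
    extras: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.base) & set(self.extras):
            raise ConfigurationError("extras must be disjoint from the base regions")
        if len(self.extras) != len(set(self.extras)):
            raise ConfigurationError("duplicate extra regions")

    @property
    def regions(self) -> tuple[str, ...]:
        return self.base + self.extras

    def __len__(self) -> int:
        return len(self.regions)


def enumerate_combinations(atlas: RoiAtlas, pool: list[str] | None = None,
                           k: int = 4) -> list[RoiCombination]:
    """All k-subsets of the pool, each on top of the fixed base.

    Deterministic lexicographic order by region id; with the default
    16-region pool and k = 4 this yields exactly 1820 combinations.
    """
    pool = default_pool(atlas) if pool is None else list(pool)
    if set(pool) & set(BASE_REGIONS):
        raise ConfigurationError(f"pool overlaps the base regions {BASE_REGIONS}")
    for name in pool:
        atlas[name]  # validates
    if k > len(pool):
        raise ConfigurationError(f"cannot choose {k} regions from a pool of {len(pool)}")
    ordered = sorted(pool, key=atlas.id_of)
    return [RoiCombination(BASE_REGIONS, extras) for extras in _combinations(ordered, k)]


def extract_roi_series(source_tc: np.ndarray, atlas: RoiAtlas,
                       combination: RoiCombination, sign_flip: bool = False) -> np.ndarray:
    """One averaged time series per combination region (6 x samples).

    Row r is the arithmetic mean over the member sources of region r, in the
    combination's region order. With ``sign_flip`` each member source is
    flipped to correlate positively with the patch's first principal
    direction before averaging, which prevents cancellation between sources
    of opposing orientation.
    """
    source_tc = np.asarray(source_tc, dtype=float)
    rows = np.empty((len(combination), source_tc.shape[1]))
    for i, name in enumerate(combination.regions):
        idx = atlas.sources_of(name)
        patch = source_tc[idx]
        if sign_flip and len(idx) > 1:
            # first principal temporal direction of the patch
            _, _, vt = np.linalg.svd(patch, full_matrices=False)
            signs = np.sign(patch @ vt[0])
            signs[signs == 0] = 1.0
            patch = patch * signs[:, None]
        rows[i] = patch.mean(axis=0)
    return rows


def select_best_combination(results: list[float]) -> tuple[int, float]:
    """Index and value of the maximum accuracy; ties go to the lowest index."""
    if len(results) == 0:
        raise ValueError("no combination results to select from")
    arr = np.asarray(results, dtype=float)
    best = int(np.argmax(arr))  # argmax returns the first maximum
    return best, float(arr[best])
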