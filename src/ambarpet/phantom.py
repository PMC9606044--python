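"""Synthetic 3-D brain phantom: ellipsoidal support, Voronoi parcellation.

The phantom stands in for a spatially normalised brain with an integer
atlas parcellation: an ellipsoid partitioned into contiguous regions by
seeded-point nearest-neighbour growth. A subset of regions is flagged as the
cerebellum (the intensity-normalisation reference) and another, disjoint
subset as the disease-affected regions (the posterior-cingulate / precuneus
/ parieto-temporal analogue) where metabolic decline is seeded.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import AtlasParcellation, Volume

__all__ = ["PhantomSpec", "build_phantom", "DEFAULT_GRID_SHAPE", "DEFAULT_VOXEL_SIZE_MM"]

DEFAULT_GRID_SHAPE = (40, 48, 40)
DEFAULT_VOXEL_SIZE_MM = 4.0
#: gray-matter probability profile: value at the centre and at the surface
_GM_CENTER, _GM_EDGE = 0.92, 0.50


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic brain phantom.

    Defaults give a desk-scale 40×48×40 grid at 4 mm isotropic — small
    enough to iterate on, large enough that an 8 mm FWHM kernel is well
    resolved. ``baseline_uptake`` maps region id → noise-free uptake
    (arbitrary counts); regions not listed get ``default_uptake``.
    """

    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM
    n_regions: int = 24
    cerebellum_region_ids: tuple[int, ...] = (1, 2)
    ad_region_ids: tuple[int, ...] = (3, 4, 5, 6)
    baseline_uptake: dict[int, float] = field(default_factory=dict)
    default_uptake: float = 100.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive integers, got {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.n_regions < 10:
            raise ValueError(f"n_regions must be ≥ 10, got {self.n_regions}")
        if not self.cerebellum_region_ids:
            raise ValueError("cerebellum_region_ids must be nonempty")
        overlap = set(self.cerebellum_region_ids) & set(self.ad_region_ids)
        if overlap:
            raise ValueError(f"cerebellum and disease region ids overlap: {sorted(overlap)}")
        all_ids = set(self.cerebellum_region_ids) | set(self.ad_region_ids)
        valid = set(range(1, self.n_regions + 1))
        if not all_ids <= valid:
            raise ValueError(
                f"region ids {sorted(all_ids - valid)} fall outside 1..{self.n_regions}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if self.default_uptake <= 0 or any(v <= 0 for v in self.baseline_uptake.values()):
            raise ValueError("baseline uptake values must be positive")

    def uptake_for(self, region_id: int) -> float:
        return float(self.baseline_uptake.get(region_id, self.default_uptake))


def _ellipsoid_r2(shape: tuple[int, int, int]) -> np.ndarray:
    """Squared normalised ellipsoid radius per voxel (1 on the surface)."""
    axes = [np.arange(s, dtype=np.float64) - (s - 1) / 2.0 for s in shape]
    semi = [0.44 * s for s in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return (xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2


def build_phantom(spec: PhantomSpec) -> tuple[AtlasParcellation, Volume, Volume]:
    """Build (parcellation, noise-free baseline uptake, GM probability).

    The brain support is the ellipsoid inscribed in the grid. Region seeds
    are drawn uniformly inside it and each in-brain voxel takes the label of
    its nearest seed (a Voronoi partition, so every region is a single
    connected component). Cerebellum-flagged regions are anchored to the
    most inferior seeds, disease-flagged regions to the most posterior of
    the rest. GM probability falls off quadratically from ``0.92`` at the
    centre to ``0.5`` at the brain surface and is 0 outside.
    """
    r2 = _ellipsoid_r2(spec.grid_shape)
    brain = r2 <= 1.0
    n_brain = int(brain.sum())
    if spec.n_regions > n_brain:
        raise ValueError(
            f"n_regions={spec.n_regions} exceeds the {n_brain} in-brain voxels of this grid"
        )
    rng = np.random.default_rng(spec.seed)
    coords = np.argwhere(brain).astype(np.float64)
    seeds = coords[rng.choice(len(coords), size=spec.n_regions, replace=False)]

    # anchor cerebellum to the most inferior seeds and the disease regions to
    # the most posterior remaining ones, then map labels accordingly
    order_inferior = np.argsort(seeds[:, 2])  # low z = inferior
    cereb_pos = list(order_inferior[: len(spec.cerebellum_region_ids)])
    remaining = [i for i in range(spec.n_regions) if i not in cereb_pos]
    remaining.sort(key=lambda i: -seeds[i, 1])  # high y = posterior
    ad_pos = remaining[: len(spec.ad_region_ids)]
    other_pos = remaining[len(spec.ad_region_ids):]
    other_ids = sorted(
        set(range(1, spec.n_regions + 1))
        - set(spec.cerebellum_region_ids)
        - set(spec.ad_region_ids)
    )
    seed_to_id = {}
    for pos, rid in zip(cereb_pos, spec.cerebellum_region_ids):
        seed_to_id[pos] = rid
    for pos, rid in zip(ad_pos, spec.ad_region_ids):
        seed_to_id[pos] = rid
    for pos, rid in zip(other_pos, other_ids):
        seed_to_id[pos] = rid

    tree = cKDTree(seeds)
    _, nearest = tree.query(coords)
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    id_lookup = np.array([seed_to_id[i] for i in range(spec.n_regions)], dtype=np.int32)
    labels[brain] = id_lookup[nearest]

    uptake = np.zeros(spec.grid_shape, dtype=np.float64)
    for rid in range(1, spec.n_regions + 1):
        uptake[labels == rid] = spec.uptake_for(rid)

    gm = np.zeros(spec.grid_shape, dtype=np.float64)
    gm[brain] = _GM_CENTER - (_GM_CENTER - _GM_EDGE) * r2[brain]

    cereb = set(spec.cerebellum_region_ids)
    ad = set(spec.ad_region_ids)
    regions = pd.DataFrame(
        {
            "region_id": range(1, spec.n_regions + 1),
            "name": [
                f"cerebellum_{r}" if r in cereb else (f"ad_region_{r}" if r in ad else f"region_{r}")
                for r in range(1, spec.n_regions + 1)
            ],
            "lobe": [
                "cerebellum" if r in cereb else ("posterior" if r in ad else "other")
                for r in range(1, spec.n_regions + 1)
            ],
            "cerebellum_flag": [r in cereb for r in range(1, spec.n_regions + 1)],
            "ad_flag": [r in ad for r in range(1, spec.n_regions + 1)],
        }
    )
    vs = (spec.voxel_size_mm,) * 3
    atlas = AtlasParcellation(labels, regions, vs)
    return atlas, Volume(uptake, vs), Volume(gm, vs)
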