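"""Temporal differencing between two registered timepoints.

New roots, destroyed biopores and created biopores come from mask
subtraction with a dilation tolerance: the subtracted mask is dilated by a
small ball so sub-voxel registration error and slight thickness changes do
not register as turnover.  A physical-volume size opening then removes
residual specks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "DynamicsResult",
    "difference_mask",
    "size_opening",
    "biopore_dynamics",
    "new_roots",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _stable_air(pore: np.ndarray) -> np.ndarray:
    """Pore space that survives a one-voxel opening: open channels and
    cavities, excluding the granular speckle porosity of cast infills."""
    structure = ndi.generate_binary_structure(3, 1)
    return ndi.binary_opening(np.asarray(pore, bool), structure=structure)


def _drop_stable_components(
    mask: np.ndarray, stable: np.ndarray, max_fraction: float = 0.5
) -> np.ndarray:
    """Remove 26-connected components lying mostly inside ``stable``."""
    labels, n = ndi.label(mask, structure=_CONN26)
    if n == 0:
        return mask
    total = np.bincount(labels.ravel())
    inside = np.bincount(labels[np.asarray(stable, bool)].ravel(), minlength=n + 1)
    keep = inside <= max_fraction * total
    keep[0] = False
    return keep[labels]


def difference_mask(a: np.ndarray, b: np.ndarray, dilation_radius_voxels: int = 1) -> np.ndarray:
    """Voxels of ``a`` not explained by ``b``: ``a AND NOT dilate(b, ball r)``.

    The dilation absorbs whole-voxel registration jitter up to the radius.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    r = int(dilation_radius_voxels)
    if r <= 0 or not b.any():
        return a & ~b
    dil = ndi.distance_transform_edt(~b) <= r
    return a & ~dil


def size_opening(mask: np.ndarray, voxel_size: float, min_volume_mm3: float = 0.3) -> np.ndarray:
    """Remove 26-connected components smaller than a physical volume.

    Components with volume >= ``min_volume_mm3`` are kept intact (the
    boundary case is kept: only strictly smaller components are removed).
    At 18 um voxels the default 0.3 mm^3 cutoff equals 51,440 voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    min_vox = min_volume_mm3 / voxel_size**3
    labels, n = ndi.label(mask, structure=_CONN26)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_vox
    keep[0] = False
    return keep[labels]


@dataclass
class DynamicsResult:
    """Turnover masks between two timepoints plus bioporosity bookkeeping."""

    destroyed: np.ndarray
    created: np.ndarray
    new_roots: np.ndarray | None = None
    bioporosity_t1_pct: float = 0.0
    bioporosity_t2_pct: float = 0.0
    destroyed_pct: float = 0.0  # % of core volume
    created_pct: float = 0.0
    params: dict = field(default_factory=dict)

    @property
    def net_change_pct(self) -> float:
        return self.created_pct - self.destroyed_pct


def biopore_dynamics(
    biopores_t1: np.ndarray,
    biopores_t2: np.ndarray,
    voxel_size: float,
    dilation_radius_voxels: int = 1,
    min_volume_mm3: float = 0.3,
    pore_t1: np.ndarray | None = None,
    pore_t2: np.ndarray | None = None,
    roots_t2: np.ndarray | None = None,
) -> DynamicsResult:
    """Destroyed and created biopores between two registered timepoints.

    Biopore turnover is a material change: a destroyed biopore is refilled
    by casts or compaction, a created one is excavated from solid.  When
    the pore binaries are supplied, each candidate turnover component is
    checked against the other timepoint's *stable* pore space (the pore
    binary after a one-voxel opening, which erases the voxel-scale speckle
    porosity of granular cast infills): a component that still lies mostly
    in stable pore space did not change materially and is segmentation
    flicker, not turnover.  ``roots_t2`` removes newly grown root tubes
    from the created-side source (roots are detected in the pore binary
    too but are not biopores).
    """
    src_t2 = biopores_t2 if roots_t2 is None else (biopores_t2 & ~np.asarray(roots_t2, bool))
    destroyed = size_opening(
        difference_mask(biopores_t1, biopores_t2, dilation_radius_voxels),
        voxel_size, min_volume_mm3,
    )
    created = size_opening(
        difference_mask(src_t2, biopores_t1, dilation_radius_voxels),
        voxel_size, min_volume_mm3,
    )
    if pore_t2 is not None:
        destroyed = _drop_stable_components(destroyed, _stable_air(pore_t2))
    if pore_t1 is not None:
        created = _drop_stable_components(created, _stable_air(pore_t1))
    n = biopores_t1.size
    return DynamicsResult(
        destroyed=destroyed,
        created=created,
        bioporosity_t1_pct=100.0 * np.count_nonzero(biopores_t1) / n,
        bioporosity_t2_pct=100.0 * np.count_nonzero(biopores_t2) / n,
        destroyed_pct=100.0 * np.count_nonzero(destroyed) / n,
        created_pct=100.0 * np.count_nonzero(created) / n,
        params=dict(
            dilation_radius_voxels=dilation_radius_voxels,
            min_volume_mm3=min_volume_mm3,
        ),
    )


def new_roots(
    roots_t1: np.ndarray,
    roots_t2: np.ndarray,
    voxel_size: float,
    dilation_radius_voxels: int = 1,
    min_volume_mm3: float = 0.3,
    exclude_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Roots present at the second timepoint but not the first.

    The difference is taken against the t1 ROOT mask, so a new root
    threading an old (air-filled) biopore is still detected.  An optional
    ``exclude_mask`` (typically the destroyed-biopore mask) removes regions
    known to be cast infill, which granular casts can otherwise leak into
    the root band.
    """
    diff = difference_mask(roots_t2, roots_t1, dilation_radius_voxels)
    if exclude_mask is not None:
        diff &= ~np.asarray(exclude_mask, dtype=bool)
    return size_opening(diff, voxel_size, min_volume_mm3)
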