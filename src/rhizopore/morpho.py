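"""Local-thickness morphometry: size distributions, porosities, root length.

Local thickness follows the maximum-inscribed-sphere definition: the
thickness at a voxel is the diameter of the largest sphere that fits
entirely inside the mask and contains that voxel.  Size distributions are
volume-weighted histograms of the thickness map; porosities are voxel
fractions; root length comes from a 3-D skeleton with per-branch diameter
classing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

__all__ = [
    "ThicknessMap",
    "SizeDistribution",
    "DEFAULT_PORE_EDGES_MM",
    "DEFAULT_ROOT_EDGES_MM",
    "local_thickness",
    "size_distribution",
    "porosity",
    "root_length_by_class",
]

# pore/biopore diameter classes (mm): sub-resolution floor at 36 um (2 voxels
# at 18 um), then the figure classes
DEFAULT_PORE_EDGES_MM = (0.036, 0.2, 0.5, 1.0, 2.0, np.inf)
# root diameter classes (mm)
DEFAULT_ROOT_EDGES_MM = (0.036, 0.2, 0.5, 1.0, np.inf)


@dataclass
class ThicknessMap:
    """Per-voxel local diameters (mm) on a mask; 0 outside the mask."""

    values: np.ndarray
    voxel_size: float

    @property
    def mask(self) -> np.ndarray:
        return self.values > 0


def local_thickness(
    mask: np.ndarray,
    voxel_size: float = 1.0,
    exact: bool | None = None,
    max_exact_radii: int = 512,
) -> ThicknessMap:
    """Maximum-inscribed-sphere local thickness of a binary mask.

    Algorithm: for each candidate inscribed-sphere radius r (descending),
    the set of sphere centres is ``EDT >= r`` and the region covered by
    spheres of that radius is ``distance-to-centres <= r``; a voxel's
    thickness is twice the largest radius that covers it.  With the exact
    set of radii this equals the exhaustive inscribed-sphere search.

    When the mask carries more than ``max_exact_radii`` distinct EDT values
    (and ``exact`` is not forced), sphere radii are quantised down to
    0.5-voxel steps; radii are then biased down by at most half a voxel,
    though thin shells at sphere boundaries may fall to the next covering
    sphere (mean thickness error stays below one voxel).
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=np.float32)
    if not mask.any():
        return ThicknessMap(out, voxel_size)
    # squared EDT distances are exact integers: compare in integer space so
    # sphere-boundary ties are handled identically to the exhaustive search
    D = ndi.distance_transform_edt(mask)
    D2 = np.rint(D**2).astype(np.int64)
    levels = np.unique(D2[mask])
    levels = levels[levels > 0]
    if exact is None:
        exact = len(levels) <= max_exact_radii
    if exact:
        remaining = int(mask.sum())
        for lvl in levels[::-1]:
            centers = D2 >= lvl
            cov2 = np.rint(ndi.distance_transform_edt(~centers) ** 2).astype(np.int64)
            new = mask & (cov2 <= lvl) & (out == 0)
            out[new] = 2.0 * np.sqrt(float(lvl))
            remaining -= int(np.count_nonzero(new))
            if remaining <= 0:
                break
    else:
        # quantise every sphere radius down to 0.5-voxel steps; each centre
        # still covers with its own (quantised) full radius
        Dq = np.floor(D * 2.0) / 2.0
        qlevels = np.unique(Dq[mask])
        qlevels = qlevels[qlevels > 0]
        remaining = int(mask.sum())
        for lvl in qlevels[::-1]:
            centers = Dq >= lvl
            covered = ndi.distance_transform_edt(~centers) <= lvl + 1e-6
            new = mask & covered & (out == 0)
            out[new] = 2.0 * lvl
            remaining -= int(np.count_nonzero(new))
            if remaining <= 0:
                break
    return ThicknessMap(out * voxel_size, voxel_size)


@dataclass
class SizeDistribution:
    """Volume per diameter class from a local-thickness map."""

    edges_mm: tuple
    volume_mm3: np.ndarray  # per class
    percent_of_core: np.ndarray
    total_volume_mm3: float
    mean_diameter_mm: float
    sub_resolution_mm3: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        labels = [
            f"{lo:g}-{hi:g} mm" if np.isfinite(hi) else f">{lo:g} mm"
            for lo, hi in zip(self.edges_mm[:-1], self.edges_mm[1:])
        ]
        return pd.DataFrame(
            {
                "class": labels,
                "volume_mm3": self.volume_mm3,
                "percent_of_core": self.percent_of_core,
            }
        )


def size_distribution(
    tmap: ThicknessMap,
    edges_mm=DEFAULT_PORE_EDGES_MM,
    core_voxels: int | None = None,
) -> SizeDistribution:
    """Volume-weighted diameter histogram of a thickness map.

    Classes are left-open, right-closed: ``edges[i] < d <= edges[i+1]``.
    Thickness below the first edge goes to an explicit sub-resolution
    account (with a warning).  Class volumes sum exactly to the mask volume
    (integer voxel counts times the voxel volume).
    """
    edges = np.asarray(edges_mm, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    vals = tmap.values[tmap.mask]
    vox_mm3 = tmap.voxel_size**3
    n_core = core_voxels if core_voxels is not None else tmap.values.size
    nbins = len(edges) - 1
    counts = np.zeros(nbins, dtype=np.int64)
    sub = 0
    if vals.size:
        idx = np.searchsorted(edges, vals, side="left") - 1
        sub = int(np.count_nonzero(idx < 0))
        if sub:
            warnings.warn(
                f"{sub} voxels have thickness below the first class edge "
                f"({edges[0]} mm); counted in a sub-resolution bin"
            )
        for b in range(nbins):
            counts[b] = np.count_nonzero(idx == b)
    volume = counts * vox_mm3
    mean_d = float(vals.mean()) if vals.size else 0.0
    return SizeDistribution(
        edges_mm=tuple(edges),
        volume_mm3=volume,
        percent_of_core=100.0 * counts / n_core,
        total_volume_mm3=float(vals.size * vox_mm3),
        mean_diameter_mm=mean_d,
        sub_resolution_mm3=sub * vox_mm3,
    )


def porosity(mask: np.ndarray, core_region: np.ndarray | None = None) -> float:
    """Percent of the core region occupied by the mask."""
    mask = np.asarray(mask, dtype=bool)
    if core_region is None:
        n_core = mask.size
    else:
        core_region = np.asarray(core_region, dtype=bool)
        if not core_region.any():
            raise ValueError("core region is empty")
        if (mask & ~core_region).any():
            raise ValueError("mask extends outside the core region")
        n_core = int(core_region.sum())
    return 100.0 * float(mask.sum()) / n_core


_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]

def _skeleton_branch_paths(skel: np.ndarray):
    """Trace a 26-connected skeleton into branch paths.

    Returns ``(coords, degree, paths)`` where each path is a list of node
    indices running terminal-to-terminal (terminals are endpoints or
    junction voxels); isolated cycles come back as closed paths.
    """
    coords = np.argwhere(skel)
    n = len(coords)
    index = -np.ones(skel.shape, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(n)
    nbrs: list[list[int]] = [[] for _ in range(n)]
    for off in _OFFSETS:
        pair = skel & _shift_bool(skel, off)
        if not pair.any():
            continue
        pts = np.argwhere(pair)
        a = index[tuple(pts.T)]
        b = index[tuple((pts - off).T)]
        for i, j in zip(a.tolist(), b.tolist()):
            nbrs[i].append(j)
            nbrs[j].append(i)
    degree = np.array([len(x) for x in nbrs])
    used = set()
    paths = []

    def walk(start, first):
        path = [start, first]
        used.add((min(start, first), max(start, first)))
        prev, cur = start, first
        while degree[cur] == 2:
            nxt = nbrs[cur][0] if nbrs[cur][0] != prev else nbrs[cur][1]
            edge = (min(cur, nxt), max(cur, nxt))
            if edge in used:
                break
            used.add(edge)
            path.append(nxt)
            prev, cur = cur, nxt
        return path

    for t in np.nonzero(degree != 2)[0]:
        for nb in nbrs[t]:
            if (min(t, int(nb)), max(t, int(nb))) not in used:
                paths.append(walk(int(t), int(nb)))
    # leftover pure cycles
    for i in range(n):
        if degree[i] == 2:
            for nb in nbrs[i]:
                if (min(i, nb), max(i, nb)) not in used:
                    paths.append(walk(i, nb))
    return coords, degree, paths


def _smooth_coords(pts: np.ndarray, window: int = 5) -> np.ndarray:
    if len(pts) <= 2:
        return pts.astype(float)
    w = min(window, 2 * (len(pts) // 2) - 1)
    if w < 3:
        return pts.astype(float)
    kernel = np.ones(w) / w
    padded = np.pad(pts.astype(float), ((w // 2, w // 2), (0, 0)), mode="edge")
    out = np.empty((len(pts), 3))
    for ax in range(3):
        out[:, ax] = np.convolve(padded[:, ax], kernel, mode="valid")[: len(pts)]
    return out


def _measured_paths(mask: np.ndarray):
    """Skeleton branch paths with per-node metric lengths.

    The skeleton is traced into branch paths; spur branches shorter than
    the local tube radius (thinning artifacts of surface bumps) are
    dropped; path coordinates are smoothed to remove digital zigzag before
    measuring; free ends are credited the end-cap erosion (EDT - 1).

    Yields ``(node_coords, per_node_length)`` per kept path, in voxels.
    """
    skel = skeletonize(mask)
    if not skel.any():
        return []
    dt = ndi.distance_transform_edt(mask)
    coords, degree, paths = _skeleton_branch_paths(skel)
    out = []
    for path in paths:
        nodes = np.array(path)
        pts = coords[nodes]
        is_end = degree[nodes[0]] <= 1, degree[nodes[-1]] <= 1
        junction_side = degree[nodes[0]] >= 3 or degree[nodes[-1]] >= 3
        sm = _smooth_coords(pts)
        seg = np.linalg.norm(np.diff(sm, axis=0), axis=1)
        plen = float(seg.sum())
        if junction_side and (is_end[0] or is_end[1]):
            # candidate spur: a short free branch hanging off a junction
            # whose tip hugs the surface (a real tube end carries a full
            # end-cap radius at its tip)
            j = nodes[0] if degree[nodes[0]] >= 3 else nodes[-1]
            tip = nodes[-1] if j == nodes[0] else nodes[0]
            d_j = float(dt[tuple(coords[j])])
            d_tip = float(dt[tuple(coords[tip])])
            if plen <= 1.3 * d_j + 1.0 and d_tip < 0.5 * d_j:
                continue
        per_node = np.zeros(len(nodes))
        per_node[:-1] += seg / 2
        per_node[1:] += seg / 2
        for k, end in ((0, is_end[0]), (-1, is_end[1])):
            if end:
                per_node[k] += max(float(dt[tuple(coords[nodes[k]])]) - 1.0, 0.0)
        out.append((pts, per_node))
    return out


def skeleton_length_mm(mask: np.ndarray, voxel_size: float) -> float:
    """Total centerline length of a mask.

    Skeleton branch paths are smoothed before measuring (removing the
    digital zigzag bias), spur branches below the local radius are pruned,
    and free tube ends are credited the thinning end-cap erosion.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    total = sum(per_node.sum() for _, per_node in _measured_paths(mask))
    return float(total) * voxel_size


def root_length_by_class(
    root_mask: np.ndarray,
    tmap: ThicknessMap,
    edges_mm=DEFAULT_ROOT_EDGES_MM,
    voxel_size: float | None = None,
) -> pd.DataFrame:
    """Root length density per diameter class (cm per cm^3 of core).

    Skeleton branch lengths are accumulated per node and assigned to the
    diameter class of the local thickness at that node.
    """
    root_mask = np.asarray(root_mask, dtype=bool)
    voxel_size = voxel_size if voxel_size is not None else tmap.voxel_size
    edges = np.asarray(edges_mm, dtype=float)
    nbins = len(edges) - 1
    labels = [
        f"{lo:g}-{hi:g} mm" if np.isfinite(hi) else f">{lo:g} mm"
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    core_cm3 = root_mask.size * (voxel_size / 10.0) ** 3
    length = np.zeros(nbins)
    for pts, per_node in _measured_paths(root_mask):
        d = tmap.values[tuple(pts.T)]
        idx = np.clip(np.searchsorted(edges, d, side="left") - 1, 0, nbins - 1)
        length += np.bincount(idx, weights=per_node, minlength=nbins)
    length = length * voxel_size / 10.0  # cm
    return pd.DataFrame(
        {"class": labels, "length_cm": length,
         "length_density_cm_cm3": length / core_cm3}
    )


def _shift_bool(arr, off):
    out = np.zeros_like(arr)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(off):
        if s > 0:
            src[ax], dst[ax] = slice(0, arr.shape[ax] - s), slice(s, None)
        elif s < 0:
            src[ax], dst[ax] = slice(-s, None), slice(0, arr.shape[ax] + s)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _shift_back(arr, off):
    return _shift_bool(arr, tuple(-s for s in off))
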