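"""Multiscale Hessian tubeness segmentation of roots and biopores.

Tubular objects (roots in the organic binary, biopores in the pore binary)
are extracted with a dual-band multiscale tubeness filter: the binary is
downscaled (mean pooling to fractional occupancy), a Hessian-eigenvalue
tubeness response is computed at a ladder of Gaussian scales, the response
is normalised per scale by the response of an ideal solid cylinder of
diameter 2*sigma, thresholded, completed by a scale-matched dilation, and
intersected with the input binary.  Touching objects are split by a
distance-transform watershed, and blob-like objects are removed by an
elongation filter (skeleton length / centerline diameter).

Roots and biopores use identical bands and filters so both are segmented
consistently over their whole size range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from skimage.morphology import skeletonize
from skimage.segmentation import watershed

__all__ = [
    "ScaleBand",
    "DEFAULT_BANDS",
    "tubeness_response",
    "multiscale_tubular_mask",
    "separate_segments",
    "segment_table",
    "filter_blobs",
    "segment_tubular",
    "segment_biopores",
    "segment_roots",
]


@dataclass(frozen=True)
class ScaleBand:
    """One downscale level with its ladder of tubeness scales.

    ``downscale_factor`` is the linear scale of the working grid relative to
    the input (0.5 = half resolution); ``sigmas`` are Gaussian scales in
    downscaled-voxel units.
    """

    downscale_factor: float
    sigmas: tuple

    def __post_init__(self):
        if not 0 < self.downscale_factor <= 1:
            raise ValueError("downscale_factor must be in (0, 1]")
        s = tuple(self.sigmas)
        if len(s) == 0 or any(b <= a for a, b in zip(s, s[1:])) or s[0] < 1:
            raise ValueError("sigmas must be nonempty, strictly increasing and >= 1")

    @property
    def block(self) -> int:
        return max(1, int(round(1.0 / self.downscale_factor)))


# 50% scale with sigma 1-4 catches fine roots; 20% scale with sigma 2-30
# catches the large biopores
DEFAULT_BANDS = (
    ScaleBand(0.5, tuple(range(1, 5))),
    ScaleBand(0.2, tuple(range(2, 31))),
)


def tubeness_response(vol: np.ndarray, sigma: float) -> np.ndarray:
    """Scale-normalised bright-tube Hessian response.

    The volume is smoothed with a Gaussian of width ``sigma``; at each voxel
    the Hessian eigenvalues lambda1 >= lambda2 >= lambda3 are computed and
    the response is ``sigma^2 * sqrt(lambda2 * lambda3)`` where both are
    negative, else 0 — large inside bright cylinders, ~0 on plates and in
    flat regions.
    """
    if sigma < 0.5:
        raise ValueError("sigma must be >= 0.5 voxels")
    vol = np.asarray(vol, dtype=np.float32)
    if not np.all(np.isfinite(vol)):
        raise ValueError("tubeness input contains non-finite values")
    axes = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    H = np.empty(vol.shape + (3, 3), dtype=np.float32)
    for i, j in axes:
        order = [0, 0, 0]
        order[i] += 1
        order[j] += 1
        d = ndi.gaussian_filter(vol, sigma, order=order, mode="nearest")
        H[..., i, j] = d
        if i != j:
            H[..., j, i] = d
    eigs = np.linalg.eigvalsh(H)  # ascending: e0 <= e1 <= e2
    e0, e1 = eigs[..., 0], eigs[..., 1]
    resp = np.where(e1 < 0, np.sqrt(np.clip(e0 * e1, 0, None)), 0.0)
    return (sigma**2 * resp).astype(np.float32)


def _gated_tubeness(vol: np.ndarray, sigma: float) -> np.ndarray:
    """Tubeness response times a cylindricity gate.

    The gate ``1 - |lambda1| / sqrt(lambda2*lambda3)`` (clipped to [0, 1])
    discriminates tubes (axial eigenvalue ~ 0, gate ~ 1) from blobs (three
    comparable negative eigenvalues, gate ~ 0), so irregular pore bodies do
    not seed the tubular mask.
    """
    vol = np.asarray(vol, dtype=np.float32)
    axes = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    H = np.empty(vol.shape + (3, 3), dtype=np.float32)
    for i, j in axes:
        order = [0, 0, 0]
        order[i] += 1
        order[j] += 1
        d = ndi.gaussian_filter(vol, sigma, order=order, mode="nearest")
        H[..., i, j] = d
        if i != j:
            H[..., j, i] = d
    eigs = np.linalg.eigvalsh(H)
    e0, e1, e2 = eigs[..., 0], eigs[..., 1], eigs[..., 2]
    core = np.sqrt(np.clip(e0 * e1, 1e-30, None))
    gate = np.clip(1.0 - np.abs(e2) / core, 0.0, 1.0)
    resp = np.where(e1 < 0, core * gate, 0.0)
    return (sigma**2 * resp).astype(np.float32)


@lru_cache(maxsize=None)
def _cylinder_peak_response(sigma: float) -> float:
    """Centerline tubeness response of an ideal solid cylinder of diameter
    2*sigma (occupancy 1) filtered at ``sigma``.

    Computed on a 2-D cross-section: an infinite cylinder's axial Hessian is
    zero and its two in-plane eigenvalues equal the 2-D disk values.
    """
    m = int(np.ceil(5 * sigma)) + 2
    yy, xx = np.mgrid[-m : m + 1, -m : m + 1]
    disk = ((yy**2 + xx**2) <= sigma**2).astype(np.float32)
    hxx = ndi.gaussian_filter(disk, sigma, order=(2, 0), mode="nearest")[m, m]
    hyy = ndi.gaussian_filter(disk, sigma, order=(0, 2), mode="nearest")[m, m]
    lam = 0.5 * (hxx + hyy)  # equal by symmetry; average the discretisation
    return float(sigma**2 * abs(lam))


def _block_mean(binary: np.ndarray, k: int) -> np.ndarray:
    """Mean-pool a binary volume over k^3 blocks (fractional occupancy)."""
    if k == 1:
        return binary.astype(np.float32)
    pad = [(0, (-s) % k) for s in binary.shape]
    arr = np.pad(binary.astype(np.float32), pad)
    s = arr.shape
    arr = arr.reshape(s[0] // k, k, s[1] // k, k, s[2] // k, k)
    return arr.mean(axis=(1, 3, 5))


def _upscale_nearest(arr: np.ndarray, k: int, shape) -> np.ndarray:
    if k == 1:
        return arr[: shape[0], : shape[1], : shape[2]]
    out = np.repeat(np.repeat(np.repeat(arr, k, axis=0), k, axis=1), k, axis=2)
    return out[: shape[0], : shape[1], : shape[2]]


def multiscale_tubular_mask(
    binary: np.ndarray,
    bands=DEFAULT_BANDS,
    response_cutoff: float = 0.5,
) -> np.ndarray:
    """Union over bands of the tubeness-selected part of ``binary``.

    Per band: downscale by mean pooling, take the voxel-wise maximum of the
    cylinder-normalised tubeness response over the band's sigmas, threshold
    at ``response_cutoff`` to get tube-core seeds, grow each seed by a ball
    of its own best scale (so the full tube cross-section is recovered, not
    just the core), upscale nearest-neighbour and intersect with the input.
    """
    if len(bands) == 0:
        raise ValueError("need at least one scale band")
    binary = np.asarray(binary, dtype=bool)
    out = np.zeros(binary.shape, dtype=bool)
    if not binary.any():
        return out
    for band in bands:
        k = band.block
        occ = _block_mean(binary, k)
        if min(occ.shape) < 8:
            warnings.warn(
                f"band at {band.downscale_factor:.0%} scale skipped: downscaled "
                f"volume {occ.shape} smaller than 8 voxels per axis"
            )
            continue
        best = np.zeros(occ.shape, dtype=np.float32)
        best_sigma = np.zeros(occ.shape, dtype=np.float32)
        for sigma in band.sigmas:
            ref = _cylinder_peak_response(float(sigma))
            resp = _gated_tubeness(occ, float(sigma)) / ref
            upd = resp > best
            best[upd] = resp[upd]
            best_sigma[upd] = sigma
        seeds = best >= response_cutoff
        if not seeds.any():
            continue
        grown = np.zeros(occ.shape, dtype=bool)
        for sigma in np.unique(best_sigma[seeds]):
            sel = seeds & (best_sigma == sigma)
            grown |= ndi.distance_transform_edt(~sel) <= sigma
        out |= _upscale_nearest(grown, k, binary.shape)
    return out & binary


def separate_segments(mask: np.ndarray) -> np.ndarray:
    """Distance-transform watershed: split touching tubes at necks.

    Seeds are regional maxima of the Euclidean distance transform after
    merging maxima shallower than 1 voxel, so a single straight tube stays
    one segment while junction arms of different calibre split.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return labels
    dt = ndi.distance_transform_edt(mask).astype(np.float32)
    # light smoothing removes the voxelisation ripple of the EDT ridge so a
    # single tube carries one marker instead of one per ripple
    dts = ndi.gaussian_filter(dt, 1.5)
    # scale-adaptive ridge markers: a voxel is on a seed ridge if nothing
    # within about twice its own inscribed radius is more than the 1-voxel
    # merge depth higher.  A uniform tube yields one connected marker; a
    # thin lateral joining a thick trunk loses its markers only near the
    # junction, so trunk and lateral split there.
    peaks = np.zeros(mask.shape, dtype=bool)
    rmax = float(dts.max())
    r = 2
    while True:
        lo, hi = r / 2.0, float(r)
        band = (dts > lo) & (dts <= hi) & mask
        if band.any():
            mf = ndi.maximum_filter(dts, size=2 * r + 1)
            peaks |= band & (dts >= mf - 1.0)
        if hi >= rmax:
            break
        r = int(np.ceil(r * 1.6))
    if not peaks.any():
        peaks = dts >= rmax - 1e-3
    markers, _ = ndi.label(peaks, structure=np.ones((3, 3, 3), dtype=bool))
    labels = watershed(-dt, markers, mask=mask).astype(np.int32)
    # any voxels in components that carried no marker: plain connected labels
    rest = mask & (labels == 0)
    if rest.any():
        extra, n = ndi.label(rest, structure=np.ones((3, 3, 3), dtype=bool))
        labels[rest] = extra[rest] + labels.max()
    return labels


_NEIGHBOR_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]


class _SkeletonInfo:
    """Skeleton voxels of a labelled mask with their 26-connectivity graph
    (metric edge lengths) and local calibre 2*EDT."""

    def __init__(self, labels: np.ndarray):
        self.labels = labels
        mask = labels > 0
        self.skel = skeletonize(mask) if mask.any() else mask
        self.dt = ndi.distance_transform_edt(mask) if mask.any() else mask.astype(float)
        self.coords = np.argwhere(self.skel)
        self.index = -np.ones(labels.shape, dtype=np.int64)
        if len(self.coords):
            self.index[tuple(self.coords.T)] = np.arange(len(self.coords))
        self.label_of = labels[tuple(self.coords.T)] if len(self.coords) else np.empty(0, int)
        self.caliber = 2.0 * self.dt[tuple(self.coords.T)] if len(self.coords) else np.empty(0)
        ii, jj, ww = [], [], []
        for off in _NEIGHBOR_OFFSETS:
            a = _shifted_and(self.skel, off)
            pts = np.argwhere(a)
            if not len(pts):
                continue
            ii.append(self.index[tuple(pts.T)])
            jj.append(self.index[tuple((pts - off).T)])
            ww.append(np.full(len(pts), float(np.linalg.norm(off))))
        if ii:
            i = np.concatenate(ii)
            j = np.concatenate(jj)
            w = np.concatenate(ww)
            n = len(self.coords)
            self.graph = coo_matrix(
                (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
                shape=(n, n),
            ).tocsr()
            self.edge_i, self.edge_j, self.edge_w = i, j, w
        else:
            self.graph = None
            self.edge_i = self.edge_j = np.empty(0, int)
            self.edge_w = np.empty(0)

    def segment_nodes(self, label: int) -> np.ndarray:
        return np.nonzero(self.label_of == label)[0]

    def longest_path(self, label: int):
        """Approximate geodesic backbone of one segment's skeleton
        (double-sweep shortest path); returns node indices along the path."""
        sel = self.segment_nodes(label)
        return self._longest_path_among(sel)

    def _longest_path_among(self, sel: np.ndarray):
        if len(sel) == 0:
            return sel
        if len(sel) == 1 or self.graph is None:
            return sel[:1]
        sub = self.graph[sel][:, sel]
        d0 = dijkstra(sub, indices=0, directed=False)
        d0[~np.isfinite(d0)] = -1
        u = int(np.argmax(d0))
        d1, pred = dijkstra(sub, indices=u, directed=False, return_predecessors=True)
        d1[~np.isfinite(d1)] = -1
        v = int(np.argmax(d1))
        path = [v]
        while path[-1] != u:
            p = pred[path[-1]]
            if p < 0:
                break
            path.append(int(p))
        return sel[np.array(path[::-1])]

    def core_backbones(self, label: int, prune_fraction: float = 0.5):
        """Backbones restricted to the segment's thick core.

        Skeleton nodes thinner than ``prune_fraction`` times the segment's
        robust (90th-percentile) calibre are pruned — they belong to
        attached side structures, not the tube itself — and a longest path
        is extracted per remaining connected piece.
        """
        sel = self.segment_nodes(label)
        if len(sel) < 3:
            return [sel] if len(sel) else []
        paths = []
        # iteratively peel off backbones so junctions of merged tubes (or
        # root laterals) each contribute their own path; the calibre-based
        # pruning threshold is recomputed per node subset so a thin tube
        # merged with a thick one keeps its own backbone
        pending = [sel]
        rounds = 0
        while pending and rounds < 24:
            nodes = pending.pop()
            if len(nodes) < 10:
                continue
            rounds += 1
            cal = self.caliber[nodes]
            thr = prune_fraction * np.percentile(cal, 90)
            core = nodes[cal >= thr]
            thin = nodes[cal < thr]
            if len(thin) >= 10:
                pending.append(thin)
            if len(core) < 10:
                continue
            sub = self.graph[core][:, core]
            n_comp, comp = connected_components(sub, directed=False)
            for c in range(n_comp):
                comp_nodes = core[comp == c]
                if len(comp_nodes) < 10:
                    continue
                path = self._longest_path_among(comp_nodes)
                if len(path) < 3:
                    continue
                paths.append(path)
                rest = np.setdiff1d(comp_nodes, path, assume_unique=False)
                if len(rest) >= 10:
                    pending.append(rest)
        return paths or [self._longest_path_among(sel)]


def segment_table(
    labels: np.ndarray, voxel_size: float, info: "_SkeletonInfo | None" = None
) -> pd.DataFrame:
    """Shape descriptors per labelled segment.

    Columns: id, voxels, volume_mm3, skeleton_length_mm (total skeleton
    edge length), mean_diameter_mm (mean calibre 2*EDT along the skeleton),
    caliber_p90_mm (robust upper calibre, insensitive to thin side
    branches), elongation (skeleton length / mean diameter), kept (filled
    by filter_blobs).
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    cols = ["id", "voxels", "volume_mm3", "skeleton_length_mm",
            "mean_diameter_mm", "caliber_p90_mm", "elongation", "kept"]
    if len(ids) == 0:
        return pd.DataFrame(columns=cols)
    if info is None:
        info = _SkeletonInfo(labels)
    counts = np.bincount(labels.ravel())
    max_id = int(labels.max())
    diam_sum = np.bincount(info.label_of, weights=info.caliber, minlength=max_id + 1)
    diam_n = np.bincount(info.label_of, minlength=max_id + 1).astype(float)
    # robust upper calibre per label
    order = np.argsort(info.label_of, kind="stable")
    sorted_lab = info.label_of[order]
    sorted_cal = info.caliber[order]
    bounds = np.searchsorted(sorted_lab, np.arange(max_id + 2))
    rows = []
    dt = info.dt
    for i in ids:
        n_vox = int(counts[i]) if i < len(counts) else 0
        if diam_n[i] > 0:
            mean_d = diam_sum[i] / diam_n[i]
            cal90 = float(np.percentile(sorted_cal[bounds[i] : bounds[i + 1]], 90))
        else:
            mean_d = 2.0 * float(dt[labels == i].max())
            cal90 = mean_d
        # geodesic (longest-path) skeleton length: a tube measures its own
        # length, while the shell-like skeleton of a compact blob measures
        # only about its diameter — the quantity the blob filter needs
        path = info.longest_path(int(i))
        if len(path) >= 2:
            pts = info.coords[path]
            skel_len = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        else:
            skel_len = 0.0
        rows.append(
            dict(
                id=int(i),
                voxels=n_vox,
                volume_mm3=n_vox * voxel_size**3,
                skeleton_length_mm=skel_len * voxel_size,
                mean_diameter_mm=mean_d * voxel_size,
                caliber_p90_mm=cal90 * voxel_size,
                elongation=skel_len / mean_d if mean_d > 0 else 0.0,
                kept=True,
            )
        )
    return pd.DataFrame(rows)


def _shift(arr, off, fill=0):
    out = np.full_like(arr, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(off):
        if s > 0:
            src[ax], dst[ax] = slice(0, arr.shape[ax] - s), slice(s, None)
        elif s < 0:
            src[ax], dst[ax] = slice(-s, None), slice(0, arr.shape[ax] + s)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _shifted_and(mask, off):
    return mask & _shift(mask, off, fill=False)


def filter_blobs(
    labels: np.ndarray,
    table: pd.DataFrame,
    min_elongation: float = 2.0,
    min_caliber_mm: float | None = None,
) -> np.ndarray:
    """Remove blob-like segments: keep only elongation >= min_elongation
    (and, when given, robust calibre >= min_caliber_mm).

    Mutates the ``kept`` column of ``table`` and returns the cleaned mask.
    """
    if len(table) == 0:
        return np.zeros(np.asarray(labels).shape, dtype=bool)
    kept = table["elongation"] >= min_elongation
    if min_caliber_mm is not None:
        kept &= table["caliber_p90_mm"] >= min_caliber_mm
    table["kept"] = kept
    keep_ids = table.loc[table["kept"], "id"].to_numpy()
    return np.isin(labels, keep_ids)


def refit_tubes(
    labels: np.ndarray,
    keep_ids,
    voxel_size: float,
    info: _SkeletonInfo | None = None,
    margin_voxels: float = 1.0,
    min_caliber_mm: float | None = None,
    min_elongation: float | None = None,
) -> np.ndarray:
    """Recover the clean tube form of each kept segment.

    For every kept segment the geodesic backbone of its skeleton is
    extracted, a smooth calibre profile is estimated along it (running
    median of the local EDT calibre), and only voxels inside the resulting
    swept sphere (plus a one-voxel margin) are retained.  Irregular pore
    bodies attached to a tube's wall fall outside the refit surface and are
    discarded.
    """
    labels = np.asarray(labels)
    keep_ids = np.asarray(list(keep_ids), dtype=labels.dtype)
    if len(keep_ids) == 0:
        return np.zeros(labels.shape, dtype=bool)
    if info is None:
        info = _SkeletonInfo(labels)
    seed_r = np.zeros(labels.shape, dtype=np.float32)
    seed_on = np.zeros(labels.shape, dtype=bool)
    fallback_ids = []
    for L in keep_ids:
        paths = info.core_backbones(int(L))
        stamped = False
        for path in paths:
            if len(path) < 3:
                continue
            radii = info.caliber[path] / 2.0
            med_vox = 2.0 * float(np.median(radii))
            # the backbone median calibre is the robust tube diameter; a
            # "tube" thinner than the calibre floor is an irregular strand
            if min_caliber_mm is not None and med_vox * voxel_size < min_caliber_mm:
                continue
            # re-apply the elongation rule on the cleaned backbone: a stub
            # shorter than min_elongation diameters is blob-like
            if min_elongation is not None:
                pts_chk = info.coords[path]
                plen = float(np.sum(np.linalg.norm(np.diff(pts_chk, axis=0), axis=1)))
                if plen < min_elongation * med_vox:
                    continue
            # running max counters the off-centre meander of the skeleton;
            # median then smooths single-node spikes
            win = min(7, 2 * (len(radii) // 2) + 1)
            if win >= 3:
                radii = ndi.maximum_filter1d(radii, size=win, mode="nearest")
                radii = ndi.median_filter(radii, size=win, mode="nearest")
            pts = info.coords[path].astype(np.float64)
            # skeletonisation erodes tube ends by roughly one radius:
            # extend the backbone linearly so the end caps are kept
            ext_pts, ext_r = [pts], [radii]
            for end, step in ((0, -1), (len(pts) - 1, 1)):
                k = min(5, len(pts) - 1)
                d = pts[end] - pts[end - step * k]
                norm = np.linalg.norm(d)
                if norm == 0:
                    continue
                d = d / norm
                r_end = radii[end]
                n_ext = int(np.ceil(r_end + margin_voxels))
                if n_ext < 1:
                    continue
                extra = pts[end] + d * np.arange(1, n_ext + 1)[:, None]
                extra = np.clip(extra, 0, np.array(labels.shape) - 1)
                ext_pts.append(extra)
                ext_r.append(np.full(len(extra), r_end))
            pts_all = np.vstack(ext_pts)
            r_all = np.concatenate(ext_r)
            iv = np.round(pts_all).astype(int)
            seed_on[iv[:, 0], iv[:, 1], iv[:, 2]] = True
            seed_r[iv[:, 0], iv[:, 1], iv[:, 2]] = np.maximum(
                seed_r[iv[:, 0], iv[:, 1], iv[:, 2]], r_all + margin_voxels
            )
            stamped = True
        if not stamped and min_caliber_mm is None:
            fallback_ids.append(L)  # too small to refit; keep verbatim
    out = np.zeros(labels.shape, dtype=bool)
    if seed_on.any():
        dist, idx = ndi.distance_transform_edt(~seed_on, return_indices=True)
        near_r = seed_r[idx[0], idx[1], idx[2]]
        out = (dist <= near_r) & np.isin(labels, keep_ids)
    if fallback_ids:
        out |= np.isin(labels, np.asarray(fallback_ids, dtype=labels.dtype))
    return out


def segment_tubular(
    binary: np.ndarray,
    voxel_size: float,
    bands=DEFAULT_BANDS,
    min_elongation: float = 2.0,
    response_cutoff: float = 0.5,
    min_caliber_mm: float | None = None,
    refit: bool = False,
):
    """Full tubular-extraction chain on one binary.

    Returns ``(mask, labels, table)``: the cleaned tubular mask, the
    watershed segment labels (over the pre-filter tubular mask) and the
    per-segment descriptor table with kept flags.
    """
    tubular = multiscale_tubular_mask(binary, bands, response_cutoff=response_cutoff)
    labels = separate_segments(tubular)
    info = _SkeletonInfo(labels)
    table = segment_table(labels, voxel_size, info=info)
    mask = filter_blobs(labels, table, min_elongation=min_elongation,
                        min_caliber_mm=min_caliber_mm)
    if refit and len(table):
        mask = refit_tubes(
            labels, table.loc[table["kept"], "id"], voxel_size, info=info,
            min_caliber_mm=min_caliber_mm,
            min_elongation=min_elongation if min_caliber_mm is not None else None,
        )
    return mask, labels, table


def coarse_band_floor_mm(voxel_size: float, bands=DEFAULT_BANDS) -> float:
    """Detectability floor of the coarsest band: 2 downscaled voxels.

    Tubes thinner than this cannot be told apart from irregular pore
    strands at the scale where large biopores are segmented.
    """
    return 2.0 * voxel_size * max(b.block for b in bands)


def segment_biopores(pore_mask: np.ndarray, voxel_size: float, bands=DEFAULT_BANDS, **kw):
    """Biopores: tubular objects of the pore binary.

    Defaults add a calibre floor at the coarse-band resolution limit and a
    backbone tube refit, separating smooth cylindrical biopores from the
    elongated strands of the irregular pore network.
    """
    kw.setdefault("min_caliber_mm", max(0.5, coarse_band_floor_mm(voxel_size, bands)))
    kw.setdefault("refit", True)
    return segment_tubular(pore_mask, voxel_size, bands, **kw)[0]


def segment_roots(
    organic_mask: np.ndarray,
    voxel_size: float,
    bands=DEFAULT_BANDS,
    opening_radius_voxels: int = 1,
    **kw,
):
    """Roots: tubular objects of the organic binary (same bands and filters
    as biopores over the shared size range; no calibre floor because the
    organic binary holds no irregular pore network).

    A small binary opening first removes voxel-scale speckle: granular
    fauna-cast infills scatter organic-gray grains through the band, while
    a real root is compact at the voxel scale and survives the opening.
    """
    organic_mask = np.asarray(organic_mask, dtype=bool)
    if opening_radius_voxels > 0:
        structure = ndi.generate_binary_structure(3, 1)
        organic_mask = ndi.binary_opening(
            organic_mask, structure=structure, iterations=int(opening_radius_voxels)
        )
    return segment_tubular(organic_mask, voxel_size, bands, **kw)[0]
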