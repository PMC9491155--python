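"""Synthetic soil-core phantom pairs with complete ground truth.

The generator emulates the gray-value structure a micro-CT soil-core
pipeline assumes: a bright mineral matrix, dark air-filled pores (irregular
blobs plus tubular biopores), intermediate-gray tubular roots, and — at the
second timepoint — destroyed biopores refilled by soil-fauna casts, newly
created biopores and newly grown roots whose growth trajectories (into
existing biopores, into other macropores, into the dense matrix) are
controlled by construction.

Geometry model: roots and biopores are swept spheres along smoothed random
walks (the "cylindrical shape" criterion that defines a biopore); irregular
pores come from a thresholded Gaussian random field; "macropore chambers"
(compact blobby cavities threaded by new roots) realise the into-macropore
trajectory class.  Gray values are flat per material class plus additive
Gaussian noise — no partial-volume blur, so with zero noise the histogram
support is exactly the planted material grays.

Every voxel of the truth labels belongs to exactly one object id, and all
planted summaries are recomputable from the label grids by voxel counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .volio import GrayVolume, write_volume

__all__ = [
    "LABELS",
    "PhantomSpec",
    "DynamicsPlan",
    "PhantomTruth",
    "PlacementError",
    "generate_core_pair",
    "plant_dynamics",
    "save_phantom",
]

# truth label codes
L_MATRIX = 0
L_MACROPORE = 1
L_BIOPORE = 2
L_ROOT_OLD = 3
L_ROOT_NEW = 4
L_CAST_EARTHWORM = 5
L_CAST_MESOFAUNA = 6
L_COMPACTION = 7

LABELS = {
    "matrix": L_MATRIX,
    "macropore": L_MACROPORE,
    "biopore": L_BIOPORE,
    "root_old": L_ROOT_OLD,
    "root_new": L_ROOT_NEW,
    "cast_earthworm": L_CAST_EARTHWORM,
    "cast_mesofauna": L_CAST_MESOFAUNA,
    "compaction": L_COMPACTION,
}

AIR_LABELS = (L_MACROPORE, L_BIOPORE)

AGENTS = ("earthworm", "mesofauna", "unidentified")
_AGENT_LABEL = {
    "earthworm": L_CAST_EARTHWORM,
    "mesofauna": L_CAST_MESOFAUNA,
    "unidentified": L_COMPACTION,
}


class PlacementError(RuntimeError):
    """Requested objects cannot be placed without excessive overlap."""


@dataclass
class DynamicsPlan:
    """What happens to the core between the two root growing periods.

    destroyed_fraction
        Fraction of the first-timepoint biopore volume refilled by casts or
        compaction.
    agent_fractions
        Split of the destroyed volume over the three destruction agents.
    created_plan
        (diameter mm, count) of biopores newly formed in the 2nd period.
    new_root_plan
        (diameter mm, count, tortuosity) of roots grown in the 2nd period.
    trajectory_fractions
        Volume split of new-root growth over the structural components it
        occupied at the first timepoint.
    """

    destroyed_fraction: float = 0.30
    agent_fractions: dict = field(
        default_factory=lambda: {"earthworm": 0.4, "mesofauna": 0.4, "unidentified": 0.2}
    )
    created_plan: list = field(default_factory=lambda: [(0.8, 2), (1.2, 1)])
    new_root_plan: list = field(
        default_factory=lambda: [(0.3, 4, 0.20), (0.4, 4, 0.20), (0.5, 2, 0.15)]
    )
    trajectory_fractions: dict = field(
        default_factory=lambda: {"into_biopore": 0.15, "into_macropore": 0.40, "into_matrix": 0.45}
    )


@dataclass
class PhantomSpec:
    """Full description of a synthetic core pair.

    Gray means are on the 0–255 scale and must satisfy air < organic <
    matrix; cast grays are free.  All planted diameters must be at least
    2 voxels (the detectability floor of the imaging model).
    """

    shape: tuple = (200, 200, 200)
    voxel_size: float = 0.04  # mm
    gray_model: dict = field(
        default_factory=lambda: {
            "matrix": 180.0,
            "air": 20.0,
            "organic": 90.0,
            "earthworm_cast": 200.0,
            # mesofauna casts render as a 50/50 speckle of these two grays
            # at `speckle_block`-voxel granularity
            "mesofauna_cast_speckle": (90.0, 180.0),
        }
    )
    speckle_block: int = 2
    noise_sd: float = 8.0
    blob_porosity_target: float = 0.15
    blob_smoothing_voxels: float = 3.0
    biopore_plan: list = field(default_factory=lambda: [(0.8, 5), (1.0, 3), (1.4, 1), (2.0, 1)])
    root_plan: list = field(
        default_factory=lambda: [(0.2, 5, 0.25), (0.3, 5, 0.25), (0.4, 5, 0.20), (0.5, 5, 0.20)]
    )
    dynamics_plan: DynamicsPlan = field(default_factory=DynamicsPlan)
    jitter_voxels: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.dynamics_plan, dict):
            self.dynamics_plan = DynamicsPlan(**self.dynamics_plan)
        g = self.gray_model
        if not (g["air"] < g["organic"] < g["matrix"]):
            raise ValueError("gray means must satisfy air < organic < matrix")
        tf = self.dynamics_plan.trajectory_fractions
        if abs(sum(tf.values()) - 1.0) > 1e-9:
            raise ValueError("trajectory fractions must sum to 1")
        af = self.dynamics_plan.agent_fractions
        if abs(sum(af.values()) - 1.0) > 1e-9 and self.dynamics_plan.destroyed_fraction > 0:
            raise ValueError("agent fractions must sum to 1")
        floor = 2 * self.voxel_size
        for d, _ in self.biopore_plan:
            if d < floor:
                raise ValueError(f"biopore diameter {d} below detectability floor {floor}")
        for d, _, _ in self.root_plan:
            if d < floor:
                raise ValueError(f"root diameter {d} below detectability floor {floor}")

    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["shape"] = list(self.shape)
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PhantomSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = yaml.safe_load(text)
        payload["shape"] = tuple(payload["shape"])
        if "gray_model" in payload and "mesofauna_cast_speckle" in payload["gray_model"]:
            payload["gray_model"]["mesofauna_cast_speckle"] = tuple(
                payload["gray_model"]["mesofauna_cast_speckle"]
            )
        for key in ("biopore_plan",):
            if key in payload:
                payload[key] = [tuple(x) for x in payload[key]]
        for key in ("root_plan",):
            if key in payload:
                payload[key] = [tuple(x) for x in payload[key]]
        if "dynamics_plan" in payload:
            dp = payload["dynamics_plan"]
            for key in ("created_plan", "new_root_plan"):
                if key in dp:
                    dp[key] = [tuple(x) for x in dp[key]]
        return cls(**payload)


@dataclass
class PhantomTruth:
    """Per-voxel ground truth plus object tables for a generated core pair."""

    spec: PhantomSpec
    labels_t1: np.ndarray  # uint8 label codes
    labels_t2: np.ndarray | None = None
    object_ids_t1: np.ndarray | None = None  # uint16, 0 = matrix
    object_ids_t2: np.ndarray | None = None
    objects: pd.DataFrame | None = None
    planted_summaries: dict = field(default_factory=dict)
    # internal geometry carried from t1 generation to dynamics planting
    geometry: dict = field(default_factory=dict, repr=False)

    def mask(self, kinds, t: int = 1) -> np.ndarray:
        """Boolean mask of one or more label-code names at timepoint t."""
        labels = self.labels_t1 if t == 1 else self.labels_t2
        if isinstance(kinds, str):
            kinds = (kinds,)
        codes = [LABELS[k] for k in kinds]
        return np.isin(labels, codes)

    def pore_mask(self, t: int = 1) -> np.ndarray:
        """All CT-dark voxels: air plus organic (roots)."""
        names = ["macropore", "biopore", "root_old"]
        if t == 2:
            names.append("root_new")
        return self.mask(names, t)

    def air_mask(self, t: int = 1) -> np.ndarray:
        return self.mask(["macropore", "biopore"], t)

    def recount(self) -> dict:
        """Recompute the planted summaries from the label grids by voxel
        counting (self-consistency check)."""
        out = {}
        n = self.labels_t1.size
        for t, labels in (("t1", self.labels_t1), ("t2", self.labels_t2)):
            if labels is None:
                continue
            counts = np.bincount(labels.ravel(), minlength=8)
            out[f"macroporosity_{t}"] = 100.0 * (counts[L_MACROPORE] + counts[L_BIOPORE]) / n
            out[f"blob_porosity_{t}"] = 100.0 * counts[L_MACROPORE] / n
            out[f"bioporosity_{t}"] = 100.0 * counts[L_BIOPORE] / n
            root = counts[L_ROOT_OLD] + (counts[L_ROOT_NEW] if t == "t2" else 0)
            out[f"root_density_{t}"] = 100.0 * root / n
        return out


# ---------------------------------------------------------------------------
# geometry helpers


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _smooth_path(pts: np.ndarray, window: int = 7) -> np.ndarray:
    if len(pts) <= window:
        return pts
    kernel = np.ones(window) / window
    padded = np.pad(pts, ((window // 2, window // 2), (0, 0)), mode="edge")
    out = np.empty_like(pts)
    for ax in range(3):
        out[:, ax] = np.convolve(padded[:, ax], kernel, mode="valid")[: len(pts)]
    return out


def _free_walk(rng, shape, r_vox, tortuosity, length, start=None):
    """Random walk with downward drift, reflecting at lateral margins.

    Axis 0 is depth.  Returns an (N, 3) float array of voxel coordinates.
    """
    margin = r_vox + 2
    lo = np.array([0.0, margin, margin])
    hi = np.array([shape[0] - 1.0, shape[1] - 1 - margin, shape[2] - 1 - margin])
    if start is None:
        start = np.array(
            [
                rng.uniform(0, 0.1 * shape[0]),
                rng.uniform(lo[1], hi[1]),
                rng.uniform(lo[2], hi[2]),
            ]
        )
    d = _unit(np.array([1.0, tortuosity * rng.normal(), tortuosity * rng.normal()]))
    pts = [np.asarray(start, dtype=float)]
    p = pts[0].copy()
    for _ in range(int(length) - 1):
        d = _unit(d + tortuosity * 0.35 * rng.normal(size=3) + np.array([0.08, 0, 0]))
        p = p + d
        for ax in (1, 2):  # reflect laterally
            if p[ax] < lo[ax]:
                p[ax] = 2 * lo[ax] - p[ax]
                d[ax] = -d[ax]
            elif p[ax] > hi[ax]:
                p[ax] = 2 * hi[ax] - p[ax]
                d[ax] = -d[ax]
        if p[0] > hi[0] or p[0] < lo[0]:
            break
        pts.append(p.copy())
    return _smooth_path(np.array(pts))


def _clearance_walk(
    rng, shape, r_vox, tortuosity, length, clearance, other_pts, min_len,
    other_r=0.0, need_pad=1.5, start_depth_frac=0.15,
):
    """Random walk constrained to stay `r_vox + need_pad` voxels clear of the
    structures encoded in the `clearance` distance grid and of previously
    planned paths (`other_pts` KD-tree data, thickest radius `other_r`).
    Returns None on failure."""
    need = r_vox + need_pad
    sep = r_vox + other_r + 1.5
    tree = cKDTree(other_pts) if len(other_pts) else None
    for _attempt in range(200):
        start = np.array(
            [
                rng.uniform(2, start_depth_frac * shape[0]),
                rng.uniform(r_vox + 3, shape[1] - r_vox - 4),
                rng.uniform(r_vox + 3, shape[2] - r_vox - 4),
            ]
        )
        iv = tuple(np.round(start).astype(int))
        if clearance[iv] <= need:
            continue
        if tree is not None and tree.query(start)[0] <= sep:
            continue
        d = _unit(np.array([1.0, tortuosity * rng.normal(), tortuosity * rng.normal()]))
        pts = [start.copy()]
        p = start.copy()
        while len(pts) < length:
            cands = [d] + [_unit(d + 0.45 * rng.normal(size=3)) for _ in range(14)]
            best, best_clear = None, -np.inf
            for c in cands:
                q = p + c
                if not (
                    1 <= q[0] < shape[0] - 2
                    and r_vox + 2 <= q[1] < shape[1] - r_vox - 3
                    and r_vox + 2 <= q[2] < shape[2] - r_vox - 3
                ):
                    continue
                qi = tuple(np.round(q).astype(int))
                cl = clearance[qi]
                if cl <= need:
                    continue
                if tree is not None and tree.query(q)[0] <= sep:
                    continue
                if cl >= need + 2.0:
                    # comfortably clear: follow the current heading
                    best, best_clear = c, cl
                    break
                # otherwise steer toward the most open acceptable step
                if cl > best_clear:
                    best, best_clear = c, cl
            if best is None:
                break
            p = p + best
            d = _unit(best + np.array([0.03, 0, 0]))
            pts.append(p.copy())
        if len(pts) >= min_len:
            return _smooth_path(np.array(pts))
    return None


def _sample_polyline(pts: np.ndarray, step: float = 0.5):
    """Resample a polyline at fixed arclength steps; returns (points, arcs)."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        return pts[:1], np.array([0.0])
    s = np.arange(0.0, total + step / 2, step)
    out = np.empty((len(s), 3))
    for ax in range(3):
        out[:, ax] = np.interp(s, arc, pts[:, ax])
    return out, s


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


class _TubeRaster:
    """Rasterise a batch of swept-sphere tubes in one EDT pass.

    Each voxel belongs to the tube whose centerline is nearest, provided the
    distance does not exceed that tube's radius there.
    """

    def __init__(self, shape):
        self.shape = shape
        self.seed_id = np.zeros(shape, dtype=np.uint16)
        self.seed_r = np.zeros(shape, dtype=np.float32)
        self.seed_arc = np.zeros(shape, dtype=np.float32)

    def add(self, obj_id: int, pts: np.ndarray, radius_vox) -> None:
        samples, arcs = _sample_polyline(pts, step=0.5)
        iv = np.round(samples).astype(int)
        ok = np.all((iv >= 0) & (iv < np.array(self.shape)), axis=1)
        iv, arcs = iv[ok], arcs[ok]
        radii = np.broadcast_to(np.float32(radius_vox), arcs.shape)
        self.seed_id[iv[:, 0], iv[:, 1], iv[:, 2]] = obj_id
        self.seed_r[iv[:, 0], iv[:, 1], iv[:, 2]] = radii
        self.seed_arc[iv[:, 0], iv[:, 1], iv[:, 2]] = arcs

    def run(self):
        """Returns (member mask, object id grid, arclength grid)."""
        if not self.seed_id.any():
            z = np.zeros(self.shape, dtype=bool)
            return z, self.seed_id, self.seed_arc
        dist, idx = ndi.distance_transform_edt(self.seed_id == 0, return_indices=True)
        near_id = self.seed_id[idx[0], idx[1], idx[2]]
        near_r = self.seed_r[idx[0], idx[1], idx[2]]
        member = dist <= near_r
        arc = np.where(member, self.seed_arc[idx[0], idx[1], idx[2]], 0.0).astype(np.float32)
        return member, np.where(member, near_id, 0).astype(np.uint16), arc


# ---------------------------------------------------------------------------
# generation


def generate_core_pair(spec: PhantomSpec):
    """Generate a co-registered pair of gray volumes and the ground truth.

    Returns ``(vol_t1, vol_t2, truth)``.  The second timepoint differs from
    the first only by the planted dynamics (destroyed/created biopores, new
    roots), an optional whole-voxel rigid jitter, and fresh noise.
    """
    shape = tuple(int(s) for s in spec.shape)
    if min(shape) < 64:
        raise ValueError(f"each axis must be >= 64 voxels, got {shape}")
    _check_feasible(spec, shape)
    ss = np.random.SeedSequence(spec.seed)
    (
        rng_geom,
        rng_noise1,
        rng_noise2,
        rng_dyn,
        rng_speckle,
    ) = [np.random.default_rng(s) for s in ss.spawn(5)]

    truth = _build_t1(spec, shape, rng_geom)
    truth = plant_dynamics(truth, spec, rng=rng_dyn)

    vol_t1 = _render_gray(spec, truth.labels_t1, rng_noise1, rng_speckle)
    vol_t2 = _render_gray(spec, truth.labels_t2, rng_noise2, rng_speckle)
    vol_t1.log(f"phantom t1 seed={spec.seed}")
    vol_t2.log(f"phantom t2 seed={spec.seed} jitter={spec.jitter_voxels}")
    return vol_t1, vol_t2, truth


def _check_feasible(spec: PhantomSpec, shape) -> None:
    core_mm3 = np.prod(shape) * spec.voxel_size**3
    planned = spec.blob_porosity_target * core_mm3
    depth_mm = shape[0] * spec.voxel_size
    for d, c in spec.biopore_plan:
        planned += c * np.pi / 4 * d**2 * 0.7 * depth_mm
    for d, c, _ in spec.root_plan:
        planned += c * np.pi / 4 * d**2 * 0.7 * depth_mm
    if planned > 0.6 * core_mm3:
        raise PlacementError(
            f"plan infeasible: planted volume ~{planned:.0f} mm^3 exceeds 60% of "
            f"the {core_mm3:.0f} mm^3 core"
        )


def _build_t1(spec: PhantomSpec, shape, rng) -> PhantomTruth:
    labels = np.zeros(shape, dtype=np.uint8)
    ids = np.zeros(shape, dtype=np.uint16)
    vsz = spec.voxel_size
    objects: list[dict] = []
    next_id = 1

    # --- irregular blob pores: thresholded Gaussian random field
    if spec.blob_porosity_target > 0:
        field_ = ndi.gaussian_filter(
            rng.standard_normal(shape).astype(np.float32), spec.blob_smoothing_voxels
        )
        thr = np.quantile(field_, spec.blob_porosity_target)
        blob = field_ < thr
        labels[blob] = L_MACROPORE
        ids[blob] = next_id
        objects.append(
            dict(id=next_id, kind="blob_pore", timepoint=1, diameter_mm=np.nan,
                 length_mm=np.nan, agent="", note="random-field blobs")
        )
        next_id += 1
        del field_

    # --- biopores: swept spheres along smoothed downward walks
    biopore_geoms = []
    raster = _TubeRaster(shape)
    starts: list[tuple[np.ndarray, float]] = []
    # place the widest tubes first: they are the hardest to fit
    for diam_mm, count in sorted(spec.biopore_plan, key=lambda x: -x[0]):
        r = diam_mm / 2 / vsz
        for _ in range(int(count)):
            start = _separated_start(rng, shape, r, starts)
            length = rng.uniform(0.55, 0.9) * shape[0]
            pts = _free_walk(rng, shape, r, tortuosity=0.12, length=length, start=start)
            raster.add(next_id, pts, r)
            biopore_geoms.append(dict(id=next_id, pts=pts, r=r, diam=diam_mm))
            objects.append(
                dict(id=next_id, kind="biopore", timepoint=1, diameter_mm=diam_mm,
                     length_mm=_polyline_length(pts) * vsz, agent="", note="")
            )
            next_id += 1
    bp_member, bp_ids, bp_arc = raster.run()
    labels[bp_member] = L_BIOPORE
    ids[bp_member] = bp_ids[bp_member]

    # --- old roots: thinner organic tubes; mutually separated (real roots
    # cross but do not fuse along their length)
    raster = _TubeRaster(shape)
    root_geoms = []
    free_grid = np.full(shape, np.inf, dtype=np.float32)
    placed_pts = np.empty((0, 3))
    placed_max_r = 0.0
    for diam_mm, count, tort in sorted(spec.root_plan, key=lambda x: -x[0]):
        r = diam_mm / 2 / vsz
        for _ in range(int(count)):
            length = rng.uniform(0.55, 0.85) * shape[0]
            pts = _clearance_walk(
                rng, shape, r, tort, length, free_grid, placed_pts,
                min_len=int(0.6 * length), other_r=placed_max_r,
            )
            if pts is None:  # crowded core: accept an unconstrained walk
                pts = _free_walk(rng, shape, r, tortuosity=tort, length=length)
            samples, _ = _sample_polyline(pts, step=1.0)
            placed_pts = np.vstack([placed_pts, samples])
            placed_max_r = max(placed_max_r, r)
            raster.add(next_id, pts, r)
            root_geoms.append(dict(id=next_id, pts=pts, r=r, diam=diam_mm))
            objects.append(
                dict(id=next_id, kind="root_old", timepoint=1, diameter_mm=diam_mm,
                     length_mm=_polyline_length(pts) * vsz, agent="", note="")
            )
            next_id += 1
    ro_member, ro_ids, _ = raster.run()
    labels[ro_member] = L_ROOT_OLD  # roots overwrite pores they cross
    ids[ro_member] = ro_ids[ro_member]
    # keep biopore bookkeeping grids consistent with the overwrite
    bp_ids[ro_member] = 0

    truth = PhantomTruth(spec=spec, labels_t1=labels, object_ids_t1=ids)
    truth.geometry = dict(
        biopores=biopore_geoms,
        roots_old=root_geoms,
        biopore_id_grid=bp_ids,
        biopore_arc_grid=bp_arc,
        next_id=next_id,
        objects=objects,
    )
    return truth


def _separated_start(rng, shape, r, starts, tries: int = 500):
    for _ in range(tries):
        cand = np.array(
            [0.0, rng.uniform(r + 3, shape[1] - r - 4), rng.uniform(r + 3, shape[2] - r - 4)]
        )
        if all(np.linalg.norm(cand[1:] - s[1:]) > r + rs + 2 for s, rs in starts):
            starts.append((cand, r))
            return cand
    raise PlacementError("could not place biopore starts with the required separation")


def plant_dynamics(truth: PhantomTruth, spec: PhantomSpec, rng=None) -> PhantomTruth:
    """Realise the dynamics plan: destroyed/created biopores and new roots.

    Fills in ``labels_t2``, ``object_ids_t2``, the object table and the
    planted summaries of ``truth`` (which must come from the t1 builder).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(5)[3])
    plan = spec.dynamics_plan
    shape = truth.labels_t1.shape
    vsz = spec.voxel_size
    geom = truth.geometry
    labels2 = truth.labels_t1.copy()
    ids2 = truth.object_ids_t1.copy()
    objects = list(geom["objects"])
    next_id = geom["next_id"]
    min_keep_vox = int(np.ceil(0.3 / vsz**3))  # survive the 0.3 mm^3 size opening

    # ---- new roots -------------------------------------------------------
    new_root_list = [
        dict(diam=d, r=d / 2 / vsz, tort=t)
        for d, c, t in plan.new_root_plan
        for _ in range(int(c))
    ]
    tf = plan.trajectory_fractions
    f_bio = tf.get("into_biopore", 0.0)
    f_mac = tf.get("into_macropore", 0.0)

    # matrix roots: walks that avoid biopores and old roots; incidental
    # crossings of irregular blob pores are allowed and accounted to the
    # into-macropore budget
    clearance = ndi.distance_transform_edt(
        ~np.isin(truth.labels_t1, (L_BIOPORE, L_ROOT_OLD))
    ).astype(np.float32)
    mc_roots, planned_pts = [], np.empty((0, 3))
    placed_max_r = 0.0
    for nr in sorted(new_root_list, key=lambda x: -x["r"]):  # thickest first
        area = np.pi * nr["r"] ** 2
        min_len = max(int(min_keep_vox / area * 1.3), int(0.35 * shape[0]))
        target_len = max(int(0.85 * shape[0]), int(1.2 * min_len))
        if min_len > 1.8 * shape[0]:
            raise PlacementError(
                f"new root O {nr['diam']} mm too thin to survive the size opening "
                f"within this core depth"
            )
        pts = _clearance_walk(
            rng, shape, nr["r"], nr["tort"], target_len, clearance, planned_pts,
            min_len, other_r=placed_max_r,
        )
        if pts is None:
            raise PlacementError("could not route a new root through the matrix")
        nr["pts"] = pts
        samples, _ = _sample_polyline(pts, step=1.0)
        planned_pts = np.vstack([planned_pts, samples])
        placed_max_r = max(placed_max_r, nr["r"])
        mc_roots.append(nr)

    # threading roots realise the into-biopore fraction; planned ~10% long
    # so the exact volume can be trimmed back after rasterisation
    v_mc = sum(np.pi * nr["r"] ** 2 * _polyline_length(nr["pts"]) for nr in mc_roots)
    thread_roots = []
    if f_bio > 0 and v_mc > 0:
        v_thread_target = 1.10 * f_bio * v_mc / (1.0 - f_bio)
        hosts = sorted(geom["biopores"], key=lambda b: -b["r"])
        remaining = v_thread_target
        r_thread = max(d for d, _, _ in plan.new_root_plan) / 2 / vsz
        for host in hosts:
            if remaining <= 0:
                break
            if host["r"] < r_thread + 2:
                continue
            area = np.pi * r_thread**2
            host_len = _polyline_length(host["pts"])
            want_len = remaining / area
            # generous margin over the size-opening floor: the difference
            # imaging erodes a little of every detected root
            min_len = min_keep_vox / area * 1.6
            length = min(host_len * 0.9, max(want_len, min_len))
            if length < min_len:
                continue
            samples, arcs = _sample_polyline(host["pts"], step=0.5)
            keep = arcs <= length
            thread_roots.append(
                dict(diam=2 * r_thread * vsz, r=r_thread, pts=samples[keep], host=host["id"])
            )
            remaining -= area * length
    host_ids = {t["host"] for t in thread_roots}

    # ---- destroyed biopores ---------------------------------------------
    bp_ids = geom["biopore_id_grid"]
    bp_arc = geom["biopore_arc_grid"]
    destroyed_total = 0
    if plan.destroyed_fraction > 0:
        vol_by_id = {
            b["id"]: int(np.count_nonzero(bp_ids == b["id"])) for b in geom["biopores"]
        }
        v_bio_total = sum(vol_by_id.values())
        budget = {a: plan.agent_fractions.get(a, 0.0) * plan.destroyed_fraction * v_bio_total
                  for a in AGENTS}
        candidates = [b for b in geom["biopores"] if b["id"] not in host_ids]
        order = rng.permutation(len(candidates))
        queue = []
        for i in order:
            pore = candidates[i]
            sel = bp_ids == pore["id"]
            n = int(np.count_nonzero(sel))
            if n >= min_keep_vox:
                queue.append(dict(pore=pore, sel=sel, arcs=bp_arc[sel], n=n, q=0.0))
        # agents consume successive arc intervals of the shuffled pores, so
        # one pore can be destroyed by several agents along its length
        for agent in AGENTS:
            want = budget[agent]
            while want >= min_keep_vox and queue:
                entry = queue[0]
                avail = entry["n"] * (1.0 - entry["q"])
                if avail < min_keep_vox:
                    queue.pop(0)
                    continue
                take = min(avail, want)
                q_new = min(entry["q"] + take / entry["n"], 1.0)
                thr_hi = np.quantile(entry["arcs"], q_new)
                if entry["q"] > 0:
                    thr_lo = np.quantile(entry["arcs"], entry["q"])
                    region = entry["sel"] & (bp_arc > thr_lo) & (bp_arc <= thr_hi)
                else:
                    region = entry["sel"] & (bp_arc <= thr_hi)
                taken = int(np.count_nonzero(region))
                if taken == 0:
                    queue.pop(0)
                    continue
                labels2[region] = _AGENT_LABEL[agent]
                ids2[region] = next_id
                objects.append(
                    dict(id=next_id, kind="cast_fill", timepoint=2,
                         diameter_mm=entry["pore"]["diam"], length_mm=np.nan,
                         agent=agent, note=f"destroys biopore {entry['pore']['id']}")
                )
                next_id += 1
                destroyed_total += taken
                want -= taken
                entry["q"] = q_new
                if entry["q"] >= 0.999:
                    queue.pop(0)
        target_total = plan.destroyed_fraction * v_bio_total
        if destroyed_total < 0.85 * target_total:
            raise PlacementError("destruction plan exceeds available biopore volume")

    # ---- rasterise new roots (after destruction so threading hosts are
    # guaranteed intact) ---------------------------------------------------
    all_new = mc_roots + thread_roots
    member = np.zeros(shape, dtype=bool)
    if all_new:
        raster = _TubeRaster(shape)
        for nr in all_new:
            nr["obj_id"] = next_id
            raster.add(next_id, nr["pts"], nr["r"])
            next_id += 1
        member, mids, new_arc = raster.run()
        labels2[member] = L_ROOT_NEW
        ids2[member] = mids[member]

        # trim threading-root tips so the into-biopore volume fraction hits
        # the plan exactly (trimmed voxels revert to biopore air)
        thread_ids = [t["obj_id"] for t in thread_roots]
        if thread_ids and f_bio > 0:
            in_bio = member & (truth.labels_t1 == L_BIOPORE)
            n_total = int(np.count_nonzero(member))
            n_bio = int(np.count_nonzero(in_bio))
            excess = int(round((n_bio - f_bio * n_total) / (1.0 - f_bio)))
            if excess > 0:
                for tid in reversed(thread_ids):
                    if excess <= 0:
                        break
                    sel = in_bio & (mids == tid)
                    n = int(np.count_nonzero(sel))
                    cut = min(excess, n)
                    if cut == 0:
                        continue
                    arcs = new_arc[sel]
                    thr = np.quantile(arcs, 1.0 - cut / n)
                    drop = sel & (new_arc > thr)
                    labels2[drop] = L_BIOPORE
                    ids2[drop] = truth.object_ids_t1[drop]
                    member[drop] = False
                    excess -= int(np.count_nonzero(drop))

    # ---- macropore chambers ---------------------------------------------
    # compact blobby cavities carved (at both timepoints) around the matrix
    # root paths until the planned into-macropore volume share is reached
    if f_mac > 0 and mc_roots:
        _carve_chambers(
            rng, shape, truth, labels2, ids2, member, mc_roots, clearance,
            f_mac, objects, next_id,
        )
        next_id += 1

    # ---- created biopores ------------------------------------------------
    if plan.created_plan:
        # burrowing creates pores through matrix and irregular blob pores
        # but not through roots, cast infills or existing biopores (tunnels
        # through existing tubes create nothing there)
        clearance2 = ndi.distance_transform_edt(
            np.isin(labels2, (L_MATRIX, L_MACROPORE))
        )
        raster = _TubeRaster(shape)
        created_info = []
        created_pts = np.empty((0, 3))
        created_max_r = 0.0
        for diam_mm, count in sorted(plan.created_plan, key=lambda x: -x[0]):
            r = diam_mm / 2 / vsz
            for _ in range(int(count)):
                min_len = max(int(0.3 * shape[0]),
                              int(1.3 * min_keep_vox / (np.pi * r**2)))
                pts = None
                for pad in (1.5, 0.5, 0.0):  # relax clearance if crowded
                    pts = _clearance_walk(
                        rng, shape, r, 0.12, int(0.7 * shape[0]), clearance2,
                        created_pts, min_len, other_r=created_max_r,
                        need_pad=pad, start_depth_frac=0.4,
                    )
                    if pts is not None:
                        break
                if pts is None:
                    raise PlacementError("could not place a created biopore")
                created_info.append(dict(id=next_id, diam=diam_mm, pts=pts))
                raster.add(next_id, pts, r)
                samples, _ = _sample_polyline(pts, step=1.0)
                created_pts = np.vstack([created_pts, samples])
                created_max_r = max(created_max_r, r)
                next_id += 1
        cmember, cmids, _ = raster.run()
        create = cmember & np.isin(labels2, (L_MATRIX, L_MACROPORE))
        labels2[create] = L_BIOPORE
        ids2[create] = cmids[create]
        for info in created_info:
            objects.append(
                dict(id=info["id"], kind="biopore_created", timepoint=2,
                     diameter_mm=info["diam"], length_mm=_polyline_length(info["pts"]) * vsz,
                     agent="", note="")
            )

    # ---- truth trajectory fractions (registered frame, before jitter) ----
    new_mask = labels2 == L_ROOT_NEW
    traj = _trajectory_lookup(truth.labels_t1, new_mask)
    for nr in all_new:
        objects.append(
            dict(id=nr["obj_id"], kind="root_new", timepoint=2, diameter_mm=nr["diam"],
                 length_mm=_polyline_length(nr["pts"]) * vsz, agent="",
                 note="threads biopore" if "host" in nr else "matrix/chamber path")
        )

    # ---- optional whole-voxel rigid jitter -------------------------------
    if spec.jitter_voxels:
        axis = int(rng.integers(1, 3))  # lateral axis
        sign = int(rng.choice([-1, 1]))
        shift = [0, 0, 0]
        shift[axis] = sign * int(spec.jitter_voxels)
        labels2 = _shift_fill(labels2, shift, fill=L_MATRIX)
        ids2 = _shift_fill(ids2, shift, fill=0)
        truth.geometry["jitter_shift"] = tuple(shift)

    truth.labels_t2 = labels2
    truth.object_ids_t2 = ids2
    truth.objects = pd.DataFrame(objects)
    truth.planted_summaries = _summarise(truth, destroyed_total, traj)
    return truth


def _carve_chambers(
    rng, shape, truth, labels2, ids2, member, mc_roots, bio_clearance,
    f_mac, objects, chamber_id,
) -> None:
    """Greedily carve compact cavities on matrix-root paths until the
    into-macropore share of the new-root volume reaches ``f_mac``."""
    labels1 = truth.labels_t1
    ids1 = truth.object_ids_t1
    n_total = int(np.count_nonzero(member))
    if n_total == 0:
        return
    target = f_mac * n_total
    current = float(np.count_nonzero(member & (labels1 == L_MACROPORE)))

    candidates = []  # (root index, center point, R)
    for ri, nr in enumerate(mc_roots):
        samples, _ = _sample_polyline(nr["pts"], step=1.0)
        R = nr["r"] * 2.0 + 1.5
        half = np.sqrt(max(R**2 - (nr["r"] + 1.0) ** 2, 1.0))
        # dense candidate ladder; the acceptance loop enforces the minimum
        # separation so chambers never chain into a tube-like cavity
        spacing = max(int(np.ceil(1.2 * half)), 2)
        margin = R + 1
        per_root = []
        for idx in range(0, len(samples), spacing):
            p = samples[idx]
            if np.any(p < margin) or np.any(p > np.array(shape) - margin - 1):
                continue
            pi = tuple(np.round(p).astype(int))
            # chambers may come close to biopores (the carve only converts
            # matrix/blob voxels) but must not swallow their walls
            if bio_clearance[pi] <= max(R - 3.0, nr["r"] + 2.0):
                continue
            per_root.append((ri, p, R, half))
        candidates.append(per_root)
    # round-robin over roots so chambers spread evenly
    ordered = []
    while any(candidates):
        for per_root in candidates:
            if per_root:
                ordered.append(per_root.pop(0))

    carved_any = False
    accepted: dict[int, list] = {}
    for ri, p, R, half in ordered:
        if current >= target:
            break
        # solid matrix bridge to every chamber already carved on this root
        if any(np.linalg.norm(p - q) < 3.0 * half for q in accepted.get(ri, [])):
            continue
        spheres = [(p, R)]
        for _ in range(2):
            off = rng.normal(scale=0.22 * R, size=3)
            spheres.append((p + off, R * rng.uniform(0.75, 0.95)))
        lo = np.maximum(np.floor(p - 1.6 * R).astype(int), 0)
        hi = np.minimum(np.ceil(p + 1.6 * R).astype(int) + 1, shape)
        box = tuple(slice(l, h) for l, h in zip(lo, hi))
        ball = np.zeros(tuple(h - l for l, h in zip(lo, hi)), dtype=bool)
        zz, yy, xx = np.ogrid[box[0], box[1], box[2]]
        for c, rad in spheres:
            ball |= (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= rad**2
        l1 = labels1[box]
        gain = int(np.count_nonzero(ball & member[box] & (l1 == L_MATRIX)))
        if gain == 0:
            continue
        if abs(current + gain - target) >= abs(current - target):
            continue  # would overshoot more than it helps
        carve1 = ball & (l1 == L_MATRIX)
        labels1[box][carve1] = L_MACROPORE
        sub_ids1 = ids1[box]
        sub_ids1[carve1 & (sub_ids1 == 0)] = chamber_id
        l2 = labels2[box]
        carve2 = ball & (l2 == L_MATRIX)
        l2[carve2] = L_MACROPORE
        sub_ids2 = ids2[box]
        sub_ids2[carve2 & (sub_ids2 == 0)] = chamber_id
        current += gain
        carved_any = True
        accepted.setdefault(ri, []).append(p)
    if carved_any:
        objects.append(
            dict(id=chamber_id, kind="blob_pore", timepoint=1, diameter_mm=np.nan,
                 length_mm=np.nan, agent="", note="macropore chambers")
        )


def _trajectory_lookup(labels_t1, new_mask) -> dict:
    n = int(np.count_nonzero(new_mask))
    if n == 0:
        return {k: 0.0 for k in ("into_biopore", "into_macropore", "into_matrix", "into_old_root")}
    prev = labels_t1[new_mask]
    return {
        "into_biopore": float(np.count_nonzero(prev == L_BIOPORE)) / n,
        "into_macropore": float(np.count_nonzero(prev == L_MACROPORE)) / n,
        "into_matrix": float(np.count_nonzero(prev == L_MATRIX)) / n,
        "into_old_root": float(np.count_nonzero(prev == L_ROOT_OLD)) / n,
    }


def _summarise(truth: PhantomTruth, destroyed_total: int, traj: dict) -> dict:
    out = truth.recount()
    n = truth.labels_t1.size
    vsz3 = truth.spec.voxel_size**3
    out["destroyed_biopore_voxels"] = int(destroyed_total)
    out["destroyed_fraction_of_t1_bioporosity"] = (
        destroyed_total / max(np.count_nonzero(truth.labels_t1 == L_BIOPORE), 1)
    )
    created = np.count_nonzero(
        (truth.labels_t2 == L_BIOPORE) & (truth.labels_t1 != L_BIOPORE)
    ) if truth.geometry.get("jitter_shift") is None else None
    if created is not None:
        out["created_biopore_voxels"] = int(created)
    out["trajectory_fractions"] = traj
    out["core_volume_mm3"] = n * vsz3
    # per-agent destroyed voxel counts
    for agent, code in _AGENT_LABEL.items():
        out[f"destroyed_by_{agent}_voxels"] = int(np.count_nonzero(truth.labels_t2 == code))
    return out


def _paint_spheres(shape, spheres) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for center, R in spheres:
        c = np.asarray(center)
        lo = np.maximum(np.floor(c - R).astype(int), 0)
        hi = np.minimum(np.ceil(c + R).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        ball = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= R**2
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= ball
    return mask


def _shift_fill(arr: np.ndarray, shift, fill) -> np.ndarray:
    out = np.full_like(arr, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(shift):
        if s > 0:
            src[ax], dst[ax] = slice(0, arr.shape[ax] - s), slice(s, None)
        elif s < 0:
            src[ax], dst[ax] = slice(-s, None), slice(0, arr.shape[ax] + s)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _render_gray(spec: PhantomSpec, labels: np.ndarray, rng_noise, rng_speckle) -> GrayVolume:
    g = spec.gray_model
    gray = np.full(labels.shape, g["matrix"], dtype=np.float32)
    gray[np.isin(labels, AIR_LABELS)] = g["air"]
    gray[(labels == L_ROOT_OLD) | (labels == L_ROOT_NEW)] = g["organic"]
    gray[labels == L_CAST_EARTHWORM] = g["earthworm_cast"]
    gray[labels == L_COMPACTION] = g["matrix"]
    meso = labels == L_CAST_MESOFAUNA
    if meso.any():
        lo, hi = g["mesofauna_cast_speckle"]
        b = spec.speckle_block
        coarse = tuple(-(-s // b) for s in labels.shape)
        blocks = rng_speckle.random(coarse) < 0.5
        fine = np.kron(blocks, np.ones((b, b, b), dtype=bool))[
            : labels.shape[0], : labels.shape[1], : labels.shape[2]
        ]
        gray[meso] = np.where(fine[meso], lo, hi)
    if spec.noise_sd > 0:
        gray = gray + rng_noise.normal(0.0, spec.noise_sd, labels.shape).astype(np.float32)
    vox = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    return GrayVolume(vox, spec.voxel_size, bit_depth=8)


def generate_feasible_pair(make_spec, seed: int, attempts: int = 6, step: int = 1009):
    """Generate a core pair, resampling the seed on placement failure.

    Random plans occasionally cannot be placed in a small, crowded core;
    this retries with deterministically derived alternative seeds so a
    batch generation never aborts on one unlucky draw.
    """
    last = None
    for k in range(attempts):
        try:
            return generate_core_pair(make_spec(int(seed) + k * step))
        except PlacementError as exc:
            last = exc
    raise last


def compact_spec(seed: int = 0, shape=(96, 96, 96), with_dynamics: bool = True) -> PhantomSpec:
    """A reduced core configuration for quick studies: the same material
    model and process mix as the default, scaled to a small volume (fewer,
    smaller tubes so placement stays feasible)."""
    dyn = DynamicsPlan(
        destroyed_fraction=0.30,
        agent_fractions={"earthworm": 0.4, "mesofauna": 0.4, "unidentified": 0.2},
        created_plan=[(0.8, 1)],
        new_root_plan=[(0.4, 2, 0.2), (0.5, 1, 0.15)],
        trajectory_fractions={"into_biopore": 0.15, "into_macropore": 0.40, "into_matrix": 0.45},
    ) if with_dynamics else DynamicsPlan(
        destroyed_fraction=0.0, created_plan=[], new_root_plan=[],
    )
    return PhantomSpec(
        shape=tuple(shape),
        biopore_plan=[(0.8, 2), (1.2, 1)],
        root_plan=[(0.3, 3, 0.25), (0.4, 3, 0.2)],
        dynamics_plan=dyn,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# persistence


def save_phantom(outdir: str | Path, vol_t1, vol_t2, truth: PhantomTruth) -> Path:
    """Write volumes (multi-page TIFF), truth labels (uint8 TIFF stacks),
    object table (CSV), summaries (JSON) and the spec (YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(vol_t1, outdir / "gray_t1.tif")
    write_volume(vol_t2, outdir / "gray_t2.tif")
    tifffile.imwrite(outdir / "labels_t1.tif", truth.labels_t1)
    tifffile.imwrite(outdir / "labels_t2.tif", truth.labels_t2)
    truth.objects.to_csv(outdir / "objects.csv", index=False)
    truth.spec.to_yaml(outdir / "spec.yaml")
    summaries = {
        k: v for k, v in truth.planted_summaries.items()
    }
    (outdir / "planted_summaries.json").write_text(json.dumps(summaries, indent=2, default=float))
    return outdir
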