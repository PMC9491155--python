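"""Structural labelling, root trajectories and cast-agent classification.

Two jobs live here.  First, the segmentation masks are combined into a
per-voxel structural label volume (matrix / macropore / biopore / old root,
with precedence old root > biopore > macropore), against which newly grown
roots are looked up to quantify where they grew (into existing biopores,
into other macropores, or into the dense matrix).

Second, destroyed-biopore infills are attributed to their agent — large
smooth earthworm casts, granular mesofauna casts, or unidentified causes
(compaction, internal erosion) — with an ensemble of decision trees on
multiscale voxel features of the gray image, followed by a per-segment
majority vote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from sklearn.ensemble import RandomForestClassifier

from .tubeseg import separate_segments

__all__ = [
    "STRUCTURE_CODES",
    "AGENT_CODES",
    "TrajectoryFractions",
    "build_structure_labels",
    "root_trajectory_fractions",
    "voxel_features",
    "sample_training_voxels",
    "train_cast_classifier",
    "classify_destroyed_biopores",
]

STRUCTURE_CODES = {"matrix": 0, "macropore": 1, "biopore": 2, "root_old": 3}
AGENT_CODES = {"earthworm_cast": 0, "mesofauna_cast": 1, "unidentified": 2}
_AGENT_NAMES = {v: k for k, v in AGENT_CODES.items()}


def build_structure_labels(
    pore_mask: np.ndarray, biopore_mask: np.ndarray, root_mask: np.ndarray
) -> np.ndarray:
    """Combine masks into one categorical volume.

    Precedence: old root > biopore > macropore (pore minus biopore minus
    root) > matrix; every voxel gets exactly one code.
    """
    shapes = {np.asarray(m).shape for m in (pore_mask, biopore_mask, root_mask)}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes differ: {shapes}")
    labels = np.zeros(pore_mask.shape, dtype=np.uint8)
    labels[np.asarray(pore_mask, bool)] = STRUCTURE_CODES["macropore"]
    labels[np.asarray(biopore_mask, bool)] = STRUCTURE_CODES["biopore"]
    labels[np.asarray(root_mask, bool)] = STRUCTURE_CODES["root_old"]
    return labels


@dataclass
class TrajectoryFractions:
    """Where new-root volume sat at the earlier timepoint."""

    volumes_mm3: dict
    percents: dict  # 4-class view, sums to 100
    percents_3class: dict  # old-root voxels folded into matrix
    total_volume_mm3: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(self.percents),
                "volume_mm3": [self.volumes_mm3[k] for k in self.percents],
                "percent": [self.percents[k] for k in self.percents],
            }
        )


def root_trajectory_fractions(
    new_root_mask: np.ndarray, labels_t1: np.ndarray, voxel_size: float
) -> TrajectoryFractions:
    """Look up each new-root voxel's structural class at the first
    timepoint and report volume fractions per class."""
    new_root_mask = np.asarray(new_root_mask, dtype=bool)
    if new_root_mask.shape != labels_t1.shape:
        raise ValueError("new-root mask and labels are not aligned")
    classes = [
        ("into_biopore", STRUCTURE_CODES["biopore"]),
        ("into_macropore", STRUCTURE_CODES["macropore"]),
        ("into_matrix", STRUCTURE_CODES["matrix"]),
        ("into_old_root", STRUCTURE_CODES["root_old"]),
    ]
    n = int(new_root_mask.sum())
    vox3 = voxel_size**3
    if n == 0:
        zero = {k: 0.0 for k, _ in classes}
        return TrajectoryFractions(dict(zero), dict(zero), {k: 0.0 for k in
                                   ("into_biopore", "into_macropore", "into_matrix")}, 0.0)
    prev = labels_t1[new_root_mask]
    volumes, percents = {}, {}
    for name, code in classes:
        c = int(np.count_nonzero(prev == code))
        volumes[name] = c * vox3
        percents[name] = 100.0 * c / n
    p3 = {
        "into_biopore": percents["into_biopore"],
        "into_macropore": percents["into_macropore"],
        "into_matrix": percents["into_matrix"] + percents["into_old_root"],
    }
    return TrajectoryFractions(volumes, percents, p3, n * vox3)


# ---------------------------------------------------------------------------
# voxel features


FEATURE_NAMES = ("gaussian", "gradient_magnitude", "laplacian",
                 "structure_tensor_max_eig", "local_variance")


def voxel_features(
    gray: np.ndarray,
    scales=(1, 2, 4),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Multiscale feature stack for voxel classification.

    Per scale: Gaussian-smoothed intensity, gradient magnitude, Laplacian,
    largest structure-tensor eigenvalue, and local variance — 5 features
    per scale.  Returns an (n_voxels, 5 * n_scales) array over ``mask``
    voxels (or all voxels, flattened, when ``mask`` is None).
    """
    data = np.asarray(gray, dtype=np.float32)
    if mask is None:
        sel = np.ones(data.shape, dtype=bool)
    else:
        sel = np.asarray(mask, dtype=bool)
    cols = []
    for s in scales:
        sm = ndi.gaussian_filter(data, s)
        cols.append(sm[sel])
        cols.append(ndi.gaussian_gradient_magnitude(data, s)[sel])
        cols.append(ndi.gaussian_laplace(data, s)[sel])
        # structure tensor: outer product of first derivatives, smoothed
        grads = [ndi.gaussian_filter(data, s, order=tuple(int(i == ax) for i in range(3)))
                 for ax in range(3)]
        T = np.empty(data.shape + (3, 3), dtype=np.float32)
        for i in range(3):
            for j in range(i, 3):
                comp = ndi.gaussian_filter(grads[i] * grads[j], s)
                T[..., i, j] = comp
                T[..., j, i] = comp
        eig = np.linalg.eigvalsh(T[sel])[:, -1]
        cols.append(eig)
        del T
        m2 = ndi.gaussian_filter(data**2, s)
        cols.append(np.clip(m2 - sm**2, 0, None)[sel])
    return np.stack(cols, axis=1)


def sample_training_voxels(
    truth_agent_labels: np.ndarray,
    destroyed_mask: np.ndarray,
    fraction: float = 0.001,
    min_per_class: int = 200,
    rng=None,
) -> np.ndarray:
    """Stratified sparse annotation: indices (flat) of a small fraction of
    destroyed voxels per agent class, emulating manual training scribbles."""
    rng = np.random.default_rng(rng)
    flat_lab = truth_agent_labels.ravel()
    flat_sel = np.asarray(destroyed_mask, bool).ravel()
    picks = []
    for code in np.unique(flat_lab[flat_sel]):
        idx = np.nonzero(flat_sel & (flat_lab == code))[0]
        k = max(min_per_class, int(len(idx) * fraction))
        k = min(k, len(idx))
        picks.append(rng.choice(idx, size=k, replace=False))
    return np.sort(np.concatenate(picks))


def train_cast_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_estimators: int = 100,
):
    """Random forest on voxel features with out-of-bag error estimate.

    Requires all three agent classes in the training voxels.  Returns
    ``(classifier, oob_error)``; training is deterministic for a fixed seed.
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    if len(present) < 3:
        raise ValueError(
            f"need training voxels from >= 3 agent classes, got {len(present)}"
        )
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        oob_score=True,
        random_state=int(seed),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # OOB warnings on tiny inputs
        clf.fit(features, labels)
    return clf, float(1.0 - clf.oob_score_)


def classify_destroyed_biopores(
    gray_t2: np.ndarray,
    destroyed_mask: np.ndarray,
    classifier,
    voxel_size: float,
    scales=(1, 2, 4),
    total_bioporosity_pct: float | None = None,
) -> pd.DataFrame:
    """Attribute each destroyed-biopore segment to its destruction agent.

    The destroyed mask is split by distance-transform watershed; every
    voxel is classified from the gray image features; each segment takes
    its majority class (ties break to the lowest class code and are
    flagged).  Returns one row per segment plus per-agent totals in the
    frame attrs.
    """
    destroyed_mask = np.asarray(destroyed_mask, dtype=bool)
    cols = ["segment", "voxels", "volume_mm3", "agent", "vote_fraction", "tie"]
    if not destroyed_mask.any():
        out = pd.DataFrame(columns=cols)
        out.attrs["per_agent"] = {}
        return out
    segments = separate_segments(destroyed_mask)
    X = voxel_features(gray_t2, scales=scales, mask=destroyed_mask)
    pred = classifier.predict(X)
    seg_of = segments[destroyed_mask]
    rows = []
    vox3 = voxel_size**3
    for seg_id in np.unique(seg_of):
        sel = seg_of == seg_id
        votes = np.bincount(pred[sel], minlength=len(AGENT_CODES))
        top = int(votes.max())
        winners = np.nonzero(votes == top)[0]
        agent_code = int(winners[0])  # deterministic tie-break: lowest code
        n = int(sel.sum())
        rows.append(
            dict(
                segment=int(seg_id),
                voxels=n,
                volume_mm3=n * vox3,
                agent=_AGENT_NAMES[agent_code],
                vote_fraction=top / n,
                tie=len(winners) > 1,
            )
        )
    out = pd.DataFrame(rows)
    per_agent = {}
    total_destroyed = float(out["volume_mm3"].sum())
    core_mm3 = destroyed_mask.size * vox3
    for name in AGENT_CODES:
        v = float(out.loc[out["agent"] == name, "volume_mm3"].sum())
        entry = {
            "volume_mm3": v,
            "percent_of_destroyed": 100.0 * v / total_destroyed if total_destroyed else 0.0,
            "percent_of_core": 100.0 * v / core_mm3,
        }
        if total_bioporosity_pct:
            entry["percent_of_bioporosity"] = (
                100.0 * (100.0 * v / core_mm3) / total_bioporosity_pct
            )
        per_agent[name] = entry
    out.attrs["per_agent"] = per_agent
    return out
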