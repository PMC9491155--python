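"""Per-core summaries, validation statistics and the pipeline driver.

`run_pipeline` strings the whole analysis together from a single YAML/dict
configuration: volume input (files or a synthetic phantom), preprocessing,
ensemble thresholding, root/biopore segmentation, local-thickness
morphometry, and — when a second timepoint is present — temporal dynamics,
root trajectories and cast-agent attribution.  Every stage's parameters are
logged to a JSON provenance file and all outputs are deterministic for a
fixed configuration and seed.
"""

from __future__ import annotations

import json
import warnings
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import classify, dynamics, morpho, phantom, threshold, tubeseg, volio

__all__ = [
    "regression_through_origin",
    "pearson_screen",
    "run_pipeline",
]


def regression_through_origin(x, y):
    """Least-squares line through the origin.

    slope = sum(x*y) / sum(x^2); R^2 = 1 - SS_res / SS_tot with SS_tot
    taken about the mean of y (the convention is stated in output headers,
    since no-intercept R^2 is ambiguous across conventions).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise ValueError("need n >= 2 paired observations")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all x are zero: slope undefined")
    slope = float(np.sum(x * y)) / sxx
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, r2


def pearson_screen(table: pd.DataFrame, p_cutoff: float = 0.01) -> pd.DataFrame:
    """All pairwise Pearson correlations with two-sided p-values.

    Pairs with p < ``p_cutoff`` are flagged significant; constant columns
    are skipped with a warning.
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("need at least 3 rows")
    cols = []
    for c in num.columns:
        if np.nanstd(num[c].to_numpy()) == 0:
            warnings.warn(f"column {c!r} is constant; skipped")
        else:
            cols.append(c)
    rows = []
    for a, b in combinations(cols, 2):
        r, p = stats.pearsonr(num[a], num[b])
        rows.append(dict(var_a=a, var_b=b, r=float(r), p=float(p),
                         significant=bool(p < p_cutoff)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline driver


class ConfigurationError(ValueError):
    pass


_DEFAULTS = {
    "preprocess": {
        "crop_margin_voxels": 0,
        "contrast_stretch": False,
        "saturation_fraction": 0.0035,
        "denoise": {"method": "median", "strength": 1.0},
    },
    "threshold": {"methods": None, "sd_multiplier": 1.0, "organic_fraction": 2.4},
    "segment": {"min_elongation": 2.0},
    "morpho": {
        "pore_edges_mm": list(morpho.DEFAULT_PORE_EDGES_MM[:-1]),
        "root_edges_mm": list(morpho.DEFAULT_ROOT_EDGES_MM[:-1]),
    },
    "dynamics": {"dilation_radius_voxels": 1, "min_volume_mm3": 0.3},
    "classify": {"scales": [1, 2, 4], "train_fraction": 0.001},
}


def _merge(defaults: dict, user: dict) -> dict:
    out = dict(defaults)
    for k, v in (user or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping or a YAML file path")
    return config


def run_pipeline(config, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis described by ``config``.

    Returns a result dictionary (summaries, tables, masks) and, when
    ``outdir`` (or ``config['out']``) is given, writes CSV/JSON artifacts.
    Rerunning with the same config and seed reproduces the outputs
    byte-for-byte.
    """
    cfg_in = _load_config(config)
    cfg = dict(cfg_in)
    for k, defaults in _DEFAULTS.items():
        cfg[k] = _merge(defaults, cfg_in.get(k, {}))
    seed = int(cfg.get("seed", 0))
    outdir = Path(outdir or cfg.get("out")) if (outdir or cfg.get("out")) else None

    inp = cfg.get("input") or {}
    truth = None
    if "phantom" in inp:
        spec_kw = dict(inp["phantom"] or {})
        spec_kw.setdefault("seed", seed)
        if "shape" in spec_kw:
            spec_kw["shape"] = tuple(spec_kw["shape"])
        spec = phantom.PhantomSpec(**spec_kw)
        vol1, vol2, truth = phantom.generate_core_pair(spec)
        voxel_size = spec.voxel_size
        two_time = bool(inp.get("use_t2", True))
    elif "t1" in inp:
        voxel_size = inp.get("voxel_size_mm") or cfg.get("voxel_size_mm")
        if not voxel_size:
            raise ConfigurationError("voxel_size_mm is required for file input")
        vol1 = volio.read_volume(inp["t1"], voxel_size)
        vol2 = volio.read_volume(inp["t2"], voxel_size) if inp.get("t2") else None
        two_time = vol2 is not None
    else:
        raise ConfigurationError("config.input must name a phantom spec or a t1 volume")

    provenance = {"config": _jsonable(cfg), "seed": seed}
    result = {"provenance": provenance}

    tp = _analyse_timepoint(vol1, cfg, "t1")
    result["t1"] = tp
    if two_time:
        tp2 = _analyse_timepoint(vol2, cfg, "t2")
        result["t2"] = tp2
        dcfg = cfg["dynamics"]
        dyn = dynamics.biopore_dynamics(
            tp["biopores_raw"], tp2["biopores_raw"], voxel_size,
            dilation_radius_voxels=dcfg["dilation_radius_voxels"],
            min_volume_mm3=dcfg["min_volume_mm3"],
            pore_t1=tp["pore"], pore_t2=tp2["pore"], roots_t2=tp2["roots"],
        )
        nr = dynamics.new_roots(
            tp["roots"], tp2["roots"], voxel_size,
            dilation_radius_voxels=dcfg["dilation_radius_voxels"],
            min_volume_mm3=dcfg["min_volume_mm3"],
            exclude_mask=dyn.destroyed,
        )
        dyn.new_roots = nr
        result["dynamics"] = dyn
        labels_t1 = classify.build_structure_labels(tp["pore"], tp["biopores"], tp["roots"])
        result["structure_labels_t1"] = labels_t1
        result["trajectory"] = classify.root_trajectory_fractions(nr, labels_t1, voxel_size)
        if truth is not None and dyn.destroyed.any():
            result["agents"] = _classify_agents(vol2, dyn.destroyed, truth, cfg, seed)

    result["core_summary"] = _core_summary(result, voxel_size, two_time)
    if outdir is not None:
        _write_outputs(result, outdir, two_time)
    return result


def _analyse_timepoint(vol: volio.GrayVolume, cfg: dict, tag: str) -> dict:
    pcfg = cfg["preprocess"]
    v = vol
    if pcfg["crop_margin_voxels"]:
        v = volio.crop_interior(v, pcfg["crop_margin_voxels"])
    if pcfg["contrast_stretch"] or v.bit_depth != 8:
        v = volio.contrast_stretch_8bit(v, pcfg["saturation_fraction"])
    v = volio.denoise(v, method=pcfg["denoise"]["method"],
                      strength=pcfg["denoise"]["strength"])
    tcfg = cfg["threshold"]
    rep = threshold.threshold_report(
        v, methods=tcfg["methods"], sd_multiplier=tcfg["sd_multiplier"],
        organic_fraction=tcfg["organic_fraction"],
    )
    pore = threshold.pore_binary(v, rep.ensemble)
    organic = threshold.organic_binary(v, rep.ensemble, rep.organic_fraction)
    scfg = cfg["segment"]
    biopores_raw = tubeseg.segment_biopores(
        pore, v.voxel_size, min_elongation=scfg["min_elongation"])
    roots = tubeseg.segment_roots(
        organic, v.voxel_size, min_elongation=scfg["min_elongation"])
    biopores = biopores_raw & ~roots  # structural precedence: root wins
    mcfg = cfg["morpho"]
    pore_edges = tuple(mcfg["pore_edges_mm"]) + (np.inf,)
    root_edges = tuple(mcfg["root_edges_mm"]) + (np.inf,)
    out = dict(
        denoised=v, threshold_report=rep, pore=pore, organic=organic,
        biopores_raw=biopores_raw, biopores=biopores, roots=roots,
        macroporosity_pct=morpho.porosity(pore),
        bioporosity_pct=morpho.porosity(biopores),
        root_density_pct=morpho.porosity(roots),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sub-resolution thickness notices
        for name, mask, edges in (
            ("pores", pore, pore_edges),
            ("biopores", biopores, pore_edges),
            ("roots", roots, root_edges),
        ):
            tmap = morpho.local_thickness(mask, v.voxel_size)
            sd = morpho.size_distribution(tmap, edges)
            out[f"psd_{name}"] = sd
            out[f"mean_diameter_{name}_mm"] = sd.mean_diameter_mm
            if name == "roots":
                out["root_length"] = morpho.root_length_by_class(
                    mask, tmap, root_edges, v.voxel_size)
                out["root_length_total_mm"] = morpho.skeleton_length_mm(mask, v.voxel_size)
    return out


def _classify_agents(vol2, destroyed, truth, cfg, seed):
    ccfg = cfg["classify"]
    # sparse training annotations from the ground truth (the synthetic
    # stand-in for manually labelled cast examples)
    agent_truth = np.full(truth.labels_t2.shape, -1, dtype=np.int8)
    for name, code in (("cast_earthworm", 0), ("cast_mesofauna", 1), ("compaction", 2)):
        agent_truth[truth.labels_t2 == phantom.LABELS[name]] = code
    trainable = destroyed & (agent_truth >= 0)
    if not trainable.any() or len(np.unique(agent_truth[trainable])) < 3:
        return None
    den2 = volio.denoise(vol2, method=cfg["preprocess"]["denoise"]["method"],
                         strength=cfg["preprocess"]["denoise"]["strength"])
    idx = classify.sample_training_voxels(
        agent_truth, trainable, fraction=ccfg["train_fraction"], rng=seed)
    X = classify.voxel_features(den2.voxels, scales=tuple(ccfg["scales"]), mask=destroyed)
    flat = np.nonzero(destroyed.ravel())[0]
    Xtr = X[np.searchsorted(flat, idx)]
    ytr = agent_truth.ravel()[idx]
    clf, oob = classify.train_cast_classifier(Xtr, ytr, seed=seed)
    report = classify.classify_destroyed_biopores(
        den2.voxels, destroyed, clf, den2.voxel_size, scales=tuple(ccfg["scales"]))
    report.attrs["oob_error"] = oob
    return report


def _core_summary(result: dict, voxel_size: float, two_time: bool) -> pd.DataFrame:
    rows = []
    for tag in ("t1", "t2") if two_time else ("t1",):
        tp = result.get(tag)
        if tp is None:
            continue
        row = dict(
            timepoint=tag,
            macroporosity_pct=tp["macroporosity_pct"],
            bioporosity_pct=tp["bioporosity_pct"],
            root_density_pct=tp["root_density_pct"],
            mean_pore_diameter_mm=tp["mean_diameter_pores_mm"],
            mean_biopore_diameter_mm=tp["mean_diameter_biopores_mm"],
            mean_root_diameter_mm=tp["mean_diameter_roots_mm"],
            root_length_mm=tp["root_length_total_mm"],
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    dyn = result.get("dynamics")
    if dyn is not None:
        df["destroyed_bioporosity_pct"] = [np.nan] * (len(df) - 1) + [dyn.destroyed_pct]
        df["created_bioporosity_pct"] = [np.nan] * (len(df) - 1) + [dyn.created_pct]
        df["net_bioporosity_change_pct"] = [np.nan] * (len(df) - 1) + [dyn.net_change_pct]
    return df


def _write_outputs(result: dict, outdir: Path, two_time: bool) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result["core_summary"].to_csv(outdir / "core_summary.csv", index=False)
    for tag in ("t1", "t2"):
        tp = result.get(tag)
        if tp is None:
            continue
        tp["threshold_report"].to_json(outdir / f"threshold_{tag}.json")
        for name in ("pores", "biopores", "roots"):
            tp[f"psd_{name}"].to_frame().to_csv(
                outdir / f"psd_{name}_{tag}.csv", index=False)
        tp["root_length"].to_csv(outdir / f"root_length_{tag}.csv", index=False)
    if "trajectory" in result:
        result["trajectory"].to_frame().to_csv(outdir / "trajectory.csv", index=False)
    agents = result.get("agents")
    if agents is not None:
        agents.to_csv(outdir / "agents.csv", index=False)
        (outdir / "agents_summary.json").write_text(
            json.dumps({"per_agent": agents.attrs.get("per_agent", {}),
                        "oob_error": agents.attrs.get("oob_error")},
                       indent=2, default=float))
    dyn = result.get("dynamics")
    if dyn is not None:
        pd.DataFrame([
            dict(quantity="bioporosity_t1_pct", value=dyn.bioporosity_t1_pct),
            dict(quantity="bioporosity_t2_pct", value=dyn.bioporosity_t2_pct),
            dict(quantity="destroyed_pct", value=dyn.destroyed_pct),
            dict(quantity="created_pct", value=dyn.created_pct),
            dict(quantity="net_change_pct", value=dyn.net_change_pct),
        ]).to_csv(outdir / "dynamics_summary.csv", index=False)
    (outdir / "provenance.json").write_text(
        json.dumps(result["provenance"], indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
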