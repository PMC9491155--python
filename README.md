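# rhizopore

Dual-timepoint X-ray micro-CT analysis of undisturbed soil cores: what
pore structure did roots and soil fauna build, and how was it reused,
destroyed and rebuilt one growing season later?

A soil core scanned twice (before and after a root growing period) contains
a complete record of its macropore system: irregular air-filled pores, the
roughly cylindrical **biopores** left by roots and earthworms, and the
roots themselves.  `rhizopore` turns such a pair of co-registered grayscale
volumes into quantitative structure and turnover measures:

* **segmentation** — a global pore threshold from an ensemble of ten
  classical histogram methods (Otsu, Kittler–Illingworth, Triangle, Huang,
  IsoData, Maximum Entropy, Li, Rényi entropy, Yen, Moments; outliers
  beyond one SD of the mean are dropped and the rest averaged); an organic
  band `T/2.4 < g ≤ T` for roots; multiscale Hessian tubeness
  (`σ²·√(λ₂λ₃)` for λ₂,λ₃ < 0, computed at 50 % scale with σ = 1–4 and at
  20 % scale with σ = 2–30) to pull tubular roots and biopores out of the
  irregular pore network, with distance-transform watershed splitting and
  removal of blob-like objects;
* **morphometry** — maximum-inscribed-sphere local thickness, pore /
  biopore / root size distributions, porosities, and skeleton-based root
  length per diameter class;
* **dynamics** — difference imaging between the timepoints (the subtracted
  mask is dilated by one voxel to absorb registration jitter, followed by
  a 0.3 mm³ size opening): new roots, destroyed biopores, created
  biopores;
* **attribution** — destroyed-biopore infills classified into earthworm
  cast / mesofauna cast / unidentified by a random forest on multiscale
  voxel features with a per-segment majority vote, and new-root growth
  attributed to the structural class it occupied before (existing biopore,
  other macropore, or dense matrix);
* **synthetic cores** — a phantom generator that builds co-registered core
  pairs with complete per-voxel ground truth (tubes as swept spheres along
  random walks, a Gaussian-random-field pore network, cast textures,
  controlled destruction/creation/trajectory plans), so every stage of the
  pipeline is testable against known answers.

## Worked example

Analyse a synthetic core pair (128³ voxels at 0.04 mm) end to end:

```python
from dataclasses import asdict
from rhizopore import phantom as ph
from rhizopore.report import run_pipeline

spec = ph.compact_spec(seed=0, shape=(128, 128, 128))
spec.biopore_plan = [(0.8, 3), (1.2, 2)]
cfg = {"seed": 0, "input": {"phantom": {
    "shape": list(spec.shape),
    "biopore_plan": [list(x) for x in spec.biopore_plan],
    "root_plan": [list(x) for x in spec.root_plan],
    "dynamics_plan": asdict(spec.dynamics_plan),
}}}
res = run_pipeline(cfg, outdir="run0")
print(res["core_summary"].round(3).to_string(index=False))
print(res["trajectory"].to_frame().round(2).to_string(index=False))
```

prints (abridged):

```
timepoint  macroporosity_pct  bioporosity_pct  root_density_pct  ...  destroyed_bioporosity_pct  created_bioporosity_pct  net_bioporosity_change_pct
       t1             27.939           12.150             1.697  ...                        NaN                      NaN                         NaN
       t2             26.398            9.894             3.543  ...                      3.751                    1.269                      -2.482

         class  volume_mm3  percent
  into_biopore        0.37    15.06
into_macropore        0.99    40.71
   into_matrix        1.08    44.23
 into_old_root        0.00     0.00
```

Reading this: the core lost about 2.5 percentage points of bioporosity in
the second growing period (3.8 % of the core volume destroyed by cast
infill or compaction, 1.3 % newly burrowed), and of the newly grown root
volume 15 % reused existing biopores, 41 % followed other macropores and
44 % penetrated the dense matrix — matching this phantom's planted ground
truth (15.4 / 40.6 / 44.0 %) within a fraction of a point.

The same pipeline runs on real data by replacing the `phantom` input with
TIFF paths:

```yaml
input: {t1: core_t1.tif, t2: core_t2.tif, voxel_size_mm: 0.018}
```

A thin CLI wraps the library: `rhizopore phantom|run|dynamics|report`.

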