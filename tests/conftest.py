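import numpy as np
import pytest

from rhizopore import classify as cl
from rhizopore import dynamics as dy
from rhizopore import phantom as ph
from rhizopore import threshold as th
from rhizopore import tubeseg as ts
from rhizopore import volio


def segment_core(vol, voxel_size):
    """Standard single-timepoint segmentation chain used by the tests."""
    den = volio.denoise(vol, method="median", strength=1)
    rep = th.threshold_report(den)
    pore = th.pore_binary(den, rep.ensemble)
    organic = th.organic_binary(den, rep.ensemble, rep.organic_fraction)
    biopores_raw = ts.segment_biopores(pore, voxel_size)
    roots = ts.segment_roots(organic, voxel_size)
    return dict(
        denoised=den, report=rep, pore=pore, organic=organic,
        biopores_raw=biopores_raw, biopores=biopores_raw & ~roots, roots=roots,
    )


def precision_recall(pred, truth):
    tp = int(np.count_nonzero(pred & truth))
    return tp / max(int(pred.sum()), 1), tp / max(int(truth.sum()), 1)


@pytest.fixture(scope="session")
def flagship():
    """The full two-timepoint study core (200^3 voxels at 0.04 mm) with its
    complete analysis, shared across the acceptance-level tests."""
    spec = ph.PhantomSpec(seed=1)
    v1, v2, truth = ph.generate_core_pair(spec)
    s1 = segment_core(v1, spec.voxel_size)
    s2 = segment_core(v2, spec.voxel_size)
    dyn = dy.biopore_dynamics(
        s1["biopores_raw"], s2["biopores_raw"], spec.voxel_size,
        pore_t1=s1["pore"], pore_t2=s2["pore"], roots_t2=s2["roots"],
    )
    new_roots = dy.new_roots(
        s1["roots"], s2["roots"], spec.voxel_size, exclude_mask=dyn.destroyed
    )
    labels1 = cl.build_structure_labels(s1["pore"], s1["biopores"], s1["roots"])
    return dict(
        spec=spec, truth=truth, v1=v1, v2=v2, s1=s1, s2=s2,
        dyn=dyn, new_roots=new_roots, labels1=labels1,
    )


@pytest.fixture(scope="session")
def compact_pair():
    """A reduced two-timepoint core for cheaper end-to-end checks."""
    spec = ph.compact_spec(seed=0)
    v1, v2, truth = ph.generate_core_pair(spec)
    return dict(spec=spec, v1=v1, v2=v2, truth=truth)
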