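"""Robust ensemble pore thresholding and derivation of pore/organic binaries.

A single global gray threshold T separates air-filled pore space from the
mineral matrix.  Rather than trusting one automatic method, T is the mean of
the thresholds proposed by ten classical histogram methods (Otsu,
Kittler-Illingworth, Triangle, Huang, IsoData, Maximum Entropy, Li, Renyi
Entropy, Yen, Moments), after discarding methods that deviate from the raw
mean by more than one standard deviation.

Binaries derived from T (tie rule: pore is gray <= T, inclusive):

* pore binary     — gray <= T          (air, water, roots, particulate OM)
* organic binary  — T/2.4 < gray <= T  (roots and other organics; the
                    darker band gray <= T/2.4 is air)

All methods operate on a 256-bin histogram of an 8-bit volume and follow
their published histogram formulations; thresholds are bin indices in
[0, 255] with the "below" class inclusive of the returned bin.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volio import GrayVolume

__all__ = [
    "DegenerateHistogramError",
    "ThresholdReport",
    "METHODS",
    "auto_thresholds",
    "ensemble_threshold",
    "histogram",
    "threshold_report",
    "pore_binary",
    "organic_binary",
]


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two nonempty bins: no threshold exists."""


# ---------------------------------------------------------------------------
# helpers

def _prepare(hist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h = np.asarray(hist, dtype=np.float64)
    if h.ndim != 1 or h.size != 256:
        raise ValueError(f"expected a 256-bin histogram, got shape {h.shape}")
    if np.any(h < 0):
        raise ValueError("histogram counts must be non-negative")
    if np.count_nonzero(h) < 2:
        raise DegenerateHistogramError("need >= 2 nonempty histogram bins")
    p = h / h.sum()
    return h, p


def _class_stats(p: np.ndarray):
    """Cumulative probability, mean and second moment of the below class
    (inclusive) for every candidate threshold t = 0..255."""
    g = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)
    s0 = np.cumsum(p * g)
    q0 = np.cumsum(p * g * g)
    return g, w0, s0, q0


def _argbest_mid(crit: np.ndarray, maximize: bool = True) -> int:
    """Index of the best criterion value; exact ties resolve to the middle
    tied index so that flat plateaus (e.g. empty valleys between two sharp
    peaks) yield a separator in the middle of the valley."""
    best = np.max(crit) if maximize else np.min(crit)
    if not np.isfinite(best):
        raise DegenerateHistogramError("threshold criterion has no valid candidate")
    idx = np.nonzero(crit == best)[0]
    return int(idx[len(idx) // 2])


# ---------------------------------------------------------------------------
# the ten methods


def otsu(hist: np.ndarray) -> int:
    """Maximise the between-class variance w0*w1*(mu0 - mu1)^2."""
    _, p = _prepare(hist)
    g, w0, s0, _ = _class_stats(p)
    mu_t = s0[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = (mu_t - s0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 <= 0) | (w1 <= 0)] = -np.inf
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    return _argbest_mid(sigma_b, maximize=True)


def isodata(hist: np.ndarray) -> int:
    """Ridler-Calvard iteration: fixed point of t = (mean_below + mean_above)/2."""
    _, p = _prepare(hist)
    g, w0, s0, _ = _class_stats(p)
    nz = np.nonzero(p)[0]
    t = int(round(float(np.sum(p * g))))  # start at the global mean
    t = min(max(t, nz[0]), nz[-1] - 1)
    for _ in range(256):
        below, above = w0[t], 1.0 - w0[t]
        if below <= 0:
            t += 1
            continue
        if above <= 0:
            t -= 1
            continue
        mb = s0[t] / below
        ma = (s0[-1] - s0[t]) / above
        t_new = int(np.floor((mb + ma) / 2.0))
        if t_new == t:
            break
        t = t_new
    return t


def li(hist: np.ndarray) -> int:
    """Li & Tam iterative minimum cross-entropy.

    Operates on gray values shifted by +1 so the logarithms are defined at
    bin 0; the result is shifted back.
    """
    _, p = _prepare(hist)
    g = np.arange(256, dtype=np.float64) + 1.0
    mean_all = float(np.sum(p * g))
    t = mean_all
    for _ in range(256):
        below = g <= t
        wb = p[below].sum()
        wf = p[~below].sum()
        if wb <= 0 or wf <= 0:
            break
        mb = float(np.sum(p[below] * g[below])) / wb
        mf = float(np.sum(p[~below] * g[~below])) / wf
        t_new = (mb - mf) / (np.log(mb) - np.log(mf))
        if abs(t_new - t) < 0.5:
            t = t_new
            break
        t = t_new
    return int(np.clip(np.floor(t - 1.0), 0, 255))


def triangle(hist: np.ndarray) -> int:
    """Geometric triangle method: maximise the distance between the histogram
    and the chord from the global peak to the far end of its longer tail."""
    h, _ = _prepare(hist)
    nz = np.nonzero(h)[0]
    first, last = nz[0], nz[-1]
    peak = int(np.argmax(h))
    # work on the longer-tail side; flip so the tail is to the right
    flipped = (peak - first) > (last - peak)
    if flipped:
        h = h[::-1]
        peak = 255 - peak
        last = 255 - first
    hmax = h[peak]
    span = last - peak
    if span <= 0:
        t = peak
    else:
        ts = np.arange(peak, last + 1)
        # distance below the chord from (peak, hmax) to (last, 0),
        # up to a constant factor
        d = span * (hmax - h[peak : last + 1]) - hmax * (ts - peak)
        t = peak + _argbest_mid(d, maximize=True)
    if flipped:
        t = 255 - t
    return int(t)


def huang(hist: np.ndarray) -> int:
    """Huang & Wang fuzzy thresholding: minimise total Shannon fuzziness of
    the membership function mu(g) = 1 / (1 + |g - mu_class| / C)."""
    h, p = _prepare(hist)
    g, w0, s0, _ = _class_stats(p)
    nz = np.nonzero(h)[0]
    first, last = nz[0], nz[-1]
    C = float(last - first)
    if C <= 0:
        return int(first)
    gf = np.arange(256, dtype=np.float64)
    crit = np.full(256, np.inf)
    for t in range(first, last):
        wb, wf = w0[t], 1.0 - w0[t]
        if wb <= 0 or wf <= 0:
            continue
        mu0 = s0[t] / wb
        mu1 = (s0[-1] - s0[t]) / wf
        centers = np.where(gf <= t, mu0, mu1)
        mu_x = 1.0 / (1.0 + np.abs(gf - centers) / C)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -mu_x * np.log(mu_x) - (1.0 - mu_x) * np.log(1.0 - mu_x)
        ent[~np.isfinite(ent)] = 0.0
        crit[t] = float(np.sum(h * ent))
    return _argbest_mid(crit, maximize=False)


def kittler(hist: np.ndarray) -> int:
    """Kittler-Illingworth minimum-error threshold: minimise the two-Gaussian
    classification-error criterion J(t)."""
    _, p = _prepare(hist)
    g, w0, s0, q0 = _class_stats(p)
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = (s0[-1] - s0) / w1
        var0 = q0 / w0 - mu0**2
        var1 = (q0[-1] - q0) / w1 - mu1**2
        J = 1.0 + 2.0 * (w0 * np.log(np.sqrt(var0)) + w1 * np.log(np.sqrt(var1))) - 2.0 * (
            w0 * np.log(w0) + w1 * np.log(w1)
        )
    valid = (w0 > 0) & (w1 > 0) & (var0 > 0) & (var1 > 0) & np.isfinite(J)
    if not np.any(valid):
        # histograms of two delta peaks have zero within-class variance;
        # fall back to the between-class-variance scan
        return otsu(hist)
    J[~valid] = np.inf
    return _argbest_mid(J, maximize=False)


def max_entropy(hist: np.ndarray) -> int:
    """Kapur-Sahoo-Wong maximum entropy: maximise H_below + H_above."""
    return _renyi_alpha(hist, alpha=1.0)


def yen(hist: np.ndarray) -> int:
    """Yen's maximum correlation criterion."""
    _, p = _prepare(hist)
    p2 = np.cumsum(p**2)
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    p2f = p2[-1] - p2
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = -np.log(p2 * p2f) + 2.0 * np.log(w0 * w1)
    crit[(w0 <= 0) | (w1 <= 0) | (p2 <= 0) | (p2f <= 0)] = -np.inf
    crit[~np.isfinite(crit)] = -np.inf
    return _argbest_mid(crit, maximize=True)


def moments(hist: np.ndarray) -> int:
    """Tsai moment-preserving threshold: choose t so the binary image keeps
    the first three gray-level moments of the input."""
    _, p = _prepare(hist)
    g = np.arange(256, dtype=np.float64)
    m1 = float(np.sum(p * g))
    m2 = float(np.sum(p * g**2))
    m3 = float(np.sum(p * g**3))
    cd = m2 - m1 * m1
    if cd <= 0:
        return otsu(hist)
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        return otsu(hist)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        return otsu(hist)
    p0 = (z1 - m1) / (z1 - z0)  # target fraction of the below class
    w0 = np.cumsum(p)
    return _argbest_mid(np.abs(w0 - p0), maximize=False)


def _renyi_alpha(hist: np.ndarray, alpha: float) -> int:
    """Threshold maximising the two-class Renyi entropy of order ``alpha``
    (the limit alpha -> 1 is the Shannon/Kapur maximum-entropy criterion)."""
    _, p = _prepare(hist)
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    nz = np.nonzero(p)[0]
    crit = np.full(256, -np.inf)
    for t in range(nz[0], nz[-1]):
        wb, wf = w0[t], w1[t]
        if wb <= 0 or wf <= 0:
            continue
        pb = p[: t + 1] / wb
        pf = p[t + 1 :] / wf
        pb = pb[pb > 0]
        pf = pf[pf > 0]
        if abs(alpha - 1.0) < 1e-12:
            crit[t] = -np.sum(pb * np.log(pb)) - np.sum(pf * np.log(pf))
        else:
            crit[t] = (np.log(np.sum(pb**alpha)) + np.log(np.sum(pf**alpha))) / (1.0 - alpha)
    if not np.any(np.isfinite(crit)):
        return otsu(hist)
    return _argbest_mid(crit, maximize=True)


def renyi_entropy(hist: np.ndarray) -> int:
    """Sahoo-Wilkins-Yeager combination of Renyi-entropy thresholds at
    alpha = 0.5, 1 and 2."""
    _, p = _prepare(hist)
    ts = sorted(_renyi_alpha(hist, a) for a in (0.5, 1.0, 2.0))
    t1, t2, t3 = ts
    w0 = np.cumsum(p)
    p1, p3 = w0[t1], w0[t3]
    omega = p3 - p1
    if abs(t1 - t2) <= 5 and abs(t2 - t3) <= 5:
        b1, b2, b3 = 1, 2, 1
    elif abs(t1 - t2) > 5 and abs(t2 - t3) > 5:
        b1, b2, b3 = 1, 2, 1
    elif abs(t1 - t2) <= 5:  # t2 close to t1, far from t3
        b1, b2, b3 = 0, 1, 3
    else:
        b1, b2, b3 = 3, 1, 0
    t = (
        t1 * (p1 + 0.25 * omega * b1)
        + 0.25 * t2 * omega * b2
        + t3 * (1.0 - p3 + 0.25 * omega * b3)
    )
    return int(np.clip(round(t), 0, 255))


METHODS = {
    "Otsu": otsu,
    "Kittler": kittler,
    "Triangle": triangle,
    "Huang": huang,
    "IsoData": isodata,
    "MaxEntropy": max_entropy,
    "Li": li,
    "RenyiEntropy": renyi_entropy,
    "Yen": yen,
    "Moments": moments,
}


def auto_thresholds(hist: np.ndarray, methods: list[str] | None = None) -> list[tuple[str, int]]:
    """Run the automatic threshold methods on a 256-bin histogram.

    Returns one ``(method_name, threshold)`` pair per method, thresholds in
    [0, 255] with the below class inclusive of the returned value.
    """
    _prepare(hist)  # validates
    names = list(METHODS) if methods is None else list(methods)
    out = []
    for name in names:
        if name not in METHODS:
            raise ValueError(f"unknown threshold method {name!r}")
        out.append((name, int(METHODS[name](hist))))
    return out


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class ThresholdReport:
    """Per-method thresholds, the outlier-cleaned subset and the ensemble T."""

    per_method: list[tuple[str, float]]
    retained: list[tuple[str, float]]
    ensemble: float
    organic_fraction: float = 2.4
    notes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "per_method": [[n, float(v)] for n, v in self.per_method],
                "retained": [[n, float(v)] for n, v in self.retained],
                "ensemble": float(self.ensemble),
                "organic_fraction": float(self.organic_fraction),
                "notes": self.notes,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def ensemble_threshold(
    values: list[float] | list[tuple[str, float]],
    sd_multiplier: float = 1.0,
    organic_fraction: float = 2.4,
) -> ThresholdReport:
    """Average the per-method thresholds after removing outliers.

    A value is an outlier when it deviates from the mean of all values by
    more than ``sd_multiplier`` standard deviations (population SD).  If the
    rule would drop everything, all values are retained with a warning.
    """
    if len(values) == 0:
        raise ValueError("need at least one threshold value")
    if values and isinstance(values[0], (tuple, list)):
        pairs = [(str(n), float(v)) for n, v in values]
    else:
        pairs = [(f"m{i}", float(v)) for i, v in enumerate(values)]
    vals = np.array([v for _, v in pairs], dtype=np.float64)
    notes = []
    mean, sd = float(vals.mean()), float(vals.std(ddof=0))
    keep = np.abs(vals - mean) <= sd_multiplier * sd
    if not np.any(keep):
        warnings.warn("outlier rule would remove every threshold; retaining all")
        notes.append("outlier rule degenerate: all values retained")
        keep = np.ones_like(keep)
    retained = [pairs[i] for i in np.nonzero(keep)[0]]
    ensemble = float(np.mean([v for _, v in retained]))
    return ThresholdReport(pairs, retained, ensemble, organic_fraction, notes)


def histogram(vol: GrayVolume) -> np.ndarray:
    """256-bin gray histogram of an 8-bit volume."""
    if vol.bit_depth != 8:
        raise ValueError("histogram thresholding expects an 8-bit volume")
    return np.bincount(vol.voxels.ravel(), minlength=256)[:256]


def threshold_report(
    vol: GrayVolume,
    methods: list[str] | None = None,
    sd_multiplier: float = 1.0,
    organic_fraction: float = 2.4,
) -> ThresholdReport:
    """Convenience: histogram -> per-method thresholds -> ensemble."""
    per = auto_thresholds(histogram(vol), methods=methods)
    return ensemble_threshold(per, sd_multiplier=sd_multiplier, organic_fraction=organic_fraction)


# ---------------------------------------------------------------------------
# binaries


def pore_binary(vol: GrayVolume, T: float) -> np.ndarray:
    """Pore mask: gray <= T (air plus the organic band)."""
    if not 0 <= T <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {T}")
    return vol.voxels <= T


def organic_binary(vol: GrayVolume, T: float, fraction: float = 2.4) -> np.ndarray:
    """Organic mask: T/fraction < gray <= T.

    The band below T/fraction is air; the organic band holds roots, water
    and particulate organic matter.  Always a subset of the pore binary.
    """
    if fraction <= 1:
        raise ValueError(f"organic fraction must be > 1, got {fraction}")
    g = vol.voxels
    return (g > T / fraction) & (g <= T)
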