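"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own MI estimator, interpolation
path and enumeration code: mutual information is computed with
np.histogram2d, sampling with scipy's RegularGridInterpolator, and subset
selection by direct bitmask enumeration of the scoring formula.
"""

import itertools

import numpy as np
from scipy.interpolate import RegularGridInterpolator


def histogram_mi_bits(a, b, bins):
    """Plug-in MI estimate (bits) from a joint histogram via np.histogram2d."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.max() == a.min() or b.max() == b.min():
        return 0.0
    h, _, _ = np.histogram2d(
        a, b, bins=bins,
        range=[[a.min(), a.max()], [b.min(), b.max()]])
    pxy = h / h.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


def exhaustive_match(reference, target, center_mm, extent_mm,
                     search_radius_mm, step_mm=0.25, bins=8,
                     sample_spacing_mm=(1.0, 1.0, 1.0)):
    """Single-level exhaustive translation search at ``step_mm`` spacing.

    Template samples lie on a ``sample_spacing_mm`` lattice centred on
    ``center_mm`` within ``extent_mm`` (the shared template definition).
    Returns the argmax-MI translation with ties broken by smallest
    Euclidean norm then lexicographic (x, y, z).
    """
    axes_pts = []
    for ax in range(3):
        half = extent_mm[ax] / 2.0
        step = sample_spacing_mm[ax]
        k = int(half // step)
        axes_pts.append(center_mm[ax] + step * np.arange(-k, k + 1))
    X, Y, Z = np.meshgrid(*axes_pts, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    grids = [reference.origin[ax]
             + np.arange(reference.shape[ax]) * reference.spacing[ax]
             for ax in range(3)]
    ref_interp = RegularGridInterpolator(grids, reference.data)
    tgt_grids = [target.origin[ax]
                 + np.arange(target.shape[ax]) * target.spacing[ax]
                 for ax in range(3)]
    tgt_interp = RegularGridInterpolator(tgt_grids, target.data)
    ref_samples = ref_interp(pts)

    offsets = np.arange(-search_radius_mm, search_radius_mm + step_mm / 2,
                        step_mm)
    offsets = offsets - offsets[np.argmin(np.abs(offsets))]
    best = None
    for tx in offsets:
        for ty in offsets:
            shifted_xy = pts.copy()
            shifted_xy[:, 0] += tx
            shifted_xy[:, 1] += ty
            for tz in offsets:
                q = shifted_xy.copy()
                q[:, 2] += tz
                mi = histogram_mi_bits(ref_samples, tgt_interp(q), bins)
                key = (-mi, tx * tx + ty * ty + tz * tz, tx, ty, tz)
                if best is None or key < best[0]:
                    best = (key, np.array([tx, ty, tz]), mi)
    return best[1], best[2]


def brute_force_subset(u_t, traces_by_id, distances=None):
    """Re-derive S*, f(S*) and the per-axis margin by direct enumeration."""
    ids = sorted(traces_by_id)
    best = None
    for r in range(1, len(ids) + 1):
        for subset in itertools.combinations(ids, r):
            mean = np.mean([traces_by_id[i] for i in subset], axis=0)
            diff = u_t - mean
            f = float(np.sqrt(np.mean(diff ** 2)))
            mean_dist = (float(np.mean([distances[i] for i in subset]))
                         if distances else 0.0)
            key = (f, len(subset), mean_dist,
                   tuple(str(i) for i in subset))
            if best is None or key < best[0]:
                best = (key, subset, f, np.max(np.abs(diff), axis=0))
    return {"subset": best[1], "f": best[2], "margin": best[3]}
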