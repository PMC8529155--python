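"""Translational template matching of fiducial markers across 4D-CT phases.

For each marker detected on the reference (0%) phase, a small template
(default 4 x 4 x 10 mm, long axis I-S) is cut from the reference image
around the detected centroid.  The marker's displacement to every other
phase is the translation that maximizes the mutual information (MI)
between the template intensities and the target-phase intensities sampled
(trilinearly) at the translated template positions.  The search is
multi-resolution: an exhaustive scan on a 1.0 mm grid within the search
radius, then refinement on successively finer grids (default 0.5 then
0.25 mm) within one previous step of the running optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .detection import MarkerDetection
from .phantom import PhaseVolume, Volume4D

__all__ = [
    "TemplateConfig",
    "Trajectory",
    "mutual_information",
    "match_template",
    "track_all",
]


@dataclass
class TemplateConfig:
    """Parameters of the template-matching search.

    ``template_extent_mm``: full size of the box cut around the detected
    centroid (mm per axis; the 10 mm axis is I-S, the dominant motion
    direction).  ``search_radius_mm``: largest translation examined per
    axis at the coarse level — it must cover the expected motion.
    ``grid_levels_mm``: strictly decreasing translation-grid steps; the
    first level scans the whole search window, each later level scans
    within one previous step of the running optimum.
    """

    template_extent_mm: Sequence[float] = (4.0, 4.0, 10.0)
    search_radius_mm: float = 15.0
    grid_levels_mm: Sequence[float] = (1.0, 0.5, 0.25)
    # A 4 x 4 x 10 mm box holds only ~75 voxels at 1 x 1 x 3 mm spacing —
    # far too few joint-histogram samples for a stable MI estimate.  The
    # template is therefore sampled on a denser sub-voxel lattice (the
    # reference is trilinearly interpolated), and the bin count is kept
    # well below sqrt(n_samples).
    template_sample_spacing_mm: Sequence[float] = (1.0, 1.0, 1.0)
    mi_bins: int = 16
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        self.template_extent_mm = np.asarray(self.template_extent_mm, float)
        if np.any(self.template_extent_mm <= 0):
            raise ValueError("template extent must be positive")
        self.template_sample_spacing_mm = np.asarray(
            self.template_sample_spacing_mm, float)
        if np.any(self.template_sample_spacing_mm <= 0):
            raise ValueError("template sample spacing must be positive")
        levels = np.asarray(self.grid_levels_mm, float)
        if levels.ndim != 1 or levels.size == 0 or np.any(levels <= 0):
            raise ValueError("grid_levels_mm must be positive")
        if np.any(np.diff(levels) >= 0):
            raise ValueError("grid_levels_mm must be strictly decreasing")
        self.grid_levels_mm = tuple(levels.tolist())
        if self.search_radius_mm <= 0:
            raise ValueError("search radius must be positive")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")
        if self.interpolation != "linear":
            raise ValueError("only linear interpolation is supported")


@dataclass
class Trajectory:
    """Tracked displacement of one marker relative to the 0% phase."""

    marker_id: int
    displacement_mm: np.ndarray          # (n_phases, 3)
    mi_score: np.ndarray                 # (n_phases,)
    failed_phases: list[int] = field(default_factory=list)

    @property
    def n_phases(self) -> int:
        return self.displacement_mm.shape[0]


# --------------------------------------------------------------------------
# mutual information
# --------------------------------------------------------------------------

def _mi_many(ref: np.ndarray, tgt: np.ndarray, bins: int) -> np.ndarray:
    """MI (bits) between ``ref`` (n,) and each row of ``tgt`` (m, n).

    Joint histogram with ``bins`` equal-width bins per signal, each
    signal's range set to its own [min, max]; a constant signal falls
    entirely into one bin, which makes its MI exactly 0.
    """
    ref = np.asarray(ref, float)
    tgt = np.atleast_2d(np.asarray(tgt, float))
    m, n = tgt.shape
    if ref.shape != (n,):
        raise ValueError("sample lengths differ")
    if n < 2:
        raise ValueError("need at least 2 samples")

    lo_a, hi_a = ref.min(), ref.max()
    scale_a = bins / (hi_a - lo_a) if hi_a > lo_a else 0.0
    ia = np.clip(((ref - lo_a) * scale_a).astype(np.int64), 0, bins - 1)

    out = np.empty(m)
    chunk = max(1, int(4e6 // (bins * bins)))
    for s in range(0, m, chunk):
        t = tgt[s:s + chunk]
        mc = t.shape[0]
        lo_b = t.min(axis=1, keepdims=True)
        hi_b = t.max(axis=1, keepdims=True)
        rng = hi_b - lo_b
        scale_b = np.where(rng > 0, bins / np.where(rng > 0, rng, 1.0), 0.0)
        ib = np.clip(((t - lo_b) * scale_b).astype(np.int64), 0, bins - 1)
        offsets = (np.arange(mc, dtype=np.int64) * bins * bins)[:, None]
        flat = offsets + ia[None, :] * bins + ib
        counts = np.bincount(flat.ravel(), minlength=mc * bins * bins)
        pxy = counts.reshape(mc, bins, bins) / n
        px = pxy.sum(axis=2)
        py = pxy.sum(axis=1)
        denom = px[:, :, None] * py[:, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = pxy * np.log2(pxy / denom)
        out[s:s + chunk] = np.where(pxy > 0, term, 0.0).sum(axis=(1, 2))
    return out


def mutual_information(a, b, bins: int = 32) -> float:
    """Shannon mutual information (bits) of two equal-length sample lists.

    MI = sum_ij p(i,j) log2[ p(i,j) / (p(i) p(j)) ] over a joint histogram
    with ``bins`` equal-width bins per signal (per-signal [min, max]
    ranges); empty joint cells contribute 0.  Constant signals give 0.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("sample lengths differ")
    return float(_mi_many(a, b[None, :], bins)[0])


# --------------------------------------------------------------------------
# template matching
# --------------------------------------------------------------------------

def _template_points(reference: PhaseVolume, center_mm: np.ndarray,
                     extent_mm: np.ndarray,
                     sample_spacing_mm=None) -> np.ndarray:
    """World coordinates (n, 3) of template sample points.

    Points lie on a lattice of ``sample_spacing_mm`` (default: the
    reference voxel spacing) centred on ``center_mm``, restricted to the
    box ``center ± extent/2``.
    """
    spacing = (reference.spacing if sample_spacing_mm is None
               else np.asarray(sample_spacing_mm, float))
    axes = []
    for ax in range(3):
        half = extent_mm[ax] / 2.0
        n = int(np.floor(half / spacing[ax]))
        axes.append(center_mm[ax] + np.arange(-n, n + 1) * spacing[ax])
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)


def _sample(volume: PhaseVolume, points_mm: np.ndarray) -> np.ndarray:
    """Trilinear samples of ``volume`` at world points (n, 3)."""
    idx = (points_mm - volume.origin) / volume.spacing
    return ndimage.map_coordinates(
        volume.data, idx.T, order=1, mode="nearest")


def _check_window(volume: PhaseVolume, lo_mm: np.ndarray, hi_mm: np.ndarray,
                  what: str, context: str) -> None:
    vol_lo = volume.origin
    vol_hi = volume.origin + (np.asarray(volume.shape) - 1) * volume.spacing
    if np.any(lo_mm < vol_lo - 1e-9) or np.any(hi_mm > vol_hi + 1e-9):
        raise ValueError(
            f"{what} out of bounds{' for ' + context if context else ''}: "
            f"[{np.round(lo_mm, 2).tolist()} .. {np.round(hi_mm, 2).tolist()}] mm "
            f"exceeds volume [{vol_lo.tolist()} .. {np.round(vol_hi, 2).tolist()}] mm"
        )


def _argbest(mi: np.ndarray, cands: np.ndarray) -> int:
    """Index of the max-MI candidate; exact ties broken by smallest
    Euclidean norm, then lexicographic (x, y, z)."""
    best = mi.max()
    tie = np.nonzero(mi == best)[0]
    if tie.size == 1:
        return int(tie[0])
    t = cands[tie]
    norms = np.einsum("ij,ij->i", t, t)
    order = np.lexsort((t[:, 2], t[:, 1], t[:, 0], norms))
    return int(tie[order[0]])


_CHUNK_SAMPLES = 8_000_000  # cap on candidate x template-point workspace


def _search_level(ref_samples: np.ndarray, target: PhaseVolume,
                  pts: np.ndarray, cands: np.ndarray,
                  bins: int) -> tuple[np.ndarray, float]:
    """Evaluate MI for every candidate translation (chunked to bound
    memory) and return the tie-broken best (translation, mi)."""
    n = pts.shape[0]
    chunk = max(1, _CHUNK_SAMPLES // n)
    best_key = None
    best = (np.zeros(3), -np.inf)
    for s in range(0, cands.shape[0], chunk):
        c = cands[s:s + chunk]
        samples = _sample_many(target, pts[None, :, :] + c[:, None, :])
        mi = _mi_many(ref_samples, samples, bins)
        k = _argbest(mi, c)
        t = c[k]
        key = (-mi[k], float(t @ t), t[0], t[1], t[2])
        if best_key is None or key < best_key:
            best_key = key
            best = (t, float(mi[k]))
    return best


def match_template(
    reference: PhaseVolume,
    target: PhaseVolume,
    center_mm,
    config: Optional[TemplateConfig] = None,
    context: str = "",
) -> tuple[np.ndarray, float]:
    """Find the translation of the template region from reference to target.

    Returns ``(translation_mm, mi)``: the argmax-MI translation at the
    finest grid level and its MI score.  ``context`` (e.g. "marker 2,
    phase 30%") is included in out-of-bounds error messages.
    """
    config = config or TemplateConfig()
    center_mm = np.asarray(center_mm, float)
    pts = _template_points(reference, center_mm, config.template_extent_mm,
                           config.template_sample_spacing_mm)
    _check_window(reference, pts.min(axis=0), pts.max(axis=0),
                  "template region", context)
    r = config.search_radius_mm
    _check_window(target, pts.min(axis=0) - r, pts.max(axis=0) + r,
                  "search window", context)
    ref_samples = _sample(reference, pts)

    levels = config.grid_levels_mm
    best_t = np.zeros(3)
    best_mi = -np.inf
    for li, step in enumerate(levels):
        if li == 0:
            off = np.arange(-r, r + step / 2, step)
            off1 = off - off[np.argmin(np.abs(off))]  # ensure 0 on the grid
            grids = (off1, off1, off1)
        else:
            prev = levels[li - 1]
            off = np.arange(-prev, prev + step / 2, step)
            grids = tuple(best_t[ax] + off for ax in range(3))
        OX, OY, OZ = np.meshgrid(*grids, indexing="ij")
        cands = np.stack([OX.ravel(), OY.ravel(), OZ.ravel()], axis=1)
        best_t, best_mi = _search_level(ref_samples, target, pts, cands,
                                        config.mi_bins)
    return best_t, best_mi


def _sample_many(volume: PhaseVolume, coords_mm: np.ndarray) -> np.ndarray:
    """Trilinear samples at world coords of shape (m, n, 3) → (m, n)."""
    m, n, _ = coords_mm.shape
    idx = (coords_mm.reshape(-1, 3) - volume.origin) / volume.spacing
    vals = ndimage.map_coordinates(volume.data, idx.T, order=1, mode="nearest")
    return vals.reshape(m, n)


def track_all(
    volumes: Volume4D,
    detections: list[MarkerDetection],
    config: Optional[TemplateConfig] = None,
) -> list[Trajectory]:
    """Track every detected marker from phase 0 to each other phase.

    Each non-reference phase is matched independently against the
    reference.  A failed phase (e.g. search window out of bounds) is
    recorded in ``failed_phases`` with NaN displacement and tracking
    continues with the remaining markers/phases.
    """
    config = config or TemplateConfig()
    reference = volumes[0]
    n_phases = volumes.n_phases
    trajectories: list[Trajectory] = []
    for det in detections:
        disp = np.zeros((n_phases, 3))
        mi = np.zeros(n_phases)
        failed: list[int] = []
        pts = _template_points(reference, np.asarray(det.centroid_mm, float),
                               config.template_extent_mm,
                               config.template_sample_spacing_mm)
        tmpl = _sample(reference, pts)
        mi[0] = mutual_information(tmpl, tmpl, config.mi_bins)
        for k in range(1, n_phases):
            try:
                t, score = match_template(
                    reference, volumes[k], det.centroid_mm, config,
                    context=f"marker {det.id}, phase {k * 100 // n_phases}%",
                )
                disp[k] = t
                mi[k] = score
            except ValueError:
                disp[k] = np.nan
                mi[k] = np.nan
                failed.append(k)
        trajectories.append(
            Trajectory(marker_id=det.id, displacement_mm=disp,
                       mi_score=mi, failed_phases=failed)
        )
    return trajectories
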