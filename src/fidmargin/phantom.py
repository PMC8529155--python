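"""Synthetic respiratory 4D-CT phantom.

Generates deterministic ten-phase CT volumes of a lung-density background
containing small high-HU gold fiducial markers (and optionally a spherical
GTV insert) that move under a cos^4 respiratory motion model,

    z(t) = z0 - b * cos^4(pi * t / tau),

so the displacement relative to the 0% phase is b * (1 - cos^4(pi*t/tau))
per axis.  Phase k of an n-phase acquisition samples the model at
t = k * tau / n.  World axes are x = R-L, y = A-P, z = I-S (mm); volumes
are stored index-order (x, y, z) with world = origin + index * spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PhaseVolume",
    "Volume4D",
    "MotionModel",
    "MarkerSpec",
    "GtvSpec",
    "PhantomSpec",
    "MotionTrace",
    "cos4_displacement",
    "analytic_trace",
    "generate_phantom",
]


# --------------------------------------------------------------------------
# volume containers
# --------------------------------------------------------------------------

@dataclass
class PhaseVolume:
    """A 3D CT intensity grid (HU) with geometry metadata.

    ``data`` is indexed (x, y, z); ``spacing`` and ``origin`` are in mm on
    the (R-L, A-P, I-S) axes.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("PhaseVolume data must be 3D")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to fractional voxel indices."""
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1D arrays of voxel-center world coordinates."""
        return tuple(
            self.origin[ax] + np.arange(self.data.shape[ax]) * self.spacing[ax]
            for ax in range(3)
        )  # type: ignore[return-value]


@dataclass
class Volume4D:
    """An ordered set of phase volumes indexed by respiratory phase."""

    phases: list[PhaseVolume]

    def __post_init__(self) -> None:
        if len(self.phases) < 2:
            raise ValueError("Volume4D needs at least 2 phases")

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def __getitem__(self, k: int) -> PhaseVolume:
        return self.phases[k]

    def __iter__(self):
        return iter(self.phases)


# --------------------------------------------------------------------------
# motion model
# --------------------------------------------------------------------------

def cos4_displacement(phase_fraction, b, phase_lag=0.0):
    """Displacement b * (1 - cos^4(pi * (phi + lag))) for phase fraction phi.

    ``phase_fraction`` may be scalar or array; ``b`` and ``phase_lag`` may be
    scalars or per-axis 3-vectors (broadcast).
    """
    phi = np.asarray(phase_fraction, dtype=float)
    b = np.asarray(b, dtype=float)
    lag = np.asarray(phase_lag, dtype=float)
    return b * (1.0 - np.cos(np.pi * (phi + lag)) ** 4)


@dataclass
class MotionModel:
    """Per-axis respiratory motion of one object.

    ``kind`` is ``"cos4"`` (parameters ``b`` peak-to-peak amplitude per axis
    in mm, ``tau`` respiration period in s, ``z0`` static rest offset in mm,
    ``phase_lag`` fractional phase offset per axis in [0, 1)) or
    ``"custom_per_phase"`` with an explicit (n_phases, 3) displacement table
    relative to phase 0.
    """

    kind: str = "cos4"
    b: Sequence[float] = (0.0, 0.0, 0.0)
    tau: float = 4.0
    z0: Sequence[float] = (0.0, 0.0, 0.0)
    phase_lag: Sequence[float] = (0.0, 0.0, 0.0)
    table: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("cos4", "custom_per_phase"):
            raise ValueError(f"unknown motion model kind {self.kind!r}")
        self.b = np.broadcast_to(np.asarray(self.b, dtype=float), (3,)).copy()
        self.z0 = np.broadcast_to(np.asarray(self.z0, dtype=float), (3,)).copy()
        self.phase_lag = np.broadcast_to(
            np.asarray(self.phase_lag, dtype=float), (3,)
        ).copy()
        if self.kind == "cos4":
            if np.any(self.b < 0):
                raise ValueError("cos4 amplitude b must be >= 0 per axis")
            if self.tau <= 0:
                raise ValueError("respiration period tau must be positive")
        else:
            if self.table is None:
                raise ValueError("custom_per_phase model requires a table")
            self.table = np.asarray(self.table, dtype=float)
            if self.table.ndim != 2 or self.table.shape[1] != 3:
                raise ValueError("table must have shape (n_phases, 3)")

    def displacement(self, phase_index: int, n_phases: int) -> np.ndarray:
        """Displacement (mm, 3-vector) of phase k relative to phase 0."""
        if self.kind == "custom_per_phase":
            assert self.table is not None
            if phase_index >= self.table.shape[0]:
                raise ValueError("phase index beyond custom table length")
            return self.table[phase_index] - self.table[0]
        phi = phase_index / n_phases
        d = cos4_displacement(phi, self.b, self.phase_lag)
        d0 = cos4_displacement(0.0, self.b, self.phase_lag)
        return np.asarray(d - d0, dtype=float)


@dataclass
class MotionTrace:
    """Per-phase 3D displacement of one object relative to the 0% phase."""

    object_id: str
    displacement_mm: np.ndarray  # (n_phases, 3)

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        if self.displacement_mm.ndim != 2 or self.displacement_mm.shape[1] != 3:
            raise ValueError("displacement_mm must have shape (n_phases, 3)")

    @property
    def n_phases(self) -> int:
        return self.displacement_mm.shape[0]


def analytic_trace(model: MotionModel, n_phases: int,
                   object_id: str = "model") -> MotionTrace:
    """Exact per-phase displacement trace of a motion model (ground truth).

    Phase k samples the model at t = k * tau / n_phases; displacements are
    relative to phase 0.  For a ``custom_per_phase`` model the table is
    returned verbatim (re-referenced to its first row).
    """
    if n_phases < 2:
        raise ValueError("need at least 2 phases")
    disp = np.stack([model.displacement(k, n_phases) for k in range(n_phases)])
    return MotionTrace(object_id=object_id, displacement_mm=disp)


# --------------------------------------------------------------------------
# phantom specification
# --------------------------------------------------------------------------

@dataclass
class MarkerSpec:
    """A gold fiducial: a capsule (cylinder + hemispherical caps) whose long
    axis is I-S, rendered at ``hu_value`` wherever a voxel center falls
    inside the displaced capsule."""

    rest_center_mm: Sequence[float]
    diameter_mm: float = 1.0
    length_mm: float = 3.0
    hu_value: float = 3000.0
    motion: MotionModel = field(default_factory=MotionModel)

    def __post_init__(self) -> None:
        self.rest_center_mm = np.asarray(self.rest_center_mm, dtype=float)
        if self.diameter_mm <= 0 or self.length_mm <= 0:
            raise ValueError("marker diameter and length must be positive")
        if self.hu_value <= 1500:
            raise ValueError("marker hu_value must exceed 1500 to be detectable")


@dataclass
class GtvSpec:
    """Optional spherical soft-tissue insert."""

    center_mm: Sequence[float]
    radius_mm: float = 8.0
    hu_value: float = 0.0
    motion: MotionModel = field(default_factory=MotionModel)

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        if self.radius_mm <= 0:
            raise ValueError("GTV radius must be positive")


@dataclass
class PhantomSpec:
    """Geometry and motion parameters for synthetic 4D-CT generation.

    Defaults emulate a 3 mm-slice ten-phase thoracic 4D CT: 1 x 1 x 3 mm
    voxels, lung-density background (-750 HU).
    """

    grid_shape: Sequence[int] = (64, 64, 40)
    spacing_mm: Sequence[float] = (1.0, 1.0, 3.0)
    background_hu: float = -750.0
    marker_specs: list[MarkerSpec] = field(default_factory=list)
    gtv_spec: Optional[GtvSpec] = None
    n_phases: int = 10
    noise_sigma_hu: float = 0.0
    seed: int = 0
    origin_mm: Sequence[float] = (0.0, 0.0, 0.0)
    # imaging blur / metal bloom scale per axis; the z value emulates the
    # slice-profile smearing of a 3 mm acquisition
    psf_sigma_mm: Sequence[float] = (0.8, 0.8, 2.0)

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing must be positive")
        if self.noise_sigma_hu < 0:
            raise ValueError("noise sigma must be >= 0")


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------
#
# Objects are rendered with a smooth point-spread falloff rather than a
# binary voxel-center membership test: a voxel's intensity contribution is
#     bg + (hu - bg) * exp(-d^2 / (2 sigma^2))
# where d is the voxel center's Euclidean distance to the object surface
# (0 inside).  This emulates the scanner PSF / metal bloom that makes a
# 1 x 3 mm gold seed visible across neighbouring voxels on real CT, and --
# crucially -- makes the rendered intensities vary continuously with
# sub-voxel object position, which is what lets template matching recover
# displacement below the 3 mm slice resolution.  A binary rendering would
# quantize all displacement information to the voxel grid.


def _render_object(vol: PhaseVolume, center: np.ndarray, radius: float,
                   half_cyl: float, hu: float, bg: float, sigma) -> None:
    """Render an I-S-aligned capsule (sphere when half_cyl = 0) with an
    anisotropic Gaussian falloff outside its envelope.

    The falloff separates into an in-plane radial term (scale = mean of
    the x/y PSF sigmas) and an axial term (scale = z PSF sigma), so a
    3 mm-slice acquisition smears the seed over neighbouring slices the
    way the scanner's slice profile does.
    """
    sigma = np.broadcast_to(np.asarray(sigma, float), (3,))
    s_r = float(sigma[:2].mean())
    s_z = float(sigma[2])
    cx, cy, cz = vol.voxel_centers()
    pad_r = radius + 4.0 * s_r
    pad_z = radius + half_cyl + 4.0 * s_z
    ix = np.nonzero(np.abs(cx - center[0]) <= pad_r)[0]
    iy = np.nonzero(np.abs(cy - center[1]) <= pad_r)[0]
    iz = np.nonzero(np.abs(cz - center[2]) <= pad_z)[0]
    if ix.size == 0 or iy.size == 0 or iz.size == 0:
        return
    X, Y, Z = np.meshgrid(cx[ix], cy[iy], cz[iz], indexing="ij")
    d_r = np.clip(np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2)
                  - radius, 0.0, None)
    d_z = np.clip(np.abs(Z - center[2]) - (half_cyl + radius), 0.0, None)
    field = bg + (hu - bg) * np.exp(
        -0.5 * ((d_r / s_r) ** 2 + (d_z / s_z) ** 2))
    idx = np.ix_(ix, iy, iz)
    vol.data[idx] = np.maximum(vol.data[idx], field.astype(np.float32))


def _check_inside(center: np.ndarray, radius: float, half_cyl: float,
                  spec: PhantomSpec, name: str, phase: int) -> None:
    lo = spec.origin_mm
    hi = spec.origin_mm + (np.asarray(spec.grid_shape) - 1) * spec.spacing_mm
    ext = np.array([radius, radius, radius + half_cyl])
    if np.any(center - ext < lo) or np.any(center + ext > hi):
        raise ValueError(
            f"{name} leaves the grid at phase {phase}: "
            f"center {np.round(center, 2).tolist()} mm with extent "
            f"{np.round(ext, 2).tolist()} mm exceeds grid "
            f"[{lo.tolist()} .. {np.round(hi, 2).tolist()}] mm"
        )


def generate_phantom(spec: PhantomSpec) -> Volume4D:
    """Render the n-phase 4D CT described by ``spec``.

    Each phase k samples every object's motion model at t = k*tau/n_phases.
    A voxel's HU is the maximum of the values claimed by background, GTV
    insert and markers (gold always wins over soft tissue).  With
    ``noise_sigma_hu`` > 0, i.i.d. Gaussian noise seeded by ``spec.seed`` is
    added; identical specs give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    phases: list[PhaseVolume] = []
    for k in range(spec.n_phases):
        vol = PhaseVolume(
            data=np.full(spec.grid_shape, spec.background_hu, dtype=np.float32),
            spacing=spec.spacing_mm,
            origin=spec.origin_mm,
        )
        if spec.gtv_spec is not None:
            g = spec.gtv_spec
            c = np.asarray(g.center_mm) + g.motion.displacement(k, spec.n_phases)
            _check_inside(c, g.radius_mm, 0.0, spec, "GTV", k)
            _render_object(vol, c, g.radius_mm, 0.0, g.hu_value,
                           spec.background_hu, spec.psf_sigma_mm)
        for i, mk in enumerate(spec.marker_specs):
            c = np.asarray(mk.rest_center_mm) + mk.motion.displacement(
                k, spec.n_phases)
            radius = mk.diameter_mm / 2.0
            half_cyl = max(mk.length_mm / 2.0 - radius, 0.0)
            _check_inside(c, radius, half_cyl, spec, f"marker {i + 1}", k)
            _render_object(vol, c, radius, half_cyl, mk.hu_value,
                           spec.background_hu, spec.psf_sigma_mm)
        if spec.noise_sigma_hu > 0:
            vol.data += rng.normal(
                0.0, spec.noise_sigma_hu, size=vol.shape
            ).astype(np.float32)
        phases.append(vol)
    return Volume4D(phases=phases)
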