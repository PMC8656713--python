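"""Synthetic head-and-neck cohort: phantoms, structure sets, daily geometry.

The real cohorts used in online-adaptation studies (daily CBCT/virtual-CT
series of head-and-neck patients) are not publicly available, so this module
generates voxel phantoms with analytically known geometry and analytically
known daily transforms.  The phantom is a water-equivalent elliptic-cylinder
"neck" containing a vertebral-column surrogate (relative stopping power 1.6)
that encloses the spinal cord, two nested CTV dose levels near the midline,
parotid glands lateral-superior, pharyngeal constrictors posterior to the
CTV, larynx inferior-anterior, and brainstem superior-posterior.

Daily geometry instances combine
  * a rigid interfraction setup error (per-patient systematic component plus
    per-fraction random component, Gaussian per axis),
  * progressive radial shrinkage of the external contour (weight loss
    surrogate, linear over the course up to a per-patient maximum), and
  * a stochastic air cavity toggle (sinus-filling surrogate).

All randomness is a pure function of (master seed, patient index, fraction
index, purpose) through ``numpy.random.SeedSequence`` spawn keys, so adding
arms or scenarios never perturbs the geometry draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import GridSpec, VoxelGrid

__all__ = [
    "ConfigurationError",
    "GenerationError",
    "PhantomGeometry",
    "Phantom",
    "PatientModel",
    "DailyInstance",
    "CohortConfig",
    "build_phantom",
    "generate_cohort",
    "daily_instance",
    "sample_setup",
    "apply_rigid_shift",
]

MANDATORY_STRUCTURES = (
    "ctv_high",
    "ctv_low",
    "cord",
    "parotid_l",
    "parotid_r",
    "constrictors",
    "larynx",
    "brainstem",
    "external",
)

AIR_RSP = 1e-3


class ConfigurationError(ValueError):
    """Phantom geometry violates a structural invariant."""


class GenerationError(RuntimeError):
    """A daily transform pushed a target structure off the grid."""


@dataclass(frozen=True)
class PhantomGeometry:
    """World-coordinate (mm) placement of all structures.

    All cylinders are along z.  ``shift`` is a rigid translation applied to
    every structure (the daily setup displacement); ``shrink`` reduces the
    external semi-axes (radial weight-loss surrogate); ``cavity`` toggles an
    air pocket anterior to the CTV.
    """

    external_semi_axes: tuple[float, float] = (55.0, 48.0)
    external_half_z: float = 52.0
    vertebra_center: tuple[float, float] = (0.0, -30.0)
    vertebra_radius: float = 12.0
    vertebra_rsp: float = 1.6
    cord_radius: float = 4.5
    ctv_low_center: tuple[float, float] = (0.0, 2.0)
    ctv_low_radius: float = 20.0
    ctv_low_z: tuple[float, float] = (-16.0, 30.0)
    ctv_high_center: tuple[float, float] = (0.0, 3.0)
    ctv_high_radius: float = 15.0
    ctv_high_z: tuple[float, float] = (-10.0, 24.0)
    parotid_center: tuple[float, float] = (40.0, 2.0)  # +/- x mirrored
    parotid_radius: float = 9.0
    parotid_z: tuple[float, float] = (14.0, 36.0)
    constrictor_half_x: float = 13.0
    constrictor_y: tuple[float, float] = (-21.0, -15.0)
    constrictor_z: tuple[float, float] = (-14.0, 28.0)
    larynx_center: tuple[float, float] = (0.0, 28.0)
    larynx_radius: float = 7.0
    larynx_z: tuple[float, float] = (-44.0, -24.0)
    brainstem_center: tuple[float, float] = (0.0, -26.0)
    brainstem_radius: float = 8.0
    brainstem_z: tuple[float, float] = (38.0, 52.0)
    cavity_center: tuple[float, float, float] = (0.0, 33.0, 8.0)
    cavity_radius: float = 6.0
    tissue_rsp: float = 1.0
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shrink: float = 0.0
    cavity: bool = False
    # displacement of the CTVs relative to the setup reference anatomy
    # (tumor position change that image-guided alignment cannot correct)
    target_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class Phantom:
    """Relative-stopping-power grid plus named boolean structure masks.

    ``target_fractions`` optionally holds fractional (partial-volume) CTV
    occupancy maps used by the planner so the optimization sees the
    continuum target shape rather than its center-sampled rasterization;
    scoring masks remain voxel-center inclusive.
    """

    rsp: VoxelGrid
    structures: dict[str, np.ndarray]
    geometry: PhantomGeometry | None = None
    target_fractions: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        shape = self.rsp.shape
        for name in MANDATORY_STRUCTURES:
            if name not in self.structures:
                raise ConfigurationError(f"missing mandatory structure {name!r}")
        for name, mask in self.structures.items():
            if mask.dtype != bool or tuple(mask.shape) != shape:
                raise ConfigurationError(f"structure {name!r} mask malformed")
        v = self.rsp.values
        if v.min() < 0 or v.max() > 3:
            raise ConfigurationError("rsp outside [0, 3]")
        s = self.structures
        if np.any(s["ctv_high"] & ~s["ctv_low"]):
            raise ConfigurationError("ctv_high not nested inside ctv_low")
        if np.any(s["ctv_low"] & ~s["external"]):
            raise ConfigurationError("ctv_low not nested inside external")

    @property
    def grid(self) -> GridSpec:
        return self.rsp.spec

    def mask(self, name: str) -> np.ndarray:
        return self.structures[name]

    def healthy_mask(self) -> np.ndarray:
        """External minus the CTVs (integral-dose scoring region)."""
        return self.structures["external"] & ~self.structures["ctv_low"]


def _cyl(X, Y, Z, cx, cy, r, z0, z1):
    return ((X - cx) ** 2 + (Y - cy) ** 2 <= r**2) & (Z >= z0) & (Z <= z1)


def build_phantom(grid: GridSpec, geometry: PhantomGeometry | None = None) -> Phantom:
    """Voxelize the parametric neck geometry onto ``grid``.

    Masks are voxel-center inclusive.  Raises :class:`ConfigurationError`
    when the configured placements violate CTV nesting, and
    :class:`GenerationError` when a CTV would be clipped by the grid
    boundary (e.g. an excessive setup shift).
    """
    g = geometry or PhantomGeometry()
    if g.ctv_high_radius > g.ctv_low_radius:
        raise ConfigurationError("ctv_high radius exceeds ctv_low radius")

    ax, ay, az = grid.axes()
    dx, dy, dz = g.shift
    # Shifting every structure by +shift is implemented by sampling the
    # parametric shapes at coordinates - shift.
    X = (ax - dx)[:, None, None]
    Y = (ay - dy)[None, :, None]
    Z = (az - dz)[None, None, :]

    ea = g.external_semi_axes[0] - g.shrink
    eb = g.external_semi_axes[1] - g.shrink
    if ea <= 0 or eb <= 0:
        raise ConfigurationError("shrink exceeds external semi-axes")
    external = ((X / ea) ** 2 + (Y / eb) ** 2 <= 1.0) & (
        np.abs(Z) <= g.external_half_z
    )

    tx, ty, tz = g.target_shift
    Xt, Yt, Zt = X - tx, Y - ty, Z - tz
    s: dict[str, np.ndarray] = {"external": external}
    s["ctv_low"] = _cyl(Xt, Yt, Zt, *g.ctv_low_center, g.ctv_low_radius, *g.ctv_low_z)
    s["ctv_high"] = _cyl(Xt, Yt, Zt, *g.ctv_high_center, g.ctv_high_radius, *g.ctv_high_z)
    s["cord"] = _cyl(X, Y, Z, *g.vertebra_center, g.cord_radius, -g.external_half_z, g.external_half_z)
    s["parotid_l"] = _cyl(X, Y, Z, g.parotid_center[0], g.parotid_center[1], g.parotid_radius, *g.parotid_z)
    s["parotid_r"] = _cyl(X, Y, Z, -g.parotid_center[0], g.parotid_center[1], g.parotid_radius, *g.parotid_z)
    s["constrictors"] = (
        (np.abs(X) <= g.constrictor_half_x)
        & (Y >= g.constrictor_y[0]) & (Y <= g.constrictor_y[1])
        & (Z >= g.constrictor_z[0]) & (Z <= g.constrictor_z[1])
    ) & external
    s["larynx"] = _cyl(X, Y, Z, *g.larynx_center, g.larynx_radius, *g.larynx_z)
    s["brainstem"] = _cyl(X, Y, Z, *g.brainstem_center, g.brainstem_radius, *g.brainstem_z)

    for name in ("ctv_low", "ctv_high"):
        m = s[name]
        if not m.any():
            raise GenerationError(f"{name} empty on this grid")
        if (
            m[0].any() or m[-1].any()
            or m[:, 0].any() or m[:, -1].any()
            or m[:, :, 0].any() or m[:, :, -1].any()
        ):
            raise GenerationError(f"{name} clipped by grid boundary")

    # Anti-aliased stopping power: 2x2x2 supersampling gives surface voxels
    # partial-volume values, so water-equivalent depths respond smoothly
    # (first order) to sub-voxel rigid shifts instead of jumping by half a
    # voxel when the binary surface re-rasterizes.
    rsp = np.zeros(grid.shape)
    frac_high = np.zeros(grid.shape)
    frac_low = np.zeros(grid.shape)
    h = np.asarray(grid.spacing)
    for ox in (-0.25, 0.25):
        for oy in (-0.25, 0.25):
            for oz in (-0.25, 0.25):
                Xs = X + ox * h[0]
                Ys = Y + oy * h[1]
                Zs = Z + oz * h[2]
                frac_low += _cyl(
                    Xs - tx, Ys - ty, Zs - tz,
                    *g.ctv_low_center, g.ctv_low_radius, *g.ctv_low_z,
                )
                frac_high += _cyl(
                    Xs - tx, Ys - ty, Zs - tz,
                    *g.ctv_high_center, g.ctv_high_radius, *g.ctv_high_z,
                )
                ext = ((Xs / ea) ** 2 + (Ys / eb) ** 2 <= 1.0) & (
                    np.abs(Zs) <= g.external_half_z
                )
                sub = np.where(ext, g.tissue_rsp, AIR_RSP)
                vert = _cyl(
                    Xs, Ys, Zs, *g.vertebra_center, g.vertebra_radius,
                    -g.external_half_z, g.external_half_z,
                )
                cord = _cyl(
                    Xs, Ys, Zs, *g.vertebra_center, g.cord_radius,
                    -g.external_half_z, g.external_half_z,
                )
                sub = np.where(vert & ext & ~cord, g.vertebra_rsp, sub)
                if g.cavity:
                    cav = (
                        (Xs - g.cavity_center[0]) ** 2
                        + (Ys - g.cavity_center[1]) ** 2
                        + (Zs - g.cavity_center[2]) ** 2
                    ) <= g.cavity_radius**2
                    sub = np.where(cav, AIR_RSP, sub)
                rsp += sub
    rsp /= 8.0

    return Phantom(
        rsp=grid.wrap(rsp),
        structures=s,
        geometry=g,
        target_fractions={"ctv_high": frac_high / 8.0, "ctv_low": frac_low / 8.0},
    )


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class CohortConfig:
    """Distributions from which per-patient variation parameters are drawn."""

    n_fractions_range: tuple[int, int] = (31, 35)
    systematic_sigma: float = 2.0      # mm, per-axis systematic setup error
    random_sigma: float = 2.0          # mm, per-axis per-fraction random error
    shrink_max_range: tuple[float, float] = (0.0, 4.0)  # mm over the course
    cavity_prob: float = 0.2
    # progressive displacement of the tumor relative to the setup
    # reference, reached at the end of the course (mm); random direction
    drift_max_range: tuple[float, float] = (0.0, 5.0)


@dataclass
class PatientModel:
    patient_id: str
    grid: GridSpec
    geometry: PhantomGeometry
    n_fractions: int
    systematic: tuple[float, float, float]
    random_sigma: float
    shrink_max: float
    cavity_prob: float
    seed: int
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)  # end-of-course, mm

    def __post_init__(self) -> None:
        if not 1 <= self.n_fractions:
            raise ConfigurationError("n_fractions must be positive")

    _planning: Phantom | None = field(default=None, repr=False, compare=False)

    @property
    def planning_phantom(self) -> Phantom:
        if self._planning is None:
            self._planning = build_phantom(self.grid, self.geometry)
        return self._planning


@dataclass
class DailyInstance:
    fraction_index: int                    # 1-based
    phantom: Phantom
    setup_transform: tuple[float, float, float]  # planning -> daily translation, mm
    anatomy_descriptor: dict


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_cohort(
    n_patients: int,
    master_seed: int,
    grid: GridSpec | None = None,
    geometry: PhantomGeometry | None = None,
    config: CohortConfig | None = None,
) -> list[PatientModel]:
    """Draw a deterministic cohort of synthetic patients.

    Fraction counts are uniform over the configured range (31-35 by
    default); variation parameters are drawn from ``config``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    from .config import PROFILES

    grid = grid or PROFILES["default"].grid
    geometry = geometry or PhantomGeometry()
    cfg = config or CohortConfig()
    patients = []
    for i in range(n_patients):
        seed = int(np.random.SeedSequence(master_seed, spawn_key=(i,)).generate_state(1)[0])
        rng = _rng(seed, 0)
        lo, hi = cfg.n_fractions_range
        n_fx = int(rng.integers(lo, hi + 1))
        systematic = tuple(rng.normal(0.0, cfg.systematic_sigma, 3))
        shrink_max = float(rng.uniform(*cfg.shrink_max_range))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        drift = tuple(float(rng.uniform(*cfg.drift_max_range)) * direction)
        patients.append(
            PatientModel(
                patient_id=f"P{i:02d}",
                grid=grid,
                geometry=geometry,
                n_fractions=n_fx,
                systematic=systematic,
                random_sigma=cfg.random_sigma,
                shrink_max=shrink_max,
                cavity_prob=cfg.cavity_prob,
                seed=seed,
                drift=drift,
            )
        )
    return patients


def sample_setup(patient: PatientModel, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Systematic and random setup components (mm) for fraction ``j``."""
    if not 1 <= j <= patient.n_fractions:
        raise ValueError(f"fraction index {j} outside 1..{patient.n_fractions}")
    rng = _rng(patient.seed, j, 1)
    random = rng.normal(0.0, patient.random_sigma, 3)
    return np.asarray(patient.systematic, float), random


def anatomy_params(patient: PatientModel, j: int) -> tuple[float, bool, np.ndarray]:
    """Shrink (mm), cavity toggle, and target drift for fraction ``j``.

    Shrink and drift grow linearly over the course to the per-patient
    maxima; the cavity toggle is an independent per-fraction Bernoulli.
    """
    if not 1 <= j <= patient.n_fractions:
        raise ValueError(f"fraction index {j} outside 1..{patient.n_fractions}")
    progress = (j - 1) / (patient.n_fractions - 1) if patient.n_fractions > 1 else 0.0
    shrink = patient.shrink_max * progress
    drift = progress * np.asarray(patient.drift, float)
    rng = _rng(patient.seed, j, 2)
    cavity = bool(rng.random() < patient.cavity_prob)
    return float(shrink), cavity, drift


def daily_instance(patient: PatientModel, j: int) -> DailyInstance:
    """Deterministic daily geometry for fraction ``j`` (1-based).

    The phantom is rebuilt parametrically at the shifted/shrunken
    configuration, so structure identity is exact (no registration error)
    and the setup transform is exactly invertible.
    """
    systematic, random = sample_setup(patient, j)
    shrink, cavity, drift = anatomy_params(patient, j)
    setup = systematic + random
    geometry = dataclasses.replace(
        patient.geometry,
        shift=tuple(setup),
        shrink=shrink,
        cavity=cavity,
        target_shift=tuple(drift),
    )
    phantom = build_phantom(patient.grid, geometry)
    return DailyInstance(
        fraction_index=j,
        phantom=phantom,
        setup_transform=tuple(float(v) for v in setup),
        anatomy_descriptor={"shrink": shrink, "cavity": cavity, "target_drift": tuple(drift)},
    )


# ---------------------------------------------------------------------------
# Rigid shifts


def shift_mask(mask: np.ndarray, delta_vox: np.ndarray) -> np.ndarray:
    """Nearest-neighbor mask translation = exact lattice roll with zero fill.

    Rounding uses round-half-to-even so that shifting by ``delta`` and then
    ``-delta`` is an exact inverse for any ``delta``.
    """
    steps = np.rint(np.asarray(delta_vox, float)).astype(int)
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, k in enumerate(steps):
        n = mask.shape[ax]
        if abs(k) >= n:
            return out
        if k >= 0:
            dst[ax] = slice(k, n)
            src[ax] = slice(0, n - k)
        else:
            dst[ax] = slice(0, n + k)
            src[ax] = slice(-k, n)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def apply_rigid_shift(phantom: Phantom, delta) -> Phantom:
    """Translate a phantom rigidly by ``delta`` (mm, world frame).

    The stopping-power grid is resampled with trilinear interpolation;
    masks are shifted nearest-neighbor, which preserves boolean identity
    and makes the shift exactly invertible for the masks.
    """
    delta = np.asarray(delta, float)
    spacing = np.asarray(phantom.rsp.spacing)
    extent = spacing * np.asarray(phantom.rsp.shape)
    if np.any(np.abs(delta) >= extent / 4):
        raise ValueError("shift exceeds a quarter of the grid extent")
    if np.all(delta == 0):
        return Phantom(
            rsp=phantom.rsp.copy(),
            structures={k: v.copy() for k, v in phantom.structures.items()},
            geometry=phantom.geometry,
        )
    dvox = delta / spacing
    rsp = ndimage.shift(
        phantom.rsp.values, dvox, order=1, mode="constant", cval=AIR_RSP
    )
    np.clip(rsp, 0.0, 3.0, out=rsp)
    structures = {k: shift_mask(v, dvox) for k, v in phantom.structures.items()}
    geometry = None
    if phantom.geometry is not None:
        old = np.asarray(phantom.geometry.shift)
        geometry = dataclasses.replace(phantom.geometry, shift=tuple(old + delta))
    return Phantom(rsp=phantom.rsp.spec.wrap(rsp), structures=structures, geometry=geometry)
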