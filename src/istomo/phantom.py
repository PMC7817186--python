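"""Synthetic two-cell conjugate phantoms with ground truth.

The generator emulates what the microscope measures: two quasi-spherical
cells in contact — an effector (T-cell-like, higher-RI cytoplasm with
high-RI granules) pressed against a target (lower-RI cytoplasm with a
nucleus-like core) — embedded in medium of known refractive index.  It
produces the RI volume, the true cell masks, the signed distance map, an
analytic description of the contact interface, and, for time series, the
full kinematic state per frame.

Kinetics model.  Contact area and center-of-mass displacement both follow
a saturating hyperbola y(t) = y_max * t / (t + tau_half).  The contact is
realized geometrically: two spheres interpenetrate by the depth whose
lens-intersection disc has exactly the prescribed area, and the voxels of
the lens are assigned to the nearer cell center (effector wins ties), so
the true interface is the radical plane of the two spheres.  Prescribed
displacements apply to the *realized density-weighted centroid* of each
cell, not the sphere center: the growing truncation shifts the centroid
away from the interface, so sphere centers are corrected by a short
fixed-point iteration until the rasterized centroids land on the
prescribed trajectory (sub-0.1-voxel residual).  The target cell moves
along the initial contact axis; the effector's direction is solved in the
contact plane so that both its displacement magnitude and the
center-distance constraint hold simultaneously.

The forward optical model is single scattering only (first order), the
same approximation the reconstruction inverts; each illumination samples
the object spectrum on its Ewald-sphere cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .io import (
    CellMaskPair,
    Tomogram,
    ValidationError,
    VolumeMetadata,
    logger,
)
from .distnet import SignedDistanceMap, build_signed_distance_target
from .recon import HologramSet

TWO_PI = 2.0 * np.pi


class GeometryError(ValueError):
    """Phantom geometry does not fit the grid or is infeasible."""


# ---------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------


@dataclass
class CellSpec:
    """One quasi-spherical cell: position and compartment refractive indices."""

    center_nm: tuple[float, float, float]      # (z, y, x)
    radius_nm: float
    cytoplasm_ri: float
    core_radius_nm: float = 0.0                # nucleus-like concentric core
    core_ri: Optional[float] = None
    n_granules: int = 0
    granule_radius_nm: float = 0.0
    granule_ri: Optional[float] = None


@dataclass
class PhantomSpec:
    """Grid, medium and the two cells of a conjugate phantom."""

    shape: tuple[int, int, int] = (48, 48, 48)         # (z, y, x) voxels
    pitch_nm: tuple[float, float, float] = (218.5,) * 3
    medium_ri: float = 1.337
    effector: CellSpec = field(default_factory=lambda: CellSpec(
        center_nm=(5240.0, 5240.0, 3300.0), radius_nm=1750.0,
        cytoplasm_ri=1.360, n_granules=6, granule_radius_nm=330.0,
        granule_ri=1.380))
    target: CellSpec = field(default_factory=lambda: CellSpec(
        center_nm=(5240.0, 5240.0, 6500.0), radius_nm=1750.0,
        cytoplasm_ri=1.350, core_radius_nm=900.0, core_ri=1.344))
    seed: int = 0

    def __post_init__(self) -> None:
        for cell in (self.effector, self.target):
            if cell.radius_nm < 0:
                raise ValidationError("cell radius must be >= 0")
            if cell.radius_nm > 0 and cell.cytoplasm_ri <= self.medium_ri:
                raise ValidationError("cell RI must exceed medium RI (positive contrast)")
            if cell.n_granules and (cell.granule_ri or 0) <= cell.cytoplasm_ri:
                raise ValidationError("granule RI must exceed the cell body RI")


@dataclass
class KineticsSpec:
    """Saturating-hyperbola kinetics of contact area and cell translocation.

    Defaults are the fitted values of the measured effector/target
    conjugate dynamics: A_max = 106.16 um^2, tau_half = 39.63 s for the
    synapse area; dd_max = 7.48 / 1.74 um with tau_half = 37.84 / 14.56 s
    for the effector / target center-of-mass displacement.
    """

    a_max_um2: float = 106.16
    tau_area_s: float = 39.63
    dd_max_um: tuple[float, float] = (7.48, 1.74)      # (effector, target)
    tau_disp_s: tuple[float, float] = (37.84, 14.56)
    frame_interval_s: float = 6.0
    duration_s: float = 300.0
    noise_ri: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a_max_um2, self.tau_area_s, *self.dd_max_um,
               *self.tau_disp_s, self.frame_interval_s, self.duration_s) <= 0:
            raise ValidationError("kinetics parameters must be positive")
        if not (3.0 <= self.frame_interval_s <= 8.0):
            logger.warning("frame interval %.1f s outside the usual 3-8 s range",
                           self.frame_interval_s)


def hyperbola(t: np.ndarray | float, y_max: float, tau_half: float):
    """Saturating hyperbola y_max * t / (t + tau_half)."""
    t = np.asarray(t, dtype=float)
    return y_max * t / (t + tau_half)


@dataclass
class InterfaceDisc:
    """Analytic truth of the contact interface: a disc on the radical plane."""

    point_nm: np.ndarray      # a point on the plane (on the center line)
    normal: np.ndarray        # unit normal, effector -> target
    radius_nm: float


@dataclass
class KinematicState:
    time_s: float = 0.0
    area_um2: float = 0.0
    disp_um: tuple[float, float] = (0.0, 0.0)
    centers_nm: Optional[np.ndarray] = None      # (2, 3) sphere centers
    centroids_nm: Optional[np.ndarray] = None    # (2, 3) realized mass centroids


@dataclass
class PhantomTruth:
    """A phantom frame: measurement plus every piece of ground truth."""

    tomogram: Tomogram
    pair: CellMaskPair
    interface: Optional[InterfaceDisc] = None
    state: KinematicState = field(default_factory=KinematicState)
    granule_mask: Optional[np.ndarray] = None
    core_mask: Optional[np.ndarray] = None
    _distmap: Optional[SignedDistanceMap] = field(default=None, repr=False)

    @property
    def distmap(self) -> SignedDistanceMap:
        if self._distmap is None:
            self._distmap = build_signed_distance_target(self.pair)
        return self._distmap


# ---------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------


def _coordinate_grids(shape, pitch_nm):
    axes = [np.arange(n, dtype=np.float64) * p for n, p in zip(shape, pitch_nm)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _check_inside(center, radius, shape, pitch_nm, margin_voxels=2):
    for c, n, p in zip(center, shape, pitch_nm):
        if c - radius < margin_voxels * p or c + radius > (n - 1 - margin_voxels) * p:
            raise GeometryError(
                f"cell (center {center}, r={radius:.0f} nm) leaves less than "
                f"{margin_voxels} voxels of margin on a {shape} grid")


def _sample_granule_offsets(cell: CellSpec, rng: np.random.Generator,
                            distal_axis: Optional[np.ndarray] = None) -> np.ndarray:
    """Granule centers relative to the cell center (body frame, nm).

    With ``distal_axis`` given, granules are confined to a cone on the
    hemisphere away from that axis so they never straddle the contact
    interface as the cells interpenetrate.
    """
    if cell.n_granules == 0:
        return np.zeros((0, 3))
    out = []
    r_lo, r_hi = 0.25 * cell.radius_nm, 0.70 * cell.radius_nm
    while len(out) < cell.n_granules:
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v) + 1e-12
        if distal_axis is not None and np.dot(v, distal_axis) > -0.5:
            continue  # keep within the distal 60-degree cone
        rad = rng.uniform(r_lo, r_hi)
        out.append(v * rad)
    return np.asarray(out)


def _rasterize(
    spec: PhantomSpec,
    centers_nm: np.ndarray,
    granule_offsets: Sequence[np.ndarray],
    check_bounds: bool = True,
) -> tuple[np.ndarray, CellMaskPair, np.ndarray, np.ndarray]:
    """Paint the two-cell RI volume and masks for given sphere centers."""
    zz, yy, xx = _coordinate_grids(spec.shape, spec.pitch_nm)
    cells = (spec.effector, spec.target)
    dist2 = []
    inside = []
    for cell, c in zip(cells, centers_nm):
        if check_bounds and cell.radius_nm > 0:
            _check_inside(c, cell.radius_nm, spec.shape, spec.pitch_nm)
        # squared distance to the center, evaluated inside a bounding box
        d2 = np.full(spec.shape, np.inf, dtype=np.float64)
        r = cell.radius_nm
        sl = tuple(slice(max(0, int((c[a] - r) / spec.pitch_nm[a]) - 1),
                         min(spec.shape[a], int((c[a] + r) / spec.pitch_nm[a]) + 2))
                   for a in range(3)) if r > 0 else (slice(0, 0),) * 3
        d2[sl] = ((zz[sl[0], :, :] - c[0]) ** 2 + (yy[:, sl[1], :] - c[1]) ** 2
                  + (xx[:, :, sl[2]] - c[2]) ** 2)
        dist2.append(d2)
        inside.append(d2 <= r**2 if r > 0 else np.zeros(spec.shape, dtype=bool))
    # lens voxels go to the nearer center; the effector wins exact ties
    eff = inside[0] & (~inside[1] | (dist2[0] <= dist2[1]))
    tgt = inside[1] & ~eff

    ri = np.full(spec.shape, spec.medium_ri, dtype=np.float32)
    core_mask = np.zeros(spec.shape, dtype=bool)
    granule_mask = np.zeros(spec.shape, dtype=bool)
    for cell, c, d2, mask, offs in zip(cells, centers_nm, dist2, (eff, tgt),
                                       granule_offsets):
        if not mask.any():
            continue
        ri[mask] = cell.cytoplasm_ri
        if cell.core_radius_nm > 0 and cell.core_ri is not None:
            core = (d2 <= cell.core_radius_nm**2) & mask
            ri[core] = cell.core_ri
            core_mask |= core
        for off in offs:
            g = np.asarray(c) + off
            rg = cell.granule_radius_nm
            # paint inside a local bounding box only
            sl = tuple(slice(max(0, int((g[a] - rg) / spec.pitch_nm[a]) - 1),
                             min(spec.shape[a],
                                 int((g[a] + rg) / spec.pitch_nm[a]) + 2))
                       for a in range(3))
            lz = zz[sl[0], :, :]
            ly = yy[:, sl[1], :]
            lx = xx[:, :, sl[2]]
            gm = (((lz - g[0]) ** 2 + (ly - g[1]) ** 2 + (lx - g[2]) ** 2
                   <= rg**2) & mask[sl])
            ri[sl][gm] = cell.granule_ri
            granule_mask[sl] |= gm

    pair = CellMaskPair(effector=eff, target=tgt, pitch=spec.pitch_nm)
    return ri, pair, granule_mask, core_mask


def _interface_of(centers: np.ndarray, r1: float, r2: float) -> Optional[InterfaceDisc]:
    d = centers[1] - centers[0]
    D = float(np.linalg.norm(d))
    if D == 0 or D >= r1 + r2 or r1 == 0 or r2 == 0:
        return None
    n = d / D
    d1 = (D**2 + r1**2 - r2**2) / (2 * D)
    a2 = r1**2 - d1**2
    if a2 <= 0:
        return None
    return InterfaceDisc(point_nm=centers[0] + d1 * n, normal=n,
                         radius_nm=float(np.sqrt(a2)))


def make_conjugate(spec: PhantomSpec) -> PhantomTruth:
    """Rasterize a static two-cell conjugate with full ground truth."""
    rng = np.random.default_rng(spec.seed)
    centers = np.asarray([spec.effector.center_nm, spec.target.center_nm], dtype=float)
    offs = [_sample_granule_offsets(spec.effector, rng),
            _sample_granule_offsets(spec.target, rng)]
    ri, pair, granules, cores = _rasterize(spec, centers, offs)
    tom = Tomogram(values=ri, pitch=spec.pitch_nm, medium_ri=spec.medium_ri)
    iface = _interface_of(centers, spec.effector.radius_nm, spec.target.radius_nm)
    state = KinematicState(centers_nm=centers,
                           centroids_nm=_density_centroids(tom, pair))
    return PhantomTruth(tomogram=tom, pair=pair, interface=iface, state=state,
                        granule_mask=granules, core_mask=cores)


def _density_centroids(tom: Tomogram, pair: CellMaskPair) -> np.ndarray:
    """RI-contrast-weighted centroid (nm) of each cell mask."""
    w = np.clip(tom.contrast, 0, None).astype(np.float64)
    out = np.zeros((2, 3))
    for i, mask in enumerate((pair.effector, pair.target)):
        ww = w * mask
        tot = ww.sum()
        if tot == 0:
            out[i] = np.nan
            continue
        idx = np.array(ndimage.center_of_mass(ww))
        out[i] = idx * np.asarray(tom.pitch)
    return out


# ---------------------------------------------------------------------
# time-lapse generation
# ---------------------------------------------------------------------


def _separation_for_area(area_um2: float, r1: float, r2: float) -> float:
    """Center distance (nm) at which the lens disc has the given area."""
    if area_um2 <= 0:
        return r1 + r2
    a = np.sqrt(area_um2 / np.pi) * 1e3  # disc radius, nm
    if a >= 0.99 * min(r1, r2):
        raise GeometryError(
            f"requested contact area {area_um2:.1f} um^2 needs a disc radius "
            f"{a:.0f} nm, too large for cell radii {r1:.0f}/{r2:.0f} nm")
    return float(np.sqrt(r1**2 - a**2) + np.sqrt(r2**2 - a**2))


def _solve_effector_angle(base: np.ndarray, dd_e: float, e1: np.ndarray,
                          e2: np.ndarray, c_t: np.ndarray, D: float) -> np.ndarray:
    """Smallest angle theta with |base + dd_e (cos t e1 + sin t e2) - c_t| = D."""
    if dd_e < 1e-9:
        return base

    def f(theta):
        c = base + dd_e * (np.cos(theta) * e1 + np.sin(theta) * e2)
        return np.linalg.norm(c - c_t) - D

    from scipy.optimize import brentq

    thetas = np.linspace(0.0, np.pi, 91)
    vals = [f(th) for th in thetas]
    for i in range(len(thetas) - 1):
        if vals[i] == 0.0:
            th = thetas[i]
            break
        if vals[i] * vals[i + 1] < 0:
            th = brentq(f, thetas[i], thetas[i + 1], xtol=1e-10)
            break
    else:
        raise GeometryError(
            "prescribed displacement and contact area are incompatible: the "
            "effector cannot both travel the prescribed distance and keep the "
            "required center separation")
    return base + dd_e * (np.cos(th) * e1 + np.sin(th) * e2)


def make_timelapse(spec: PhantomSpec, kin: KineticsSpec) -> list[PhantomTruth]:
    """Generate a time series of conjugate frames following the kinetics spec.

    Frame 0 has the cells exactly touching (zero contact area); later
    frames realize A(t) through sphere interpenetration and move the
    *realized* density-weighted centroid of each cell by dd(t): the target
    along the initial contact axis, the effector along a direction solved
    in the contact plane.  A fixed-point loop (3 iterations) compensates
    the centroid shift caused by the growing truncation of each sphere.
    """
    rng = np.random.default_rng(spec.seed)
    r1, r2 = spec.effector.radius_nm, spec.target.radius_nm
    if min(r1, r2) <= 0:
        raise GeometryError("time-lapse needs two cells of positive radius")
    _separation_for_area(hyperbola(kin.duration_s, kin.a_max_um2, kin.tau_area_s),
                         r1, r2)  # fail early if the saturated area cannot fit

    c_e0 = np.asarray(spec.effector.center_nm, dtype=float)
    axis = np.asarray(spec.target.center_nm, dtype=float) - c_e0
    axis /= np.linalg.norm(axis) + 1e-12
    c_t0 = c_e0 + (r1 + r2) * axis           # exact touching at t = 0
    # in-plane second direction for the effector trajectory
    trial = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(trial, axis)) > 0.9:
        trial = np.array([1.0, 0.0, 0.0])
    e2 = trial - np.dot(trial, axis) * axis
    e2 /= np.linalg.norm(e2)

    offs = [_sample_granule_offsets(spec.effector, rng, distal_axis=axis),
            _sample_granule_offsets(spec.target, rng, distal_axis=-axis)]

    times = np.arange(0.0, kin.duration_s + 1e-9, kin.frame_interval_s)
    frames: list[PhantomTruth] = []
    # realized centroid offsets relative to sphere centers, warm-started
    o_e = np.zeros(3)
    o_t = np.zeros(3)
    q_e0 = q_t0 = None

    for k, t in enumerate(times):
        A = float(hyperbola(t, kin.a_max_um2, kin.tau_area_s))
        dd_e = float(hyperbola(t, kin.dd_max_um[0], kin.tau_disp_s[0])) * 1e3
        dd_t = float(hyperbola(t, kin.dd_max_um[1], kin.tau_disp_s[1])) * 1e3
        D = _separation_for_area(A, r1, r2)

        if k == 0:
            centers = np.stack([c_e0, c_t0])
            ri, pair, granules, cores = _rasterize(spec, centers, offs)
            tom = Tomogram(values=ri, pitch=spec.pitch_nm, medium_ri=spec.medium_ri)
            cents = _density_centroids(tom, pair)
            q_e0, q_t0 = cents[0].copy(), cents[1].copy()
            o_e, o_t = cents[0] - centers[0], cents[1] - centers[1]
        else:
            q_t = q_t0 - dd_t * axis          # target pushed back along the axis
            for _ in range(3):
                c_t = q_t - o_t
                base = q_e0 - o_e
                c_e = _solve_effector_angle(base, dd_e, axis, e2, c_t, D)
                centers = np.stack([c_e, c_t])
                ri, pair, granules, cores = _rasterize(spec, centers, offs)
                tom = Tomogram(values=ri, pitch=spec.pitch_nm,
                               medium_ri=spec.medium_ri)
                cents = _density_centroids(tom, pair)
                o_e = cents[0] - centers[0]
                o_t = cents[1] - centers[1]

        if kin.noise_ri > 0:
            noisy = tom.values + rng.normal(
                0.0, kin.noise_ri, size=tom.values.shape).astype(np.float32)
            tom = Tomogram(values=noisy, pitch=spec.pitch_nm,
                           medium_ri=spec.medium_ri, timestamp=float(t))
        else:
            tom.timestamp = float(t)
        iface = _interface_of(centers, r1, r2)
        state = KinematicState(time_s=float(t), area_um2=A,
                               disp_um=(dd_e / 1e3, dd_t / 1e3),
                               centers_nm=centers.copy(),
                               centroids_nm=cents.copy())
        frames.append(PhantomTruth(tomogram=tom, pair=pair, interface=iface,
                                   state=state, granule_mask=granules,
                                   core_mask=cores))
    return frames


def default_timelapse_spec(pitch_nm: float = 218.5) -> tuple[PhantomSpec, KineticsSpec]:
    """Grid and cells sized so the reference kinetics fit with margin.

    Two 6.2-um-radius cells on a 14 x 19 x 28 um field (a (64, 88, 128)
    grid at the default 218.5 nm pitch); the saturated contact disc
    (radius 5.8 um) and both displacement trajectories (including the
    effector's mid-trajectory lateral excursion of about 3.5 um) stay at
    least two voxels inside.  A finer ``pitch_nm`` keeps the physical
    geometry and refines the grid: contact-area voxelization bias is
    linear in the pitch, so half pitch halves it.
    """
    p0 = 218.5
    shape = tuple(int(round(n * p0 / pitch_nm)) for n in (64, 88, 128))
    eff = CellSpec(center_nm=(32 * p0, 36 * p0, 32 * p0), radius_nm=6200.0,
                   cytoplasm_ri=1.360, n_granules=8, granule_radius_nm=450.0,
                   granule_ri=1.380)
    tgt = CellSpec(center_nm=(32 * p0, 36 * p0, 32 * p0 + 12400.0), radius_nm=6200.0,
                   cytoplasm_ri=1.350, core_radius_nm=2000.0, core_ri=1.344)
    spec = PhantomSpec(shape=shape, pitch_nm=(pitch_nm,) * 3, medium_ri=1.337,
                       effector=eff, target=tgt, seed=7)
    return spec, KineticsSpec()


def training_conjugate_spec(seed: int) -> PhantomSpec:
    """A randomized small conjugate for network training/validation sets.

    (32, 32, 64) voxels at 218.5 nm pitch; radii, penetration, granule
    layout and compartment RIs jitter with the seed so each phantom is a
    distinct conjugate while staying in the same contrast regime.
    """
    rng = np.random.default_rng(seed)
    p = 218.5
    r1 = rng.uniform(7.0, 8.5) * p
    r2 = rng.uniform(7.0, 8.5) * p
    pen = rng.uniform(1.0, 3.5) * p          # interpenetration depth
    cy, cz = 16 * p + rng.uniform(-1, 1) * p, 16 * p + rng.uniform(-1, 1) * p
    x1 = 32 * p - (r1 + r2 - pen) / 2
    eff = CellSpec(center_nm=(cz, cy, x1), radius_nm=r1,
                   cytoplasm_ri=rng.uniform(1.357, 1.363),
                   n_granules=int(rng.integers(3, 7)),
                   granule_radius_nm=rng.uniform(280, 380),
                   granule_ri=rng.uniform(1.376, 1.384))
    tgt = CellSpec(center_nm=(cz + rng.uniform(-1, 1) * p, cy,
                              x1 + r1 + r2 - pen), radius_nm=r2,
                   cytoplasm_ri=rng.uniform(1.347, 1.353),
                   core_radius_nm=rng.uniform(0.3, 0.5) * r2,
                   core_ri=rng.uniform(1.342, 1.346))
    return PhantomSpec(shape=(32, 32, 64), pitch_nm=(p, p, p), medium_ri=1.337,
                       effector=eff, target=tgt, seed=seed)


# ---------------------------------------------------------------------
# simple sphere phantom for optical tests
# ---------------------------------------------------------------------


def make_sphere_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    pitch_nm: float = 100.0,
    medium_ri: float = 1.337,
    radius_nm: float = 1000.0,
    delta_n: float = 0.02,
    center_vox: Optional[tuple[float, float, float]] = None,
    edge_sigma_voxels: float = 1.0,
) -> tuple[Tomogram, np.ndarray]:
    """A homogeneous sphere of RI contrast ``delta_n`` plus its support mask.

    The edge is softened with a Gaussian of ``edge_sigma_voxels`` so the
    rasterized object is band-limited on the grid (anti-aliased forward
    modelling); the support mask is the sharp geometric ball.
    """
    if center_vox is None:
        center_vox = tuple((s - 1) / 2 for s in shape)
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                             indexing="ij", sparse=True)
    d2 = ((zz - center_vox[0]) ** 2 + (yy - center_vox[1]) ** 2
          + (xx - center_vox[2]) ** 2)
    r_vox = radius_nm / pitch_nm
    support = d2 <= r_vox**2
    ball = support.astype(np.float64)
    if edge_sigma_voxels > 0:
        ball = ndimage.gaussian_filter(ball, edge_sigma_voxels)
    tom = Tomogram(values=(medium_ri + delta_n * ball).astype(np.float32),
                   pitch=(pitch_nm,) * 3, medium_ri=medium_ri)
    return tom, support


# ---------------------------------------------------------------------
# first-order scattering forward model
# ---------------------------------------------------------------------


def illumination_directions(meta: VolumeMetadata, medium_ri: float) -> np.ndarray:
    """Unit direction cosines (z, y, x): one normal beam plus a uniform
    azimuthal fan on a cone at the illumination NA."""
    n = meta.n_illuminations
    dirs = np.zeros((n, 3))
    dirs[0] = (1.0, 0.0, 0.0)
    if n > 1:
        sin_t = meta.na_illumination / medium_ri
        if sin_t >= 1.0:
            raise ValidationError("illumination NA exceeds the medium index")
        cos_t = np.sqrt(1.0 - sin_t**2)
        phi = TWO_PI * np.arange(n - 1) / (n - 1)
        dirs[1:, 0] = cos_t
        dirs[1:, 1] = sin_t * np.sin(phi)
        dirs[1:, 2] = sin_t * np.cos(phi)
    return dirs


def forward_scatter(
    truth: PhantomTruth | Tomogram,
    meta: VolumeMetadata,
    strict: bool = False,
) -> HologramSet:
    """Simulate angle-scanned complex fields from an RI volume.

    For each illumination the 2D field spectrum is sampled from the
    scattering-potential spectrum on the corresponding Ewald cap (weak-
    scattering first-order model, valid for RI contrast <~ 0.05).  The
    z-transform onto the (generally off-grid) axial frequency is evaluated
    exactly, so the mapping is self-consistent with the reconstruction's
    nearest-voxel gridding up to the gridding step itself.  Fields are the
    *total* fields at the in-focus plane through the volume center,
    including the tilted-plane-wave carrier of each illumination.
    """
    tom = truth.tomogram if isinstance(truth, PhantomTruth) else truth
    contrast = float(np.max(np.abs(tom.contrast)))
    if contrast > 0.05:
        msg = (f"maximum RI contrast {contrast:.3f} exceeds 0.05; the "
               "first-order (Rytov) forward model is unreliable")
        if strict:
            raise ValidationError(msg)
        logger.warning(msg)

    nz, ny, nx = tom.shape
    pz, py, px = tom.pitch
    lam = meta.wavelength_nm
    # match the volume's float32 rounding so zero contrast scatters nothing
    n_m = float(np.float32(tom.medium_ri))
    nu_m = n_m / lam                                   # cycles/nm
    k0_sq = (TWO_PI / lam) ** 2

    # scattering potential and its lateral spectra per slice
    V = (k0_sq * (tom.values.astype(np.float64) ** 2 - n_m**2))
    Vhat2 = np.fft.fft2(V, axes=(1, 2)) * (py * px)    # (z, qy, qx)
    z_c = (np.arange(nz) - nz // 2) * pz

    qy = np.fft.fftfreq(ny, d=py)
    qx = np.fft.fftfreq(nx, d=px)
    QY, QX = np.meshgrid(qy, qx, indexing="ij")
    nyq_z = 0.5 / pz

    dirs = illumination_directions(meta, n_m)
    fields = np.zeros((len(dirs), ny, nx), dtype=np.complex128)
    for i, s in enumerate(dirs):
        nu_i = nu_m * s                                # (z, y, x)
        PY, PX = QY + nu_i[1], QX + nu_i[2]            # detector-frame frequency
        p2 = PY**2 + PX**2
        with np.errstate(invalid="ignore"):
            nu_z = np.sqrt(np.maximum(nu_m**2 - p2, 0.0))
        kz = nu_z - nu_i[0]
        ok = ((p2 < nu_m**2)
              & (p2 <= (meta.na_detection / lam) ** 2)
              & (np.abs(kz) <= nyq_z))
        # exact z-transform of the slice spectra onto the cap
        phase = np.exp(-2j * np.pi * kz[None, :, :] * z_c[:, None, None])
        Vcap = np.einsum("zyx,zyx->yx", Vhat2, phase) * pz
        psi_hat = np.zeros_like(Vcap)
        psi_hat[ok] = (1j / (4 * np.pi * nu_z[ok])) * Vcap[ok]
        psi = np.fft.ifft2(psi_hat) / (py * px)
        # total field = incident tilted plane wave modulated by exp(psi)
        yy = np.arange(ny) * py
        xx = np.arange(nx) * px
        carrier = np.exp(2j * np.pi * (nu_i[1] * yy[:, None] + nu_i[2] * xx[None, :]))
        fields[i] = carrier * np.exp(psi)

    return HologramSet(fields=fields, directions=dirs, wavelength_nm=lam,
                       pitch_nm=(py, px), pitch_z_nm=pz, n_z=nz,
                       medium_ri=n_m, na_detection=meta.na_detection)


def synthesize_hologram(field: np.ndarray, carrier: tuple[float, float],
                        pitch_nm: tuple[float, float],
                        ref_amplitude: float = 1.0) -> np.ndarray:
    """Off-axis hologram |field + reference|^2 with a tilted reference wave.

    ``carrier`` is the reference spatial frequency in cycles/nm (y, x).
    """
    ny, nx = field.shape
    yy = np.arange(ny) * pitch_nm[0]
    xx = np.arange(nx) * pitch_nm[1]
    ref = ref_amplitude * np.exp(
        2j * np.pi * (carrier[0] * yy[:, None] + carrier[1] * xx[None, :]))
    return np.abs(field + ref) ** 2
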