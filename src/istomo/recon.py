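"""Tomographic reconstruction of refractive index from angle-scanned fields.

Pipeline: off-axis holograms are demodulated to complex fields
(:func:`retrieve_field`), converted to the complex Rytov phase
(:func:`rytov_field`), and each field's 2D spectrum is placed on the Ewald
cap of its illumination in the 3D object spectrum (:func:`map_to_spectrum`,
the Fourier diffraction theorem under the weak-scattering Rytov
approximation).  Limited numerical apertures leave a cone of axial
frequencies unsampled ("missing cone"), which elongates the reconstruction
axially; :func:`regularize_nonneg` fills it by Gerchberg-Papoulis-style
alternating projections between the non-negativity of the RI contrast in
object space and fidelity to the measured voxels in Fourier space.

The scattering potential convention is V(r) = (2 pi / lambda)^2
(n(r)^2 - n_m^2) with spatial frequencies in cycles/nm throughout, under
which a thin slab of thickness d delays the transmitted phase by
2 pi delta_n d / lambda, and the measured cap value relates to the Rytov
spectrum by V_cap = 4 pi nu_z psi_hat / i.

RI maps convert to protein concentration through the refractive-index
increment alpha = dRI/dc (0.185 mL/g by default): c = (n - n_m) / alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.restoration import unwrap_phase

from .io import (
    FG_PER_UM3_PER_G_PER_ML,
    ShapeError,
    Tomogram,
    ValidationError,
    VolumeMetadata,
    logger,
)

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------


@dataclass
class HologramSet:
    """Per-illumination complex fields plus the acquisition geometry.

    ``fields`` holds total complex fields at the in-focus mid-plane (one
    per illumination, including the tilted plane-wave carrier); optional
    ``holograms`` are real off-axis intensity images with ``carrier`` the
    reference frequency (cycles/nm).
    """

    fields: np.ndarray                       # (n, ny, nx) complex
    directions: np.ndarray                   # (n, 3) unit (z, y, x) cosines
    wavelength_nm: float
    pitch_nm: tuple[float, float]            # lateral (y, x)
    pitch_z_nm: float
    n_z: int
    medium_ri: float
    na_detection: float = 1.2
    holograms: Optional[np.ndarray] = None
    carrier: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields)
        self.directions = np.asarray(self.directions, dtype=float)
        if self.fields.ndim != 3:
            raise ShapeError("fields must be (n_illuminations, ny, nx)")
        if len(self.directions) != len(self.fields):
            raise ShapeError("one direction per field required")
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValidationError("direction cosines must be unit vectors")

    @property
    def n_illuminations(self) -> int:
        return len(self.fields)


@dataclass
class SpectrumAccumulator:
    """3D object spectrum under construction: complex sums + occupancy counts.

    ``occupancy`` counts deposited samples per voxel (fractional when the
    deposition kernel spreads one sample over neighbouring voxels);
    ``n_z_object`` records the z extent of the object grid when the
    spectrum is k_z-oversampled for finer gridding.
    """

    spectrum: np.ndarray                     # (nz, ny, nx) complex
    occupancy: np.ndarray                    # (nz, ny, nx) counts (may be fractional)
    pitch_nm: tuple[float, float, float]
    medium_ri: float
    wavelength_nm: float
    n_discarded: int = 0
    n_z_object: Optional[int] = None

    def __post_init__(self) -> None:
        if self.spectrum.shape != self.occupancy.shape:
            raise ShapeError("spectrum and occupancy must share one shape")
        if np.any(self.occupancy < 0):
            raise ValidationError("occupancy counts must be >= 0")
        if np.any((self.occupancy == 0) & (self.spectrum != 0)):
            raise ValidationError("spectrum must be zero where occupancy is zero")

    @property
    def measured(self) -> np.ndarray:
        return self.occupancy > 0

    def averaged(self) -> np.ndarray:
        """Occupancy-averaged spectrum (zero where unmeasured)."""
        out = np.zeros_like(self.spectrum)
        m = self.measured
        out[m] = self.spectrum[m] / self.occupancy[m]
        return out


@dataclass
class ProteinDensityMap:
    """Protein concentration in fg/um^3 derived from RI contrast."""

    values: np.ndarray
    pitch: tuple[float, float, float]
    alpha_ml_per_g: float
    medium_ri: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("density map contains non-finite values")
        if self.alpha_ml_per_g <= 0:
            raise ValidationError("refractive-index increment must be positive")


@dataclass
class ResolutionReport:
    """Nyquist-period resolution bounds of the tomographic system."""

    lateral_nm: float
    axial_nm: float
    formula: str

    def __post_init__(self) -> None:
        if self.lateral_nm <= 0 or self.axial_nm <= 0:
            raise ValidationError("resolution periods must be positive")
        if self.axial_nm < self.lateral_nm:
            raise ValidationError("axial period cannot beat the lateral period")


# ---------------------------------------------------------------------
# field retrieval
# ---------------------------------------------------------------------


class CarrierOverlapError(ValueError):
    """Off-axis carrier too close to the baseband for side-band demodulation."""


def retrieve_field(
    hologram: np.ndarray,
    carrier: tuple[float, float],
    pitch_nm: tuple[float, float],
    crop_radius: Optional[float] = None,
    ref_amplitude: float = 1.0,
) -> np.ndarray:
    """Demodulate an off-axis hologram into a complex field.

    The +1 diffraction order at the ``carrier`` frequency (cycles/nm) is
    cropped in Fourier space with a circular window, recentered to DC and
    inverse-transformed.  ``crop_radius`` defaults to half the carrier
    magnitude, the largest window that cannot touch the autocorrelation
    term at DC.
    """
    holo = np.asarray(hologram, dtype=np.float64)
    if holo.ndim != 2:
        raise ShapeError("hologram must be a 2D real image")
    fc = float(np.hypot(*carrier))
    if fc <= 0:
        raise CarrierOverlapError("zero carrier frequency: side bands overlap DC")
    if crop_radius is None:
        crop_radius = fc / 2.0
    if crop_radius >= fc:
        raise CarrierOverlapError(
            f"crop radius {crop_radius:.3g} reaches the DC term (carrier {fc:.3g})")

    ny, nx = holo.shape
    fy = np.fft.fftfreq(ny, d=pitch_nm[0])
    fx = np.fft.fftfreq(nx, d=pitch_nm[1])
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    H = np.fft.fft2(holo)

    win = (FY - carrier[0]) ** 2 + (FX - carrier[1]) ** 2 <= crop_radius**2
    if not win.any():
        raise CarrierOverlapError("carrier lies outside the sampled frequency band")
    side = np.where(win, H, 0.0)
    # the +carrier side band holds conj(field) * reference: demodulate by the
    # conjugate reference in image space, then undo the conjugation
    yy = np.arange(ny) * pitch_nm[0]
    xx = np.arange(nx) * pitch_nm[1]
    ref = np.exp(2j * np.pi * (carrier[0] * yy[:, None] + carrier[1] * xx[None, :]))
    return np.conj(np.fft.ifft2(side) * np.conj(ref)) / ref_amplitude


def unwrap_phase_2d(phase: np.ndarray) -> np.ndarray:
    """2D phase unwrapping (reliability-sorted); deterministic raster tie-break."""
    return np.asarray(unwrap_phase(np.asarray(phase, dtype=np.float64)))


def rytov_field(total: np.ndarray, incident: np.ndarray) -> np.ndarray:
    """Complex Rytov phase log(total / incident) with unwrapped imaginary part.

    The real part is the log-amplitude perturbation, the imaginary part the
    unwrapped phase delay.
    """
    total = np.asarray(total)
    incident = np.asarray(incident)
    if total.shape != incident.shape:
        raise ShapeError("total and incident field shapes differ")
    if np.any(incident == 0):
        raise ZeroDivisionError("incident field contains zeros")
    ratio = total / incident
    log_amp = np.log(np.abs(ratio))
    phase = unwrap_phase_2d(np.angle(ratio))
    return log_amp + 1j * phase


# ---------------------------------------------------------------------
# Fourier-diffraction mapping
# ---------------------------------------------------------------------


def incident_plane_wave(hset: HologramSet, index: int) -> np.ndarray:
    """The tilted plane-wave carrier of illumination ``index`` at the
    in-focus plane (matching the forward model's field convention)."""
    ny, nx = hset.fields.shape[1:]
    py, px = hset.pitch_nm
    nu_m = hset.medium_ri / hset.wavelength_nm
    s = hset.directions[index]
    yy = np.arange(ny) * py
    xx = np.arange(nx) * px
    return np.exp(2j * np.pi * nu_m * (s[1] * yy[:, None] + s[2] * xx[None, :]))


def map_to_spectrum(
    hset: HologramSet,
    z_spread: str = "linear",
    z_oversample: int = 2,
) -> SpectrumAccumulator:
    """Grid every Rytov field onto its Ewald cap in the 3D object spectrum.

    For each illumination, lateral frequencies are already on the 2D grid;
    the axial frequency k_z = sqrt((n_m/lambda)^2 - |k_lat + k_ill,lat|^2)
    - k_ill,z is generally off-grid and is deposited either on the nearest
    z-frequency voxel (``z_spread='nearest'``) or split linearly between
    the two neighbouring voxels (``'linear'``, the default), with
    occupancy-weight averaging resolving overlaps.  ``z_oversample``
    refines the k_z grid by zero-padding the object in z (standard
    oversampled gridding; the reconstruction is cropped back to the
    acquisition depth).  Frequencies beyond the detection NA, evanescent
    components and axial frequencies beyond the grid Nyquist are discarded
    and counted.
    """
    if z_spread not in ("nearest", "linear"):
        raise ValidationError(f"unknown z_spread {z_spread!r}")
    if z_oversample < 1:
        raise ValidationError("z_oversample must be >= 1")
    n, ny, nx = hset.fields.shape
    nz_obj = hset.n_z
    nz = nz_obj * z_oversample
    py, px = hset.pitch_nm
    pz = hset.pitch_z_nm
    lam = hset.wavelength_nm
    nu_m = hset.medium_ri / lam

    qy = np.fft.fftfreq(ny, d=py)
    qx = np.fft.fftfreq(nx, d=px)
    QY, QX = np.meshgrid(qy, qx, indexing="ij")
    dkz = 1.0 / (nz * pz)
    nyq_z = 0.5 / pz
    z0 = (nz_obj // 2) * pz
    vox = pz * py * px

    spectrum = np.zeros((nz, ny, nx), dtype=np.complex128)
    occupancy = np.zeros((nz, ny, nx), dtype=np.float64)
    discarded = 0

    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    for i in range(n):
        psi = rytov_field(hset.fields[i], incident_plane_wave(hset, i))
        psi_hat = np.fft.fft2(psi) * (py * px)
        nu_i = nu_m * hset.directions[i]
        PY, PX = QY + nu_i[1], QX + nu_i[2]
        p2 = PY**2 + PX**2
        with np.errstate(invalid="ignore"):
            nu_z = np.sqrt(np.maximum(nu_m**2 - p2, 0.0))
        kz = nu_z - nu_i[0]
        ok = ((p2 < nu_m**2)
              & (p2 <= (hset.na_detection / lam) ** 2)
              & (np.abs(kz) <= nyq_z))
        discarded += int(np.size(ok) - np.count_nonzero(ok))

        vcap = np.zeros_like(psi_hat)
        vcap[ok] = 4 * np.pi * nu_z[ok] * psi_hat[ok] / 1j
        # recenter the z-origin to index 0 to match the DFT convention,
        # then normalize to plain fftn values of V
        vals = vcap[ok] * np.exp(-2j * np.pi * kz[ok] * z0) / vox
        zf = kz[ok] / dkz                    # fractional z-frequency index
        if z_spread == "nearest":
            zidx = np.rint(zf).astype(np.int64) % nz
            np.add.at(spectrum, (zidx, iy[ok], ix[ok]), vals)
            np.add.at(occupancy, (zidx, iy[ok], ix[ok]), 1.0)
        else:
            lo = np.floor(zf).astype(np.int64)
            frac = zf - lo
            for zi, w in ((lo % nz, 1.0 - frac), ((lo + 1) % nz, frac)):
                np.add.at(spectrum, (zi, iy[ok], ix[ok]), vals * w)
                np.add.at(occupancy, (zi, iy[ok], ix[ok]), w)

    if discarded:
        logger.info("map_to_spectrum: %d frequency samples outside the "
                    "detection band were discarded", discarded)
    return SpectrumAccumulator(spectrum=spectrum, occupancy=occupancy,
                               pitch_nm=(pz, py, px), medium_ri=hset.medium_ri,
                               wavelength_nm=lam, n_discarded=discarded,
                               n_z_object=nz_obj)


def _potential_to_ri(V: np.ndarray, medium_ri: float, wavelength_nm: float) -> np.ndarray:
    k0_sq = (TWO_PI / wavelength_nm) ** 2
    n_sq = np.maximum(medium_ri**2 + V / k0_sq, 0.0)
    return np.sqrt(n_sq)


def regularize_nonneg(
    acc: SpectrumAccumulator,
    medium_ri: Optional[float] = None,
    iterations: int = 100,
    tolerance: float = 1e-6,
) -> Tomogram:
    """Missing-cone filling by alternating projections with a non-negativity
    constraint on the RI contrast.

    Each iteration replaces the measured Fourier voxels by their measured
    values, returns to object space, and clamps the scattering potential
    (equivalently the RI contrast) to be non-negative.  The loop stops at
    the iteration cap or when the relative object change drops below
    ``tolerance``.  ``iterations=0`` returns the plain unregularized
    inversion.
    """
    if iterations < 0:
        raise ValidationError("iterations must be >= 0")
    n_m = acc.medium_ri if medium_ri is None else medium_ri
    measured = acc.measured
    meas_vals = acc.averaged()[measured]
    nz_obj = acc.n_z_object or acc.spectrum.shape[0]

    def project_object(V):
        """Non-negative RI contrast; zero outside the acquisition depth
        (the k_z-oversampled grid pads the object with known empty space)."""
        V = np.maximum(V, 0.0)
        V[nz_obj:] = 0.0
        return V

    S = acc.averaged()
    V = np.real(np.fft.ifftn(S))
    if iterations == 0:
        return Tomogram(values=_potential_to_ri(V[:nz_obj], n_m, acc.wavelength_nm),
                        pitch=acc.pitch_nm, medium_ri=n_m)

    V = project_object(V)
    for _ in range(iterations):
        S = np.fft.fftn(V)
        S[measured] = meas_vals                      # Fourier fidelity
        V_new = project_object(np.real(np.fft.ifftn(S)))  # object constraint
        change = np.linalg.norm(V_new - V) / (np.linalg.norm(V) + 1e-30)
        V = V_new
        if change < tolerance:
            break
    return Tomogram(values=_potential_to_ri(V[:nz_obj], n_m, acc.wavelength_nm),
                    pitch=acc.pitch_nm, medium_ri=n_m)


def reconstruct(hset: HologramSet, iterations: int = 100,
                tolerance: float = 1e-6) -> Tomogram:
    """Convenience composition: map_to_spectrum then regularize_nonneg."""
    return regularize_nonneg(map_to_spectrum(hset), iterations=iterations,
                             tolerance=tolerance)


# ---------------------------------------------------------------------
# resolution bounds
# ---------------------------------------------------------------------


def compute_resolution(
    meta: VolumeMetadata,
    medium_ri: float,
    axial_formula: str = "two_cone",
) -> ResolutionReport:
    """Nyquist-period resolution bounds from the synthetic-aperture extent.

    lateral period = lambda / (2 (NA_ill + NA_det)); the axial band is the
    sum of the illumination- and detection-side cap depths,
    axial period = lambda / (2 [(n_m - sqrt(n_m^2 - NA_ill^2)) +
    (n_m - sqrt(n_m^2 - NA_det^2))]) for the default ``two_cone`` variant,
    or detection-cap only for ``single_cone``.
    """
    lam = meta.wavelength_nm
    na_i, na_d = meta.na_illumination, meta.na_detection
    if na_i > medium_ri or na_d > medium_ri:
        raise ValidationError("NA cannot exceed the medium refractive index")
    lateral = lam / (2.0 * (na_i + na_d))
    depth_det = medium_ri - np.sqrt(medium_ri**2 - na_d**2)
    depth_ill = medium_ri - np.sqrt(medium_ri**2 - na_i**2)
    if axial_formula == "two_cone":
        axial = lam / (2.0 * (depth_ill + depth_det))
    elif axial_formula == "single_cone":
        axial = lam / (2.0 * depth_det)
    else:
        raise ValidationError(f"unknown axial formula variant {axial_formula!r}")
    return ResolutionReport(lateral_nm=float(lateral), axial_nm=float(axial),
                            formula=axial_formula)


# ---------------------------------------------------------------------
# dry-mass conversion
# ---------------------------------------------------------------------


def ri_to_density(tom: Tomogram, alpha_ml_per_g: float = 0.185) -> ProteinDensityMap:
    """Convert RI contrast to protein concentration, c = (n - n_m) / alpha.

    alpha is the refractive-index increment dRI/dc in mL/g; the result is
    expressed in fg/um^3 (1 g/mL = 1000 fg/um^3).  Negative contrasts are
    clamped to zero with a logged count.
    """
    if alpha_ml_per_g <= 0:
        raise ValidationError("refractive-index increment must be positive")
    contrast = tom.contrast.astype(np.float64)
    n_neg = int(np.count_nonzero(contrast < 0))
    if n_neg:
        logger.info("ri_to_density: clamped %d voxels of negative contrast", n_neg)
    c = np.clip(contrast, 0.0, None) / alpha_ml_per_g * FG_PER_UM3_PER_G_PER_ML
    return ProteinDensityMap(values=c.astype(np.float32), pitch=tom.pitch,
                             alpha_ml_per_g=alpha_ml_per_g, medium_ri=tom.medium_ri)
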