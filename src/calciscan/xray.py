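"""Polychromatic scan simulation and filtered back projection.

The forward model is 2D parallel-beam (one reconstructed slice per scan):
the instrument's cone-beam geometry is deliberately out of scope because
every density claim downstream is about *relative* attenuation, which the
parallel geometry reproduces at a fraction of the cost.

Attenuation follows a two-term photoelectric + scatter model,
``mu = density * (A * E**-3 + B)`` (1/um), so mu falls steeply with
energy: the precondition for beam hardening.  Because mu is linear in
density, each ray's energy-resolved path integral reduces to a single
density line integral (computed with :func:`skimage.transform.radon`)
scaled per energy bin.

Per-scan drift is modelled as a multiplicative factor on the recorded
log-attenuations (an effective source/detector response change between
scans).  It rescales the reconstructed grayscale linearly — exactly the
kind of fluctuation the standard-calcite CCN normalization cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon, radon

from calciscan.config import (
    AL_FILTER_DENSITY,
    AL_FILTER_THICKNESS_UM,
    ATTEN_A,
    ATTEN_B,
    MAX_TUBE_KEV,
    MIN_KEV,
)
from calciscan.errors import CalciscanError, ValidationError
from calciscan.phantom import ShellPhantom
from calciscan.volume import AttenuationVolume


def attenuation_coefficient(density, energy):
    """Linear attenuation mu (1/um) for a material of given density (g/cm^3).

    Strictly decreasing in energy, linear in density.  Energy must lie in
    (5, 80] keV (single-value or array inputs).
    """
    energy = np.asarray(energy, dtype=np.float64)
    density = np.asarray(density, dtype=np.float64)
    if np.any(density < 0):
        raise ValidationError("density must be nonnegative")
    if np.any((energy <= MIN_KEV) | (energy > MAX_TUBE_KEV)):
        raise ValidationError(f"energy must be in ({MIN_KEV}, {MAX_TUBE_KEV}] keV")
    mu = density * (ATTEN_A * energy ** -3 + ATTEN_B)
    return float(mu) if mu.ndim == 0 else mu


@dataclass(frozen=True)
class BeamSpectrum:
    """Discrete X-ray spectrum: energy bins (keV) and normalized weights."""

    energies: np.ndarray
    weights: np.ndarray
    gain_drift: float = 1.0

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=np.float64)
        w = np.asarray(self.weights, dtype=np.float64)
        if e.shape != w.shape or e.ndim != 1 or e.size == 0:
            raise ValidationError("energies and weights must be matching 1D arrays")
        if np.any(e > MAX_TUBE_KEV) or np.any(e <= MIN_KEV):
            raise ValidationError(f"energies must lie in ({MIN_KEV}, {MAX_TUBE_KEV}]")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValidationError("weights must be nonnegative with positive sum")
        if self.gain_drift <= 0:
            raise ValidationError("gain_drift must be positive")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w / w.sum())

    @property
    def is_monochromatic(self) -> bool:
        return self.energies.size == 1

    def with_drift(self, gain_drift: float) -> "BeamSpectrum":
        return BeamSpectrum(self.energies, self.weights, gain_drift)


def monochromatic(energy: float = 40.0, gain_drift: float = 1.0) -> BeamSpectrum:
    return BeamSpectrum(np.array([energy]), np.array([1.0]), gain_drift)


def polychromatic(kvp: float = MAX_TUBE_KEV, n_bins: int = 12, *,
                  aluminum_filter: bool = True,
                  gain_drift: float = 1.0) -> BeamSpectrum:
    """Kramers-like bremsstrahlung spectrum, optionally hardened by a
    0.2 mm aluminium pre-filter (Beer-Lambert on the bin weights)."""
    if n_bins < 1 or n_bins > 16:
        raise ValidationError("n_bins must be in [1, 16]")
    edges = np.linspace(10.0, kvp, n_bins + 1)
    energies = 0.5 * (edges[:-1] + edges[1:])
    weights = np.clip(kvp - energies, 0, None) / energies
    if aluminum_filter:
        mu_al = attenuation_coefficient(AL_FILTER_DENSITY, energies)
        weights = weights * np.exp(-mu_al * AL_FILTER_THICKNESS_UM)
    return BeamSpectrum(energies, weights, gain_drift)


@dataclass
class Sinogram:
    """Log-attenuation projections: shape (n_detector, n_angles)."""

    values: np.ndarray
    angles_deg: np.ndarray
    detector_pitch: float  # um
    grid: int  # reconstruction grid edge (pixels)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != self.angles_deg.size:
            raise ValidationError("sinogram must be (n_detector, n_angles)")
        if not np.all(np.isfinite(self.values)):
            raise CalciscanError("non-finite projection values (zero intensity ray?)")
        if np.any(self.values < -1e-9):
            raise CalciscanError("negative log-attenuation")
        self.values = np.clip(self.values, 0.0, None)

    @property
    def n_angles(self) -> int:
        return self.angles_deg.size


def simulate_scan(density: np.ndarray, voxel_size: float,
                  spectrum: BeamSpectrum, n_angles: int = 360, *,
                  seed: int | None = None,
                  photons: float | None = None) -> Sinogram:
    """Scan a 2D density slice (g/cm^3) into a log-attenuation sinogram.

    For each ray the detected intensity is
    ``I = gain * sum_E w(E) * exp(-mu_E_per_density * L(ray))`` with
    ``L`` the density line integral (g/cm^3 * um); the recorded value is
    ``gain_drift * -log(I / I0)`` (flat-field normalized per scan).
    Optional Poisson counting noise with ``photons`` per ray.
    """
    density = np.asarray(density, dtype=np.float64)
    if density.ndim != 2:
        raise ValidationError("simulate_scan expects a 2D density slice")
    if density.size == 0 or density.shape[0] != density.shape[1]:
        raise ValidationError("density slice must be square and nonempty")
    if np.any(density < 0):
        raise ValidationError("negative density")
    if n_angles < 16:
        raise ValidationError("need at least 16 projection angles")

    angles = np.linspace(0.0, 360.0, n_angles, endpoint=False)
    # density line integrals in (g/cm^3 * um)
    line = radon(density, theta=angles, circle=True) * voxel_size
    coeff = ATTEN_A * spectrum.energies ** -3 + ATTEN_B  # per unit density, 1/um
    frac = np.einsum("e,dae->da",
                     spectrum.weights,
                     np.exp(-line[..., None] * coeff[None, None, :]))
    if photons is not None:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(frac * photons)
        if np.any(counts <= 0):
            raise CalciscanError("ray with zero detected photons; raise `photons`")
        frac = counts / photons
        values = np.clip(-np.log(frac), 0.0, None)
    else:
        values = -np.log(frac)
    return Sinogram(values=values * spectrum.gain_drift, angles_deg=angles,
                    detector_pitch=voxel_size, grid=density.shape[0])


def reconstruct_fbp(sino: Sinogram) -> AttenuationVolume:
    """Ramp-filtered parallel-beam back projection of one slice.

    Returns effective attenuation per um on the original grid.
    """
    if sino.n_angles < 16:
        raise ValidationError("need at least 16 projection angles")
    recon = iradon(sino.values, theta=sino.angles_deg, circle=True,
                   filter_name="ramp", output_size=sino.grid)
    return AttenuationVolume(values=recon / sino.detector_pitch,
                             voxel_size=sino.detector_pitch)


def compose_scene(phantoms: list[ShellPhantom], *, grid: int | None = None,
                  include_standard: bool = True,
                  standard_density: float | None = None,
                  margin: int = 6) -> tuple[np.ndarray, dict[str, np.ndarray], float]:
    """Place phantom central slices in a row inside one square scan field.

    Returns ``(density_slice, region_labels, voxel_size)``; labels mark the
    standard-calcite disk and an air reference disk, both inside the
    reconstruction circle and clear of the specimens.
    """
    if not phantoms:
        raise ValidationError("empty scene")
    voxel = phantoms[0].voxel_size
    if any(abs(p.voxel_size - voxel) > 1e-12 for p in phantoms):
        raise ValidationError("phantoms must share a voxel size")
    slices = []
    for p in phantoms:
        sl = p.density_volume[p.density_volume.shape[0] // 2]
        nz = np.argwhere(sl > 0)
        if nz.size == 0:  # central slice may miss the shell; take densest
            k = int(np.argmax((p.density_volume > 0).sum(axis=(1, 2))))
            sl = p.density_volume[k]
            nz = np.argwhere(sl > 0)
        r0, c0 = nz.min(axis=0)
        r1, c1 = nz.max(axis=0) + 1
        slices.append(sl[r0:r1, c0:c1])

    from calciscan.config import CALCITE_DENSITY

    std_density = standard_density if standard_density is not None else CALCITE_DENSITY
    widths = [s.shape[1] for s in slices]
    heights = [s.shape[0] for s in slices]
    row_w = sum(widths) + margin * (len(slices) - 1)
    row_h = max(heights)
    rad = 8  # reference disk radius: >= 100 voxels after one-voxel erosion
    if grid is None:
        # the specimen row must fit the reconstruction circle, and the
        # reference disks need vertical headroom above/below the row
        diag = int(np.ceil(np.hypot(row_w, row_h)))
        grid = max(diag + 2 * margin, row_h + 7 * rad)
    scene = np.zeros((grid, grid), dtype=np.float64)
    cy = cx = grid // 2
    x = (grid - row_w) // 2
    if x < 0:
        raise ValidationError("scene objects do not fit in the field of view")
    for s, h in zip(slices, heights):
        y = cy - h // 2
        scene[y:y + h, x:x + s.shape[1]] += s
        x += s.shape[1] + margin

    yy, xx = np.indices((grid, grid))
    circle = (yy - cy) ** 2 + (xx - cx) ** 2 <= (grid // 2 - 2) ** 2
    # reference disks: midway between the row edge and the circle edge
    d = ((row_h // 2 + rad + 2) + (grid // 2 - 2 - rad)) // 2
    labels: dict[str, np.ndarray] = {}
    air = (yy - (cy - d)) ** 2 + (xx - cx) ** 2 <= rad ** 2
    if np.any(scene[air] > 0) or not np.all(circle[air]):
        raise ValidationError("air reference region collides with the scene")
    labels["air"] = air
    if include_standard:
        std = (yy - (cy + d)) ** 2 + (xx - cx) ** 2 <= rad ** 2
        if np.any(scene[std] > 0) or not np.all(circle[std]):
            raise ValidationError("standard-calcite region collides with the scene")
        scene[std] = std_density
        labels["calcite_standard"] = std
    return scene, labels, voxel
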