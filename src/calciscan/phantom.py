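"""Synthetic shell phantoms with known density and wall thickness.

A phantom is a trochospiral sequence of hollow spherical chambers (three
chambers per whorl, chamber radius growing geometrically) carried on a
cubic voxel grid, optionally perforated by radial cylindrical pores.
Because the geometry is generative, the true local wall thickness is
known exactly on every shell voxel, which gives downstream thickness
estimators a ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from calciscan.config import CALCITE_DENSITY
from calciscan.errors import ResolutionError, ValidationError


@dataclass(frozen=True)
class ShellGeometry:
    """Generative parameters of a trochospiral shell phantom."""

    n_chambers: int = 5
    first_radius_um: float = 10.0
    growth_factor: float = 1.2
    wall_um: float = 4.0
    #: fraction of the sum of adjacent outer radii used as center spacing;
    #: < 1 makes consecutive chambers overlap (shared apertures).
    overlap: float = 0.75
    #: vertical rise per chamber as a fraction of the chamber radius
    #: (the "trocho" in trochospiral).
    rise: float = 0.35
    pores_per_chamber: int = 0
    pore_radius_um: float = 1.0
    density: float = CALCITE_DENSITY

    def __post_init__(self) -> None:
        if self.n_chambers < 1:
            raise ValidationError("n_chambers must be >= 1")
        if not 0 < self.density <= CALCITE_DENSITY:
            raise ValidationError(
                f"density must be in (0, {CALCITE_DENSITY}]: {self.density}")
        if self.first_radius_um <= self.wall_um:
            raise ValidationError("first_radius_um must exceed wall_um")


@dataclass
class ShellPhantom:
    """Ground-truth density field plus exact wall-thickness map."""

    density_volume: np.ndarray  # g/cm^3, 0 outside the shell
    thickness_truth: np.ndarray  # um, > 0 only on shell voxels
    voxel_size: float  # um / voxel
    geometry: ShellGeometry
    seed: int

    @property
    def shell_mask(self) -> np.ndarray:
        return self.density_volume > 0


def _chamber_centers(geom: ShellGeometry, rng: np.random.Generator):
    """Chamber centers (um, relative to origin) and outer radii (um)."""
    radii = geom.first_radius_um * geom.growth_factor ** np.arange(geom.n_chambers)
    centers = [np.zeros(3)]
    theta = rng.uniform(0, 2 * np.pi)
    for k in range(1, geom.n_chambers):
        theta += 2 * np.pi / 3  # three chambers per whorl
        step = geom.overlap * (radii[k - 1] + radii[k] - geom.wall_um)
        dz = geom.rise * radii[k]
        horiz = np.sqrt(max(step ** 2 - dz ** 2, (0.3 * step) ** 2))
        centers.append(centers[-1] +
                       np.array([dz, horiz * np.sin(theta), horiz * np.cos(theta)]))
    return np.array(centers), radii


def make_shell_phantom(geometry: ShellGeometry | None = None, *,
                       seed: int = 0, voxel_size: float = 0.8,
                       grid: int = 128) -> ShellPhantom:
    """Build a shell phantom on a ``grid**3`` voxel lattice.

    Deterministic for a fixed ``(geometry, seed, voxel_size, grid)``.
    Raises :class:`ResolutionError` when the wall spans fewer than two
    voxels, below which thickness cannot be measured.
    """
    geom = geometry or ShellGeometry()
    if geom.wall_um < 2 * voxel_size:
        raise ResolutionError(
            f"wall {geom.wall_um} um < 2 voxels at {voxel_size} um/voxel")
    rng = np.random.default_rng(seed)
    centers, radii = _chamber_centers(geom, rng)
    # center the bounding box of the chamber cluster on the grid
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    extent = hi - lo
    if np.any(extent > grid * voxel_size):
        raise ValidationError(
            f"shell extent {extent} um exceeds grid {grid * voxel_size} um")
    offset = (grid * voxel_size - extent) / 2 - lo
    centers = centers + offset

    coords = (np.indices((grid,) * 3).astype(np.float64) + 0.5) * voxel_size
    solid = np.zeros((grid,) * 3, dtype=bool)
    lumen = np.zeros((grid,) * 3, dtype=bool)
    for c, r in zip(centers, radii):
        d2 = ((coords[0] - c[0]) ** 2 + (coords[1] - c[1]) ** 2 +
              (coords[2] - c[2]) ** 2)
        solid |= d2 <= r ** 2
        lumen |= d2 <= (r - geom.wall_um) ** 2
    shell = solid & ~lumen

    if geom.pores_per_chamber > 0:
        pts = np.argwhere(shell)
        p_um = (pts + 0.5) * voxel_size
        keep = np.ones(len(pts), dtype=bool)
        for c, r in zip(centers, radii):
            for _ in range(geom.pores_per_chamber):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                rel = p_um - c
                t = rel @ d
                perp = np.linalg.norm(rel - np.outer(t, d), axis=1)
                keep &= ~((t > 0) & (perp <= geom.pore_radius_um))
        shell = np.zeros_like(shell)
        shell[tuple(pts[keep].T)] = True

    density = np.where(shell, geom.density, 0.0).astype(np.float32)
    thickness = np.where(shell, geom.wall_um, 0.0).astype(np.float32)
    return ShellPhantom(density_volume=density, thickness_truth=thickness,
                        voxel_size=voxel_size, geometry=geom, seed=seed)
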