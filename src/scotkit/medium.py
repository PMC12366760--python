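"""Optical media, voxel grids, flow perturbations and correlation curves.

Units are fixed package-wide: lengths in mm, coefficients in 1/mm, times in
seconds, diffusion coefficients in mm^2/s.  Vacuum wavelengths are given in
nm and converted once at medium construction, so that e.g. an 852 nm source
yields a wavevector k0 = 2*pi/lambda of about 7375 rad/mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: speed of light in vacuum, mm/s
C_VACUUM_MM_S = 2.99792458e11


@dataclass(frozen=True)
class OpticalMedium:
    """Static optical and dynamic properties of a homogeneous medium.

    Parameters
    ----------
    mua : float
        Absorption coefficient (1/mm), >= 0.
    musp : float
        Reduced scattering coefficient (1/mm), > 0.
    n : float
        Refractive index.  Default 1.33 (water-like tissue).
    wavelength_nm : float
        Vacuum wavelength of the source (nm).
    Db0 : float
        Baseline Brownian diffusion coefficient of the moving scatterers
        (mm^2/s); for tissue, red blood cells.
    """

    mua: float = 0.0
    musp: float = 1.0
    n: float = 1.33
    wavelength_nm: float = 800.0
    Db0: float = 1e-6

    def __post_init__(self) -> None:
        if self.mua < 0:
            raise ValueError(f"mua must be >= 0, got {self.mua}")
        if self.musp <= 0:
            raise ValueError(f"musp must be > 0, got {self.musp}")
        if self.Db0 <= 0:
            raise ValueError(f"Db0 must be > 0, got {self.Db0}")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be > 0")

    @property
    def k0(self) -> float:
        """Wavevector 2*pi/lambda in the medium's units (rad/mm)."""
        return 2.0 * np.pi / (self.wavelength_nm * 1e-6)

    @property
    def v(self) -> float:
        """Speed of light in the medium (mm/s)."""
        return C_VACUUM_MM_S / self.n

    @property
    def Dp(self) -> float:
        """Photon diffusion coefficient v/(3*musp) (mm^2/s)."""
        return self.v / (3.0 * self.musp)

    @property
    def z0(self) -> float:
        """Depth of the equivalent isotropic source, 1/musp (mm)."""
        return 1.0 / self.musp

    @property
    def zb(self) -> float:
        """Extrapolated-boundary distance (5/3)/musp (mm)."""
        return (5.0 / 3.0) / self.musp


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid in the half-space z >= 0 (z = 0 is the surface).

    Voxel centers sit at ``origin + (index + 0.5) * spacing`` with 0-based
    indices in (x, y, z) order.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive in all axes")
        if any(n <= 0 for n in self.shape):
            raise ValueError("shape must be positive in all axes")

    @classmethod
    def from_bounds(
        cls,
        lo: Sequence[float],
        hi: Sequence[float],
        voxel_mm: float | Sequence[float],
    ) -> "VoxelGrid":
        """Grid covering the box [lo, hi] with (approximately) cubic voxels."""
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        sp = np.broadcast_to(np.asarray(voxel_mm, float), (3,)).copy()
        shape = np.maximum(1, np.round((hi - lo) / sp)).astype(int)
        return cls(tuple(lo), tuple(sp), tuple(int(s) for s in shape))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        """Voxel volume (mm^3); the quadrature weight of the perturbation sum."""
        return float(np.prod(self.spacing))

    def centers(self) -> np.ndarray:
        """(N, 3) array of voxel-center coordinates, C-order over (x, y, z)."""
        axes = [
            self.origin[k] + (np.arange(self.shape[k]) + 0.5) * self.spacing[k]
            for k in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (for NIfTI export)."""
        aff = np.eye(4)
        for k in range(3):
            aff[k, k] = self.spacing[k]
            aff[k, 3] = self.origin[k] + 0.5 * self.spacing[k]
        return aff


@dataclass(frozen=True)
class BoxInclusion:
    """Axis-aligned box with a uniform relative flow value rDb."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]
    rDb: float = 1.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError("box size must be positive")
        if self.rDb <= 0:
            raise ValueError("rDb must be > 0")

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.center) - 0.5 * np.asarray(self.size)

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.center) + 0.5 * np.asarray(self.size)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (N, 3) whose coordinates fall in the box."""
        pts = np.atleast_2d(points)
        return np.all((pts >= self.lo) & (pts < self.hi), axis=1)

    def clipped_to_halfspace(self) -> "BoxInclusion":
        """Truncate the box at the surface z = 0 if it protrudes."""
        lo, hi = self.lo.copy(), self.hi
        if lo[2] >= 0:
            return self
        lo[2] = 0.0
        c = 0.5 * (lo + hi)
        return BoxInclusion(tuple(c), tuple(hi - lo), self.rDb)

    def overlaps(self, other: "BoxInclusion") -> bool:
        return bool(np.all(self.lo < other.hi) and np.all(other.lo < self.hi))


@dataclass
class FlowPerturbation:
    """Per-voxel relative Brownian diffusion coefficient rDb on a grid.

    rDb = 1 is baseline; the perturbation entering the forward model is
    Delta_Db(r') = (rDb(r') - 1) * Db0.
    """

    grid: VoxelGrid
    rDb: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rDb is None:
            self.rDb = np.ones(self.grid.n_voxels)
        self.rDb = np.asarray(self.rDb, float).ravel()
        if self.rDb.size != self.grid.n_voxels:
            raise ValueError("rDb size does not match grid voxel count")
        if np.any(self.rDb <= 0):
            raise ValueError("rDb must be > 0 everywhere")

    @classmethod
    def from_boxes(
        cls,
        grid: VoxelGrid,
        boxes: Sequence[BoxInclusion],
        background: float = 1.0,
    ) -> "FlowPerturbation":
        """Compile box inclusions onto the grid (later boxes overwrite)."""
        rdb = np.full(grid.n_voxels, background)
        pts = grid.centers()
        for box in boxes:
            rdb[box.contains(pts)] = box.rDb
        return cls(grid, rdb)

    def delta_Db(self, Db0: float) -> np.ndarray:
        """Per-voxel absolute perturbation (rDb - 1) * Db0 (mm^2/s)."""
        return (self.rDb - 1.0) * Db0


@dataclass
class CorrelationCurve:
    """Field autocorrelation G1 (or normalized g1) on a lag-time grid."""

    tau: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, float).ravel()
        self.values = np.asarray(self.values, float).ravel()
        if self.tau.size != self.values.size:
            raise ValueError("tau and values must have equal length")
        if self.tau.size < 2 or self.tau[0] != 0.0:
            raise ValueError("tau grid must start at 0 and have >= 2 points")
        if np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau grid must be strictly increasing")

    def normalized(self) -> "CorrelationCurve":
        """g1(tau) = G1(tau)/G1(0)."""
        return CorrelationCurve(self.tau, self.values / self.values[0])

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"tau_s": self.tau, "g1": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrelationCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["tau_s"].to_numpy(), df["g1"].to_numpy())

    def to_hdf5(self, group) -> None:
        """Write tau/values datasets into an open h5py group."""
        group.create_dataset("tau_s", data=self.tau)
        group.create_dataset("g1", data=self.values)
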