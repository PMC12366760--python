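"""Momentum-transfer photon Monte Carlo: the ground-truth g1 oracle.

Photons are launched as a collimated beam normally incident on a
semi-infinite medium and random-walked with isotropic scattering at the
reduced scattering coefficient (similarity relation: g = 0, mus = musp).
For each photon re-emitted into a detector annulus we record its total
pathlength L and accumulated dimensionless momentum transfer
Y = sum q^2/(2 k0^2) = sum (1 - cos theta), optionally restricted to tagged
box regions.  The field autocorrelation then follows as

    g1(tau) = C/Np * sum_n exp(-(1/3) Y_n k0^2 <dr^2(tau)>) * exp(-mua L_n)

with <dr^2(tau)> = 6 Db tau, and per-region flow perturbations applied
through the region-restricted momentum transfer of each photon.  Absorption
enters only through the exp(-mua L) weights at analysis time, so one run is
reusable across mua values.

A second, fluence-based mode turns a static MC into a G1(tau) solver on a
voxelized heterogeneous medium by replacing absorption with the effective
absorption mua_eff = mua + 2*alpha*musp*k0^2*Db*tau, one run per tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .medium import BoxInclusion, CorrelationCurve, OpticalMedium, VoxelGrid

__all__ = [
    "McRun",
    "FluenceResult",
    "simulate_histories",
    "g1_from_histories",
    "fluence_effective_absorption",
    "VoxelMedium",
]

# termination guards for the random walk; photons travelling this deep or
# this far are fully decorrelated at any lag of interest and cannot return
# to a ~30 mm detector with non-negligible weight
_MAX_DEPTH_FACTOR = 4.0  # times rho, min 100 mm
_MAX_STEPS = 200_000


@dataclass
class McRun:
    """Detected-photon histories of one seeded simulation."""

    L: np.ndarray            # total pathlength per detected photon (mm)
    Y: np.ndarray            # total dimensionless momentum transfer
    Y_region: np.ndarray     # (Np, n_regions) per-region momentum transfer
    exit_radius: np.ndarray  # radial exit coordinate on z=0 (mm)
    n_photons: int
    rho: float
    annulus_halfwidth: float
    seed: int
    medium: OpticalMedium
    regions: tuple[BoxInclusion, ...] = ()

    @property
    def n_detected(self) -> int:
        return int(self.L.size)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("L_mm", data=self.L)
            f.create_dataset("Y", data=self.Y)
            f.create_dataset("Y_region", data=self.Y_region)
            f.create_dataset("exit_radius_mm", data=self.exit_radius)
            f.attrs["n_photons"] = self.n_photons
            f.attrs["rho_mm"] = self.rho
            f.attrs["annulus_halfwidth_mm"] = self.annulus_halfwidth
            f.attrs["seed"] = self.seed
            for k in ("mua", "musp", "n", "wavelength_nm", "Db0"):
                f.attrs[f"medium_{k}"] = getattr(self.medium, k)
            f.attrs["region_lo"] = np.array([r.lo for r in self.regions]).reshape(-1, 3)
            f.attrs["region_hi"] = np.array([r.hi for r in self.regions]).reshape(-1, 3)

    @classmethod
    def from_hdf5(cls, path) -> "McRun":
        import h5py

        with h5py.File(path, "r") as f:
            med = OpticalMedium(
                mua=float(f.attrs["medium_mua"]),
                musp=float(f.attrs["medium_musp"]),
                n=float(f.attrs["medium_n"]),
                wavelength_nm=float(f.attrs["medium_wavelength_nm"]),
                Db0=float(f.attrs["medium_Db0"]),
            )
            lo = np.asarray(f.attrs["region_lo"]).reshape(-1, 3)
            hi = np.asarray(f.attrs["region_hi"]).reshape(-1, 3)
            regions = tuple(
                BoxInclusion(tuple((l + h) / 2), tuple(h - l)) for l, h in zip(lo, hi)
            )
            return cls(
                L=f["L_mm"][:],
                Y=f["Y"][:],
                Y_region=f["Y_region"][:],
                exit_radius=f["exit_radius_mm"][:],
                n_photons=int(f.attrs["n_photons"]),
                rho=float(f.attrs["rho_mm"]),
                annulus_halfwidth=float(f.attrs["annulus_halfwidth_mm"]),
                seed=int(f.attrs["seed"]),
                medium=med,
                regions=regions,
            )


@njit(cache=True)
def _walk_photons(
    n_photons: int,
    musp: float,
    rho_min: float,
    rho_max: float,
    region_lo: np.ndarray,
    region_hi: np.ndarray,
    max_depth: float,
    max_steps: int,
    seed: int,
    n_rel: float,
):  # pragma: no cover - exercised through simulate_histories
    np.random.seed(seed)
    # unpolarized Fresnel reflection at the z=0 interface (n_rel = n_in/n_out);
    # n_rel = 1 recovers an index-matched (fully transparent) boundary
    sin2_crit = (1.0 / n_rel) ** 2 if n_rel > 1.0 else 2.0
    n_regions = region_lo.shape[0]
    cap = 4096
    out_L = np.empty(cap)
    out_Y = np.empty(cap)
    out_Yr = np.empty((cap, n_regions))
    out_r = np.empty(cap)
    ndet = 0
    mfp = 1.0 / musp
    # per-photon scattering-event buffer: the detector is an annulus around
    # the source, so each detected path is rotated about z to put its exit
    # at azimuth 0 (the nominal detector direction) before region tallying.
    # Valid because the baseline medium is azimuthally symmetric; without
    # the rotation an asymmetric region's momentum transfer would be
    # averaged over all exit azimuths and badly diluted.
    ev_x = np.empty(max_steps)
    ev_y = np.empty(max_steps)
    ev_z = np.empty(max_steps)
    ev_q = np.empty(max_steps)
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        L = 0.0
        Y = 0.0
        n_ev = 0
        for _step in range(max_steps):
            s = -np.log(np.random.random()) * mfp
            nz = z + uz * s
            if nz < 0.0:
                # photon reaches the surface: Fresnel-reflect or transmit
                t = -z / uz
                xe = x + ux * t
                ye = y + uy * t
                L += t
                if n_rel > 1.0:
                    ci = -uz  # cosine of the angle of incidence
                    si2 = 1.0 - ci * ci
                    if si2 >= sin2_crit:
                        refl = 1.0  # total internal reflection
                    else:
                        st2 = n_rel * n_rel * si2
                        ct = np.sqrt(1.0 - st2)
                        rs_ = (n_rel * ci - ct) / (n_rel * ci + ct)
                        rp_ = (n_rel * ct - ci) / (n_rel * ct + ci)
                        refl = 0.5 * (rs_ * rs_ + rp_ * rp_)
                    if np.random.random() < refl:
                        x = xe
                        y = ye
                        z = 0.0
                        uz = -uz
                        # free paths are memoryless: draw afresh next step
                        continue
                r = np.sqrt(xe * xe + ye * ye)
                if rho_min <= r <= rho_max:
                    if ndet == cap:
                        cap *= 2
                        tmp = np.empty(cap)
                        tmp[:ndet] = out_L
                        out_L = tmp
                        tmp = np.empty(cap)
                        tmp[:ndet] = out_Y
                        out_Y = tmp
                        tmp2 = np.empty((cap, n_regions))
                        tmp2[:ndet] = out_Yr
                        out_Yr = tmp2
                        tmp = np.empty(cap)
                        tmp[:ndet] = out_r
                        out_r = tmp
                    cpsi = xe / r
                    spsi = ye / r
                    for k in range(n_regions):
                        out_Yr[ndet, k] = 0.0
                    for m in range(n_ev):
                        rx = ev_x[m] * cpsi + ev_y[m] * spsi
                        ry = -ev_x[m] * spsi + ev_y[m] * cpsi
                        rz = ev_z[m]
                        for k in range(n_regions):
                            if (
                                region_lo[k, 0] <= rx < region_hi[k, 0]
                                and region_lo[k, 1] <= ry < region_hi[k, 1]
                                and region_lo[k, 2] <= rz < region_hi[k, 2]
                            ):
                                out_Yr[ndet, k] += ev_q[m]
                    out_L[ndet] = L
                    out_Y[ndet] = Y
                    out_r[ndet] = r
                    ndet += 1
                break
            x += ux * s
            y += uy * s
            z = nz
            L += s
            if z > max_depth:
                break
            # isotropic scattering: new direction uniform on the sphere
            cz = 2.0 * np.random.random() - 1.0
            phi = 2.0 * np.pi * np.random.random()
            sz = np.sqrt(1.0 - cz * cz)
            nux = sz * np.cos(phi)
            nuy = sz * np.sin(phi)
            nuz = cz
            dmt = 1.0 - (ux * nux + uy * nuy + uz * nuz)  # q^2/(2 k0^2)
            Y += dmt
            if n_regions > 0:
                ev_x[n_ev] = x
                ev_y[n_ev] = y
                ev_z[n_ev] = z
                ev_q[n_ev] = dmt
                n_ev += 1
            ux = nux
            uy = nuy
            uz = nuz
    return out_L[:ndet], out_Y[:ndet], out_Yr[:ndet], out_r[:ndet]


def simulate_histories(
    medium: OpticalMedium,
    regions: Sequence[BoxInclusion] = (),
    rho: float = 30.0,
    n_photons: int = 1_000_000,
    seed: int = 0,
    annulus_halfwidth: float = 0.5,
    n_external: float = 1.0,
) -> McRun:
    """Random-walk ``n_photons`` and collect detected-photon histories.

    The detector is an annulus of half-width ``annulus_halfwidth`` (mm)
    centered at radius ``rho`` on the surface z = 0; all exit angles are
    accepted.  The boundary applies unpolarized Fresnel reflection for the
    index step from ``medium.n`` to ``n_external`` (default air), which is
    the physical counterpart of the extrapolated-boundary distance
    zb = (5/3)/musp used by the analytic model at n = 1.33; passing
    ``n_external = medium.n`` gives a transparent, index-matched boundary.
    A transmitted photon is terminated whether or not it hits the annulus.
    Identical arguments and seed produce bit-identical history sets.
    """
    if n_photons <= 0:
        raise ValueError("n_photons must be positive")
    lo = np.array([r.lo for r in regions], float).reshape(-1, 3)
    hi = np.array([r.hi for r in regions], float).reshape(-1, 3)
    max_depth = max(100.0, _MAX_DEPTH_FACTOR * rho)
    L, Y, Yr, r = _walk_photons(
        int(n_photons),
        medium.musp,
        rho - annulus_halfwidth,
        rho + annulus_halfwidth,
        lo,
        hi,
        max_depth,
        _MAX_STEPS,
        int(seed) & 0x7FFFFFFF,
        medium.n / n_external,
    )
    if L.size == 0:
        raise RuntimeError(
            f"no photons detected at rho={rho} mm with n_photons={n_photons}"
        )
    return McRun(
        L=L,
        Y=Y,
        Y_region=Yr,
        exit_radius=r,
        n_photons=int(n_photons),
        rho=float(rho),
        annulus_halfwidth=float(annulus_halfwidth),
        seed=int(seed),
        medium=medium,
        regions=tuple(regions),
    )


def g1_from_histories(
    run: McRun,
    tau: np.ndarray,
    region_rdb: Sequence[float] | None = None,
    Db0: float | None = None,
    mua: float | None = None,
    return_sem: bool = False,
) -> CorrelationCurve | tuple[CorrelationCurve, np.ndarray]:
    """History-based g1(tau), optionally with per-region flow perturbations.

    Each detected photon contributes exp(-2 k0^2 tau * [Y_n Db0 +
    sum_r Y_{n,r} (rDb_r - 1) Db0]) weighted by exp(-mua L_n); the curve is
    normalized so g1(0) = 1 (the weights are part of the normalization).
    ``return_sem`` additionally yields the per-tau standard error of the
    normalized estimate (delta method for the weighted mean).
    """
    tau = np.asarray(tau, float)
    if tau[0] != 0.0:
        raise ValueError("tau grid must include 0")
    Db0 = run.medium.Db0 if Db0 is None else Db0
    mua = run.medium.mua if mua is None else mua
    k0 = run.medium.k0
    eff_Y_Db = run.Y * Db0
    if region_rdb is not None:
        region_rdb = np.asarray(region_rdb, float)
        if region_rdb.size != run.Y_region.shape[1]:
            raise ValueError(
                f"{region_rdb.size} rDb values for {run.Y_region.shape[1]} tagged regions"
            )
        eff_Y_Db = eff_Y_Db + run.Y_region @ ((region_rdb - 1.0) * Db0)
    w = np.exp(-mua * run.L)
    wsum = w.sum()
    # chunk over photons to bound the (Np, ntau) intermediate
    g1 = np.zeros(tau.size)
    sq = np.zeros(tau.size)
    step = max(1, int(4e6 // max(tau.size, 1)))
    for i in range(0, run.n_detected, step):
        decay = np.exp(-2.0 * k0**2 * np.outer(eff_Y_Db[i : i + step], tau))
        contrib = w[i : i + step, None] * decay
        g1 += contrib.sum(axis=0)
        sq += (contrib**2).sum(axis=0)
    g1 /= wsum
    curve = CorrelationCurve(tau, g1)
    if not return_sem:
        return curve
    # SEM of the self-normalized estimator: var of (w*decay - g1*w)/sum(w)
    sem = np.sqrt(np.maximum(sq / wsum**2 - g1**2 * np.sum(w**2) / wsum**2, 0.0))
    return curve, sem


# ---------------------------------------------------------------------------
# effective-absorption fluence mode
# ---------------------------------------------------------------------------


@dataclass
class VoxelMedium:
    """Voxelized optical/dynamic properties for the fluence solver.

    Per-voxel arrays on ``grid`` (x, y, z index order): absorption ``mua``
    (1/mm), reduced scattering ``musp`` (1/mm) and the dynamic product
    ``alphaDb`` (mm^2/s) of the dynamic-scatterer fraction alpha with the
    Brownian coefficient Db, as tabulated for head-tissue layers.
    """

    grid: VoxelGrid
    mua: np.ndarray
    musp: np.ndarray
    alphaDb: np.ndarray
    wavelength_nm: float = 852.0
    n: float = 1.33

    def __post_init__(self) -> None:
        shape = self.grid.shape
        for name in ("mua", "musp", "alphaDb"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != grid shape {shape}")
            setattr(self, name, arr)

    @property
    def k0(self) -> float:
        return 2.0 * np.pi / (self.wavelength_nm * 1e-6)

    @classmethod
    def homogeneous(
        cls, grid: VoxelGrid, medium: OpticalMedium, alphaDb: float | None = None
    ) -> "VoxelMedium":
        alphaDb = medium.Db0 if alphaDb is None else alphaDb
        full = np.full(grid.shape, 1.0)
        return cls(
            grid,
            medium.mua * full,
            medium.musp * full,
            alphaDb * full,
            wavelength_nm=medium.wavelength_nm,
            n=medium.n,
        )

    @classmethod
    def layered(
        cls,
        grid: VoxelGrid,
        layers: Sequence[tuple[float, float, float, float]],
        wavelength_nm: float = 852.0,
        n: float = 1.33,
    ) -> "VoxelMedium":
        """Stack of z-layers given as (thickness_mm, mua, musp, alphaDb).

        The last layer is extended to the bottom of the grid.
        """
        mua = np.empty(grid.shape)
        musp = np.empty(grid.shape)
        adb = np.empty(grid.shape)
        zc = grid.origin[2] + (np.arange(grid.shape[2]) + 0.5) * grid.spacing[2]
        ztop = grid.origin[2]
        for i, (thick, a, sp, d) in enumerate(layers):
            zbot = np.inf if i == len(layers) - 1 else ztop + thick
            sel = (zc >= ztop) & (zc < zbot)
            mua[:, :, sel] = a
            musp[:, :, sel] = sp
            adb[:, :, sel] = d
            ztop = zbot
        return cls(grid, mua, musp, adb, wavelength_nm=wavelength_nm, n=n)


@dataclass
class FluenceResult:
    """Per-tau fluence volumes proportional to G1(rs, r', tau)."""

    grid: VoxelGrid
    tau: np.ndarray
    volumes: np.ndarray  # (ntau, nx, ny, nz)
    source: tuple[float, float, float]
    n_photons: int
    seed: int

    def g1_at(self, index: tuple[int, int, int]) -> CorrelationCurve:
        """Normalized autocorrelation at one voxel (ratio to tau = 0)."""
        vals = self.volumes[(slice(None),) + tuple(index)]
        if vals[0] <= 0:
            raise ValueError(f"no fluence recorded at voxel {index}")
        return CorrelationCurve(self.tau, vals / vals[0])

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("tau_s", data=self.tau)
            f.create_dataset("fluence", data=self.volumes)
            f.attrs["source_mm"] = np.asarray(self.source)
            f.attrs["n_photons"] = self.n_photons
            f.attrs["seed"] = self.seed
            f.attrs["grid_origin"] = np.asarray(self.grid.origin)
            f.attrs["grid_spacing"] = np.asarray(self.grid.spacing)


def effective_mua(vmedium: "VoxelMedium", tau: float) -> np.ndarray:
    """Effective absorption mua + 2*alpha*musp*k0^2*Db*tau per voxel (1/mm)."""
    return vmedium.mua + 2.0 * vmedium.musp * vmedium.k0**2 * vmedium.alphaDb * tau


@njit(cache=True)
def _fluence_kernel(
    n_photons: int,
    mua_eff: np.ndarray,
    musp: np.ndarray,
    origin: np.ndarray,
    spacing: np.ndarray,
    sx: float,
    sy: float,
    seed: int,
):  # pragma: no cover - exercised through fluence_effective_absorption
    np.random.seed(seed)
    nx, ny, nz = mua_eff.shape
    flu = np.zeros((nx, ny, nz))
    # Woodcock (delta-collision) tracking with a global majorant
    mut_max = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                m = mua_eff[i, j, k] + musp[i, j, k]
                if m > mut_max:
                    mut_max = m
    if mut_max <= 0.0:
        return flu
    inv_mut = 1.0 / mut_max
    for _ in range(n_photons):
        x = sx
        y = sy
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        for _step in range(100_000):
            s = -np.log(np.random.random()) * inv_mut
            x += ux * s
            y += uy * s
            z += uz * s
            i = int((x - origin[0]) / spacing[0])
            j = int((y - origin[1]) / spacing[1])
            k = int((z - origin[2]) / spacing[2])
            if z < 0.0 or i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                break
            # track-length/collision estimator: every (real or virtual)
            # collision deposits w/mut_max, an unbiased fluence tally
            flu[i, j, k] += w * inv_mut
            mut = mua_eff[i, j, k] + musp[i, j, k]
            if np.random.random() < mut * inv_mut:
                # real collision: survive with the scattering albedo
                w *= musp[i, j, k] / mut
                if w < 1e-4:
                    if np.random.random() < 0.1:
                        w *= 10.0
                    else:
                        break
                cz = 2.0 * np.random.random() - 1.0
                phi = 2.0 * np.pi * np.random.random()
                szn = np.sqrt(1.0 - cz * cz)
                ux = szn * np.cos(phi)
                uy = szn * np.sin(phi)
                uz = cz
    return flu


def fluence_effective_absorption(
    vmedium: VoxelMedium,
    source: Sequence[float],
    tau: np.ndarray,
    n_photons: int = 100_000,
    seed: int = 0,
) -> FluenceResult:
    """Voxel fluence volumes proportional to G1(rs, r', tau), one MC per tau.

    At each lag the absorption is replaced by the effective absorption
    mua_eff = mua + 2*alpha*musp*k0^2*Db*tau (with alpha*Db the tabulated
    product), so the static fluence of run #i is the unnormalized field
    autocorrelation at tau_i; at tau = 0 it is the ordinary fluence.  Lags
    large enough to extinguish the fluence yield zero voxels, not NaN.
    """
    tau = np.asarray(tau, float)
    src = np.asarray(source, float)
    if abs(src[2]) > 1e-9:
        raise ValueError("source must lie on the surface z = 0")
    k0 = vmedium.k0
    vols = np.empty((tau.size,) + vmedium.grid.shape)
    origin = np.asarray(vmedium.grid.origin)
    spacing = np.asarray(vmedium.grid.spacing)
    voxvol = vmedium.grid.voxel_volume
    for i, t in enumerate(tau):
        mua_eff = effective_mua(vmedium, t)
        vols[i] = _fluence_kernel(
            int(n_photons),
            mua_eff,
            vmedium.musp,
            origin,
            spacing,
            float(src[0]),
            float(src[1]),
            (int(seed) + i) & 0x7FFFFFFF,
        ) / (n_photons * voxvol)
    return FluenceResult(
        grid=vmedium.grid,
        tau=tau,
        volumes=vols,
        source=tuple(src),
        n_photons=int(n_photons),
        seed=int(seed),
    )
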