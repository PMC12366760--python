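"""Linearity validation experiments for the SCOT forward and inverse models.

Three experiments probe where the linear model breaks down:

1. *Inclusion sweep* — a single box inclusion (small 10x10x10 mm^3 or large
   60x50x40 mm^3) under a 30 mm channel; the relative flow change rDb - 1
   is swept and each method's signal is compared against a through-origin
   linear fit of its small-signal regime (rDb - 1 <= 0.1).
2. *Spatial linearity* — two adjacent 30x50x40 mm^3 regions perturbed
   individually and together; the sum of the individual signals is compared
   against the joint signal (no fit involved).
3. *Reconstruction linearity* — forward signals on the 50-channel
   hexagonal probe are inverted with Tikhonov regularization and the
   region-averaged reconstruction is compared against the true value.

Deviations greater than 5% are considered significant throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import cde, speckle
from .medium import BoxInclusion, FlowPerturbation, OpticalMedium, VoxelGrid
from .probe import Probe, build_hex_probe
from .recon import build_sensitivity, region_average, tikhonov_invert

log = logging.getLogger(__name__)

#: medium of the semi-infinite phantom experiments
PHANTOM_MEDIUM = OpticalMedium(mua=0.0, musp=1.0, n=1.33, wavelength_nm=800.0, Db0=1e-6)
PHANTOM_TEXP = 2e-3
PHANTOM_RHO = 30.0

#: box geometries (centers interpret the channel as source at the origin,
#: detector at (30, 0, 0); the inclusion center sits on the midpoint plane)
GEOMETRIES = {
    "small": BoxInclusion((15.0, 0.0, 30.0), (10.0, 10.0, 10.0)),
    "large": BoxInclusion((15.0, 0.0, 30.0), (60.0, 50.0, 40.0)),
}

SMALL_SIGNAL_MAX = 0.1


def default_rdb_grid() -> np.ndarray:
    """rDb - 1 swept over (0, 1] in steps of 0.02."""
    return np.round(np.arange(0.02, 1.0001, 0.02), 10)


def linear_fit_through_origin(x: np.ndarray, y: np.ndarray) -> float:
    """OLS slope of a through-origin line (zero signal at zero change)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return float(np.sum(x * y) / np.sum(x * x))


def small_signal_slope(
    rdb_grid: np.ndarray, signals: np.ndarray, s_max: float = SMALL_SIGNAL_MAX
) -> float:
    m = rdb_grid <= s_max * (1 + 1e-9)
    if not m.any():
        raise ValueError(f"no grid points at or below {s_max}")
    return linear_fit_through_origin(rdb_grid[m], signals[m])


@dataclass
class LinearitySweep:
    """Signals and percent errors of one linearity experiment."""

    rdb_grid: np.ndarray
    signals: dict[str, np.ndarray]
    slopes: dict[str, float] = field(default_factory=dict)
    percent_error: dict[str, np.ndarray] = field(default_factory=dict)
    signal_kind: str = "inv_contrast"

    def to_frame(self):
        import pandas as pd

        data = {"rdb_minus_1": self.rdb_grid}
        for k, v in self.signals.items():
            data[f"signal_{k}"] = v
        for k, v in self.percent_error.items():
            data[f"pct_error_{k}"] = v
        return pd.DataFrame(data)


def threshold_detect(
    rdb_grid: np.ndarray, percent_error: np.ndarray, tolerance_pct: float = 5.0
) -> float | None:
    """Smallest rDb - 1 at which |percent error| exceeds the tolerance.

    Linear interpolation of |error| between the bracketing grid points;
    ``None`` if the tolerance is never exceeded.
    """
    rdb_grid = np.asarray(rdb_grid, float)
    percent_error = np.asarray(percent_error, float)
    if rdb_grid.size == 0:
        raise ValueError("empty sweep")
    if np.any(np.diff(rdb_grid) <= 0):
        raise ValueError("rdb grid must be strictly increasing")
    err = np.abs(percent_error)
    above = np.nonzero(err > tolerance_pct)[0]
    if above.size == 0:
        return None
    i = above[0]
    if i == 0:
        return float(rdb_grid[0])
    x0, x1 = rdb_grid[i - 1], rdb_grid[i]
    y0, y1 = err[i - 1], err[i]
    return float(x0 + (tolerance_pct - y0) / (y1 - y0) * (x1 - x0))


def _phi_unit(
    medium: OpticalMedium,
    boxes: list[BoxInclusion],
    tau: np.ndarray,
    voxel_mm: float = 1.0,
) -> np.ndarray:
    """Phi_s(tau) for rDb - 1 = 1 in the union of boxes (scales linearly)."""
    boxes = [b.clipped_to_halfspace() for b in boxes]
    lo = np.min([b.lo for b in boxes], axis=0)
    hi = np.max([b.hi for b in boxes], axis=0)
    grid = VoxelGrid.from_bounds(lo, hi, voxel_mm)
    pert = FlowPerturbation.from_boxes(
        grid, [BoxInclusion(b.center, b.size, 2.0) for b in boxes]
    )
    rs = np.array([0.0, 0.0, 0.0])
    rd = np.array([PHANTOM_RHO, 0.0, 0.0])
    return cde.phi_s(medium, pert, rs, rd, tau)


def _analytic_signals(
    phi_unit: np.ndarray,
    g10: np.ndarray,
    tau: np.ndarray,
    rdb_grid: np.ndarray,
    method: str,
    signal_kind: str,
    Texp: float,
    beta: float = 1.0,
) -> np.ndarray:
    phis = rdb_grid[:, None] * phi_unit[None, :]
    if method == "born":
        g1p = g10 * (1.0 + phis)
    elif method == "rytov":
        g1p = g10 * np.exp(phis)
    else:
        raise ValueError(f"unknown analytic method {method!r}")
    return speckle.signals_from_g1_matrix(tau, g10, g1p, Texp, beta, signal_kind)


def _mc_signals(run, tau, rdb_grid, region_index, signal_kind, Texp):
    from . import montecarlo as mc

    g0 = mc.g1_from_histories(run, tau)
    K20 = speckle.contrast_from_g1(g0, Texp).K2
    n_regions = run.Y_region.shape[1]
    out = np.empty(rdb_grid.size)
    for i, s in enumerate(rdb_grid):
        rdb = np.ones(n_regions)
        rdb[region_index] = 1.0 + s
        g1p = mc.g1_from_histories(run, tau, region_rdb=rdb)
        K2 = speckle.contrast_from_g1(g1p, Texp).K2
        out[i] = K20 / K2 - 1.0 if signal_kind == "inv_contrast" else K2 / K20 - 1.0
    return out


def run_inclusion_sweep(
    geometry: str = "large",
    methods: tuple[str, ...] = ("born", "rytov"),
    rdb_grid: np.ndarray | None = None,
    signal_kind: str = "inv_contrast",
    medium: OpticalMedium = PHANTOM_MEDIUM,
    Texp: float = PHANTOM_TEXP,
    voxel_mm: float = 1.0,
    mc_photons: int = 1_000_000,
    seed: int = 0,
) -> LinearitySweep:
    """Single-inclusion linearity sweep (the first validation experiment).

    ``geometry`` is 'small' (10x10x10 mm^3) or 'large' (60x50x40 mm^3), both
    centered at 30 mm depth on the channel midpoint plane.  Methods 'born'
    and 'rytov' are deterministic; 'mc' re-weights a seeded history set.
    """
    if geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}; expected {set(GEOMETRIES)}")
    box = GEOMETRIES[geometry]
    if rdb_grid is None:
        rdb_grid = default_rdb_grid()
    tau = speckle.default_tau_grid(Texp)
    g10 = cde.baseline_curve(medium, PHANTOM_RHO, tau).normalized().values
    phi1 = _phi_unit(medium, [box], tau, voxel_mm)
    sweep = LinearitySweep(rdb_grid, {}, signal_kind=signal_kind)
    for method in methods:
        if method in ("born", "rytov"):
            sig = _analytic_signals(
                phi1, g10, tau, rdb_grid, method, signal_kind, Texp
            )
        elif method == "mc":
            from . import montecarlo as mc

            run = mc.simulate_histories(
                medium, regions=[box], rho=PHANTOM_RHO, n_photons=mc_photons, seed=seed
            )
            sig = _mc_signals(run, tau, rdb_grid, 0, signal_kind, Texp)
        else:
            raise ValueError(f"unknown method {method!r}")
        slope = small_signal_slope(rdb_grid, sig)
        sweep.signals[method] = sig
        sweep.slopes[method] = slope
        sweep.percent_error[method] = (sig - slope * rdb_grid) / (slope * rdb_grid) * 100.0
    return sweep


#: the two adjacent spatial-linearity regions: halves of the large box,
#: tops 10 mm below the surface, splitting at the channel midpoint plane
SPATIAL_R1 = BoxInclusion((0.0, 0.0, 30.0), (30.0, 50.0, 40.0))
SPATIAL_R2 = BoxInclusion((30.0, 0.0, 30.0), (30.0, 50.0, 40.0))


def run_spatial_linearity(
    R1: BoxInclusion = SPATIAL_R1,
    R2: BoxInclusion = SPATIAL_R2,
    methods: tuple[str, ...] = ("born", "rytov"),
    rdb_grid: np.ndarray | None = None,
    signal_kind: str = "inv_contrast",
    medium: OpticalMedium = PHANTOM_MEDIUM,
    Texp: float = PHANTOM_TEXP,
    voxel_mm: float = 1.0,
    mc_photons: int = 1_000_000,
    seed: int = 0,
) -> dict[str, LinearitySweep]:
    """Spatial linearity: signal(R1) + signal(R2) versus signal(R1 and R2).

    Returns one sweep per method with signal curves 'R1', 'R2', 'sum',
    'both' and the sum-versus-both percent error under key 'sum_vs_both'.
    """
    if R1.overlaps(R2):
        raise ValueError("spatial-linearity regions must be disjoint")
    if rdb_grid is None:
        rdb_grid = default_rdb_grid()
    tau = speckle.default_tau_grid(Texp)
    g10 = cde.baseline_curve(medium, PHANTOM_RHO, tau).normalized().values
    out: dict[str, LinearitySweep] = {}
    phis = {}
    needs_analytic = any(m in ("born", "rytov") for m in methods)
    if needs_analytic:
        phis["R1"] = _phi_unit(medium, [R1], tau, voxel_mm)
        phis["R2"] = _phi_unit(medium, [R2], tau, voxel_mm)
        phis["both"] = phis["R1"] + phis["R2"]  # exact additivity of Phi_s
    mc_run = None
    if "mc" in methods:
        from . import montecarlo as mc

        mc_run = mc.simulate_histories(
            medium, regions=[R1, R2], rho=PHANTOM_RHO, n_photons=mc_photons, seed=seed
        )
    for method in methods:
        sweep = LinearitySweep(rdb_grid, {}, signal_kind=signal_kind)
        if method in ("born", "rytov"):
            for key in ("R1", "R2", "both"):
                sweep.signals[key] = _analytic_signals(
                    phis[key], g10, tau, rdb_grid, method, signal_kind, Texp
                )
        elif method == "mc":
            from . import montecarlo as mc

            g0 = mc.g1_from_histories(mc_run, tau)
            K20 = speckle.contrast_from_g1(g0, Texp).K2
            for key, rdbsel in (("R1", [1, 0]), ("R2", [0, 1]), ("both", [1, 1])):
                sig = np.empty(rdb_grid.size)
                for i, s in enumerate(rdb_grid):
                    rdb = 1.0 + s * np.asarray(rdbsel, float)
                    g1p = mc.g1_from_histories(mc_run, tau, region_rdb=rdb)
                    K2 = speckle.contrast_from_g1(g1p, Texp).K2
                    sig[i] = (
                        K20 / K2 - 1.0 if signal_kind == "inv_contrast" else K2 / K20 - 1.0
                    )
                sweep.signals[key] = sig
        else:
            raise ValueError(f"unknown method {method!r}")
        sweep.signals["sum"] = sweep.signals["R1"] + sweep.signals["R2"]
        sweep.percent_error["sum_vs_both"] = (
            (sweep.signals["sum"] - sweep.signals["both"])
            / sweep.signals["both"]
            * 100.0
        )
        out[method] = sweep
    return out


#: reconstruction-experiment geometry: inclusion 40x40x40 mm^3, top 10 mm
#: below the surface at (x, y) = (40, 40) mm — the probe is centered on the
#: same axis (probe coordinates run from 0 to 80 mm across the footprint)
RECON_INCLUSION = BoxInclusion((40.0, 40.0, 30.0), (40.0, 40.0, 40.0))


def recon_rdb_grid() -> np.ndarray:
    """True rDb - 1 values: dense over (0, 1], log-extended to ~19."""
    lin = np.round(np.arange(0.1, 1.0001, 0.1), 10)
    ext = np.geomspace(1.3, 19.0, 12)
    return np.unique(np.concatenate([lin, ext]))


def run_reconstruction_linearity(
    probe: Probe | None = None,
    inclusion: BoxInclusion = RECON_INCLUSION,
    rdb_grid: np.ndarray | None = None,
    medium: OpticalMedium = PHANTOM_MEDIUM,
    Texp: float = PHANTOM_TEXP,
    alpha: float = 1e-3,
    recon_voxel_mm: float = 4.0,
    forward_voxel_mm: float = 2.0,
    grid_margin_mm: float = 24.0,
) -> dict:
    """Reconstructed versus true rDb - 1 with the hexagonal probe.

    Forward channel signals are generated with the Rytov model for the
    true inclusion (voxelized at ``forward_voxel_mm``), the sensitivity
    matrix is assembled on a coarser grid (``recon_voxel_mm``) covering the
    probe and inclusion, and each sweep point is inverted with Tikhonov
    regularization; the reconstruction is averaged over the inclusion box.
    Returns the sweep values plus the through-origin fit of the [0, 1]
    regime and the 5% departure threshold.
    """
    if probe is None:
        # center the array over the inclusion axis
        probe = build_hex_probe().translated((40.0, 40.0, 0.0))
    if rdb_grid is None:
        rdb_grid = recon_rdb_grid()
    tau = speckle.default_tau_grid(Texp)
    # reconstruction grid covering probe footprint and inclusion
    opt = np.array(
        [p for p in probe.sources.values()] + [p for p in probe.detectors.values()]
    )
    lo = np.minimum(opt.min(axis=0), inclusion.lo) - grid_margin_mm
    hi = np.maximum(opt.max(axis=0), inclusion.hi) + grid_margin_mm
    lo[2] = 0.0
    hi[2] = max(hi[2], inclusion.hi[2] + 10.0)
    grid = VoxelGrid.from_bounds(lo, hi, recon_voxel_mm)
    log.info("reconstruction grid %s (%d voxels)", grid.shape, grid.n_voxels)
    A = build_sensitivity(probe, medium, grid, Texp=Texp, tau=tau)
    # forward Rytov signals for the true inclusion on each channel
    fwd_grid = VoxelGrid.from_bounds(inclusion.lo, inclusion.hi, forward_voxel_mm)
    pts = fwd_grid.centers()
    clamp = 0.5 * min(fwd_grid.spacing)
    phi1 = np.empty((probe.n_channels, tau.size))
    g10s = []
    for i, (rs_pos, rd_pos) in enumerate(probe.channel_positions()):
        W = cde.phi_s_weights(
            medium, medium.Db0, pts, fwd_grid.voxel_volume, rs_pos, rd_pos, tau, clamp
        )
        phi1[i] = W.sum(axis=1) * medium.Db0
        rho = float(np.linalg.norm(rs_pos - rd_pos))
        g10s.append(cde.baseline_curve(medium, rho, tau).normalized().values)
    g10s = np.asarray(g10s)
    reconstructed = np.empty(rdb_grid.size)
    for k, s in enumerate(rdb_grid):
        g1p = g10s * np.exp(s * phi1)
        y = np.empty(probe.n_channels)
        for i in range(probe.n_channels):
            y[i] = speckle.signals_from_g1_matrix(tau, g10s[i], g1p[i], Texp)
        recon = tikhonov_invert(A, y, alpha=alpha)
        reconstructed[k] = region_average(recon, inclusion)
    m = rdb_grid <= 1.0 + 1e-9
    slope = linear_fit_through_origin(rdb_grid[m], reconstructed[m])
    fit = slope * rdb_grid
    pct = (reconstructed - fit) / fit * 100.0
    resid = reconstructed[m] - fit[m]
    ss_tot = np.sum((reconstructed[m] - reconstructed[m].mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return {
        "rdb_grid": rdb_grid,
        "reconstructed": reconstructed,
        "slope": slope,
        "percent_error": pct,
        "r_squared_0_1": float(r2),
        "threshold_rdb_minus_1": threshold_detect(rdb_grid, pct),
        "alpha": alpha,
        "grid": grid,
    }
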