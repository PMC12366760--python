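"""Analytic correlation-diffusion forward model.

The field autocorrelation G1(tau) in a dynamic scattering medium obeys a
Helmholtz-type correlation diffusion equation (CDE).  For a homogeneous
semi-infinite medium the solution between surface optodes is the classic
extrapolated-boundary image-source expression; localized changes of the
Brownian diffusion coefficient Db enter through a perturbation integral
Phi_s built from products of Green's functions, which yields the first Born
approximation G1 = G10*(1 + Phi_s) and the Rytov approximation
G1 = G10*exp(Phi_s).
"""

from __future__ import annotations

import logging

import numpy as np

from .medium import CorrelationCurve, FlowPerturbation, OpticalMedium

log = logging.getLogger(__name__)

#: default lower clamp (mm) on Green's-function distances for direct calls;
#: voxelized sums clamp at half the smallest voxel spacing instead.
DEFAULT_CLAMP_MM = 1e-9


def decay_constant(
    medium: OpticalMedium, Db: float, tau: np.ndarray | float
) -> np.ndarray | float:
    """Decay constant C(tau) (1/mm) of the CDE Helmholtz operator.

    C^2 = v*(mua + (1/3)*musp*k0^2*<dr^2(tau)>)/Dp with <dr^2> = 6*Db*tau,
    which simplifies (Dp = v/(3*musp)) to

        C = sqrt(3*musp*mua + 6*musp^2*k0^2*Db*tau).
    """
    tau = np.asarray(tau, float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    c2 = 3.0 * medium.musp * medium.mua + 6.0 * medium.musp**2 * medium.k0**2 * Db * tau
    return np.sqrt(c2)


def g1_semiinf(
    medium: OpticalMedium,
    Db: float,
    rho: float,
    tau: np.ndarray | float,
) -> np.ndarray | float:
    """Unnormalized G1(rho, tau) between two surface optodes.

    Semi-infinite image-source solution (source strength S = 1):

        G1 = (3*musp/4pi) * [exp(-C r1)/r1 - exp(-C r2)/r2]

    with r1 = sqrt(rho^2 + z0^2), r2 = sqrt(rho^2 + (z0 + 2 zb)^2).
    """
    if rho <= 0:
        raise ValueError("rho must be > 0 (on-axis evaluation is undefined)")
    C = decay_constant(medium, Db, tau)
    z0, zb = medium.z0, medium.zb
    r1 = np.hypot(rho, z0)
    r2 = np.hypot(rho, z0 + 2.0 * zb)
    pref = 3.0 * medium.musp / (4.0 * np.pi)
    return pref * (np.exp(-C * r1) / r1 - np.exp(-C * r2) / r2)


def _effective_source(point: np.ndarray, z0: float) -> np.ndarray:
    """An optode on the surface acts as an isotropic source at depth z0."""
    p = np.array(point, float)
    if p[2] == 0.0:
        p = p.copy()
        p[2] = z0
    return p


def _greens_pair(
    medium: OpticalMedium,
    Db: float,
    src: np.ndarray,
    pts: np.ndarray,
    tau: np.ndarray,
    clamp: float,
) -> np.ndarray:
    """Image-source Green's function from ``src`` to points, shape (ntau, npts).

    The negative image of the source is its reflection about the extrapolated
    boundary plane z = -zb.  Distances are clamped below at ``clamp``.
    """
    pts = np.atleast_2d(pts)
    img = src.copy()
    img[2] = -2.0 * medium.zb - src[2]
    d1 = np.linalg.norm(pts - src, axis=1)
    d2 = np.linalg.norm(pts - img, axis=1)
    n_clamped = int(np.count_nonzero(d1 < clamp))
    if n_clamped:
        log.debug(
            "%d field point(s) within %.3g mm of a source; distance clamped",
            n_clamped,
            clamp,
        )
    d1 = np.maximum(d1, clamp)
    d2 = np.maximum(d2, clamp)
    C = np.atleast_1d(decay_constant(medium, Db, tau))[:, None]
    pref = 3.0 * medium.musp / (4.0 * np.pi)
    return pref * (np.exp(-C * d1) / d1 - np.exp(-C * d2) / d2)


def g1_point_interior(
    medium: OpticalMedium,
    Db: float,
    a: np.ndarray,
    b: np.ndarray,
    tau: np.ndarray | float,
    clamp: float = DEFAULT_CLAMP_MM,
) -> np.ndarray | float:
    """G1 between an optode and an interior point (or two interior points).

    The point lying on the surface (z = 0) is represented by an isotropic
    source at depth z0 beneath it, with a negative image reflected about
    z = -zb; when both points are on the surface this reduces exactly to
    :func:`g1_semiinf`.  The value is reciprocal in its two arguments.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a[2] < 0 or b[2] < 0:
        raise ValueError("points must lie in the half-space z >= 0")
    # canonical ordering keeps the evaluation symmetric: the shallower point
    # plays the role of the (possibly optode) source
    if (b[2], tuple(b)) < (a[2], tuple(a)):
        a, b = b, a
    src = _effective_source(a, medium.z0)
    tau_arr = np.atleast_1d(np.asarray(tau, float))
    out = _greens_pair(medium, Db, src, b[None, :], tau_arr, clamp)[:, 0]
    return out if np.ndim(tau) else float(out[0])


def phi_s_weights(
    medium: OpticalMedium,
    Db: float,
    points: np.ndarray,
    dV: float,
    rs: np.ndarray,
    rd: np.ndarray,
    tau: np.ndarray,
    clamp: float,
) -> np.ndarray:
    """Per-voxel Born kernel, shape (ntau, nvox), per unit Delta_Db.

    ``phi_s = weights @ delta_Db``.  Each column is the contribution of one
    voxel (midpoint quadrature, weight dV):

        w_j = -dV * 2*musp*k0^2*tau * H(r'_j, rd) * G10(rs, r'_j) / G10(rs, rd)

    (the Green's-function prefactors v, Dp and S cancel in this
    combination; written for source strength S = 1).

    The physical source optode is modeled as an isotropic point source at
    depth z0; the detector-side factor H is the true delta-source Green's
    function evaluated at the detector's surface position (no depth shift).
    This distinction matters: shifting the detector too overestimates the
    first-order kernel by ~60% against the exact homogeneous-perturbation
    derivative, while the unshifted form agrees with it to ~1%.
    """
    rs = _effective_source(np.asarray(rs, float), medium.z0)
    rd = np.asarray(rd, float)
    tau = np.atleast_1d(np.asarray(tau, float))
    Gs = _greens_pair(medium, Db, rs, points, tau, clamp)
    Gd = _greens_pair(medium, Db, rd, points, tau, clamp)
    # surface-to-surface baseline between the two optodes
    rho = float(np.linalg.norm(np.asarray(rs)[:2] - np.asarray(rd)[:2]))
    g0 = np.atleast_1d(g1_semiinf(medium, Db, rho, tau))[:, None]
    coef = -dV * 2.0 * medium.musp * medium.k0**2 * tau[:, None]
    return coef * Gs * Gd / g0


def phi_s(
    medium: OpticalMedium,
    perturbation: FlowPerturbation,
    rs: np.ndarray,
    rd: np.ndarray,
    tau: np.ndarray | float,
    clamp: float | None = None,
) -> np.ndarray | float:
    """Perturbation term Phi_s(rs, rd, tau) for a voxelized rDb map.

    Negative for flow increases; exactly additive over disjoint perturbed
    regions; identically zero at tau = 0 and for rDb = 1 everywhere.
    """
    grid = perturbation.grid
    if clamp is None:
        clamp = 0.5 * min(grid.spacing)
    tau_arr = np.atleast_1d(np.asarray(tau, float))
    dDb = perturbation.delta_Db(medium.Db0)
    active = np.nonzero(dDb)[0]
    if active.size == 0:
        out = np.zeros(tau_arr.size)
    else:
        pts = grid.centers()[active]
        n_near = int(
            np.count_nonzero(
                (np.linalg.norm(pts - np.asarray(rs, float), axis=1) < clamp)
                | (np.linalg.norm(pts - np.asarray(rd, float), axis=1) < clamp)
            )
        )
        if n_near:
            log.warning(
                "%d perturbed voxel(s) touch an optode; distances clamped at %.3g mm",
                n_near,
                clamp,
            )
        W = phi_s_weights(
            medium, medium.Db0, pts, grid.voxel_volume, rs, rd, tau_arr, clamp
        )
        out = W @ dDb[active]
    return out if np.ndim(tau) else float(out[0])


def g1_born(baseline: CorrelationCurve, phis: np.ndarray) -> CorrelationCurve:
    """First Born approximation G1 = G10 * (1 + Phi_s).

    May go negative for large |Phi_s|; values are reported as-is (this is
    the breakdown mode of the Born solution, not an error).
    """
    phis = np.asarray(phis, float)
    if phis.shape != baseline.tau.shape:
        raise ValueError("phis must be sampled on the baseline tau grid")
    return CorrelationCurve(baseline.tau, baseline.values * (1.0 + phis))


def g1_rytov(baseline: CorrelationCurve, phis: np.ndarray) -> CorrelationCurve:
    """Rytov approximation G1 = G10 * exp(Phi_s); strictly positive."""
    phis = np.asarray(phis, float)
    if phis.shape != baseline.tau.shape:
        raise ValueError("phis must be sampled on the baseline tau grid")
    return CorrelationCurve(baseline.tau, baseline.values * np.exp(phis))


def baseline_curve(
    medium: OpticalMedium, rho: float, tau: np.ndarray
) -> CorrelationCurve:
    """Homogeneous semi-infinite G1 curve for a surface channel."""
    return CorrelationCurve(tau, g1_semiinf(medium, medium.Db0, rho, tau))
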