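"""Forward photophysics: order parameters and polarised intensities.

One-photon polarised fluorescence from dipole probes in a cylindrically
symmetric filament system only determines the ensemble averages of the
second and fourth even Legendre polynomials of cos(theta), <P2> and <P4>,
where theta is the polar angle between the probe dipole and the filament
axis. Probe motion on timescales faster than the fluorescence lifetime
scales each even rank multiplicatively: observed = fast x slow.

The forward intensity model used by :func:`intensities_to_order_params`
is self-consistent rather than a reproduction of any published
correction algebra: absorption photoselects with cos^2 of the angle to the
excitation polarisation, emission through an analyser contributes
(1 + 2 * p2_fast * P2(cos angle to the analyser)) / 3 after azimuthal
averaging of the fast wobble about the mean dipole axis. Measurements on
two illumination axes orthogonal to the fibre (x and y) jointly determine
(p2, p4, p2_fast) up to a common intensity scale; the module guarantees
an exact round trip through its own forward map and the correct isotropic
and parallel-delta limits.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import InfeasibleDataError, NormalizationError
from .frames import DomainOrientation, ProbeGeometry, rotation_zyz
from .omap import OrientationMap, cos_theta_grid

__all__ = [
    "OrderParameters",
    "WobbleModel",
    "PolarizedIntensitySet",
    "P2_MIN",
    "P4_MIN",
    "legendre_p2",
    "legendre_p4",
    "probe_polar_angle",
    "forward_order_params",
    "order_params_from_delta",
    "intensity_model",
    "intensities_to_order_params",
    "feasible",
]

P2_MIN = -0.5
P4_MIN = -3.0 / 7.0


def legendre_p2(x):
    """P2(x) = (3x^2 - 1)/2 on [-1, 1]."""
    x = np.asarray(x, float)
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ValueError("cosine argument outside [-1, 1]")
    return (3.0 * x**2 - 1.0) / 2.0


def legendre_p4(x):
    """P4(x) = (35x^4 - 30x^2 + 3)/8 on [-1, 1]."""
    x = np.asarray(x, float)
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ValueError("cosine argument outside [-1, 1]")
    return (35.0 * x**4 - 30.0 * x**2 + 3.0) / 8.0


@dataclasses.dataclass
class OrderParameters:
    """<P2>, <P4> of one probe, with optional measurement s.d."""

    p2: float
    p4: float
    sigma_p2: float | None = None
    sigma_p4: float | None = None

    def __post_init__(self):
        if not (P2_MIN - 1e-9 <= self.p2 <= 1 + 1e-9):
            raise ValueError(f"p2={self.p2} outside [{P2_MIN}, 1]")
        if not (P4_MIN - 1e-9 <= self.p4 <= 1 + 1e-9):
            raise ValueError(f"p4={self.p4} outside [{P4_MIN}, 1]")
        for s in (self.sigma_p2, self.sigma_p4):
            if s is not None and s < 0:
                raise ValueError("sigma must be >= 0")


def _cone_p4(p2_fast: float) -> float:
    """<P4> of uniform wobble in a cone whose <P2> equals p2_fast.

    The cap average of P2 over cos(theta) in [u, 1] is u(1+u)/2; inverting
    for u and evaluating the cap average of P4, u(1+u)(7u^2-3)/8, ties the
    two fast order parameters to a single cone half-angle.
    """
    if not (0.0 <= p2_fast <= 1.0):
        raise ValueError("p2_fast must be in [0, 1]")
    # solve u(1+u)/2 = p2_fast for u in [0, 1]
    u = (-1.0 + np.sqrt(1.0 + 8.0 * p2_fast)) / 2.0
    return float(u * (u + 1.0) * (7.0 * u**2 - 3.0) / 8.0)


@dataclasses.dataclass
class WobbleModel:
    """Fast-wobble correction factors; p2_fast = p4_fast = 1 is a rigid probe."""

    p2_fast: float = 1.0
    p4_fast: float | None = None  # default: one-parameter cone model

    def __post_init__(self):
        if not (0.0 <= self.p2_fast <= 1.0):
            raise ValueError("p2_fast must be in [0, 1]")
        if self.p4_fast is None:
            self.p4_fast = _cone_p4(self.p2_fast)

    @property
    def rigid(self) -> bool:
        return self.p2_fast == 1.0 and self.p4_fast == 1.0


@dataclasses.dataclass
class PolarizedIntensitySet:
    """Four intensities for one illumination axis (x or y, both normal to z).

    Keys: excitation/emission polarisation parallel (z) or perpendicular
    to the fibre axis, in arbitrary common units.
    """

    illumination: str  # "x" or "y"
    I_pp: float  # excitation parallel, emission parallel
    I_pq: float  # excitation parallel, emission perpendicular
    I_qp: float
    I_qq: float

    def __post_init__(self):
        if self.illumination not in ("x", "y"):
            raise ValueError("illumination axis must be 'x' or 'y'")
        for v in (self.I_pp, self.I_pq, self.I_qp, self.I_qq):
            if v < 0:
                raise ValueError("intensities must be >= 0")


def probe_polar_angle(
    probe: ProbeGeometry, orientation: DomainOrientation
) -> float:
    """Polar angle (deg) of the probe dipole to the filament axis at (beta, gamma).

    Independent of the inaccessible azimuth about the filament axis.
    """
    c = cos_theta_grid(
        probe.dipole_mol, [orientation.beta], [orientation.gamma]
    )[0, 0]
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def forward_order_params(
    dist: OrientationMap,
    probe: ProbeGeometry,
    wobble: WobbleModel | None = None,
    norm_tol: float = 1e-6,
) -> OrderParameters:
    """<P2>, <P4> of a probe under a (beta, gamma) orientation distribution.

    Midpoint quadrature with the sin(beta) measure on the map's grid;
    the fast-wobble factors multiply each rank.
    """
    wobble = wobble or WobbleModel()
    dist.check_normalized(norm_tol)
    c = cos_theta_grid(probe.dipole_mol, dist.beta_deg, dist.gamma_deg)
    p2 = wobble.p2_fast * dist.expectation(legendre_p2(c))
    p4 = wobble.p4_fast * dist.expectation(legendre_p4(c))
    return OrderParameters(
        p2=float(np.clip(p2, P2_MIN, 1.0)), p4=float(np.clip(p4, P4_MIN, 1.0))
    )


def order_params_from_delta(
    probe: ProbeGeometry,
    orientation: DomainOrientation,
    wobble: WobbleModel | None = None,
) -> OrderParameters:
    """Order parameters of a probe for a single (delta) domain orientation."""
    wobble = wobble or WobbleModel()
    theta = np.radians(probe_polar_angle(probe, orientation))
    c = np.cos(theta)
    return OrderParameters(
        p2=float(np.clip(wobble.p2_fast * legendre_p2(c), P2_MIN, 1.0)),
        p4=float(np.clip(wobble.p4_fast * legendre_p4(c), P4_MIN, 1.0)),
    )


def _moments(p2: float, p4: float):
    """<cos^2>, <cos^4> from the slow order parameters."""
    m2 = (2.0 * p2 + 1.0) / 3.0
    m4 = (8.0 * p4 + 20.0 * p2 + 7.0) / 35.0
    return m2, m4


def intensity_model(
    p2: float, p4: float, p2_fast: float = 1.0, scale: float = 1.0
) -> tuple:
    """Forward map (p2, p4, p2_fast) -> the 8 polarised intensities.

    Returns (x-illumination, y-illumination) PolarizedIntensitySet pair.
    With azimuthal symmetry the two axes carry the same static information;
    both are emitted so the inversion can consume real two-axis data.
    """
    m2, m4 = _moments(p2, p4)
    d = p2_fast
    # I(a, e) = scale * < (a.u)^2 (1 + 2 d P2(e.u)) > over the slow density,
    # with the fast wobble azimuthally averaged about the mean dipole u.
    s2c2 = m2 - m4  # <sin^2 cos^2>
    s2 = 1.0 - m2
    s4 = 1.0 - 2.0 * m2 + m4  # <sin^4>
    I_zz = scale * (m2 + d * (3.0 * m4 - m2))
    I_zq = scale * (m2 - d * (3.0 * m4 - m2) / 2.0)
    I_qz = scale * (s2 / 2.0 + d * (3.0 * s2c2 - s2 / 2.0))
    # <sin^4 cos^4 phi> = 3/8 <sin^4>; P2 of the in-plane analyser direction
    I_qq = scale * (s2 / 2.0 + d * (9.0 / 8.0 * s4 - s2 / 2.0))
    x = PolarizedIntensitySet("x", I_pp=I_zz, I_pq=I_zq, I_qp=I_qz, I_qq=I_qq)
    y = PolarizedIntensitySet("y", I_pp=I_zz, I_pq=I_zq, I_qp=I_qz, I_qq=I_qq)
    return x, y


def _predict_vector(p2, p4, d, scale):
    x, _ = intensity_model(p2, p4, d, scale)
    one = np.array([x.I_pp, x.I_pq, x.I_qp, x.I_qq])
    return np.concatenate([one, one])


def intensities_to_order_params(
    data: tuple,
    residual_tol: float = 1e-6,
) -> tuple:
    """Invert measured intensities to (OrderParameters, WobbleModel).

    ``data`` is an (x-illumination, y-illumination) PolarizedIntensitySet
    pair. For each trial fast factor the model is linear in
    (scale, scale*p2, scale*p4); a bounded 1-D search over p2_fast plus a
    linear solve recovers all parameters. Degenerate data (e.g. all
    intensities equal, which only a fully randomising fast wobble can
    produce) resolve to the maximum-entropy choice p2 = p4 = 0. Data
    outside the model's range space raise InfeasibleDataError carrying the
    residual.
    """
    from scipy.optimize import minimize_scalar

    x, y = data
    if {x.illumination, y.illumination} != {"x", "y"}:
        raise InfeasibleDataError("need one x- and one y-illumination set")
    meas = np.array(
        [x.I_pp, x.I_pq, x.I_qp, x.I_qq, y.I_pp, y.I_pq, y.I_qp, y.I_qq]
    )
    if np.any(meas <= 0):
        raise InfeasibleDataError("intensities must be > 0 for inversion")
    scale0 = meas.sum()

    def design(d):
        # columns: coefficients of (scale, scale*p2, scale*p4); the model is
        # linear in these at fixed fast factor d, so finite differences of
        # the closed form recover the design matrix exactly
        e = np.zeros((8, 3))
        base = _predict_vector(0.0, 0.0, d, 1.0)
        dp2 = _predict_vector(0.5, 0.0, d, 1.0) - base
        dp4 = _predict_vector(0.0, 0.5, d, 1.0) - base
        e[:, 0] = base
        e[:, 1] = dp2 / 0.5
        e[:, 2] = dp4 / 0.5
        return e

    def solve_at(d):
        A = design(d)
        coef, res, rank, sv = np.linalg.lstsq(A, meas, rcond=None)
        if rank < 3 or sv[-1] < 1e-8 * sv[0]:
            # rank-deficient (d ~ 0): ridge toward the isotropic solution
            lam = 1e-10 * scale0**2
            AtA = A.T @ A + lam * np.diag([0.0, 1.0, 1.0])
            coef = np.linalg.solve(AtA, A.T @ meas)
        resid = float(np.linalg.norm(A @ coef - meas))
        return coef, resid

    obj = lambda d: solve_at(d)[1]
    opt = minimize_scalar(obj, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-12})
    d = float(opt.x)
    # the bounded minimiser never lands exactly on the rim; polish the ends
    for d_try in (0.0, 1.0, d):
        if obj(d_try) < obj(d) - 1e-15:
            d = d_try
    coef, resid = solve_at(d)
    scale, sp2, sp4 = coef
    if scale <= 0:
        raise InfeasibleDataError("inverted intensity scale is non-positive",
                                  residual=resid)
    p2 = float(sp2 / scale)
    p4 = float(sp4 / scale)
    rel = resid / np.linalg.norm(meas)
    if rel > residual_tol:
        raise InfeasibleDataError(
            f"intensity set outside the forward model's range "
            f"(relative residual {rel:.3e})",
            residual=rel,
        )
    if not (P2_MIN - 1e-6 <= p2 <= 1 + 1e-6 and P4_MIN - 1e-6 <= p4 <= 1 + 1e-6):
        raise InfeasibleDataError(
            f"inverted order parameters out of physical bounds: "
            f"p2={p2:.4f}, p4={p4:.4f}",
            residual=rel,
        )
    ops = OrderParameters(p2=float(np.clip(p2, P2_MIN, 1.0)),
                          p4=float(np.clip(p4, P4_MIN, 1.0)))
    return ops, WobbleModel(p2_fast=d)


def feasible(p: OrderParameters, grid_deg: float = 0.5, slack: float = 1e-4) -> bool:
    """Whether (p2, p4) is attainable by some density on theta in [0, 180].

    Linear program over a theta grid: exists w >= 0 with sum w = 1,
    sum w P2 = p2, sum w P4 = p4. The default slack absorbs the curvature
    of the moment map between grid nodes (a delta between nodes is
    otherwise reported infeasible at machine precision).
    """
    from scipy.optimize import linprog

    theta = np.radians(np.arange(0.0, 180.0 + grid_deg / 2, grid_deg))
    c = np.cos(theta)
    A = np.vstack([np.ones_like(c), legendre_p2(c), legendre_p4(c)])
    b = np.array([1.0, p.p2, p.p4])
    res = linprog(
        c=np.zeros(len(theta)),
        A_ub=np.vstack([A, -A]),
        b_ub=np.concatenate([b + slack, -(b - slack)]),
        bounds=(0, None),
        method="highs",
    )
    return bool(res.success)
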