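"""Reference axes and tilt/twist (beta, gamma) domain orientations.

A domain's orientation in a filament system is described by two angles:
``beta``, the polar angle between a molecule-fixed reference axis (for the
regulatory N-lobe of TnC: the D-helix; for the IT arm: the TnI/TnT
coiled-coil) and the filament axis (+z toward the pointed end of actin),
and ``gamma``, the rotation of the domain about that reference axis,
counterclockwise when viewed from the C-terminal end of the axis. The
azimuth about the filament axis is inaccessible to polarised fluorescence
in a cylindrically symmetric sample and never appears in any output.

Angle extraction uses the z-y-z Euler convention: with the molecular basis
``M = [ref_perp, axis x ref_perp, axis]`` expressed in the filament basis
``F``, the relative rotation ``R = F^T M = Rz(alpha) Ry(beta) Rz(gamma)``
gives ``beta = acos(R[2,2])`` and ``gamma = atan2(R[2,1], -R[2,0])``.
Because a fluorescence dipole has no head, (beta, gamma) and
(180-beta, gamma+-180) are physically indistinguishable; the canonical
representative has beta <= 90.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import (
    AtomMissingError,
    InsufficientPointsError,
    NotACoiledCoilError,
)
from .structio import AtomSelection, StructureModel, select_atoms

__all__ = [
    "AxisFrame",
    "DomainOrientation",
    "ProbeGeometry",
    "fit_helix_axis",
    "fit_coiled_coil_axis",
    "fit_filament_axis",
    "domain_orientation",
    "dipole_from_cys_pair",
    "interhelix_angle",
    "rotation_zyz",
    "frame_from_angles",
]


def _unit(v):
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _perp_component(v, axis):
    v = np.asarray(v, float)
    return v - np.dot(v, axis) * np.asarray(axis, float)


@dataclasses.dataclass
class AxisFrame:
    """A unit reference axis plus a perpendicular vector defining gamma = 0."""

    origin: np.ndarray
    axis: np.ndarray
    ref_perp: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.axis = _unit(self.axis)
        self.ref_perp = _unit(_perp_component(self.ref_perp, self.axis))
        assert abs(np.dot(self.axis, self.ref_perp)) < 1e-8

    def basis(self) -> np.ndarray:
        """3x3 matrix with columns (ref_perp, axis x ref_perp, axis)."""
        y = np.cross(self.axis, self.ref_perp)
        return np.column_stack([self.ref_perp, y, self.axis])

    def with_ref_toward(self, point) -> "AxisFrame":
        """Same axis, gamma=0 direction re-set toward an external point.

        Used for the filament frame: the zero of gamma is the radial
        direction from the filament axis to the domain of interest.
        """
        r = _perp_component(np.asarray(point, float) - self.origin, self.axis)
        if np.linalg.norm(r) < 1e-9:
            raise ValueError("reference point lies on the axis")
        return AxisFrame(self.origin, self.axis, r)

    def transformed(self, R, t=(0.0, 0.0, 0.0)) -> "AxisFrame":
        R = np.asarray(R, float)
        return AxisFrame(
            R @ self.origin + np.asarray(t, float), R @ self.axis, R @ self.ref_perp
        )


@dataclasses.dataclass(frozen=True)
class DomainOrientation:
    """Tilt/twist pair; beta in [0, 180], gamma in (-180, 180] degrees."""

    beta: float
    gamma: float
    degenerate: bool = False  # gamma undefined (beta at a pole)

    def __post_init__(self):
        if not (0.0 <= self.beta <= 180.0):
            raise ValueError(f"beta={self.beta} outside [0, 180]")
        if not (-180.0 < self.gamma <= 180.0 + 1e-12):
            raise ValueError(f"gamma={self.gamma} outside (-180, 180]")

    def canonical(self) -> "DomainOrientation":
        """Fold to the dipole-equivalent representative with beta <= 90."""
        b, g = self.beta, self.gamma
        if b > 90.0:
            b = 180.0 - b
            g = wrap_angle(g + 180.0)
        return DomainOrientation(b, wrap_angle(g), self.degenerate)

    def mate(self) -> "DomainOrientation":
        """The other end of the dipole: (180 - beta, gamma +- 180)."""
        return DomainOrientation(
            180.0 - self.beta, wrap_angle(self.gamma + 180.0), self.degenerate
        )


def wrap_angle(g: float) -> float:
    """Wrap to (-180, 180]."""
    g = (float(g) + 180.0) % 360.0 - 180.0
    return 180.0 if g == -180.0 else g


@dataclasses.dataclass
class ProbeGeometry:
    """A bifunctional probe: cysteine pair and its dipole in the molecular frame.

    The fluorescence dipole of a bifunctional rhodamine is taken parallel
    to the vector joining the beta-carbons of the two cross-linked
    cysteines. The sign of the dipole is physically meaningless.
    """

    label: str
    cys_pair: tuple  # ((chain, resnum), (chain, resnum))
    dipole_mol: np.ndarray  # unit 3-vector in the molecular frame

    def __post_init__(self):
        self.dipole_mol = _unit(self.dipole_mol)


def fit_helix_axis(
    model_or_positions, sel: AtomSelection | None = None,
    twist_deg: float = 100.0,
) -> AxisFrame:
    """Fit the axis of an alpha-helix from its CA trace.

    A weighted running average over 4 consecutive CA positions cancels the
    ~100 degree/residue helical wobble (kernel [1, c, c, 1] with
    c = -cos(3t/2)/cos(t/2), which nulls the helical phasor exactly at
    twist t); the axis is the principal direction of the averaged curve,
    oriented N->C. The origin is the CA centroid and the gamma=0 reference
    is the perpendicular component of the vector from the origin to the
    first CA (molecule-fixed, deterministic).
    """
    if isinstance(model_or_positions, StructureModel):
        pos = select_atoms(model_or_positions, sel)
    else:
        pos = np.asarray(model_or_positions, float)
    n = len(pos)
    if n < 5:
        raise InsufficientPointsError(f"helix axis fit needs >=5 CA atoms, got {n}")
    t = np.radians(twist_deg)
    c = -np.cos(1.5 * t) / np.cos(0.5 * t)
    kernel = np.array([1.0, c, c, 1.0])
    kernel = kernel / kernel.sum()
    smooth = np.column_stack(
        [np.convolve(pos[:, k], kernel, mode="valid") for k in range(3)]
    )
    centred = smooth - smooth.mean(axis=0)
    _, _, Vt = np.linalg.svd(centred, full_matrices=False)
    axis = Vt[0]
    if np.dot(axis, smooth[-1] - smooth[0]) < 0:
        axis = -axis
    origin = pos.mean(axis=0)
    ref = _perp_component(pos[0] - origin, axis)
    if np.linalg.norm(ref) < 1e-9:  # first CA on the axis: fall back to second
        ref = _perp_component(pos[1] - origin, axis)
    return AxisFrame(origin, axis, ref)


def fit_coiled_coil_axis(
    model: StructureModel,
    sel_helix1: AtomSelection,
    sel_helix2: AtomSelection,
    max_divergence_deg: float = 60.0,
) -> AxisFrame:
    """Common axis of two (anti)parallel helices: mean of co-oriented axes."""
    f1 = fit_helix_axis(model, sel_helix1)
    f2 = fit_helix_axis(model, sel_helix2)
    a1, a2 = f1.axis, f2.axis
    if np.dot(a1, a2) < 0:  # co-orient (antiparallel coiled-coil)
        a2 = -a2
    ang = np.degrees(np.arccos(np.clip(np.dot(a1, a2), -1, 1)))
    if ang > max_divergence_deg:
        raise NotACoiledCoilError(
            f"helix axes diverge by {ang:.1f} deg (> {max_divergence_deg})"
        )
    axis = _unit(a1 + a2)
    origin = 0.5 * (f1.origin + f2.origin)
    ref = _perp_component(f1.origin - origin, axis)
    if np.linalg.norm(ref) < 1e-9:
        ref = _perp_component(f1.ref_perp, axis)
    return AxisFrame(origin, axis, ref)


def fit_filament_axis(
    model: StructureModel,
    subunit_chain_ids,
    pointed_end_chain: str | None = None,
) -> AxisFrame:
    """Principal axis through the centroids of filament subunits.

    ``pointed_end_chain`` names the subunit nearest the pointed (slow-growing)
    end; the axis is signed so that +axis points toward it. By default the
    last listed chain is taken as pointed-end-most, matching deposited thin
    filament models oriented with the pointed end up.
    """
    chains = list(subunit_chain_ids)
    if len(chains) < 3:
        raise InsufficientPointsError(
            f"filament axis fit needs >=3 subunits, got {len(chains)}"
        )
    cents = []
    for c in chains:
        p = np.asarray([a.pos for a in model.atoms if a.chain == c], float)
        if len(p) == 0:
            raise InsufficientPointsError(f"chain {c} has no atoms")
        cents.append(p.mean(axis=0))
    cents = np.asarray(cents)
    centred = cents - cents.mean(axis=0)
    _, _, Vt = np.linalg.svd(centred, full_matrices=False)
    axis = Vt[0]
    pointed = pointed_end_chain if pointed_end_chain is not None else chains[-1]
    ip = chains.index(pointed)
    if np.dot(axis, cents[ip] - cents.mean(axis=0)) < 0:
        axis = -axis
    origin = cents.mean(axis=0)
    ref = _perp_component(cents[0] - origin, axis)
    if np.linalg.norm(ref) < 1e-9:
        # pick any perpendicular deterministically
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, axis)) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        ref = _perp_component(trial, axis)
    return AxisFrame(origin, axis, ref)


def rotation_zyz(alpha_deg: float, beta_deg: float, gamma_deg: float) -> np.ndarray:
    """Rz(alpha) Ry(beta) Rz(gamma), angles in degrees."""
    a, b, g = np.radians([alpha_deg, beta_deg, gamma_deg])

    def rz(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])

    def ry(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])

    return rz(a) @ ry(b) @ rz(g)


def frame_from_angles(
    beta_deg: float,
    gamma_deg: float,
    alpha_deg: float = 0.0,
    filament_frame: AxisFrame | None = None,
    origin=(0.0, 0.0, 0.0),
) -> AxisFrame:
    """Construct the molecular frame sitting at (beta, gamma) in a filament frame."""
    F = (
        filament_frame.basis()
        if filament_frame is not None
        else np.eye(3)
    )
    M = F @ rotation_zyz(alpha_deg, beta_deg, gamma_deg)
    return AxisFrame(np.asarray(origin, float), M[:, 2], M[:, 0])


def domain_orientation(
    domain_frame: AxisFrame,
    filament_frame: AxisFrame,
    pole_tol: float = 1e-6,
) -> DomainOrientation:
    """Tilt and twist of a domain frame relative to the filament frame.

    beta is the angle between the domain axis and the filament +z axis;
    gamma the rotation of the domain about its own axis, counterclockwise
    viewed from the C-terminal (+axis) end, measured from the gamma=0
    convention carried by the two frames' ref_perp vectors. When beta is
    within ``pole_tol`` of 0 or 180 the twist is undefined and returned as
    0 with ``degenerate=True``.
    """
    R = filament_frame.basis().T @ domain_frame.basis()
    beta = float(np.degrees(np.arccos(np.clip(R[2, 2], -1.0, 1.0))))
    if beta < pole_tol or beta > 180.0 - pole_tol:
        return DomainOrientation(beta=min(max(beta, 0.0), 180.0), gamma=0.0,
                                 degenerate=True)
    gamma = float(np.degrees(np.arctan2(R[2, 1], -R[2, 0])))
    return DomainOrientation(beta=beta, gamma=wrap_angle(gamma))


def dipole_from_cys_pair(
    model: StructureModel,
    cys1: tuple,
    cys2: tuple,
    frame: AxisFrame | None = None,
    label: str | None = None,
) -> ProbeGeometry:
    """Unit C-beta -> C-beta vector of a labelled cysteine pair.

    If a molecular ``frame`` is given, the dipole is expressed in that
    frame's basis (so it can be carried to any (beta, gamma) placement).
    Pre-mutation residues are accepted: the C-beta position is
    backbone-determined to first order, so the native residue's C-beta
    stands in for the engineered cysteine's.
    """

    def cb(chain, resnum):
        for a in model.atoms:
            if a.chain == chain and a.resnum == resnum and a.name == "CB":
                return np.asarray(a.pos, float)
        raise AtomMissingError(f"no CB atom at {chain}/{resnum} (glycine or absent)")

    v = cb(*cys2) - cb(*cys1)
    d = _unit(v)
    if frame is not None:
        d = frame.basis().T @ d
    return ProbeGeometry(
        label=label or f"BR_{cys1[1]}-{cys2[1]}",
        cys_pair=(tuple(cys1), tuple(cys2)),
        dipole_mol=d,
    )


def interhelix_angle(frame1: AxisFrame, frame2: AxisFrame) -> float:
    """Angle in [0, 180] degrees between two helix axes (N->C direction-sensitive)."""
    c = np.clip(np.dot(frame1.axis, frame2.axis), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))
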