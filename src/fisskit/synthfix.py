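"""Synthetic fixtures with known ground truth.

Everything the test-suite consumes is generated here: ideal poly-alanine
alpha-helices placed at known (beta, gamma), toy multi-helix domains
carrying cysteine-pair probes, point-subunit filament arrays with polarity
metadata, noisy order-parameter datasets, and Hill titration curves. A
fixture is a pure function of its parameters and seed (identical inputs
give byte-identical files).

The generators emulate the statistical structure the inversion assumes:
Gaussian i.i.d. measurement noise on order parameters and delta or
wrapped-Gaussian orientation distributions. They do not emulate thermal
ensembles, probe-linker dynamics or real side-chain geometry; the C-beta
is placed radially at the standard bond length, which is all the dipole
geometry (C-beta to C-beta directions) depends on.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import InsufficientPointsError
from .frames import (
    AxisFrame,
    DomainOrientation,
    ProbeGeometry,
    dipole_from_cys_pair,
    rotation_zyz,
)
from .omap import OrientationMap
from .photophys import (
    OrderParameters,
    P2_MIN,
    P4_MIN,
    WobbleModel,
    forward_order_params,
    order_params_from_delta,
)
from .structio import Atom, StructureModel
from .titration import hill_predict

__all__ = [
    "FixtureSpec",
    "make_helix",
    "make_filament",
    "make_labelled_domain",
    "make_probe_dataset",
    "make_titration_curve",
]

CA_RADIUS = 2.3  # A, alpha-helix C-alpha radius
CB_BOND = 1.53  # A, C-alpha -- C-beta bond length


def _as_orientation(orientation) -> DomainOrientation:
    if isinstance(orientation, DomainOrientation):
        return orientation
    return DomainOrientation(*orientation)


def make_helix(
    n_res: int,
    rise: float = 1.5,
    twist: float = 100.0,
    orientation=(0.0, 0.0),
    chain: str = "A",
    first_res: int = 1,
    origin=(0.0, 0.0, 0.0),
    alpha: float = 0.0,
) -> StructureModel:
    """Ideal poly-alanine helix (CA + CB) placed at (beta, gamma).

    Built along +z (N to C) with the given rise/residue and twist/residue,
    then rotated so that its fitted frame sits at the requested tilt and
    twist in the laboratory (filament) frame. The base frame is known
    analytically: axis +z, origin at the CA centroid, gamma=0 reference
    along the perpendicular component of the first CA.
    """
    if n_res < 4:
        raise InsufficientPointsError(f"helix fixture needs >= 4 residues, got {n_res}")
    o = _as_orientation(orientation)
    phases = np.radians(twist) * np.arange(n_res)
    ca = np.column_stack(
        [CA_RADIUS * np.cos(phases), CA_RADIUS * np.sin(phases),
         rise * np.arange(n_res)]
    )
    radial = np.column_stack([np.cos(phases), np.sin(phases), np.zeros(n_res)])
    cb = ca + CB_BOND * radial
    centroid = ca.mean(axis=0)
    ref0 = ca[0] - centroid
    ref0[2] = 0.0
    base = AxisFrame(centroid, np.array([0.0, 0.0, 1.0]), ref0)
    target = rotation_zyz(alpha, o.beta, o.gamma)
    T = target @ base.basis().T
    shift = np.asarray(origin, float)
    atoms = []
    for i in range(n_res):
        for name, pos in (("CA", ca[i]), ("CB", cb[i])):
            p = T @ (pos - centroid) + shift
            atoms.append(
                Atom(chain=chain, resnum=first_res + i, resname="ALA",
                     name=name, pos=tuple(np.round(p, 6)))
            )
    return StructureModel(
        atoms=atoms, source_id=f"helix_n{n_res}_b{o.beta:g}_g{o.gamma:g}"
    )


def make_filament(
    n_subunits: int = 14,
    rise: float = 27.5,
    twist: float = -166.7,
    radius: float = 25.0,
    orientation=(0.0, 0.0),
) -> StructureModel:
    """Point-subunit helical array emulating an actin filament.

    One single-atom chain per subunit; chains are lettered in order of
    increasing position along the +axis, so the last chain is nearest the
    pointed end (the polarity convention the filament-axis fit defaults to).
    """
    if n_subunits < 3:
        raise InsufficientPointsError(
            f"filament fixture needs >= 3 subunits, got {n_subunits}"
        )
    if n_subunits > 26:
        raise ValueError("at most 26 single-letter chains")
    o = _as_orientation(orientation)
    phases = np.radians(twist) * np.arange(n_subunits)
    pos = np.column_stack(
        [radius * np.cos(phases), radius * np.sin(phases),
         rise * np.arange(n_subunits)]
    )
    centroid = pos.mean(axis=0)
    T = rotation_zyz(0.0, o.beta, o.gamma)
    atoms = []
    for i in range(n_subunits):
        p = T @ (pos[i] - centroid)
        atoms.append(
            Atom(chain=chr(ord("A") + i), resnum=1, resname="ALA",
                 name="CA", pos=tuple(np.round(p, 6)))
        )
    return StructureModel(atoms=atoms, source_id=f"filament_n{n_subunits}")


#: fixed placements (azimuth alpha, tilt beta, chain) of the toy domain's
#: helices: the helix (and hence dipole) direction is (alpha, beta) in the
#: molecular frame, chosen to spread the dipoles over the sphere
_DOMAIN_HELICES = [
    (0.0, 0.0, "A"),
    (0.0, 70.0, "B"),
    (120.0, 70.0, "C"),
    (-120.0, 70.0, "D"),
    (60.0, 40.0, "E"),
]


def make_labelled_domain(n_probes: int = 5):
    """Toy multi-helix domain with one cysteine-pair probe per helix.

    Returns (model, reference_frame, probes): the reference frame is that
    of helix A (the domain's 'D-helix' analogue, along +z of the molecular
    frame); each helix carries a probe between residues 3 and 10
    (seven apart, the standard surface-helix spacing), with the dipole
    expressed in the reference frame.
    """
    if not 1 <= n_probes <= len(_DOMAIN_HELICES):
        raise ValueError(f"n_probes must be 1..{len(_DOMAIN_HELICES)}")
    atoms = []
    offsets = {
        "A": (0.0, 0.0, 0.0),
        "B": (12.0, 0.0, 0.0),
        "C": (-6.0, 10.0, 0.0),
        "D": (-6.0, -10.0, 0.0),
        "E": (0.0, 0.0, 14.0),
    }
    for alpha, beta, chain in _DOMAIN_HELICES[:n_probes]:
        helix = make_helix(
            12, orientation=(beta, 0.0), alpha=alpha, chain=chain,
            origin=offsets[chain],
        )
        atoms.extend(helix.atoms)
    model = StructureModel(atoms=atoms, source_id=f"toy_domain_{n_probes}probe")
    ref_frame = AxisFrame(
        origin=np.zeros(3),
        axis=np.array([0.0, 0.0, 1.0]),
        ref_perp=np.array([1.0, 0.0, 0.0]),
    )
    # molecular frame of the construction is the identity; express dipoles
    # in the reference-helix frame so they can be carried to any placement
    probes = [
        dipole_from_cys_pair(
            model, (chain, 3), (chain, 10), frame=ref_frame,
            label=f"{chain}-helix BR_3-10",
        )
        for _, _, chain in _DOMAIN_HELICES[:n_probes]
    ]
    return model, ref_frame, probes


def make_probe_dataset(
    probes,
    true_dist,
    noise_sd: float = 0.0,
    seed: int = 0,
    wobble: WobbleModel | None = None,
):
    """Order parameters for a probe set under a known orientation truth.

    ``true_dist`` is a (beta, gamma) tuple / DomainOrientation (delta
    distribution) or an OrientationMap. Gaussian i.i.d. noise with the
    given s.d. is added to every order parameter; the sigma columns store
    the generating noise level (0 rows leave them empty). Returns
    (DataFrame with columns probe_label, p2, p4, sigma_p2, sigma_p4;
    truth record dict).
    """
    rng = np.random.default_rng(seed)
    wobble = wobble or WobbleModel()
    rows = []
    for probe in probes:
        if isinstance(true_dist, OrientationMap):
            ops = forward_order_params(true_dist, probe, wobble)
            truth = {"kind": "map"}
        else:
            o = _as_orientation(true_dist)
            ops = order_params_from_delta(probe, o, wobble)
            truth = {"kind": "delta", "beta": o.beta, "gamma": o.gamma}
        p2 = float(np.clip(ops.p2 + rng.normal(0.0, noise_sd), P2_MIN, 1.0)) \
            if noise_sd > 0 else ops.p2
        p4 = float(np.clip(ops.p4 + rng.normal(0.0, noise_sd), P4_MIN, 1.0)) \
            if noise_sd > 0 else ops.p4
        rows.append(
            {
                "probe_label": probe.label,
                "p2": p2,
                "p4": p4,
                "sigma_p2": noise_sd if noise_sd > 0 else np.nan,
                "sigma_p4": noise_sd if noise_sd > 0 else np.nan,
            }
        )
    truth.update({"noise_sd": noise_sd, "seed": seed,
                  "p2_fast": wobble.p2_fast, "p4_fast": wobble.p4_fast})
    return pd.DataFrame(rows), truth


def make_titration_curve(
    pca50: float = 6.0,
    n_h: float = 2.5,
    n_points: int = 9,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Synthetic steady-state titration over pCa 7.5 .. 4.5."""
    rng = np.random.default_rng(seed)
    pca = np.linspace(7.5, 4.5, n_points)
    y = hill_predict(pca, pca50, n_h)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    return pd.DataFrame({"pca": pca, "y": y})


@dataclasses.dataclass
class FixtureSpec:
    """Declarative fixture request; identical spec+seed -> identical fixture."""

    kind: str  # helix | domain | filament | op-dataset | titration
    params: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    def build(self):
        kinds = {
            "helix": lambda: make_helix(**self.params),
            "domain": lambda: make_labelled_domain(**self.params),
            "filament": lambda: make_filament(**self.params),
            "titration": lambda: make_titration_curve(seed=self.seed, **self.params),
        }
        if self.kind == "op-dataset":
            _, _, probes = make_labelled_domain(
                self.params.get("n_probes", 5)
            )
            return make_probe_dataset(
                probes,
                self.params.get("true_dist", (82.0, 10.0)),
                noise_sd=self.params.get("noise_sd", 0.0),
                seed=self.seed,
            )
        if self.kind not in kinds:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        return kinds[self.kind]()
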