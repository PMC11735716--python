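"""Probability density on a (beta, gamma) orientation grid.

The grid is midpoint-rule: cell centres beta in (0, 180), gamma in
(-180, 180], with sin(beta) d(beta) d(gamma) as the integration measure
(solid-angle weight for the polar tilt; the inaccessible azimuth is
already integrated out). A normalized map satisfies
sum f sin(beta) d(beta) d(gamma) = 1 with angles in radians.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import NormalizationError

__all__ = ["OrientationMap", "cos_theta_grid"]


@dataclasses.dataclass
class OrientationMap:
    beta_deg: np.ndarray  # (nb,) cell centres
    gamma_deg: np.ndarray  # (ng,) cell centres
    density: np.ndarray  # (nb, ng), >= 0

    @classmethod
    def regular(cls, spacing_deg: float = 2.0, density=None) -> "OrientationMap":
        nb = int(round(180.0 / spacing_deg))
        ng = int(round(360.0 / spacing_deg))
        beta = (np.arange(nb) + 0.5) * spacing_deg
        gamma = -180.0 + (np.arange(ng) + 0.5) * spacing_deg
        if density is None:
            density = np.ones((nb, ng))
        m = cls(beta, gamma, np.asarray(density, float))
        return m.normalized()

    def __post_init__(self):
        self.beta_deg = np.asarray(self.beta_deg, float)
        self.gamma_deg = np.asarray(self.gamma_deg, float)
        self.density = np.asarray(self.density, float)
        if self.density.shape != (len(self.beta_deg), len(self.gamma_deg)):
            raise ValueError("density shape does not match the grids")
        if np.any(self.density < -1e-12):
            raise ValueError("negative density")

    @property
    def spacing(self):
        db = float(self.beta_deg[1] - self.beta_deg[0])
        dg = float(self.gamma_deg[1] - self.gamma_deg[0])
        return db, dg

    def weights(self) -> np.ndarray:
        """Quadrature weights sin(beta) d(beta) d(gamma) (radians), shape (nb, ng)."""
        db, dg = self.spacing
        w_beta = np.sin(np.radians(self.beta_deg)) * np.radians(db)
        return np.outer(w_beta, np.full(len(self.gamma_deg), np.radians(dg)))

    def integral(self) -> float:
        return float(np.sum(self.density * self.weights()))

    def normalized(self) -> "OrientationMap":
        z = self.integral()
        if z <= 0:
            raise NormalizationError("map integrates to zero")
        return OrientationMap(self.beta_deg, self.gamma_deg, self.density / z)

    def check_normalized(self, tol: float = 1e-6):
        if abs(self.integral() - 1.0) > tol:
            raise NormalizationError(
                f"map integral {self.integral():.8f} != 1 (tol {tol})"
            )

    def entropy(self) -> float:
        """Differential entropy -sum f log f w relative to the angular measure."""
        w = self.weights()
        f = np.clip(self.density, 1e-300, None)
        return float(-np.sum(f * np.log(f) * w))

    def expectation(self, values: np.ndarray) -> float:
        return float(np.sum(self.density * values * self.weights()))

    def dipole_folded(self) -> "OrientationMap":
        """Symmetrize under the dipole substitution (b, g) -> (180-b, g+-180)."""
        half = 0.5 * (self.density + self._mate_values(self.density))
        return OrientationMap(self.beta_deg, self.gamma_deg, half)

    def _mate_values(self, arr: np.ndarray) -> np.ndarray:
        # beta -> 180-beta flips the beta index; gamma -> gamma+180 rolls by ng/2
        ng = len(self.gamma_deg)
        return np.roll(arr[::-1, :], ng // 2, axis=1)

    def dipole_asymmetry(self) -> float:
        return float(np.max(np.abs(self.density - self._mate_values(self.density))))

    def to_dataframe(self):
        import pandas as pd

        B, G = np.meshgrid(self.beta_deg, self.gamma_deg, indexing="ij")
        return pd.DataFrame(
            {
                "beta_deg": B.ravel(),
                "gamma_deg": G.ravel(),
                "density": self.density.ravel(),
            }
        )

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OrientationMap":
        import pandas as pd

        df = pd.read_csv(path)
        beta = np.unique(df["beta_deg"].to_numpy())
        gamma = np.unique(df["gamma_deg"].to_numpy())
        dens = (
            df.pivot(index="beta_deg", columns="gamma_deg", values="density")
            .to_numpy()
        )
        return cls(beta, gamma, dens)

    def plot(self, ax=None, truth=None, peaks=None):
        """Contour plot; hotter colours = more probable orientations."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        G, B = np.meshgrid(self.gamma_deg, self.beta_deg)
        cs = ax.contourf(G, B, self.density, levels=20, cmap="jet")
        ax.figure.colorbar(cs, ax=ax, label="probability density")
        if truth is not None:
            ax.plot(truth[1], truth[0], "wx", markersize=10, mew=2)
        if peaks is not None:
            for p in peaks:
                ax.plot(p.gamma, p.beta, "k+", markersize=10, mew=2)
        ax.set_xlabel("gamma (deg)")
        ax.set_ylabel("beta (deg)")
        return ax


def cos_theta_grid(dipole_mol, beta_deg, gamma_deg) -> np.ndarray:
    """cos(theta) of a molecular-frame dipole to the filament axis on a grid.

    For a domain at Euler placement (alpha, beta, gamma) the lab dipole is
    Rz(alpha) Ry(beta) Rz(gamma) d; its z component (independent of the
    azimuth alpha) is cos(beta) d_z - sin(beta) (cos(gamma) d_x -
    sin(gamma) d_y).
    """
    d = np.asarray(dipole_mol, float)
    b = np.radians(np.asarray(beta_deg, float))[:, None]
    g = np.radians(np.asarray(gamma_deg, float))[None, :]
    return np.cos(b) * d[2] - np.sin(b) * (np.cos(g) * d[0] - np.sin(g) * d[1])
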