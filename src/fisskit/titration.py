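"""Calcium-titration curves and the Hill equation.

Steady-state responses Y (normalised 0-1) as a function of pCa
(-log10 free [Ca2+]) are fitted with the Hill equation

    Y = 1 / (1 + 10^(nH (pCa - pCa50)))

where pCa50 is the pCa of half-maximal response and nH the Hill
cooperativity coefficient. Some sources print the form without the
"1 +" in the denominator, which has no half-maximum at pCa50 and
contradicts the definition of pCa50; it is available behind
``literal_form=True`` for comparison but is treated as a typographical
omission and never fitted by default.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import FitError

__all__ = ["TitrationCurve", "HillResults", "HillModel", "hill_predict", "hill_fit"]


def hill_predict(pca, pca50: float, n_h: float, literal_form: bool = False):
    """Hill-equation response at pCa; Y(pCa50) = 0.5, Y -> 1 as pCa -> -inf."""
    if n_h <= 0:
        raise ValueError("Hill coefficient must be > 0")
    pca = np.asarray(pca, float)
    t = 10.0 ** np.clip(n_h * (pca - pca50), -300.0, 300.0)
    y = 1.0 / t if literal_form else 1.0 / (1.0 + t)
    return float(y) if np.isscalar(pca) or y.ndim == 0 else y


@dataclasses.dataclass
class TitrationCurve:
    """pCa / normalised-response pairs from a steady-state titration."""

    pca: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.pca = np.asarray(self.pca, float)
        self.y = np.asarray(self.y, float)
        if self.pca.shape != self.y.shape or self.pca.ndim != 1:
            raise ValueError("pca and y must be equal-length 1-D arrays")
        if len(self.pca) < 4:
            raise ValueError(f"need >= 4 titration points, got {len(self.pca)}")
        if len(np.unique(self.pca)) != len(self.pca):
            raise ValueError("pCa values must be distinct")

    @classmethod
    def from_csv(cls, path) -> "TitrationCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["pca"].to_numpy(), df["y"].to_numpy())


@dataclasses.dataclass
class HillResults:
    """Fitted Hill parameters and diagnostics."""

    pca50: float
    n_h: float
    rss: float
    n_points: int

    def __post_init__(self):
        if self.n_h <= 0:
            raise ValueError("fitted Hill coefficient must be > 0")

    def predict(self, pca):
        return hill_predict(pca, self.pca50, self.n_h)

    def summary(self) -> str:
        return "\n".join(
            [
                "Hill-equation fit",
                "=================",
                f"pCa50 : {self.pca50:.4f}",
                f"nH    : {self.n_h:.4f}",
                f"RSS   : {self.rss:.3e}  over {self.n_points} points",
            ]
        )


class HillModel:
    """Nonlinear least-squares Hill fit with a deterministic multi-start grid.

    Starts cover pCa50 over the data range and nH in {1, 2, 4}; the best
    converged minimum is returned.
    """

    def __init__(self, curve: TitrationCurve):
        self.curve = curve

    def fit(self) -> HillResults:
        from scipy.optimize import least_squares

        pca, y = self.curve.pca, self.curve.y

        def resid(params):
            return hill_predict(pca, params[0], np.exp(params[1])) - y

        best = None
        pgrid = np.linspace(pca.min(), pca.max(), 5)
        for p0 in pgrid:
            for nh0 in (1.0, 2.0, 4.0):
                res = least_squares(
                    resid, [p0, np.log(nh0)], xtol=1e-14, ftol=1e-14, gtol=1e-14
                )
                if not res.success:
                    continue
                rss = float(np.sum(res.fun**2))
                if best is None or rss < best[0]:
                    best = (rss, res.x)
        if best is None:
            raise FitError("Hill fit did not converge from any start")
        rss, x = best
        return HillResults(
            pca50=float(x[0]),
            n_h=float(np.exp(x[1])),
            rss=rss,
            n_points=len(pca),
        )


def hill_fit(curve: TitrationCurve) -> HillResults:
    """Functional wrapper around HillModel(curve).fit()."""
    return HillModel(curve).fit()
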