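"""Mathematical models of tea-leaf morphology.

Three small parametric models describe the shape of a tea leaf:

* **Vein curve** — the main vein is treated as a cylindrical cantilever beam
  clamped at the stem and bent by the distributed gravity load of the
  lamina.  Integrating the beam equation
  ``E*I*y1'' = q*sin(theta)*(L - x1)^2 / 2`` with ``y1(0) = y1'(0) = 0``
  gives the quartic deflection

  ``y1(x1) = kappa * sin(theta) / 24 * (x1^4 - 4 L x1^3 + 6 L^2 x1^2)``

  in the beam frame, where ``kappa = q / (E*I)`` bundles the load and
  stiffness coefficients (only their ratio shapes the curve).  The beam
  frame is rotated by the stem-leaf angle ``theta`` into the leaf frame,
  so the curve leaves the stem at angle ``theta`` and sags downward.

* **Leaf length by order** — along a branch the leaf length first grows
  with leaf order ``N`` and then shrinks; a Gaussian-in-order law
  ``LL(N) = LM * exp(La * (N/NM - 1)^2)`` with shape parameter ``La < 0``
  peaks at the order ``NM`` of the longest leaf.

* **Width profile and area** — the half-width along the vein follows a
  normalized quadratic ``lw/LW = a s^2 + b s + c`` with ``s = ll/LL``; the
  leaf area is ``LA = k * LW * LL`` where the shape factor ``k`` equals the
  integral of the width profile and empirically falls in ``[0.67, 0.8]``.

All lengths are unit-agnostic (the pipeline uses pixels); angles are in
degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VeinCurveParams",
    "LeafLengthModel",
    "LeafWidthModel",
    "LeafAreaModel",
    "vein_curve",
    "vein_deflection",
    "leaf_length_by_order",
    "leaf_width_profile",
    "leaf_area",
    "fit_width_profile",
    "DEFAULT_WIDTH_COEFFS",
]

#: Default normalized width-profile coefficients: zero width at base and
#: tip, maximum width LW at mid-leaf.  Integrates to 2/3, the bottom of the
#: empirical range of the area shape factor k.
DEFAULT_WIDTH_COEFFS = (-4.0, 4.0, 0.0)


@dataclass(frozen=True)
class VeinCurveParams:
    """Cantilever-beam vein parameters.

    Parameters
    ----------
    L : float
        Vein length (pixels or any length unit), > 0.
    theta : float
        Stem-leaf angle in degrees, in (0, 180).
    kappa : float
        Bending coefficient ``q / (E*I)`` in 1/length^3, >= 0.  Zero gives
        a straight vein.
    """

    L: float
    theta: float
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"vein length must be positive, got {self.L}")
        if not 0.0 < self.theta < 180.0:
            raise ValueError(f"stem-leaf angle must lie in (0, 180) degrees, got {self.theta}")
        if self.kappa < 0:
            raise ValueError(f"bending coefficient must be >= 0, got {self.kappa}")


def vein_deflection(params: VeinCurveParams, x1: np.ndarray | float) -> np.ndarray | float:
    """Deflection ``y1(x1)`` of the vein in the rotated beam frame."""
    x1 = np.asarray(x1, dtype=np.float64)
    st = np.sin(np.radians(params.theta))
    return params.kappa * st / 24.0 * (x1**4 - 4.0 * params.L * x1**3 + 6.0 * params.L**2 * x1**2)


def vein_curve(params: VeinCurveParams, n_samples: int = 50) -> np.ndarray:
    """Sample the vein curve in the leaf (x, y) frame.

    ``x1`` is sampled uniformly on ``[0, L]``; the beam-frame point
    ``(x1, y1)`` maps to the leaf frame by the rotation
    ``x = y1 cos(theta) + x1 sin(theta)``,
    ``y = y1 sin(theta) - x1 cos(theta)``.
    With the stem pointing along ``-y``, the straight (``kappa = 0``) vein
    leaves the stem at angle ``theta`` and a positive deflection bends the
    tip toward ``+y`` (downward sag).

    Returns an ``(n_samples, 2)`` polyline.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    x1 = np.linspace(0.0, params.L, n_samples)
    y1 = vein_deflection(params, x1)
    th = np.radians(params.theta)
    x = y1 * np.cos(th) + x1 * np.sin(th)
    y = y1 * np.sin(th) - x1 * np.cos(th)
    return np.column_stack([x, y])


@dataclass(frozen=True)
class LeafLengthModel:
    """Leaf length as a function of leaf order along the branch.

    ``LM`` is the maximum single-leaf length, ``NM`` the order of the
    longest leaf (a variety parameter), ``La`` the shape parameter —
    negative so that ``LM`` is indeed the maximum.
    """

    LM: float
    NM: float
    La: float

    def __post_init__(self) -> None:
        if not self.LM > 0:
            raise ValueError("maximum leaf length LM must be positive")
        if not self.NM >= 1:
            raise ValueError("order of the longest leaf NM must be >= 1")
        if self.La > 0:
            warnings.warn(
                "shape parameter La > 0: LM is no longer the maximum leaf length",
                stacklevel=3,
            )


def leaf_length_by_order(model: LeafLengthModel, N: np.ndarray | float) -> np.ndarray | float:
    """Evaluate ``LL(N) = LM * exp(La * (N/NM - 1)^2)`` for leaf order N >= 1."""
    N = np.asarray(N, dtype=np.float64)
    if np.any(N < 1):
        raise ValueError("leaf order must be >= 1")
    out = model.LM * np.exp(model.La * (N / model.NM - 1.0) ** 2)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LeafWidthModel:
    """Quadratic normalized width profile of a leaf.

    ``lw(ll) = LW * (a (ll/LL)^2 + b (ll/LL) + c)``, clamped at zero.
    The coefficients are normalized so the profile's maximum on [0, 1] is 1,
    making ``LW`` the attained maximum width.
    """

    a: float
    b: float
    c: float
    LW: float
    LL: float

    def __post_init__(self) -> None:
        if not (self.LW > 0 and self.LL > 0):
            raise ValueError("LW and LL must be positive")
        s = np.linspace(0.0, 1.0, 513)
        prof = self.a * s**2 + self.b * s + self.c
        if abs(prof.max() - 1.0) > 1e-6:
            warnings.warn(
                f"width profile maximum is {prof.max():.6f}, not 1: "
                "LW will not be the attained maximum width",
                stacklevel=3,
            )
        if np.mean(prof < 0) > 0.10:
            warnings.warn(
                "width profile negative over more than 10% of the leaf: "
                "model validity is doubtful",
                stacklevel=3,
            )

    @property
    def k(self) -> float:
        """Area shape factor implied by the profile: ``a/3 + b/2 + c``."""
        return self.a / 3.0 + self.b / 2.0 + self.c


def leaf_width_profile(model: LeafWidthModel, ll: np.ndarray | float) -> np.ndarray | float:
    """Leaf width at arc position ``ll`` along the vein, in model units."""
    ll = np.asarray(ll, dtype=np.float64)
    if np.any(ll < -1e-9) or np.any(ll > model.LL * (1 + 1e-9)):
        raise ValueError("arc position ll must lie in [0, LL]")
    s = ll / model.LL
    lw = model.LW * (model.a * s**2 + model.b * s + model.c)
    out = np.maximum(lw, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LeafAreaModel:
    """Leaf area as ``LA = k * LW * LL`` with shape correction factor k."""

    k: float = 0.7

    def __post_init__(self) -> None:
        if not 0.67 <= self.k <= 0.8:
            warnings.warn(
                f"shape factor k={self.k} outside the usual range [0.67, 0.8]",
                stacklevel=3,
            )


def leaf_area(model: LeafAreaModel, LW: float, LL: float) -> float:
    """Leaf area from length, maximum width and the shape factor."""
    if LW < 0 or LL < 0:
        raise ValueError("LW and LL must be non-negative")
    return model.k * LW * LL


def fit_width_profile(
    samples: np.ndarray, LL: float, LW: float
) -> tuple[LeafWidthModel, float]:
    """Least-squares fit of the quadratic width profile to (ll, lw) samples.

    Parameters
    ----------
    samples : (n, 2) array
        Measured ``(ll, lw)`` pairs along the leaf, pixel units.
    LL, LW : float
        Leaf length and maximum width used to normalize the coordinates.

    Returns
    -------
    (model, rms)
        The fitted :class:`LeafWidthModel` and the residual RMS in the
        normalized width coordinate.
    """
    pts = np.asarray(samples, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (ll, lw) samples")
    s = pts[:, 0] / LL
    w = pts[:, 1] / LW
    design = np.column_stack([s**2, s, np.ones_like(s)])
    if np.linalg.matrix_rank(design) < 3:
        raise np.linalg.LinAlgError("rank-deficient design: samples do not determine a quadratic")
    coeffs, *_ = np.linalg.lstsq(design, w, rcond=None)
    resid = design @ coeffs - w
    rms = float(np.sqrt(np.mean(resid**2)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LeafWidthModel(a=float(coeffs[0]), b=float(coeffs[1]), c=float(coeffs[2]), LW=LW, LL=LL)
    return model, rms
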