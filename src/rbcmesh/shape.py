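"""Quartic implicit model of the discocyte red-blood-cell surface.

The membrane is the zero set of a degree-4 polynomial in Cartesian
coordinates,

    F(x, y, z) = (x^2 + y^2 + z^2)^2 + P (x^2 + y^2) + Q z^2 + R ,

whose coefficients are fixed by three principal distances of the cell: the
main diameter ``d``, the thickness at the centre of the dimples ``b``, and
the maximum height at the rim ``h`` (all in µm, so F carries units of µm^4).
The construction forces the rim circle (radius d/2 in the z = 0 plane) and
the dimple-centre points (0, 0, ±b/2) to lie exactly on the surface, while
``h`` enters through ``P`` and sets the maximum half-height h/2.

All derivatives used downstream (gradient, Hessian, Hessian adjugate) are
closed-form; numerical differentiation never appears in the production path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = [
    "RBCGeometry",
    "ShapeCoefficients",
    "ImplicitSurface",
    "compute_coefficients",
    "discocyte_surface",
    "adjugate3",
]


@dataclass(frozen=True)
class RBCGeometry:
    """Principal distances of the discocyte, in µm.

    Defaults are the normal human RBC values (d = 8, b = 1, h = 2.12 µm)
    which give an enclosed volume of ~86 µm^3 (= 86 fL) and a surface area
    of ~128 µm^2.
    """

    d: float = 8.0
    b: float = 1.0
    h: float = 2.12

    def __post_init__(self) -> None:
        if not (self.d > 0 and self.b > 0 and self.h > 0):
            raise ValueError("all dimensions must be positive")
        if self.b > self.h:
            raise ValueError(
                f"dimple thickness b={self.b} must not exceed rim height h={self.h} "
                "(square root in the P coefficient would be imaginary)"
            )
        if self.h >= self.d:
            raise ValueError("rim height h must be smaller than diameter d")

    def scaled(self, s: float) -> "RBCGeometry":
        """Uniformly scaled geometry (used for curvature scaling checks)."""
        return RBCGeometry(self.d * s, self.b * s, self.h * s)


@dataclass(frozen=True)
class ShapeCoefficients:
    """Coefficients of the quartic: P, Q in µm^2... (P, Q: µm^2; R: µm^4)."""

    P: float
    Q: float
    R: float


def compute_coefficients(geom: RBCGeometry) -> ShapeCoefficients:
    """Coefficients P, Q, R from the principal distances.

    P encodes the rim height through the square-root term; Q and R are then
    chosen so that the rim (±d/2, 0, 0) lies on the surface exactly and the
    dimple centre (0, 0, ±b/2) lies on it identically in exact arithmetic.
    """
    d2, b2, h2 = geom.d**2, geom.b**2, geom.h**2
    ratio = d2 / b2 - 1.0
    root = np.sqrt(1.0 - b2 / h2)
    P = -d2 / 2.0 + (h2 / 2.0) * ratio * (1.0 - root)
    Q = P * d2 / b2 + (b2 / 4.0) * (d2 * d2 / (b2 * b2) - 1.0)
    R = -P * d2 / 4.0 - d2 * d2 / 16.0
    return ShapeCoefficients(P=float(P), Q=float(Q), R=float(R))


def adjugate3(H: np.ndarray) -> np.ndarray:
    """Adjugate (classical adjoint) of a stack of 3x3 matrices.

    Satisfies H @ adjugate3(H) = det(H) * I even when H is singular, which
    is why it is preferred over det*inv here.
    """
    H = np.asarray(H, dtype=float)
    a, b, c = H[..., 0, 0], H[..., 0, 1], H[..., 0, 2]
    d, e, f = H[..., 1, 0], H[..., 1, 1], H[..., 1, 2]
    g, h, i = H[..., 2, 0], H[..., 2, 1], H[..., 2, 2]
    adj = np.empty_like(H)
    adj[..., 0, 0] = e * i - f * h
    adj[..., 0, 1] = c * h - b * i
    adj[..., 0, 2] = b * f - c * e
    adj[..., 1, 0] = f * g - d * i
    adj[..., 1, 1] = a * i - c * g
    adj[..., 1, 2] = c * d - a * f
    adj[..., 2, 0] = d * h - e * g
    adj[..., 2, 1] = b * g - a * h
    adj[..., 2, 2] = a * e - b * d
    return adj


class ImplicitSurface:
    """Evaluator bundle for an implicit surface {F = 0}.

    Bundles closed-form evaluators for F, ∇F and the Hessian H[F], plus the
    Hessian adjugate (computed algebraically from H). An optional 3x3
    ``inverse_map`` A is pre-composed into the evaluation, so the object
    represents G(p) = F(A p); its zero set is the image of {F = 0} under
    A⁻¹. The chain rule gives ∇G = Aᵀ ∇F(Ap) and H[G] = Aᵀ H[F](Ap) A.

    Parameters
    ----------
    value_fn, grad_fn, hess_fn:
        Vectorized callables taking points of shape (..., 3).
    bounds:
        (2, 3) array [lo, hi] enclosing the zero set (pre-composition
        coordinates of the *visible* surface, i.e. after any inverse map).
    scale:
        Characteristic length (µm), used for on-surface and singular-gradient
        tolerances (F scales like length^4 for the quartic).
    """

    def __init__(
        self,
        value_fn: Callable[[np.ndarray], np.ndarray],
        grad_fn: Callable[[np.ndarray], np.ndarray],
        hess_fn: Callable[[np.ndarray], np.ndarray],
        bounds: np.ndarray,
        scale: float,
        inverse_map: Optional[np.ndarray] = None,
    ) -> None:
        self._value_fn = value_fn
        self._grad_fn = grad_fn
        self._hess_fn = hess_fn
        self.bounds = np.asarray(bounds, dtype=float).reshape(2, 3)
        self.scale = float(scale)
        self.inverse_map = None if inverse_map is None else np.asarray(inverse_map, float)

    # -- tolerances ------------------------------------------------------
    @property
    def on_surface_tol(self) -> float:
        """|F| below this counts as on-surface (quartic units grow as L^4)."""
        return 1e-9 * self.scale**4

    @property
    def singular_grad_tol(self) -> float:
        return 1e-10 * self.scale**3

    # -- evaluation ------------------------------------------------------
    def _pre(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        if self.inverse_map is None:
            return p
        return p @ self.inverse_map.T

    def value(self, points: np.ndarray) -> np.ndarray:
        return self._value_fn(self._pre(points))

    def gradient(self, points: np.ndarray) -> np.ndarray:
        g = self._grad_fn(self._pre(points))
        if self.inverse_map is not None:
            g = g @ self.inverse_map
        return g

    def hessian(self, points: np.ndarray) -> np.ndarray:
        H = self._hess_fn(self._pre(points))
        if self.inverse_map is not None:
            A = self.inverse_map
            H = np.einsum("ji,...jk,kl->...il", A, H, A)
        return H

    def hessian_adjugate(self, points: np.ndarray) -> np.ndarray:
        return adjugate3(self.hessian(points))

    def derivatives(self, points: np.ndarray):
        """(gradient, Hessian, Hessian adjugate, trace of Hessian)."""
        g = self.gradient(points)
        H = self.hessian(points)
        return g, H, adjugate3(H), np.trace(H, axis1=-2, axis2=-1)

    def with_inverse_map(self, inverse_map: np.ndarray, bounds: np.ndarray) -> "ImplicitSurface":
        """New surface evaluating this one at ``inverse_map @ p``."""
        if self.inverse_map is not None:
            inverse_map = self.inverse_map @ np.asarray(inverse_map, float)
        return ImplicitSurface(
            self._value_fn, self._grad_fn, self._hess_fn,
            bounds=bounds, scale=self.scale, inverse_map=inverse_map,
        )


def discocyte_surface(geom: RBCGeometry | None = None,
                      coeffs: ShapeCoefficients | None = None) -> ImplicitSurface:
    """Implicit surface of the discocyte.

    Either a geometry (coefficients computed from it) or explicit
    coefficients may be given; with both, the explicit coefficients win.
    """
    if geom is None:
        geom = RBCGeometry()
    if coeffs is None:
        coeffs = compute_coefficients(geom)
    P, Q, R = coeffs.P, coeffs.Q, coeffs.R

    def value(p: np.ndarray) -> np.ndarray:
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        r2 = x * x + y * y + z * z
        return r2 * r2 + P * (x * x + y * y) + Q * z * z + R

    def grad(p: np.ndarray) -> np.ndarray:
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        r2 = x * x + y * y + z * z
        g = np.empty_like(p)
        g[..., 0] = 4.0 * x * r2 + 2.0 * P * x
        g[..., 1] = 4.0 * y * r2 + 2.0 * P * y
        g[..., 2] = 4.0 * z * r2 + 2.0 * Q * z
        return g

    def hess(p: np.ndarray) -> np.ndarray:
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        r2 = x * x + y * y + z * z
        H = np.empty(p.shape[:-1] + (3, 3), dtype=float)
        H[..., 0, 0] = 4.0 * r2 + 8.0 * x * x + 2.0 * P
        H[..., 1, 1] = 4.0 * r2 + 8.0 * y * y + 2.0 * P
        H[..., 2, 2] = 4.0 * r2 + 8.0 * z * z + 2.0 * Q
        H[..., 0, 1] = H[..., 1, 0] = 8.0 * x * y
        H[..., 0, 2] = H[..., 2, 0] = 8.0 * x * z
        H[..., 1, 2] = H[..., 2, 1] = 8.0 * y * z
        return H

    half = np.array([geom.d / 2.0, geom.d / 2.0, geom.h / 2.0])
    bounds = np.array([-half, half])
    return ImplicitSurface(value, grad, hess, bounds=bounds, scale=geom.d)
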