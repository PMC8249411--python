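"""Quadric test surfaces with closed-form curvature.

These are validation shapes for the curvature machinery: implicit quadrics
whose Gaussian and mean curvature have textbook closed forms, so the
gradient–Hessian–adjugate expressions can be checked point-by-point against
an independent formula.
"""

from __future__ import annotations

import numpy as np

from .shape import ImplicitSurface

__all__ = ["QuadricFixture", "make_fixture"]


class QuadricFixture(ImplicitSurface):
    """Implicit quadric with closed-form curvature accessors.

    ``closed_form_gaussian`` / ``closed_form_mean`` evaluate the analytic
    curvature of the ellipsoid x²/a² + y²/b² + z²/c² = 1 at on-surface
    points (sphere: a = b = c = r). The mean-curvature sign follows the
    outward-normal convention, so a sphere gives K_M = −1/r.
    """

    def __init__(self, a: float, b: float, c: float) -> None:
        if min(a, b, c) <= 0:
            raise ValueError("semi-axes must be positive")
        self.semi_axes = (float(a), float(b), float(c))
        inv2 = np.array([a, b, c], dtype=float) ** -2

        def value(p):
            return np.einsum("...i,i->...", np.asarray(p, float) ** 2, inv2) - 1.0

        def grad(p):
            return 2.0 * np.asarray(p, float) * inv2

        def hess(p):
            p = np.asarray(p, float)
            H = np.zeros(p.shape[:-1] + (3, 3), dtype=float)
            for i in range(3):
                H[..., i, i] = 2.0 * inv2[i]
            return H

        half = np.array([a, b, c], dtype=float)
        super().__init__(value, grad, hess,
                         bounds=np.array([-half, half]), scale=float(max(a, b, c)))

    def _w(self, points: np.ndarray) -> np.ndarray:
        a, b, c = self.semi_axes
        p = np.asarray(points, dtype=float)
        return np.sqrt(p[..., 0] ** 2 / a**4 + p[..., 1] ** 2 / b**4
                       + p[..., 2] ** 2 / c**4)

    def closed_form_gaussian(self, points: np.ndarray) -> np.ndarray:
        a, b, c = self.semi_axes
        return 1.0 / (a**2 * b**2 * c**2 * self._w(points) ** 4)

    def closed_form_mean(self, points: np.ndarray) -> np.ndarray:
        a, b, c = self.semi_axes
        p = np.asarray(points, dtype=float)
        num = (p**2).sum(axis=-1) - (a**2 + b**2 + c**2)
        return num / (2.0 * a**2 * b**2 * c**2 * self._w(points) ** 3)

    def random_surface_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n points exactly on the quadric (radial scaling of random rays)."""
        a, b, c = self.semi_axes
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        return u * np.array([a, b, c])


def make_fixture(name: str, **params: float) -> QuadricFixture:
    """Build a named fixture surface.

    ``sphere`` takes ``r``; ``ellipsoid`` takes semi-axes ``a``, ``b``, ``c``.
    """
    if name == "sphere":
        r = float(params.get("r", 1.0))
        return QuadricFixture(r, r, r)
    if name == "ellipsoid":
        return QuadricFixture(float(params.get("a", 2.0)),
                              float(params.get("b", 1.0)),
                              float(params.get("c", 1.0)))
    raise ValueError(f"unknown fixture {name!r} (expected 'sphere' or 'ellipsoid')")
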