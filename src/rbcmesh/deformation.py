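"""Affine rotation + volume-preserving strain of the implicit surface.

A cell suspended in gel sits at some orientation θ (rotation about the
x-axis, degrees) before a linear strain field is switched on along z. The
strain tensor S_ξ = diag(1/√ξ, 1/√ξ, ξ) elongates along z by the factor ξ
while shrinking the transverse directions, so det S_ξ = 1 and volume is
preserved exactly. The composite map is M = S_ξ · R_θ (rotate first, then
strain); the deformed membrane is the image M·{F = 0}, evaluated implicitly
as F(M⁻¹ p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .shape import ImplicitSurface

__all__ = ["rotation_matrix", "strain_matrix", "AffineDeformation", "transformed_surface"]


def rotation_matrix(theta_deg: float) -> np.ndarray:
    """Euler rotation about the x-axis; θ = 0 is the original orientation."""
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1.0, 0.0, 0.0],
                     [0.0, c, -s],
                     [0.0, s, c]])


def strain_matrix(xi: float) -> np.ndarray:
    """Volume-preserving uniaxial strain along z; ξ = 1 is the relaxed shape."""
    if xi <= 0:
        raise ValueError(f"strain factor xi must be positive, got {xi}")
    return np.diag([xi**-0.5, xi**-0.5, float(xi)])


@dataclass(frozen=True)
class AffineDeformation:
    """Rotation angle θ (degrees, about x) and strain factor ξ (along z).

    ``matrix`` is M = S_ξ · R_θ and ``inverse`` its exact inverse
    R_θᵀ · S_ξ⁻¹; det M = 1 by construction.
    """

    theta_deg: float = 0.0
    xi: float = 1.0
    matrix: np.ndarray = field(init=False, repr=False)
    inverse: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        R = rotation_matrix(self.theta_deg)
        S = strain_matrix(self.xi)
        Sinv = np.diag(1.0 / np.diag(S))
        object.__setattr__(self, "matrix", S @ R)
        object.__setattr__(self, "inverse", R.T @ Sinv)

    @property
    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.theta_deg)

    @property
    def strain(self) -> np.ndarray:
        return strain_matrix(self.xi)


def transformed_surface(surface: ImplicitSurface,
                        deformation: AffineDeformation) -> ImplicitSurface:
    """Implicit surface of the deformed membrane.

    The returned evaluator computes F(M⁻¹ p); its zero set is exactly the
    image under M of the original zero set. Derivatives follow by the chain
    rule inside :class:`~rbcmesh.shape.ImplicitSurface`.
    """
    M = deformation.matrix
    lo, hi = surface.bounds
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    tc = corners @ M.T
    bounds = np.array([tc.min(axis=0), tc.max(axis=0)])
    return surface.with_inverse_map(deformation.inverse, bounds=bounds)
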