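"""Quadrature rules on reference simplices.

Rules are built by collapsing tensor-product Gauss-Legendre rules onto the
simplex (Duffy transform).  The collapsed map is polynomial, so a rule built
with ``n`` points per direction integrates all polynomials of total degree
``2n - 2`` exactly on the simplex (the Jacobian adds at most two to the
per-direction degree, which the choice of ``n`` below accounts for).

Reference elements: the unit triangle {x, y >= 0, x + y <= 1} and the unit
tetrahedron {x, y, z >= 0, x + y + z <= 1}.  Weights sum to the reference
measure (1/2 and 1/6 respectively).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def triangle_rule(degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Points ``(nq, 2)`` and weights ``(nq,)`` exact for polynomials of
    total degree ``degree`` on the unit triangle."""
    n = max(1, (degree + 3) // 2 + 1)
    g, w = np.polynomial.legendre.leggauss(n)
    u = 0.5 * (g + 1.0)  # [0, 1]
    wu = 0.5 * w
    U, V = np.meshgrid(u, u, indexing="ij")
    WU, WV = np.meshgrid(wu, wu, indexing="ij")
    # Duffy: x = u, y = v (1 - u); Jacobian (1 - u)
    x = U.ravel()
    y = (V * (1.0 - U)).ravel()
    wts = (WU * WV * (1.0 - U)).ravel()
    return np.column_stack([x, y]), wts


@lru_cache(maxsize=None)
def tetrahedron_rule(degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Points ``(nq, 3)`` and weights ``(nq,)`` exact for polynomials of
    total degree ``degree`` on the unit tetrahedron."""
    n = max(1, (degree + 4) // 2 + 1)
    g, w = np.polynomial.legendre.leggauss(n)
    u = 0.5 * (g + 1.0)
    wu = 0.5 * w
    U, V, W = np.meshgrid(u, u, u, indexing="ij")
    WU, WV, WW = np.meshgrid(wu, wu, wu, indexing="ij")
    # Duffy: x = u, y = v (1 - u), z = w (1 - u - v(1 - u)) = w (1-u)(1-v)
    x = U.ravel()
    y = (V * (1.0 - U)).ravel()
    z = (W * (1.0 - U) * (1.0 - V)).ravel()
    wts = (WU * WV * WW * (1.0 - U) ** 2 * (1.0 - V)).ravel()
    return np.column_stack([x, y, z]), wts


def map_to_cells(ref_pts: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Map reference-tet points to physical points for a batch of cells.

    ``verts`` has shape ``(ncells, 4, 3)``; returns ``(ncells, nq, 3)``.
    """
    lam0 = 1.0 - ref_pts.sum(axis=1)
    bary = np.column_stack([lam0, ref_pts])  # (nq, 4)
    return np.einsum("qi,cix->cqx", bary, verts)


def map_to_facets(ref_pts: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Map reference-triangle points to physical points for a batch of
    triangles ``(nfacets, 3, 3)``; returns ``(nfacets, nq, 3)``."""
    lam0 = 1.0 - ref_pts.sum(axis=1)
    bary = np.column_stack([lam0, ref_pts])  # (nq, 3)
    return np.einsum("qi,fix->fqx", bary, verts)
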