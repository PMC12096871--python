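"""Discrete image gradient, its exact adjoint, and isotropic total variation.

Forward differences with a replicate (Neumann) boundary: the difference at
the last row/column is zero.  ``grad_adjoint`` is the exact matrix adjoint of
``grad`` (a negative divergence with matching boundary handling), verified by
dot-product tests.
"""
from __future__ import annotations

import numpy as np

__all__ = ["grad", "grad_adjoint", "grad_magnitude", "isotropic_tv", "grad_abs_col_sums"]


def grad(image: np.ndarray) -> np.ndarray:
    """Forward-difference gradient; returns (2, ny, nx): (d/dy, d/dx)."""
    f = np.asarray(image, dtype=float)
    g = np.zeros((2,) + f.shape)
    g[0, :-1, :] = f[1:, :] - f[:-1, :]
    g[1, :, :-1] = f[:, 1:] - f[:, :-1]
    return g


def grad_adjoint(g: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`grad` (negative divergence)."""
    gy, gx = g[0], g[1]
    out = np.zeros_like(gy)
    # adjoint of y-differences
    out[:-1, :] -= gy[:-1, :]
    out[1:, :] += gy[:-1, :]
    # adjoint of x-differences
    out[:, :-1] -= gx[:, :-1]
    out[:, 1:] += gx[:, :-1]
    return out


def grad_magnitude(g: np.ndarray) -> np.ndarray:
    """Per-pixel isotropic gradient magnitude."""
    return np.sqrt(g[0] ** 2 + g[1] ** 2)


def isotropic_tv(image: np.ndarray) -> float:
    """|| |grad f| ||_1 : the l1 norm of per-pixel gradient magnitudes."""
    return float(grad_magnitude(grad(image)).sum())


def grad_abs_col_sums(ny: int, nx: int) -> np.ndarray:
    """Column sums of |grad| from the stencil: each pixel is touched by its
    own forward differences and by those of its left/upper neighbors."""
    c = np.zeros((ny, nx))
    c[:-1, :] += 1.0  # own y-difference
    c[1:, :] += 1.0   # neighbor's y-difference
    c[:, :-1] += 1.0  # own x-difference
    c[:, 1:] += 1.0   # neighbor's x-difference
    return c
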