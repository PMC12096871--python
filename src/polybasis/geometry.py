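"""Discrete 2-D fan-beam x-ray transform as a matched forward/adjoint pair.

Ray weights a_ji are exact ray-pixel intersection lengths (cm), computed by a
Siddon-style traversal, so the operator is nonnegative and sparse-row; its
absolute row/column sums (needed by the diagonally preconditioned solver)
equal plain applications to all-ones vectors.

Coordinate conventions (fixed here; they are package conventions):
  * pixel-centered image grid, rotation center at the image center,
    x increasing with column index, y increasing with row index;
  * the source sits at angle theta, measured counter-clockwise from +x,
    at distance ``sor`` from the rotation center; the first view is theta=0;
  * the detector coordinate increases with the detector bin index along the
    direction (-sin theta, cos theta).

Rays that miss the image grid are kept as all-zero rows so that
J = n_views * n_bins always; sinogram ordering is view-major.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse

__all__ = ["FanBeamGeometry", "RayOperator", "build_projector", "operator_norm"]


@dataclass(frozen=True)
class FanBeamGeometry:
    """Circular fan-beam scan geometry.

    Parameters
    ----------
    sor, sod : float
        Source-to-rotation-center and source-to-detector distances (cm),
        with sod > sor > 0.
    detector_kind : {"linear", "curved"}
        Equispaced linear detector (bin_size in cm) or equiangular curved
        detector (bin_size in radians).
    n_bins, n_views : int
        Detector bins per view and number of views; view angles are uniform
        over [0, 2*pi) starting at 0 unless ``view_angles`` is given.
    nx, ny : int
        Image array size (columns, rows); pixel_size in cm.
    """

    sor: float
    sod: float
    detector_kind: str
    n_bins: int
    bin_size: float
    n_views: int
    nx: int
    ny: int
    pixel_size: float
    view_angles: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.sod > self.sor > 0):
            raise ValueError("need sod > sor > 0")
        if self.detector_kind not in ("linear", "curved"):
            raise ValueError("detector_kind must be 'linear' or 'curved'")
        for name in ("n_bins", "n_views", "nx", "ny"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.bin_size <= 0 or self.pixel_size <= 0:
            raise ValueError("bin_size and pixel_size must be positive")
        if self.view_angles is None:
            angles = 2.0 * np.pi * np.arange(self.n_views) / self.n_views
        else:
            angles = np.asarray(self.view_angles, dtype=float)
            if angles.shape != (self.n_views,):
                raise ValueError("view_angles length must equal n_views")
        object.__setattr__(self, "view_angles", angles)

    @property
    def J(self) -> int:
        return self.n_views * self.n_bins

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny


@njit(cache=True)
def _siddon_rays(sx, sy, ex, ey, nx, ny, h, rows, cols, vals):  # pragma: no cover
    """Trace all rays; fill COO triplets, return the number emitted.

    (sx, sy) -> (ex, ey) are per-ray segment endpoints chosen to bracket the
    image; the grid spans [-nx*h/2, nx*h/2] x [-ny*h/2, ny*h/2].
    """
    x0 = -0.5 * nx * h
    y0 = -0.5 * ny * h
    nnz = 0
    eps = 1e-12
    for j in range(sx.size):
        px, py = sx[j], sy[j]
        dx = ex[j] - px
        dy = ey[j] - py
        length = np.sqrt(dx * dx + dy * dy)
        if length <= 0.0:
            continue
        # slab clipping to the grid bounding box
        tmin, tmax = 0.0, 1.0
        ok = True
        if abs(dx) > eps:
            t1 = (x0 - px) / dx
            t2 = (x0 + nx * h - px) / dx
            if t1 > t2:
                t1, t2 = t2, t1
            tmin = max(tmin, t1)
            tmax = min(tmax, t2)
        elif px <= x0 or px >= x0 + nx * h:
            ok = False
        if abs(dy) > eps:
            t1 = (y0 - py) / dy
            t2 = (y0 + ny * h - py) / dy
            if t1 > t2:
                t1, t2 = t2, t1
            tmin = max(tmin, t1)
            tmax = min(tmax, t2)
        elif py <= y0 or py >= y0 + ny * h:
            ok = False
        if not ok or tmax <= tmin:
            continue
        # entry pixel
        xin = px + tmin * dx
        yin = py + tmin * dy
        ix = int(np.floor((xin - x0) / h))
        iy = int(np.floor((yin - y0) / h))
        if ix < 0:
            ix = 0
        if ix > nx - 1:
            ix = nx - 1
        if iy < 0:
            iy = 0
        if iy > ny - 1:
            iy = ny - 1
        # parametric steps to next x/y grid-line crossings
        if dx > eps:
            stepx = 1
            tx = ((x0 + (ix + 1) * h) - px) / dx
            dtx = h / dx
        elif dx < -eps:
            stepx = -1
            tx = ((x0 + ix * h) - px) / dx
            dtx = -h / dx
        else:
            stepx = 0
            tx = 1e30
            dtx = 1e30
        if dy > eps:
            stepy = 1
            ty = ((y0 + (iy + 1) * h) - py) / dy
            dty = h / dy
        elif dy < -eps:
            stepy = -1
            ty = ((y0 + iy * h) - py) / dy
            dty = -h / dy
        else:
            stepy = 0
            ty = 1e30
            dty = 1e30
        t = tmin
        while t < tmax - eps:
            if tx < ty:
                tnext = tx
            else:
                tnext = ty
            if tnext > tmax:
                tnext = tmax
            seg = (tnext - t) * length
            if seg > 0.0:
                rows[nnz] = j
                cols[nnz] = iy * nx + ix
                vals[nnz] = seg
                nnz += 1
            if tx <= ty:
                ix += stepx
                tx += dtx
            else:
                iy += stepy
                ty += dty
            t = tnext
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny:
                break
    return nnz


@dataclass
class RayOperator:
    """Matched forward/adjoint discrete x-ray transform for one geometry.

    The sparse intersection-length rows are built lazily on first use and
    cached (CSR for the forward pass, CSC-equivalent transpose for the
    adjoint), keeping construction of large geometries cheap.
    """

    geometry: FanBeamGeometry
    _A: sparse.csr_matrix | None = field(default=None, repr=False)
    _AT: sparse.csr_matrix | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple:
        g = self.geometry
        return (g.J, g.n_pixels)

    # -- ray endpoints -----------------------------------------------------
    def _ray_endpoints(self):
        g = self.geometry
        thetas = g.view_angles
        srcx = g.sor * np.cos(thetas)  # (n_views,)
        srcy = g.sor * np.sin(thetas)
        # central-ray direction (unit, source -> rotation center)
        cx, cy = -np.cos(thetas), -np.sin(thetas)
        # detector direction (unit, increasing bin index)
        ux, uy = -np.sin(thetas), np.cos(thetas)
        offs = (np.arange(g.n_bins) - (g.n_bins - 1) / 2.0) * g.bin_size
        if g.detector_kind == "linear":
            # detector line perpendicular to the central ray at distance sod
            ex = (srcx[:, None] + g.sod * cx[:, None] + offs[None, :] * ux[:, None])
            ey = (srcy[:, None] + g.sod * cy[:, None] + offs[None, :] * uy[:, None])
        else:
            # equiangular: rotate the central direction by the fan angle
            cosf, sinf = np.cos(offs), np.sin(offs)
            dirx = cosf[None, :] * cx[:, None] + sinf[None, :] * ux[:, None]
            diry = cosf[None, :] * cy[:, None] + sinf[None, :] * uy[:, None]
            ex = srcx[:, None] + g.sod * dirx
            ey = srcy[:, None] + g.sod * diry
        sx = np.broadcast_to(srcx[:, None], ex.shape)
        sy = np.broadcast_to(srcy[:, None], ey.shape)
        return (
            np.ascontiguousarray(sx, dtype=np.float64).ravel(),
            np.ascontiguousarray(sy, dtype=np.float64).ravel(),
            ex.astype(np.float64).ravel(),
            ey.astype(np.float64).ravel(),
        )

    def _build(self) -> None:
        if self._A is not None:
            return
        g = self.geometry
        sx, sy, ex, ey = self._ray_endpoints()
        max_nnz = g.J * (g.nx + g.ny + 3)
        rows = np.empty(max_nnz, dtype=np.int64)
        cols = np.empty(max_nnz, dtype=np.int64)
        vals = np.empty(max_nnz, dtype=np.float64)
        nnz = _siddon_rays(
            sx, sy, ex, ey, g.nx, g.ny, float(g.pixel_size), rows, cols, vals
        )
        A = sparse.csr_matrix(
            (vals[:nnz], (rows[:nnz], cols[:nnz])), shape=(g.J, g.n_pixels)
        )
        self._A = A
        self._AT = A.T.tocsr()

    @property
    def matrix(self) -> sparse.csr_matrix:
        """The cached sparse intersection-length matrix (J x I)."""
        self._build()
        return self._A

    # -- operator interface ------------------------------------------------
    def project(self, image: np.ndarray) -> np.ndarray:
        """Forward projection: (ny, nx) image -> J sinogram (value * cm)."""
        g = self.geometry
        img = np.asarray(image, dtype=float)
        if img.shape == (g.ny, g.nx):
            flat = img.ravel()
        elif img.shape == (g.n_pixels,):
            flat = img
        else:
            raise ValueError(
                f"image shape {img.shape} does not match ({g.ny}, {g.nx})"
            )
        self._build()
        return self._A @ flat

    def backproject(self, sino: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`project`; returns an (ny, nx) image."""
        g = self.geometry
        s = np.asarray(sino, dtype=float).ravel()
        if s.size != g.J:
            raise ValueError(f"sinogram length {s.size} != J = {g.J}")
        self._build()
        return (self._AT @ s).reshape(g.ny, g.nx)

    def abs_row_sums(self) -> np.ndarray:
        """|A| 1 per ray; equals project(ones) since a_ji >= 0."""
        g = self.geometry
        return self.project(np.ones((g.ny, g.nx)))

    def abs_col_sums(self) -> np.ndarray:
        """|A^T| 1 per pixel; equals backproject(ones)."""
        g = self.geometry
        return self.backproject(np.ones(g.J))


def build_projector(geometry: FanBeamGeometry) -> RayOperator:
    """Construct the fan-beam x-ray transform for ``geometry`` (lazy rows)."""
    return RayOperator(geometry)


def operator_norm(
    apply,
    adjoint_apply,
    shape: tuple,
    iters: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
) -> float:
    """Largest singular value of a matched linear operator pair.

    Power iteration on A^T A from a seeded random start; stops after
    ``iters`` iterations or when the estimate's relative change drops
    below ``tol``.
    """
    _, n = shape
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    nx_ = np.linalg.norm(x)
    if nx_ == 0:
        raise ValueError("degenerate start vector")
    x /= nx_
    est = 0.0
    for _ in range(iters):
        y = np.asarray(apply(x)).ravel()
        z = np.asarray(adjoint_apply(y)).ravel()
        nz = np.linalg.norm(z)
        if not np.isfinite(nz):
            raise FloatingPointError("power iteration produced non-finite values")
        if nz == 0:
            return 0.0
        new_est = np.sqrt(nz)
        x = z / nz
        if est > 0 and abs(new_est - est) <= tol * est:
            est = new_est
            break
        est = new_est
    return float(est)
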