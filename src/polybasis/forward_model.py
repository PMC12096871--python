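"""The polychromatic nonlinear data model, its linearization, and the
nonlinearity residual.

Model data for ray j:

    g_j(b') = -ln sum_m q_jm exp(-sum_k mu_km t_jk),

where t_jk (g/cm^2) is the path length of material k along ray j, obtained by
forward-projecting the per-material basis images assembled from the
basis-region image b'.  Linearizing at an expansion point bbar' gives the
J x N_b Jacobian H(bbar') whose action is a spectrum-weighted projection
with per-ray effective weights

    w_jk(bbar') = sum_m mu_km N_jm(bbar') / sum_m N_jm(bbar'),

and the nonlinearity residual Delta g = g'(b') - H(bbar') b', so that
g' = H b' + Delta g holds exactly by construction.  For a monochromatic
spectrum w_jk = mu_k exactly and Delta g vanishes identically.

All operators here are matrix-free in b'; the only stored dense object is the
J x K effective-weight array.  The log-sum over energy bins is computed as a
shifted log-sum-exp so that long metal paths cannot underflow.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RayOperator
from .materials import MaterialSet, Spectrum
from .regions import BasisRegionPartition

__all__ = [
    "PolyForwardModel",
    "material_path_lengths",
    "poly_project",
    "effective_weights",
    "linearized_apply",
    "linearized_adjoint",
    "delta_g",
    "h_abs_row_sums",
    "h_abs_col_sums",
]


def _dot_rows(t: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise contraction sum_k t_jk w_jk with a fixed summation order.

    Used for every reduction over the material index so that algebraically
    equal quantities (e.g. g' and H b' in the monochromatic case) are equal
    bitwise.
    """
    out = t[:, 0] * w[:, 0]
    for k in range(1, t.shape[1]):
        out = out + t[:, k] * w[:, k]
    return out


@dataclass
class PolyForwardModel:
    """Bundles the x-ray transform, partition, spectrum and mu tables.

    The spectrum and material set must share one working energy grid.
    """

    system: RayOperator
    partition: BasisRegionPartition
    spectrum: Spectrum
    mus: MaterialSet
    _t_ones: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.spectrum.grid.M != self.mus.grid.M or not np.allclose(
            self.spectrum.grid.energies, self.mus.grid.energies
        ):
            raise ValueError("spectrum and material set must share one energy grid")
        if self.partition.K != self.mus.K:
            raise ValueError(
                f"partition indexes {self.partition.K} materials, "
                f"material set has {self.mus.K}"
            )
        g = self.system.geometry
        if (g.ny, g.nx) != self.partition.shape:
            raise ValueError("geometry image grid does not match partition")

    # -- shapes ------------------------------------------------------------
    @property
    def J(self) -> int:
        return self.system.geometry.J

    @property
    def K(self) -> int:
        return self.mus.K

    @property
    def N_b(self) -> int:
        return self.partition.N_b

    # -- path lengths ------------------------------------------------------
    def _full_stack(self, bprime: np.ndarray) -> np.ndarray:
        """Assembled basis images as an (I, K) dense stack."""
        b = np.asarray(bprime, dtype=float).ravel()
        if b.size != self.N_b:
            raise ValueError(f"b' length {b.size} != N_b = {self.N_b}")
        part = self.partition
        out = np.zeros((part.n_pixels, self.K))
        for l, k, sl in part.blocks():
            out[part.region_pixels[l], k] += b[sl]
        return out

    def path_lengths(self, bprime: np.ndarray) -> np.ndarray:
        """t_jk = [A b_k]_j for every material, as one J x K array (g/cm^2)."""
        return self.system.matrix @ self._full_stack(bprime)

    # -- nonlinear model ---------------------------------------------------
    def _line_integrals(self, t: np.ndarray) -> np.ndarray:
        """s_jm = sum_k mu_km t_jk (J x M), fixed summation order over k."""
        mu = self.mus.mu  # K x M
        s = t[:, 0:1] * mu[0][np.newaxis, :]
        for k in range(1, self.K):
            s = s + t[:, k : k + 1] * mu[k][np.newaxis, :]
        return s

    def g_from_t(self, t: np.ndarray) -> np.ndarray:
        """g_j = -ln sum_m q_jm exp(-s_jm) via a shifted log-sum-exp."""
        s = self._line_integrals(t)
        smin = s.min(axis=1, keepdims=True)
        acc = np.sum(self.spectrum.q * np.exp(smin - s), axis=-1)
        return smin[:, 0] - np.log(acc)

    def project(self, bprime: np.ndarray) -> np.ndarray:
        """The nonlinear data model g'(b') (J post-log values)."""
        return self.g_from_t(self.path_lengths(bprime))

    # -- linearization -----------------------------------------------------
    def weights_from_t(self, t: np.ndarray) -> np.ndarray:
        """Effective weights w_jk = sum_m mu_km N_jm / sum_m N_jm (J x K)."""
        s = self._line_integrals(t)
        smin = s.min(axis=1, keepdims=True)
        e = self.spectrum.q * np.exp(smin - s)
        p = e / e.sum(axis=-1, keepdims=True)
        # w = p @ mu^T with sequential accumulation over m
        mu = self.mus.mu
        w = np.zeros((t.shape[0], self.K))
        for m in range(mu.shape[1]):
            w = w + p[:, m : m + 1] * mu[:, m][np.newaxis, :]
        return w

    def weights(self, bbar_prime: np.ndarray) -> np.ndarray:
        return self.weights_from_t(self.path_lengths(bbar_prime))

    def H_apply_t(self, t_x: np.ndarray, w: np.ndarray) -> np.ndarray:
        """[H x]_j from precomputed path lengths of x."""
        return _dot_rows(t_x, w)

    def H_apply(self, x: np.ndarray, w: np.ndarray) -> np.ndarray:
        """H(bbar') x, with w the effective weights at bbar'."""
        return _dot_rows(self.path_lengths(x), w)

    def H_adjoint(self, y: np.ndarray, w: np.ndarray) -> np.ndarray:
        """H(bbar')^T y as a congregated N_b vector."""
        y = np.asarray(y, dtype=float).ravel()
        if y.size != self.J:
            raise ValueError(f"sinogram length {y.size} != J = {self.J}")
        z = self.system.matrix.T @ (w * y[:, np.newaxis])  # (I, K)
        part = self.partition
        out = np.empty(self.N_b)
        for l, k, sl in part.blocks():
            out[sl] = z[part.region_pixels[l], k]
        return out

    def H_adjoint_with_colsums(self, y: np.ndarray, w: np.ndarray) -> tuple:
        """(H^T y, |H^T| 1) in one pass over the sparse rows.

        Column c of a sparse-times-dense product is computed exactly as the
        corresponding matrix-vector product, so both outputs equal their
        one-column counterparts bitwise.
        """
        y = np.asarray(y, dtype=float).ravel()
        K = self.K
        Y = np.empty((self.J, 2 * K))
        Y[:, :K] = w * y[:, np.newaxis]
        Y[:, K:] = w
        Z = self.system.matrix.T @ Y
        part = self.partition
        hty = np.empty(self.N_b)
        colsums = np.empty(self.N_b)
        for l, k, sl in part.blocks():
            hty[sl] = Z[part.region_pixels[l], k]
            colsums[sl] = Z[part.region_pixels[l], K + k]
        return hty, colsums

    def delta_g_from_t(self, t: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Delta g = g'(b') - H(bbar') b' given path lengths of b'."""
        return self.g_from_t(t) - _dot_rows(t, w)

    def delta_g(self, bprime: np.ndarray, w: np.ndarray) -> np.ndarray:
        return self.delta_g_from_t(self.path_lengths(bprime), w)

    # -- absolute row/col sums of H ---------------------------------------
    def _ones_path_lengths(self) -> np.ndarray:
        if self._t_ones is None:
            part = self.partition
            stack = np.zeros((part.n_pixels, self.K))
            for l, k, _ in part.blocks():
                stack[part.region_pixels[l], k] = 1.0
            self._t_ones = self.system.matrix @ stack
        return self._t_ones

    def h_row_sums(self, w: np.ndarray) -> np.ndarray:
        """|H| 1 = H 1 (J,), valid since w >= 0 and a_ji >= 0."""
        return _dot_rows(self._ones_path_lengths(), w)

    def h_col_sums(self, w: np.ndarray) -> np.ndarray:
        """|H^T| 1 = H^T 1 (N_b,)."""
        return self.H_adjoint(np.ones(self.J), w)


# ---------------------------------------------------------------------------
# functional surface

def material_path_lengths(bprime, system, partition, spectrum, mus) -> np.ndarray:
    """Per-material path lengths t (J x K, g/cm^2) of a basis-region image."""
    return PolyForwardModel(system, partition, spectrum, mus).path_lengths(bprime)


def poly_project(bprime, system, partition, spectrum, mus) -> np.ndarray:
    """The polychromatic data model g'(b') (J,)."""
    return PolyForwardModel(system, partition, spectrum, mus).project(bprime)


def effective_weights(bbar_prime, system, partition, spectrum, mus) -> np.ndarray:
    """Effective weights of the linearization at bbar' (J x K, cm^2/g)."""
    return PolyForwardModel(system, partition, spectrum, mus).weights(bbar_prime)


def linearized_apply(x, weights, system, partition, spectrum, mus) -> np.ndarray:
    """H(bbar') x for precomputed effective weights."""
    return PolyForwardModel(system, partition, spectrum, mus).H_apply(x, weights)


def linearized_adjoint(y, weights, system, partition, spectrum, mus) -> np.ndarray:
    """H(bbar')^T y for precomputed effective weights."""
    return PolyForwardModel(system, partition, spectrum, mus).H_adjoint(y, weights)


def delta_g(bprime, bbar_prime, system, partition, spectrum, mus) -> np.ndarray:
    """Nonlinearity residual Delta g(b', bbar') = g'(b') - H(bbar') b'."""
    model = PolyForwardModel(system, partition, spectrum, mus)
    w = model.weights(bbar_prime)
    return model.delta_g(bprime, w)


def h_abs_row_sums(weights, system, partition, spectrum, mus) -> np.ndarray:
    return PolyForwardModel(system, partition, spectrum, mus).h_row_sums(weights)


def h_abs_col_sums(weights, system, partition, spectrum, mus) -> np.ndarray:
    return PolyForwardModel(system, partition, spectrum, mus).h_col_sums(weights)
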