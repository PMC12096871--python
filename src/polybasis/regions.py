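"""Basis-region bookkeeping: partitions, restriction/embedding, basis-image
assembly, VMI synthesis, and the volume-conservation (VC) constraint.

The image array is partitioned into L basis regions; region l is assumed to
contain a known set Phi_l of at most two basis materials, and each region's
material set is unique.  The unknowns actually solved for are the
"basis-region image" b': per-region, per-material pixel values, congregated
into one vector of length N_b = sum_l K_l I_l <= 2 I.

Congregated ordering (fixed convention): blocks by region index l ascending,
then by material order within Phi_l.  Labels use 1..L; 0 means "unassigned"
and is rejected by validation, making partition errors explicit.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import MaterialSet

__all__ = [
    "BasisRegionPartition",
    "validate_partition",
    "restrict",
    "embed",
    "assemble_basis_images",
    "compute_vmi",
    "vc_residual",
    "to_hounsfield",
]


@dataclass(frozen=True)
class BasisRegionPartition:
    """A validated basis-region partition with cached derived structure.

    Attributes
    ----------
    labels : (ny, nx) int array with values in 1..L (every pixel labeled).
    phi : tuple of per-region material-index tuples Phi_l (0-based, ordered).
    psi_vc : tuple of region indices (0-based) under the VC constraint.
    K : total number of basis materials indexable by phi.
    region_pixels : per-region flat pixel-index arrays (row-major).
    offsets : per-(l, k-slot) start offsets into the congregated vector.
    """

    labels: np.ndarray
    phi: tuple
    psi_vc: tuple
    K: int
    region_pixels: tuple = field(init=False)
    block_offsets: tuple = field(init=False)
    N_b: int = field(init=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        L = len(self.phi)
        pixels = []
        for l in range(L):
            idx = np.flatnonzero(labels.ravel() == l + 1)
            pixels.append(idx)
        offsets = []
        off = 0
        for l in range(L):
            row = []
            for _ in self.phi[l]:
                row.append(off)
                off += pixels[l].size
            offsets.append(tuple(row))
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "region_pixels", tuple(pixels))
        object.__setattr__(self, "block_offsets", tuple(offsets))
        object.__setattr__(self, "N_b", off)

    @property
    def L(self) -> int:
        return len(self.phi)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def n_pixels(self) -> int:
        return int(self.labels.size)

    def I_l(self, l: int) -> int:
        return int(self.region_pixels[l].size)

    def psi_k(self, k: int) -> list:
        """Regions (0-based) containing material k."""
        return [l for l in range(self.L) if k in self.phi[l]]

    def block(self, l: int, k: int) -> slice:
        """Slice of the congregated vector for region l, material k."""
        slot = self.phi[l].index(k)
        off = self.block_offsets[l][slot]
        return slice(off, off + self.I_l(l))

    def blocks(self):
        """Iterate (l, k, slice) over all blocks in congregated order."""
        for l in range(self.L):
            for slot, k in enumerate(self.phi[l]):
                off = self.block_offsets[l][slot]
                yield l, k, slice(off, off + self.I_l(l))


def validate_partition(
    labels: np.ndarray, phi, psi_vc, K: int
) -> BasisRegionPartition:
    """Validate a label map + region scheme and build the partition.

    ``labels`` holds region ids 1..L; ``phi`` lists, per region, the 0-based
    material indices present (at most two, unique set per region); ``psi_vc``
    lists the 0-based region indices subject to volume conservation (these
    must be two-material regions).
    """
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("labels must be an integer array")
    phi = tuple(tuple(int(k) for k in row) for row in phi)
    psi_vc = tuple(int(l) for l in psi_vc)
    L = len(phi)
    if L < 1:
        raise ValueError("need at least one basis region")
    present = np.unique(labels)
    if present.min() < 1 or present.max() > L:
        bad = present[(present < 1) | (present > L)]
        raise ValueError(
            f"labels contain values {bad.tolist()} outside 1..{L} "
            "(0 means unassigned)"
        )
    for l, mats in enumerate(phi):
        if not 1 <= len(mats) <= 2:
            raise ValueError(f"region {l + 1}: need 1 or 2 materials, got {len(mats)}")
        if len(set(mats)) != len(mats):
            raise ValueError(f"region {l + 1}: duplicate material index")
        for k in mats:
            if not 0 <= k < K:
                raise ValueError(f"region {l + 1}: material index {k} outside 0..{K - 1}")
        if np.count_nonzero(labels == l + 1) == 0:
            raise ValueError(f"region {l + 1} has no pixels")
    sets = [frozenset(m) for m in phi]
    if len(set(sets)) != len(sets):
        raise ValueError("each basis region must have a unique material set")
    for l in psi_vc:
        if not 0 <= l < L:
            raise ValueError(f"VC region index {l} out of range")
        if len(phi[l]) != 2:
            raise ValueError(
                f"VC constraint applies only to two-material regions; "
                f"region {l + 1} has {len(phi[l])}"
            )
    part = BasisRegionPartition(labels, phi, psi_vc, int(K))
    assert part.N_b <= 2 * part.n_pixels
    return part


def restrict(full_image: np.ndarray, partition: BasisRegionPartition, l: int) -> np.ndarray:
    """R'_l applied to a full image: the I_l pixel values of region l."""
    img = np.asarray(full_image, dtype=float)
    if img.size != partition.n_pixels:
        raise ValueError("image size does not match partition")
    return img.ravel()[partition.region_pixels[l]]


def embed(region_values: np.ndarray, partition: BasisRegionPartition, l: int) -> np.ndarray:
    """R'_l^T applied to region values: a full image, zero outside region l."""
    v = np.asarray(region_values, dtype=float)
    if v.size != partition.I_l(l):
        raise ValueError(
            f"region {l} expects {partition.I_l(l)} values, got {v.size}"
        )
    out = np.zeros(partition.n_pixels)
    out[partition.region_pixels[l]] = v
    return out.reshape(partition.shape)


def assemble_basis_images(
    bprime: np.ndarray, partition: BasisRegionPartition
) -> np.ndarray:
    """Assemble full-array basis images b_k = sum_{l in Psi_k} R'_l^T b'_lk.

    Returns a (K, ny, nx) stack; b_k is zero outside the regions listing
    material k.
    """
    b = np.asarray(bprime, dtype=float).ravel()
    if b.size != partition.N_b:
        raise ValueError(f"b' length {b.size} != N_b = {partition.N_b}")
    ny, nx = partition.shape
    out = np.zeros((partition.K, ny * nx))
    for l, k, sl in partition.blocks():
        out[k, partition.region_pixels[l]] += b[sl]
    return out.reshape(partition.K, ny, nx)


def compute_vmi(
    bprime: np.ndarray,
    partition: BasisRegionPartition,
    mus: MaterialSet,
    m: int,
) -> np.ndarray:
    """Virtual monochromatic image at energy-bin index m (1/cm):
    f'_m = sum_l sum_{k in Phi_l} mu_km R'_l^T b'_lk."""
    if not 0 <= m < mus.grid.M:
        raise ValueError(f"energy bin {m} outside 0..{mus.grid.M - 1}")
    b = np.asarray(bprime, dtype=float).ravel()
    if b.size != partition.N_b:
        raise ValueError(f"b' length {b.size} != N_b = {partition.N_b}")
    out = np.zeros(partition.n_pixels)
    for l, k, sl in partition.blocks():
        out[partition.region_pixels[l]] += mus.mu[k, m] * b[sl]
    return out.reshape(partition.shape)


def vc_residual(
    bprime: np.ndarray,
    partition: BasisRegionPartition,
    lc: int,
    densities: np.ndarray,
) -> np.ndarray:
    """Per-pixel volume-conservation residual in region lc:
    sum_{k in Phi_lc} b'_lc,k / rho_k - 1 (dimensionless; 0 iff volume
    fractions sum to one)."""
    if lc not in partition.psi_vc:
        raise ValueError(f"region {lc} is not VC-constrained")
    b = np.asarray(bprime, dtype=float).ravel()
    rho = np.asarray(densities, dtype=float)
    res = -np.ones(partition.I_l(lc))
    for k in partition.phi[lc]:
        res += b[partition.block(lc, k)] / rho[k]
    return res


def to_hounsfield(vmi: np.ndarray, mu_water_m: float) -> np.ndarray:
    """Convert a VMI (1/cm) to Hounsfield units at the same energy."""
    if mu_water_m <= 0:
        raise ValueError("water attenuation must be positive")
    return 1000.0 * (np.asarray(vmi, dtype=float) - mu_water_m) / mu_water_m
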