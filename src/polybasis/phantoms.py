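"""Synthetic phantoms, simulated sinograms, and truth-derived TV bounds.

Two generators emulate the study objects:

* :func:`make_chest_like` -- a digital chest-like phantom: water body with
  air lungs, bone spine/ribs, iodine-solution vessels, a titanium implant and
  (in the full scheme) a stainless-steel needle; basis regions follow the
  air/water, water/bone, water/iodine, titanium, air/steel scheme with water
  spanning the first three regions.
* :func:`make_de_disk` -- a dual-energy-style disk phantom: a water disk with
  iodine- and calcium-solution inserts at known concentrations plus air
  holes, partitioned into water/calcium, water/iodine, and air/water regions.

Insert concentrations map to VOLUME fractions of the reference-concentration
basis material (c mg/ml -> fraction c/c_ref of the reference solution and
1 - c/c_ref water), so every truth pixel satisfies the volume-conservation
constraint exactly.  Phantom primitive coordinates are analogous to, never
identical with, any published object.

Noise model: Poisson counts on the transmitted intensity, N ~ Poisson(N0
exp(-g)), then g = ln(N0 / N); zero sampled counts are clamped to one count
and logged.  Real-data inconsistencies (scatter, spectrum error) are not
simulated.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .forward_model import PolyForwardModel
from .geometry import RayOperator
from .materials import MaterialSet, Spectrum, load_fixture_material
from .regions import (
    BasisRegionPartition,
    assemble_basis_images,
    compute_vmi,
    validate_partition,
)
from .tv import isotropic_tv

__all__ = ["TruthBundle", "make_chest_like", "make_de_disk", "simulate_sinogram", "tv_params_from_truth"]

logger = logging.getLogger(__name__)

CHEST_MATERIALS_FULL = ("air", "water", "bone_cortical", "iodine_solution_20mgml", "titanium", "steel")
CHEST_MATERIALS_REDUCED = CHEST_MATERIALS_FULL[:5]
DE_DISK_MATERIALS = ("air", "water", "calcium_solution_600mgml", "iodine_solution_20mgml")


@dataclass(frozen=True)
class TruthBundle:
    """Ground truth for a synthetic study: partition, b', materials."""

    partition: BasisRegionPartition
    bprime: np.ndarray
    material_names: tuple
    pixel_cm: float
    insert_truth: tuple = ()  # (label, material_name, mg_per_ml, mask) records

    def basis_images(self) -> np.ndarray:
        """Truth basis images b_k as a (K, ny, nx) stack (g/cm^3)."""
        return assemble_basis_images(self.bprime, self.partition)

    def material_set(self, grid) -> MaterialSet:
        """Fixture materials of this phantom sampled on ``grid``."""
        mats = [load_fixture_material(n) for n in self.material_names]
        return MaterialSet(tuple(mats), grid)


def _ellipse_mask(ny, nx, cx, cy, ax, ay):
    """Boolean mask of an axis-aligned ellipse given in unit coordinates."""
    yy, xx = np.mgrid[0:ny, 0:nx]
    u = (xx + 0.5) / nx
    v = (yy + 0.5) / ny
    return ((u - cx) / ax) ** 2 + ((v - cy) / ay) ** 2 <= 1.0


def _rect_mask(ny, nx, x0, x1, y0, y1):
    yy, xx = np.mgrid[0:ny, 0:nx]
    u = (xx + 0.5) / nx
    v = (yy + 0.5) / ny
    return (u >= x0) & (u <= x1) & (v >= y0) & (v <= y1)


def _mixture_bprime(partition: BasisRegionPartition, fractions: dict, densities: np.ndarray) -> np.ndarray:
    """Build a truth b' from per-pixel volume fractions.

    ``fractions`` maps material index k to an (ny, nx) array of volume
    fractions; within every region the fractions of its materials sum to one,
    so the VC constraint holds exactly by construction.
    """
    b = np.zeros(partition.N_b)
    for l, k, sl in partition.blocks():
        frac = fractions[k].ravel()[partition.region_pixels[l]]
        b[sl] = frac * densities[k]
    return b


def make_chest_like(
    nx: int = 256,
    ny: int = 200,
    pixel_cm: float = 0.14,
    seed: int = 0,
    scheme: str = "full",
) -> TruthBundle:
    """Digital chest-like phantom.

    ``scheme="full"`` gives 6 materials / 5 regions (air-water, water-bone,
    water-iodine, titanium, air-steel); ``scheme="reduced"`` drops the steel
    needle (5 materials / 4 regions).  The VC constraint is applied to every
    two-material region.
    """
    if min(nx, ny) < 32:
        raise ValueError("grid must be at least 32x32")
    if scheme not in ("full", "reduced"):
        raise ValueError("scheme must be 'full' or 'reduced'")
    rng = np.random.default_rng(seed)
    names = CHEST_MATERIALS_FULL if scheme == "full" else CHEST_MATERIALS_REDUCED
    densities = np.array([load_fixture_material(n).density for n in names])
    AIR, WATER, BONE, IODINE, TITAN = 0, 1, 2, 3, 4

    body = _ellipse_mask(ny, nx, 0.5, 0.52, 0.44, 0.40)
    lungs = _ellipse_mask(ny, nx, 0.34, 0.45, 0.13, 0.18) | _ellipse_mask(
        ny, nx, 0.66, 0.45, 0.13, 0.18
    )
    spine = _ellipse_mask(ny, nx, 0.5, 0.80, 0.065, 0.07)
    ribs = np.zeros((ny, nx), dtype=bool)
    for ang in np.linspace(0.25, 0.75, 6) * np.pi + rng.uniform(-0.02, 0.02, 6):
        cx = 0.5 + 0.38 * np.cos(ang)
        cy = 0.52 - 0.33 * np.sin(ang)
        ribs |= _ellipse_mask(ny, nx, cx, cy, 0.022, 0.028)
    bone = (spine | ribs) & body
    bone_region = ndimage.binary_dilation(bone, iterations=2) & body

    vessels = [
        (_ellipse_mask(ny, nx, 0.50, 0.40, 0.035, 0.045), 1.0),
        (_ellipse_mask(ny, nx, 0.38, 0.63, 0.030, 0.038), 0.5),
        (_ellipse_mask(ny, nx, 0.62, 0.63, 0.030, 0.038), 0.25),
    ]
    iodine_mask = np.zeros((ny, nx), dtype=bool)
    for m, _ in vessels:
        iodine_mask |= m
    iodine_region = ndimage.binary_dilation(iodine_mask, iterations=2) & body & ~bone_region

    titan = _ellipse_mask(ny, nx, 0.50, 0.655, 0.020, 0.026) & body

    labels = np.ones((ny, nx), dtype=np.int32)  # region 1: air/water
    labels[bone_region] = 2
    labels[iodine_region] = 3
    labels[titan] = 4

    phi = [(AIR, WATER), (WATER, BONE), (WATER, IODINE), (TITAN,)]
    psi_vc = [0, 1, 2]

    if scheme == "full":
        STEEL = 5
        needle = _rect_mask(ny, nx, 0.70, 0.88, 0.285, 0.305) & body
        needle_region = ndimage.binary_dilation(needle, iterations=1) & body
        labels[needle_region & ~titan] = 5
        needle = needle & (labels == 5)
        phi.append((AIR, STEEL))
        psi_vc.append(4)

    K = len(names)
    fractions = {k: np.zeros((ny, nx)) for k in range(K)}
    water_frac = (body & ~lungs).astype(float)
    fractions[WATER] = water_frac
    fractions[AIR] = 1.0 - water_frac  # complement inside region 1
    fractions[BONE][bone] = 1.0
    fractions[WATER] = np.where(bone, 0.0, fractions[WATER])
    for mask, f in vessels:
        fractions[IODINE][mask] = f
        fractions[WATER][mask] = 1.0 - f
    fractions[TITAN][titan] = 1.0
    if scheme == "full":
        fractions[STEEL][needle] = 1.0
        fractions[AIR] = np.where((labels == 5) & ~needle, 1.0, fractions[AIR])
        fractions[AIR][needle] = 0.0
        fractions[WATER][labels == 5] = 0.0
    # inside bone/iodine regions the complement material is water
    fractions[WATER] = np.where(bone_region & ~bone, 1.0, fractions[WATER])
    fractions[WATER] = np.where(iodine_region & ~iodine_mask, 1.0, fractions[WATER])

    part = validate_partition(labels, phi, psi_vc, K)
    b = _mixture_bprime(part, fractions, densities)
    inserts = tuple(
        (f"vessel{i}", "iodine_solution_20mgml", 20.0 * f, m)
        for i, (m, f) in enumerate(vessels)
    )
    return TruthBundle(part, b, tuple(names), float(pixel_cm), inserts)


def make_de_disk(
    n_iodine: int = 7,
    n_calcium: int = 7,
    iodine_mgml=(2.0, 2.5, 5.0, 7.5, 10.0, 15.0, 20.0),
    calcium_mgml=(50.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0),
    seed: int = 0,
    nx: int = 512,
    ny: int = 512,
    pixel_cm: float = 0.08,
    n_air: int = 8,
) -> TruthBundle:
    """Dual-energy-style disk phantom with iodine/calcium inserts and air holes.

    Reference bases are the 20 mg/ml iodine and 600 mg/ml calcium solutions;
    an insert at c mg/ml is the volume mixture c/c_ref reference solution +
    (1 - c/c_ref) water.
    """
    if min(nx, ny) < 32:
        raise ValueError("grid must be at least 32x32")
    iodine_mgml = tuple(float(c) for c in iodine_mgml)[:n_iodine]
    calcium_mgml = tuple(float(c) for c in calcium_mgml)[:n_calcium]
    if any(c > 20.0 for c in iodine_mgml):
        raise ValueError("iodine concentration above the 20 mg/ml reference basis")
    if any(c > 600.0 for c in calcium_mgml):
        raise ValueError("calcium concentration above the 600 mg/ml reference basis")
    names = DE_DISK_MATERIALS
    densities = np.array([load_fixture_material(n).density for n in names])
    AIR, WATER, CALC, IOD = 0, 1, 2, 3

    disk = _ellipse_mask(ny, nx, 0.5, 0.5, 0.43, 0.43)
    r_ins = 0.035

    def ring(n, radius, phase):
        out = []
        for i in range(n):
            a = 2 * np.pi * i / max(n, 1) + phase
            out.append((0.5 + radius * np.cos(a), 0.5 + radius * np.sin(a)))
        return out

    calc_masks = [
        _ellipse_mask(ny, nx, cx, cy, r_ins, r_ins) for cx, cy in ring(len(calcium_mgml), 0.30, 0.0)
    ]
    iod_masks = [
        _ellipse_mask(ny, nx, cx, cy, r_ins, r_ins)
        for cx, cy in ring(len(iodine_mgml), 0.155, np.pi / 7)
    ]
    air_masks = [
        _ellipse_mask(ny, nx, cx, cy, 0.018, 0.018) for cx, cy in ring(n_air, 0.385, np.pi / 8)
    ]

    calc_region = np.zeros((ny, nx), dtype=bool)
    for m in calc_masks:
        calc_region |= ndimage.binary_dilation(m, iterations=2)
    iod_region = np.zeros((ny, nx), dtype=bool)
    for m in iod_masks:
        iod_region |= ndimage.binary_dilation(m, iterations=2)
    iod_region &= ~calc_region

    labels = np.full((ny, nx), 3, dtype=np.int32)  # region 3: air/water
    labels[calc_region] = 1
    labels[iod_region] = 2
    phi = ((WATER, CALC), (WATER, IOD), (AIR, WATER))
    psi_vc = (0, 1, 2)

    fractions = {k: np.zeros((ny, nx)) for k in range(4)}
    fractions[WATER] = disk.astype(float)
    fractions[AIR] = 1.0 - fractions[WATER]
    inserts = []
    for i, (c, m) in enumerate(zip(calcium_mgml, calc_masks)):
        f = c / 600.0
        fractions[CALC][m] = f
        fractions[WATER][m] = 1.0 - f
        inserts.append((f"calcium{i}", names[CALC], c, m))
    for i, (c, m) in enumerate(zip(iodine_mgml, iod_masks)):
        f = c / 20.0
        fractions[IOD][m] = f
        fractions[WATER][m] = 1.0 - f
        inserts.append((f"iodine{i}", names[IOD], c, m))
    for m in air_masks:
        fractions[AIR][m] = 1.0
        fractions[WATER][m] = 0.0

    part = validate_partition(labels, phi, psi_vc, len(names))
    b = _mixture_bprime(part, fractions, densities)
    return TruthBundle(part, b, names, float(pixel_cm), tuple(inserts))


def simulate_sinogram(
    truth: TruthBundle,
    system: RayOperator,
    spectrum: Spectrum,
    mus: MaterialSet,
    n0_photons: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Simulate conventional (post-log) data from the truth basis-region image.

    ``n0_photons=None`` (or inf) returns the noiseless model data; otherwise
    Poisson noise is applied to transmitted counts with N0 photons per ray.
    """
    model = PolyForwardModel(system, truth.partition, spectrum, mus)
    g = model.project(truth.bprime)
    if n0_photons is None or np.isinf(n0_photons):
        return g
    if n0_photons <= 0:
        raise ValueError("n0_photons must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(n0_photons * np.exp(-g)).astype(float)
    n_zero = int(np.count_nonzero(counts == 0))
    if n_zero:
        logger.warning("clamped %d zero-count rays to one count", n_zero)
        counts = np.maximum(counts, 1.0)
    return np.log(n0_photons / counts)


def tv_params_from_truth(
    truth: TruthBundle, mus: MaterialSet, m1: int, m2: int
) -> tuple:
    """Isotropic TV of the truth VMIs at energy bins m1, m2 (gamma bounds)."""
    g1 = isotropic_tv(compute_vmi(truth.bprime, truth.partition, mus, m1))
    g2 = isotropic_tv(compute_vmi(truth.bprime, truth.partition, mus, m2))
    return g1, g2
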