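"""Post-reconstruction quantification: ROI statistics, iodine-concentration
estimation, LAC-vs-energy curves, and image-error metrics.

Conventions: ROI standard deviations are POPULATION SDs (divide by n).
Iodine concentration uses an affine map c = a*b + d on the iodine-basis
pixel values; the default calibration anchors the reference basis
(a = c_ref / rho_ref, d = 0), so a pixel equal to the reference-solution
density reads exactly the reference concentration.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import MaterialSet
from .regions import BasisRegionPartition, compute_vmi

__all__ = ["ROI", "disk_roi", "nrmse", "roi_stats", "iodine_concentration", "lac_curve"]


@dataclass(frozen=True)
class ROI:
    """A labeled region of interest: boolean mask + optional reference value."""

    label: str
    mask: np.ndarray
    reference: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"ROI {self.label!r} is empty")
        object.__setattr__(self, "mask", mask)


def disk_roi(
    label: str,
    shape: tuple,
    pixel_cm: float,
    center_cm: tuple,
    radius_cm: float,
    reference: float | None = None,
    units: str = "",
) -> ROI:
    """Disk ROI given in physical coordinates (origin at the image center)."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    x = (xx + 0.5 - nx / 2.0) * pixel_cm
    y = (yy + 0.5 - ny / 2.0) * pixel_cm
    mask = (x - center_cm[0]) ** 2 + (y - center_cm[1]) ** 2 <= radius_cm**2
    return ROI(label, mask, reference, units)


def nrmse(b: np.ndarray, truth: np.ndarray) -> float:
    """||b - truth||_2 / ||truth||_2 over concatenated basis images."""
    b = np.asarray(b, dtype=float)
    t = np.asarray(truth, dtype=float)
    if b.shape != t.shape:
        raise ValueError("shape mismatch")
    nt = np.linalg.norm(t)
    if nt == 0:
        raise ValueError("truth norm is zero")
    return float(np.linalg.norm(b - t) / nt)


def roi_stats(image: np.ndarray, roi: ROI) -> tuple:
    """(mean, population SD) of the image over the ROI pixels."""
    vals = np.asarray(image, dtype=float)[roi.mask]
    return float(vals.mean()), float(vals.std())


def iodine_concentration(
    iodine_basis_image: np.ndarray,
    roi: ROI,
    rho_ref: float,
    c_ref: float = 20.0,
    affine: tuple | None = None,
) -> tuple:
    """(mean mg/ml, SD, bias) of the iodine concentration over an ROI.

    Per-pixel c = a*b + d with default calibration (c_ref/rho_ref, 0); the
    bias is mean - roi.reference when a reference is attached, else None.
    """
    if rho_ref <= 0:
        raise ValueError("reference density must be positive")
    a, d = affine if affine is not None else (c_ref / rho_ref, 0.0)
    conc = a * np.asarray(iodine_basis_image, dtype=float) + d
    mean, sd = roi_stats(conc, roi)
    bias = mean - roi.reference if roi.reference is not None else None
    return mean, sd, bias


def lac_curve(
    bprime: np.ndarray,
    partition: BasisRegionPartition,
    mus: MaterialSet,
    roi: ROI,
    energy_bins,
) -> list:
    """[(E_keV, mean LAC 1/cm, SD), ...] from VMIs at the requested bins."""
    out = []
    for m in energy_bins:
        m = int(m)
        vmi = compute_vmi(bprime, partition, mus, m)
        mean, sd = roi_stats(vmi, roi)
        out.append((float(mus.grid.energies[m]), mean, sd))
    return out
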