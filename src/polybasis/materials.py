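"""Energy grids, x-ray spectra, and mass-attenuation tables.

The physics inputs of the polychromatic data model live here: a working
energy grid of bin centers (keV), a normalized spectrum q_m on that grid
(optionally per-ray), and per-material mass-attenuation tables mu/rho
(cm^2/g) with known densities rho_k (g/cm^3).  A ``MaterialSet`` samples all
tables onto a shared grid, producing the K x M matrix used by the forward
model and by virtual-monochromatic-image (VMI) synthesis.

Interpolation of mu/rho tables is linear in log(E)-log(mu/rho), the standard
convention for attenuation data away from K-edges; K-edge materials (iodine)
carry denser tabulation around the edge in the shipped fixtures.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "EnergyGrid",
    "Spectrum",
    "Material",
    "MaterialSet",
    "default_grid",
    "normalize_spectrum",
    "resample_material",
    "resample_spectrum",
    "make_toy_spectrum",
    "load_fixture_material",
    "load_fixture_spectrum",
    "list_fixture_materials",
]

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class EnergyGrid:
    """Strictly increasing energy-bin centers in keV."""

    energies: np.ndarray

    def __post_init__(self) -> None:
        e = np.atleast_1d(np.asarray(self.energies, dtype=float))
        if e.ndim != 1 or e.size < 1:
            raise ValueError("energy grid must be a non-empty 1-D array")
        if np.any(e <= 0):
            raise ValueError("energies must be positive")
        if e.size > 1 and np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        object.__setattr__(self, "energies", e)

    @property
    def M(self) -> int:
        return int(self.energies.size)

    def index_of(self, energy_kev: float) -> int:
        """Index of the bin center nearest to ``energy_kev``."""
        return int(np.argmin(np.abs(self.energies - float(energy_kev))))


def default_grid(e_min: float = 10.0, e_max: float = 150.0) -> EnergyGrid:
    """1-keV bin centers over [e_min, e_max], the diagnostic CT range."""
    return EnergyGrid(np.arange(float(e_min), float(e_max) + 0.5, 1.0))


@dataclass(frozen=True)
class Spectrum:
    """Normalized effective spectrum q_m on an energy grid.

    ``q`` is either shape (M,) shared by all rays, or (J, M) per ray.  Each
    ray's weights are nonnegative and sum to one within 1e-12.
    """

    grid: EnergyGrid
    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim == 1:
            q = q[np.newaxis, :] if False else q
        if q.shape[-1] != self.grid.M:
            raise ValueError(
                f"spectrum has {q.shape[-1]} bins but grid has {self.grid.M}"
            )
        if np.any(q < 0):
            raise ValueError("spectrum weights must be nonnegative")
        sums = q.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > _NORM_TOL):
            raise ValueError("spectrum weights must sum to 1 per ray")
        object.__setattr__(self, "q", q)

    @property
    def per_ray(self) -> bool:
        return self.q.ndim == 2


def normalize_spectrum(raw_weights: np.ndarray, grid: EnergyGrid) -> Spectrum:
    """Normalize raw fluence weights to unit sum; zero bins stay zero."""
    w = np.asarray(raw_weights, dtype=float)
    if w.shape[-1] != grid.M:
        raise ValueError("weight count does not match grid size")
    if np.any(w < 0):
        raise ValueError("spectrum weights must be nonnegative")
    s = w.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("at least one weight must be positive")
    return Spectrum(grid, w / s)


def resample_spectrum(spectrum: Spectrum, grid: EnergyGrid) -> Spectrum:
    """Linearly interpolate relative fluence onto ``grid`` and renormalize.

    Energies outside the source tabulation get zero fluence.
    """
    if spectrum.per_ray:
        raise ValueError("resampling of per-ray spectra is not supported")
    src_e = spectrum.grid.energies
    w = np.interp(grid.energies, src_e, spectrum.q, left=0.0, right=0.0)
    return normalize_spectrum(w, grid)


@dataclass(frozen=True)
class Material:
    """A basis material: name, density (g/cm^3), and mu/rho table (cm^2/g)."""

    name: str
    density: float
    table_energies: np.ndarray
    table_mu_over_rho: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.table_energies, dtype=float)
        m = np.asarray(self.table_mu_over_rho, dtype=float)
        if self.density <= 0:
            raise ValueError(f"material {self.name!r}: density must be positive")
        if e.ndim != 1 or e.shape != m.shape or e.size < 1:
            raise ValueError("mu/rho table must be two matching 1-D columns")
        if np.any(np.diff(e) <= 0):
            raise ValueError("table energies must be strictly increasing")
        if np.any(m <= 0):
            raise ValueError("mass attenuation values must be positive")
        object.__setattr__(self, "table_energies", e)
        object.__setattr__(self, "table_mu_over_rho", m)


def resample_material(material: Material, grid: EnergyGrid) -> np.ndarray:
    """Sample mu/rho (cm^2/g) onto ``grid``, log-log interpolated.

    Raises if the grid extends beyond the tabulated range.
    """
    e, m = material.table_energies, material.table_mu_over_rho
    g = grid.energies
    if g[0] < e[0] - 1e-9 or g[-1] > e[-1] + 1e-9:
        raise ValueError(
            f"grid [{g[0]:g}, {g[-1]:g}] keV outside table range "
            f"[{e[0]:g}, {e[-1]:g}] keV for material {material.name!r}"
        )
    out = np.exp(np.interp(np.log(g), np.log(e), np.log(m)))
    # snap exact node hits to the tabulated value (log/exp round-trip is
    # otherwise only accurate to a few ulp)
    idx = np.searchsorted(e, g)
    idx = np.clip(idx, 0, e.size - 1)
    hit = e[idx] == g
    out[hit] = m[idx[hit]]
    return out


@dataclass(frozen=True)
class MaterialSet:
    """Ordered basis materials sampled onto a shared working grid."""

    materials: tuple
    grid: EnergyGrid
    mu: np.ndarray = field(init=False)  # K x M linear-attenuation-per-density

    def __post_init__(self) -> None:
        mats = tuple(self.materials)
        if len(mats) < 1:
            raise ValueError("need at least one material")
        names = [m.name for m in mats]
        if len(set(names)) != len(names):
            raise ValueError("material names must be unique")
        mu = np.vstack([resample_material(m, self.grid) for m in mats])
        object.__setattr__(self, "materials", mats)
        object.__setattr__(self, "mu", mu)

    @property
    def K(self) -> int:
        return len(self.materials)

    @property
    def names(self) -> list:
        return [m.name for m in self.materials]

    @property
    def densities(self) -> np.ndarray:
        return np.array([m.density for m in self.materials])

    def index_of(self, name: str) -> int:
        return self.names.index(name)


def make_toy_spectrum(
    M: int, peak_keV: float, width_keV: float, grid: EnergyGrid | None = None
) -> Spectrum:
    """A normalized, unimodal (Gaussian-profile) stand-in spectrum.

    If ``grid`` is omitted, M 1-keV-spaced bins centered on ``peak_keV`` are
    used.  The profile peaks at the bin nearest ``peak_keV``.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if width_keV <= 0:
        raise ValueError("width must be positive")
    if grid is None:
        e0 = peak_keV - (M - 1) / 2.0
        grid = EnergyGrid(e0 + np.arange(M, dtype=float))
    if grid.M != M:
        raise ValueError("grid size does not match M")
    w = np.exp(-0.5 * ((grid.energies - peak_keV) / width_keV) ** 2)
    return normalize_spectrum(w, grid)


# ---------------------------------------------------------------------------
# file formats and shipped fixtures

def read_material_csv(path_or_buf) -> Material:
    """Read a material CSV: ``# name=``/``# density_g_per_cm3=`` metadata
    lines followed by ``energy_kev,mass_atten_cm2_per_g`` rows."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as f:
            text = f.read()
    name = None
    density = None
    energies, mus = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("#").strip().partition("=")
            if key.strip() == "name":
                name = val.strip()
            elif key.strip() == "density_g_per_cm3":
                density = float(val)
            continue
        if line.startswith("energy_kev"):
            continue
        e, m = line.split(",")
        energies.append(float(e))
        mus.append(float(m))
    if name is None or density is None:
        raise ValueError("material file missing name/density metadata")
    return Material(name, density, np.array(energies), np.array(mus))


def write_material_csv(path, material: Material) -> None:
    with open(path, "w") as f:
        f.write(f"# name={material.name}\n")
        f.write(f"# density_g_per_cm3={material.density:.6g}\n")
        f.write("energy_kev,mass_atten_cm2_per_g\n")
        for e, m in zip(material.table_energies, material.table_mu_over_rho):
            f.write(f"{e:g},{m:.6g}\n")


def read_spectrum_csv(path_or_buf) -> Spectrum:
    """Read a 2-column ``energy_kev,relative_fluence`` CSV and normalize."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as f:
            text = f.read()
    energies, w = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("energy_kev"):
            continue
        e, q = line.split(",")
        energies.append(float(e))
        w.append(float(q))
    grid = EnergyGrid(np.array(energies))
    return normalize_spectrum(np.array(w), grid)


def _fixture_text(filename: str) -> io.StringIO:
    ref = resources.files("polybasis.data").joinpath(filename)
    return io.StringIO(ref.read_text())


def list_fixture_materials() -> list:
    ref = resources.files("polybasis.data")
    return sorted(
        p.name[:-4]
        for p in ref.iterdir()
        if p.name.endswith(".csv") and not p.name.startswith("spectrum")
    )


def load_fixture_material(name: str) -> Material:
    """Load one of the shipped surrogate mu-table fixtures by name."""
    try:
        buf = _fixture_text(f"{name}.csv")
    except FileNotFoundError:
        raise KeyError(
            f"no fixture material {name!r}; available: {list_fixture_materials()}"
        ) from None
    return read_material_csv(buf)


def load_fixture_spectrum(name: str) -> Spectrum:
    """Load a shipped tabulated toy spectrum ('80kv' or '140kv')."""
    try:
        buf = _fixture_text(f"spectrum_{name}.csv")
    except FileNotFoundError:
        raise KeyError(f"no fixture spectrum {name!r}") from None
    return read_spectrum_csv(buf)
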