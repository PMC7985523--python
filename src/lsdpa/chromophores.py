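"""Wavelength-resolved optical properties of tissue constituents.

Absorption of whole blood is modeled as a linear mix of fully oxygenated and
fully deoxygenated hemoglobin at a reference concentration of 150 g/L; bulk
tissue absorption is the volume-fraction-weighted superposition of blood,
melanin, and water.  Reduced scattering follows a power law in wavelength
anchored at 800 nm.

Units: wavelengths in nm, absorption/scattering coefficients in cm^-1,
volume fractions and sO2 in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import DataError, ValidationError, WavelengthRangeError

REFERENCE_HB_CONCENTRATION_G_L = 150.0
REFERENCE_WAVELENGTH_NM = 800.0
#: relative Hb/HbO2 difference allowed at the 800 nm isosbestic point
ISOSBESTIC_TOLERANCE = 0.05

_COLUMNS = ("mu_a_hbo2", "mu_a_hb", "mu_a_water", "mu_a_melanin")


@dataclass(frozen=True)
class ChromophoreTable:
    """Tabulated absorption spectra of the modeled tissue constituents.

    ``mu_a_hbo2``/``mu_a_hb`` are whole-blood coefficients at the reference
    hemoglobin concentration of 150 g/L; ``mu_a_water``/``mu_a_melanin`` are
    pure-constituent coefficients.  Queries between grid nodes are linearly
    interpolated; queries outside the grid raise ``WavelengthRangeError``.
    """

    wavelength_grid: np.ndarray
    mu_a_hbo2: np.ndarray
    mu_a_hb: np.ndarray
    mu_a_water: np.ndarray
    mu_a_melanin: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_grid, dtype=float)
        object.__setattr__(self, "wavelength_grid", wl)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if wl[0] > 660.0 or wl[-1] < 960.0:
            raise ValidationError("table must cover at least 660-960 nm")
        for name in _COLUMNS:
            col = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, col)
            if col.shape != wl.shape:
                raise ValidationError(f"{name} length mismatch")
            if np.any(col < 0) or not np.all(np.isfinite(col)):
                raise ValidationError(f"{name} must be finite and >= 0")
        iso_o = self._interp(self.mu_a_hbo2, 800.0)
        iso_d = self._interp(self.mu_a_hb, 800.0)
        if abs(iso_o - iso_d) / iso_d >= ISOSBESTIC_TOLERANCE:
            raise ValidationError("800 nm is not isosbestic in this table")

    # -- queries ----------------------------------------------------------
    def _check_range(self, wavelength_nm) -> np.ndarray:
        wl = np.asarray(wavelength_nm, dtype=float)
        lo, hi = self.wavelength_grid[0], self.wavelength_grid[-1]
        if np.any(wl < lo) or np.any(wl > hi):
            raise WavelengthRangeError(
                f"wavelength outside table range [{lo:g}, {hi:g}] nm"
            )
        return wl

    def _interp(self, column: np.ndarray, wavelength_nm):
        wl = self._check_range(wavelength_nm)
        return np.interp(wl, self.wavelength_grid, column)

    def hbo2(self, wavelength_nm):
        """Whole-blood absorption at sO2 = 1, 150 g/L (cm^-1)."""
        return self._interp(self.mu_a_hbo2, wavelength_nm)

    def hb(self, wavelength_nm):
        """Whole-blood absorption at sO2 = 0, 150 g/L (cm^-1)."""
        return self._interp(self.mu_a_hb, wavelength_nm)

    def water(self, wavelength_nm):
        return self._interp(self.mu_a_water, wavelength_nm)

    def melanin(self, wavelength_nm):
        return self._interp(self.mu_a_melanin, wavelength_nm)


@dataclass(frozen=True)
class TissueComposition:
    """Volume-fraction composition plus scattering model of one tissue type."""

    blood_volume_fraction: float = 0.0
    oxygenation: float = 0.0
    melanin_fraction: float = 0.0
    water_fraction: float = 0.0
    hemoglobin_concentration: float = REFERENCE_HB_CONCENTRATION_G_L
    mus_prime_ref: float = 10.0   # reduced scattering at 800 nm, cm^-1
    scatter_power: float = 0.0    # mus'(lambda) ~ (lambda/800)^-scatter_power
    anisotropy: float = 0.9

    def __post_init__(self) -> None:
        for name in ("blood_volume_fraction", "oxygenation",
                     "melanin_fraction", "water_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.hemoglobin_concentration <= 0:
            raise ValidationError("hemoglobin_concentration must be > 0")
        if self.mus_prime_ref < 0:
            raise ValidationError("mus_prime_ref must be >= 0")
        if not -1.0 < self.anisotropy < 1.0:
            raise ValidationError("anisotropy must lie in (-1, 1)")


def load_chromophore_table(source: str = "jacques") -> ChromophoreTable:
    """Load a bundled chromophore table by identifier.

    The only bundled table, ``"jacques"``, is compiled from the standard
    literature compilations of tissue optical properties (see the data-file
    header for provenance).
    """
    if source != "jacques":
        raise DataError(f"unknown bundled chromophore table {source!r}")
    try:
        path = resources.files("lsdpa.data").joinpath("chromophores.tsv")
        text = path.read_text()
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise DataError("bundled chromophore table missing") from exc
    rows = [
        line.split("\t")
        for line in text.splitlines()
        if line and not line.startswith("#")
    ]
    header, data = rows[0], rows[1:]
    expected = ("wavelength_nm",) + _COLUMNS
    if tuple(header) != expected or not data:
        raise DataError("bundled chromophore table is corrupt")
    arr = np.array(data, dtype=float)
    return ChromophoreTable(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4])


def blood_absorption(so2, chb, wavelength_nm, table: ChromophoreTable):
    """Whole-blood absorption coefficient (cm^-1).

    Linear in both sO2 and hemoglobin concentration:
    (chb/150) * (so2 * mu_a_HbO2 + (1 - so2) * mu_a_Hb).
    """
    so2 = np.asarray(so2, dtype=float)
    if np.any(so2 < 0) or np.any(so2 > 1):
        raise ValidationError("so2 outside [0, 1]")
    if np.any(np.asarray(chb) <= 0):
        raise ValidationError("hemoglobin concentration must be > 0")
    scale = np.asarray(chb, dtype=float) / REFERENCE_HB_CONCENTRATION_G_L
    return scale * (so2 * table.hbo2(wavelength_nm)
                    + (1.0 - so2) * table.hb(wavelength_nm))


def tissue_absorption(comp: TissueComposition, wavelength_nm,
                      table: ChromophoreTable):
    """Bulk absorption of a tissue: superposition of its constituents."""
    mu = np.zeros_like(np.asarray(wavelength_nm, dtype=float))
    if comp.blood_volume_fraction > 0:
        mu = mu + comp.blood_volume_fraction * blood_absorption(
            comp.oxygenation, comp.hemoglobin_concentration,
            wavelength_nm, table)
    else:
        table._check_range(wavelength_nm)
    if comp.melanin_fraction > 0:
        mu = mu + comp.melanin_fraction * table.melanin(wavelength_nm)
    if comp.water_fraction > 0:
        mu = mu + comp.water_fraction * table.water(wavelength_nm)
    return mu


def tissue_scattering(comp: TissueComposition, wavelength_nm):
    """Scattering coefficient and anisotropy of a tissue.

    mus'(lambda) = mus_prime_ref * (lambda/800 nm)^(-scatter_power);
    mus = mus' / (1 - g).  scatter_power = 0 gives wavelength-constant
    scattering.
    """
    if comp.anisotropy >= 1.0:
        raise ValidationError("anisotropy g = 1 leaves mus undefined")
    wl = np.asarray(wavelength_nm, dtype=float)
    mus_prime = comp.mus_prime_ref * (wl / REFERENCE_WAVELENGTH_NM) ** (
        -comp.scatter_power)
    mus = mus_prime / (1.0 - comp.anisotropy)
    return mus, comp.anisotropy
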