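"""Circular-dichroism bookkeeping for peptide ensembles.

Raw CD instruments report ellipticity in millidegrees; comparisons across
samples use the mean residue ellipticity

    [theta]_MR = 100 * theta_deg / (c_MR * l),   c_MR = n * c,

with molar concentration c (mol/L), path length l (cm) and residue count
n, giving deg cm^2 dmol^-1.  The polyproline-II content of a short
proline-rich peptide is estimated from the 228 nm band by the empirical
calibration

    %PPII = ([theta]_228 + 6100) / 137,

and theoretical spectra are assembled as convex combinations of per-class
basis spectra (fractions x basis), optionally rescaled onto a measured
reference by a least-squares scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Empirical 228 nm calibration: %PPII = (theta + PPII_INTERCEPT) / PPII_SLOPE_INV
PPII_INTERCEPT = 6100.0
PPII_SLOPE_INV = 137.0


@dataclass(frozen=True)
class SampleInfo:
    """CD sample description: molar concentration, path length, residues."""

    concentration_molar: float
    path_length_cm: float
    n_residues: int

    def __post_init__(self) -> None:
        if self.concentration_molar <= 0:
            raise ValueError("concentration must be positive")
        if self.path_length_cm <= 0:
            raise ValueError("path length must be positive")
        if self.n_residues < 1 or int(self.n_residues) != self.n_residues:
            raise ValueError("residue count must be a positive integer")

    @property
    def mean_residue_concentration(self) -> float:
        """c_MR = n * c (mol residues / L)."""
        return self.n_residues * self.concentration_molar


@dataclass(frozen=True)
class CDSpectrum:
    """Wavelength grid (nm) with mean residue ellipticity values."""

    wavelengths_nm: np.ndarray
    values: np.ndarray  # deg cm^2 dmol^-1
    provenance: str = "measured"  # measured | calculated | scaled

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.shape != vals.shape or wl.ndim != 1:
            raise ValueError("wavelengths and values must be matching 1-D arrays")
        if wl.size and (np.any(np.diff(wl) <= 0)):
            raise ValueError("wavelengths must be strictly increasing")
        if wl.size and (wl[0] < 170.0 or wl[-1] > 280.0):
            raise ValueError("wavelength grid must lie within 170-280 nm")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    def value_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated ellipticity at one wavelength."""
        wl = self.wavelengths_nm
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise ValueError(f"{wavelength_nm} nm outside grid [{wl[0]}, {wl[-1]}]")
        return float(np.interp(wavelength_nm, wl, self.values))

    def to_table(self, path: str | Path, sep: str = ",") -> Path:
        path = Path(path)
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths_nm, "mre_deg_cm2_dmol": self.values}
        ).to_csv(path, sep=sep, index=False, float_format="%.10g")
        return path

    @classmethod
    def from_table(cls, path: str | Path, provenance: str = "measured") -> "CDSpectrum":
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        wl_col, val_col = df.columns[:2]
        return cls(
            wavelengths_nm=df[wl_col].to_numpy(dtype=float),
            values=df[val_col].to_numpy(dtype=float),
            provenance=provenance,
        )


def millideg_to_mre(
    wavelengths_nm,
    ellipticity_mdeg,
    sample: SampleInfo,
) -> CDSpectrum:
    """Convert raw millidegree ellipticity to mean residue ellipticity."""
    theta_deg = np.asarray(ellipticity_mdeg, dtype=float) / 1000.0
    mre = 100.0 * theta_deg / (sample.mean_residue_concentration * sample.path_length_cm)
    return CDSpectrum(
        wavelengths_nm=np.asarray(wavelengths_nm, dtype=float),
        values=mre,
        provenance="measured",
    )


def mre_to_millideg(spectrum: CDSpectrum, sample: SampleInfo) -> np.ndarray:
    """Inverse of :func:`millideg_to_mre` (values back in millidegrees)."""
    return (
        spectrum.values
        * sample.mean_residue_concentration
        * sample.path_length_cm
        / 100.0
        * 1000.0
    )


def ppii_from_ellipticity(theta_228: float) -> float:
    """%PPII from the 228 nm mean residue ellipticity (deg cm^2 dmol^-1)."""
    if not np.isfinite(theta_228):
        raise ValueError("ellipticity must be finite")
    return (theta_228 + PPII_INTERCEPT) / PPII_SLOPE_INV


def ppii_from_spectrum(spectrum: CDSpectrum, wavelength_nm: float = 228.0) -> float:
    """%PPII read off a spectrum at the calibration wavelength."""
    return ppii_from_ellipticity(spectrum.value_at(wavelength_nm))


def scale_factor(calculated: CDSpectrum, reference: CDSpectrum) -> float:
    """Least-squares scalar s minimizing sum (s*calc - ref)^2 on the overlap.

    The coarser spectrum is linearly interpolated onto the finer grid
    restricted to the common wavelength range; closed form s =
    sum(calc*ref) / sum(calc^2).
    """
    lo = max(calculated.wavelengths_nm[0], reference.wavelengths_nm[0])
    hi = min(calculated.wavelengths_nm[-1], reference.wavelengths_nm[-1])
    if hi <= lo:
        raise ValueError("spectra have no overlapping wavelength range")
    finer = (
        calculated
        if calculated.wavelengths_nm.size >= reference.wavelengths_nm.size
        else reference
    )
    grid = finer.wavelengths_nm
    grid = grid[(grid >= lo) & (grid <= hi)]
    calc = np.interp(grid, calculated.wavelengths_nm, calculated.values)
    ref = np.interp(grid, reference.wavelengths_nm, reference.values)
    denom = float(np.sum(calc**2))
    if denom == 0.0:
        raise ValueError("calculated spectrum is identically zero on the overlap")
    return float(np.sum(calc * ref) / denom)


def apply_scale(spectrum: CDSpectrum, s: float) -> CDSpectrum:
    """Multiply a spectrum by a scalar, tagging provenance as 'scaled'."""
    return replace(spectrum, values=spectrum.values * s, provenance="scaled")


def combine_basis(fractions: dict[str, float], basis: dict[str, CDSpectrum]) -> CDSpectrum:
    """Pointwise convex combination sum_c fraction_c * basis_c(lambda).

    Fraction keys must exactly match the basis classes, be non-negative and
    sum to 1 within 1e-6.  All basis spectra must share one wavelength grid.
    """
    if set(fractions) != set(basis):
        raise ValueError(
            f"class mismatch: fractions {sorted(fractions)} vs basis {sorted(basis)}"
        )
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"fractions sum to {total}, not 1")
    if any(f < 0 for f in fractions.values()):
        raise ValueError("fractions must be non-negative")
    classes = sorted(basis)
    grid = basis[classes[0]].wavelengths_nm
    for c in classes[1:]:
        if not np.array_equal(basis[c].wavelengths_nm, grid):
            raise ValueError("basis spectra must share one wavelength grid")
    values = np.zeros_like(grid, dtype=float)
    for c in classes:
        values += fractions[c] * basis[c].values
    return CDSpectrum(wavelengths_nm=grid, values=values, provenance="calculated")


def read_basis_table(path: str | Path) -> dict[str, CDSpectrum]:
    """Read a three-column basis file: class, wavelength_nm, value."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cls_col, wl_col, val_col = df.columns[:3]
    out = {}
    for cls, grp in df.groupby(cls_col, sort=True):
        grp = grp.sort_values(wl_col)
        out[str(cls)] = CDSpectrum(
            wavelengths_nm=grp[wl_col].to_numpy(dtype=float),
            values=grp[val_col].to_numpy(dtype=float),
            provenance="measured",
        )
    return out
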