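"""Per-frame dihedral time series: the pipeline's universal input container.

A :class:`DihedralTrajectory` holds per-site omega series (and optionally
phi, psi, chi2), a per-frame boost energy dV, the frame spacing in ps and
the simulation temperature.  It round-trips losslessly through a delimited
text table (comma or tab, autodetected on read) with a mandatory header::

    frame,time_ps,omega_<site>[,phi_<site>,psi_<site>,chi2_<site>...],deltaV_kcal_mol

Lines starting with '#' are treated as comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .potentials import wrap_degrees

_ANGLE_CHANNELS = ("omega", "phi", "psi", "chi2")


@dataclass
class DihedralTrajectory:
    """Frames x sites dihedral series with per-frame boost energies."""

    dt_ps: float
    omega: np.ndarray
    delta_v: np.ndarray
    sites: tuple[str, ...]
    temperature: float = 300.0
    phi: np.ndarray | None = None
    psi: np.ndarray | None = None
    chi2: np.ndarray | None = None
    replicate: str | None = None

    def __post_init__(self) -> None:
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        if self.omega.ndim != 2:
            raise ValueError("omega must be a (n_frames, n_sites) array")
        self.sites = tuple(self.sites)
        if self.omega.shape[1] != len(self.sites):
            raise ValueError(
                f"{self.omega.shape[1]} omega columns but {len(self.sites)} site names"
            )
        self.delta_v = np.asarray(self.delta_v, dtype=float)
        if self.delta_v.shape != (self.n_frames,):
            raise ValueError("delta_v must have one value per frame")
        if np.any(self.delta_v < 0):
            raise ValueError("boost energies must be >= 0")
        if self.dt_ps <= 0:
            raise ValueError("time step must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name in ("omega", "phi", "psi", "chi2"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            if arr.shape != self.omega.shape:
                raise ValueError(f"{name} shape {arr.shape} != omega shape {self.omega.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite angles")
            setattr(self, name, wrap_degrees(arr))

    @property
    def n_frames(self) -> int:
        return self.omega.shape[0]

    @property
    def n_sites(self) -> int:
        return self.omega.shape[1]

    @property
    def time_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ps

    def site_index(self, site: str) -> int:
        try:
            return self.sites.index(site)
        except ValueError:
            raise KeyError(f"unknown site {site!r}; have {self.sites}") from None

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {
            "frame": np.arange(self.n_frames),
            "time_ps": self.time_ps,
        }
        for channel in _ANGLE_CHANNELS:
            arr = getattr(self, channel)
            if arr is None:
                continue
            for j, site in enumerate(self.sites):
                cols[f"{channel}_{site}"] = arr[:, j]
        cols["deltaV_kcal_mol"] = self.delta_v
        return pd.DataFrame(cols)

    def to_table(self, path: str | Path, sep: str = ",") -> Path:
        """Write the delimited text table (deterministic float formatting)."""
        path = Path(path)
        self.to_dataframe().to_csv(path, sep=sep, index=False, float_format="%.10g")
        return path

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        dt_ps: float | None = None,
        temperature: float = 300.0,
        replicate: str | None = None,
    ) -> "DihedralTrajectory":
        if "deltaV_kcal_mol" not in df.columns:
            raise ValueError("missing required column 'deltaV_kcal_mol'")
        omega_cols = [c for c in df.columns if c.startswith("omega_")]
        if not omega_cols:
            raise ValueError("no omega_<site> columns found")
        sites = tuple(c[len("omega_"):] for c in omega_cols)
        if dt_ps is None:
            if "time_ps" in df.columns and len(df) > 1:
                dt_ps = float(df["time_ps"].iloc[1] - df["time_ps"].iloc[0])
            else:
                dt_ps = 1.0
        channels: dict[str, np.ndarray | None] = {}
        for channel in ("phi", "psi", "chi2"):
            cols = [f"{channel}_{s}" for s in sites]
            if all(c in df.columns for c in cols):
                channels[channel] = df[cols].to_numpy(dtype=float)
            else:
                channels[channel] = None
        return cls(
            dt_ps=dt_ps,
            omega=df[omega_cols].to_numpy(dtype=float),
            delta_v=df["deltaV_kcal_mol"].to_numpy(dtype=float),
            sites=sites,
            temperature=temperature,
            phi=channels["phi"],
            psi=channels["psi"],
            chi2=channels["chi2"],
            replicate=replicate,
        )

    @classmethod
    def from_table(
        cls,
        path: str | Path,
        temperature: float = 300.0,
        replicate: str | None = None,
    ) -> "DihedralTrajectory":
        """Read a trajectory table; delimiter sniffed, '#' lines ignored."""
        df = read_delimited(path)
        return cls.from_dataframe(df, temperature=temperature, replicate=replicate)


def read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with '#' comment lines."""
    return pd.read_csv(path, sep=None, engine="python", comment="#")


@dataclass
class TableDiagnostics:
    """Schema/content check result for a trajectory table."""

    path: str
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_table(path: str | Path) -> TableDiagnostics:
    """Validate a trajectory table: required columns, angle bounds, dV >= 0.

    Out-of-range angles are reported as warnings (they are wrapped on load);
    structural problems (missing columns, negative dV, non-finite values)
    are errors.
    """
    diag = TableDiagnostics(path=str(path))
    try:
        df = read_delimited(path)
    except Exception as exc:  # surface parse failures as diagnostics
        diag.errors.append(f"unreadable table: {exc}")
        return diag
    if "deltaV_kcal_mol" not in df.columns:
        diag.errors.append("missing required column 'deltaV_kcal_mol'")
    omega_cols = [c for c in df.columns if c.startswith("omega_")]
    if not omega_cols:
        diag.errors.append("no omega_<site> columns found")
    if "time_ps" not in df.columns:
        diag.warnings.append("no time_ps column; frame spacing defaults to 1 ps")
    for col in df.columns:
        if col in ("frame",):
            continue
        series = df[col]
        if not np.all(np.isfinite(series.to_numpy(dtype=float))):
            bad = int((~np.isfinite(series.to_numpy(dtype=float))).sum())
            diag.errors.append(f"column {col}: {bad} non-finite values")
    if "deltaV_kcal_mol" in df.columns:
        dv = df["deltaV_kcal_mol"].to_numpy(dtype=float)
        if np.any(dv < 0):
            rows = np.nonzero(dv < 0)[0][:5].tolist()
            diag.errors.append(f"deltaV_kcal_mol negative at rows {rows}")
    for col in df.columns:
        if any(col.startswith(p + "_") for p in _ANGLE_CHANNELS):
            vals = df[col].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.max() > 180.0 or finite.min() <= -180.0):
                diag.warnings.append(
                    f"column {col}: angles outside (-180, +180] will be wrapped"
                )
    return diag
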