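"""Cosine-series torsion potentials with an optional harmonic boost.

The peptide-bond (omega) torsion is modelled in the Amber functional form

    U(omega) = sum_n (V_n / 2) * (1 + cos(n*omega - gamma_n)),

with multiplicity ``n``, barrier coefficient ``V_n`` (kcal/mol) and phase
``gamma_n`` (degrees).  For a pure 2-fold term with phase 180 deg the
cis<->trans interconversion barrier equals ``V_2`` exactly, which is why the
2-fold coefficient alone controls isomerization kinetics.

A Gaussian-accelerated-MD style boost fills the wells below a threshold
energy ``E``:

    dV(omega) = k/2 * (E - U(omega))^2   if U(omega) < E, else 0.

Unbiased equilibrium properties of any spec defined here are available
analytically (by quadrature), which makes these potentials usable as ground
truth for reweighting estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

#: Boltzmann constant in kcal/(mol K).
KB_KCAL = 0.0019872041

#: Amber ff14SB 2-fold peptide-bond barrier coefficient, kcal/mol.
DEFAULT_PEPTIDE_BARRIER = 20.0
#: Lowered 2-fold barrier used to accelerate cis/trans sampling, kcal/mol.
LOWERED_PEPTIDE_BARRIER = 15.0


def thermal_energy(temperature: float) -> float:
    """kT in kcal/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL * temperature


def wrap_degrees(angle):
    """Wrap angles (degrees) into (-180, +180]."""
    wrapped = np.mod(np.asarray(angle, dtype=float), 360.0)
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # map -180 (from exact multiples after where) onto +180
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class TorsionTerm:
    """One cosine term of an Amber-form torsion series."""

    n: int
    v: float
    gamma_deg: float

    def __post_init__(self) -> None:
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError(f"multiplicity n must be a positive integer, got {self.n}")
        if not math.isfinite(self.v) or self.v < 0:
            raise ValueError(f"barrier V_n must be finite and >= 0, got {self.v}")


@dataclass(frozen=True)
class BoostSpec:
    """Harmonic boost parameters: threshold energy E and force constant k."""

    threshold: float
    k: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"boost force constant must be >= 0, got {self.k}")


@dataclass(frozen=True)
class TorsionPotentialSpec:
    """A torsion potential, optional boost, and simulation temperature."""

    terms: tuple[TorsionTerm, ...]
    boost: BoostSpec | None = None
    temperature: float = 300.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if not self.terms:
            raise ValueError("torsion spec needs at least one term")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def kt(self) -> float:
        return thermal_energy(self.temperature)

    @property
    def beta(self) -> float:
        return 1.0 / self.kt


def evaluate_potential(spec: TorsionPotentialSpec, omega_deg):
    """Unboosted torsion energy U(omega) in kcal/mol; periodic in 360 deg."""
    omega = np.deg2rad(np.asarray(omega_deg, dtype=float))
    u = np.zeros_like(omega)
    for term in spec.terms:
        u += 0.5 * term.v * (1.0 + np.cos(term.n * omega - math.radians(term.gamma_deg)))
    if np.ndim(omega_deg) == 0:
        return float(u)
    return u


def boost_energy(spec: TorsionPotentialSpec, omega_deg):
    """Boost dV(omega) = k/2 (E - U)^2 below threshold, 0 above; >= 0."""
    u = evaluate_potential(spec, omega_deg)
    if spec.boost is None or spec.boost.k == 0.0:
        return np.zeros_like(np.asarray(u, dtype=float)) if np.ndim(u) else 0.0
    gap = spec.boost.threshold - np.asarray(u, dtype=float)
    dv = 0.5 * spec.boost.k * np.square(np.clip(gap, 0.0, None))
    if np.ndim(u) == 0:
        return float(dv)
    return dv


def total_energy(spec: TorsionPotentialSpec, omega_deg):
    """Boosted energy U*(omega) = U + dV."""
    return evaluate_potential(spec, omega_deg) + boost_energy(spec, omega_deg)


def _refine_extremum(spec: TorsionPotentialSpec, lo: float, hi: float, sign: float) -> float:
    res = minimize_scalar(
        lambda w: sign * evaluate_potential(spec, w),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return sign * res.fun


def barrier_height(spec: TorsionPotentialSpec, grid_step: float = 0.05) -> float:
    """Global max minus global min of U over the dihedral circle (kcal/mol).

    Coarse grid scan followed by bounded 1-D refinement around the grid
    extremes; exact to optimizer tolerance for smooth cosine series.
    """
    grid = np.arange(-180.0, 180.0 + grid_step, grid_step)
    u = evaluate_potential(spec, grid)
    i_max, i_min = int(np.argmax(u)), int(np.argmin(u))
    u_max = _refine_extremum(spec, grid[i_max] - grid_step, grid[i_max] + grid_step, -1.0)
    u_min = _refine_extremum(spec, grid[i_min] - grid_step, grid[i_min] + grid_step, 1.0)
    return u_max - u_min


def peptide_bond_spec(
    barrier: float = LOWERED_PEPTIDE_BARRIER,
    temperature: float = 300.0,
    boost: BoostSpec | None = None,
) -> TorsionPotentialSpec:
    """Pure 2-fold peptide-bond torsion: minima at 0 (cis) and 180 (trans).

    With phase 180 deg the term vanishes at both isomer minima and peaks at
    +-90 deg, so the cis/trans barrier equals ``barrier`` exactly.
    """
    return TorsionPotentialSpec(
        terms=(TorsionTerm(n=2, v=barrier, gamma_deg=180.0),),
        boost=boost,
        temperature=temperature,
    )


def lowered_barrier_spec(**kwargs) -> TorsionPotentialSpec:
    """Peptide-bond preset with the lowered 15 kcal/mol 2-fold barrier."""
    return peptide_bond_spec(barrier=LOWERED_PEPTIDE_BARRIER, **kwargs)


def default_barrier_spec(**kwargs) -> TorsionPotentialSpec:
    """Peptide-bond preset with the force-field default 20 kcal/mol barrier."""
    return peptide_bond_spec(barrier=DEFAULT_PEPTIDE_BARRIER, **kwargs)


def _boltzmann_integral(spec, lo, hi, n, kt, u_ref, boosted):
    grid = np.linspace(lo, hi, n)
    u = total_energy(spec, grid) if boosted else evaluate_potential(spec, grid)
    return np.trapezoid(np.exp(-(u - u_ref) / kt), grid)


def analytic_state_probability(
    spec: TorsionPotentialSpec,
    omega_range: tuple[float, float],
    tol: float = 1e-6,
    boosted: bool = False,
) -> float:
    """Equilibrium probability of ``omega_range`` under the Boltzmann density.

    ``omega_range = (lo, hi)`` is an interval on the circle; ``hi <= lo``
    means the interval wraps through 180/-180.  Trapezoid quadrature with
    grid doubling, refined until successive estimates differ by < ``tol``.
    ``boosted=True`` integrates exp(-U*/kT) instead (the sampled density).
    """
    lo, hi = float(omega_range[0]), float(omega_range[1])
    if hi == lo:
        return 0.0  # zero-measure interval
    if hi < lo:
        hi += 360.0
    if hi - lo >= 360.0:
        return 1.0
    kt = spec.kt
    # reference energy avoids underflow for large barriers
    probe = np.linspace(-180.0, 180.0, 3601)
    u_probe = total_energy(spec, probe) if boosted else evaluate_potential(spec, probe)
    u_ref = float(np.min(u_probe))

    n = 2049
    prev = None
    for _ in range(16):
        num = _boltzmann_integral(spec, lo, hi, n, kt, u_ref, boosted)
        den = _boltzmann_integral(spec, -180.0, 180.0, 2 * n, kt, u_ref, boosted)
        p = num / den
        if prev is not None and abs(p - prev) < tol:
            return float(p)
        prev = p
        n = 2 * n - 1
    return float(p)


def estimate_boost(
    spec: TorsionPotentialSpec,
    target_mean_beta_dv: float = 1.0,
    grid_step: float = 0.05,
) -> BoostSpec:
    """Choose boost parameters for a spec without running any dynamics.

    Threshold ``E`` is set to the potential maximum over the circle (the
    upper-bound threshold convention), and ``k`` is solved from the target
    Boltzmann-average boost, beta*<dV> = beta*k/2*<(E-U)^2> = target, with
    the expectation taken over the unboosted equilibrium density.
    """
    if target_mean_beta_dv < 0:
        raise ValueError("target mean beta*dV must be >= 0")
    grid = np.arange(-180.0, 180.0, grid_step)
    u = evaluate_potential(spec, grid)
    e_thresh = float(np.max(u))
    w = np.exp(-(u - np.min(u)) / spec.kt)
    w /= w.sum()
    mean_sq_gap = float(np.sum(w * (e_thresh - u) ** 2))
    if mean_sq_gap == 0.0:
        return BoostSpec(threshold=e_thresh, k=0.0)
    k = 2.0 * target_mean_beta_dv / (spec.beta * mean_sq_gap)
    return BoostSpec(threshold=e_thresh, k=k)


@dataclass(frozen=True)
class MultiSiteSpec:
    """Torsion specs for several proline sites plus a coupling mode."""

    sites: tuple[TorsionPotentialSpec, ...]
    coupling: str = "independent"
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        if not self.sites:
            raise ValueError("need at least one site spec")
        if self.coupling not in ("independent", "locked"):
            raise ValueError(
                f"unknown coupling {self.coupling!r}; expected 'independent' or 'locked'"
            )
        if not self.names:
            object.__setattr__(
                self, "names", tuple(f"pro{i + 1}" for i in range(len(self.sites)))
            )
        if len(self.names) != len(self.sites):
            raise ValueError("names and sites length mismatch")
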