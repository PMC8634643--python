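"""Synthetic boosted dihedral trajectories with known unbiased equilibria.

Frames are drawn by Metropolis Monte Carlo on the boosted surface
U*(omega) = U(omega) + dV(omega), so the retained ensemble converges to
exp(-U*/kT) and carries the per-frame boost energy needed by the
reweighting estimators.  Only equilibrium populations are meaningful;
"time" is retained-frame index times a nominal frame spacing, and flipping
frequencies measured on these chains are per-frame-interval event rates,
not physical kinetics.

Backbone (phi, psi, omega) series with prescribed polyproline helix content
are generated by :func:`emulate_backbone`, drawing uniformly inside the
canonical PPII / PPI dihedral boxes.
"""

from __future__ import annotations

import math

import numpy as np

from .potentials import (
    MultiSiteSpec,
    TorsionPotentialSpec,
    boost_energy,
    wrap_degrees,
)
from .structure import PPI_BOX, PPII_BOX
from .trajectory import DihedralTrajectory

DEFAULT_PROPOSAL_WIDTH = 30.0
DEFAULT_BURN_IN = 10_000
#: Nominal retained-frame spacing, ps (matches a 0.1 ps trajectory output).
DEFAULT_DT_PS = 0.1


def metropolis_acceptance(spec: TorsionPotentialSpec, omega_from: float, omega_to: float) -> float:
    """Acceptance probability min(1, exp(-dU*/kT)) for a symmetric proposal."""
    from .potentials import total_energy

    du = total_energy(spec, omega_to) - total_energy(spec, omega_from)
    return min(1.0, math.exp(-du / spec.kt))


def _run_chain(
    spec: TorsionPotentialSpec,
    n_frames: int,
    rng: np.random.Generator,
    proposal_width: float,
    burn_in: int,
) -> np.ndarray:
    """Metropolis chain on U* = U + dV; returns retained omega (degrees)."""
    n_steps = n_frames + burn_in
    deltas = rng.uniform(-proposal_width, proposal_width, size=n_steps)
    log_u = np.log(rng.random(size=n_steps))

    # unpack terms once; per-step energy via math.cos is the hot path
    terms = [(t.n, 0.5 * t.v, math.radians(t.gamma_deg)) for t in spec.terms]
    boost = spec.boost
    if boost is not None and boost.k > 0.0:
        e_thresh, half_k = boost.threshold, 0.5 * boost.k
    else:
        e_thresh, half_k = None, 0.0
    inv_kt = 1.0 / spec.kt

    def u_star(w_rad: float) -> float:
        u = 0.0
        for n, v_half, gamma in terms:
            u += v_half * (1.0 + math.cos(n * w_rad - gamma))
        if e_thresh is not None and u < e_thresh:
            gap = e_thresh - u
            u += half_k * gap * gap
        return u

    two_pi = 2.0 * math.pi
    w = math.radians(float(rng.uniform(-180.0, 180.0)))
    e = u_star(w)
    out = np.empty(n_frames)
    deltas_rad = np.deg2rad(deltas)
    for i in range(n_steps):
        w_new = w + deltas_rad[i]
        if w_new > math.pi:
            w_new -= two_pi
        elif w_new <= -math.pi:
            w_new += two_pi
        e_new = u_star(w_new)
        if e_new <= e or log_u[i] < (e - e_new) * inv_kt:
            w, e = w_new, e_new
        if i >= burn_in:
            out[i - burn_in] = w
    return wrap_degrees(np.rad2deg(out))


def sample_boosted_trajectory(
    spec: TorsionPotentialSpec,
    n_frames: int,
    seed: int | np.random.SeedSequence,
    proposal_width: float = DEFAULT_PROPOSAL_WIDTH,
    burn_in: int = DEFAULT_BURN_IN,
    dt_ps: float = DEFAULT_DT_PS,
    site: str = "pro1",
    replicate: str | None = None,
) -> DihedralTrajectory:
    """Sample a single-site boosted trajectory.

    The chain targets exp(-U*/kT); the recorded ``delta_v`` column is
    dV(omega) recomputed from each retained frame, so reweighting by
    exp(+beta dV) recovers unbiased averages.  Identical ``(spec, seed)``
    give byte-identical output tables.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducible sampling")
    if not (0.0 < proposal_width <= 180.0):
        raise ValueError("proposal width must be in (0, 180] degrees")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    rng = np.random.default_rng(seed)
    omega = _run_chain(spec, n_frames, rng, proposal_width, burn_in)
    dv = np.asarray(boost_energy(spec, omega), dtype=float)
    return DihedralTrajectory(
        dt_ps=dt_ps,
        omega=omega[:, None],
        delta_v=dv,
        sites=(site,),
        temperature=spec.temperature,
        replicate=replicate,
    )


def generate_multisite(
    spec: MultiSiteSpec,
    n_frames: int,
    seed: int | np.random.SeedSequence,
    proposal_width: float = DEFAULT_PROPOSAL_WIDTH,
    burn_in: int = DEFAULT_BURN_IN,
    dt_ps: float = DEFAULT_DT_PS,
    replicate: str | None = None,
) -> DihedralTrajectory:
    """Sample a multi-site trajectory with independent or locked coupling.

    ``independent``: each site runs its own chain from a distinct child of
    the given seed — isomerization across sites is stochastic and
    uncorrelated by construction.  ``locked``: all sites share one omega
    series sampled from the first site's spec — the maximal-correlation
    fixture.  The per-frame boost energy is the sum of each site's dV
    evaluated at that site's angle.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible sampling")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(int(seed))
    )
    n_sites = len(spec.sites)
    if spec.coupling == "locked":
        base = sample_boosted_trajectory(
            spec.sites[0], n_frames, ss.spawn(1)[0], proposal_width, burn_in, dt_ps
        )
        omega = np.repeat(base.omega, n_sites, axis=1)
        dv_total = np.zeros(n_frames)
        for j, site_spec in enumerate(spec.sites):
            dv_total += np.asarray(boost_energy(site_spec, omega[:, j]), dtype=float)
    else:
        children = ss.spawn(n_sites)
        omega = np.empty((n_frames, n_sites))
        dv_total = np.zeros(n_frames)
        for j, (site_spec, child) in enumerate(zip(spec.sites, children)):
            rng = np.random.default_rng(child)
            omega[:, j] = _run_chain(site_spec, n_frames, rng, proposal_width, burn_in)
            dv_total += np.asarray(boost_energy(site_spec, omega[:, j]), dtype=float)
    return DihedralTrajectory(
        dt_ps=dt_ps,
        omega=omega,
        delta_v=dv_total,
        sites=spec.names,
        temperature=spec.sites[0].temperature,
        replicate=replicate,
    )


def emulate_backbone(
    labels,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (phi, psi, omega) series realizing per-frame helix labels.

    For each frame labelled ``PPII`` or ``PPI`` the triple is drawn
    uniformly inside the canonical dihedral box of that class; ``other``
    frames get omega in the unassigned gap (+50..+100 deg) with phi, psi
    uniform on the circle, which no helix box contains.  Round-tripping the
    output through the classifier recovers the labels exactly.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    rng = np.random.default_rng(seed)
    n = labels.size
    phi = np.empty(n)
    psi = np.empty(n)
    omega = np.empty(n)
    for i, label in enumerate(labels):
        if label == "PPII":
            box = PPII_BOX
        elif label == "PPI":
            box = PPI_BOX
        elif label == "other":
            phi[i] = rng.uniform(-180.0, 180.0)
            psi[i] = rng.uniform(-180.0, 180.0)
            omega[i] = rng.uniform(50.0 + 1e-9, 100.0 - 1e-9)
            continue
        else:
            raise ValueError(f"unknown label {label!r}; expected PPII, PPI or other")
        phi[i] = rng.uniform(*box.phi)
        psi[i] = wrap_degrees(rng.uniform(*box.psi_unwrapped))
        omega[i] = wrap_degrees(rng.uniform(*box.omega_unwrapped))
    return phi, psi, wrap_degrees(omega)
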