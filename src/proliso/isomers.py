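"""Omega-angle state analysis: cis/trans classification and statistics.

The peptide-bond dihedral is assigned to ``cis`` for omega in [-90, +50)
degrees and ``trans`` for omega in [+100, +240) (equivalently
[+100, +180] union (-180, -120) after wrapping); angles in the two gaps are
``unassigned`` barrier-region frames.  Intervals are half-open at the upper
bound so boundary angles classify deterministically.

All ensemble statistics accept normalized per-frame weights so that boosted
trajectories can be analyzed with their reweighting factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .potentials import wrap_degrees
from .trajectory import DihedralTrajectory

#: cis state: omega in [-90, +50) degrees.
CIS_RANGE = (-90.0, 50.0)
#: trans state: omega in [+100, +240) degrees (wraps through 180).
TRANS_RANGE = (100.0, 240.0)

CIS, TRANS, UNASSIGNED = "cis", "trans", "unassigned"


def in_circular_interval(angle, lo: float, hi: float):
    """Membership of wrapped angle in the half-open circular interval [lo, hi)."""
    angle = np.asarray(angle, dtype=float)
    span = (hi - lo) % 360.0
    if span == 0.0:
        span = 360.0
    return np.mod(angle - lo, 360.0) < span


def classify_omega(
    omega,
    cis_range: tuple[float, float] = CIS_RANGE,
    trans_range: tuple[float, float] = TRANS_RANGE,
):
    """Classify omega angle(s) into cis / trans / unassigned.

    Any real input is accepted (wrapped internally), so classification is
    invariant to adding multiples of 360 degrees.
    """
    arr = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("omega contains non-finite values")
    wrapped = np.asarray(wrap_degrees(arr))
    states = np.full(wrapped.shape, UNASSIGNED, dtype=object)
    states[in_circular_interval(wrapped, *cis_range)] = CIS
    states[in_circular_interval(wrapped, *trans_range)] = TRANS
    if np.ndim(omega) == 0:
        return str(states[()])
    return states


@dataclass
class IsomerStateSeries:
    """Per-frame, per-site cis/trans/unassigned state assignments."""

    states: np.ndarray  # (n_frames, n_sites) of labels
    sites: tuple[str, ...]
    dt_ps: float
    cis_range: tuple[float, float] = CIS_RANGE
    trans_range: tuple[float, float] = TRANS_RANGE

    def __post_init__(self) -> None:
        self.states = np.atleast_2d(np.asarray(self.states, dtype=object))
        self.sites = tuple(self.sites)
        if self.states.shape[1] != len(self.sites):
            raise ValueError("states columns must match site names")

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    def is_cis(self) -> np.ndarray:
        return self.states == CIS

    def is_assigned(self) -> np.ndarray:
        return self.states != UNASSIGNED

    def n_cis_per_frame(self) -> np.ndarray:
        return self.is_cis().sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        frames, sites = np.meshgrid(
            np.arange(self.n_frames), np.arange(len(self.sites)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "frame": frames.ravel(),
                "site": np.asarray(self.sites, dtype=object)[sites.ravel()],
                "state": self.states.ravel(),
            }
        )


def classify_trajectory(
    traj: DihedralTrajectory,
    cis_range: tuple[float, float] = CIS_RANGE,
    trans_range: tuple[float, float] = TRANS_RANGE,
) -> IsomerStateSeries:
    """Assign every frame of every site to cis / trans / unassigned."""
    return IsomerStateSeries(
        states=classify_omega(traj.omega, cis_range, trans_range),
        sites=traj.sites,
        dt_ps=traj.dt_ps,
        cis_range=cis_range,
        trans_range=trans_range,
    )


def _check_weights(weights, n_frames: int) -> np.ndarray:
    w = np.asarray(getattr(weights, "weights", weights), dtype=float)
    if w.shape != (n_frames,):
        raise ValueError(f"weights length {w.shape} does not match {n_frames} frames")
    return w


def cis_percentage(states: IsomerStateSeries, weights=None) -> pd.Series:
    """Per-site percent of (weighted) assigned frames in the cis state.

    Unassigned barrier-region frames are excluded from the denominator, so
    cis% + trans% = 100 for every site.
    """
    if weights is None:
        w = np.full(states.n_frames, 1.0 / states.n_frames)
    else:
        w = _check_weights(weights, states.n_frames)
    out = {}
    for j, site in enumerate(states.sites):
        assigned = states.states[:, j] != UNASSIGNED
        denom = w[assigned].sum()
        if denom == 0.0:
            raise ValueError(f"site {site!r} has no assigned frames")
        cis_mass = w[assigned & (states.states[:, j] == CIS)].sum()
        out[site] = 100.0 * cis_mass / denom
    return pd.Series(out, name="cis_pct")


def flip_frequency(states: IsomerStateSeries, dt_ps: float | None = None) -> pd.Series:
    """Per-site cis<->trans transition rate in events per ns.

    Transitions are counted between consecutive *assigned* frames:
    unassigned barrier frames are bridged, so a crossing seen as
    cis -> unassigned -> trans counts once.  The denominator is the total
    simulated span (n_frames - 1) * dt.
    """
    if states.n_frames < 2:
        raise ValueError("need at least 2 frames to count transitions")
    dt = states.dt_ps if dt_ps is None else dt_ps
    span_ns = (states.n_frames - 1) * dt / 1000.0
    if span_ns <= 0:
        raise ValueError("zero time span")
    out = {}
    for j, site in enumerate(states.sites):
        col = states.states[:, j]
        assigned = col[col != UNASSIGNED]
        flips = int(np.count_nonzero(assigned[1:] != assigned[:-1]))
        out[site] = flips / span_ns
    return pd.Series(out, name="flips_per_ns")


def omega_histogram(
    omega,
    weights=None,
    bins: int = 60,
) -> pd.DataFrame:
    """Weighted circular histogram of omega, density-normalized per degree."""
    omega = np.asarray(wrap_degrees(np.asarray(omega, dtype=float))).ravel()
    if weights is None:
        w = np.full(omega.size, 1.0 / omega.size)
    else:
        w = _check_weights(weights, omega.size)
    edges = np.linspace(-180.0, 180.0, bins + 1)
    hist, _ = np.histogram(omega, bins=edges, weights=w)
    width = edges[1] - edges[0]
    return pd.DataFrame(
        {
            "bin_center_deg": 0.5 * (edges[:-1] + edges[1:]),
            "density_per_deg": hist / (w.sum() * width),
            "weight_sum": hist,
        }
    )


@dataclass
class JointDistribution:
    """Reweighted probability over (number of sites in cis, observable bin)."""

    n_cis_values: np.ndarray  # 0..S
    observable_edges: np.ndarray
    probability: np.ndarray  # (S+1, n_bins)

    def __post_init__(self) -> None:
        total = float(self.probability.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"joint distribution sums to {total}, not 1")
        if np.any(self.probability < 0):
            raise ValueError("negative probability cell")

    @property
    def observable_centers(self) -> np.ndarray:
        return 0.5 * (self.observable_edges[:-1] + self.observable_edges[1:])

    def marginal_n_cis(self) -> np.ndarray:
        return self.probability.sum(axis=1)

    def marginal_observable(self) -> np.ndarray:
        return self.probability.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, k in enumerate(self.n_cis_values):
            for j, c in enumerate(self.observable_centers):
                rows.append((int(k), float(c), float(self.probability[i, j])))
        return pd.DataFrame(rows, columns=["n_cis", "observable_bin_center", "probability"])


def joint_distribution(
    states: IsomerStateSeries,
    observable,
    weights=None,
    observable_bins: int | np.ndarray = 30,
) -> JointDistribution:
    """Joint (n_cis, observable) probability table, e.g. end-to-end distance.

    Reweighted two-dimensional histogram over the number of sites
    simultaneously in cis and a per-frame scalar observable.
    """
    obs = np.asarray(observable, dtype=float)
    if obs.shape != (states.n_frames,):
        raise ValueError("observable length must match frame count")
    if weights is None:
        w = np.full(states.n_frames, 1.0 / states.n_frames)
    else:
        w = _check_weights(weights, states.n_frames)
    n_sites = len(states.sites)
    n_cis = states.n_cis_per_frame()
    if np.isscalar(observable_bins):
        lo, hi = float(obs.min()), float(obs.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, int(observable_bins) + 1)
    else:
        edges = np.asarray(observable_bins, dtype=float)
    prob = np.zeros((n_sites + 1, edges.size - 1))
    for k in range(n_sites + 1):
        mask = n_cis == k
        if mask.any():
            prob[k], _ = np.histogram(obs[mask], bins=edges, weights=w[mask])
    prob /= prob.sum()
    return JointDistribution(
        n_cis_values=np.arange(n_sites + 1),
        observable_edges=edges,
        probability=prob,
    )


def running_average(series, window: int) -> np.ndarray:
    """Centered moving mean with shrinking windows at the edges."""
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > x.size:
        raise ValueError(f"window {window} exceeds series length {x.size}")
    half_lo = (window - 1) // 2
    half_hi = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(x.size)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, x.size)
    return (csum[hi] - csum[lo]) / (hi - lo)
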