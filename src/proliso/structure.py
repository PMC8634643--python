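"""Polyproline helix and proline ring-pucker assignment from dihedrals.

A residue-frame is assigned to the left-handed PPII helix or right-handed
PPI helix when its (phi, psi, omega) triple falls inside the canonical
dihedral box of that class:

    PPII: phi in [-104.6, -46.6], psi in [+107.9, +165.9], omega trans
    PPI:  phi in [-104.6, -46.6], psi in [+131, +189],     omega cis

The PPI psi upper bound of +189 wraps to -171 in the (-180, +180]
convention.  The omega requirement reuses the cis/trans ranges of
:mod:`proliso.isomers`, which keeps the two boxes disjoint (a peptide bond
cannot be cis and trans at once).  Ring pucker is read from chi2 alone:
up above +10 degrees, down below -10, planar between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .isomers import CIS_RANGE, TRANS_RANGE, in_circular_interval
from .potentials import wrap_degrees

PPII_LABEL, PPI_LABEL, OTHER_LABEL = "PPII", "PPI", "other"
UP, DOWN, PLANAR = "up", "down", "planar"

#: chi2 magnitude (degrees) separating up/down pucker from planar.
PUCKER_CUTOFF = 10.0


@dataclass(frozen=True)
class HelixBox:
    """Canonical dihedral-angle box defining one polyproline helix class.

    ``psi_unwrapped`` / ``omega_unwrapped`` may extend past +180; membership
    is evaluated on the circle after wrapping.
    """

    phi: tuple[float, float]
    psi_unwrapped: tuple[float, float]
    omega_unwrapped: tuple[float, float]

    def contains(self, phi, psi, omega) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        psi = np.asarray(wrap_degrees(np.asarray(psi, dtype=float)))
        omega = np.asarray(omega, dtype=float)
        phi_ok = (phi >= self.phi[0]) & (phi <= self.phi[1])
        lo, hi = self.psi_unwrapped
        psi_ok = np.mod(psi - lo, 360.0) <= (hi - lo)  # closed circular interval
        omega_ok = in_circular_interval(omega, *self.omega_unwrapped)
        return phi_ok & psi_ok & omega_ok


PPII_BOX = HelixBox(phi=(-104.6, -46.6), psi_unwrapped=(107.9, 165.9), omega_unwrapped=TRANS_RANGE)
PPI_BOX = HelixBox(phi=(-104.6, -46.6), psi_unwrapped=(131.0, 189.0), omega_unwrapped=CIS_RANGE)

HELIX_LABELS = (PPII_LABEL, PPI_LABEL, OTHER_LABEL)


def assign_ppii_ppi(phi, psi, omega):
    """Label residue-frames PPII / PPI / other from (phi, psi, omega)."""
    phi_a = np.asarray(phi, dtype=float)
    psi_a = np.asarray(psi, dtype=float)
    omega_a = np.asarray(omega, dtype=float)
    for name, arr in (("phi", phi_a), ("psi", psi_a), ("omega", omega_a)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite angles")
    labels = np.full(np.broadcast(phi_a, psi_a, omega_a).shape, OTHER_LABEL, dtype=object)
    labels[PPII_BOX.contains(phi_a, psi_a, omega_a)] = PPII_LABEL
    labels[PPI_BOX.contains(phi_a, psi_a, omega_a)] = PPI_LABEL
    if np.ndim(phi) == 0 and np.ndim(psi) == 0 and np.ndim(omega) == 0:
        return str(labels[()])
    return labels


def pucker_state(chi2):
    """Ring pucker from chi2: up (> +10), down (< -10) or planar."""
    arr = np.asarray(chi2, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("chi2 contains non-finite angles")
    wrapped = np.asarray(wrap_degrees(arr))
    labels = np.full(wrapped.shape, PLANAR, dtype=object)
    labels[wrapped > PUCKER_CUTOFF] = UP
    labels[wrapped < -PUCKER_CUTOFF] = DOWN
    if np.ndim(chi2) == 0:
        return str(labels[()])
    return labels


@dataclass
class SSAssignment:
    """Per-frame, per-residue helix labels with optional pucker labels."""

    labels: np.ndarray  # (n_frames, n_residues) of PPII/PPI/other
    residues: tuple[str, ...]
    pucker: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.atleast_2d(np.asarray(self.labels, dtype=object))
        self.residues = tuple(self.residues)
        if self.labels.shape[1] != len(self.residues):
            raise ValueError("label columns must match residue names")
        if self.pucker is not None:
            self.pucker = np.atleast_2d(np.asarray(self.pucker, dtype=object))
            if self.pucker.shape != self.labels.shape:
                raise ValueError("pucker shape must match labels")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        frames, res = np.meshgrid(
            np.arange(self.n_frames), np.arange(len(self.residues)), indexing="ij"
        )
        df = pd.DataFrame(
            {
                "frame": frames.ravel(),
                "residue": np.asarray(self.residues, dtype=object)[res.ravel()],
                "ss_label": self.labels.ravel(),
            }
        )
        if self.pucker is not None:
            df["pucker_label"] = self.pucker.ravel()
        return df


def assign_trajectory(traj) -> SSAssignment:
    """Helix (and pucker, when chi2 is present) assignment for a trajectory."""
    if traj.phi is None or traj.psi is None:
        raise ValueError("trajectory lacks phi/psi channels required for helix assignment")
    labels = assign_ppii_ppi(traj.phi, traj.psi, traj.omega)
    pucker = pucker_state(traj.chi2) if traj.chi2 is not None else None
    return SSAssignment(labels=labels, residues=traj.sites, pucker=pucker)


def ss_fraction_by_residue(assignment: SSAssignment, weights=None) -> pd.DataFrame:
    """Reweighted fraction of frames in each helix class, per residue.

    Returns a residues x {PPII, PPI, other} table whose rows sum to 1; the
    peptide-average PPII content is the mean of the PPII column.
    """
    n = assignment.n_frames
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(getattr(weights, "weights", weights), dtype=float)
        if w.shape != (n,):
            raise ValueError("weights length must match frame count")
    rows = []
    for j in range(len(assignment.residues)):
        col = assignment.labels[:, j]
        rows.append([w[col == label].sum() / w.sum() for label in HELIX_LABELS])
    return pd.DataFrame(rows, index=list(assignment.residues), columns=list(HELIX_LABELS))


def peptide_average_ppii(fractions: pd.DataFrame) -> float:
    """Mean PPII fraction over residues (the per-peptide PPII content)."""
    return float(fractions[PPII_LABEL].mean())
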