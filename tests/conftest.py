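"""Shared fixtures: synthetic ensembles with analytically known equilibria.

Heavy Monte Carlo fixtures are session-scoped so the sampling cost is paid
once.  Validation chains use a 120-degree proposal width (shorter
autocorrelation time than the 30-degree production default) so that
equilibrium comparisons have useful effective sample sizes.
"""

from __future__ import annotations

import numpy as np
import pytest

from proliso import (
    MultiSiteSpec,
    TorsionPotentialSpec,
    TorsionTerm,
    estimate_boost,
    generate_multisite,
    peptide_bond_spec,
    sample_boosted_trajectory,
)

VALIDATION_PROPOSAL_WIDTH = 120.0


def make_boosted_spec(barrier: float = 4.0, target_beta_dv: float = 1.0) -> TorsionPotentialSpec:
    """2-fold peptide-bond spec with a well-depth-filling harmonic boost."""
    bare = peptide_bond_spec(barrier=barrier)
    return TorsionPotentialSpec(
        terms=bare.terms, boost=estimate_boost(bare, target_beta_dv), temperature=300.0
    )


def make_asymmetric_spec(
    v2: float = 4.0, v1: float = 1.0, boost: bool = True
) -> TorsionPotentialSpec:
    """2-fold + 1-fold torsion: cis and trans wells of unequal depth."""
    terms = (
        TorsionTerm(n=2, v=v2, gamma_deg=180.0),
        TorsionTerm(n=1, v=v1, gamma_deg=0.0),
    )
    spec = TorsionPotentialSpec(terms=terms, temperature=300.0)
    if boost:
        spec = TorsionPotentialSpec(
            terms=terms, boost=estimate_boost(spec, 1.0), temperature=300.0
        )
    return spec


#: Five sites with graded cis penalties, emulating a proline-rich chain
#: whose marginal cis fractions span roughly 10-30 %.
FIVE_SITE_V1 = (0.5, 0.7, 0.9, 1.1, 1.3)


def make_five_site_spec(coupling: str = "independent") -> MultiSiteSpec:
    return MultiSiteSpec(
        sites=tuple(make_asymmetric_spec(v1=v1, boost=False) for v1 in FIVE_SITE_V1),
        coupling=coupling,
    )


@pytest.fixture(scope="session")
def boosted_run():
    """10^6-frame boosted chain on the symmetric 4 kcal/mol 2-fold potential."""
    spec = make_boosted_spec()
    traj = sample_boosted_trajectory(
        spec, 1_000_000, seed=1234, proposal_width=VALIDATION_PROPOSAL_WIDTH
    )
    return spec, traj


@pytest.fixture(scope="session")
def asymmetric_boosted_run():
    """2x10^5-frame boosted chain on the asymmetric (2-fold + 1-fold) potential."""
    spec = make_asymmetric_spec()
    traj = sample_boosted_trajectory(
        spec, 200_000, seed=4321, proposal_width=VALIDATION_PROPOSAL_WIDTH
    )
    return spec, traj


@pytest.fixture(scope="session")
def five_site_replicates():
    """Four independent-replicate chains of five uncoupled sites."""
    spec = make_five_site_spec()
    ss = np.random.SeedSequence(20211115)
    return spec, [
        generate_multisite(
            spec, 200_000, child, proposal_width=VALIDATION_PROPOSAL_WIDTH
        )
        for child in ss.spawn(4)
    ]
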