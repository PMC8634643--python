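"""Independence analysis of multi-proline cis states.

For every subset of proline sites the expected percent of the ensemble
with all members simultaneously cis — assuming sites isomerize
independently, i.e. the product of the marginal cis fractions — is compared
with the observed simultaneous-cis percentage.  Agreement across all
subsets indicates purely stochastic, uncooperative isomerization; a locked
chain (all sites flipping together) maximally violates it.

No formal hypothesis test is attached: expected and observed are reported
with across-replicate standard deviations, and "significance" is read as
non-overlap of the +-1 s.d. intervals, descriptively.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .isomers import CIS, IsomerStateSeries


def expected_joint_cis(marginals, subset) -> float:
    """Percent expected with all subset sites cis if sites are independent.

    ``marginals`` maps site name -> cis fraction in [0, 1]; the result is
    100 x the product over the subset.
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    product = 1.0
    for site in subset:
        p = float(marginals[site])
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"marginal for {site!r} outside [0, 1]: {p}")
        product *= p
    return 100.0 * product


def observed_joint_cis(states: IsomerStateSeries, weights=None, subset=None) -> float:
    """Reweighted percent of frames with every subset site simultaneously cis."""
    subset = tuple(states.sites if subset is None else subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    cols = []
    for site in subset:
        if site not in states.sites:
            raise KeyError(f"subset site {site!r} not in {states.sites}")
        cols.append(states.sites.index(site))
    if weights is None:
        w = np.full(states.n_frames, 1.0 / states.n_frames)
    else:
        w = np.asarray(getattr(weights, "weights", weights), dtype=float)
        if w.shape != (states.n_frames,):
            raise ValueError("weights length must match frame count")
    all_cis = np.all(states.states[:, cols] == CIS, axis=1)
    return 100.0 * float(w[all_cis].sum() / w.sum())


def cis_marginals(states: IsomerStateSeries, weights=None) -> dict[str, float]:
    """Per-site cis fraction of total weight (all frames in the denominator)."""
    if weights is None:
        w = np.full(states.n_frames, 1.0 / states.n_frames)
    else:
        w = np.asarray(getattr(weights, "weights", weights), dtype=float)
    return {
        site: float(w[states.states[:, j] == CIS].sum() / w.sum())
        for j, site in enumerate(states.sites)
    }


def enumerate_subsets(sites, max_size: int, min_size: int = 2):
    """All site subsets with min_size <= size <= max_size, in canonical order."""
    sites = tuple(sites)
    upper = min(max_size, len(sites))
    for k in range(min_size, upper + 1):
        yield from combinations(sites, k)


def correlation_report(
    replicates,
    max_subset_size: int | None = None,
    min_subset_size: int = 2,
) -> pd.DataFrame:
    """Expected vs. observed joint-cis percentages for all site subsets.

    ``replicates`` is a sequence of ``(states, weights)`` pairs, one per
    independent simulation (weights may be None for unweighted data).  Each
    replicate is reweighted independently; expected and observed values are
    averaged unweighted across replicates, with the sample standard
    deviation (ddof=1) reported across replicates — NaN for a single
    replicate.

    Returns a table with columns: subset, size, expected_pct,
    observed_pct_mean, observed_pct_sd, n_replicates.
    """
    replicates = list(replicates)
    if not replicates:
        raise ValueError("need at least one replicate")
    sites = replicates[0][0].sites
    for states, _ in replicates:
        if states.sites != sites:
            raise ValueError("replicates disagree on site names")
    if max_subset_size is None:
        max_subset_size = len(sites)
    per_rep = []
    for states, weights in replicates:
        marg = cis_marginals(states, weights)
        per_rep.append((states, weights, marg))
    rows = []
    n_rep = len(replicates)
    for subset in enumerate_subsets(sites, max_subset_size, min_subset_size):
        expected = np.array(
            [expected_joint_cis(marg, subset) for _, _, marg in per_rep]
        )
        observed = np.array(
            [observed_joint_cis(states, weights, subset) for states, weights, _ in per_rep]
        )
        rows.append(
            {
                "subset": "+".join(subset),
                "size": len(subset),
                "expected_pct": expected.mean(),
                "expected_pct_sd": expected.std(ddof=1) if n_rep > 1 else np.nan,
                "observed_pct_mean": observed.mean(),
                "observed_pct_sd": observed.std(ddof=1) if n_rep > 1 else np.nan,
                "n_replicates": n_rep,
            }
        )
    return pd.DataFrame(rows)
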