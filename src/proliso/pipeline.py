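"""End-to-end orchestration: simulate/ingest -> reweight -> classify -> report.

A single :class:`RunConfig` (usually loaded from YAML) drives the whole
analysis.  Exactly one of ``inputs`` (trajectory table paths) or
``synthetic`` (a multi-site torsion spec) must be present; synthetic runs
require a seed.  All stage outputs are delimited text tables plus one
machine-readable ``summary.yaml`` whose content is a pure function of the
config and seed (reruns are byte-identical).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .correlation import correlation_report, observed_joint_cis
from .isomers import (
    IsomerStateSeries,
    cis_percentage,
    classify_trajectory,
    flip_frequency,
)
from .potentials import (
    BoostSpec,
    MultiSiteSpec,
    TorsionPotentialSpec,
    TorsionTerm,
    estimate_boost,
)
from .reweight import (
    FrameWeights,
    anharmonicity,
    exact_weights,
    maclaurin_weights,
    pmf_cumulant2,
    pmf_from_weights,
    uniform_weights,
)
from .structure import assign_trajectory, ss_fraction_by_residue
from .synthetic import DEFAULT_BURN_IN, DEFAULT_DT_PS, DEFAULT_PROPOSAL_WIDTH, generate_multisite
from .trajectory import DihedralTrajectory, validate_table


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


@dataclass
class SyntheticConfig:
    """Synthetic multi-site generator settings."""

    sites: MultiSiteSpec
    n_frames: int = 100_000
    replicates: int = 1
    proposal_width: float = DEFAULT_PROPOSAL_WIDTH
    burn_in: int = DEFAULT_BURN_IN
    dt_ps: float = DEFAULT_DT_PS


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    output_dir: Path
    inputs: list[Path] = field(default_factory=list)
    synthetic: SyntheticConfig | None = None
    seed: int | None = None
    temperature: float = 300.0
    reweight_method: str = "maclaurin"
    maclaurin_order: int = 10
    pmf_bins: int = 60
    max_subset_size: int | None = None
    raw: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if bool(self.inputs) == (self.synthetic is not None):
            raise ValueError("exactly one of 'inputs' or 'synthetic' must be given")
        if self.synthetic is not None and self.seed is None:
            raise ValueError("synthetic runs require a seed")


def _parse_site(entry: dict, temperature: float) -> tuple[str, TorsionPotentialSpec]:
    terms = tuple(
        TorsionTerm(n=int(t["n"]), v=float(t["v"]), gamma_deg=float(t["gamma_deg"]))
        for t in entry["terms"]
    )
    spec = TorsionPotentialSpec(terms=terms, boost=None, temperature=temperature)
    boost_cfg = entry.get("boost")
    boost: BoostSpec | None = None
    if boost_cfg:
        if "k" in boost_cfg:
            boost = BoostSpec(threshold=float(boost_cfg["threshold"]), k=float(boost_cfg["k"]))
        elif "target_mean_beta_dv" in boost_cfg:
            boost = estimate_boost(spec, float(boost_cfg["target_mean_beta_dv"]))
        else:
            raise ValueError("boost config needs either (threshold, k) or target_mean_beta_dv")
    spec = TorsionPotentialSpec(terms=terms, boost=boost, temperature=temperature)
    return str(entry.get("name", "")), spec


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration (documented schema in the README)."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    temperature = float(raw.get("temperature", 300.0))
    synthetic = None
    if "synthetic" in raw:
        syn = raw["synthetic"]
        names, specs = [], []
        for i, entry in enumerate(syn["sites"]):
            name, spec = _parse_site(entry, temperature)
            names.append(name or f"pro{i + 1}")
            specs.append(spec)
        synthetic = SyntheticConfig(
            sites=MultiSiteSpec(
                sites=tuple(specs),
                coupling=syn.get("coupling", "independent"),
                names=tuple(names),
            ),
            n_frames=int(syn.get("n_frames", 100_000)),
            replicates=int(syn.get("replicates", 1)),
            proposal_width=float(syn.get("proposal_width", DEFAULT_PROPOSAL_WIDTH)),
            burn_in=int(syn.get("burn_in", DEFAULT_BURN_IN)),
            dt_ps=float(syn.get("dt_ps", DEFAULT_DT_PS)),
        )
    return RunConfig(
        output_dir=Path(raw.get("output_dir", "proliso_out")),
        inputs=[Path(p) for p in raw.get("inputs", [])],
        synthetic=synthetic,
        seed=raw.get("seed"),
        temperature=temperature,
        reweight_method=str(raw.get("reweighting", {}).get("method", "maclaurin")),
        maclaurin_order=int(raw.get("reweighting", {}).get("order", 10)),
        pmf_bins=int(raw.get("pmf", {}).get("bins", 60)),
        max_subset_size=raw.get("correlation", {}).get("max_subset_size"),
        raw=raw,
    )


def compute_weights(
    traj: DihedralTrajectory, method: str, order: int = 10
) -> FrameWeights:
    """Frame weights for one trajectory by the configured estimator."""
    if method == "exact":
        return exact_weights(traj.delta_v, traj.temperature)
    if method == "maclaurin":
        return maclaurin_weights(traj.delta_v, traj.temperature, order=order)
    if method == "uniform":
        return uniform_weights(traj.n_frames, traj.temperature)
    raise ValueError(f"unknown reweighting method {method!r}")


def _load_replicates(config: RunConfig) -> list[DihedralTrajectory]:
    if config.synthetic is not None:
        syn = config.synthetic
        ss = np.random.SeedSequence(int(config.seed))
        children = ss.spawn(syn.replicates)
        return [
            generate_multisite(
                syn.sites,
                syn.n_frames,
                child,
                proposal_width=syn.proposal_width,
                burn_in=syn.burn_in,
                dt_ps=syn.dt_ps,
                replicate=f"rep{i + 1}",
            )
            for i, child in enumerate(children)
        ]
    trajs = []
    for p in config.inputs:
        diag = validate_table(p)
        if not diag.ok:
            raise PipelineError("ingest", f"{p}: " + "; ".join(diag.errors))
        trajs.append(
            DihedralTrajectory.from_table(p, temperature=config.temperature, replicate=str(p))
        )
    return trajs


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and write all tables plus ``summary.yaml``.

    Returns the summary dictionary.  Stage failures raise
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    trajs = _load_replicates(config)
    sites = trajs[0].sites

    replicate_rows = []
    rep_pairs: list[tuple[IsomerStateSeries, FrameWeights]] = []
    for i, traj in enumerate(trajs):
        label = traj.replicate or f"rep{i + 1}"
        if config.synthetic is not None:
            traj.to_table(outdir / f"trajectory_{label}.csv")
        try:
            weights = compute_weights(traj, config.reweight_method, config.maclaurin_order)
        except ValueError as exc:
            raise PipelineError("reweight", f"replicate {label}: {exc}") from exc
        states = classify_trajectory(traj)
        rep_pairs.append((states, weights))
        cis = cis_percentage(states, weights)
        flips = flip_frequency(states)
        for site in sites:
            replicate_rows.append(
                {
                    "replicate": label,
                    "site": site,
                    "cis_pct": float(cis[site]),
                    "flips_per_ns": float(flips[site]),
                }
            )
    import pandas as pd

    per_rep = pd.DataFrame(replicate_rows)
    per_rep.to_csv(outdir / "isomer_stats.csv", index=False, float_format="%.10g")

    # pooled per-site PMFs and anharmonicity over concatenated replicates
    pooled_dv = np.concatenate([t.delta_v for t in trajs])
    summary_sites: dict[str, Any] = {}
    for j, site in enumerate(sites):
        omega = np.concatenate([t.omega[:, j] for t in trajs])
        try:
            weights = compute_weights(
                DihedralTrajectory(
                    dt_ps=trajs[0].dt_ps,
                    omega=omega[:, None],
                    delta_v=pooled_dv,
                    sites=(site,),
                    temperature=config.temperature,
                ),
                config.reweight_method,
                config.maclaurin_order,
            )
            pmf_w = pmf_from_weights(omega, weights, bins=config.pmf_bins)
            pmf_c2 = pmf_cumulant2(omega, pooled_dv, config.temperature, bins=config.pmf_bins)
            anh = anharmonicity(omega, pooled_dv, bins=config.pmf_bins)
        except ValueError as exc:
            raise PipelineError("pmf", f"site {site}: {exc}") from exc
        pmf_w.to_table(outdir / f"pmf_{site}_{weights.method}.csv")
        pmf_c2.to_table(outdir / f"pmf_{site}_cumulant2.csv")
        anh.to_dataframe().to_csv(
            outdir / f"anharmonicity_{site}.csv", index=False, float_format="%.10g"
        )
        grp = per_rep[per_rep["site"] == site]
        summary_sites[site] = {
            "cis_pct_mean": float(grp["cis_pct"].mean()),
            "cis_pct_sd": float(grp["cis_pct"].std(ddof=1)) if len(grp) > 1 else None,
            "flips_per_ns_mean": float(grp["flips_per_ns"].mean()),
            "pmf_barrier_kcal_mol": {
                weights.method: round(pmf_w.barrier_height(), 6),
                "cumulant2": round(pmf_c2.barrier_height(), 6),
            },
            "anharmonicity_avg": round(anh.average, 8),
            "anharmonicity_passed": anh.passed,
        }

    summary: dict[str, Any] = {
        "provenance": {
            "package": "proliso",
            "version": __version__,
            "seed": config.seed,
            "config": config.raw or None,
        },
        "n_replicates": len(trajs),
        "n_frames_per_replicate": trajs[0].n_frames,
        "sites": summary_sites,
    }

    if len(sites) >= 2:
        report = correlation_report(rep_pairs, max_subset_size=config.max_subset_size)
        report.to_csv(outdir / "correlation.csv", index=False, float_format="%.10g")
        all_trans = [
            100.0 - observed_joint_cis_any(states, weights) for states, weights in rep_pairs
        ]
        summary["all_trans_pct_mean"] = float(np.mean(all_trans))
        summary["all_trans_pct_sd"] = (
            float(np.std(all_trans, ddof=1)) if len(all_trans) > 1 else None
        )

    if trajs[0].phi is not None and trajs[0].psi is not None:
        fracs = []
        for (states, weights), traj in zip(rep_pairs, trajs):
            assignment = assign_trajectory(traj)
            fracs.append(ss_fraction_by_residue(assignment, weights))
        mean_frac = sum(fracs) / len(fracs)
        mean_frac.to_csv(outdir / "ss_fractions.csv", float_format="%.10g")
        summary["ppii_fraction_peptide_mean"] = float(mean_frac["PPII"].mean())
        summary["ppi_fraction_peptide_mean"] = float(mean_frac["PPI"].mean())

    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True, default_flow_style=False)
    return summary


def observed_joint_cis_any(states: IsomerStateSeries, weights=None) -> float:
    """Percent of frames with at least one site in cis (100 - all-trans%).

    'All trans' here means no site is cis; unassigned barrier frames on a
    site count as not-cis for that site.
    """
    if weights is None:
        w = np.full(states.n_frames, 1.0 / states.n_frames)
    else:
        w = np.asarray(getattr(weights, "weights", weights), dtype=float)
    any_cis = np.any(states.states == "cis", axis=1)
    return 100.0 * float(w[any_cis].sum() / w.sum())
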