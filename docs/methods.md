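# Methods

## Model

The peptide-bond (ω) torsion is modelled in the Amber cosine-series form

    U(ω) = Σ_n (V_n / 2) (1 + cos(nω − γ_n)),

angles in degrees, energies in kcal/mol. For a pure 2-fold term with phase
γ = 180° the minima sit exactly at ω = 0° (cis) and ω = 180° (trans) and the
interconversion barrier equals V₂; this coefficient alone controls the
cis/trans barrier without touching any other coordinate, which is why the
package ships two presets: the force-field default V₂ = 20 kcal/mol and a
lowered V₂ = 15 kcal/mol used to accelerate isomer sampling. Asymmetric
cis/trans populations are produced by adding a 1-fold term (γ = 0°
penalizes cis by V₁ at ω = 0°).

The Gaussian boost is harmonic below a threshold:

    ΔV(ω) = ½ k (E − U(ω))²  for U < E,  else 0,

with k ≥ 0 in (kcal/mol)⁻¹. Engine-side boost estimation is out of scope;
`estimate_boost` offers a closed-form helper that sets E to the potential
maximum (upper-bound threshold convention) and solves k from a target
unboosted Boltzmann average of βΔV. Boltzmann constant
k_B = 0.0019872041 kcal/(mol·K); default temperature 300 K.

## Synthetic sampler

Frames are generated by Metropolis Monte Carlo on U* = U + ΔV with a
symmetric uniform proposal (default half-width 30°), burn-in 10⁴ steps,
every step retained; the retained ensemble converges to ∝ e^{−U*/kT} and
satisfies detailed balance exactly (tested as an identity on the acceptance
ratio). A Monte Carlo chain was chosen over Langevin dynamics because only
equilibrium populations and their reweighting are analyzed downstream; a
"flipping frequency" measured on these chains is an event rate per
retained-frame interval (nominal spacing 0.1 ps), not physical kinetics.
Multi-site chains are either *independent* (one chain per site, seeded from
distinct children of one seed sequence — isomerization uncorrelated by
construction) or *locked* (all sites share one ω series — the
maximal-correlation fixture); the per-frame ΔV is summed over sites.

What the generator emulates: boosted multi-state ω dynamics with exactly
known unbiased equilibria, per-frame boost energies consistent with the
recorded angles, and backbone (φ, ψ, ω) series with prescribed
PPII/PPI/other occupancies (drawn uniformly inside the canonical boxes).
What it does not emulate: solvent and full-system energetics (ΔV here is a
deterministic function of ω, so its within-bin distribution is *not*
Gaussian the way a real total-energy boost is — see anharmonicity below),
true isomerization kinetics, and coupling mechanisms other than the
locked/independent extremes. Passing tests therefore certify the
estimators and classifiers, not any property of real peptides.

Validation fixtures in the test suite use a proposal half-width of 120°
rather than the 30° default: the wider proposal shortens the chain's
autocorrelation time by over an order of magnitude, so equilibrium
comparisons at 10⁵–10⁶ frames have useful effective sample sizes. Problem
sizes used by the suite: 10⁶ frames for the single-site reweighting/PMF
checks, 4 replicates × 2×10⁵ frames × 5 sites for the independence
property.

## Reweighting estimators

Exact weights w_j ∝ e^{βΔV_j} (computed with the max subtracted before
exponentiation). Maclaurin weights truncate the exponential at order K
(default 10); order 0 gives uniform weights. For βΔV ≤ 1 the order-10
truncation error is bounded by e·(βΔV)¹¹/11! < 10⁻⁷ relative, which the
tests assert. Truncation damps the largest-boost frames, so the
Maclaurin PMF systematically does not exceed the cumulant-2 barrier; the
suite asserts barrier(Maclaurin) ≤ barrier(cumulant2) + 0.1 kcal/mol on
near-Gaussian-boost data.

PMFs along ω use 60 bins of 6° over (−180°, +180°] by default (the source
binning being unstated, 6° resolves the ~140°-wide wells comfortably while
keeping ≥10³ frames per occupied bin at the fixture sizes). Two
estimators:

- weight-based: F_j = −kT ln(Σ_{i∈j} w_i) + C;
- cumulant-2: F_j = −kT ln p*_j − [⟨ΔV⟩_j + (β/2)σ²_ΔV,j] + C, with the
  in-bin mean and variance taken unweighted over the frames in the bin
  (the unweighted choice is the natural reading of a per-bin expansion of
  the biased ensemble; the alternative is not implemented).

C min-shifts the profile so the lowest occupied bin is exactly 0. Empty
bins carry NaN and never participate in the min-shift. Degenerate inputs:
an all-empty histogram raises; a single-frame trajectory yields weight 1.

Standard errors of reweighted means come from a block bootstrap (20
contiguous blocks, 200 resamples, weights recomputed per resample), which
absorbs both chain autocorrelation and weight renormalization; per-replicate
scatter (mean ± sd over independent chains, ddof = 1) is reported alongside.

## Anharmonicity

Per ω-bin, γ = S_gauss − S_emp, where S_emp is the differential entropy of
the in-bin ΔV sample (histogram estimator, Freedman–Diaconis bin width,
Scott fallback for zero IQR) and S_gauss = ½ ln(2πe σ²) for the same bin;
bins with fewer than two frames or zero variance contribute γ = 0. Since
the Gaussian maximizes entropy at fixed variance, γ ≥ 0 in expectation;
finite samples fluctuate slightly negative, so the pass criterion compares
|population-weighted average γ| < 10⁻³. On an exactly Gaussian boost the
average is below 10⁻² at 10⁵ frames and shrinks with sample size (tested).
On the synthetic generator's deterministic boost the diagnostic reports
γ ≈ 0.2–0.5 — correctly, because a deterministic function of ω restricted
to a narrow bin is near-uniform, not Gaussian; the pass flag is honest
there and the diagnostic is meaningful primarily for noisy (full-system)
boosts.

## State and structure classification

cis = [−90°, +50°), trans = [+100°, +240°) ≡ [+100°, +180°] ∪ (−180°, −120°)
after wrapping to (−180°, +180]; intervals are half-open at the upper bound
so boundary angles classify deterministically. Frames in the two gaps are
*unassigned*: excluded from cis/trans percentages (so cis% + trans% = 100)
and bridged in flip counting (cis → unassigned → trans counts one flip),
so brief barrier excursions are not double-counted. Flip rates divide by
the span (n_frames − 1)·Δt.

Helix boxes: PPII requires φ ∈ [−104.6°, −46.6°], ψ ∈ [+107.9°, +165.9°]
and ω trans; PPI requires the same φ, ψ ∈ [+131°, +189°] (upper bound
wrapping to −171°) and ω cis. φ and ψ bounds are closed; ω reuses the
half-open cis/trans ranges, which keeps the boxes disjoint. Assignment is
per-residue, per-frame with no minimum run length. Pucker from χ₂: up
> +10°, down < −10°, planar in between. Ring-pucker and helix fractions
are reported as reweighted per-residue fractions; peptide-level PPII is
the unweighted mean over residues.

## Correlation analysis

For every subset of sites (sizes 2 up to the site count by default) the
expected simultaneous-cis percentage under independence, 100·Π p_i, is
compared with the observed reweighted percentage. Marginals for the
expectation use all frames (a site's unassigned frames count as not-cis),
matching the observed-joint convention so the locked fixture gives exact
equality observed = marginal and expected = marginalᵏ. Each replicate is
reweighted independently; subsets are summarized as mean ± sd (ddof = 1)
across replicates, NaN for a single replicate. No hypothesis test is
attached — disagreement is read descriptively as non-overlap of ±1 sd
intervals.

## CD bookkeeping

[θ]_MR = 100·θ_deg/(c_MR·l) with c_MR = n·c; the conversion is linear and
round-trips exactly with its inverse. %PPII = ([θ]₂₂₈ + 6100)/137 with θ in
deg·cm²·dmol⁻¹ — the denominator is 137.00 (a value of 13700 would be
inconsistent with the published percentage/ellipticity pairs this
calibration reproduces: −796 → 38.7%, −334 → 42.1%). One published
in-vitro pair (−1300 → 35.5%) is internally inconsistent with the same
formula, which gives 35.0%; the formula is implemented as stated, not
patched per data point. Spectrum scaling is the closed-form least-squares
scalar Σ(calc·ref)/Σ(calc²) over the full common wavelength range by
default (the fitting sub-range being unstated, full overlap is the least
arbitrary choice; a sub-range is configurable). Basis combination is the
plain convex combination Σ f_c·B_c(λ); basis sets themselves are
user-supplied tables, never bundled.

## Pipeline

One YAML config drives simulate/ingest → reweight → classify → statistics
→ reports. All randomness derives from a single seed through
`numpy.random.SeedSequence` children, and the summary contains no
timestamps, so reruns are byte-identical. The CLI (`proliso`) is a thin
wrapper over the library; exit codes: 0 ok, 1 input error, 2 numerical
failure. Optional conversion of coordinate trajectories to dihedral tables
is deliberately left to external tools (mdtraj/MDAnalysis one-liners); the
core consumes angle tables only, which keeps it testable without
structural files.

## Known limitations

- Monte Carlo "time" is not physical; flip frequencies are comparable
  between runs of the same settings only.
- The anharmonicity diagnostic is conservative on deterministic synthetic
  boosts (see above).
- The cumulant-2 PMF assumes near-Gaussian in-bin boosts; on strongly
  anharmonic data both estimators are reported but neither is certified.
- Expected-joint-cis error bars do not propagate marginal uncertainty
  within a replicate; only across-replicate scatter is reported.
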