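# Methods

This note records the model the package implements, the algorithmic and
numerical choices behind it, what the synthetic fixtures do and do not
emulate, and known limitations.

## The probabilistic model

The thermodynamic state of a network with `m` metabolites and a
constrained reaction set Γ (size γ) is the vector
`t = [ln c, ΔrG′°, ΔrG′]` of log molar concentrations, standard
transformed Gibbs reaction energies (kJ/mol, assumed already corrected
for pH, ionic strength and transport) and actual reaction energies.
Priors are Gaussian: `ln c ~ N(μ_c, Σ_c)` (log-normal concentrations,
natural log) and `ΔrG′° ~ N(μ°, Σ°)`, where Σ° is typically
rank-deficient because group-contribution estimators share error terms
across reactions.  The linear identity
`ΔrG′ = ΔrG′° + RT·S_Γᵀ·ln c` makes `t` jointly Gaussian with mean
`[μ_c, μ°, R·[μ_c; μ°]]` and a block covariance determined by
`R = [RT·S_Γᵀ, I]`.

Plausible states are restricted to a confidence region
`(t−μ_t)ᵀ Σ_t⁺ (t−μ_t) ≤ χ²_{q,α}` with `q = rank(Σ_t)`.  The package
works in whitened coordinates `t = μ_t + Q·m` where `Σ_t = QQᵀ` and `m`
is a standard normal of dimension `q`; the confidence region becomes the
ball `‖m‖² ≤ χ²_{q,α}`.

**Factor construction.**  `Q` is built by eigendecomposing the *prior*
covariance `blkdiag(Σ_c, Σ°) = PPᵀ` (eigenvalue cutoff `1e−9·λ_max`,
columns scaled by √λ so `m` is standard normal) and pushing it through
the linear map: `Q = [P; R·P]`.  This is algebraically identical to a
matrix square root of Σ_t, but the energy-decomposition identity then
holds *exactly by construction* for every generated `t` rather than up
to eigensolver error, and `‖m‖²` still equals the Mahalanobis form
because `Q` has full column rank.  The reduced energy-only space uses
its own factor `Σ_r = Q_r Q_rᵀ` of rank `q_r`; on rank-deficient priors
`q_r < γ`, which is exactly the dimensionality saving the sampler
exploits.

Default confidence is α = 0.95 (configurable; there is no canonical
value).  Units are fixed internally: molar concentrations, kJ/mol
energies, `R = 8.314e−3 kJ·mol⁻¹·K⁻¹`, `T = 298.15 K` by default.

## Second law and the steady-state thermodynamic space

Every reaction in Γ must carry non-zero flux (`|v_i| ≥ v_min`, default
`1e−6 mmol·gDW⁻¹·h⁻¹`) in the direction of negative energy, with the
strict inequality implemented as `sign(v_i)·ΔrG′_i ≤ −ε`,
ε = 0.1 kJ/mol.  Both constants are configurable; they are numerical
stand-ins for strict inequalities and the results are insensitive to
them over several orders of magnitude.  Structurally blocked reactions
(zero flux in every steady-state solution, detected by per-reaction flux
maximization LPs at tolerance 1e−9) are removed from Γ automatically
with a warning, since they cannot satisfy the non-zero flux requirement.

The *steady-state thermodynamic space* is the confidence ball
intersected with the direction orthants whose sign pattern admits a
steady-state flux distribution (an LP check, memoized per sign
signature).

## PMO: the most probable state

The mode of the constrained distribution solves
`min ‖m‖² s.t. steady state, second law, confidence ball`.  The
continuous relaxation within a fixed direction assignment is the
Euclidean projection of the origin onto a polyhedron (the sign
constraints are linear in `m`), solved by the dual bound-constrained
quadratic program with L-BFGS-B followed by an active-set polish that
recovers the solution to ~1e−12.  The ball constraint never binds
inside an orthant: the projection is the orthant's minimum, so the
orthant is simply infeasible if the minimum exceeds the threshold.

The discrete directions are searched by depth-first branch-and-bound:
a node's partial assignment yields (i) an LP feasibility check with the
assigned sign/flux constraints and (ii) a convex lower bound from the
projection onto the assigned constraints only.  Both prune monotonely,
so the search is exact; equal-objective optima break ties toward the
lexicographically smallest direction signature (forward before
backward).  At the network sizes this package targets (desk-scale,
γ ≤ ~20) this is fast; it is not a substitute for an industrial MIQCP
solver at genome scale.

Big-M style formulations are avoided entirely — the branch-and-bound
never needs the coupling constants, which removes their numerical
pathologies.

**z-scores and anomalies.**  `z_i = (t*_i − μ_i)/σ_i` with σ from the
diagonal of Σ_t; zero-variance components get z = 0 at the mean and an
infinite flag otherwise.  Metabolites are anomalous when `|z| > θ`
(default θ = 1 — deliberately conservative, because the mode is the
*best case* and underestimates true deviations) or when a
non-intracellular metabolite is predicted at ≥ 10 mM.  Anomalies are
reported, never auto-curated: high-|z| pathway intermediates typically
indicate substrate channeling, wrong irreversibilities or bad standard
energies, and the right fix is a modeling decision.

**Initial points for the sampler.**  For every reversible reaction in Γ,
flux maximization and minimization LPs propose direction assignments;
PMO completes each into a feasible orthant, and a 30-step bisection on a
joint margin δ (sign constraints tightened by `δ·‖row‖`, ball radius
shrunk by δ) finds a strictly interior point.  Duplicate orthants are
merged; the unconstrained PMO orthant is always included.  The "distance
from the boundary" is a Chebyshev-like proxy mixing energy units and
ball units; any choice that keeps points uniformly away from all
boundaries serves the purpose (numerical robustness of the first ray
intersections).

## Structural assessment

Internal elementary flux modes are enumerated on the internal subnetwork
(exchange, biomass and maintenance reactions blocked) by the classical
double-description tableau on the reversible-split cone, with a
support-minimality filter per step, removal of forward/backward
two-cycles, and a hard cap (default 1e6 intermediate rays) that fails
loudly instead of truncating.  Enumeration is exact and intended for
reduced or toy models.

A cycle is *forced* when it is active, with its specific signs, in every
non-zero flux distribution.  The certificate has two parts, each an LP:

1. **Cannot be switched off** — with the cycle's support pinned to zero,
   no other reaction can carry flux ≥ 1e−6 (checked by maximizing each
   remaining reaction in both directions).
2. **Cannot run differently** — every single sign flip *and the full
   reversal* of the cycle is infeasible (all joint flips available via a
   flag).  The full reversal matters: a fully reversible cycle has
   infeasible single flips (flux coupling) but a feasible reversal, and
   is correctly not forced.

Reported cycles list their irreversible member reactions as suggested
reversibility relaxations; relaxing all of them makes the reversal
feasible and clears the cycle.

## TFS: sampling the thermodynamic space

Sampling runs in the reduced coordinates of the reaction energies
(dimension `q_r`), where the target is a standard normal truncated to
the ball and to feasible orthants.  Each Hit-and-Run step:

1. draws a ray direction (isotropic by default),
2. intersects the ray with the ball (quadratic formula) and with the
   half-spaces of irreversible reactions' fixed signs,
3. splits the chord at the zeros of the γ linear energy functions
   (crossings closer than 1e−12 in ray parameter are merged),
4. LP-checks each sub-segment's orthant (memoized),
5. samples a segment with probability proportional to its 1-D Gaussian
   mass — computed with `log_ndtr` differences, so far-tail segments
   (8σ+) keep finite log-weights — and a point within the segment by
   the truncated-normal inverse CDF.

Because the 1-D density along the ray is the exact conditional of the
target, the move leaves the target invariant for *any* symmetric
full-support ray distribution.  The segment containing the current point
is always present, guaranteeing aperiodicity; if every segment's weight
underflows the chain stays put rather than producing NaNs.

**Ray-orthant bound.**  A ray crosses at most γ+1 orthants — one more
than the number of sign hyperplanes, each crossed at most once.  When
the priors are full-rank (`q_r = γ`) this equals `q_r + 1`.  With
rank-deficient priors the γ hyperplanes persist inside the reduced
space, so the ambient bound γ+1 is the correct one and `q_r + 1` can be
exceeded (e.g. 4 crossings with `q_r = 2`, γ = 3 on the shortcut
fixture); the sampler records the maximum per run and the tests assert
the applicable bound.

**Convergence and adaptation.**  Chains (≥ 2, default 4) start from the
over-dispersed PMO interior points.  Diagnostics are rank-normalized
split PSRF and Geyer-truncated multi-chain ESS.  Optional adaptation
runs a 10% pilot, then inflates ray components of dimensions with
PSRF > 1.1 proportionally to PSRF² — a proposal change only, so the
stationary distribution is provably unchanged (each move still samples
the exact conditional along its ray).  This replaces basis-rescaling
plus density-reweighting schemes, which achieve the same goal with more
bookkeeping.  Burn-in defaults to 20% of steps; retained samples are
evenly thinned to a configured count.

**Orthant probabilities and their errors.**  Probabilities are
post-burn-in visit frequencies pooled over chains.  Their standard
errors combine the effective-sample-size estimate of the visit indicator
with a regenerative floor `p·√(2/E)`, `E` the number of excursions into
the orthant: rare orthants are visited in a few correlated clumps, and
the excursion count — not the step count — is the effective number of
independent events.  Without the floor, rare-orthant SEs are
systematically optimistic (verified against the across-seed spread of
repeated runs).

**Conditional concentrations.**  Given sampled energies, the conditional
law of `[ln c, ΔrG′°]` is Gaussian with mean linear in the energies and
a constant covariance (Schur complement; generalized inverse of Σ_r via
the same eigendecomposition), so one factorization serves all draws.
`ln c` is drawn from this conditional and `ΔrG′°` is reconstructed
through the energy decomposition, which the conditional satisfies almost
surely — every returned triple obeys the identity to machine precision
(~1e−15, against a 1e−8 contract).

## Flux sampling with the thermodynamic prior

Each direction assignment turns the flux space into a convex polytope:
bounds intersected with `v_i ≥ v_min` (or ≤ −v_min) for Γ, the same
`v_min` the sampler uses, so "non-zero flux" means one thing everywhere.
The polytope is parametrized on the null space of S around a
Chebyshev-style interior point (common-slack LP).  Coordinate
Hit-and-Run runs in a rounded basis estimated iteratively: short pilot
runs provide a sample covariance whose Cholesky factor approximates the
body's inertial ellipsoid (two rounds by default).  This serves the same
isotropy purpose as a maximum-volume inscribed ellipsoid without
requiring an SDP solver; for badly elongated polytopes more rounding
rounds may be needed.  Dimensions of numerically zero feasible width are
collapsed with a warning.

Orthants for the mixture are drawn without replacement with probability
proportional to their estimated mass; each selected orthant receives
draws proportional to its renormalized probability, allocated by largest
remainder so totals are exact and deterministic.  Direction calls label
a reaction irreversible when ≥ 95% of samples (flux signs, or negated
energy signs) agree.

## Synthetic fixtures and oracles

The generator produces chains, branch points, cycles, the
two-steps-plus-shortcut network, an irreversibility-conflict cycle, and
random chain-backbone networks with shortcut reactions (regenerated
deterministically until no internal reaction is blocked).  Default
priors: `ln c ~ N(ln 1e−4, 1²)` (0.1 mM with a one-log-unit spread, a
physiological scale), standard-energy means with 5 kJ/mol spread and
4 kJ/mol marginal SD — near-equilibrium values typical of central
metabolism, chosen so that several orthants carry appreciable mass.
Rank-deficient priors are built from fewer latent group contributions
than reactions; the shortcut fixture additionally ties its third energy
to the sum of the first two, and the conflict-cycle fixture's energies
sum to zero around the loop, making it thermodynamically infeasible by
construction.

Two independent oracles ground-truth the samplers: exact rejection
sampling from the prior (filtered by ball, irreversibility signs and
per-orthant LP) and exhaustive orthant enumeration with scrambled-Sobol
quasi-Monte-Carlo masses (γ ≤ 6).  The fixtures emulate the *structure*
of real problems — flux coupling, correlated energy uncertainties,
irreversibility conflicts — but not their scale, nor real measurement
noise, nor compartment effects; passing tests demonstrate algorithmic
correctness, not biological accuracy on any particular organism.

**Statistical test design.**  Sampler-versus-oracle comparisons use
per-orthant z-statistics with combined MC standard errors, restricted to
orthants whose expected visit count is in the normal regime (≥ 20); the
rare remainder is checked in aggregate.  The sampled SE carries an
allowance for its own estimation error (relative `1/√(2E)`).  Across the
~90 simultaneous comparisons of the acceptance suite, one borderline
3-SE exceedance is expected even under perfect agreement, so the gate
admits at most one comparison between 3 and 4 SE; genuine sampler
defects produce |z| in the 5–20 range and remain detected.

## Problem sizes

The shipped tests and the acceptance script run on networks with up to
8 constrained reactions, million-draw oracles, and sampler runs of
5000 steps × 4 chains — sizes chosen so the whole validation cycle
completes in minutes on one CPU while keeping every Monte-Carlo
comparison well-resolved.  All sizes scale up through configuration.

## Known limitations

* PMO's branch-and-bound and the EFM enumeration are exact but
  exponential in the worst case; genome-scale use requires model
  reduction first (out of scope here).
* No pH/ionic-strength transformations: standard energies are consumed
  already transformed.
* The CHRR rounding is covariance-based, not a true inscribed-ellipsoid
  computation; extremely anisotropic polytopes may mix slowly.
* Orthant probabilities for orthants rarer than the sampler's excursion
  resolution are reported but carry large relative errors, reflected in
  their SE.
* The KL screening statistic fits a Gaussian to the posterior by moment
  matching; strongly multimodal marginals (possible across orthants) are
  summarized coarsely.
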