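# Methods

## The estimation problem

Physician adoption of a new drug is modeled as a linear probability in the
peer adoption rates of four networks (patient-sharing P, medical group G,
hospital H, training T) plus physician covariates and peer-composition
controls. The linear-in-means structure makes the peer rates endogenous
twice over: simultaneity (each physician's outcome enters their peers' peer
rates) and correlated unobservables (shocks shared among peers). Estimation
is by two-stage least squares. The first stage regresses each peer adoption
rate on **all** instrument columns plus every included exogenous column; the
second stage substitutes fitted rates. Standard errors use the proper 2SLS
residual — computed with the *observed* endogenous columns — with the HC1
heteroskedasticity-robust sandwich, the convention of the major econometric
packages for robust IV inference.

Peer-mean instruments follow the exclusion logic of the peer-effects
literature: peer sex composition and peer payer mix predict peer adoption
(through the peers' own adoption equations) but have no direct route into a
physician's decision once the peer adoption rate itself is controlled. Peer
specialty mix and peer prescribing volume are deliberately *not* instruments
— a colleague's specialty or volume can influence referral and prescribing
behavior directly — so they enter as controls (c̄, v̄), and the instrument
builder refuses them outright.

Diagnostics implemented:

- per-endogenous **first-stage F** on the excluded instruments — robust Wald
  form by default, classical form retained because it ties analytically to
  the Cragg–Donald statistic (equality in the single-endogenous case is a
  regression test);
- **Cragg–Donald minimum eigenvalue** for any designated subset of
  endogenous columns, computed from the concentration matrix after
  partialling the included exogenous columns;
- **Sargan** overidentification statistic n·R² from regressing the 2SLS
  residual on instruments plus included exogenous columns, χ² with
  (instruments − endogenous) degrees of freedom; a just-identified model
  returns an explicit "undefined, df = 0" result rather than raising;
- an **LPM-versus-logit** fitted-probability comparison (mean, median,
  quartiles of the per-physician difference), with logistic separation
  flagged instead of propagated.

Networks whose first-stage F is at or below 10 are tagged "not reliable" in
all outputs; their coefficients are reported but should not be interpreted.

## The synthetic cohort generator

The generator emulates the study design end to end. Adoption propensities
solve the simultaneous system

    p = clip(β₀ + Xβ + Σ_k γ_k W_k p + u, 0.01, 0.99)

by fixed-point iteration; with row-stochastic W_k and Σ|γ_k| < 1 the map is
a contraction (clipping is 1-Lipschitz), so the equilibrium is unique and
iteration converges from any start. β₀ is calibrated by a secant search so
the mean propensity hits the target adoption rate to ±0.005 (requirement:
±0.02). Observed adoption is an independent Bernoulli draw from p. Those
draws are the package's central design decision: they act as classical
measurement error in observed peer rates — uncorrelated with the peer-mean
instruments — so 2SLS remains consistent while OLS is attenuated. A binary
best-response game would have changed the estimand itself.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| target_adoption_rate | 0.25 | first-in-class drug in the 25% adoption regime; 0.083 emulates a slow adopter market |
| target_median | 7 prescriptions | the median-rule threshold the prescribing counts are built around |
| true_gamma | P 0.6, H 0.3, G 0, T 0 | patient-sharing strongest, hospital moderate, group/training nil |
| true_beta | medicare_share 0.45, small demographic effects | Medicare-heavy panels adopt an anticoagulant-class drug more; keeps propensity dispersion small enough that clipping stays ≈4% |
| patients_per_physician_mean, sharing_concentration | 4.0, 1.7 | sparse patient-sharing (mean degree ≈7) — thin networks carry more identifying variation per peer |
| payer_community_sd | 0.28 | community-level spread of the Medicare weight (bounded uniform multiplier on the Dirichlet concentration) |
| confounder_sd / confounder_unit | 0 (off); 0.03 canonical when on / "group" | shared shock within a medical group — unobserved factors common among groups of peers |
| idiosyncratic_sd | 0.02 | latent taste heterogeneity beyond the Bernoulli draw |
| clip_bounds | (0.01, 0.99) | keeps the linear model interior and the contraction well-defined |

Two structural choices matter for identification and deserve explanation:

1. **Community-level payer mix.** The Medicare weight of each physician's
   payer mix carries a practice-community multiplier (bounded uniform, so no
   heavy left tail can push whole communities against the probability
   floor). Patient-sharing peers concentrate within a community while
   hospital peers average across a whole location, so the peer-mean Medicare
   instrument varies at community level for ȳ_P but is smoothed for ȳ_H —
   this is what separates γ_P from γ_H. Without spatial structure, peer
   means of individually-drawn covariates shrink as 1/√(peers) and the
   instruments are weak.
2. **Group-level confounder.** When enabled, a N(0, confounder_sd) shock is
   shared by all members of a medical group (solo physicians draw alone).
   The sharing unit is deliberately *different* from the communities that
   power the instruments: a confounder clustered on the same unit as the
   instruments inflates the finite-sample cross-moments that drive 2SLS bias
   toward OLS, which is a property of the experimental design rather than of
   the estimator. With `confounder_unit="community"` that regime can be
   produced on purpose (it is how the strong upward OLS bias demonstration
   is generated).

Prescribing counts are constructed so the median rule is exactly invertible:
adopters draw `median + extra` with half the mass exactly at the intended
median, non-adopters prescribe the drug at all with probability below
r/(2(1−r)), so adopters form a strict majority of ever-prescribers and the
realized cohort median equals the intended threshold. Class-level counts
are ≥1 every quarter so the default cohort passes the minimal-prescribing
filter intact. Affiliations are location-stratified (groups ~9 physicians,
hospitals ~3× larger, coverage 72%/90%), which keeps pairwise edge overlap
between the four networks near 0.13, inside the <0.20 regime that justifies
one joint model.

### What the generator does not emulate

No real geography or market shares, no patient-level clinical covariates,
no formulary or promotion effects, no time-varying adoption hazard, and
covariates are independent across physicians except for the payer-mix
community structure. Parameter recovery on these cohorts demonstrates that
the estimator and its diagnostics are implemented correctly under the
model's own assumptions — not that peer effects in any real cohort are
identified; that depends on the exclusion restrictions holding in the real
data.

## Social multiplier

The influence convention: adoption by physician i raises peer j's peer rate
by W[j, i] (the weight *j places on i*), so the first-order term of i's
multiplier is the i-th column sum of γW, and the full series sums to the
column sums of γW(I − γW)⁻¹. The closed form solves one sparse linear
system (I − γW′)m = γW′1; the truncated series is retained both as an
independent cross-check (agreement ≤1e-8 is a standing test) and for very
large cohorts where factorization is unattractive. Row-normalized W is used
rather than raw shared-patient counts because the series need not converge
under raw counts, and because the same W defines the model whose estimated
γ_P is plugged in as attenuation. Isolated physicians get multiplier 0; the
series diverges only if |γ| ≥ 1, which is refused.

Decile targeting ranks physicians by patient-sharing degree and separately
by class prescribing volume (ties broken by stable physician-id order so
reruns are identical), reports the mean multiplier per decile, and the three
headline ratios: top/bottom within each ranking and top-degree versus
top-volume.

## Numerical choices

- Fixed-point tolerance 1e-13 (max-norm), so re-applying the structural map
  moves no entry beyond 1e-10; non-convergence raises with the residual.
- Median rule uses the lower median for even support sizes — the threshold
  is then always an attained integer count, preserving "at least the
  median" semantics.
- Rank checks use QR with a numpy-style tolerance and name the offending
  columns; constant columns (e.g. a no-peer indicator when nobody is
  isolated) are dropped from the default model specification before
  fitting.
- Peer rates and shares are clipped to [0, 1] after the sparse dot product
  to absorb last-bit floating error in row sums.
- The 2SLS condition number of X̂′X̂ is checked; values above 1e10 emit a
  near-singularity warning rather than an error.

## Problem sizes used in validation

The test suite validates parameter recovery on 100 independent cohorts of
4,000 physicians (confounder on), the null world on 100 cohorts of 2,000,
Sargan size on 500 replicates of the compact linear-IV process at n = 2,000,
and consistency across n ∈ {1,000, 4,000, 16,000}. The acceptance script
uses one 2,000-physician pipeline run, 40 recovery cohorts at 4,000, and 200
calibration replicates. These sizes give Monte Carlo standard errors well
inside the asserted tolerances while keeping a full run in minutes on one
CPU.

## Known limitations

- Estimates for networks with weak instruments (typically T: training peers
  share school and graduation year, so their peer means are nearly collinear
  with own covariates — the structural reason training-network instruments
  are weak) are reported but unreliable; no LIML/GMM fallback is provided.
- The Sargan test is the homoskedastic form; with strong heteroskedasticity
  its size can drift from nominal.
- The clipping of propensities makes the structural model mildly nonlinear
  at the boundaries; at default dispersion ~4% of physicians sit on a bound.
- `compare_lpm_logit` enters endogenous columns as-is in both models; it
  compares functional forms, not causal estimates.
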