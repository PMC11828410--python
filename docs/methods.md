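# Methods

## Model

Conjugative transfer is modelled as a two-step contact process

    D + R  ⇌  C  →  D + T        (encounter k_on/A · D·R, dissolution k_off, resolution k_c = 1/τ)

with, in conjugation mode, the mirrored channels for transconjugants
acting as donors (T + R ⇌ C' → T + T). Treating the pair C as a
quasi-steady-state intermediate (and folding any reversibility k_off into
an effective k_on, as in Haldane's treatment of enzyme kinetics) gives the
Holling type-II per-donor transfer rate φ(R) = R·k_on/(1 + R·k_on·τ).
With recipients in excess, integrating over a mating time t yields
T/D = φ·t for mobilization and ln(1 + T/D) = φ·t for conjugation, where
the exponential form expresses the autocatalysis of secondary transfer.
The closed forms assume:

1. recipients effectively constant over the mating (excess recipients,
   short times, and/or growth replenishing what transfer consumes);
2. engagement equilibrates fast relative to the yield dynamics
   (quasi-steady state);
3. donors and transconjugants grow at equal rates, so vegetative growth
   cancels from the T/D ratio.

## Parameters

| parameter | units | meaning | default / notes |
|---|---|---|---|
| k_on | μm²·h⁻¹ (surface), ml·h⁻¹ (liquid) | area/volume searched per donor per time | per plasmid; reference values 90–215 μm²·h⁻¹ |
| τ | h | mean time per successful transfer (1/k_c) | per plasmid; reference values 0.13–0.33 h |
| k_off | h⁻¹ | pair dissolution | 0 (simulator only; absorbed into k_on analytically) |
| doubling times | h | vegetative growth of free D, R, T | ∞ (off) in unit tests; 1 h in validation runs |
| t_deficit | – | fractional growth handicap of T vs D | 0; scanned 0.1–0.9 in robustness checks |

Internal unit conventions: hours, μm² and cells/μm² for surface matings
(ml and cells/ml in liquid); plate areas given in cm² are converted at
1 cm² = 10⁸ μm². Mixing per-area and per-volume quantities is an error.

## Two simulation schemes

`build_network` assembles either of two exact continuous-time Markov
chains, sampled by the direct Gillespie method (numba-compiled kernel; a
pure-Python event-resolved sampler cross-checks it in the tests):

* **pair** (default): the mechanistic mass-action network above, with
  explicit pair species. It carries the structural invariants — path-wise
  conservation of the donor side (D + C) and of total cells without
  growth — and is the network the master-equation oracle integrates.
* **effective**: the quasi-steady-state reduction, a single transfer
  reaction per donor class whose propensity *is* the saturating response
  (k_on/A)·X·R/(1 + (k_on·τ/A)·R). Its ensemble mean is what the closed
  forms describe, so it is the scheme used to validate them.

The distinction matters: at the validation density (0.05 cells/μm²,
pKM101 parameters) the mechanistic pair network's true exponential growth
rate (the dominant eigenvalue of the engagement linearization, 3.73 h⁻¹)
sits well below the Holling rate φ = 4.48 h⁻¹, because newly minted
transconjugants start unpaired and pair equilibration is not fast on the
yield timescale. The closed forms are therefore a model of the
*quasi-steady-state* dynamics, and their stochastic validation is
performed against the reduced scheme; the pair network remains the
mechanistic reference for structural and small-instance checks.

Other simulator conventions: pairs neither divide nor engage further;
new transconjugants are immediately transfer-competent (no maturation
lag); growth is pure exponential (all modelled experiments last ≤ 3 h, so
no carrying capacity); the measured T/D follows the plating convention
(a paired cell plates as what it currently is: donors = D + C,
transconjugants = T + C').

## Validation conditions and problem sizes

The reference validation mates 500 donors with 50,000 recipients on a
10⁶ μm² patch (N ≈ 0.05 cells/μm², D:R = 1:100) for one generation
(1 h doubling time for D, R and T), with 200 seeded replicates — a
desk-scale population chosen so a full ensemble runs in seconds while
keeping relative Monte-Carlo error near 0.1%. At one generation the
ensemble mean agrees with the conjugation closed form to ~1% normalized
error (|a−b|/((a+b)/2)); by 1.5 h recipients are exhausted and the closed
form overshoots grossly, which is why parameter estimation uses short
matings. Growth is load-bearing here: without replenishment, recipient
consumption alone drives ~37% error at 1 h at this density.

The growth-deficit robustness scan repeats this condition with
transconjugant growth scaled by (1 − deficit) for deficits 0.1–0.9. The
normalized deviation from the closed form crosses the 10% envelope
between deficits 0.3 (≈8%) and 0.4 (≈12%) — the same crossing the
deterministic mean-field of the reduced scheme predicts — so moderate
fitness costs of carriage begin to bias closed-form estimates noticeably
once they reach ~40%.

The master-equation oracle enumerates the reachable state space
breadth-first (explicit cap, default 10⁴ states; growth makes the space
unbounded and triggers the cap) and integrates dP/dt = QP with a Krylov
matrix-exponential action. It is exact to solver tolerance and is used on
instances of ≤ 5 cells, where the stochastic sampler's end-state
frequencies are checked against it by chi-square at α = 0.01.

## Estimation

The quantity that is log-normally distributed in these assays is T/D,
so fitting is done on a log-type scale: conjugation mode fits y = ln(1 + T/D) (zero-T
rows retained, ln 1 = 0 is informative), mobilization fits ln(T/D) on
positive rows, reporting the excluded count. Optimization is bounded
nonlinear least squares over (ln k_on, ln τ) — k_on ∈ (0, 10⁶],
τ ∈ (10⁻⁴, 10²] h — started from regime-specific initial values: k_on
from the slope of the lowest-density tercile, τ from the plateau of the
highest. Working in log-parameters makes the fit invariant to
unit-consistent density rescaling. Degenerate inputs: fewer than four
distinct densities raise; a design whose fitted saturation indices
s = R·k̂_on·τ̂ never exceed 0.1 (all-DDT) flags τ as unidentifiable, one
whose indices never drop below 10 (all-FDT) flags k_on; flagged
parameters get an infinite interval upper limit rather than a spurious
finite one. Estimates at an optimizer bound are likewise flagged.

### Confidence intervals

Intervals come from a case bootstrap: replicate rows are resampled with
replacement within each density condition and the model refitted
(B = 1000 by default, fully seeded). Because the strata are triplicates,
the raw resampling distribution underestimates sampling variance by
(m−1)/m; all rules expand log-scale deviations by √(m/(m−1)). The default
interval is symmetric-t on the log scale (bootstrap SE × t quantile with
df = Σ(m_h − 1)), which in a 200-repetition calibration study at the
generator's own noise model covered the truth 91.5% (k_on) and 90.5% (τ)
of the time at nominal 95% — plain percentile intervals, kept as an
option, covered only 84%/77% at this stratum size. Curvature-based
(Jacobian) intervals are attached at fit time for comparison. Prediction
bands are pointwise envelopes of the fitted curve over the bootstrap
draws.

## Synthetic data

The generator emulates the two assay designs: a serial-dilution titration
(default: base density 0.01 cells/μm² diluted 10²×–10⁻⁴× in half-log
steps, D:R 1:100, 1 h mating, triplicates, counts referred to a 2 cm²
well) and an invasion time course (≈1 cell/μm², D:R 1:100 and 1:10⁴,
abort times up to 3 h, backed by the stochastic simulator with growth).
Biological noise is multiplicative log-normal on T/D (σ_log default 0.3 —
a modelling choice, surfaced in the config, since the assay scatter is of
that order on the log scale); optional plating noise draws Poisson counts
on the aliquot dilution that would give 30–300 colonies and scales back.
With noise off, generated ratios sit exactly on the closed-form curve
(counts may then be non-integral — an idealization flagged in the API
docs). Not emulated: antibiotic selection, counting saturation, colony
overlap, spatial structure within the mating patch, plasmid loss. Passing
tests on these data therefore demonstrate correctness of the machinery
and calibration under the stated noise model, not robustness to every
artefact of real plates.

## Numerical choices

* Overflow: conjugation-mode exponents > 700 return `inf` (an explicit
  saturated sentinel), never a silent wrap.
* Seeding: every stochastic entry point takes one integer seed; replicate
  and sub-task seeds are spawned from it via `SeedSequence`, so outputs
  are bit-reproducible.
* The SSA is the exact direct method; populations in scope (≤ 10⁶ cells)
  make leaping unnecessary.
* Normalized error of two zero frequencies is defined as 0.
* Fit tolerances are set to machine level (xtol = ftol = gtol = 10⁻¹⁵) so
  noiseless round-trips recover parameters to ≲ 10⁻⁶ relative.

## Known limitations

* The closed forms degrade at high density and long times (recipient
  exhaustion; engagement-equilibration lag in the mechanistic network) —
  estimation should use short matings with excess recipients.
* The identifiability flags are design-level heuristics (regime coverage
  of the fitted curve), not profile-likelihood certificates.
* No spatial structure: the model is well-mixed within the mating patch,
  so colony-edge effects in dense surface matings are out of scope.
* Mobilization-mode fitting discards zero-transconjugant rows, which can
  bias very-low-density fits when detection limits bite.
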