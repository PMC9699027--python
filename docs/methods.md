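# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `mcrkin`. It is written for a reader who wants to judge what
the package computes and what its validation does (and does not) establish.

## Bilinear model and soft MCR-ALS

Spectra are modelled as `X = C Sᵗ + E` with `X` (I samples × J wavenumbers),
`C` (I × N) concentrations, `S` (J × N) pure-component spectra. Alternating
least squares estimates one factor with the other fixed:

* **C-step** — the unconstrained estimate `C_in = X (Sᵗ)⁺` is refined by the
  constraints, in a fixed order: fixed concentration values are substituted;
  any shared free scalar (the blister weighting factor) is estimated by 1-D
  least squares over all samples jointly; the remaining free columns are
  re-solved against the residual left by the constrained columns — by
  per-sample non-negative least squares when non-negativity is requested, by
  ordinary least squares otherwise; finally closure rescales each sample's
  subset to the closure constant. Re-solving the free columns on the deflated
  residual (rather than keeping the joint unconstrained values) keeps each
  half-step an exact constrained LS minimisation.
* **S-step** — spectra flagged known pass through unchanged; unknown columns
  are solved from the deflated matrix `X − C₁S₁ᵗ` against the corresponding
  concentration columns, per wavelength, with NNLS when non-negativity is on.

Non-negativity is always enforced by NNLS, never by clipping: clipping the
unconstrained solution is not the constrained optimum, and the difference is
measurable (the test suite checks NNLS optimality against brute-force grid
search). For speed, the unconstrained solution is computed for all rows at
once and only rows with negative entries are re-solved by active-set NNLS.

Pseudo-inverses use SVD with a relative singular-value cutoff of 1e-10;
rank deficiency beyond the cutoff warns and returns the minimum-norm
solution.

**Closure** is implemented as row rescaling after the LS/NNLS solve (soft
closure), not as equality-constrained LS. Rows whose subset sum is ≤ 1e-15
cannot be rescaled; they are left as-is and flagged on the result object.

### Convergence and stopping

Lack of fit, `LoF = ‖X − C Sᵗ‖_F / ‖X‖_F`, is evaluated after each full
iteration. The iteration stops when

* the relative LoF change between successive iterates falls below `tol`
  (default 1e-8; the iteration cap is 500), or
* the LoF is numerically zero (< 1e-12), or
* the best LoF has not improved for 8 consecutive iterations, or
* the LoF has increased for 3 consecutive iterations.

The last two rules exist because soft closure makes the iteration a
non-descent fixed-point map: after reaching the neighbourhood of a solution
the iterates can wander with slowly varying LoF rather than settling. The
run then returns the **best** iterate seen. A sustained increase is only an
error (`MCRDivergenceError`) when the current LoF has drifted more than 1 %
above the best — that indicates a genuinely unstable configuration rather
than post-optimum wander. The recorded `lof_trace` contains the accepted
(best-so-far) values and is non-increasing by construction.

When every spectrum is known the problem is linear and a single C-step
returns the solution.

### Rotational ambiguity and minimal-admixture selection

With only soft constraints, a closure-constrained bilinear fit is invariant
under transformations `s_j → (s_j − g·s_m)/(1 − g)`, `c_m → c_m + g·c_j`,
`c_j → (1 − g)·c_j` whenever the transformed spectrum stays non-negative:
there is a continuum of solutions with identical fit. Alternating least
squares lands somewhere on this continuum determined by its initialisation,
which systematically biases the downstream kinetic constants (in simulation,
up to ~8 % in k at zero noise).

`minimize_spectral_admixture` therefore post-processes every fit with
estimated spectra: each unknown spectrum is moved to the extreme point of the
equivalent-solution set at which it contains no removable multiple of any
other component, with the exact compensating concentration update (the
reconstruction, the closure sums and non-negativity are all preserved). The
removable fraction `g` is the minimum of the spectral ratio `s_j/s_m` over
the support of `s_m` (points above 5 % of its maximum). Component spectra
that vanish somewhere on each other's support — the generic situation for
banded vibrational spectra — make the true solution exactly this extreme
point. Because a pointwise minimum of a noisy ratio chases the deepest noise
dip and under-corrects, the ratio is evaluated on moving-average smoothed
spectra (15 grid points by default). In simulation this step removes nearly
all of the initialisation-dependent bias: at zero noise the recovered
constants match the generating values to <0.5 %, and at 1 % noise to a few
percent.

The same degeneracy appears in the fresh-tablet stage between the unknown
excipient spectrum and the blister weighting factor (any multiple of the PVC
spectrum can migrate between them). It is resolved the same way: the
removable PVC multiple is stripped from the Rest estimate and credited back
to the weighting factor.

## Kinetic model and estimation

The sequential scheme API → Inter → Prod with first-order steps has the
closed form given in the README; the confluent limit `k1 = k2` uses
`c0·k1·t·exp(−k1·t)` and is switched on when `|k1 − k2| < 1e-8·max(k1, k2)`
(profiles on either side of the switch agree to <1e-6). Mass conservation
holds by construction. The closed form is validated against an independent
ODE integration (`solve_ivp`, LSODA, rtol 1e-12) to 1e-8.

`fit_rate_constants` minimises the squared deviation of **all three**
profiles jointly with equal weights. Which components enter the objective
and with what weights is a genuine design choice; all-three-equal is the
simplest defensible option and makes the fit identifiable — the intermediate
profile alone has an exchange symmetry (k1 ↔ k2 give proportional shapes),
which the simultaneous API decay breaks. Optimisation is multi-start: an
8 × 8 log-spaced grid over k ∈ [1e-4, 1] month⁻¹ ranks starting points, the
best three are refined with bounded `least_squares`. Parameter uncertainty is
reported through the Gauss–Newton covariance `σ²(JᵗJ)⁻¹`.

`fit_joint` fits tablets and substances together with a shared first-stage
constant and dataset-specific second-stage constants (k1, k21, k22),
starting from the two independent fits; it always reports the fully split
residual too, so the nested hypotheses can be compared (rss_shared ≥
rss_split necessarily).

### Uncertain substance ages

Substance production dates are only known to within a few months, so Step 1
alternates a rate-constant fit with a bounded per-sample 1-D refinement of
each age: `t_i` is searched within ±6 months (configurable) of its nominal
value, under a quadratic pull-back penalty `λ(t − t_nom)²` with
`λ = 1e-3 × mean(C²)` by default, until the penalised rss changes by less
than 1e-10 (at most 100 outer rounds). With exact nominal times the penalty
keeps the optimum at the nominal values; with a bound of 0 the procedure
reduces identically to the plain fit. The penalty weight and bound are
heuristic: they encode "nominal ages are approximately right" without a
formal error model for the production dates.

Tablet ages are treated as exact (manufacturing dates are reliable) — no
adjustment in Steps 2.2/3. The Step-3 joint fit uses the Step-1 adjusted
substance ages.

## Pipeline conventions

* Preprocessing order: wavenumber range selection (9000–4000 cm⁻¹ closed
  interval), replicate averaging per sample, then baseline correction.
  Averaging first lowers the noise the baseline estimate sees.
* Baseline correction default is `offset`: subtract each spectrum's minimum,
  estimated on a 15-point moving average. The smoothing matters: the plain
  minimum subtracts the deepest noise excursion (≈ −2.9σ), leaving a
  systematic positive floor in every spectrum that closure then converts
  into a kinetic bias of tens of percent. A `linear` (two-endpoint) method
  and `none` are available; the true instrumental baseline procedure of any
  given study is rarely documented, and this configurable stand-in makes no
  claim to reproduce one.
* Tablet composition: 100 mg API / 90 mg MCC / 85 mg other excipients give
  relative concentrations 0.36 / 0.33 / 0.31 (masses over total, rounded to
  two decimals, summing to 1.00). The cleaning stage divides by the API
  fraction 0.36 so that cleaned tablet spectra live on the same closure-1
  scale as substance spectra — which is what allows Step 3 to stack them.
* Negative values in cleaned spectra are retained (noise around zero), not
  clipped; their fraction is logged.
* The blister weighting factor is one scalar shared by all tablets of a
  dataset. It is a spectral contribution coefficient, not a mass fraction,
  so it takes part in no closure.
* Step-1 initialisation of the unknown spectra is data-driven and
  deterministic: the product from the oldest sample and the intermediate
  from the sample nearest the median age, each deflated by the projection
  onto the API spectrum and clipped at zero (seeded random fallback for
  degenerate cases). The minimal-admixture step above removes most of the
  residual initialisation dependence.
* `run_pipeline` is deterministic given `seed`: dataset seeds are derived
  from it, and two runs with the same config produce byte-identical
  constants tables.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes:

* **Spectra.** Gaussian-band pure-component spectra on a 4000–9000 cm⁻¹ grid
  at 8 cm⁻¹ spacing (626 points; the narrowest default band has σ = 70 cm⁻¹,
  so this grid fully resolves every band). Default bands overlap heavily in
  the combination region to make the unmixing non-trivial; the intermediate
  carries a hydroxyl-like band near 5000 cm⁻¹. All bands decay to ≈0 at the
  high-wavenumber edge (the weak second-overtone region), which makes an
  additive per-spectrum offset removable by minimum-subtraction.
* **Substances.** 36 samples with true ages even over 0–120 months,
  concentrations exactly on the two-step profile (defaults k1 = 0.023,
  k2 = 0.01 month⁻¹), three replicates, additive iid Gaussian noise with sd
  = 1 % of the mean signal, per-spectrum constant offsets (sd 0.5 %), and
  nominal ages jittered uniformly within ±3 months of truth.
* **Tablets.** 5 batches × ages {0, 9, 18, 76, 79} months × 2 tablets × 3
  replicates (150 spectra, near the ~165 of a realistic campaign); defaults
  k1 = 0.028, k2 = 0.003 month⁻¹, blister weight 0.4; exact ages; same
  noise model. Per tablet the degradation subsystem carries 0.36 × the
  kinetic profile, plus fixed 0.33 MCC and 0.31 Rest and the weighted PVC
  contribution.

What the generator does **not** emulate: multiplicative scatter effects,
instrument line-shape and resolution functions, water-vapour bands, detector
drift, batch-to-batch composition variability, or any optical non-linearity
of the blister beyond a linear weighting. Passing the recovery tests
therefore shows that the pipeline solves the *statistical* problem it is
designed for — bilinear mixtures with kinetic structure, noise, offsets and
age uncertainty — not that it is robust to every artefact of real NIR
hardware.

## Validation design

* Unit and property tests validate each operation against independent
  oracles (ODE integration, brute-force grids, direct algebra, a minimal
  lstsq-alternation ALS for the unconstrained case).
* Recovery experiments generate studies with known constants and require the
  full pipeline to return them within 10 % at 1 % noise; the noiseless limit
  must collapse to the exact answer (constants to <0.5 %, end-to-end LoF
  below 1e-6 % — the noiseless check disables baseline correction, since
  with no offsets the minimum-subtraction would remove genuine signal, and
  raises the ALS iteration cap to let the flat-valley iteration close in).
* `scripts/acceptance.py` re-runs the two benchmark recoveries from scratch
  for any seed.

## Known limitations

* Rotational ambiguity is resolved by the minimal-admixture convention, not
  by computing feasible bands; if the true component spectra did not vanish
  anywhere on each other's support, the convention would still pick the
  extreme solution and bias the constants accordingly.
* The ALS plateau rule returns the best iterate of a non-monotone iteration;
  on ill-conditioned problems different platforms may stop within the
  plateau at slightly different points (the constants are insensitive to
  this at the documented tolerances).
* Only one closure group is supported, and the component count per stage is
  fixed by the study design (3 or 4); there is no automated rank estimation.
* The time-adjustment penalty is heuristic (see above), and `k2` estimates
  from tablet designs with few distinct ages are intrinsically the least
  stable quantity in the pipeline.
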