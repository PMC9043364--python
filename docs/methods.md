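# Methods

`cwbind` implements the quantitative core of a biophysical characterisation
of a histone-reader CW domain binding methylated H3K4 peptides: ITC binding
thermodynamics, fluorescence-monitored thermal denaturation, NMR
chemical-shift-perturbation and heteronuclear-NOE analysis, and the ring-plane
geometry of the tryptophan binding pocket.  This note records the models,
their assumptions, the defaults and why, and what the synthetic-data tests do
and do not demonstrate.

## ITC: single-site ("independent") binding model

Each injection adds ligand X to a perfusion cell of active volume `V0`
containing macromolecule M with `n` identical independent sites.  After
injection `i` (cumulative injected volume `d_i`) the effective totals follow
the standard displacement approximation

    Mt_i = M0 (1 − d_i/2V0) / (1 + d_i/2V0),
    Xt_i = X0 (d_i/V0) / (1 + d_i/2V0),

the bound concentration solves 1:1 mass action,

    [MX] = (b − sqrt(b² − 4 n Mt Xt)) / 2,  b = n Mt + Xt + Kd,

computed through the conjugate form `2 n Mt Xt / (b + sqrt(·))` so the
small-root cancellation is numerically stable down to c ≪ 1, and cumulative
heat is `Q_i = ΔH · V0 · [MX]_i`.  Injection heats carry the displacement
correction `q_i = Q_i − Q_{i−1} + (v_i/V0)(Q_i + Q_{i−1})/2`.  With this form
the cumulative binding heat per mole of macromolecule saturates at `n·ΔH`,
which is the identity the Wiseman isotherm normalisation relies on.

Fitting minimises Σ(q_obs − q_pred)² over (log Kd, ΔH, n) with
`scipy.optimize.least_squares` (TRF, bounds Kd ∈ [1e−12, 1] M,
|ΔH| ≤ 500 kJ/mol, n ∈ [0.1, 10]; n fixable at 1).  Standard errors come from
the Jacobian covariance at the optimum.  Initialisation: ΔH from the mean of
the first three normalised heats, a mid-range Kd from the half-height molar
ratio, n = 1.  Fits with c = n·M0/Kd < 1 are flagged "weak-binding: parameters
unreliable" — the regime in which the weakest-binding constructs could not be
characterised.  State functions: ΔG = RT ln Kd (R = 8.314 J/mol·K),
TΔS = ΔH − ΔG, ΔS = 1000·TΔS/T; T defaults to 298.15 K, matching the 25 °C
experiments.

Defaults: `V0 = 185 µl` (a typical low-volume calorimeter cell; the working
volume is configurable, and because every simulate-and-refit round trip
generates and fits with the same V0 the choice cancels), 22 × 2 µl
injections, 80 µM cell / 800 µM syringe (inside the instruments' 50–180 /
400–1800 µM working ranges).  The first injection can optionally be
discarded (common practice); default keeps it.  Group comparison uses the
pooled two-sample Student's t-test with the degenerate conventions p = 1
(zero variance, equal means) and p = 0 (zero variance, unequal means).

## Thermal denaturation

Unfolding is monitored as the I328/I352 emission-intensity ratio against
temperature; wavelengths snap to the nearest grid point on the 310–410 nm
1 nm grid (interpolation would change nothing at that spacing), and blank
spectra of identical shape are subtracted first when given.  The melting
curve is fitted with the four-parameter logistic

    f(x) = y0 + a / (1 + exp(−b (x − x0)))

and T_m is the inflection x0.  Initialisation: y0 from the first three
ratios, a from last-minus-first, x0 at the maximum finite-difference slope,
b = 4 / (span of the central half of the amplitude).

Sigmoidality gate.  A fitted T_m is only reported when all of the following
hold: the optimiser converged; |a| ≥ 3 × residual RMS; x0 inside the sampled
temperature range; |b| × (sampled span) ≥ 1; se(x0) ≤ 5 °C.  The fourth
check exists because a logistic with near-zero steepness reproduces a
straight line arbitrarily well and would otherwise pass — truly linear data
must be rejected, mirroring the mutant whose denaturation data displayed no
sigmoidal model.  Failed checks are enumerated in `reasons`.

T_m is fitted per replicate and averaged across triplicates by default; a
pooled fit over concatenated replicates is available because instrument
software often fits "between parallels".  One-way fixed-effects ANOVA (with
a between-group sum of squares below 1e−12 of the total snapped to zero so
identical groups give exactly F = 0, p = 1) compares T_m groups at the 0.05
threshold.  The synthetic schedule uses 2.5 °C steps over 5–90 °C for fit
stability; the experimental 5–10 °C schedule is available for realism tests.
No van 't Hoff ΔH/ΔG extraction is attempted — only T_m is interpreted.

## Chemical-shift perturbation

Combined amide shifts use `Δppm = sqrt(ΔδHN² + (αN ΔδN)²)` with αN = 0.17.
Assigned lists are compared by residue id; ids present in only one list
(exchange-broadened or unassigned) are reported separately.  Unassigned
fingerprints are paired by greedy matching in order of increasing scaled
distance (ties by lowest reference id, each peak used once), which is
mutual-nearest-neighbour whenever matching is unambiguous.  The ">0.2 ppm"
substantially-shifted criterion is evaluated in the same αN-scaled metric —
the only shift metric the analysis defines.  `fraction_shifted` reports the
percentage of matched pairs over threshold; unmatched peaks are listed but
excluded from the denominator, and both counts are reported because the
appropriate denominator (all picked peaks vs assigned amides) is a judgement
call.  Greedy matching degrades as peak density approaches the displacement
scale; the generator enforces a minimum separation of twice the displacement
precisely to stay in the unambiguous regime, so matching-error growth at
higher densities is a documented limitation, not an asserted property.

## Relaxation

hetNOE = I_sat/I_ref with first-order error propagation
`σ = |noe|·sqrt((σ_sat/I_sat)² + (σ_ref/I_ref)²)`; noise floors are supplied
by the user, not estimated from spectra.  Residues with noe < 0.75 are
classed flexible (strict inequality): the cutoff sits midway between the
~0.8 typical of an ordered backbone at high field and the 0.5–0.7 band of
mobile loops, and is configurable because no universal threshold exists.
T1/T2 series on the standard 11/12-point delay schedules are fitted with
`I(t) = I0 exp(−t/T)` (log-linear start, nonlinear refinement); non-decaying
data return a failure flag.  No Lipari–Szabo model-free analysis is layered
on top.

## Pocket geometry

For each tryptophan the nine indole ring atoms (CG, CD1, CD2, NE1, CE2,
CE3, CZ2, CZ3, CH2) are fitted with a total-least-squares plane (SVD of the
centred coordinates; the normal is the least-variance direction, which
minimises the out-of-plane RMS over all planes).  CB is excluded by default:
it is sp³ and off the aromatic plane; an `include_cb` flag quantifies the
sensitivity.  Two angle conventions are reported because a plane normal has
no intrinsic sign: the unsigned angle arccos|n1·n2| ∈ [0°, 90°] (primary,
convention-free) and an oriented angle ∈ [0°, 180°] in which each fitted
normal is signed to agree with the Newell-method normal of the canonical
perimeter winding CG→CD1→NE1→CE2→CZ2→CH2→CZ3→CE3→CD2, making obtuse pocket
angles reproducible.  Parsing is PDB-format only (via gemmi), altloc
restricted to blank/'A', chain A by convention; NMR ensembles are evaluated
per model with model 1 as the headline and the spread reported, since which
ensemble member underlies any published single-number angle is generally
unknowable.

## Synthetic data

Generators are pure functions of parameters + seed (bit-identical on
replay) and their output round-trips through the corresponding readers.
Noise models are Gaussian: additive for heats (default σ = 2 µJ, which
propagates to triplicate K_d scatter of roughly a quarter of K_d, the
spread typical of replicate titrations) and ratios (default σ = 0.01),
multiplicative for NMR intensities.  The melting generator's spectral mode
mixes two log-normal emission bands peaking near 330/355 nm by the logistic
folded fraction, with the mixing weight solved so the 328/352 ratio equals
the target logistic exactly; only that ratio is contractual, not band
shapes.  Fingerprint peaks are placed uniformly at random over the amide
window (¹H 6.5–10.5, ¹⁵N 105–135 ppm) under a minimum scaled separation of
2× the displacement; near the packing limit (60 peaks at 0.3 ppm
displacement is close to it) placement falls back to a lightly jittered
hexagonal lattice in the scaled metric.  Exactly `round(n·f)` peaks are
displaced by the designed scaled distance in a random direction.  Ring
pairs are built from an idealized planar indole template, the second ring
rotated about a shared in-plane axis and the whole model given a random
rigid motion, so the designed angle is recovered under arbitrary pose.

What passing these tests shows — and does not.  Round trips establish that
the fitting code inverts its own forward model to stated precision and that
the statistics reproduce hand-computable references; they do not validate
the forward models against real instruments (no baseline drift, no
injection-syringe artefacts, no photobleaching, no peak overlap, ideal
two-state melting).  Real-data deviations from these idealisations are the
dominant error source in practice.

## Problem sizes and numerical choices

Stochastic recovery studies use 100 seeds (ITC: σ = 2 µJ; melt: σ = 0.01),
enough to estimate medians and coverage to the asserted tolerances while
keeping the suite fast.  Optimiser tolerances are 1e−14 (xtol/ftol) so
round-trip accuracy is limited by conditioning, not stopping rules.
Equilibrium roots are validated against bracketed bisection to 1e−10
relative (absolute floor 2e−18, the oracle's own tolerance).  PDB text
carries 3-decimal coordinates, limiting angles recovered through
serialisation to ~0.02°; in-memory models recover designed angles to 1e−6°.

## Known limitations

- Multi-site, sequential and cooperative ITC models are out of scope, as are
  raw power thermograms (inputs are integrated heats).
- The melting analysis reports only T_m, with no scan-rate or reversibility
  corrections.
- Peak picking and resonance assignment are upstream of this package.
- mmCIF is not parsed; PDB format only.
- Greedy fingerprint matching mis-pairs in dense, heavily shifted spectra.
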