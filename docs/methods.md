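# Methods

This note documents the models, estimators and numerical choices behind
each analysis stage, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Photobleaching model and calibration

A particle carrying *n* fluorophores (default 4: the motor is a
homotetramer with one GFP per subunit) emits intensity *u*·(number still
fluorescing) plus Gaussian camera noise.  Each fluorophore bleaches
irreversibly at an exponential time with mean lifetime λ (default 23 s);
blinking is not modeled.  Movies are 90 s at 1 s intervals (91 samples).

**Step detection.** The trace is segmented by an exact penalized
least-squares change-point program (dynamic programming over segment
boundaries, minimum plateau length `window` = 3 frames, penalty
2σ̂²·log n with σ̂ from the median absolute first difference, floored at
a tiny positive value so that a noiseless k-step staircase yields
exactly k segments).  Adjacent plateaus whose drop is below
`min_amplitude` (default half the expected unit) are merged, so only
downward steps are reported; levels are flanking plateau means.

**Unit calibration.** The unit intensity is the mean step amplitude with
SEM.  At 1 s sampling a few-percent of bleach pairs fall within the
detector's resolution and appear as double-amplitude steps;
`single_step_filter` removes amplitudes outside (0.5, 1.5)× the median
before averaging, the programmatic analogue of reading only single steps
by eye.  The single-molecule gate is *n*·*u*, applied strictly: a
particle exactly at the gate counts as a cluster.

**Lifetime.** Two estimators are provided.  Given only step times, the
plain mean with empirical SEM (direct averaging; biased low when the
movie is not much longer than λ, because long-lived fluorophores are
censored).  Given the traces and the calibrated unit, the right-censored
exponential MLE: total fluorophore time-at-risk is the trapezoid area
under each trace divided by *u* (a censored fluorophore automatically
contributes the full movie), the event count is the net intensity loss
in units, and λ̂ = time-at-risk / events with asymptotic SEM λ̂/√n.  The
MLE is the default in the pipeline because it is unbiased at the study's
movie length and robust to unresolved coincident steps; the simple mean
is retained for compatibility with direct averaging of hand-read steps.

## Mean-displacement velocity

Tracks are 1-D signed positions along the MT axis, plus-end positive.
MD(t) is the mean of x(t₀+t) − x(t₀) over all tracks alive at elapsed
time t from their own start (pooled over trajectories, not per movie).
The velocity is the unweighted least-squares slope of MD = v·t through
the origin, over lags supported by at least `min_tracks_per_lag` = 5
tracks.  Because MD values at different lags share tracks, the slope's
standard error is computed from the spread of per-track through-origin
slopes (SEM over tracks), not from fit residuals, which would be
optimistic by roughly the square root of the number of lags.

Only motors that start moving within the first 30 s are analyzed
(motion onset: first |x − x(0)| > 50 nm, ≈3× localization error), so the
≈23 s fluorophore lifetime cannot bias the sample toward early movers;
tracks failing the single-molecule intensity gate are dropped.  Run
length is the net start-to-end displacement magnitude per track (not
path length).

## Sliding classification

Events are 400 s movies at 10 s intervals of a mobile MT's position
along a surface-anchored MT.  Excursions are monotone runs; reversals
smaller than the noise floor (default 0.2 µm ≈ 2 px) are merged, and
frames with displacement at or below `pause_eps` (default 0: any exactly
zero step) are pauses excluded from moving time.  Classification, with
amplitude threshold 0.64 µm:

* directional: |net| > 0.64 µm and no opposite excursion that is both
  > 0.64 µm *and* longer than 30% of the total moving time (the two
  disqualifying clauses are conjunctive, which makes the directional and
  bi-directional definitions complementary for two-direction tracks);
* bi-directional: excursions > 0.64 µm both ways and the main direction
  holds < 70% of moving time;
* static otherwise.

Plus-end velocity is summed plus-direction continuous displacement over
its moving time; events with no plus excursion raise an explicit
undefined-velocity error rather than returning 0.

## Image quantitation

Phansalkar thresholding uses the canonical parameters k = 0.25, r = 0.5,
p = 2, q = 10 in a square window of half-width 15 px on images brought
into [0, 1] (identity if already there, else min–max; the local mean is
clipped at 0 because box-filter round-off on empty regions would
otherwise flip the strict comparison at T = 0).  Particles are
8-connected components of at least 4 px, measured on the original image.
Skeleton length counts axial neighbour pairs as 1 px and diagonal pairs
as √2 px.  A motor particle is MT-bound when its centroid lies within
1 px of the MT mask.  Spindles are categorized monopolar / short / long
with the measure-zero 2.0 µm boundary assigned to "long".  The particle
linker is greedy nearest-neighbour with a per-frame jump cap; it is
intended for well-separated particles (no crossing resolution).

## H-bond geometry

Donors are backbone N–H (non-proline), Ser/Thr hydroxyls, Asn/Gln
side-chain amides and Lys Nζ; acceptors are backbone carbonyl O and
Ser/Thr/Asn/Gln side-chain oxygens.  A pair bonds when the heavy-atom
distance is below 0.36 nm (the stringent cutoff under which the variant
bond arrays are tabulated; 0.35 nm is available via `dmax_nm`) and the
angle at the donor between D→H and D→A is below 30°, minimized over the
donor's hydrogens — bifurcated bonds are therefore allowed.  Pairs
within one residue's backbone and pairs at covalent distance (< 2 Å) are
excluded.  Missing backbone amide hydrogens are placed 1.01 Å from N in
the C(i−1)–N–CA plane opposite the bisector; rotatable donors (hydroxyl,
ammonium) without an explicit H may be evaluated at the orientation that
minimizes the angle, i.e. the distance criterion decides — an
approximation appropriate when rotamers are free.

Latch reports assign each bond to one region keyed on the Cin8 residue
numbering: N-latch (position 522 against the α1–β3 loop at 157 or β7 at
412/414), intra-NL (both residues in 516–528), β7–β10 (412/414 against
NL positions other than 522), cover strand (73–75 against the NL), and
flag the conserved 157(O)↔522(N) backbone bond.

## Growth curves and statistics

Doubling time is ln 2 over the least-squares slope of ln(OD_t/OD₀)
against time; non-growing cultures raise an explicit signal.  Normality
is screened with a one-sample KS test against a normal with estimated
mean and SD; with estimated parameters the nominal p-values are
conservative (the Lilliefors situation), which is accepted and
documented rather than corrected.  Box-Cox uses the profile-likelihood
λ (scipy's MLE) with y = (x^λ − 1)/λ.

Dunnett's many-to-one comparison uses Tᵢ = (x̄ᵢ − x̄_c)/√(s²(1/nᵢ + 1/n_c))
with the pooled within-group variance, compared against the
equicoordinate two-sided critical point of the k-variate t distribution
with common correlation ½ (the balanced-design value, used even for
mildly unequal group sizes, matching tabulated constants).  The critical
point solves P(maxᵢ|Tᵢ| ≤ c) = 1 − α via the representation
Tᵢ = (Zᵢ − Z₀)/(√2·S), νS² ~ χ²_ν, integrated with 120-node
Gauss–Hermite quadrature over Z₀ and 400-node Gauss–Legendre quadrature
over the scale S weighted by its chi density; accuracy is better than
±0.005 (verified against a 10⁵–10⁶-draw Monte-Carlo max-|t| oracle and
against quadrature refinement).  For k = 1 the Student-t quantile is
returned exactly.  Tukey's method uses the studentized-range quantile
with the Tukey-Kramer statistic.  Both procedures hold their familywise
error at α = 0.05 ± 0.01 in 10⁴-replicate null simulations.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure each analysis
assumes: exponential per-fluorophore bleaching on a 90 s / 1 s grid;
drift–diffusion tracks x(t+Δ) = x(t) + vΔ + N(0, 2DΔ) with exponential
detachment (the study does not report diffusion coefficients or detach
rates, so D = 2000 nm²/s and configurable rates are generator
conventions, not measured values); sliding events constructed per class
and re-checked through the classifier (generation fails loudly if the
construction misses its class); image fields as Gaussian-blurred lines
and points with Gaussian noise on a 0.1 µm/px grid over a 346 µm²
field; exponential OD₆₀₀ growth with multiplicative noise; and
coordinate fixtures in which requested donor–acceptor pairs are laid
out by a small least-squares relaxation (bond distances near 0.29 nm,
donor cones within 25°, non-bonded compatible pairs pushed beyond the
cutoff, remaining residue atoms parked on a well-separated lattice) and
verified with the detector before being returned.  The fixtures are
synthetic geometric realizations, not homology models: they share only
the bond topology with real structures.

Consequently, passing tests demonstrate estimator correctness and
pipeline integrity under the assumed models — they do not validate the
models against real microscopy artefacts (uneven illumination, focal
drift, MT crossings, camera gain, blinking), which are out of scope.

## Problem sizes and determinism

Default analysis scales: 10³ traces for calibration recovery, 100 tracks
× 200 replicates for velocity recovery, 10³ seeds per class for the
sliding round-trip, 50 random images for threshold-oracle equality, and
10⁴ replicates for familywise-error calibration.  All generators take
explicit integer seeds (numpy `default_rng`); a fixed seed gives
bit-identical outputs, and the pipeline derives per-stage seeds from the
config seed by hashing, so stages are independently reproducible.

## Known limitations

* Step detection assumes piecewise-constant traces; gradual photophysics
  (partial quenching) would be mis-segmented.
* The balanced-correlation Dunnett constant is an approximation for
  strongly unequal group sizes; the exact unequal-n computation is not
  implemented.
* The particle linker does not resolve crossing trajectories.
* H-bond detection is purely geometric; no energy or secondary-structure
  criteria.
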