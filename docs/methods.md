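# Methods

This note documents the models and procedures noesykit implements, the
defaults it ships, the synthetic data its tests run on, and the limits of
what those tests demonstrate.

## Background

Iterative NOE assignment programs (ARIA, CYANA) convert NOESY cross-peaks
into ambiguous distance restraints, calculate an ensemble of conformers,
and use the ensemble to prune the restraint list before the next iteration.
noesykit implements the restraint-handling layer of that loop — peak-list
pre-filters, r⁻⁶ effective distances, consistent-violation analysis with a
fixed or adaptive tolerance, the FBHW and log-harmonic restraint potentials
with automatic weighting, and the softened geometric force-field parameters
— together with a desk-scale driver and seeded synthetic fixtures so the
whole loop can be exercised end-to-end without spectrometer data or a
molecular dynamics engine.

## Peak-list pre-filters

**Shift-match filter.** A peak survives only if every dimension matches at
least one assigned chemical shift of the same nucleus within the
per-nucleus tolerance (closed window, `|Δppm| ≤ tol`). Bonding consistency
between the heavy atom and its proton is deliberately not checked; this is
a pure shift-match screen, as in ARIA's own input filtering.

**Weak-peak filter.** Peak *p* is weak iff
`|I_p|^(-1/6) > |I_min|^(-1/6) · f` with fraction *f* = 0.9 and `I_min` the
smallest intensity magnitude in the list. Equivalently, a weak peak's
calibrated distance would exceed 90 % of the longest calibrated distance.
Magnitudes are used because NOESY volumes can be negative from phasing.
The sweep is single-pass against the original `I_min`; re-applying the
filter to its own output recomputes `I_min` and may remove more peaks
(documented non-idempotence).

**High-density-line filter.** All peaks are projected onto the
heteronuclear 2D plane (the NOE-proton dimension is dropped), binned on a
grid whose cell edge is twice the assignment tolerance per dimension, and
every peak in a cell whose count strictly exceeds `⟨ρ⟩ + n·σ_ρ` (default
n = 1) is discarded as a solvent-line artifact. Conventions:

* the grid is anchored at the minimum projected coordinates and has
  `floor(span/width) + 1` cells per dimension, so an exactly grid-aligned
  span still gives every peak its own cell;
* binning is half-open, `[origin + k·w, origin + (k+1)·w)`, with the
  maximal coordinate clamped into the last cell;
* `⟨ρ⟩` and `σ_ρ` are population moments over **all** cells of the
  bounding grid, empty cells counting zero ("density over the full
  spectrum"). Whether empty cells enter the statistics, and whether the SD
  is population or sample, materially changes the threshold; both choices
  are made explicitly here and the brute-force oracle in the test suite
  re-implements them independently.

Composition order in the CLI is shift-match → weak → density, matching the
successive application of the new filters after the built-in one.

## Restraints and effective distances

A restraint holds a target distance `d_target`, bounds `[L, U]`, and one or
more contributions (candidate atom pairs). Against a single conformer the
contributions combine as `d = (Σ_a d_a⁻⁶)^(-1/6)`; against an ensemble of S
conformers the effective distance is the **arithmetic mean over conformers
of the per-conformer r⁻⁶ sums** — the literal reading of the printed
formula, not an r⁻⁶ average across conformers (older literature is
ambiguous on the order of averaging; the mean-of-sums form is used
throughout and stated here once).

Targets are calibrated from intensities via `d_p = c·|I_p|^(-1/6)`, with
*c* fixed by pinning the median calibrated distance to 3.0 Å. Bounds
default to symmetric ±25 % of the target: the package never publishes
bound widths as science — under the log-harmonic potential bounds only
decide which restraints count as violated — and loose symmetric bounds are
the conventional, fully configurable choice.

## Violation analysis

A conformer violates a restraint when its r⁻⁶ distance falls outside the
bounds by **more than** the tolerance t (`θ(0) = 0`; a distance exactly on
the tolerated bound does not violate). The violated fraction f over the S
analysed conformers is compared strictly against the threshold (default
0.5); restraints with `f > 0.5` are deactivated, never deleted.

Two nine-iteration schedules are shipped:

| mode | values (iterations 0–8) |
|---|---|
| fixed t (Å) | 1000.0, 5.0, 3.0, 1.0, 1.0, 1.0, 0.1, 0.1, 0.1 |
| adaptive T | 200, 6.0, 3.0, 2.0, 1.0, 1.0, 0.5, 0.5, 0.5 |

In adaptive mode the tolerance is `t = D·T`, where D is the **population**
standard deviation (N denominator, the moment form of the printed formula)
of the effective-minus-target differences `ec_i` over the currently active
restraints only — rejected restraints no longer inform convergence. The
worse the ensemble fits the data, the larger D, the more tolerant the
rejection; as the calculation converges D shrinks and the pruning
tightens. D is undefined for fewer than two restraints (validation error);
identical `ec` values collapse t to zero with a logged warning.

## Restraint potentials and weighting

**FBHW** (flat-bottom harmonic wall): zero on `[L, U]`, harmonic `k(d−U)²`
on `(U, U+s]`, linear with matched slope `2ks` beyond, plain harmonic
below L. The switch offset s defaults to 1.0 Å (standard soft-asymptote
behaviour); energy and first derivative are continuous at L, U and U+s.

**Log-harmonic**: `E = k·ln²(d/d_target)`, gradient `2k·ln(d/d_target)/d`.
The published work adopts this potential by citation without printing the
functional form; the form used here reproduces every stated property —
a single target value instead of an interval, a sharp rise below the
target (divergent as d → 0⁺), an asymptotic slope of zero, and lower
attraction than FBHW from roughly three target distances outward (verified
numerically over a parameter sweep in the tests).

**Automatic weighting**: `k = N / Σ_i ln²(d_eff,i/d_target,i)`, capped at
`k_max = 10⁴` (the cap is returned for a perfect fit). This estimator is a
deliberate approximation to the full Bayesian treatment of the
restraint-error scale (whose gamma-prior hyperparameters live in the cited
derivations): it shrinks quadratically with the log-misfit, so convergence
is never forced by restraints the structures cannot satisfy.

**Force-field modifications**: bond-angle and improper-dihedral force
constants are divided by 10 (500 → 50 kcal·mol⁻¹, per-radian units as
conventionally printed, though per-rad² is what dimensional analysis
expects — stored as printed), and the pairwise hydrogen–hydrogen van der
Waals radii are raised to aliphatic HA 1.2 Å, amide H 1.0 Å, charged HC
1.0 Å. The pairwise override is emitted NBFIX-style, one line per
unordered type pair (six lines), with the combined radius taken as the sum
of the two per-type radii — the simplest contract consistent with
per-type radii. Double application of the modifications is refused.

## Synthetic fixtures

All generators are pure functions of (parameters, seed); a master seed
derives per-generator substreams by fixed offsets, so composite fixtures
regenerate bit-identically.

* **Reference chain**: a self-avoiding 3D random walk, consecutive points
  exactly 3.8 Å apart (the CA–CA virtual bond), non-consecutive pairs at
  least 3.0 Å apart.
* **Ensemble**: reference plus i.i.d. Gaussian displacement (per-coordinate
  SD σ, default 0.5 Å for the composite fixture).
* **Restraints**: every pair `|i−j| ≥ 2` within 5.5 Å becomes a true
  restraint with the exact reference distance as target; noise restraints
  are random non-contact pairs given plausible-looking targets uniform in
  [2.5, 5.0] Å, at 10 % of the list by default.
* **Peak list**: 600 real peaks uniform over aliphatic ¹³C/¹H ranges with
  intensities following the d⁻⁶ law for d ∈ [2.2, 5.0] Å; 60 weak peaks
  with intensities strictly inside the weak regime; 100 solvent peaks on
  the water frequency (4.7 ppm) in **both** proton dimensions with heavy
  shifts along a narrow band. Placing the attached proton on the water
  line as well (the exchange/water–water artifact) is what makes the
  solvent population a high-density column of the projected grid — a
  solvent frequency in the NOE-proton dimension alone would be invisible
  to a projection that drops that dimension.

The fixture peak list uses deliberately coarse tolerances (¹³C 1.0 ppm,
¹H 0.25 ppm). Rationale: real lists carry 13–19k peaks, giving the
conventional 2×(0.2, 0.02) ppm grid a per-cell occupancy near one. A
desk-scale list of ~800 peaks on that fine grid would occupy < 2 % of
cells, and full-spectrum population statistics would then flag every
occupied cell as a high-density line. The coarse grid restores the
occupancy regime of real data, which is the property the filter's
selectivity depends on. What the fixture does **not** emulate: clustering
of real peaks at shared HSQC positions, chemical-shift statistics of real
proteins, lineshapes, peak overlap, or diagonal peaks — so passing
selectivity tests here demonstrates the algorithm's behaviour in the
intended density regime, not performance on any particular spectrometer's
output.

## Desk-scale iterative driver

The driver exists to exercise calibrate → fit → analyse → reject →
re-weight end-to-end, standing in for a simulated-annealing engine at desk
size. Conformers are point-atom chains minimized by steepest descent with
a backtracking (halving) line search under

    E = Σ_i w_i·E_pot(d_eff,i) + k_rep·Σ_pairs max(0, r_min − d)²,

with `r_min` twice the aliphatic-H radius of the force field and
`k_rep = 10`. The accepted-step energy trace is non-increasing by
construction; a vanishing gradient or an exhausted line search stops the
run. Each protocol iteration minimizes 20 Gaussian-perturbed copies of an
extended chain (start SD 2.0 Å), selects the `min(15, S)` lowest-energy
conformers for analysis, applies the scheduled violation analysis, and
re-estimates the weight when auto-weighting is on. Rejected restraints are
never re-admitted within a run (re-admission is an extension point).
Ensemble precision is the mean RMSD of conformers to their superposed mean
(least-squares/Kabsch superposition); accuracy is the RMSD of that mean to
the reference.

Numerical choices: the per-conformer minimization budget is 800 steps —
enough for the toy energy to converge; with substantially fewer steps a
residually unconverged conformer set can spuriously reject a satisfiable
restraint. Conformer ranking uses a stable sort so ties cannot reorder
across platforms; all stochastic draws come from a single seeded generator
per run, making decision histories bit-identical for a fixed seed.

### What the toy driver can and cannot show

On the default fixture (40 atoms, 5.5 Å cutoff) the true restraint network
carries ~44 constraints against 114 internal degrees of freedom. Such a
network is far from rigid: a competent minimizer can satisfy the union of
the true and the planted noise restraints simultaneously, so the noise
restraints are *not* consistent violators of the generated ensembles and
the protocol-level rejection rate for them is honestly zero. Consistent-
violation pruning presupposes a data set redundant enough to over-determine
the structure — the regime of real NOE data (tens of restraints per
residue), not of a sparse point-atom toy. Experiments with chain-bond
terms, compact references and distance-geometry-seeded starts confirm the
picture: whenever the optimizer is good enough to fold the toy chain, it
also folds it around the noise restraints; whenever it is not, true
restraints are lost alongside noise.

The rejection machinery itself is therefore validated where the conditions
for it hold: one analyse/reject pass at late-iteration adaptive settings
(T = 0.5) against the perturbed-reference ensemble removes 100 % of the
planted noise restraints while keeping 100 % of the true ones (the noise
targets contradict the ensemble; the true targets match it). The protocol-
level tests assert what the toy scale genuinely supports: full retention of
true restraints on noise-free data, monotone non-increase of the active
count, shrinking adaptive tolerance as ensembles tighten, and bitwise
deterministic decision histories.

## Degenerate inputs and tie-breaks

* Zero intensities are validation errors wherever `|I|^(-1/6)` is needed,
  naming the offending peak id.
* A distance exactly at `U + t` or `L − t` does not violate; a violated
  fraction exactly at the threshold does not reject.
* `σ_ρ = 0` (uniform density) removes nothing at any n (strict `>`).
* Single-restraint lists cannot drive the adaptive tolerance (D needs
  N ≥ 2); all-identical `ec` gives t = 0 with a warning.
* Restraint TSV round-trips bit-identically (`repr` floats); the CNS
  ASSIGN dialect is write-only.
* PDB ensembles: all MODELs of the first chain, altloc 'A', atom identity
  = (residue serial, atom name).

## Known limitations

* No simulated annealing, torsion-angle dynamics, or water refinement; the
  steepest-descent driver is a stand-in whose folds are not publication-
  quality structures (mirror-image folds, in particular, are degenerate
  under distance-only restraints).
* No RDC or dihedral restraints, restraint combination, or network
  anchoring.
* The automatic weight is a capped moment estimator, not the full
  posterior treatment.
* The pre-filters operate on peak lists only; no spectrum-level processing
  or peak picking.
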