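# Methods

This note records the models, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Kinetic model

Seeded aggregation is described by the first two moments of the fibril
length distribution, number concentration `P(t)` and mass concentration
`M(t)` (both molar, monomer equivalents), with free monomer
`m = m_tot − M`:

    dP/dt = k_n·m^n_c + k_2·m^n_2/(1 + (m/K_M)^n_2)·M + k_minus·M
    dM/dt = 2·k_plus·m·P

The three `P`-producing terms are primary nucleation, surface-catalysed
secondary nucleation with single-site saturation (`K_M → ∞` recovers the
unsaturated law), and fragmentation.  Mass enters fibrils only through
elongation at the `2P` ends.  The model assumes well-mixed bulk kinetics,
no length-dependent fragmentation, no depolymerization, and a fibril long
enough that end effects are negligible — the standard two-moment closure
for self-replicating filament growth.  Both fragmentation and saturated
secondary nucleation give an effective replication rate
`kappa = sqrt(2·k_plus·B·m)` (with `B` the per-mass end-production rate)
that scales as `m^(1/2)`, hence the diagnostic half-time scaling exponent
`gamma ≈ −1/2` for seeded assays dominated by either process; unsaturated
secondary nucleation of order `n_2 = 2` gives `gamma ≈ −3/2`.

Reaction orders default to `n_c = n_2 = 2`, the convention of the
moment-model literature for tau-like systems.  Seeds are specified as mass
(`M_0`, monomer equivalents); the number concentration is `P_0 = M_0/L_0`
with a configurable mean seed length, default `L_0 = 1e4` monomers
(micron-scale unsonicated fibrils).  Since bulk traces constrain only
combinations such as `k_plus·P_0` and `kappa^2 ∝ k_plus·k_2`, `L_0` trades
off exactly against `k_plus`; tests therefore assert identifiable
combinations, not individually unidentifiable constants.

### Integration

The ODEs are integrated with adaptive LSODA (stiffness-switching),
relative tolerance 1e-8 by default (1e-10 where analytic limits are
verified), absolute tolerances scaled separately for `P` and `M` because
they differ by ~4 orders of magnitude.  Mass conservation holds by
construction (`m ≡ m_tot − M`); the integration is rejected if `M`
overshoots `m_tot` by more than 100× the 1e-6·m_tot tolerance, and
sub-tolerance ripple is clipped and made monotone.  Correctness is checked
against (a) the closed-form elongation-only solution at early times and
(b) an independent fixed-step RK4 integrator of the three-variable system
(`P, M, m`) at 1e4 steps (half-time agreement to 0.5%, mass balance to
1e-6 relative).

### Half-times

`t_1/2` is the midpoint of a four-parameter logistic
`base + amp/(1 + exp(−(t − t50)/tau))` fitted to the raw signal;
baseline and plateau come from the same fit, and normalization maps them
to 0/1.  A trace whose 2.5–97.5 percentile range is below 5× the noise SD
(robustly estimated from lag-1 differences) is declared non-aggregating
and reported as a sentinel, never a number.  Fits whose transition has not
completed by the end of the trace (`t50 + 2·tau > t_max`) are flagged
`incomplete`.  The logistic midpoint agrees with the model-free
half-crossing time to within 2% on simulated traces; the residual
difference reflects the slight asymmetry of moment-model curves.

### Global fitting

Free rate constants are fitted in log10 space by least squares jointly
over all traces (each trace carries its own `m_tot`, `M_0`, `P_0`), with
multi-start optimisation (default N = 20 log-uniform draws inside the
bounds; the RNG seed is recorded in the output).  Parameters ending within
1e-3 log-units of a bound are flagged.  Misfit is reported per trace and
in total, along with every start's final misfit.

## Inhibitor mechanism

The vehicle (0-dose) condition is fitted first to pin the control
constants; each dose is then refitted with only the chosen subset of
{`k_2`, `k_plus`} free, all structural constants held.  When high-seed
(2.5 µM seed) traces are available alongside the low-seed (50 nM) series,
each dose is fitted jointly on both regimes: the high-seed data pin
`k_plus`, the low-seed data pin the self-replication constants.  The
sequential alternative (elongation from high-seed alone, then `k_2`) is
biased here because self-replication is not negligible over a 48 h
high-seed trace, and is therefore not the default.  Fractional reductions
are `1 − k(dose)/k(control)`, with the headline value at the highest dose;
values outside [−1, 1] are flagged.  On synthetic data with only one
constant perturbed, the other's fitted reduction stays within ~5 points of
zero (cross-talk control).

Elongation rates are also available model-free as ordinary least-squares
slopes over the first 10 h of high-seed traces; the slope ratio versus
control approximates the `k_plus` ratio but inherits curvature bias when
the trace departs from linearity inside the window, which is why the
mechanism deconvolution uses the ODE refit.

**KIC50.** Approximate rates `1/t_1/2` are normalized so the vehicle
control is 100 and complete arrest 0 (the natural anchoring; configurable).
A descending logistic in log dose with top fixed at 100, bottom fixed at
0 and free Hill slope is fitted — four doses cannot support four free
parameters.  Series in which no dose depresses the rate below 75 carry no
midpoint information and return a `> max dose` bound; non-monotone series
are flagged but fitted.

## Binding

One-site fits of FP titrations use the non-depleting hyperbola
`delta_mP = B_max·[F]/(K_D + [F])` with fibril concentration in monomer
equivalents (site multiplicity folds into `B_max`).  A quadratic
ligand-depletion variant is available behind a flag because the ligand
(10 µM) and the affinities are comparable; the hyperbola remains the
default one-step binding form.  The fit is **unweighted** by default:
per-level SDs estimated from three replicates are themselves so noisy that
inverse-SD weighting destabilizes `K_D` catastrophically on weakly
saturating curves (verified by simulation across tens of seeds); weighted
fitting remains available.  `K_D` is flagged poorly determined when the
curve shows no saturation evidence (max signal < 2× the
lowest-concentration signal, or fitted `K_D` beyond two-thirds of the
fibril range, i.e. the curve reaches < ~60% of its plateau) or when the
asymptotic SD reaches half the estimate.

## Active-learning loop

Molecules are featurized with hashed Morgan fingerprints (radius 2, 2048
bits; optional physicochemical descriptor block).  The featurizer is a
plain function of SMILES so learned embeddings can be substituted — the
loop is featurizer-agnostic.  The surrogate is a random forest (500 trees)
plus a Gaussian process (RBF + white noise, hyperparameters by marginal
likelihood, 2 restarts) fitted to the forest's training residuals;
prediction is RF mean + GP residual mean, uncertainty is the GP predictive
SD.  Acquisition is the upper confidence bound `mean + beta·sd` with
`beta = 1` by default; ties break lexicographically by molecule id so
selection is deterministic.  Batches may optionally reject candidates too
similar (Tanimoto > cutoff) to an already-selected member, backfilling by
score if the filter over-prunes.  Campaigns seed with a user-supplied id
list ("docking hits") or a uniform random draw (default 105), then iterate
train → score → select → measure; history records per-iteration potent /
highly-potent counts and hit rate under the strict 1.5/2 thresholds.

Chemotype grouping is leader-style Butina clustering on fingerprint
Tanimoto similarity (cutoff 0.78); every member is within the cutoff of
its cluster centroid by construction, which the tests verify against the
full pairwise similarity matrix.  The CNS multiparameter-optimization
score sums six piecewise-linear desirability components (calculated logP;
a logD proxy — calculated logP reused, declared in the output; molecular
weight; TPSA; H-bond donors; and a substructure-based most-basic-pKa
proxy), each in [0, 1]; the default pass threshold is 4 of 6.  The pKa
proxy is deliberately crude (amine/amidine/azine substructure classes)
and is the first thing to replace if a real predictor is available.

## Synthetic data: what is and is not emulated

The generators reproduce the assay geometry of the quiescent seeded-tau
screen: reads every 900 s; 5 µM monomer + 50 nM (1%) seeds for low-seed
screens; 3.2–15 µM monomer dilutions; 1×/2×/4× molar-equivalent dose
ladders (5/10/20 µM); 2.5 µM seed high-seed elongation assays over 48 h;
10 µM compound FP titrations over a 2-fold fibril ladder topping at
12.5 µM; three replicates per condition (replicate counts are otherwise
unstated; n = 3 is the field default).

The ThT readout is linear in fibril mass, `signal = a + b·M(t)`, with
additive Gaussian noise (default 20 AU on a ~2000 AU dynamic range, i.e.
~1%); fibril-polymorph amplitude differences are modelled as distinct
gains only.  Not emulated: fluorophore photophysics, inner-filter and
quenching effects, evaporation drifts, well-position effects, or any
secondary structure readout — so passing tests demonstrate correctness of
the analysis given the model, not robustness to instrument artefacts.

Ground-truth rate constants (not available from the source data) were
fixed once at `k_plus = 5e3 /M/s`, `k_minus = 1e-8 /s` (fragmentation
variant) or `k_2 = 1e4` with `K_M = 1 µM` (saturating-secondary variant),
chosen so `kappa(5 µM) ≈ 2.2e-5 /s` puts seeded half-times at tens of
hours — the timescale of the emulated assays — and so both self-replication
variants give `gamma ≈ −1/2` over the dilution series.  Planted inhibitor
effects scale with dose by a hyperbolic law normalized to reach the
planted maximal reduction exactly at the top dose (the true dose law is
unknown; this is the simplest saturating choice).

The screening library enumerates a two-slot scaffold–substituent grammar
(10 scaffolds × 16 substituents², ~2,200 valid unique molecules, including
two oxadiazole-bearing scaffolds) and samples 2,000 deterministically —
desk scale versus the millions of a real vendor library, so enrichment
properties rather than absolute hit rates are the meaningful test surface.
Hidden actives (default 8) are drawn from the oxadiazole family; the
measurement oracle is `1 + (max_ratio − 1)·exp(−d²/w²) + noise` with `d`
the Tanimoto distance to the nearest active (`w = 0.3`,
`max_ratio = 3`, noise SD 0.1), yielding a ~3% base hit rate comparable to
an unenriched screen.  Oracle noise derives from a stable hash of the
canonical SMILES plus the seed, so it is reproducible across calls and
invariant under SMILES rewriting.

## Problem sizes and determinism

Dilution and dose simulations use 150 h of 15-min reads (~600 points per
trace, 18–24 traces per family); mechanism refits use 3 multi-start draws
per dose (the 1–2 parameter refits are well conditioned, and 20 starts
change nothing but runtime); campaign demonstrations use the 2,000-molecule
library with batches 105/32/45/49 and 10 seeded replicates.  Every
generator and every stochastic fit takes an explicit seed; fixed seed and
configuration give bit-identical outputs, which the test suite asserts.

## Known limitations

- Bulk traces cannot separate `k_plus` from `P_0` (seed length); only
  products are identifiable without an independent length measurement.
- The logistic half-time is a convention, biased by ~1–2% against the
  model-free half-crossing for asymmetric curves; both are exposed.
- The CNS MPO pKa/logD components use declared proxies, not predictors.
- The GP is fitted on up to a few hundred points; beyond ~2,000 labelled
  molecules the exact GP would need replacing with a sparse approximation.
- The fragmentation and saturating-secondary variants fit seeded data
  equally well (both give `gamma ≈ −1/2`); distinguishing them requires
  unseeded or agitation-varied experiments outside this scope.
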