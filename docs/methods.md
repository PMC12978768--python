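# Methods

This note documents the models implemented in `ecga`, the choices made
where the published procedure is under-specified, what the synthetic
generators emulate, and the package's known limitations.

## Activity conventions

IC50 values in nM are converted to pIC50 on the molar scale,
pIC50 = 9 − log10(IC50/nM), which reproduces the 5.0–9.301 range of the
packaged activity table.  Compounds with pIC50 ≥ 7.61 are high-activity;
the comparison is inclusive.  The packaged table's printed labels split the
54 compounds 27/27 under this threshold, whereas the accompanying text
reports 28/26; the fixture keeps the printed labels verbatim and the reader
surfaces threshold disagreements as a report (`ActivityTable.label_overrides`)
rather than silently reconciling them.

## ECMC construction

The matrix of contiguity of a conformer carries an atomic electronic
property on the diagonal and, off the diagonal, a bond descriptor for bonded
pairs or the Euclidean distance for nonbonded pairs.  Defaults are partial
atomic charge (e) and bond order, matching the properties displayed for the
reference compound; both are configurable (valence, polarizability,
HOMO/LUMO energies; Wiberg index, bond energy, bond polarizability) since
the method admits alternatives.  Bonded C–H entries are masked from every
comparison — they are invariant across the series — but hydrogen atoms
remain eligible pharmacophore members (the published six-atom pharmacophore
contains H9).  Distances are rotation/translation invariant by
construction; this is property-tested with random rigid transforms.

Conformer retention follows the published filter: conformers with imaginary
frequencies are dropped, a 1.5 kcal/mol window is applied above the
ensemble minimum, at most 100 conformers are kept, and relative energies
are re-referenced so the retained minimum is exactly 0.  Boltzmann weights
use w_i ∝ exp(−E_i/RT) with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹.  The activity
formula's "kT" is read as RT with energies in kcal/mol, consistent with the
symbol list that names R the gas constant.  The temperature is not stated
in the source; the default is 298.15 K and it is configurable everywhere.

## Submatrix matching

A k×k reference submatrix matches a candidate ECMC when an injective,
element-compatible assignment of reference atoms to candidate atoms exists
under which every unmasked element agrees within its tolerance,
*inclusively* (tolerances are reported as attained maxima of deviations,
which must themselves match).  The search is deterministic backtracking:
candidate atoms are tried in increasing index order, partial assignments
are pruned as soon as any element exceeds its tolerance, and the first
complete assignment wins.  This makes match results reproducible; it does
not attempt symmetry-aware enumeration of all assignments.  A brute-force
enumerator over all injective assignments (candidates ≤ 10 atoms) is the
independent oracle; a 200-instance seeded suite asserts verdict and
assignment agreement.

## Pharmacophore discovery

The reference pattern is the ECMC of the lowest-energy conformer of the
most active compound.  The published account of the submatrix search is a
procedure sketch, so the concrete contract here is: candidate atom subsets
of the reference are enumerated breadth-first (sizes ascending within a
3–8 atom range, lexicographic position order within a size); each candidate
is screened against the lowest-energy conformer of every compound under the
initial tolerances (0.25 diagonal / 1.30 off-diagonal, the published
screening limits); and candidates are ranked by α_a, with ties broken by
higher P_a, then smaller size, then lexicographically earlier atom labels
(unlabeled atoms sort after all labeled ones).  Stage two — per-conformer
screening of the discovered submatrix — produces the δ_ni flags for the
activity formula; compound-level presence is the OR over retained
conformers.  Class-wise tolerance matrices are attained maxima of
per-element deviations over the matching conformers of each class, so
re-screening the derivation subset under its own tolerances always
succeeds.

α_a is computed with the square root of k1k2k3k4 in the denominator.  The
source prints the product bare, but the bare form is inconsistent with the
printed value (0.8261) by orders of magnitude, while the rooted form is the
standard φ coefficient bounded in [−1, 1]; the rooted form is therefore
used.  The printed quality values P_a = 0.8402 / α_a = 0.8261 admit no
consistent integer contingency under the P_a formula with 28 actives, so
they are documented here but not used as numerical targets.  Likewise the
all-conformer tolerance table is shipped as a fixture only: its entries are
not the elementwise maximum of the class tables, implying derivation over
conformers that are not published.

## Activity model and fitting

The ensemble activity formula is implemented as

A_n = A0 · [Σ_i δ_ni e^(−S_ni) e^(−E_ni/RT)] / [Σ_i e^(−E_ni/RT)],

with both sums over the retained conformers of compound n and δ gating the
numerator only — the only reading consistent with A_n = 0 for compounds
with no matching conformer (the printed equation is typographically
garbled).  The exponential uses e^(−S) as printed; the prose mentions an
e^(+S) dependence, but the equation is taken as normative and the sign is
absorbed by the fitted κ.  A0 is fixed to the reference compound's
experimental pIC50 rather than fitted, which reproduces the published
behavior of the reference compound being predicted exactly at its
experimental value.  Descriptors enter S unscaled: the published κ
magnitudes (−17.633 … 0.001) indicate the original fit ran on raw
descriptor values.

κ is fitted by trust-region nonlinear least squares (scipy
`least_squares`, analytic Jacobian) initialized at κ = 0 with tolerance
1e−10 on the objective; a seeded multistart is available but defaults to a
single start.  A descent safeguard returns the zero vector if the optimizer
ever ends above the initial objective.  Compounds with no matching
conformer predict 0 for every κ; by default they stay in the fit with
residual (A_exp − 0)² — the model treats the pharmacophore as necessary —
and a flag excludes them instead; a warning is emitted either way.
Leave-one-out predictions refit κ from scratch n times (verified against
naive refits); E statistics are PRESS ratios E_j = PRESS_N /
PRESS_{N−1,drop j}, lower meaning more influential, undefined (NaN) when
the reduced PRESS is 0.

## GA descriptor selection

A chromosome is a fixed-cardinality set of descriptor indices: the model
size (default 12, from the 5:1 observations-per-parameter guideline) is a
constraint, not an objective, which resolves the ambiguity between
fixed-size and binary-mask encodings.  Fitness is the LOO-PRESS of the κ
model on the subset, memoized by sorted subset so revisits are free.
Operators: tournament selection of size 2 (the selection operator is not
published; tournament-2 with elitism 1 is standard, reproducible, and
yields the monotone best-fitness trace that is asserted on every run),
uniform crossover with repair (deduplicate, refill from unused indices),
and per-gene mutation to a random unused index.  Published budget defaults
(population 500, 500 generations, crossover 0.5, mutation 0.01) are
configuration values; tests and the oracle cross-checks run at reduced
sizes (population ≤ 40, generations ≤ 50, p = 8, N = 2), where exhaustive
enumeration over all C(8,2) subsets is feasible and the GA provably reaches
the global optimum.  The redundant "iterations 500 / generations 500"
wording is read as a single 500-generation budget plus an optional restart
count (default 1).

## Validation statistics

PRESS, SSY, q² = 1 − PRESS/SSY, and the two external-set variants (ext1
normalizes by deviations from the training mean, ext2 by the test-set total
sum of squares) follow the standard definitions; ext1 = ext2 exactly when
the two reference means coincide (property-tested).  R² is reported as the
squared Pearson correlation — the convention consistent with the published
training/test R² columns — while coefficient-of-determination readings are
available through the q²-style functions, so neither convention is
ambiguous.  k-fold Q² pools out-of-fold residuals over seeded shuffled
folds against the full-sample mean; the repetition count of "repeated
5-fold" is not published and defaults to 1.

## Hybrid ML stack

Z-scoring uses training-set statistics only (population standard deviation,
denominator n, matching the scikit-learn scaler convention); zero-variance
columns are centered and flagged.  RFE is scikit-learn's recursive feature
elimination wrapped around the random-forest regressor with step 1, keeping
30 descriptors; a flag additionally records the k-fold CV score of the
final selection (off by default to keep runs cheap).  Baselines run the
published default hyperparameters: GBM (learning rate 0.1, 100 stages,
depth 3, subsample 1.0, squared error), RF (100 trees, squared error,
unlimited depth, sqrt feature sampling, bootstrap), decision tree
(squared error, unlimited depth), and an optional MLP (one hidden layer of
100 ReLU units, Adam, learning rate 0.001, 200 iterations).  The "LR"
baseline is implemented as ridge regression with α = 1.0: the published
configuration (L2, C = 1.0, lbfgs) describes a classifier, and ridge is its
regression analog at the same regularization strength.

Stacking trains the GBM first and feeds its score to an RF meta-learner.
Two ambiguities are resolved explicitly.  (1) *What the RF sees*: the score
is appended to the descriptor matrix by default ("used as input" read
additively); a score-only mode trains the RF on the 1-D score alone.
(2) *Which scores the RF trains on*: by default out-of-fold GBM scores
(5-fold, seeded), so the meta-feature of a training row comes from a model
that never saw it; the naive in-sample mode is retained deliberately
because near-unity training R² of in-sample stacking is itself an
instructive pathology, and the suite asserts naive training R² ≥ out-of-fold
Q² on the same data.  Published dataset-bound performance numbers are not
reproduction targets: they depend on a proprietary 273-descriptor panel and
an unpublished train/test split.

## Synthetic generators

All generators are pure functions of a seed-bearing spec (identical spec ⇒
byte-identical output).

*Planted pharmacophore sets* embed a k-atom reference fragment (charges in
[−0.4, 0.4] e, pairwise distances in [1.8, 6] Å) in every compound.
Pharmacophore atoms carry distinct elements and decoy atoms are hydrogens
on a conserved scaffold shared by the whole series, so (a) the fragment
admits exactly one element-compatible assignment and (b) no
decoy-containing submatrix can separate the classes.  Actives jitter all
positions by at most half the off-diagonal tolerance times
`tolerance_scale` (so no distance moves more than the scaled tolerance) and
charges within the scaled diagonal tolerance.  Each inactive displaces one
pharmacophore atom — cycling over the k atoms across inactives — radially
past twice the fragment diameter, which makes *every* distance involving it
deviate by more than three tolerances; consequently a submatrix
discriminates all inactives only if it contains every planted atom, which
is what makes exact recovery a provable property rather than a statistical
one.  Conformer energies are exponential with mean `energy_scale`
(1 kcal/mol default); each conformer is randomly rotated and translated.
These sets emulate the active/inactive contrast, not chemistry: geometries
are not valence-consistent molecules, and electronic properties are not
derived from any Hamiltonian — passing tests demonstrate the mining
machinery, not quantum-chemical realism.

*Forward-simulated activity data* draw per-conformer descriptors from
N(0, 1), set κ nonzero on the designated signal columns (magnitudes
uniform in [0.2, 0.8], random sign), and emit activities from the ensemble
formula plus Gaussian noise.  Defaults mirror the recovery study
conditions: 40 compounds, 4 signal descriptors among 8, noise 0.05 pIC50
units, A0 = 9.0.

*ML tables* use standard-normal features and a target with a smooth sine
term, one pairwise interaction, a step, and a linear term on each signal
column, plus noise.  The high-SNR benchmark configuration (n = 200, 10
columns, 4 informative, noise 0.1) has most of its variance in components
tree ensembles can learn, which is what a "high-SNR" benchmark is meant to
provide; a pure-noise configuration (`signal_indices=()`) serves as the
null.

## Numerical choices and degenerate inputs

Tolerance comparisons are inclusive (≤); the boundary behavior is tested
with dyadic values so floating point cannot blur it.  Boltzmann weights
subtract the minimum energy before exponentiating.  Zero contingency
marginals raise an explicit degenerate-marginal error instead of returning
NaN; zero-variance targets raise degenerate-target errors in every
variance-normalized statistic.  Matching ties are broken by the
deterministic search order; GA and k-fold procedures are reproducible from
their seeds.

## Problem sizes

The test suite and the acceptance script run at desk scale: pharmacophore
sets of 10–12 compounds with ≤ 10 atoms and 5 conformers each, activity
fits with ≤ 40 compounds, GA oracle checks on C(8,2) subset spaces, ML
benchmarks with n = 200, and one 273-column RFE run at n = 100.  These
sizes were chosen so every check completes in seconds to a couple of
minutes on a single CPU while still exercising the full code paths.

## Known limitations

Quantum-chemical property calculation, conformer generation physics, and
vendor file formats are out of scope; ensembles must arrive as the
documented JSON (or geometry-only SDF).  The discovery search enumerates
subsets of one reference conformer and does not canonicalize graph
symmetries.  The original study's descriptor panels are not recoverable, so
its dataset-bound statistics (panel-specific R²/q² values and the published
P_a/α_a pair) are context, not targets.  Synthetic data validate
correctness of the algorithms, not their performance on real conformer
ensembles.
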