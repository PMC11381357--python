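# Methods

This note records the models implemented in `tmsdkit`, the parameter
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices a maintainer would want to
know.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Displacement systems

A system is three strands written 5′→3′: a 22-nt invader (6-nt toehold +
16-nt branch-migration region), the 22-nt substrate (full reverse
complement of the invader, fluorophore-labelled in the emulated assay), and
the 16-nt incumbent (identical to the invader's branch region, so it covers
the substrate everywhere except the toehold overhang).  These invariants
are enforced at construction; loaders report per-row violations with the
offending positions.  Strand lengths other than 22/16 are accepted (the
external-test protocol deliberately probes 20–23-nt invaders) as long as
the complementarity relations hold.

## Secondary-structure model

The structure space is all *nested* sets of Watson–Crick pairs (A·T, G·C
only, no pseudoknots, no wobble pairs) with at least 3 unpaired bases in
every closing span (`min_loop = 3`).  A structure's free energy is

E(S) = Σ_pairs e_pair(i,j) + Σ_stacked steps e_stack ,

where a stacked step means pairs (i,j) and (i+1,j−1) are both present.
Stack energies default to the unified nearest-neighbor DNA ΔG°₃₇ table
(SantaLucia & Hicks 2004, kcal/mol); per-pair terms default to 0, so helix
stability comes entirely from stacking and isolated pairs are energetically
neutral.  Loop penalties, dangling ends, coaxial stacking and salt
corrections are deliberately omitted: the model stays desk-scale and every
structure can be scored exactly by the enumeration oracle.  Agreement with
any external tool's probabilities is therefore not expected numerically;
workflows that need tool-exact values import them through the ppairs
adapter, which validates bounds and row sums and feeds the same
featurization path.

Three routes cover the same space:

* `enumerate_structures` — exhaustive recursion, capped at 20 nt; the
  testing oracle.
* `partition_pair_probabilities` — inside/outside dynamic programming.
  The inside pass uses a left-anchored interval decomposition with a
  stacking correction on the closing pair.  The outside (exterior) weight
  of a pair (i,j) is summed over its innermost enclosing pair (a,b): the
  strips between them can only hold local structures, and the only
  interior/exterior cross term is the (i−1,j+1) stack, handled as a
  single-term correction.  The O(n⁴) exterior sum is evaluated as small
  matrix-vector products; a 22-nt strand takes ~3 ms.  Equality with the
  enumeration oracle to ≤ 1e-9 on random 12-mers is the module's central
  correctness property (observed agreement is at machine precision).
* `mfe_structure` — the same decomposition minimizing (energy, number of
  pairs, pair list).  Ties therefore resolve to the fewest pairs and then
  the lexicographically smallest sorted pair list; the lexicographic key is
  resolved greedily per subproblem (candidate structures are materialized
  and compared), which is exact except in pathological all-tie energy
  models where a full Pareto front would be required.  Temperature enters
  only through kT (default 298.15 K, the midpoint of the kinetics runs);
  the ΔG°₃₇ stack table is treated as a fixed parameter set, not split into
  enthalpy and entropy.

## Toehold intermediate

The displacement intermediate is modelled as a two-state hybridization of
the 6-nt toehold duplex: ΔG° = nearest-neighbor stack sum + bimolecular
initiation penalty (default +1.96 kcal/mol), K = exp(−ΔG°/kT) (1 M
reference), and at equal strand concentrations c₀ the bound fraction solves
the mass-action quadratic θ = ((1+2Kc₀) − √(1+4Kc₀))/(2Kc₀) (a series
expansion is used for Kc₀ < 1e-8 to avoid cancellation).  Each toehold
base's interstrand pairing probability is θ·(1 − p_intra(i)), discounting
bases already occupied by intramolecular folding.  A full two-strand
partition function is deliberately out of scope; the two-state model
exposes K, θ and concentration cleanly and is overridable (`binding_k`)
for hypothetical or non-complementary cases.

## The sixteen variables

With h(A)=h(T)=2 and h(G)=h(C)=3 H-bonds per base in a WC pair, p(i) the
intramolecular pairing probability of invader base i and p(i,j) the pair
probabilities: X1/X4/X8 are expected free bases (toehold / whole invader /
branch region); X2/X5 the corresponding free H-bond sites weighted by h;
X3 the toehold G/C count; X6/X7 total H-bond capacities; X9 the expected
number of pairs touching branch-region indices; X10 the ensemble free
energy −kT ln Z; X11 the ensemble-weighted intramolecular H-bond count
Σ p(i,j)·h_pair; X12 the unpaired bases inside MFE hairpin loops; X13 the
MFE pair count; X14 = Σ_toehold h(i)·θ·(1−p(i)); X15 the intermediate
concentration θ·c₀ (stored in molar; standardization handles the scale);
X16 the toehold-duplex ΔG°.  X11 is ensemble-weighted rather than an
integer MFE count — that is what makes reported values of this quantity
non-integer — and the identity X5 = X7 − 2·X11 then holds exactly because
each pair consumes one h-worth of sites on both partners.  The registry is
a fixed X1…X16 column order so datasets are schema-stable.

The ranking key for near-identical designs is score = z(X2) + z(X5) −
z(X11) with within-set standardization (a zero-variance feature contributes
0); ties are flagged and keep input order.  The design-rule report checks
(i) toehold length against the 6-nt budget, (ii) toehold G/C fraction
(default threshold 0.5), and (iii) toehold occlusion: more than 2 toehold
bases paired in the MFE flags the design.

## Kinetics

Fluorescence traces are converted to product concentration through a
linear standard curve (OLS on the dilution series, default 10–100 nM) and
a measured background, clipped at zero, then fitted with the
equal-concentration irreversible second-order law c(t) = c₀²kt/(1+c₀kt)
with c₀ = 50 nM (1:1 mix of 100 nM stocks).  The fit optimizes log₁₀k
against the dimensionless progress curve c/c₀ — both are O(1), whereas
molar-scale residuals (~1e-9) would fall below standard optimizer
tolerances — seeded from the observed half-completion time (k₀ = 1/(c₀·t½))
with a log-grid fallback over k ∈ [1e2, 1e8].  Flat traces are reported as
k = 0 with a no-reaction flag; replicate fits (default 3, emulating
parallel experiments) are combined by geometric mean because k spans
orders of magnitude.

The time to equilibrium uses completion fraction f* = 0.95 (configurable):
t_eq = f*/((1−f*)·k·c₀).  Rate classes: t_eq < 1000 s → class 0,
1000 ≤ t_eq ≤ 3600 s → class 1 (both boundaries in the closed middle
interval), t_eq > 3600 s → class 2.  Apparent activation energies come
from an OLS line of ln k against 1/T over the four temperatures
15/20/25/30 °C, Ea = −slope·R.

## Synthetic study conditions

The generator emulates the study design: uniform random 6-nt toeholds on a
fixed 16-nt branch region (default `CCACATACATCATATT`, the canonical
branch-migration domain of Zhang & Winfree 2009, swappable by config), a
planted rate model log₁₀k = β₀ + Σ β_f·X_f + ε, and fully calibrated
fluorescence traces (slope 10 a.u./nM, background 50 a.u., read noise
5 a.u. ≈ 1% of the 50 nM amplitude, 5 s sampling over 2 h).  Default
planted coefficients β = (X2: +0.08, X5: +0.05, X11: −0.15) encode the
observed monotonicity — faster with free H-bond sites, slower with
intramolecular pairing; β₀ = 4.0 was calibrated once against the
generator's own feature distribution so the planted log₁₀k (mean ≈ 5.3,
SD ≈ 0.55 with ε-SD 0.25) straddles the class boundaries at
log₁₀k ≈ 5.02 and 5.58, giving roughly balanced thirds.  Per-system
random streams are spawned from the master seed by (system index, stream)
keys, so enlarging a study never perturbs earlier systems.

What the generator does **not** emulate: photobleaching and drift,
temperature-dependent folding of the invader, reversible or zero-toehold
kinetics, pipetting/concentration errors, and any coupling of trace noise
to intensity (noise is additive Gaussian at fixed gain — the simplest model
consistent with shot/read noise).  Passing tests therefore demonstrate
correctness of the analysis pipeline under these idealized conditions, not
instrument-level robustness.

## Evaluation protocol

Classifiers: one-vs-rest logistic regression and an RBF-kernel SVM on
standardized features, and a raw-feature decision tree; class scores for
ROC are predicted probabilities (margins for the SVM).  Defaults: 80/20
stratified split, 5 stratified CV folds, 500-tree random forest for
importance — all config keys.  The recovery studies use pooled
cross-validated predictions (every sample scored once by a model that
never saw it) as the held-out metric: on 300 planted systems a single
60-sample split has binomial noise of several accuracy points, while the
pooled estimate is stable.  The planted recovery study is run with ε-SD 0
(the rate class is then a deterministic, monotone function of the
features; the only stochasticity is the 1% read noise), which is the
designed separation between "can the models recover a clean planted
structure" (this check) and "how do they degrade with label noise" (the
generator's default ε-SD 0.25, exercised in the unit suite).

Problem sizes in the recovery studies — 100 random 12-mers for the
DP/enumeration equivalence, 50 rate constants log-uniform in [1e3, 1e7]
M⁻¹s⁻¹, 100 Arrhenius replicates, 1000 systems for the conservation
identity, 300 systems for classification, 20 label permutations, 10 forest
seeds — keep the whole acceptance run around half a minute on one CPU.

## Known limitations

* The builtin energy model is intentionally minimal; absolute free
  energies and probabilities differ from full-featured thermodynamic tools
  (no loops/dangles/salt).  Import tool-computed ppairs files when
  numerical agreement with such tools matters.
* The two-state intermediate ignores partial toehold hybridization and
  three-strand ensemble effects.
* The second-order law assumes irreversible displacement at equal initial
  concentrations; strongly reversible (very short toehold) systems violate
  it.
* Feature definitions beyond the seven explicitly named key variables
  (X2, X5, X9, X11, X12, X14, X15) are a documented completion within the
  stated categories (interaction energy, free bases, H-bond counts); the
  registry is data-driven so alternative definitions can be swapped in.
* X15 is stored as a molar concentration; normalize by c₀ where a bound
  fraction is preferred.
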