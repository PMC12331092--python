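# Methods

## The model system

Arrestin-2's inactive state is locked by a buried polar core (Asp27, Arg170,
Asp292, Asp299, Arg394) and by the three-element hydrophobic interface that
anchors the C-tail to the N-domain. The activation intermediate this package
quantifies is the *arginine switch*: Arg394 leaving its salt bridge with the
gate-loop aspartate (Asp299) and being captured by a glutamate (Glu358) of a
phosphorylated receptor-tail peptide, while the C-tail remains otherwise
attached. All analyses reduce to observables of that transition: a
switch–gate distance, contact stabilities of the peptide interface (site I,
the phosphate-clamping arginines Arg77/Arg148/Arg166; site II, the
Glu358–Arg394 pair), conformer populations of the switch residue, peptide
RMSF, a two-site binding isotherm, and differential amide exchange.

## Trajectory layer

Coordinates are Å throughout; residue ids are author numbering from the
source file (no renumbering), so the switch residue is always 394 and the
gate 299. Multi-model PDB is the canonical trajectory format (self-contained
and text-only); DCD is read behind the same interface. Phosphoserine /
phosphothreonine are recognised as SEP/TPO or as SER/THR carrying a `P`
atom. Superposition is the least-squares (Kabsch) fit on a selection,
applied rigidly to all atoms; selections use a small conjunctive grammar
(`resid … and name … and chain …`) with deterministic, sorted resolution.
Analysis windows (`all`, `last T ns`, `last N frames`) are applied per
replicate set; equilibrated-tail analysis conventionally uses the last 50 ns
of each run, and full-window analysis the complete 300 ns stability runs.

## Observables and conventions

* **Polar-core metric**: d(Cζ(R394)–Cγ(D299)), the charged-group carbons —
  consistent with the carbon-atom convention used for the site-II
  monitoring distance (Cδ(E358)–Cζ(R394)). Engaged iff d ≤ 6.0 Å, midway
  between the intact (~6 Å average with re-formation events) and disrupted
  (~10 Å average) regimes; the threshold is configurable.
* **Salt-bridge contact**: min over side-chain acidic/phosphate oxygens ×
  basic nitrogens ≤ 4.0 Å, the standard geometric criterion. Stability % is
  the pooled frame fraction; the pooled value is by construction the
  frame-count-weighted mean of per-replicate fractions. The monitoring
  distances (P–Cζ, Cδ–Cζ) are reported separately and are *not* the contact
  rule.
* **QT clustering**: greedy quality threshold on a precomputed RMSD matrix.
  RMSD is evaluated after one *global* superposition (the source ensembles
  are backbone-restrained, so what is clustered is the switch conformation
  relative to the fixed body), never per-pair fitting. Ties in neighbour
  count break to the lowest frame index, making results deterministic;
  cluster ids are discovery order, which the greedy argument makes
  non-increasing in size. Cutoffs: 3.7 Å for broad rebinding ensembles,
  1.0 Å for tight relaxation ensembles. Frames are pooled across replicates
  by default (per-replicate clustering is a caller choice).
* **RMSF**: two-pass iterative superposition onto the time-averaged
  structure, then per-atom fluctuation about the mean position; replicate
  profiles are averaged. For isotropic per-atom jitter σ the expected value
  is σ√3, which the tests use as a closed-form oracle. Alignment can be
  disabled for pre-aligned or synthetic coordinates.
* **Mann–Whitney U**: exact two-sided p by the standard counting recurrence
  when the smaller sample has ≤ 10 observations, there are no ties and the
  larger sample ≤ 500; otherwise the normal approximation with continuity
  and tie correction. Observations are per-frame distances pooled across
  replicates (matching how the boxplot comparisons are constructed); frames
  within a replicate are autocorrelated, so these p-values overstate
  independent evidence — a per-replicate-mean mode is the conservative
  alternative.
* **HDX rule**: per timepoint, Δ = mean(B) − mean(A), pooled-variance
  Student t (with two groups identical to the one-way ANOVA, F = t²);
  significant iff p < 0.05 AND |Δ| ≥ 0.2 Da. The floor applies to the
  *observed* difference and dominates regardless of variance. No
  multiple-testing correction is applied by default (a Benjamini–Hochberg
  option exists); no back-exchange correction (state comparisons only).
  Classification: increased / decreased / ns / mixed from the signs of
  significant timepoints.

## ITC model

Two *independent* site classes (not sequential/cooperative): the biphasic
titration reflects a high-affinity site I and low-affinity site II that can
be occupied separately, so a product of single-site binding polynomials is
the appropriate form. Free ligand solves
L + M·(n₁L/(K_D1+L) + n₂L/(K_D2+L)) = L_tot, strictly monotone in L, by
bisection + Newton polish (machine precision). Heats are kcal per mol of
injectant with perfusion bookkeeping: injection i dilutes prior contents by
(1 − vᵢ/V₀) and the measured heat includes half the displaced volume's heat
content. Defaults: 200 μL cell (instrument cell volume is not otherwise
pinned; it only scales absolute heats, not per-mole fits), 200 μM
macromolecule, 1 mM syringe, 40 × 2.5 μL injections at 298 K — 40 so the
titration reaches molar ratio ≈ 3, past the two-site stoichiometry of 2;
with fewer injections the low-affinity phase is uncovered and the fit is
ill-posed.

Fitting: multi-start (8 starts, K_D jittered ×/÷3 geometrically around an
equivalence-point-scale guess; ΔH from plateau heights, baseline from the
tail) trust-region least squares in log K_D, with physically motivated
bounds (K_D ∈ [10⁻⁴, 10⁴] μM, |ΔH| ≤ 50 kcal/mol, n ∈ [0.05, 5],
|baseline| ≤ 5). Without the bounds the optimiser finds degenerate
enthalpy/baseline-cancellation minima on noisy data. The two-site result is
reported with K_D1 ≤ K_D2.

Model selection: extra-sum-of-squares F test (7 vs 4 parameters), two-site
preferred iff p < 0.05 and each |ΔH| exceeds its noise floor — twice its
linearised standard error (with a 3×RMSE absolute backstop). Spurious
splits of a single site pass the F test occasionally but leave the extra
enthalpy weakly determined, which the per-parameter floor rejects; genuine
sites with decisive F statistics pass it.

**Identifiability caveat.** At 200 μM cell concentration a 1.1 μM site has
c = M/K_D ≈ 180: the first transition is nearly stoichiometric and carries
little K_D information. A linearised (Cramér–Rao) analysis at these
conditions with 2 % heat noise gives sd(log K_D1) ≈ 0.47 for the full
7-parameter fit (≈ 0.29 even with n and baseline known), i.e. individual
K_D1 estimates scatter by tens of percent; the *model class* and the
site-I/site-II affinity ordering remain robustly identified. Monte-Carlo
recovery in the test suite reflects this.

## Synthetic generators

The switch generator emits a pseudo-molecule containing only the atoms the
metrics touch (switch/gate/anchor residues, the site-I arginines, the
peptide phosphoresidues and glutamate) — full-protein realism would add
nothing testable. Hidden states follow a first-order two-state Markov chain
(the simplest process with the observed dwell structure); coordinates are
the state's base geometry (engaged: Cζ–Cγ = 3.9 Å; disengaged: 10.0 Å with
Cζ 4.2 Å from the peptide Cδ) plus isotropic Gaussian noise (σ = 0.2 Å,
small enough that the states are > 6σ apart in the distance metric).
Charged groups are oriented toward their partners so the min-O–N criterion
registers formed contacts; the site-I phosphate clamp is static (its
contacts read ~100 % stable — real ensembles show 80–86 %, a breathing the
generator deliberately omits). Preset transition probabilities emulate the
two reported regimes: `BOUND_LIKE` (stationary disengaged fraction ≈ 0.95,
mean metric ≈ 9.7 Å) and `APO_LIKE` (≈ 0.34 disengaged, mean ≈ 6 Å).
What passing tests show is therefore that the *analysis chain* is correct
on data with known truth — not that real trajectories are this clean: real
ensembles have correlated, anisotropic fluctuations, intermediate
geometries and slow drift that the generator does not model.

The ITC generator adds i.i.d. Gaussian noise scaled to a fraction of the
maximum |heat|; the HDX generator uses a single intrinsic rate and
protection factor per peptide and state, replicate noise floored at zero
(real peptides mix per-amide rates; the single-exponential form is the
minimal shape with the right monotonicity and saturation).

## Numerical choices and degenerate inputs

Bisection depth (30 halvings + 4 Newton steps) reaches machine precision on
the mass balance; optimizer tolerances are 1e-10. Distance series must be
positive and finite; empty selections are legal but warn; single-frame RMSF
returns zeros with a warning, and perfectly static trajectories return
exact zeros (superposition is skipped). A blank titration (zero syringe
concentration) uses the injection index as abscissa since molar ratio is
undefined. Exact Mann–Whitney p-values cap at 1; approximate ones are
clamped away from exact zero. Config-driven runs write
timestamp-free JSON so identical configs reproduce byte-identical reports,
and every output file is registered in a SHA-256 manifest.

## Known limitations

* Benchmark-scale claims (ensemble statistics of the deposited ~1.6 μs MD)
  require downloading those trajectories; the package analyses them through
  the same interfaces but no such data ships here.
* The contact criterion and analysis window behind published stability
  percentages are not uniquely determined; both are config-exposed.
* Mann–Whitney on pooled frames ignores within-replicate autocorrelation
  (see above).
* No hydrogen-bond angle criterion, no χ-angle analysis, no cooperative or
  sequential ITC models, no spectral-level HDX processing.
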