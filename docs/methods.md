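# Methods

## Thermodynamic model

A variant is a binary vector x over the K substitutions of a combinatorial
library. Per biophysical trait t ∈ {folding, binding} the total free energy
is additive,

    ΔG_t(x) = ΔG_t^wt + Σ_i x_i ΔΔG_t,i + Σ_{i<j} x_i x_j ΔΔΔG_t,ij ,

the coupling sum being present only in second-order models
(`max_interaction_order = 2`). Folding is a two-state equilibrium
(unfolded/folded); binding a three-state equilibrium (unfolded-unbound,
folded-unbound, folded-bound), with the unfolded-and-bound state assumed
negligible. State probabilities follow the Boltzmann distribution:

    p_f  = K_f/(1 + K_f),                  K_f = exp(−ΔG_f/RT)
    p_fb = K_f K_b c/(1 + K_f + K_f K_b c), K_b = exp(−ΔG_b/RT)

with R = 0.001987 kcal K⁻¹ mol⁻¹ and T = 303 K. The ligand concentration c
is not separately identifiable from ΔG_b^wt and is fixed at 1 (absorbed
into the binding energy); it is exposed as a constant for completeness.
Measured fitness per phenotype is an affine transform a + b·p (p = p_f for
abundance, p_fb for binding). Internally all parameters are dimensionless
(θ = ΔG/RT); reported energies are θ·RT.

Probabilities are evaluated with branch-stable logistic/log-sum-exp forms;
the generic tanh-based logistic loses ~4 significant digits on the deep
tails, which is visible against the explicit partition-sum oracle used in
the tests (agreement demanded to 1e-12 relative).

## Training protocol

Loss: weighted, regularized mean absolute error
L = (1/N) Σ |y_n − ŷ_n| σ_n⁻¹ + λ₂‖θ‖², λ₂ = 1e-6, where σ_n is the
variant's fitness standard error and θ collects all trainable parameters
(energies and affine). Optimization is Adam (β = 0.9/0.999, ε = 1e-8),
initial learning rate 0.05 (0.005 selectable for very large libraries),
at most 1,000 epochs. Variants are split 70/20/10 into
train/validation/test (the wild type always trains). The batch size is the
tuned hyperparameter: each candidate in {512, 1024, 2048} is trained for
100 epochs and the one with the smallest validation loss wins. The
learning rate decays by γ = 0.98 whenever the mean validation loss over
the last 10 epochs has not improved on the preceding 10; training stops
early once the wild-type free energies' standard deviation over the last
10 epochs is ≤ 1e-3 kcal/mol. With a fixed seed the whole procedure is
deterministic.

### Initialization (warm start)

The loss surface has a sloppy valley in which the affine scale b partially
compensates the energy scale: plain random initialization reproducibly
converges there (predictions near-perfect, energies wrong, even at
vanishing noise). Initialization therefore proceeds in three steps, none
of which alters the training objective:

1. affine parameters from the 5th/95th percentiles of observed fitness
   (the assay plateaus);
2. energy terms from a weighted least-squares solve of the logit-inverted
   state probabilities on the genotype design (rows near the plateaus are
   downweighted, where the inversion is ill-conditioned); for binding, the
   three-state relation is inverted given the folding-energy estimate;
3. a damped Gauss–Newton polish of all parameters against the smooth L2
   analogue of the objective (`scipy.optimize.least_squares`, analytic
   Jacobian, ridge 1.0). The ridge pins coefficients the data leave flat —
   e.g. couplings of pairs never co-observed in the folding transition —
   near zero instead of letting them drift along zero-curvature
   directions. It applies to the warm start only.

The Adam protocol above then runs unchanged from this starting point.

### Gauge and canonicalization

Folding-only models have a discrete symmetry: negating every folding
energy while mapping (a, b) → (a + b, −b) leaves all predictions
unchanged. Fitted models are canonicalized to b > 0 for the abundance
phenotype (fitness increases with the folded fraction), which is the
orientation in which parameter-recovery comparisons are made. The joint
folding+binding model has no such symmetry. No constraint is imposed
during optimization.

### Resampling and uncertainty

`resample_training` replaces training fitness with a draw from each
variant's error distribution, taken as Gaussian with the variant's σ (the
error distribution's published form is not more specific than that);
validation and test data are never altered. Single fits do not resample by
default — parameter-recovery oracles are cleaner without the extra noise —
but `monte_carlo_uncertainty` always does: it refits
`n_mc_models = 10` models under independent random splits and independent
fitness resamples, and reports per-coefficient mean, sd, the 2.5–97.5
percentile span as the 95% CI, and a `confident` flag for CI width
< 1 kcal/mol. Failed member fits are reported; intervals are computed only
if at least 8 members survive.

### Linear baselines

`fit_linear_baseline` fits weighted least squares of fitness on genotype
products up to order 1–3 (1 + Σ_k C(K,k) parameters), on the same splits
as the energy model. The 1/σ weights mirror the energy model's
downweighting. Energy models are implemented only to order 2; order 3
exists solely as a linear baseline.

## Synthetic data

The generator emulates the statistical structure the analysis assumes —
it is the package's test bed, not a simulator of any particular assay:

- genotypes from the 2^K biallelic space (distinct uniform draws, equal
  per-order allocation, or exhaustive enumeration);
- fitness = affine(Boltzmann probability of additive energies + sparse
  pairwise couplings);
- per-replicate Gaussian noise with σ_v = σ0 + 2σ1·min(p, 1−p), a
  bounded-assay heteroscedasticity largest mid-transition (σ1 = 0 gives
  the constant-noise mode used in clean oracle tests); reported σ is
  σ_v/√R for R replicates.

Energy distributions (defaults, kcal/mol): first-order folding effects
Normal(+1.0, 1.0) — destabilization-biased, as observed for random
substitutions; couplings sparse zero-centred Normal(0, 0.25) with
nonzero fraction 0.2; binding effects Normal(+0.5, 0.5); ΔG_f^wt = −2.5,
ΔG_b^wt = −1.5; affine (0, 1) per phenotype. Two presets adjust these to
specific study regimes:

- `TruthSpec.combinatorial` (ΔΔG_f ~ Normal(+0.4, 0.4)): a designed
  fold-preserving library, whose deliberately mild substitutions keep
  multi-mutants near the folding transition. This is the parameter-recovery
  regime: with strongly destabilizing defaults a K = 15 library collapses
  onto the unfolded plateau where couplings are unidentifiable.
- `TruthSpec.strong_nonlinearity` (ΔΔG_f ~ Normal(+1.2, 0.6), no
  couplings): every substitution firmly destabilizing, sweeping variants
  across both plateaus — the regime in which a linear fitness model is
  systematically biased (residuals correlate with mutant order) while the
  energy model is not.

What the generator does not emulate: read-count statistics, replicate
batch effects, sequencing errors, position-specific effect structure, or
correlations between a substitution's folding and binding effects.
Passing recovery tests therefore demonstrate the inference machinery is
correct and well-calibrated under the model's own assumptions, not that
real libraries satisfy those assumptions.

### Problem sizes

Recovery runs use 20,000 distinct variants from a 2^15 space (the scale of
an exhaustively measured combinatorial library); nonlinearity
discrimination uses the exhaustive 2^14 space; Monte Carlo uncertainty
behaviour the exhaustive 2^8 space with first-order models; the greedy
design oracle K = 12 (where per-step enumeration is exact). Small-K
identities use exhaustive 2^K tables throughout.

## Library design

Candidate substitutions are filtered to confident (95% CI < 1 kcal/mol on
every trait used), well-observed (≥ 20 genetic backgrounds) and
single-nucleotide-reachable effects. Synonymous "substitutions" are not
candidates: reachability of a codon's own amino acid is defined false.

The greedy search starts from one substitution and repeatedly appends, at
a not-yet-mutated position, the candidate maximizing the objective of the
cumulative mutant — the geometric mean of the model-predicted growth rates
over the declared phenotypes (a single phenotype reduces to that growth
rate). Predicted growth rates are floored at 1e-6 before the geometric
mean, as assay growth rates are non-negative by construction and an exact
zero would otherwise annihilate the objective. Ties break by (position,
mutant amino acid), making the whole design deterministic. The search is
repeated from every possible start.

Library viability: the median predicted growth rate per phenotype of a
random 10,000-variant sample of each candidate library (exhaustive when
2^m ≤ 10,000); a library is viable when the geometric mean of those
medians is ≥ 70% of the maximal value. "Maximal value" is read as the
wild-type predicted geometric mean (default); a `reference="max"` switch
instead uses the best candidate library, as the phrase is genuinely
ambiguous. The returned design is the largest viable m over all starts.
Greedy selection is not guaranteed optimal; on small instances
`exhaustive_best_subset` computes the true optimum and the gap is logged,
never hidden.

Window-based designs (mild substitutions within a contiguous primary-
sequence window, avoiding binding-interface residues) are supported as a
sliding-window counting filter over widths {20, 21, 22}; saturation
designs at physically proximal surface residues are supported by the
structure module's contact-map and RSASA filters rather than an automated
clustering step.

## Structural analysis

Distances are minimal side-chain heavy-atom distances from a single-model
PDB chain (hydrogens and backbone atoms N/CA/C/O/OXT excluded). Glycine
has no side-chain heavy atom: its Cα stands in, flagged in the log. An
explicit offset map translates 1-based sequence positions to PDB residue
numbers where numbering drifts. Contact maps use an 8 Å threshold,
diagonal excluded; "long-range" means backbone separation |i−j| > 5
residues (index difference, not inclusive counting).

The 12-feature coupling-strength model regresses |ΔΔΔG_f| on: backbone
distance, 3D side-chain distance, counts (0/1/2) of core (RSASA < 0.25),
binding-interface (ligand distance < 5 Å) and β-strand residues in the
pair, and seven bond counts consumed from a GetContacts-style file
(backbone–backbone, side-chain–backbone and side-chain–side-chain
H-bonds, π–cation, π-stacking, salt bridges, van der Waals; each listed
row counts once, repeated rows accumulate; unknown interaction labels are
ignored with a warning; RSASA, secondary structure and ligand distances
are consumed as annotation inputs, never recomputed). Features are
z-scored before ordinary least squares — significance ranking is
scale-free and the raw features mix units — and per-coefficient two-sided
t-test p-values are reported uncorrected. Evaluation on a held-out pair
set enforces train/test disjointness. Coupling-versus-distance statistics
report unweighted Spearman ρ overall and restricted (backbone-distal
pairs; contact-excluded pairs), plus binned means with 2.5–97.5 percentile
bands across the 10 Monte Carlo refits.

## Numerical and interface conventions

- Residue numbering is 1-based on the supplied wild-type sequence;
  structure mapping is explicit.
- Classification thresholds are strict: folded means p_f > 0.5, bound
  p_fb > 0.5; a variant exactly at 0.5 classifies negative.
  Wild-type indistinguishability is a two-sided z-test,
  z = (y_v − y_wt)/√(σ_v² + σ_wt²), p = 2Φ(−|z|) > 0.05.
- Variant tables: tab-separated, `variant` column as comma-separated
  substitution codes (e.g. `P11A,G18C`, empty/`WT` for wild type) or a
  full amino-acid sequence; rows missing fitness or with σ ≤ 0 for a
  declared phenotype are dropped with a logged count; a flag restricts to
  complete-replicate rows.
- Model files are JSON with coefficients keyed by substitution code and
  code pairs; coefficient exports are tab-separated with mean/sd/CI and
  the confident flag.
- All randomness flows from a single seed; every CLI stage derives its
  sub-seeds deterministically and writes a manifest (inputs, seed,
  version, wall time).

## Known limitations

- Energy models beyond pairwise couplings are out of scope; apparent
  higher-order epistasis will be absorbed into couplings and residuals.
- The Gaussian resampling form and heteroscedastic noise shape are
  assumptions, documented above.
- Coupling identifiability degrades for pairs rarely co-observed in the
  folding transition; the warm-start ridge and the L2 penalty keep such
  coefficients near zero rather than estimating them.
- The CLI's `simulate` names sites `A<i>V` as placeholders; real analyses
  supply a library definition with true wild-type sequences.
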