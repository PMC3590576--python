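# Methods

## Problem and model

`turnklr` predicts, per residue, whether a protein chain position lies in a
β-turn — the most common turn motif, covering roughly a quarter of residues
in globular proteins, with a biological run structure of at least four
adjacent turn residues.  The classifier is kernel logistic regression (KLR):
the posterior is modelled through a logit link,

    P(turn | x) = 1 / (1 + exp(−f(x))),    f(x) = wᵀφ(x) + b,

with φ the feature map of an RBF kernel K(x, x′) = exp(−γ‖x − x′‖²), and the
parameters estimated by minimising the penalized negative log likelihood

    J(w, b) = ½ wᵀw + (λ/2) Σᵢ log(1 + exp(−yᵢ f(xᵢ))),   yᵢ ∈ {±1}.

Note the convention: λ weights the **loss**, not the penalty, so λ plays the
role of 2C in the usual C-parameterisation of regularised logistic models.
The intercept b is unpenalised.  A sign ambiguity exists in some statements
of the logit model for this classifier (assigning exp(f)/(1+exp(f)) to the
negative class); we resolve it so that f is the log-odds of the positive
(turn) class, which is the only convention consistent with the loss
log(1 + exp(−y f)) above.

Exact KLR is cubic in the number of training residues (the dual expansion
f(x) = Σ αᵢ K(x, xᵢ) + b runs over all N points), which is impractical for
chain datasets with 10⁴–10⁵ residues.  The fixed-size variant (FS-KLR)
restricts the expansion to m ≪ N prototype vectors (PVs):

1. **Prototype selection.**  k-means with k = m (k-means++ initialisation,
   seeded, Lloyd iterations to relative inertia change < 1e−4) acts as the
   k-center surrogate: the Nyström approximation error is controlled by the
   quantization error of the landmark set, which k-means locally minimises.
   Each cluster contributes its medoid (the data row nearest the centroid),
   so PVs are always actual residue feature vectors.  Clusters smaller than
   `outlier_min_frac · n` (default 0.1%) are treated as outlier clusters and
   their slots refilled once from the largest clusters; this keeps rare
   noise points from occupying PV slots.  `m = n` short-circuits to "every
   point is a prototype", which is the regime used by the equivalence tests.
2. **Nyström map.**  The m×m prototype kernel matrix is eigendecomposed,
   K_m = U Λ Uᵀ; components with λᵢ ≤ eps·λ_max (eps = 1e−12, relative) are
   dropped, leaving p components.  The explicit map Φ = K_{n,m} U_p Λ_p^{−1/2}
   satisfies Φ Φᵀ = K_{n,m} K_m⁻¹ K_{m,n} (the Nyström approximation of the
   full kernel matrix, exact on the landmarks, exact everywhere at m = n with
   full rank).  The classical eigen-extension λ̃ᵢ = (n/m) λᵢ,
   ũᵢ = √(m/n) (1/λᵢ) K_{n,m} uᵢ is recovered exactly as the scaled column
   structure of the map: Φ eᵢ = √(λ̃ᵢ) ũᵢ.  This identity — not the
   (approximate) eigenvalue relation to the full kernel — is what the tests
   verify numerically.
3. **Primal fit.**  With features made explicit, the objective is an ordinary
   regularised logistic regression in p+1 dimensions, minimised by a
   trust-region Newton method: Steihaug truncated conjugate-gradient inner
   solves with forcing tolerance min(0.1, √(‖g‖/‖g₀‖)) — cheap approximate
   steps early, essentially full Newton directions near the optimum — and a
   trust radius that shrinks (×0.25) when the actual/predicted reduction
   ratio falls below 0.25 and doubles when it exceeds 0.75 with the step at
   the boundary.  Convergence: ‖g‖ ≤ tol·max(1, ‖g₀‖), tol = 1e−6 by
   default.  The intercept is an appended unregularised coordinate.

The exact dense dual solver (damped Newton/IRLS with step-halving, jitter
1e−10 on the normal-equations diagonal) is kept as a first-class estimator:
it fits small problems directly and serves as the independent correctness
oracle — at m = n the fixed-size model must reproduce its probabilities,
which the suite checks to 1e−3 (observed agreement is ~1e−8 at tight solver
tolerances).

## Features

Each residue is encoded with 216 features (window 7):

* **PSSM block (140).**  The position-specific scoring matrix (L×20 integer
  log-odds from iterative profile search) is squashed elementwise with the
  logistic 1/(1+e^−x) into [0,1] — a position-independent choice that cannot
  leak dataset-level statistics across folds, unlike min–max scaling — and
  the rows of a 7-residue window centred on the residue are concatenated.
  Off-chain window positions contribute zeros: under the scaled
  representation zero is the natural "no evidence" value.
* **Secondary-structure block (76).**  Four external 3-state predictors
  (order fixed by configuration: psipred, jnet, transec, proteus) each
  provide a per-residue state in {H, E, C} and a 0–9 confidence digit.
  Blocks: (a) 12 = per-source one-hot (H,E,C order) of the central residue;
  (b) 4 = per-source central confidence ÷ 10; (c) 48 = per-source, per-state
  S, indicators for the 3-residue patterns SSS, SSX, XSS, XSX over
  (pos−1, pos, pos+1), where X means "not S" — evaluated only when both
  neighbours exist, else all four are 0; (d) 12 = per-source, per-state
  count within the 7-residue window ÷ 7 (off-chain positions count no
  state).

**Feature selection** reduces 216 → 90 by a filter: each feature is
discretised into 10 equal-width bins on [0,1]; information gain
IG(f) = H(y) − H(y | bin(f)) and the χ² statistic of the bin×class table are
computed; features are ordered by the average of the two rank positions,
ties broken by lower feature index (the combination rule and discretisation
are our choices; 10 bins is coarse enough to be stable at fold sizes of a
few thousand residues and is configurable).  The selector is fitted on
training folds only by default; retained columns keep their original order
so matrices stay aligned with the encoder layout.

## Smoothing rules

Raw thresholded labels (t iff P(turn) ≥ 0.45) are rewritten by four ordered
passes: tnt→ttt, ntn→nnn, nttn→tttt, and ntttn→ttttn/ntttt where the flank
with the higher predicted probability flips (ties to the left).  Within a
pass all matches are found on the pass-input string and flipped
simultaneously — this avoids left-to-right cascade ambiguity (e.g. tntnt
flips both n's in pass 1).  Motifs must lie fully inside the chain; no
virtual residues are imagined beyond the termini, so truncated patterns at
chain ends do not fire.  Consequence (tested exhaustively to length 8):
after smoothing, every maximal turn run flanked by non-turns on both sides
has length ≥ 4; runs touching a chain end may remain shorter.  One caveat
discovered during verification: because the passes run once in order, a
rule-3 flip can re-create a tnt motif that rule 1 (already executed) would
have removed — e.g. tnnttn → tntttt.  The engine is therefore *not*
idempotent with respect to rules 1–2 in general; the brute-force equivalence
test pins the exact single-pass semantics instead.

## Evaluation protocol

Chains are assigned to seven folds by seeded shuffle + round-robin
(chain-level: all residues of a chain share a fold; folds keep the natural
class proportion, no stratification).  Per fold: selector and model are
fitted on the six training folds, the held-out chains are predicted,
optionally smoothed, and scored by pooling all their residues; the reported
figures are arithmetic means over the seven folds.  Measures: MCC, Q_total,
Q_predicted, Q_observed and specificity (percentages), with any 0/0 ratio
reported as an explicit undefined sentinel rather than 0, and ROC/AUC
computed on the raw probabilities (the rules are threshold-dependent, so a
threshold-free measure must precede them).  Hyperparameters (λ, γ) are tuned
once per dataset by grid search on mean CV MCC of the smoothed predictions
(ties: higher Q_total, then smaller γ, then larger λ); the prototype count m
is chosen by incremental search — evaluate m, m+step, … and stop after two
consecutive steps without an MCC improvement > 0.005.  A jackknife
(leave-one-chain-out) is available as k = number of chains but is not the
default given its cost.

## Synthetic study conditions

The generator emulates the statistical structure of the real inputs; its
defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| n_chains | 100 | chains per dataset |
| length_range | 40–100 | residues per chain (uniform) |
| turn_fraction | 0.25 | target turn prevalence |
| min_run | 4 | minimum turn-segment length |
| pssm_effect δ | 1.0 | log-odds mean shift on signal columns |
| n_signal_cols | 8 | informative PSSM columns |
| ss_accuracy | 0.85 | per-source P(report latent state) |
| confidence_fidelity | 0.8 | P(confidence digit reflects correctness) |

Labels come from a two-state renewal process (turn length = 4 + Geometric(½)
− 1, mean 5; gap length geometric with mean calibrated to the prevalence);
segments are never truncated into interior runs shorter than 4.  PSSM rows
are Normal(±δ/2, 1) on the signal columns and Normal(0, 1) elsewhere,
rounded to integers — real profiles carry integer log-odds, and rounding
makes the write→read fixture round trip exact.  Each residue has a latent
3-state structure (C for turns; H/E/C = 0.4/0.3/0.3 elsewhere); the four
sources report it independently with probability `ss_accuracy` (else one of
the other two states uniformly), with confidence digits centred at 7 when
correct and 3 when wrong (degraded to uniform with probability
1 − `confidence_fidelity`).

What the generator does **not** emulate: realistic amino-acid composition or
Dirichlet profile mixtures, correlation among the four predictors beyond the
shared latent state (real predictors share training data and are more
correlated), position-dependent profile structure, or turn-type substructure.
Synthetic separability is consequently higher than on real benchmark chains
— cross-validated MCC ≈ 0.88 here versus ≈ 0.5 for state-of-the-art methods
on real data — so passing the end-to-end checks demonstrates that the
pipeline recovers planted signal and that its components interlock
correctly, not that these figures transfer to real proteins.

## Numerical choices and defaults

* Window 7, 90 retained features, threshold 0.45, 7 folds — the method's
  standard settings.
* λ = 1, γ = 0.05, m = 60 are the package defaults for the synthetic
  conditions: γ is set by the ~1/d heuristic for 90 features on [0,1]
  (typical squared distances of order 10), λ = 1 leaves the fit mildly
  regularised under the loss-weighted parameterisation, and m = 60 sits on
  the plateau found by the prototype search on these data.  On any new
  dataset λ, γ should be re-tuned via the protocol module.
* Eigenvalue cutoff eps = 1e−12 (relative) defines the retained Nyström
  rank; duplicated PVs are handled by this cutoff rather than an error.
* IRLS: gradient tolerance 1e−8, jitter 1e−10, step-halving line search.
* TRON: tolerance 1e−6 (relative), ratio thresholds 0.25/0.75, radius
  factors 0.25/2, CG budget 10(p+1) iterations per subproblem.
* Degenerate inputs: single-class targets, non-PSD kernels, empty
  prototype sets and width mismatches raise immediately with context.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run entirely on synthetic data:
feature geometry on 8 chains (~250 residues); oracle equivalence on
50-point problems (5 seeds) and 20×5 trust-region problems; Nyström checks
on 40×3 and 10×3 sets; the rules engine exhaustively on all 510 t/n strings
of length ≤ 8; end-to-end CV on the default 100-chain conditions (~7,000
residues, m = 60); the prototype search on 50 chains (~2,500 residues,
m = 10…plateau).  These sizes were chosen so the whole battery completes in
well under a minute on one CPU while still exercising every code path at
meaningful scale.

## Known limitations

* Real benchmark evaluation (BT426/BT547/BT823) requires externally
  generated PSSMs and predictor outputs; the package reads them via the
  documented formats but does not produce them.
* The four-predictor block assumes exactly four sources with confidence
  digits; predictors that emit no confidence must be mapped onto 0–9 by the
  caller.
* Multiclass turn-type prediction is out of scope (the logistic machinery
  extends naturally, but nothing here implements it).
* The m-search trace is a CV estimate; on small datasets its plateau
  detection (two stalled steps at tol 0.005) can stop one step early under
  noise.
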