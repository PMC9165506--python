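# Methods

## The model family

All methods in `synpolar` address the same inference task: given a directed
connectome mask `C` over `N` neurons, assign each present connection a
polarity in {−1, +1}, using whatever side information is available.

**Connectome model (CM).** With presynaptic neurotransmitter expression
`X` (N × #NT), postsynaptic receptor expression `Y` (N × #R) and a curated
ternary wiring-rule matrix `O` (#NT × #R), the connection weight is
`B = Xb O Ybᵀ`, where `Xb`, `Yb` are expression thresholded to
presence/absence (`expressed ⇔ value > 0`).  `B[i,j]` therefore counts
positive minus negative *contributing rules* — pairs `(k, l)` with
`Xb[i,k] = Yb[j,l] = 1` and `O[k,l] ≠ 0` — and the inferred polarity is
`sign(B)`.  Binarization is deliberate: the curated inputs are
presence/absence calls, and the model counts rules rather than weighting
them by expression level.  Present pairs are classified from their
contributing rules: `known_±` (≥1 rule, all of one sign), `complex` (both
signs; resolved by the CM when the counts do not cancel), `unknown`
(expression on both sides but no applicable rule), `excluded` (presynaptic
neuron expresses no NT, or postsynaptic neuron no R).  A borderline case is
a postsynaptic neuron whose receptors participate only in rules for
transmitters its partner does not express: we classify such pairs `unknown`
(expression exists; no rule contributes), reserving `excluded` for absent
expression on either side.

**Spatial connectome model (SCM).** When rules are unknown but some
polarities are, the linear model `A = X O Yᵀ` is inverted for a minimal
real-valued rule matrix.  Row-major vectorization turns the model into
`a = (X ⊗ Y) o`; rows are kept only for connections of known polarity
(spatial truncation), giving `a′ = K′ o`, solved by ridge regression

    o~ = (K′ᵀ K′ + α I)⁻¹ K′ᵀ a′ .

Design rows are built pair by pair (one Kronecker product of an X row with
a Y row each), so the full N² × (#NT·#R) matrix is never materialized.  At
`α = 0` the solver switches to the Moore–Penrose pseudoinverse (minimum-norm
least squares) and warns when the normal matrix is singular; at `α → ∞` the
solution is proportional to `K′ᵀa′`.  The learned `O~` is pushed back
through the CM to score every connection.

**Generalized connectome model (GCM).** With only the signed network as
input, eliminating the expression matrices yields the self-consistent
equation `A = A W A` in a neuron-space rule matrix `W`.  Two solution paths
are provided, because they answer different questions:

* `gcm_fit` — the regression form.  The row for training pair `(i, j)` is
  `kron(A[i, :], A[:, j])`, truncated to known-polarity pairs and solved in
  the dual: `w = K′ᵀ (G + αI)⁻¹ a′`, where the Gram matrix factorizes as
  `⟨row(i,j), row(i′,j′)⟩ = ⟨A_i·, A_i′·⟩ · ⟨A_·j, A_·j′⟩` — no Kronecker
  row is ever materialized, and the solve is O(n_train²) memory instead of
  O(N⁴).  This is the form used for training-based prediction and
  cross-validation.
* `gcm_closed_form_rules` — the analytic regularization family
  `W(α) = (AᵀA + αI)⁻¹Aᵀ`.  Its limits are exactly the two behaviors of
  interest: `α → 0` gives `W = A†`, the overfitting solution with
  `A W A = A` (no new information), and `α → ∞` gives `W ∝ Aᵀ`, whose
  prediction `A AᵀA` is precisely the signed length-3 score.  The truncated
  regression form does **not** share the second limit — its `α → ∞`
  prediction is `S_out A S_in`, a length-5 path count whose ranking
  correlates with, but is not identical to, SL3 (Spearman ≈ 0.98 on random
  networks).  The limit-equivalence statement is therefore a property of the
  closed-form family, and that is where the package tests it.

The default GCM operating point is the heavily regularized limit,
implemented directly as the SL3 closed form (`gcm_sl3_limit`); finite-α
paths exist for regularization sweeps.

**Signed network predictors.** SL2 (`AᵀA + AAᵀ`, structural balance over
shared pre- and postsynaptic partners), SL3 (`A AᵀA`, forward–backward–
forward paths), and SPA (`k⁺ᵒᵘᵗᵢ k⁺ⁱⁿⱼ − k⁻ᵒᵘᵗᵢ k⁻ⁱⁿⱼ`, independent
preferential attachment in the positive and negative layers).  All use
integer arithmetic on ternary inputs so score thresholds are exact.  Edges
of unknown polarity are zeros in `A` and contribute to neither paths nor
degrees: the formulas are defined on signed degrees, and an unsigned edge
has none.

## Evaluation protocol

Predictions are ranked by |score| descending, ties broken by
(presynaptic label, postsynaptic label) so rankings are deterministic and
independent of input order; zero-score pairs are excluded (no sign to
predict).  Precision at rank is `p(r) = (1/r) Σ_{i≤r} 1[ŝ(i) = s(i)]`
against a reference signing; ranked pairs absent from the reference are
dropped before ranks are recounted.  The operating point for a target
precision is the *largest* rank `r` with `p(r) ≥ target` and the |score| at
that rank; if no rank qualifies the extraction returns nothing, with a
warning.  The analytic baseline for sign-matched random guessing with
positive fraction `p` is `p² + (1−p)²` (0.5392 at p = 0.64).

Two references are supported: the rule-resolved complex set (pairs the CM
resolves, disjoint from the SCM's training data) and held-out known labels.
k-fold cross-validation partitions the known pairs uniformly at random
(unstratified, seed recorded), removes the test fold from the input network,
trains on the rest, ranks the test pairs, and averages the per-rank
precision over folds, truncated to the shortest fold.  α selection scans a
logarithmic grid (default 10⁻³…10³, 121 points) and keeps the α maximizing
the rank at which the precision target is still met, ties toward the larger
α (stronger regularization at equal performance).

## Synthetic benchmark

The planted-rule generator draws independent Bernoulli presence/absence
expression (`p_express_nt = 0.5` per transmitter, `p_express_r = 0.1` per
receptor), a planted ternary rule matrix with a *fixed* composition — 32 of
126 slots nonzero (`rule_density = 0.25`), 19 positive / 13 negative
(`p_rule_positive = 0.6`), random placement — a Bernoulli(0.05) directed
mask without self-connections over 295 neurons, and the implied truth
`A = sign(Xb O Yb ᵀ)` on the mask.  Categories are derived with the same
classifier used on real data; zero-weight complex pairs remain unresolved in
the truth.  `hide_fraction` relabels a random share of known pairs as
unknown (their true signs remain available separately as prediction
targets) and `label_noise` flips observed signs, with categories updated to
match.

The defaults were calibrated once to the structure of the curated nematode
dataset this benchmark emulates — ~4300 present connections, ~1700 known
labels (the 1.5k–3k band), positive share 0.63–0.65 in the mean over seeds
(64% target) — and then frozen.  The rule composition is fixed rather than
Bernoulli because the positive-label share would otherwise fluctuate by ±10
percentage points across seeds with only ~32 rules.  Two real-data features
are deliberately *not* modeled: anatomically clustered expression (real
neurons express one transmitter class and correlated receptor sets, which
raises the known-label share to ~48% of present pairs versus ~40% here) and
multi-synapse connections.  Consequently, passing tests demonstrate correct
recovery of the model family's own generative structure, not performance on
biologically structured expression.

## Numerical choices and problem sizes

* Ridge solves use explicit normal equations (`numpy.linalg.solve`) — the
  feature dimension is at most #NT·#R = 126 (SCM) or n_train (GCM dual) —
  with a pseudoinverse branch at `α = 0`.  Oracle tests require agreement
  with brute-force solves (and scikit-learn's Ridge) to 1e−8.
* The GCM dual solve is preferred whenever n_train < N², i.e. always in
  practice; primal/dual equivalence is tested on ≤5-node networks.
* Degenerate inputs fail loudly: empty training sets, folds without
  scoreable predictions, rankings with no reference overlap, and
  out-of-range model parameters all raise `ValidationError`.
* Test and acceptance problem sizes: oracle checks run on 5–6 neuron
  instances; the limit-equivalence check uses 20 random 60-node networks at
  density 0.4 (dense enough that integer-score ties do not dominate rank
  correlations); recovery and robustness experiments use the full 295-neuron
  default model, with the subsampling experiment at 10 fractions × 10
  repetitions.  The whole suite runs in well under a minute.

## Known limitations

* The robustness experiment's "precision above the full-data cutoff" is
  only informative when the full-data precision curve is not saturated; on
  noiseless planted data the full-data fit is perfect, the 95% operating
  point is the last rank, and the quantity collapses to overall precision
  (~0.8 with 5% of labels, limited by rule slots unsupported in small
  samples).
* Learned rule matrices (`O~`, `W~`) are minimal in the squared-weight
  sense; nothing guarantees biological interpretability of individual
  entries.
* Polarity is modeled per connection, not per synapse; methods cannot add
  neurons, only densify signs among existing ones.
* Statistical significance via degree-preserving randomized ensembles is
  out of scope.
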