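# Methods

## Model

Two raters assess the same N subjects on an ordered q-level scale
(q = 2 is the dichotomous case; q = 5 covers scales like BI-RADS). The data
are a q × q contingency table n(i, j): subjects rated i by the row rater and
j by the column rater. All probabilities are plug-in frequencies — the joint
is p(i, j) = n(i, j)/N, the marginals are its row/column sums. No
small-sample bias correction (Miller–Madow or similar) is applied; the
indexes are descriptive statistics of the observed table.

Two agreement indexes are computed from the same table:

* **Cohen's kappa** κ = (p_o − p_e)/(1 − p_e), where p_o is the diagonal
  mass of the joint and p_e the diagonal mass of the product of marginals.
  κ ∈ [−1, 1] and uses only the diagonals of the observed and expected
  matrices.
* **Informational agreement** IA = MI(X, Y) / min{H(X), H(Y)}, with MI the
  mutual information of the joint and H the marginal Shannon entropies.
  Since 0 ≤ MI ≤ min{H(X), H(Y)}, IA ∈ [0, 1]; IA = 0 iff the raters are
  independent and IA = 1 when either rating determines the other. The
  normalisation by the *smaller* entropy removes the penalty MI would
  otherwise pay when one rater concentrates almost all subjects in one
  category (which drives its entropy, and hence MI, toward 0 even for a
  perfect rater pair).

The channel view factors the joint as p(x, y) = p_X(x) · Γ(y|x): Γ_q is the
column-stochastic transition matrix of the virtual agreement channel and
carries the rater-to-rater relationship, while the condition's prevalence
enters only through the input distribution P_X. MI — and therefore IA — is a
function of (P_X, Γ_q) alone, which supports prevalence sweeps at a fixed
channel and a generative simulator (`simulate_ratings`) used for recovery
tests and fixtures.

## Conventions and parameters

* **Log base.** Entropies and MI default to base q (so a uniform marginal
  has entropy exactly 1 and MI ≤ 1); base 2 (bits) or any base > 1 can be
  requested. IA is base-invariant, so the choice affects only the reported
  entropies/MI.
* **Zero cells.** The convention 0·log 0 = 0 applies: empty joint cells and
  unused categories contribute nothing. This equals the right-limit
  construction in which every zero count is replaced by ε → 0+;
  `ia_epsilon_probe` computes that ε-perturbed IA and the tests confirm
  agreement within 1e-6 at ε = 1e-9 on all zero-containing tables.
* **Degenerate tables.** A rater that uses a single category makes IA a 0/0
  form; both raters constant on the same category make κ one too. These are
  reported as *undefined* with an explicit diagnostic (exception in the
  low-level functions, independent validity flags in `agreement_report`) —
  never silently 0 or 1. The two indexes carry separate flags, so κ is still
  reported when only IA is degenerate and vice versa.
* **Orientation.** The conditioning variable X of the transition matrix is
  the *column* rater (categories across the top of the typeset table); a
  `transpose` flag swaps the roles. κ and IA are exactly transpose-invariant,
  so orientation matters only for Γ itself and for sensitivity/specificity,
  which read Γ₂(1,1) and Γ₂(2,2) with category 1 meaning "condition
  present".
* **Counts are integers.** Fractional weights are rejected; the indexes are
  defined on count tables.
* **Dichotomisation.** Threshold t (1 ≤ t ≤ q−1) puts categories 1..t in
  class 1 and the rest in class 2, summing the corresponding blocks. The
  threshold scan evaluates κ and IA at every t and reports each argmax; ties
  break toward the smallest t (the more conservative split) — a documented
  deterministic choice where no convention exists. Thresholds whose
  collapsed table leaves an index undefined are excluded from that argmax.
* **Kappa interpretation bands.** The conventional verbal scale is applied
  as a partition: [0, 0.2) none-to-slight, [0.2, 0.4) fair, [0.4, 0.6)
  moderate, [0.6, 0.8) substantial, [0.8, 1.0] almost-perfect; negative κ is
  annotated as below-chance. Published versions of this scale have
  overlapping bracket notation at 0.2; the half-open partition resolves it.
  No analogous scale is defined for IA, deliberately.
* **Rounding.** Golden-value comparisons round half away from zero
  (`round_half_away`), matching how published tables report 3- and
  2-decimal values; Python's built-in banker's rounding would disagree at
  exact midpoints.

## Numerical choices

* MI is computed as Σ p·(log p − log p_X − log p_Y) over nonzero cells, with
  the terms **summed in sorted order**. The sum then depends only on the
  multiset of terms, which makes MI exactly transpose-symmetric and exactly
  equal to the marginal entropy on diagonal joints (so IA = 1 exactly
  there). Entropy sums its terms the same way. Round-off can still make MI
  of a near-independent joint infinitesimally negative; it is clipped at 0,
  and IA is clipped at 1.
* Identity checks (chain rule MI = H(Y) − H(Y/X) both ways, the bound
  MI ≤ min entropy, the channel decomposition vs the direct joint MI) are
  asserted at 1e-10 absolute on 1000 random Dirichlet joints; probability
  normalisation is validated at 1e-12.
* `simulate_ratings` uses numpy's seeded PCG64 generator; the same seed
  yields the identical table on one platform/numpy version. Recovery of Γ by
  column normalisation of a simulated table converges at the binomial
  O(1/√n) rate; the tests check both the rate (median error shrinking ≥3×
  from n = 500 to n = 50 000) and an absolute criterion (max-abs error
  < 0.02 at n = 50 000 in ≥95% of 200 seeds).

## Bundled fixtures and what they show

The `fixtures` module carries ten small published tables: six 2 × 2
scenarios constructed to exhibit kappa's pathologies (nearly equal κ ≈ 0.5
for tables with 73% vs 99% raw agreement; the symmetric- and
asymmetric-unbalance paradoxes), the 5 × 5 ultrasound-vs-ABVS BI-RADS table
(N = 186) with its standard dichotomisation, and two classifier-correctness
agreement tables from the Tic-Tac-Toe benchmark where κ and IA order the
model pairs oppositely. Every fixture self-validates on load: κ and IA are
recomputed and compared with the bundled published values at their stated
precision, so transcription drift in the count matrices fails loudly.

Training of the classifier models behind the correctness tables (random
forest, kNN, SGD, naive Bayes under 10-fold cross-validation on UCI data)
is out of scope; the `comparison` module starts from correctness vectors or
the printed agreement matrices. Pearson/Spearman correlations go through
scipy.stats (average ranks on ties). Published rank correlations are only
asserted for the iris-benchmark row, whose index values are tie-free at the
reported 2-decimal precision — rows with rounding-induced ties would need
the unrounded values to reproduce their published ranks.

## What the simulator does and does not emulate

`simulate_ratings` draws i.i.d. subjects through the (P_X, Γ) channel: it
reproduces sampling noise in the counts but not reader drift over time,
correlated difficulty across subjects, or case-mix effects beyond the
prevalence encoded in P_X. Passing recovery tests therefore demonstrate
estimator consistency under the model, not robustness to those real-data
violations.

## Known limitations

* No confidence intervals or significance tests for κ or IA.
* No weighted kappa, multi-rater (Fleiss) kappa, or intraclass correlation.
* Single-threshold dichotomisation only; no k-way coarsening search.
* Plug-in MI is biased upward in small samples; with q ≥ 5 and N in the low
  hundreds the bias can be visible in the third decimal.
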