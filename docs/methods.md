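# Methods

## Pairing model

A β-pairing joins two equal-length stretches (k,l) and (m,n) of the same
sequence, placed on two different chains, in parallel or antiparallel
orientation. Its energy is the sum of residue-pair terms from an
orientation-specific 20×20 table: parallel pairs residue k+i with m+i,
antiparallel pairs k+i with n−i. Tables are dimensionless, lower = more
stabilizing, and are *not* symmetrized implicitly (an explicit
`symmetrized()` helper exists). Pairings are unordered, so they are stored
canonically with m ≥ k; the register shift S = m − k = n − l is then
non-negative, S = 0 being the in-register self-pairing characteristic of
amyloid. Intra-chain pairing and hetero-sequence pairing are out of scope.

Only pairings of at least `min_lp` residues are considered. `min_lp`
defaults to 4: one- or two-residue "pairings" are not β-structure, and the
hydrophobic stretches this scan is meant to pick out are typically 4–8
residues long. It is a keyword argument everywhere.

### Scan algorithm

The energy of a pairing is a contiguous-segment sum on a diagonal of the
pair-energy matrix e(seq[a], seq[b]):

- parallel, shift S: segment of the offset-S main diagonal
  d_S[j] = e(seq[j], seq[j+S]);
- antiparallel: segment of the anti-diagonal with constant index sum
  c = a + b, d_c[a] = e(seq[a], seq[c−a]), subject to k + l ≤ c (the
  canonical half; equality is the antiparallel self-pairing).

Per diagonal, the minimum-sum segment of length ≥ `min_lp` is found with
prefix sums and a running prefix maximum (segment sum = ps[e+1] − ps[k], so
minimizing it means maximizing ps over allowed starts), in linear time per
diagonal and O(N²) overall. A brute-force enumerator over all
(orientation, k, m ≥ k, lp) is retained purely as the test oracle; the
tests assert the two paths agree on hundreds of random sequences and
tables.

Note that for the antiparallel orientation a register shift does not index
a diagonal (a pairing with shift S lies on anti-diagonal c = 2k + S + lp − 1,
which depends on where it starts); the anti-diagonal is the only axis along
which the minimum-segment decomposition holds. Antiparallel candidates are
therefore de-duplicated per anti-diagonal, and their shift is computed from
the winning coordinates.

### Top-5 candidates and tie-breaks

A raw top-5 over all pairings would consist of one-residue trims of the
single best pairing, making the mean register shift degenerate. The
candidate set is instead one optimal pairing per (orientation, diagonal);
the k_best = 5 lowest-energy candidates are kept. E and lp come from the
single best candidate — which provably attains the global minimum of the
full enumeration, since every pairing lives on some diagonal — and S is
the mean shift over the kept candidates (over fewer if fewer exist).

Ties in energy resolve deterministically: longer pairing first, then
smaller shift, then smaller k, then parallel before antiparallel. Within a
diagonal: longer first, then leftmost. On an all-zero table the best
pairing is therefore the full-chain in-register parallel self-pairing.

## Features and composite scores

Per sequence: E/N (energy density, motivated by mean-field Flory–Huggins
reasoning — the single pairing's contribution to demixing of the whole
chain must be normalized by chain length), ln(S+1) and ln(lp) (entropy-like
transforms of counts of consecutive residues), the external pi–pi score P,
and the fractional position f = min((m+n)/2N, 1 − (m+n)/2N) of the best
stretch (1-based inclusive indices of the first stretch; f ∈ (0, ½] for
any stretch of ≥ 2 residues, f = ½ at the chain center). With 1-based
indices, mirroring a stretch changes f by exactly 1/N; the mirror-symmetry
test asserts equality to that tolerance. The six scores s0–s4 are exact
linear combinations (see README); s0/s00 carry a fixed unit coefficient on
E/N and no P, s1–s4 a fixed unit coefficient on P, which pins the overall
scale so fitted weights are comparable across folds.

P is always read from a user-supplied table and never imputed; sequences
the external scorer cannot handle (length < 140, the configurable default
mirroring the constraint of the published script, or letters outside the
20 standard amino acids) are excluded by the compatibility filter. A crude
`pi_contact_stub` (fraction of pi-capable residues) exists for synthetic
tests only and is clearly labeled as not being the published score.

The two-sample comparison of fractional-position sets reports
Z = (mean_A − mean_B)/√(sem_A² + sem_B²). Applied to the published means
0.232 ± 0.020 vs 0.158 ± 0.020 this standard formula gives Z ≈ 2.6, not
the printed 3.7; the original test statistic is unstated, so the standard
formula is implemented and the discrepancy noted here.

## Evaluation

Predicted positive ⇔ score ≥ threshold. AUC is the trapezoidal area under
the empirical ROC curve (equivalently the Mann–Whitney rank statistic with
half-credit for ties; the tests verify this equivalence on random
instances). MCC follows the standard product formula with the convention
that any zero denominator factor gives 0, consistent with both ROC
corners. max-MCC scans thresholds midway between consecutive distinct
scores plus ±∞ — this exhausts all distinct confusion tables — breaking
ties toward the highest threshold. MCC values are size-dependent:
`mcc_dilution_check` shows MCC → 0 as the negative set grows at fixed
TPR/FPR, so MCC is not comparable across differently sized negative sets.
One-way ANOVA (F, p, η² = SS_between/SS_total) compares AUC distributions
between scores; the KS normality check estimates mean and sd from the
sample (Lilliefors caveat: the p-value is anti-conservative) and is used
only to switch between mean and median in summaries (threshold p > 0.05).

## Training

The dataset (union of positive and negative sets) is randomly partitioned
into k near-equal folds, unstratified by default (an optional stratified
mode exists). Each fold serves once as test; the free weights of the
chosen score are fitted on the remaining folds by Nelder–Mead maximization
of the exact rank AUC. Defaults are k = 5 and M = 25 realisations (the
source material also mentions k = 4 in one place; k is a config knob).

Exact AUC is piecewise constant in the weights, so a single simplex run
can stall on a plateau. The fit therefore multi-starts: the zero vector
(which guarantees the fitted training AUC is at least that of the fixed
unit-coefficient term alone) plus `n_restarts` random starts scaled to
1/sd of each feature, each with a widened initial simplex. Optionally
(default on) the best point is polished against a smoothed surrogate —
mean sigmoid((s_pos − s_neg)/τ) over class pairs, τ = 5% of the current
score sd, pairs subsampled beyond `max_pairs` — and kept only if it
improves the exact AUC. The reported training AUC is always the exact rank
AUC. Tolerances: xatol 1e-3, fatol 1e-5, 400 iterations per start. All
randomness flows from `random_state` / config seeds via
`numpy.random.default_rng` and `SeedSequence.spawn`, making every run
bitwise reproducible.

Folds whose training or test part contains a single class are skipped with
a warning rather than aborting the run (relevant only for tiny synthetic
sets). Summaries report mean ± sd when the KS flag accepts normality of
the k×M fold values, median ± sd otherwise.

## Synthetic data

The generators define the study conditions for all tests:

- **Energy tables.** Style `hydrophobic` uses the Kyte–Doolittle hydropathy
  scale rescaled to h ∈ [0, 1] (V, I, L, F rank highest) and sets
  e(a,b) = 0.3 − h(a)h(b), antiparallel scaled by 0.9. The 0.3 offset makes
  typical polar pairs mildly destabilizing while hydrophobic pairs stay
  net-attractive; without it every entry is ≤ 0 and the minimum-sum segment
  degenerates to the whole chain, which no physical pairing potential does.
  Styles `zero` and `random` (normal entries, sd 0.5) support the oracle
  and tie-break tests.
- **Sequences.** Polar-enriched background composition (V/I/L/F/C/M kept
  rare), lengths uniform in 160–260 so regular records pass the length-140
  filter; positives carry one planted stretch of 4–8 residues drawn from
  {V,I,L,F} at a recorded position. Optional short and
  non-standard-letter records exercise the filter. The generator emulates
  the qualitative phenomenology of short hydrophobic β-prone stretches in
  polar contexts; it does not emulate real proteome composition, disorder
  content, or the published datasets' AUC levels, so passing tests
  demonstrate correctness and signal-detection behavior, not real-data
  performance.
- **Planted features.** N ~ U{140..1000}, E/N = −Gamma(4, 0.01)
  (mean −0.04), S ~ Exp(1.5), lp ~ U{4..12}, P ~ N(0, 2); planted weights
  (α*, β*, γ*) = (86, −0.56, −1.40), echoing the magnitudes reported for
  the trained s4; labels are Bernoulli(logistic((s4* − median)/T)) with
  T = 1 (the median centering keeps both classes populated — the raw
  logistic location would otherwise set the class balance arbitrarily).

## Verification design

Problem sizes were chosen so the full suite runs in under two minutes on
one CPU: oracle equivalences use 200 random instances each (sequences up
to 30 residues for the O(N⁴) enumerator); weight recovery uses 6
independent datasets of n = 2000, each cross-validated with k = 5, M = 1.
The recovery check compares the grand-mean recovered weights against the
planted values using the standard error across the 6 independent dataset
replicates. Folds within one dataset share most of their training samples,
so the naive sd/√(k·M) over fold values understates the simulation SE
badly and would flag even an unbiased estimator; the replicate-level SE is
the statistically meaningful one. The end-to-end check plants pairing
signal while P is pure noise, and requires the cross-validated s1/s4 to
beat the P-only baseline on the same test folds by more than 3 fold-level
SEs of the paired AUC difference.

## Known limitations

- The placeholder energy tables are hydrophobicity rank-one surrogates;
  real predictions require published β-pairing potentials.
- AUC maximization is a cube-root-rate estimator; recovered weights
  fluctuate more than likelihood-based fits would, and on small training
  sets plateaus can leave the optimizer short of the global maximum
  despite restarts.
- The fractional-position formula yields f = 0 only for a single-residue
  stretch at the C-terminus, which cannot arise for β-stretches
  (min_lp ≥ 2); no special-casing is applied.
- MCC comparisons across datasets of different size are meaningless by
  construction (see dilution check); summaries report it per dataset only.
- Temperature dependence of phase behavior, intrinsic-disorder prediction,
  and the internals of the pi–pi score are out of scope.
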