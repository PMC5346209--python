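# Methods

## The inference model

For a query compound *q* and a target *t* annotated with curated ligands
L(t), the evidence used is deliberately minimal: the most-similar ligand

    m = argmax_{l in L(t)} Tc(q, l)

where Tc is the Tanimoto coefficient |A∩B|/|A∪B| over fingerprint on-bits.
The pair (Tc_most, pKi_most) = (Tc(q, m), pKi(m)) is fed to a classifier
that returns p_a = p(active | Tc_most, pKi_most) and p_i = 1 − p_a. The
query is called active on the target when p_a > p_i; an exact tie is
called inactive (the conservative choice for a screening tool). The
working assumption is the similarity principle — structurally similar
compounds tend to share bioactivity — sharpened by the observation that
the *potency* of the nearest neighbor carries information that a bare
active/inactive annotation discards.

Two activity encodings are supported. *Explicit*: pKi_most enters as a
real number. *Implicit*: pKi_most is collapsed to the indicator
1[pKi_most ≥ threshold], with the binarization threshold deliberately
coupled to the activity-labeling threshold (5 or 6); decoupling them has
no clear use and would multiply the configuration space.

Backends: unpenalized logistic regression (the reference model; its
coefficients (a0, a1, a2) are exposed and interpretable against the
sigmoid above), Gaussian naive Bayes (class-conditional Gaussians per
feature — the features are continuous, and the implicit-mode indicator is
modeled as Gaussian too, for uniformity), and a 100-tree random forest
(default depth, probability = mean leaf class frequency, seeded). No
feature scaling is applied: both features are bounded/low-range and
scaling would destroy the correspondence between fitted and generative
coefficients. One **global** model is trained on rows pooled across all
targets rather than per-target models: the two-feature representation is
target-agnostic by construction, pooling gives the fit thousands of rows
instead of dozens, and a single model can then be applied to targets
never seen in training (as a panel scan requires).

## Curation of raw Ki tables

Raw bioactivity exports are reduced to one consensus pKi per
(target, ligand) pair:

1. **Quality filter** — keep records with assay type "Ki", confidence
   score 9 (direct binding), a positive value, recognizable units
   (pM/nM/uM/M, case-insensitive, µ≡u), a reference id, and relation
   `=`. Censored (`>`, `<`), approximate (`~`) and missing relations are
   ambiguous about the actual value and are dropped. The filter never
   raises; every rejected record is tallied per rule in a
   machine-readable audit log.
2. **Within one reference** — the smallest Ki survives, reflecting
   experimental optimization and ambiguous stereoisomer annotations.
3. **Across references** — the per-reference minima are averaged on the
   Ki (concentration) scale, then converted to pKi = −log10(Ki in mol/L).
   Averaging concentrations is the literal reading of "mean Ki"; a
   `scale="pki"` switch provides geometric-mean averaging for users who
   prefer log-scale pooling (off by default).
4. **Panel size filter** — targets with fewer than 10 or more than
   10,000 curated ligands are removed (counted after deduplication,
   before labeling). Too few ligands make the neighbor statistic
   meaningless; pathologically large sets indicate promiscuous assays.

Activity labels are 1[pKi ≥ threshold] with threshold 5 (10 µM) or
6 (1 µM).

## Validation protocols

**Sevenfold cross-validation.** Within each target, ligands are randomly
partitioned into 7 disjoint folds (~14.3% each); fold i is the test set
and the remainder the training set, so the union of test sets covers the
panel exactly once. The often-quoted alternative — seven independent 15%
draws — cannot guarantee full coverage of the data; the disjoint
partition honors that intent while staying deterministic, and a
`resample15` mode reproduces the literal independent draws when wanted.
Training features are built by leave-one-out neighbor search inside each
target's training ligands; test ligands are matched against training
ligands only. Metrics are pooled confusion counts over all targets
(accuracy = (TP+TN)/total; MCC, with the 0/0 convention MCC = 0), and
fold summaries are reported as mean ± standard deviation (labeled as
such) across the 7 folds. A per-target breakdown can be recovered from
the per-prediction trace that every run emits.

**Temporal validation.** The full earlier-release panel trains the
model; the test set is exactly the (target, ligand) pairs present in the
later release but not the earlier one, restricted to targets present in
both. This mimics prospective prediction and avoids the optimism of
random splits.

**Trade-off curves.** From a per-prediction trace, f_TP(k) and f_FP(k)
are the fractions of true/false positives retained when predictions are
filtered by Tc_most ≥ k (grid 0–1, step 0.05) or p_value ≤ t (grid
0.5→0, step 0.025); the difference f_TP − f_FP is the trade-off index
and its argmax the recommended operating point. When a trace contains no
TP (or FP), the corresponding fraction is reported as NaN rather than 0.

## Multi-target scanning and FDR control

Scanning one query against a panel yields one p-value per target
(p_i from the explicit-mode logistic model is the intended
configuration; other backends can be scanned, and outputs are labeled
with the model configuration). With m targets tested simultaneously,
raw p-values are corrected by (a) Benjamini–Hochberg step-up adjustment,
p̃(i) = min_{j≥i} min(1, p(j)·m/j) over the ascending order, and
(b) Storey q-values, q = π̂0 · p̃ with the fixed-λ estimator
π̂0 = #{p > λ}/(m(1−λ)) at λ = 0.5, clipped to (0, 1]; if every p-value
falls below λ the estimate degenerates and falls back to π̂0 = 1 (plain
BH) with a warning. Hits are ranked by (adjusted p ascending, Tc_most
descending, target id) — a total, deterministic order. No Tc floor is
applied by default (the p-value, not the similarity, is the filtering
instrument); a `min_tc` option exists for users who want one.

These p-values are model probabilities, not frequentist tail
probabilities from a calibrated null; the FDR machinery is used as a
pragmatic guard against multiplicity, and the null-panel simulation
(below) checks that it behaves conservatively when there is nothing to
find.

## The synthetic data generator

The generator emulates a curated bioactivity world in which every
quantity the pipeline estimates has a known planted value.

*Structures.* Each target owns a trisubstituted-benzene core defined by
two chains (heteroatom prefix O/N/C, lengths 1–4) — up to 144 distinct
cores. A target's ligands are grouped into slots; each slot attaches one
substituent family from a 12-entry catalogue (ether, amines, phenyl,
amide, ester, thioether, piperazine, cyclohexyl, aryl ether, pyridyl,
glycolamide) with an alkyl tail. A slot contributes a *reference* ligand
(tail length 2) under two ligand ids — a deliberate structural
duplicate — and a *probe* whose tail is extended by 1–2 carbons. The
catalogue is diverse enough that, by measured Morgan Tanimoto, a probe's
nearest neighbor within its target is always its own slot's reference
(verified by a generator test), and a reference's nearest neighbor is
its duplicate. The duplication makes the nearest neighbor robust to fold
splitting: the probability that a random 7-fold partition strands a
probe without either reference copy is below 2%.

*Activity.* Reference pKi values are drawn from a well-separated
potent/weak mixture, 0.6·N(7.5, 0.4) + 0.4·N(3.5, 0.4) — mirroring the
potency skew of curated Ki panels, where most published ligands are
sub-micromolar, while keeping the region around the labeling threshold
sparse so that reference labels are consistent with the planted law
(below). Each probe's truth is a Bernoulli draw with

    P(active) = sigmoid(a0 + a1·Tc_ref + a2·pKi_ref),   (a0,a1,a2) = (−10, 6, 1)

where Tc_ref is the probe's *realized* best similarity to its target's
references and pKi_ref that reference's potency — exactly the feature
pair nearest-neighbor search will present to the classifier (>99% of
cross-validation predictions see the planted features). The probe's own
pKi is then placed above or below the labeling threshold (threshold ±
(0.3 + |N(0, 0.8)|)) so the curation-derived label equals the drawn
truth. Setting a1 = a2 = 0 produces the *null* panel: every probe truth
is an independent coin flip and reference potencies are threshold-coded
coin flips too, leaving no structure–activity signal for a model to
exploit beyond the unavoidable self-identification of duplicated
references.

*Analytic yardstick.* The generator reports the expected accuracy of
the Bayes-optimal classifier on the realized panel: Bernoulli rows
contribute max(p, 1−p) (label noise no classifier can beat) and
deterministic rows contribute 1, with a binomial standard error from the
planted probabilities. The end-to-end benchmark requires the
cross-validated accuracy to match this value within 4 standard errors
plus a 0.02 allowance — fixed in advance — for finite-sample fitting and
for the logistic model's approximation of the deterministic reference
component.

*Raw tables.* A panel can be wrapped into raw records with planted
pathologies: same-reference duplicates with a larger Ki (the minimum
rule must discard them), cross-reference duplicates whose per-reference
minima average to a value the generator records in its answer key,
random unit choices (pM–M), and "ineffective" records cycling through
every drop rule. Two-release fixtures assign probes a synthetic
deposition date, holding a fraction (plus one whole extra target, which
a correct temporal comparison must ignore) out of the early release.

*What the generator does not emulate.* Real chemical space is vastly
more diverse than a substituted-benzene family; real similarity
distributions are long-tailed rather than clustered; real false
positives concentrate at high similarity with weak potency, whereas the
planted panel's label noise sits at moderate similarity. Consequently,
passing the synthetic benchmark demonstrates that the pipeline's
machinery is correct and recovers a plantable signal — it does not
certify the head-line accuracies achievable on real curated panels, and
on the synthetic panel a Tc threshold happens to filter false positives
more sharply at its optimum than it can on real data (the p ≤ 0.1
retention property f_TP > f_FP holds either way).

## Numerical choices and conventions

- Morgan fingerprints: radius 2, folded to 2048 bits, no chirality or
  feature invariants (the community default; exposed in code). FP2: Open
  Babel's 1024-bit path fingerprint via the `obabel` CLI; the hex dump is
  decoded with a fixed bit convention (Tanimoto depends only on
  intersection/union cardinalities, so any consistent decoding is
  equivalent, and the decoded values are cross-checked against obabel's
  own Tanimoto output in the tests). Both schemes reduce to on-bit sets
  so one Tanimoto code path serves both.
- Tanimoto of two all-zero fingerprints is defined as 0 (featureless
  molecules are treated as dissimilar, not identical).
- Nearest-neighbor ties are broken toward higher pKi, then
  lexicographically smaller ligand id, making the result independent of
  ligand list order.
- BH adjustment clamps the adjusted value to be ≥ the raw p-value,
  guarding the one-ulp rounding of p·m/m.
- The logistic backend is fitted unpenalized (lbfgs, tol 1e−10) so its
  coefficients estimate the generative ones; p_i is computed as 1 − p_a,
  making complementarity exact.
- Models persist as versioned JSON text: naive Bayes and logistic store
  their parameters; random forests store each tree's node arrays, which
  a small pure-Python traversal re-evaluates on load (round-trip
  verified against scikit-learn's probabilities at 1e−12).
- All randomness (splits, simulations, forests) flows from explicit
  integer seeds; reruns are bit-identical.

## Problem sizes

The shipped benchmarks use a 50-target panel with 36 ligands per target
(1,800 pairs), 10,000 feature rows for coefficient recovery, and 200
queries × 50 targets (10,000 tests) for the null-FDR check. These sizes
put the binomial standard error of the benchmark accuracy below 0.005
while keeping a full validation run in the seconds-to-a-minute range on
a single CPU; all of them are configuration parameters, not constants.

## Known limitations

- The approach is blind to targets whose nearest annotated ligand is
  structurally unrelated to the query: with low Tc_most everywhere, all
  probabilities shrink toward the base rate, which is the honest answer
  but not a useful one for novel chemotypes.
- p_i is a model probability; its use as a p-value is heuristic, and the
  FDR guarantees are only as good as the model's calibration.
- Curated panels are heavily skewed toward actives (publication bias);
  MCC is reported alongside accuracy because accuracy alone flatters
  such skew.
- The Gaussian assumption of the naive Bayes backend is a convenience,
  not a fact about the features; it is included for comparison, and the
  logistic model is the reference configuration.
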