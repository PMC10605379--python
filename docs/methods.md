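# Methods

## Fusion model

`lesionfuse` treats base classifiers as opaque producers of per-class
score rows and combines them by weighted summation, never by
retraining. Two architectures are implemented over a fixed, ordered
class catalog (default `mel, nv, bcc, bkl`).

**Direct fusion.** For model m and class c, the fused total is
`S(c) = Σ_m p_m(c)·w_{m,c}` and the prediction is the argmax. Weights
live in [0, 1] and are keyed by *(model id, class name)* rather than by
position: class numbering conventions vary between sources, and
name-keying removes any chance of a silently transposed weight matrix.
Fused totals are deliberately not normalised by the weight sums — the
argmax is invariant to a global rescaling, and keeping the raw weighted
vote mass makes the per-model breakdown table additive and auditable.

**One-vs-one fusion.** Each base model contributes C(K,2) pairwise
branches. A branch over pair (a, b) emits a two-sided decision summing
to one; class c's total collects, across models, decision mass for c
from the K−1 branches containing c, each multiplied by that branch's
weight for c. Classes outside a branch's pair receive nothing from it.
With unit weights this is exactly unweighted pairwise vote counting;
the weighted form is the default because branch quality differs
markedly between class pairs and the weights let reliable branches
dominate.

**Decisions: soft vs hard.** Base-model outputs are soft score rows by
default (matching softmax outputs); a hard mode one-hots every row (or
branch decision) before fusing. Soft mode subsumes hard mode — a
one-hot table fuses identically in both — so soft is the default.

**Tie-breaking.** When fused totals tie within 1e-12, the earliest
class in catalog order wins and the result carries a tie flag. The
default catalog puts melanoma first, so exact ties resolve toward the
most dangerous diagnosis. The tolerance is far below any plausible
score resolution; it exists to make floating-point ties deterministic,
not to absorb modelling noise. Soft score rows must sum to one within
1e-9 — loose enough for accumulated float error in 4-16 columns, tight
enough to catch a genuinely unnormalised row.

## Weight estimation

Direct-fusion weights are the per-class F1 scores of each model's
validation confusion matrix. F1 balances the two failure modes that
matter here (missed lesions and false alarms) in a single [0, 1]
number, and a model that is strong on `nv` but weak on `bkl` gets
exactly that profile of voting power. Branch weights are each pair
member's F1 in the branch's 2×2 validation table, restricted to
validation samples whose true class belongs to the pair; `accuracy`
(both sides share the branch accuracy) and `unit` policies are
selectable. A branch whose validation slice contains only one of its
two classes cannot be scored and falls back to unit weights with a
warning rather than an error — the fusion can still run, just
unweighted on that branch.

Zero-division convention: any indicator with a zero denominator is 0,
including F1 for a class with no true positives. An entirely empty
confusion matrix is a structural error, not a 0 or 1 — scoring nothing
is a caller bug.

## Dataset preparation

The preparation pipeline mirrors how multi-source dermoscopy archives
are cleaned: (1) every lesion with more than one image is removed
*entirely*, because keeping any image of a duplicated lesion risks
near-duplicate leakage across splits; (2) classes outside the study
catalog are dropped; (3) the dominant `nv` class is thinned by a seeded
random 20% (`round(0.20·n)` exactly; the fraction is configurable);
(4) records are split 75/15/10. Splitting is stratified by class —
balanced per-class handling downstream (augmentation targets,
per-class F1 weights) presumes each split sees every class at its
overall rate. Partition sizes use largest-remainder rounding; remainder
ties break toward the partition currently lagging its global quota,
then toward train before validation before test, so per-class
roundings cannot all drift the same way and 1,000 records land exactly
on 750/150/100.

Augmentation planning assigns each original image an integer number of
extra copies such that the class total hits its target exactly and
multiplicities within a class differ by at most one. The transforms
themselves (90° rotations, flips) are a thin utility for toy images
only.

## Synthetic generators

**Prediction simulator.** A classifier profile is a row-stochastic
target confusion plus a sharpness. Sampling is two-stage: the predicted
class is drawn from the profile row of the sample's true class, then a
soft row is drawn from a Dirichlet with concentration `sharpness` on
the drawn class and 1 elsewhere (if the Dirichlet mode strays, the two
entries are swapped so the hardened argmax always equals the drawn
class). Sharpness defaults to 12, giving confident rows (winning mass
≈ 0.8) typical of trained softmax classifiers. The empirical
row-normalised confusion is then binomial around the target, which the
tests verify at 3 standard errors.

**Branch simulator.** Pairwise decisions derive from the same profile
by conditioning the relevant confusion row on the branch's two classes
(probability of siding with a is `row[a]/(row[a]+row[b])`, 0.5 when
both vanish); the winning side's score is drawn in (0.5, 1]. One
generator therefore grounds both ensemble modes consistently, and
conditioning naturally reproduces the observation that binary branches
are more accurate than the 4-class models they come from.

**Complementary-error scenario.** Three profiles share a strong
per-class accuracy of 0.94 except each is weak (0.70, the designed
floor) on one distinct class, with missed mass spread evenly. Because
no class is weak for two classifiers, fusion can outvote every
individual mistake; the tests check that both fused accuracies reach at
least the best individual accuracy on 2,000 test samples (500 per
class), with weights estimated on a separate 250-per-class validation
draw. This is a designed-scenario property — fusion is *not* claimed to
beat its members on arbitrary inputs.

**Toy images.** Each image is one elliptical blob on a light
skin-toned background; class identity is encoded by base hue, axis
ratio and border-roughness amplitude, and a configurable fraction of
images get dark random-walk strokes mimicking hair artifacts. The
images are deliberately not photorealistic: they only need enough
separable structure for a tiny logistic-regression classifier (three
feature variants — color moments, hue histogram, shape descriptors —
chosen so variants err on different samples) to train in seconds and
for every pipeline stage to be exercised honestly. Passing toy-scale
tests demonstrates the *fusion machinery* end to end; it says nothing
about performance on real dermoscopy data, where base models, not the
fusion arithmetic, dominate.

## Problem sizes

The default study sizes are chosen as the smallest that make each
claim statistically meaningful: exhaustive enumeration (64 vote
configurations; 2⁶ branch outcomes) where the space is finite; 10,000
samples per class for confusion recovery (binomial SE ≈ 0.002-0.005
per entry); 2,000 test samples for the ensemble-gain scenario; 160 toy
images (40 per class at 40 px, split 120/24/16) for the train-and-fuse
run with its 3 multi-class variants and 18 binary branches.

## Known limitations

- Base-model quality is out of scope: the package fuses scores, it
  does not train CNNs, and nothing here reproduces archive-scale
  accuracy figures.
- The toy-image domain is linearly separable by design; ensemble gains
  there are modest because individual variants are already near
  ceiling.
- Branch weights estimated from very small validation slices are
  noisy; the unit-weight policy is the safer choice below a few dozen
  validation samples per pair.
- The one-vs-one simulator conditions a single 4-class confusion on
  each pair; real pairwise-trained networks can have error structure
  not expressible that way.
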