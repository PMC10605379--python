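# lesionfuse

Weighted decision-fusion ensembles for multi-class skin-lesion
classification.

Dermoscopy classifiers for lesion classes such as melanoma (`mel`),
melanocytic nevus (`nv`), basal cell carcinoma (`bcc`) and benign
keratosis (`bkl`) are usually trained as independent networks whose
individual error patterns differ. `lesionfuse` combines any such set of
opaque base classifiers into one prediction using two fusion
architectures, together with the confusion-matrix metrics, the
archive-preparation pipeline, and synthetic generators that make the
whole stack testable at desk scale — no image archives or GPU training
required. It is aimed at people studying or prototyping decision-fusion
strategies for medical image classification.

## The two fusion rules

**Direct weighted score fusion.** Each of M base models emits a
per-class score row p_m (softmax-like, summing to 1). With per-model,
per-class weights w_{m,c}, the fused score of class c is

    S(c) = Σ_m  p_m(c) · w_{m,c},        ŷ = argmax_c S(c)

The weights default to each model's per-class F1 measured on a
validation split, so a model votes on a class in proportion to how well
it separated that class on held-out data.

**One-vs-one decomposition fusion.** Each base model is replaced by
C(K,2) pairwise binary models (6 for K = 4: `mel_nv`, `mel_bcc`,
`mel_bkl`, `nv_bcc`, `nv_bkl`, `bcc_bkl`; 18 binary models for three
base networks). For a sample, every branch emits a two-sided decision
d; the total for class c sums, over all models and over the K−1
branches whose pair contains c, the decision mass for c times that
branch's weight for c:

    S(c) = Σ_m  Σ_{b ∋ c}  d_{m,b}(c) · w_{m,b,c},        ŷ = argmax_c S(c)

Branch weights default to each side's F1 in the branch's 2×2
validation confusion matrix; with unit weights the rule reduces to
plain vote counting over all branches. Ties always resolve to the
earliest class in catalog order (melanoma first by default, so ties
favor the clinically dangerous call), and fused totals are never
normalised by weight sums.

Metrics follow the standard binary contingency definitions (TPR, TNR,
PPV, ACC, F1, Jaccard) and the multiclass per-class F1

    F1_j = 2·TP_j / (2·TP_j + Σ FP_j + Σ FN_j)

computed from the K×K confusion matrix (rows = true, columns =
predicted).

## Worked example

Fusing one sample's soft scores from three base models under published
per-class F1 weights:

```python
import lesionfuse as lf

P = lf.PredictionMatrix.from_dict({
    "mobilenet":    {"mel": 0.70, "nv": 0.10, "bcc": 0.10, "bkl": 0.10},
    "densenet":     {"mel": 0.05, "nv": 0.05, "bcc": 0.10, "bkl": 0.80},
    "efficientnet": {"mel": 0.60, "nv": 0.20, "bcc": 0.10, "bkl": 0.10},
})
W = lf.WeightMatrix.from_dict({
    "mobilenet":    {"mel": 0.82, "nv": 0.90, "bcc": 0.85, "bkl": 0.67},
    "densenet":     {"mel": 0.85, "nv": 0.91, "bcc": 0.89, "bkl": 0.74},
    "efficientnet": {"mel": 0.85, "nv": 0.92, "bcc": 0.86, "bkl": 0.63},
})
res = lf.fuse_model1(P, W)
print(res.predicted)           # mel
print(res.scores.scores)       # {'mel': 1.1265, 'nv': 0.3195, 'bcc': 0.26, 'bkl': 0.722}
print(res.breakdown.round(4))
```

prints

```
mel
{'mel': 1.1265, 'nv': 0.3195, 'bcc': 0.26, 'bkl': 0.722}
                 mel      nv    bcc    bkl
mobilenet     0.5740  0.0900  0.085  0.067
densenet      0.0425  0.0455  0.089  0.592
efficientnet  0.5100  0.1840  0.086  0.063
```

Two models lean melanoma, one leans benign keratosis; the F1-weighted
totals give melanoma 1.1265 against bkl's 0.7220, so the fused call is
`mel`. The breakdown table shows each model's weighted contribution per
class, making every prediction auditable term by term.

## Command line

```
lesionfuse simulate --out bundle --seed 3          # seeded fixture bundle
lesionfuse fuse --predictions bundle/predictions_test.csv \
    --validation bundle/predictions_validation.csv \
    --mode model1 --out fused                      # decisions + confusion + metrics
lesionfuse fuse --predictions bundle/binary_test.csv \
    --validation bundle/binary_validation.csv \
    --mode model2 --out fused2
lesionfuse prepare --metadata meta.csv --out prepared.csv --seed 4
lesionfuse metrics --decisions fused/decisions.csv
```

`prepare` applies the archive rules: lesions photographed more than
once are removed entirely, out-of-scope classes are dropped, ~20% of
the majority `nv` class is randomly discarded, and records are split
75/15/10 (train/validation/test) stratified by class. `simulate` writes
score tables for three emulated classifiers with complementary error
structure; `fuse` estimates weights from a validation table and fuses a
test table in either mode.

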