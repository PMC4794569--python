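# hep2cad

A workbench for computer-aided reading of HEp-2 indirect-immunofluorescence
(IIF) images — the standard assay for detecting antinuclear antibodies (ANA)
in patient serum. It is aimed at people building or evaluating CAD
("second reader") systems for autoimmune serology: it provides a synthetic,
fully ground-truthed well simulator, classical cell segmentation, a
108-value per-cell descriptor, a multi-classifier fusion pipeline producing
intensity and staining-pattern calls per image and per well, and the
agreement statistics used to compare human readers with a CAD.

## The problem and the model

An IIF well is read in three steps, each a pattern-recognition problem:

1. **Fluorescence intensity** — the well is triaged into *negative*,
   *intermediate* or *positive*. Only non-negative wells proceed to
   pattern analysis. Here this is a cascade of two margin classifiers
   (negative vs rest, then intermediate vs positive) on per-image summary
   features.
2. **Mitosis recognition** — at least one mitotic cell certifies correct
   well preparation; a non-negative well with no detected mitosis is
   *discarded*. Mitoses come in two phenotypes: *negative mitosis*
   (fluorescent cell body, dark collapsed-chromosome mass) and *positive
   mitosis* (the opposite). Two small feed-forward networks score each
   segmented cell for the two phenotypes.
3. **Staining pattern** — non-negative interphase nuclei show one of seven
   patterns (homogeneous, fine speckled, coarse speckled, nucleolar,
   centromere, nuclear dots, nuclear pore complex), indicative of
   autoantibody specificity. Seven one-vs-all classifiers each emit a
   membership score, and a K-nearest-neighbour classifier fuses the nine
   per-cell scores (7 pattern + 2 mitosis) into the final pattern call.
   Image calls are majorities over cells, well calls majorities over the
   well's three images.

Each segmented cell is described by 27 features — 9 intensity statistics,
8 geometry measures, 8 shape/morphology measures, 2 gradient-histogram
entropies — computed at four gray-level quantizations (256, 128, 64, 32),
for a 4 × 27 = 108-value descriptor.

Performance is reported with the multi-class reader-study metrics: the
per-class correct classification rate CCR_k = T_k / N_k, the class-size
weighted Accuracy = Σ_k CCR_k·N_k / Σ_k N_k (≡ trace/N), the Mean Class
Accuracy MAC = (1/k) Σ_k CCR_k, Cohen's κ = (p_o − p_e)/(1 − p_e) for
two-reader agreement, Pearson's χ² for independence, and McNemar's test
(exact binomial or continuity-corrected) for paired proportions.

Because clinical IIF image sets are not redistributable, the package ships
a synthetic well generator that emulates the acquisition conventions of
real ANA reading (24-bit RGB frames, FITC signal in the green channel, one
image per negative well and three per positive well, ~10% negative sera)
with exact per-cell ground truth, so the entire pipeline is testable
end to end.

## Worked example

```bash
python examples/train_and_classify.py
```

trains every stage on a 3-wells-per-pattern synthetic dataset (seed 7) and
classifies a disjoint 2-wells-per-pattern set (seed 8), printing:

```
cross-validated MAC per pattern model:
  homogeneous            1.000
  fine_speckled          0.961
  coarse_speckled        0.916
  nucleolar              0.895
  centromere             0.895
  nuclear_dots           0.866
  nuclear_pore_complex   1.000
fusion K = 7
intensity correct: 14/16 wells
pattern correct:   13/14 positive wells
discarded (no mitosis detected): 2
```

The per-model numbers are cross-validated mean class accuracies of the
seven one-vs-all pattern classifiers; `fusion K` is the neighbourhood size
the fusion stage selected by cross-validation; the last lines are held-out
well-level results, including two wells discarded because no mitotic cell
was detected in any of their images.

`examples/reader_agreement.py` analyzes the bundled 589-well two-senior-
reader concordance table and prints its observed agreement (71%) and
Cohen's kappa (0.64), plus a simulated reader + CAD second-reader
workflow. The other examples cover dataset simulation and feature
extraction. A thin CLI mirrors these workflows:

```bash
hep2cad simulate --out ds --wells-per-class 5 --seed 1
hep2cad train    --dataset ds --out bundle --seed 1
hep2cad classify --dataset ds --bundle bundle --out reports
hep2cad agreement --fixture
```

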