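# tfdiff

**Which sequence features explain why a transcription factor binds here in one
cell type (or treatment, or paralog) and there in another?**

`tfdiff` compares two sets of ChIP-seq peaks for the same TF (or two
paralogous TFs) and learns a sparse, fully interpretable model of their
differences from sequence alone. It is aimed at regulatory genomicists who
have two peak files, a genome FASTA and JASPAR-format motifs, and want a
ranked, positioned list of the sequence features that separate the two
binding repertoires — not a black-box classifier.

## The model

Peak sequences are aligned on their most likely binding site (best log-odds
hit of the TF's motif within 500 bp of the peak summit) and trimmed to 1 kb.
Three feature classes are then extracted, and a penalized logistic model
predicts the class of each sequence *s*:

```
P(class 1 | s) = sigmoid( a·DM(s) + Σᵢ bᵢ·NEᵢ(s) + Σⱼ cⱼ·CFⱼ(s) )
```

- **DM** — a *discriminative* position weight matrix over the aligned core
  sites (plus 4 flanking bases on each side). Each site is one-hot encoded
  and a logistic model with one coefficient per (position, nucleotide) cell
  is fitted with an L1 penalty: `DM(s) = Σₖ Σⱼ a_{k,j} s_{k,j}` is literally
  a PWM score, and because the penalized likelihood is convex the fitted
  matrix is the *optimal* discriminative PWM for aligned fixed-length sites.
  Signed weights are rendered as "mirror logos" (positive = class 1).
- **NEᵢ** — nucleotidic environment: the frequency of a short k-mer (2–4 bp)
  in a data-chosen region of consecutive bins (7 bins over the 1 kb window),
  found by exhaustive region search plus greedy k-mer extension. The core
  site is masked first so no core information leaks in.
- **CFⱼ** — co-factors: for every motif in a PWM library, the best log-odds
  score inside a data-chosen region (13 bins; all 91 contiguous regions
  scored exactly via a children-max lattice).

The LASSO penalty zeroes most coefficients; λ is set by 10-fold
cross-validation in which the (k-mer, region) and (PWM, region) *selection*
is re-run inside every fold, so held-fold deviance is free of selection
optimism. Accuracy is the AUROC on a held-out 30% of sequences, and the
contribution of each feature class is the test-AUROC drop when its
coefficient group is zeroed (no retraining). A built-in generator produces
synthetic two-class datasets with planted core-position, k-mer-region and
co-factor signals, so every claim the package makes can be checked against
a known ground truth.

## Worked example

```python
from tfdiff import DifferentialBindingModel
from tfdiff.synth import generate_dataset, recovery_config, toy_library

library = toy_library(10)                      # 10 synthetic co-factor motifs
cfg = recovery_config(n_per_class=300, seed=7, library=library)
data = generate_dataset(cfg)                   # two classes of raw peak windows

model = DifferentialBindingModel(data.windows_a, data.windows_b,
                                 target_versions=[cfg.core_ppm],
                                 library=library)
results = model.fit(seed=0)
print(results.summary())
```

```
Differential binding model
========================================
sequences: 558 (train 395 / test 163)
features: 26 (4 selected, lambda=0.0572)

Test AUROC by model variant:
  full                  0.938
  cf_whole_sequence     0.918
  wo_NE                 0.890
  wo_DM                 0.884
  wo_CF                 0.867
  dm_only               0.797
  two_ppm               0.779
  original_pwm          0.765

Importance profile (AUROC loss when ablated):
  DM   +0.054
  NE   +0.048
  CF   +0.071

Top variables (compact-model importance):
   1. CF:LIB00_GATCATGG@[-269:+116] class1 dAUROC=+0.074
   2. NE:ACA@[-71:+500]            class1 dAUROC=+0.058
   3. DM                           class1 dAUROC=+0.056
   ...
```

The generator planted exactly three differences between the classes: a core
position carried at 0.75 vs 0.25, the 3-mer ACA enriched 1.4× over
[−150, +500], and co-factor LIB00 planted in [−250, 0] of class 1. The model
recovers all three as its top variables, with regions overlapping the
planted ones; the full model (0.938) beats every reduced variant, and the
ablation profile shows all three feature classes contributing. `original_pwm`
is the scanning motif's own best-hit AUROC — the baseline the discriminative
machinery improves on.

On real data, start from BED files instead:

```bash
tfdiff run --bed-a exp1.bed --bed-b exp2.bed --genome hg38.fa \
           --target-motif MA0102.jaspar --library jaspar_pfms/ \
           --seed 1 --out results/
```

which writes `run.json`, `features.tsv`, `dm_pwm.tsv` (mirror-logo weights),
`class_ppms.txt`, `radar.tsv`, `location.tsv`, `ne_features.tsv`,
`cf_features.tsv` and the peak-partition BEDs. `tfdiff synth --out demo/`
emits a complete synthetic dataset (genome FASTA, BEDs, motifs, ground
truth) to try the command line on.

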