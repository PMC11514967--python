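# Methods

## Problem and model

Given two ChIP-seq experiments targeting the same transcription factor (or
two paralogous TFs), `tfdiff` asks which sequence features distinguish the
peaks unique to one experiment from those unique to the other. Working on
the *differences* sidesteps the notorious background-definition problem of
bound-vs-unbound classification: both classes are bona fide peaks, and the
model only has to explain what separates them.

The classifier is a logistic regression over three feature groups,

P(class 1 | s) = σ( a·DM(s) + Σᵢ bᵢ·NEᵢ(s) + Σⱼ cⱼ·CFⱼ(s) ),

fitted with an L1 (LASSO) penalty. The three groups map onto three
biological hypotheses: the core recognition motif itself differs (DM), the
broader nucleotide composition around the site differs (NE), or the
presence/placement of co-factor motifs differs (CF). Because every variable
is hand-constructed and named, the model's explanation is read directly off
the nonzero coefficients, and the weight of each hypothesis is quantified by
zeroing its coefficient group and measuring the held-out AUROC drop
(ablation without retraining — the "importance profile" 3-vector).

Assumptions worth stating: sequences are treated as independent; the
0-order view of composition (k-mers up to 4) and a best-single-occurrence
view of co-factors (no occurrence counting) are deliberate simplifications;
and every positional statement is relative to an anchor that is itself
inferred (the best core-motif hit), so systematic anchoring errors would
blur regional features rather than bias them.

## Pipeline

1. **Peak selection.** BED intervals; a peak is "common" when a peak of the
   other experiment lies within `window_bp` (default 1000, the `bedtools
   window` default) — overlap counts as distance 0. Default comparison is
   unique-vs-unique; unique-vs-common and as-given are options. The Jaccard
   distance 1 − |A∩B|/|A∪B| is computed on merged matched peaks.
2. **Alignment.** The larger class is randomly down-sampled to balance the
   classes. Each peak's ±500 bp around the summit (narrowPeak column 10
   when configured, else interval midpoint) is scanned on both strands with
   the target motif's log-odds PWM (uniform background, pseudocount 0.01);
   when several motif versions exist, the version whose best-hit scores
   best separate the *training* classes is used, and its test AUROC is the
   "original PWM" baseline. The best hit with p ≤ 1e−4 (exact DP score
   distribution under the background, 1e−3 discretization — the FIMO
   default threshold) anchors a 1-kb window centered on the hit midpoint;
   sequences with no passing hit are dropped and counted. Windows whose
   best hit is on the − strand are reverse-complemented so that all
   sequences read in motif orientation and flank positions are comparable
   (whether the original tool does this is unknowable from its description;
   we chose the orientation-consistent frame). Anchor-relative coordinate 0
   is the core midpoint; the window spans [−500, +500).
3. **DM.** Core occurrences plus 4 flanking bases per side (length K+8) are
   one-hot encoded; an L1-logistic fit (λ by internal 10-fold CV, deviance
   minimum) gives the discriminative PWM. N positions encode as all-zero
   rows. The intercept is fitted but excluded from the exported matrix.
   Per-class PPMs (nucleotide frequencies of the same core sites,
   pseudocount 0.5) are emitted to aid interpretation, and feed the two-PPM
   logistic baseline.
4. **NE.** The core span is masked to N's. The 1-kb window is split into 7
   bins (widths 143×6 + 142; leading bins take the remainder). For each of
   the 16 dinucleotides the most class-discriminant region of consecutive
   bins (28 candidates, folded AUROC max(a, 1−a)) is found by exhaustive
   enumeration over precomputed per-bin counts; the k-mer is then extended
   one base at a time on either side (up to length 4), keeping an extension
   only if the folded AUROC gains ≥ 0.01. A k-mer window belongs to the
   bin/region containing its START (it may overhang the region end by up to
   k−1 bp); windows containing N are excluded from numerator and
   denominator. This start-assignment makes regional aggregation of bin
   counts *exact*, which the tests assert against direct counting.
5. **CF.** 13 bins (widths 77×12 + 76). For each library PWM the best
   window log-odds per bin is stored (window assigned to the bin of its
   start; strand max; any window containing N scores −∞; a bin with no
   valid window gets the PWM's minimum score − 1 as a finite floor). The
   best score of every contiguous region — 91 for 13 bins — follows from
   the children-max lattice recurrence, and the region with the highest
   folded training AUROC defines the feature. Forcing the region to the
   lattice top gives the position-agnostic whole-sequence baseline.
6. **Global fit.** Features are standardized to training mean 0 / sd 1
   (training statistics only; heterogeneous scales). Ties in any region
   argmax go to the widest region, then the leftmost; ties in best-hit
   scanning go to the hit closest to the summit, then leftmost, then '+'.

## λ selection and the nested CV

The λ path is geometric from the data-derived λ_max down to λ_max/100
(30 points); per-λ solutions come from liblinear with C = 1/(nλ). For the
DM fit, λ is the 10-fold CV deviance minimum. For the *global* model we use
the 1-SE rule — and, more importantly, the CV is **nested**: the NE and CF
variables are *selected* to discriminate the training rows, so a λ-CV run
against those same rows inherits the selection optimism and retains noise
variables (measured on label-free data: held-fold deviance fell from 1.386
to ~1.01 and nearly all columns survived). We therefore re-run the
label-dependent region/k-mer selection inside each CV fold — the
label-independent per-bin counts and score matrices are computed once, so
this costs only the cheap AUROC scans — and each fold's deviance is
measured on rows the selection never saw. The DM column is fitted once on
the full training split (its own CV is internal and its single coefficient
contributes little optimism; on label-free data it is constant and
dropped).

## Reports

- **Radar record**: test AUROCs of the full model, the three group
  ablations, the DM-only score, the selected original PWM, the two-PPM
  baseline, and the whole-sequence-CF variant (8 entries).
- **Location record**: the model on the λ path with ~15 nonzero terms is
  taken, each variable's importance is the test-AUROC drop from zeroing its
  coefficient, and variables are reported with identity, bp region, rank
  and associated class (coefficient sign; positive = class 1). A compact
  10-term variant feeds the recovery checks.
- **Importance-profile clustering**: K-means (k = 3, 25 restarts, fixed
  seed) over per-experiment 3-vectors, with an inertia/elbow curve.
- A small exact two-sided binomial sign test (minimum-likelihood-sum
  convention) is included for co-factor expression concordance counts.

## Synthetic data

The generator draws 1-kb-plus-jitter windows over a 0-order background
(uniform by default — a 0-order null makes planted composition the only NE
signal) and plants, per class: a core site sampled from an 11-bp consensus
PPM at 0.95 conservation (chosen so ~98% of true sites pass the p ≤ 1e−4
scan threshold, matching the low no-motif fraction seen in curated peak
sets), at a uniform offset within ±50 bp of the nominal summit so anchoring
does real work; optional core-position overrides (nucleotide carried with
class-specific probability); optional k-mer enrichment in a region,
implemented by planting Poisson(m₀·(f−1)) extra occurrences at random
offsets (scaling the mean regional frequency by f); and optional co-factor
sites planted with class-specific probability at uniform positions in a
region. 2% of sequences carry no core. BED/FASTA emission packs windows
into per-class chromosomes with 1.5-kb spacers.

The canonical recovery conditions put one moderate signal in each group —
DM 0.75/0.25 (closed-form binary-feature AUROC 0.75), NE "ACA" ×1.4 over
[−150, +500] (~0.8), CF plant 0.8/0.05 in [−250, 0] (~0.88) — so the joint
model must integrate all three. The CF plant is stronger than the naive
closed form would suggest because the co-factor's own k-mer content is
partly absorbed by correlated NE variables; with a weaker plant the CF
group has no unique test-AUROC contribution to detect.

What the generator does *not* emulate: GC/composition heterogeneity across
loci, repeats, higher-order background structure, read-level peak shape,
replicate structure, and correlated motif families beyond what the toy
library happens to contain. Passing tests therefore demonstrate the
machinery recovers what it models, not that real binding differences
decompose this way.

## Problem sizes

Tests and the acceptance script use: end-to-end recovery at 1000
sequences/class with a 10-PWM library; a signal-free-group control at
600/class; null calibration over 20 replicates at 200/class; positional-CF
comparison at 400/class; DM closed-form check at 2000 sites/class; lattice
exactness over 1000 random 13-bin instances and 100 exhaustive 7-bin
region-search comparisons.

## Known limitations

- **Two-sample nulls are not empty.** With identical generating parameters,
  two finite samples still differ by chance (e.g., a realized CG-content
  shift), and an adaptive search over ~10³ candidate (k-mer/PWM, region)
  directions reliably finds the largest such difference. These discoveries
  *generalize within the dataset* (held-out AUROC moves off 0.5 in the same
  direction), so the penalized model is right to keep them — but it means
  occasional nonzero models on "null" data at any sample size, a property
  users should expect on weakly different real experiment pairs as well.
- Correlated variables (near-identical library PWMs; NE k-mers sharing a
  co-factor's composition) split or swap coefficients, so per-variable
  importances understate correlated groups; the group-level ablations are
  the robust statement. Consult motif-family clusterings before naming a
  specific co-factor.
- The model scores a single best occurrence per PWM and region; repeated
  occurrences are only visible through NE composition.
- An incomplete motif library pushes genuine co-factor signal into the NE
  group or loses it entirely.
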