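# khiblearn

Machine-learning prediction of **lysine 2-hydroxyisobutyrylation (Khib)
sites** from protein sequence.

Khib is an acyl post-translational modification that adds a
2-hydroxyisobutyryl group (+86 Da) to lysine side chains, neutralising their
positive charge and influencing chromatin dynamics, transcription and
metabolism.  Experimentally mapping Khib sites by mass spectrometry is slow
and incomplete, so sequence-based predictors are used to prioritise candidate
lysines.  `khiblearn` implements a complete, offline-testable pipeline for
this task, aimed at computational biologists who need a fast, classical
(non-deep-learning) predictor they can train on their own site tables.

## Method

Each candidate lysine is represented by a 43-residue window (21 flanking
residues per side, `X`-padded at protein termini).  Windows are encoded with
three complementary feature families:

* **CTD descriptors** (147 dims): for seven three-group physicochemical
  partitions of the alphabet (hydrophobicity, van der Waals volume, polarity,
  polarizability, charge, secondary structure, solvent accessibility),
  composition `C_i = n_i / L`, adjacent-pair transition frequencies
  `T_ij = n_ij / (L - 1)`, and the relative positions of the first /25 %/50
  %/75 %/last group occurrences (`D`, ×100).
* **AAindex encoding** (860 dims): each position mapped to 20 amino-acid
  property scales (position-specific physicochemistry).
* **Embeddings** (480 dims): mean-pooled per-residue vectors from a pluggable
  provider.  The built-in provider is a deterministic hashing feature map; a
  protein-language-model embedder (e.g. ESM-2) can be plugged in through the
  same interface.

The concatenated 1487-dimensional matrix is reduced to the top *k* = 700
features by mutual information with the label,
`I(X;Y) = Σ p(x,y) ln[p(x,y)/(p(x)p(y))]`, estimated on equal-frequency bins,
and classified with a gradient-boosted tree ensemble (LightGBM; 500 trees,
learning rate 0.1, depth 11, 89 leaves, L1 = 1.15e−5, L2 = 4.4e−8).
Evaluation covers ACC/SN/SP/PR/F1/MCC, ROC/AUC with Hanley–McNeil standard
errors and correlated-AUC comparison, two-sample-logo position statistics,
and silhouette / Davies–Bouldin cluster quality.

Dataset assembly mirrors standard PTM-predictor practice: redundancy removal
by greedy identity clustering at a 40 % threshold (CD-HIT-style), class
balancing by cluster representatives, a stratified 90/10 train/test split and
stratified 10-fold cross-validation.

A synthetic-data generator plants species-preset motif signal (upstream K
enrichment with maxima of 14.5 %/13.5 %/12.7 % for the human / parasite /
plant presets, E enrichment, P/S/R depletion) so the entire pipeline is
testable without downloads.

## Worked example

```python
import numpy as np
from khiblearn import (SyntheticConfig, generate_windows, encode_windows,
                       KhibModel, two_sample_logo)

cfg = SyntheticConfig(n_pos=500, n_neg=500, preset="human", seed=42)
windows = generate_windows(cfg)
features = encode_windows(windows)          # 1000 x 1487

model = KhibModel(features, k_features=700)
print(model.cross_validate(n_folds=5, seed=42).summary())
results = model.fit(seed=42)
print(results.summary())
```

prints

```
5-fold cross-validation (seed 42)
  ACC: 0.6180 +/- 0.0368
  SN: 0.5900 +/- 0.0771
  SP: 0.6460 +/- 0.0532
  PR: 0.6251 +/- 0.0370
  F1: 0.6053 +/- 0.0503
  MCC: 0.2375 +/- 0.0738
  AUC: 0.6709 +/- 0.0365

KhibModel fit summary
====================================================
samples:            1000
features (input):   1487
features (kept):    700
category mix (%):   aaidx=51.43, ctd=9.43, esm=39.14
...
```

The cross-validated AUC of 0.67 is the discrimination recoverable from the
planted motif signal at this sample size (chance would be 0.50); the category
mix shows that position-specific physicochemical features carry most of the
retained information, with embeddings second — the qualitative pattern
expected for this encoding stack.  The motif itself is visible directly:

```python
pos = [w for w in windows if w.label == "positive"]
neg = [w for w in windows if w.label == "negative"]
logo = two_sample_logo(pos, neg, alpha=0.05)
print(logo.flagged().head())
```

recovers the planted upstream lysine enrichment (e.g. K at offsets −1…−5,
frequency differences of +10 to +14 percentage points, p < 1e−7).

A `khiblearn` command-line interface wraps every stage
(`simulate`, `extract-windows`, `balance-split`, `build-features`,
`select-features`, `train`, `cv`, `tune`, `predict`, `evaluate`,
`compare-auc`, `logo`, `window-scan`); run `khiblearn --help`.

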