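# Methods notes

This note documents the models, estimators, defaults and numerical choices
behind `khiblearn`, and what its synthetic benchmarks do and do not show.

## Peptide windows and dataset assembly

Site positions are 1-based (UniProt convention).  A window is the closed
interval `[pos − flank, pos + flank]`; out-of-range positions are padded with
`X`, which may only appear as a contiguous prefix/suffix.  The default flank
of 21 (43-residue windows) follows the window-size optimum commonly found for
lysine-acylation predictors; `window_size_scan` re-evaluates the full
pipeline over any odd sizes (35–47 by default).  Non-standard letters
(B, Z, U, O, J) are mapped to `X` with a logged warning.  In strict mode the
central residue must be K.

**Redundancy removal** is greedy incremental identity clustering, a
documented simplification of CD-HIT (word size 2, threshold 0.4): windows are
processed in a canonical order (sequence, accession, position — making the
result independent of input order) and each joins the first cluster whose
*representative* shares identity above the threshold, else founds a new
cluster.  Identity between padded windows is defined as

    matches / union,

where `matches` counts positions with the same non-`X` residue in both
windows and `union` counts positions where at least one window is non-`X`;
`X` never matches anything.  The merge condition is `identity > threshold`,
with exact duplicates (`identity == 1`) always merging, so a threshold of 1.0
merges only duplicates.  No k-mer prefilter is applied: no cheap bound on the
padded-identity definition is sound, and exact vectorised comparison is fast
at package scale.  This procedure shares CD-HIT's intent (one representative
per similarity cluster) but is not a bit-for-bit reproduction of the external
binary.

**Balancing** keeps one representative per positive cluster and draws an
equal number of negative representatives uniformly *without replacement*
(seeded).  The stratified 90/10 split and stratified 10-fold assignment are
produced with scikit-learn splitters from the same seed (default 42); fold
class counts deviate from the global ratio by at most one sample.

## Feature encoders

**CTD.**  Seven three-group partitions are configured by default:
hydrophobicity (polar {R,K,E,D,Q,N} / neutral {G,A,S,T,P,H,Y} / hydrophobic
{C,L,V,I,M,F,W}) plus the canonical Dubchak-style partitions for normalised
van der Waals volume, polarity, polarizability, charge, secondary structure
and solvent accessibility.  All are user-configurable.  Composition and
transition use the de-padded length L′ in their denominators; distribution
percentile occurrences use round-half-up(p·n) clamped to [1, n] (so 1.75→2,
3.5→4, 5.25→5), with absent groups encoded as five zeros.  The 21-dim
transition block counts **unordered** group pairs (3 pairs × 7 attributes);
an ordered (directional) count for a single pair is available via
`mode="directional"` because the classical worked example for this
descriptor is directional — the two conventions are both exposed rather than
silently merged.

**AAindex.**  Position-major `L × 20` encoding; `X` contributes zeros.  The
default 20 scales (see `aaindex_scales.py`) cover hydrophobicity,
hydrophilicity, transfer free energy, polarity, charge, pI, volume, weight,
bulkiness, polarizability, refractivity, EIIP, flexibility, accessibility,
helix/sheet/turn propensity, mutability and codon-degeneracy information
content.  They are a declared default — any other 20-scale table can be
supplied as a delimited file — and no claim is made that they coincide with
any particular curated selection.

**Embeddings.**  The provider contract is `dim` plus
`embed_residues(depadded) -> (L', dim)`; window vectors are the mean over
non-pad residues.  The built-in `HashingEmbedder` maps each residue to the
mean of two fixed Gaussian vectors keyed by stable hashes of the residue
letter and its local context trigram (self-padded at sequence edges, so
homopolymers embed uniformly).  It is a random feature map, not a learned
model: it carries composition and local-context information deterministically
and offline.  A transformer protein language model (e.g. a 480-dimensional
ESM-2 layer) plugs into the same interface when richer evolutionary signal is
wanted.

No per-feature standardisation is applied by default (trees are
scale-invariant); the encoders are pure functions of their inputs.

## Feature selection

Mutual information is estimated by the direct plug-in formula on an
equal-frequency discretisation (≤ 20 bins; features with few distinct values
keep them as categories), natural log, with `0·log 0 = 0`.  This estimator is
deterministic and invariant under strictly monotone feature transforms (up to
tie effects), and only ranks matter downstream.  Ranking is score-descending
with ties broken by ascending column index; the default k = 700 retains the
plateau region where adding further features stops improving
cross-validated AUC (a `--k-scan` style sweep is available by calling
`rank_and_select` at several k and cross-validating).

## Classifier

LightGBM binary classifier consumed as an engine, defaults: 500 estimators,
learning rate 0.1, max depth 11, 89 leaves, L1 = 1.15e−5, L2 = 4.4e−8;
`colsample_bytree`, `subsample` and `min_child_samples` stay at engine
defaults unless tuned.  Training is single-threaded and deterministic by
default so seeded runs are bit-reproducible on one platform.  Prediction
aligns columns by *name*, never by position.  `tune()` is a seeded random
search over the bounded space (the documented tested ranges for the six
parameters above; [0.5, 1] for the two sampling fractions and [5, 100] for
min_child_samples), maximising mean CV AUC; 100 trials by default.
Cross-validation refits the MI selection inside every training fold to avoid
selection leakage into validation folds.  The confusion threshold is 0.5
(configurable).

## Evaluation

AUC is the normalised Mann–Whitney statistic with half credit for ties
(identical to trapezoidal integration of the step ROC); its standard error
and the correlated-AUC z-test follow Hanley & McNeil, with the correlation
term estimated as the mean of the within-positives and within-negatives
Pearson correlations of the two score vectors — a continuous surrogate for
the original table lookup, adequate at the sample sizes used here (the test
suite verifies its type-I error ≈ 0.05 by simulation).  MCC is defined as 0
when its denominator vanishes.

The two-sample logo compares per-(position, residue) occurrence indicators
with a Welch t-test (a two-proportion z-test is available; the two agree
asymptotically).  No multiple-testing correction is applied across cells —
the output is a screening display, and the false-positive rate among null
cells is therefore ≈ α by construction.  Padded positions are excluded.

Cluster quality (silhouette, Davies–Bouldin) accepts either raw scores or
any user-supplied low-dimensional coordinates; the package does not compute
t-SNE itself.

## Synthetic data generator

Negatives are i.i.d. draws from the background distribution (uniform 1/20 by
default; a natural-abundance table is provided) with a fixed central K;
positives apply per-(offset, residue) frequency deltas on top, with the
remaining residues rescaled proportionally.  Presets plant the qualitative
motif story of real Khib data:

* **human** — K enriched at offsets −1…−8, maximum +0.145 at −1 decaying
  linearly to +0.05 at −8; E enriched at +1…+6 (+0.08→+0.04); P depleted
  (−0.03) at ±1…±3.
* **parasite** — K maximum +0.135; A enriched +1…+5; weaker E; S depleted
  (−0.035) at −6…−1; P depleted.
* **plant** — K maximum +0.127; stronger E (+0.10→+0.05 at ±1…±6); R depleted
  (−0.035) at −6…−1; P depleted.
* **null** — no effects.

The K-enrichment maxima are the reported species-level values; the linear
decay with |offset| and the depletion magnitudes are explicit modelling
choices — in particular, depletions are capped below the uniform background
frequency of 0.05 (a −0.08…−0.10 serine depletion, as observed against
natural backgrounds, is impossible under a uniform background).  Deltas that
would drive any frequency negative raise an error.

What the generator does **not** emulate: homology structure between windows
(every window is independent, so clustering barely merges anything),
long-range positional correlations, mass-spectrometry acquisition bias, and
realistic residue backgrounds (unless the natural-abundance option is used).
Passing end-to-end tests therefore demonstrates that the pipeline recovers
planted per-position signal at realistic effect sizes — not that it attains
any particular performance on curated proteome data, which requires real
site tables and real embeddings.

## Problem sizes used by the test suite

The end-to-end recovery check runs the human preset at 2000+2000 windows
through the full pipeline (1487 features → MI top-700 → default booster,
stratified 10-fold CV); with the pinned seed this yields mean CV AUC ≈ 0.74,
and the suite asserts the pre-stated floor of 0.65 plus a 3-standard-
deviation margin above chance.  The chance-level check runs the null preset
at 1000+1000 with the same pipeline and asserts mean CV AUC ∈ [0.45, 0.55].
The correlated-AUC type-I simulation uses 600 replicates of n = 500.  These
sizes keep the default test run to a few minutes on one CPU while leaving
the binomial/CV noise well inside the asserted tolerances.

## Known limitations

* The clustering is a CD-HIT-style approximation, not CD-HIT.
* The hashing embedder carries no evolutionary information; plugging in a
  real protein language model is expected to change (usually improve)
  real-data performance but is deliberately outside the offline test surface.
* The default AAindex scale set is a documented stand-in for whichever
  curated 20 scales a user prefers.
* Random search, not Bayesian optimisation, backs `tune()`; with 100 trials
  over this 9-parameter space the difference is modest, and the interface
  allows swapping the sampler.
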