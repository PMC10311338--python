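# Methods

This note documents the models, conventions and numerical choices behind
`adenpredict`, and what the synthetic-data tests do and do not establish
about real A-domain data.

## Signatures

An A-domain is ~400 residues; its substrate specificity is concentrated in
the residues lining the binding pocket. The package represents each domain
by the 34 residues aligned to a configured set of match states of an
AMP-binding profile HMM ("extended binding-pocket signature"). Extraction
runs a HMMER search of the query against the profile (in-process via
`pyhmmer`) and walks the domain alignment: profile columns marked as
inserts are skipped, match columns map state index → query residue, and a
match state inside a deletion (or outside the aligned envelope) contributes
`-`. Signatures are concatenated in the order the positions are listed.

Choices and caveats:

* **Position set.** The shipped `data/positions.json` lists 34 strictly
  increasing match-state indices in the binding-pocket region of an
  AMP-binding profile. It is a *convention default*: the mapping of pocket
  residues onto match states depends on the profile build, so for
  production use the set should be validated against a labeled reference
  (e.g. check that known specificity pairs land in the same signature) or
  replaced with a curated set for the user's profile version. Every
  pipeline step treats the position set as data, so swapping it is a
  config change, not a code change.
* **Significance threshold.** A domain hit is accepted when its
  conditional (per-domain) E-value is ≤ 1e-5; configurable. Below that the
  record raises a "no A-domain hit" error (single-record API) or is logged
  and skipped (batch API).
* **Multiple hits.** Each passing domain hit in a protein yields its own
  signature; secondary hits get ids suffixed with hit index and envelope
  coordinates (1-based, inclusive).
* **Deduplication.** Labeled sets collapse identical signature strings to
  one datapoint. Conflicting labels resolve by majority; exact ties are
  dropped with a warning, since the data cannot decide them. Output is
  sorted by signature, making the operation deterministic and idempotent,
  and guaranteeing every post-dedup pair is at Hamming distance ≥ 1.

## Encodings

All schemes concatenate one numeric block per signature position:

* **one-hot** — 20-dim indicator per residue (680 total). Block offsets
  follow the fixed alphabet `ACDEFGHIKLMNPQRSTVWY`; this order is part of
  persisted-model metadata.
* **physiochemical** — 12 AAindex descriptors + 3 z-scales (hydrophobicity,
  steric bulk, electronic properties), 15 per residue (510 total). Each
  descriptor is z-standardized across the 20 canonical residues — a fixed,
  dataset-independent transform, so encodings never leak information
  between train and test. Whether and how to standardize is a convention;
  standardizing over the residue alphabet keeps descriptor scales
  comparable without touching the data. A constant descriptor is rejected
  as a configuration error. The 12 shipped AAindex accessions (hydropathy,
  polarity, volume, isoelectric point, mass, surface areas, van der Waals
  volume, helix/sheet propensities, hydrophilicity, consensus
  hydrophobicity) are an editable default standing for the classical
  physiochemical feature sets used in this field.
* **external** — per-residue feature rows from a TSV
  (`id`, `position`, features...), e.g. structure-derived property
  predictions produced by an external tool. One row per (id, position
  1..34) is required; missing rows and ragged widths are hard errors.

`-` (deletion) and `X` (ambiguous) encode as all-zero blocks in every
scheme; under standardized physiochemical features the zero block is the
residue-population mean, a neutral imputation.

## Classification and weight balancing

Backends are scikit-learn estimators (extra-trees, random forest, logistic
regression, decision tree, RBF-SVM with probability calibration, k-NN,
MLP, Bernoulli/Gaussian naive Bayes, ridge and ridge-CV) behind one
train/predict/persist surface. Defaults: 500 trees for the forest
ensembles, one hidden layer of width 128 for the MLP; all overridable via
`hyperparams`. A `gnn` token is reserved but unsupported. Determinism: one
base seed feeds every stochastic backend, so identical inputs give
identical fitted models and predictions.

With weight balancing on, example `t` receives weight `1 / b_t`, `b_t`
being the number of training points sharing its label; the weights of each
class therefore sum to exactly 1 and all classes contribute equally to the
loss. Backends that cannot weight samples in their fit criterion (k-NN,
MLP) reject the flag explicitly rather than silently ignoring it.

Predictions are probability vectors over the sorted label vocabulary.
Ridge backends have no calibrated probabilities; their decision scores pass
through a softmax and should be read as rankings. Ties rank alphabetically.
Persisted models carry a metadata header (backend, scheme, vocabulary,
seed, feature length, checksum) validated on load, and a feature-length
guard rejects probes encoded under a different scheme.

## Evaluation and Hamming buckets

Evaluation is repeated random holdout: `n_repeats` (default 20) plain
unstratified 80:20 splits, repeat `r` seeded `base_seed + r`. Per-bucket
accuracies, the confusion matrix (rows true, columns predicted) and
per-class F1 are pooled over all repeats — pooling stabilizes sparse
high-`k` buckets, which per-repeat averaging would leave noisy — while the
overall accuracy is the mean of per-repeat accuracies. Bucket distance is
computed on raw signature strings (with `-`/`X` compared literally), so
bucket membership is independent of the encoding scheme. A repeat whose
training split collapses to one class is re-drawn (logged); test points
whose class is absent from their training split count as errors. Report
serialization sorts keys for diffability.

## Substrate properties

The label → property table is curated chemistry, not learned. Conventions:
charge is assigned at physiological pH (asp/glu and the aryl acids
negative; lys/arg/orn/dab positive, his grouped with the basics);
"large side chain" means more than four heavy (non-hydrogen) atoms;
aromatic monomers are never classed hydrophobic-aliphatic (enforced at
load); hydrophobicity uses the three-way split hydrophilic /
hydrophobic-aliphatic / hydrophobic-aromatic. For aryl-acid monomers
(2,3-dihydroxybenzoate, salicylate) the "side chain" is read as the
substituted ring plus carboxylate. Each entry records a provenance string;
the table is user-extensible JSON, and an uncovered label is an error so
new monomers must be curated explicitly. One classifier is trained per
attribute; attributes are not modeled jointly.

## Atlas

Clustering is K-means (k-means++, `n_init` 10, euclidean), with a
mini-batch option for large collections. The stored inertia is recomputed
from the final assignment, so the invariant `inertia = Σ‖x − c(x)‖²` holds
exactly. Elbow selection normalizes the inertia-vs-K curve to the unit
square and picks the K where the curve dips furthest below the chord
joining its endpoints (kneedle-style); the dip depth ("knee strength") is
reported, and curves whose maximum dip is below 0.2 are flagged as having
no pronounced elbow — in signature-encoding dimension a structureless
point cloud yields a nearly linear curve, well below the flag, while
planted partitions exceed it by a wide margin. A plain second-difference
curvature rule was rejected because smooth convex decay (single isotropic
blob at moderate dimension) also produces high curvature at small K. The
2D map is t-SNE (perplexity 30, clipped below the sample count; PCA
initialization; fixed seed → identical embeddings). The novelty report
ranks clusters by size (ties by index), and lists those among the top `n`
(default 50) with zero labeled members, together with every top cluster's
label composition.

## Synthetic data

The generator emulates the *shape* of labeled A-domain data: length-34
signatures over the 20-residue alphabet where a chosen subset of motif
positions carries a class-specific residue with probability
`motif_strength`, over a background distribution (uniform by default).
Class residues are drawn without replacement per position, so classes are
perfectly distinguishable at strength 1. What it deliberately does not
model: phylogenetic correlation between signatures, position-position
dependence, realistic residue composition, or label noise. Passing tests
on this data therefore establish that the pipeline's machinery is correct
— encodings faithful, weights conserved, buckets exact, planted structure
recovered — not that any particular accuracy will be attained on real
A-domains, which is an empirical matter for the user's dataset.

Probe construction for the bucket metric copies a training signature and
mutates exactly `k` positions, preferring residues unseen at that position
anywhere in the training set (such positions add 1 to the distance against
*every* training point, making even `k = 34` constructible); to keep unseen
residues available the probe generator restricts the default background to
14 of the 20 residues. Every probe is verified by brute force before being
returned; `k = 0` is rejected because deduplicated data cannot contain it.

The toy alignment fixture builds a 50-match-state profile from copies of a
random consensus (no residue repeated within a 3-window, so engineered
deletions have an unambiguous alignment column) and threads query
sequences with known flanks, an internal insertion and a deletion at one
configured position. The construction itself is the oracle: extraction
must return the threaded residues verbatim, with `-` at the deletion.
Fixture files are byte-identical across runs with one seed.

## Test and verification scale

The shipped checks run at desk scale, chosen to exercise every code path
within interactive runtimes: brute-force bucket verification on random
train/test pairs up to 500×500, motif recovery on 8 classes × 40
signatures over 5 holdout repeats (with a permuted-label chance control),
minority-rescue on 500-point 90:10 two-class sets over 5 seeds, clustering
and elbow selection on 10 planted blobs of 30, and 1000-multiset weight
conservation. The atlas-scale defaults (K = 200, top-50 novelty) are the
intended settings for real mining-scale collections and are exercised at
reduced K in tests.

## Known limitations

* The default position set and AAindex descriptor list are conventions;
  results on real data depend on replacing or validating them against the
  user's profile and reference set.
* Extraction consumes protein FASTA; locating A-domains in genomes
  (antiSMASH or similar) is upstream of this package.
* Probability outputs of ridge backends are softmax-rescaled scores, not
  calibrated probabilities.
* t-SNE on very large collections should use the `--sample` option;
  exact K-means on hundreds of thousands of points should use the
  mini-batch mode.
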