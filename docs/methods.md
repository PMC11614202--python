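# Methods

## The model

`viralmil` predicts the host species of a virus from the virus's proteins
alone, treating each virus as a *bag* of per-protein feature vectors with a
single label. Instance (protein) labels are latent: under the standard
multiple-instance assumption a virus is associated with a host as soon as
at least one of its proteins carries the host-specific signal

    Y = 0  iff  Σ_m y_m = 0,   Y = 1 otherwise,

so the classifier must both aggregate over an unordered, variable-size set
of proteins and locate the informative ones. Both needs are met by
attention pooling. For a bag X = {x_1..x_M}, x_m ∈ ℝ^d:

    u_m = ReLU(W₁ x_m + c₁)                    embedding layer, d → h
    a_m = softmax_m( wᵀ tanh(V u_m) )          attention, V ∈ ℝ^{L×h}, w ∈ ℝ^L
    z   = Σ_m a_m u_m
    θ(X) = g(bᵀ z + c)                          g = logistic (binary)
                                                or softmax over K classes

The bag label is Bernoulli(θ) in the binary case and categorical in the
multi-class case; training minimizes the mean negative log-likelihood. The
attention weights a_m (positive, summing to 1, equivariant under instance
permutation) double as per-protein importance scores: ranking a virus's
proteins by a_m and keeping the top 5 is the package's interpretation
output. The plain tanh attention form is used, not the gated variant.

Defaults: h = 800 (the width used with 1280-d protein-language-model
embeddings), L = 128. The binary head uses a single logit; the multi-class
head uses K logits with softmax (equivalent to a K−1 parameterization).
Probabilities are clipped at ε = 1e-7 inside the log; a binary tie at
θ = 0.5 breaks to the negative class.

## Features

Three k-mer composition featurizers turn raw sequences into fixed-length
instance vectors; each vector is the normalized count of all length-k
windows, so entries are non-negative and sum to 1:

| scheme | alphabet                | k | dim  | instance unit |
|--------|-------------------------|---|------|---------------|
| DNA_5  | A,C,G,T                 | 5 | 1024 | one CDS       |
| AA_2   | 20 amino acids          | 2 | 400  | protein fragment |
| PC_3   | 7 physiochemical groups | 3 | 343  | protein fragment |

The physiochemical alphabet pools residues into AGV | C | FILP | MSTY |
HNQW | DE | KR before 3-mer counting. Windows containing out-of-alphabet
symbols (N, X, …) are skipped rather than the sequence rejected, since
real RefSeq records carry ambiguity codes. k-mer index order is
lexicographic over the declared alphabet (for PC_3, the group order as
printed above); any fixed order is valid — this one is documented for
reproducibility. DNA k-mers are counted on the given strand without
reverse-complement canonicalization.

Externally computed 1280-d per-fragment protein embeddings enter through
`featurize.EmbeddingTable`, a `(virus, protein, fragment) → vector` adapter
backed by one TSV per virus plus a manifest. The adapter validates
dimension only; producing embeddings is out of scope.

## Sequence preparation

Embedding models accept at most 1022 residues, so proteins are cut into
1022-residue fragments left to right; a protein shorter than 1022 + 25 is
truncated to at most 1022, and a final fragment shorter than 25 residues is
discarded as uninformative. Retained fragments always reconstruct a prefix
of the protein, each fragment becomes its own bag instance, and fragment
provenance (parent protein + index) is kept so attention weights can be
reported per fragment (the default) or summed per protein.

The ambiguity code J (Leu/Ile) is resolved by a seeded uniform coin flip
per occurrence — the substitution rule is explicitly random, so the seed is
recorded to keep runs reproducible. A terminal `*` (translated stop) is
stripped; it is not an amino acid. Other ambiguity codes (B, Z, X, U, O)
pass through for k-mer purposes, where windows containing them are skipped,
and are rejected only on the embedding-adapter path.

## Datasets

Balanced binary datasets per host are built from a virus-host association
table carrying each host's lineage (genus…kingdom) and each virus's genus.
Positives are the host's known viruses (segmented viruses pooled into one
record first); an equal number of negatives is drawn without replacement,
uniformly and seeded, from the same host domain (prokaryote/eukaryote,
an input column) under:

* **strategy 1** — candidates exclude every virus whose *virus genus*
  occurs among the positives, minimizing false negatives. A variant that
  excludes by host taxonomy instead is exposed as
  `exclude_by="host_taxonomy"`.
* **strategy 2 (rank)** — candidates are viruses of *other hosts* sharing
  the focal host's taxon at the chosen rank; pools are nested from genus up
  to phylum, so the task hardens as the rank descends.

Host-eligibility thresholds of 50 (prokaryotic) and 125 (eukaryotic)
positive viruses reflect that bags of eukaryotic (often RNA) viruses hold
only 2–23 proteins versus 45–212 for dsDNA phages, so more bags are needed
for comparable training signal. Multi-class datasets keep one class per
host with at least 30 viruses; a virus associated with several eligible
hosts keeps one labelled copy per association row (documented so users may
deduplicate). If a candidate pool cannot fill a balanced set the build
fails loudly with the pool size.

## Training

Optimization is mini-batch Adam (β = 0.9/0.999) on the bag likelihood,
written directly in numpy with analytic gradients (verified against
numerical differentiation to ~1e-7 relative error). Initialization is a
seeded uniform fan-in scheme; one integer seed fixes initialization,
shuffling and augmentation. Defaults: learning rate 1e-3, batch 8,
100 epochs, L2 weight decay 1e-4 on the three weight matrices (never on
the attention vector w, which must grow for attention to sharpen), early
stopping on validation AUC with patience 10.

Bags are small-sample objects: a few hundred training bags against an
h = 800 network memorize within tens of epochs. `MILConfig.small_data`
bundles the package's small-sample recipe: weight decay 0.03, Gaussian
input-noise augmentation at 1× each feature's standard deviation,
20% instance dropout (each training bag randomly loses instances,
keeping at least one — label semantics survive because positive bags carry
the signal redundantly), batch 32, 300 epochs, and stochastic weight
averaging over the second half of the run in place of early stopping.
SWA-averaged parameters are markedly more stable than any single iterate.

## Evaluation protocol

A stratified 80/20 outer split is followed by stratified 5-fold
cross-validation on the 80%; each fold's model (trained on 4 folds, the
held-out fold serving as its monitor) is evaluated on the untouched 20%,
and the fold with the highest monitor AUC is flagged best. Metrics follow
the confusion-matrix formulas (accuracy, sensitivity, specificity,
precision), macro-averaged F1, and ROC-AUC with midrank tie handling
(multi-class: macro one-vs-rest). Ratios with zero denominators are
reported as NaN sentinels rather than silent zeros so macro averages stay
honest. Rank-level accuracy scores a prediction as correct at a taxonomic
rank when the predicted and true hosts share that rank's taxon; viruses
whose lineage lacks the rank are excluded there, with exclusion counts
reported. The expected accuracy of a uniform random K-class classifier,
1/K, is the reference baseline (0.045 at K = 22, 0.028 at K = 36).

## Synthetic data and what it shows

The generator emits the structure the MIL assumption describes: background
instances are iid N(0, σ²I) and each positive bag carries
`witness_count` instances shifted by `witness_shift` along a fixed
coordinate (class c's coordinate in the K-class case). Defaults — 200
balanced bags, sizes uniform in 5..30, dim 64, shift 3, noise σ = 1 —
define the package's recovery benchmark. Two witnesses per positive bag
(not one) is the default: with bags of up to 30 unit-noise instances, the
exact likelihood-ratio detector tops out near AUC 0.90 for a single
witness at shift 3, whereas two witnesses admit ≈ 0.97, leaving a
learnable margin. Even so, the protocol measures AUC on a 40-bag test
split, whose oracle ceiling fluctuates by ±0.05 across seeds; benchmark
numbers should be read with that sampling noise in mind. The generator's
witness mask is withheld from training and used only to score whether the
top attention weight lands on a planted instance.

What passing these benchmarks does *not* show: real protein embeddings are
not isotropic noise plus an axis-aligned shift; host signal in real data is
distributed over correlated features and many proteins, bags are not
balanced, and labels contain false negatives. The synthetic results
establish correctness of the machinery (pooling, attention, training,
protocol), not field performance.

## Known limitations

* Training is CPU-bound numpy; it is sized for desk-scale experiments
  (hundreds of bags), not the full association-database corpora.
* Attention weights are a model-internal importance measure; near-uniform
  weights on small bags carry little signal, and weights of correlated
  proteins split arbitrarily.
* Probability outputs are not calibrated.
* Multi-class AUC uses macro one-vs-rest; other schemes (e.g. pairwise)
  would give different numbers on imbalanced class sets.
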