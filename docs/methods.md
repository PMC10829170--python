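# Methods

## Contrastive pre-training of the SMILES encoder

### Views and objective

The self-supervision signal is SMILES non-uniqueness. For each molecule we
keep a pool of up to 50 distinct randomized spellings, produced by
shuffling the atom order with a seeded RNG and re-emitting the SMILES
without canonicalization; every view canonicalizes back to its parent, a
contract tested exhaustively. Each training epoch a molecule contributes
its canonical SMILES plus one view drawn from the pool, so the augmentation
stream changes per epoch yet is reproducible: one master seed derives the
pool seeds and the per-epoch draw seeds.

For a minibatch of m molecules (2m views), the loss for an ordered positive
pair (i, j) is

    L(i,j) = −log [ exp(sim(z_i, z_j)/τ) / Σ_{k≠i} exp(sim(z_i, z_k)/τ) ]

with cosine similarity `sim` and temperature τ. We average over all 2m
ordered pairs (the symmetric SimCLR-style aggregation; each per-pair term
is the loss above unchanged). The implementation subtracts the row maximum
before the log-sum-exp; correctness is pinned by a brute-force double-loop
oracle at 1e−6 and by closed forms (log(2m−1) for identical projections, 0
for a single pair). Degenerate zero-norm projections raise rather than
silently regularize.

### Architecture

Token ids → embedding (148 × 116) → three convolution blocks (Conv1d →
batch norm → ReLU → dropout 0.1), default channels 128/192/256 with kernels
5/5/3 → global max-pool over positions → linear to the representation
h ∈ R^262 → projection head 262→256→128 (ReLU between). Pooling had to be
chosen; global max-pooling is used for robustness to sequence length and
padding. τ defaults to 0.5. All of this sits in `EncoderConfig` and is
overridable; the widths 148/116/262 are the reference configuration and are
asserted in tests.

The vocabulary is frozen in `ddikit/data/vocab.txt`: a pad token, all 118
element symbols, the aromatic organic-subset symbols c/n/o/p/s, digits 0–9
and fourteen punctuation characters `()[]=#-+/\:%.@` — 148 entries.
Tokenization is greedy longest-match so `Cl`/`Br` are single tokens; a
purely per-character scheme could not represent two-letter elements. The
aromatic `b` is omitted to keep the inventory at 148; borole-type rings are
the rarest of the aromatic set, and an out-of-vocabulary character raises a
named error rather than being silently dropped. Greedy matching implies
rare mis-segmentations (e.g. `Cn` reads as copernicium rather than
C + aromatic n); this only relabels token ids, never breaks the
encode→decode round trip, and mirrors the inherent ambiguity of
character-level SMILES schemes. Default max_len is 250 with prefix-keeping
truncation and a logged warning.

### Training loop

AdamW (decoupled weight decay, lr 1e−3, weight decay 1e−6) with cosine
annealing to zero over the epoch budget. The validation set is the diverse
side of a greedy MaxMin split (Tanimoto distance on ECFP radius-2/2048
fingerprints, seeded uniform first pick, fraction 0.2): diversity picking
makes validation representative of the library's chemical range instead of
an arbitrary random sample. The checkpoint with the lowest validation
InfoNCE loss is retained. Per-epoch history records train loss, validation
loss and validation acc_top1 (fraction of molecules whose randomized view
is the strict nearest neighbor of the canonical view among all validation
candidates; ties count as failures).

The whole network, including backpropagation, AdamW and batch-norm running
statistics, is written in NumPy (`ddikit._nn`). No GPU framework is used;
runs of a few hundred molecules for tens of epochs take around a minute on
one CPU core, and identical seeds give bit-identical histories.

## Transfer to DDI classification

Both drugs of a pair are embedded with the frozen encoder (feature-extractor
transfer; only new layers train) and concatenated to a 2×262 = 524-wide
feature. Concatenation is order-sensitive; by default pairs are used in
their given order, matching the literal transfer procedure, with an opt-in
`symmetrize_pairs` flag that adds the swapped order to the training set.
The classifier is a feed-forward net (default 1024→512, ReLU, dropout 0.2)
with a log-softmax output trained by negative log-likelihood, default batch
size 256 over 200 epochs, reusing the AdamW + cosine-annealing recipe. The
epoch with the best validation weighted F1 (the headline metric family) is
restored for inference. The un-pretrained ablation arm replaces the trained
encoder with a frozen randomly initialized encoder of identical shape, so
the two arms differ only in the learned weights.

Three samplers address imbalance. `balanced_batch` (default) emits batches
whose per-class counts differ by at most one, resampling minority classes
with replacement; when classes outnumber the batch size it degrades to
rotating coverage of distinct classes, logged. `class_weight` draws classes
with the inverse-frequency weight 1/n_c applied per member — class masses
n_c·(1/n_c) equalize, so class marginals become uniform — then a uniform
member. `weighted_random` draws examples with replacement with probability
proportional to 1/(class frequency), the weighted-random-sampler recipe.
The literal "class sampled inversely proportional to its frequency" reading
would over-represent minorities beyond parity and invert the imbalance;
the per-member interpretation is the one whose 90/10 two-class marginal is
50/50, which is the behavior the strategy exists to produce.

## Evaluation schemes and metrics

Task 1 is a per-class stratified 80:10:10 random split (largest-remainder
allocation keeps every class within ±1 of its target in each partition;
classes with fewer than three examples are pooled best-effort into val/test
with a warning). Tasks 2 and 3 hold out a fraction of drugs (default 10%,
configurable) as "new": pairs with both drugs known form the shared
training pool (validation carved out stratified from known-drug pairs),
pairs with exactly one new drug are the Task 2 test set, pairs with two new
drugs the Task 3 test set. Every pair lands in exactly one bucket and the
bucket invariants are machine-checkable via `SplitSpec.validate`, exercised
on 100 random generated datasets.

Accuracy, precision, recall and F1 are support-weighted one-vs-rest
aggregates (plain accuracy, not balanced); AUROC and AUPRC are macro
averages over classes that have both positives and negatives in the ground
truth — classes without a definable curve are skipped, not zero-filled,
to avoid deflating the average with undefined values. SNN is the mean
nearest-neighbor Tanimoto of a query set against a reference set; Scaff is
the cosine similarity of two sets' scaffold-frequency vectors, with acyclic
molecules pooled into one "no-scaffold" bucket.

## Scaffold analyses

Drug pairs become transactions of their two Murcko scaffolds (optionally
plus the side-effect label — both encodings are supported because either
reading is defensible). FP-Growth (FP-tree with conditional pattern bases,
written here; supports are exact fractions) returns every itemset at or
above the support threshold, verified itemset-for-itemset against a
brute-force Apriori enumeration on random transaction sets. Association
rules enumerate every antecedent/consequent bipartition of each frequent
itemset with support, confidence and lift.

Profile matrices are deliberately binary (presence/absence, not counts) to
remove frequency bias: interaction mode is directional (position-1 ×
position-2 scaffolds), side-effect mode pools scaffolds from either
position. Rows are clustered by single-linkage on Jaccard distance and cut
with the inconsistency criterion at threshold 1.0 by default (the
documented default criterion of the underlying flat-clustering routine); a
raw-distance criterion is exposed because the inconsistency coefficient
cannot separate rows whose merge heights are all equal. All-zero rows have
undefined Jaccard similarity and become singletons with a warning. The five
binary similarity metrics follow the standard popcount formulas; the
Rogot–Goldberg variant is validated against the RDKit implementation rather
than a hand-derived closed form. Cluster summaries pool pairwise
similarities within clusters of size ≥ 2 (intra) and across distinct
clusters (inter).

## The synthetic data generator

The generator emulates the structural premise under test: molecules come in
scaffold families — a ring template (benzene, pyridine, naphthalene,
cyclohexane, piperidine, thiophene, furan, quinoline, …) decorated at
carbon positions with one to three small substituents (methyl, amino,
hydroxyl, halogens, methoxy, ethyl, cyano, trifluoromethyl) — and a drug
pair's side-effect class is a seeded deterministic function of its
unordered scaffold combination, optionally flipped with a label-noise
probability. Class marginals follow a geometric profile decay^c (default
decay 0.5 over 6 classes), emulating the skew of real side-effect
taxonomies. Because labels are scaffold-determined, scaffold-aware
representations genuinely help, which is exactly the property the
contrastive encoder is supposed to deliver; a logistic model on
scaffold-combination indicators is near-perfect at zero noise and degrades
monotonically as noise rises, confirming the signal is real and titratable.

What the generator does not emulate: real pharmacology (labels follow no
mechanism), stereochemistry, salts, the long tail of ring systems in public
libraries, or textual interaction semantics. Passing tests therefore show
the pipeline's statistical machinery works under its stated assumptions —
not that the learned representations transfer to DrugBank-scale data.

## Desk-scale experiment sizes

The test experiments use a 264-molecule library over 8 scaffold families
(200 molecules pre-trained for 30 epochs, 64 held out), a 1200-pair DDI
table with 6 classes and 5% label noise, a lighter convolution stack
(64/96/128) with max_len 48, and a 256/128 classifier trained for 30
epochs. These sizes were chosen so the full suite runs in minutes on one
CPU core while keeping every qualitative property of interest measurable:
pre-training beats the random-matching baseline by more than 5× on held-out
view pairs, the pretrained frozen encoder beats the random frozen encoder
on DDI transfer (median over 5 seeds), cold-start (both-unseen) performance
does not exceed the random-split ceiling, and 8-family pre-training matches
or beats 2-family pre-training on held-out view matching at equal epochs.

## Known limitations

- Greedy tokenization mis-segments a few two-letter sequences (see above).
- The MaxMin picker is the exact greedy algorithm, O(N·k); fine for
  libraries of thousands, not millions.
- `class_weight` and `weighted_random` equalize class marginals only in
  expectation; `balanced_batch` enforces them exactly per batch.
- Inconsistency-based cluster cuts are scale-free but opaque; the
  raw-distance criterion is provided when interpretability of the cut
  height matters.
- Representations are trained on enumeration invariance only; nothing
  enforces invariance to tautomers, protonation states or stereochemistry.
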