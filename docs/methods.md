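# Methods

## Problem and model

The package addresses first-step biotransformation of xenobiotics by the
human gut microbiota. The working assumption is enzyme promiscuity: an
enzyme tends to act on molecules structurally similar to its known
substrates, so a query molecule's enzyme can be inferred from the
substructure profile of curated substrates. The predictor is
hierarchical: a 6-way random-forest over EC classes, then a per-class
forest over EC subclasses, then a similarity search that resolves the
four-digit EC within the predicted subclass. The hierarchy means the
final EC can never contradict the class/subclass decision, and a query
that cannot be placed confidently halts with an explicit outcome rather
than a forced guess.

## Substrate curation

Filters run in a fixed order: cofactor removal and multi-EC-class
removal (both per-record predicates, hence commuting) first, redundancy
removal last, because the representative choice depends on which records
survive. Redundancy removal is greedy leader clustering in stable input
order — the first member of a cluster is its representative — merging on
Tanimoto strictly greater than 0.95 (equality keeps both) under the
path-based 1024-bit family by default; both threshold and family are
parameters. Records with all-zero fingerprints are excluded with a
warning since Tanimoto is undefined against an empty bit set. The
cofactor list ships as an editable two-column SMILES file matched by
canonical structure, replacing manual curation with a reproducible rule.
Multi-fragment inputs keep the largest covalent fragment, logged in the
record's provenance.

## Fingerprint families

Families are RDKit-backed, registered with fixed lengths, and pure
functions of the heavy-atom graph (implicit hydrogens, stereochemistry
retained in the canonical key): path1024, graph1024 (bond orders
ignored), maccs166 (RDKit's 167 keys minus the permanently unused bit
0), estate79 (E-state key presence), pattern1024, avalon512, morgan1024,
atompair1024 and torsion1024. Count-valued families are binarized
(count > 0 → 1) because both CFS and Tanimoto are defined on binary
vectors. The method depends on family *diversity*, not on any one bit
dialect; no CACTVS/PubChem-key equivalent exists in the toolkit, and
none is emulated. Column ids `family:bitindex` (0-based) are the stable
currency between the feature table, the hybrid spec and the models.

## Hybrid fingerprint selection

Per family: (1) drop columns whose majority value covers more than 99%
of rows (constant and near-constant bits); (2) CFS with best-first
search. Symmetric uncertainty `2·MI/(H(X)+H(Y))` is the association
measure; a zero-entropy pair scores 0. The search starts from the empty
set, expands states by single-bit addition or removal in best-merit
order (priority queue; merit updated incrementally in O(k) per child),
and stops after 5 consecutive expansions without improving the best
merit found; queue ties resolve by insertion order, so the selection is
fully deterministic and row-order invariant. Per-family selections are
concatenated in registration order.

Selection labels: the default pipeline selects against the joint
class+subclass label rather than the class label alone. Both cascade
levels consume the same hybrid; on strongly class-separable data a
class-only target can be satisfied by a handful of bits that carry no
subclass signal, starving the second level. The joint label is the
finest target the hybrid must serve; `build_hybrid` itself accepts any
label vector, and the CLI exposes `--labels class|subclass`.

Note one property of the merit worth knowing: adding an exact duplicate
of a selected column leaves the merit unchanged (r̄_ff = 1 makes the
k-column merit collapse to r̄_cf), so de-duplication relies on the
search not preferring larger subsets at equal merit, which the
stale-stop rule provides.

## Cascade training and tuning

Upsampling balances every class to the majority count by sampling with
replacement within class, keeping all originals. It is applied per
model, and in evaluation protocols strictly inside the training
partition, after splitting — duplicated rows must never straddle a
train/test boundary.

mtry search starts at round-half-up of sqrt(p) (15 for a 219-bit table),
probing outward by factor 2 in each direction while the relative OOB
improvement is ≥ 0.05; all probes are recorded and the returned value
minimises OOB error in the trace. ntree is the grid 100–500 step 100,
lowest OOB error, ties to the largest value (reading saturation). OOB
error is the misclassification rate of out-of-bag votes; rows in-bag for
every tree are excluded from the rate. Subclasses with fewer than 2
records are excluded from subclass training (a singleton cannot be
validated) but stay in the substrate database for the similarity stage;
a class without at least two trainable subclasses gets no subclass model
and predictions fall back to the class-level output.

Tuning is performed on whatever training set the sampling mode produces
(up-sampled when upsampling is on). Default training uses
mtry = round(sqrt(p)) and ntree = 500 without search; `--tune` enables
the full per-model search.

## Metrics and protocols

TPR, TNR, PPV and ACC are reported in percent, MCC in [−1, 1], per class
one-vs-rest and macro-averaged (the averaging behind single-row
multi-class summaries is a convention; macro treats classes
symmetrically). Zero denominators yield 0 for the rates and 0 for MCC,
preventing NaN propagation. Protocols: stratified 10-fold CV with counts
pooled over folds; stratified 75/25 split; blind protocol withdrawing
round-half-up 10% of each class (≥1 where the class has ≥2 members,
nothing from singletons) before any training, scoring once, then
retraining production models on the full data. The PCA diagnostic
(centered, full SVD) reports non-increasing variance fractions; a
slowly decaying spectrum indicates a heterogeneous substrate set that
resists low-dimensional shortcuts.

## Similarity stage

Consensus search uses path1024, pattern1024 and maccs166. Per family,
candidates rank by TC with lexicographic-id tie-breaks; if ≥2 families
agree on the top candidate it wins regardless of a higher coefficient in
the dissenting family; a three-way split resolves to the globally
highest TC. The winner's EC tags are filtered to the predicted
(class, subclass) — the stage refines the cascade's decision and may
never contradict it; a substrate serving several same-subclass enzymes
yields all of them. Default TC cutoff is 0.5 (user-settable): a winner
below it returns "no-confident-EC" with the best sub-threshold hit kept
for transparency.

## Enzyme database

Best-hit EC transfer from 13-column tabular alignment hits (standard 12
columns plus subject EC). Eligibility is strict: identity > 40%, query
coverage > 80%, E-value < 1e-15; boundary values are rejected. The best
eligible hit has the highest bitscore, ties broken by lowest E-value,
then lexicographic subject id — a deterministic refinement of the usual
best-hit convention. Query coverage is alignment length over query
length × 100 when query lengths are supplied. Records join to genomes
and ordered taxonomic lineages; partial-EC lookup matches every non-wild
level.

## Synthetic data

Each (class, subclass) pair is anchored by a distinct ring/heteroatom
scaffold template decorated with two seeded carbon-led substituents.
Rejection sampling guarantees all base molecules are pairwise
non-redundant (TC ≤ 0.95 under the default family), so the curation
ground truth is exact: planted duplicates (identical structures, new
ids) collapse onto their parents, planted multi-class and cofactor rows
are filtered, nothing else moves. The default preset `separable6` is
6 classes × 3 subclasses × 20 molecules (360 base records) with 5%
duplicates, 3% multi-class rows and 5 cofactors; `imbalanced6` skews
class weights 0.36/0.30/0.17/0.10/0.04/0.03, mirroring real substrate
sets where the two largest classes hold about two thirds of records and
the two smallest about 7%. The enzyme world plants 1–3 proteins per EC
across six genomes with full lineages, one clear winning hit and one
weaker eligible hit each, decoys failing single cutoffs, and dedicated
rows sitting exactly on 40/80/1e-15.

What the fixtures do not emulate: real within-class chemical diversity,
overlapping scaffolds between classes, noisy or conflicting EC
annotations, and realistic alignment-score distributions. Perfect
accuracy on `separable6` therefore validates the implementation, not
real-world predictive performance.

## Problem sizes and numerical choices

Tests and the acceptance script run on the 360-record preset with a
two-family hybrid (maccs166 + pattern1024), ntree 300 for protocol
evaluation and ntree 500 for final models — sizes chosen so the full
suite exercises every code path in about a minute on one CPU while
leaving the statistics (10-fold CV, 36-molecule blind set) meaningful.
Floating-point comparisons in the search use a 1e-12 improvement margin;
seeds propagate from a single integer (per-fold and per-class-model
seeds are derived offsets) and keep below 2^31 for the forest
implementation.

## Known limitations

Only the first biotransformation step is modelled — no products, no
multi-step metabolism, and no enzymes outside the predicted subclass.
The class-level model caps the whole cascade: a wrong class cannot be
recovered downstream. EC transfer by best alignment hit inherits that
method's known failure modes (promiscuous families, horizontal
transfer). Probabilities are raw forest vote fractions, uncalibrated.
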