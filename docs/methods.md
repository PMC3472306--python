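# Methods

This note documents the models implemented in `tfbslens`, the choices made
where the procedure admitted more than one reading, and what the synthetic
worlds do and do not establish.

## Feature definitions

**Sequence.** For a segment of the PWM's length, the score is
`Σ_j f(b_j, j) · C_j` with `C_j = Σ_i f_ij log2(f_ij / P_i)`; the convention
`0·log 0 = 0` applies, no pseudocount is added to `f` for scoring (a
zero-frequency base contributes zero), and the background `P` defaults to
uniform 0.25 (it may be replaced by the mononucleotide frequencies of the
fitted background chain). Both strands are evaluated and the larger score is
kept, so the feature is invariant under reverse complementation. When an
instance is longer than the PWM, the best-scoring window is used — curated
site lengths vary around the matrix length, and the best window is the
natural reading of "the site's similarity to the matrix". The score is the
raw, unnormalized sum; the Match-style **control** score is its min–max
normalization `(Current − Min)/(Max − Min)` over the possible per-position
extremes, which lies in [0, 1] and equals 1 for the consensus.

**Structure.** Mean of the attribute value over the `n−1` overlapping
dinucleotides, computed on the segment as written (the defining formula makes
no strand statement, so no strand flip is applied). The bundled default
property table (`data/dinucleotide_properties_synthetic.tsv`) is a synthetic
stand-in for a curated compendium: three rows are the unified
nearest-neighbor thermodynamic scales (duplex ΔG°37, ΔH°, ΔS°; SantaLucia
1998, kcal/mol and cal/mol·K), the other 35 are synthetic scales frozen once
from a seeded draw with literature-like locations and spreads. All downstream
code treats the table as opaque (only its shape and attribute identity
matter); analyses that need a *real* structural interpretation of individual
attributes should substitute a curated table via `read_property_table`.

**Evolution.** The maximal conservation score among catalog motifs whose
similarity to the segment reaches the threshold (default 0.95), else 0.
Similarity is the best ungapped overlap of the shorter string slid along the
longer, over both strands of the segment, scored as the fraction of
positions of the shorter string compatible with the IUPAC code — the
simplest alignment-free similarity for which a 0.95 threshold is meaningful
(conserved motifs are strandless, hence the double-strand scan).

## Background model and datasets

Negatives come from an **order-3 Markov chain** (no hidden states — nothing
in the procedure identifies any) fitted on promoter sequences with add-one
smoothing, emitting 5 kb pseudo-promoters that are tiled into non-overlapping
windows of the TF's average site length (nearest integer); per TF, ten
balanced sets each combine all positives with an equal-size draw from this
pool (without replacement within a set, independent across sets).

## Recognition models and evaluation

Trees are grown with scikit-learn's entropy criterion (minimum leaf size 2)
and post-pruned by **reduced error** on a held-out, stratified 10% of the
training data: bottom-up, a subtree collapses to a leaf unless it saves
strictly more than one held-out error. The one-case margin keeps a single
lucky holdout case from preserving a spurious split; on label-independent
data the tree collapses to a near-stump, while strongly separating splits
survive. Class scores are the leaf's positive fraction. Everything is
deterministic under a seed.

The **hybrid** model applies correlation-based feature selection (CFS) to
the 40-column block inside each training fold: merit
`k·mean|r_cf| / sqrt(k + k(k−1)·mean|r_ff|)`, maximized by best-first
forward search that stops after five non-improving expansions; merit ties
(e.g. a duplicated feature) resolve to the smaller subset, and an empty
result falls back to the single best-correlated column.

The **control** model thresholds the Match-style score at a cutoff chosen on
the training folds by maximizing specificity subject to positive
sensitivity, reproducing the characteristic high-specificity /
low-sensitivity control profile.

Evaluation is stratified 10-fold cross-validation. Feature values are
per-instance constants with no training-set dependence, so they are computed
once per instance set; only CFS and the control cutoff — the
training-dependent steps — run inside the fold (a property test verifies the
selection never sees test-fold rows). Confusion counts and scores are pooled
(micro-averaged) over folds, which is stable for sets of tens of instances;
sensitivity, specificity and accuracy follow their defining ratios (an empty
denominator yields NaN, never a silent zero) and AUC is the rank-based
Mann–Whitney statistic with half-credit ties. A suite summary reports mean,
SD and the 5/25/50/75/95th percentiles per model and metric.

## Correspondence analyses

**Sequence level.** Clustering emulates blastclust semantics: two sequences
link when a local alignment (BLOSUM62 with gap −11/−1 for proteins; +1/−2
match/mismatch, gap −5/−2 for DNA) covers at least the fraction `L` of
*both* sequences with at least `S`% identity over the aligned columns;
clusters are single-linkage components. An ungapped overlap is itself a
local alignment, so a fast ungapped screen can confirm (never deny) a link
before the affine aligner runs. Exact agreement with the NCBI binary is not
promised. Each TFBS cluster is rewritten to its set of owning TF names; a TF
cluster matches when >90% of it lies in one rewritten cluster or the
intersection rate `|A∩B|/|A∪B|` exceeds 2/3; the match rate is the fraction
of TF clusters with a match. The association test — left undefined by the
procedure — is a one-sided Fisher exact over unordered TF pairs, crossing
"same TF cluster" with "co-occurring in some rewritten TFBS cluster".

**Structure level.** Attribute frequency is the fraction of trained
structure/hybrid trees whose pruned tree splits on the attribute at least
once. A 10,000-replicate bootstrap (resampling the 38 frequencies) of the
75th quantile yields a 2.5/97.5 interval; attributes strictly above the
interval midpoint are selected ("midpoint" being the deterministic reading
of the interval's middle; a flat profile selects nothing). Binding sites are
then encoded through the five highest-frequency selected attributes — a
fixed 5-dimension encoding, matching the dimensionality the original
analysis used — as the per-TF mean over positive sites. The class number is
chosen by BIC over Gaussian-mixture fits (k = 1..10) with **tied** full
covariance: the structure attributes all derive from the same dinucleotide
counts and are strongly mutually correlated, which a diagonal model
systematically misreads as extra components. Assignment is by K-means
(k-means++, 50 restarts, seeded); each annotated TF class maps to its
best-overlapping cluster and is "mapped" when the rate exceeds 0.9.

**Evolution level.** TF conservation is the ortholog count divided by the
reference species count (the packaged 270-TF table's granularity is
consistent with a denominator near 96); TFBS conservation is the mean
evolution feature over the TF's positive sites. Correspondence is Spearman's
rank correlation with average ranks, one-sided positive p-value via
`t = ρ√((n−2)/(1−ρ²))` on n−2 degrees of freedom. On the packaged table this
gives ρ = 0.122, p = 0.023 (computed, not asserted).

## Synthetic worlds

The generator emulates the statistical shape of a curated TF compendium.
Defaults (the package's study conditions): 4 families × 5 TFs, protein
length 120, within-family per-site substitution 0.05 versus 0.5 between
families; PWM length 16 with Dirichlet concentration 20 around a family
consensus (consensus probability ≈ 0.87) and small member-level
perturbations; 30 sites per TF (the inclusion rule demands more than 10);
a 174-motif catalog with scores uniform on [1, 100]; a flank of 10 nt on
the right of each site copying a family template with 10% per-base
mutation; promoters (50 × 2 kb ≈ 100 kb) from i.i.d. draws with base
probabilities A/C/G/T = 0.30/0.20/0.20/0.30 — a degenerate Markov process
that the pipeline still summarizes with its order-3 chain.

Two design points deserve explanation:

* **Flanks carry the evolution signal.** Embedding a catalog motif *inside*
  a PWM-sampled core would destroy the sequence signal; placing it in a
  family-templated flank keeps the three signals separable, keeps sites of
  one family mutually alignable (so sequence-level clustering can recover
  families), and is biologically reasonable (conserved motifs adjacent to
  the core site).
* **One copula latent drives the conservation plant.** The Spearman
  correlation between TF conservation and the mean evolution feature is
  planted by a Gaussian copula (`r = 2 sin(πρ/6)`): one latent uniform maps
  to the ortholog count (binomial quantile, n = 96, rate 0.35), its
  correlated partner maps to *both* the TF's motif-embedding probability
  (uniform on [0.3, 0.95]) and the rank of its assigned motif in the
  score-sorted catalog. Making the motif's score comonotone with the
  embedding rate removes multiplicative score noise that would otherwise
  attenuate the planted correlation far below target; residual attenuation
  from finite sites is small relative to sampling error at n = 270.

`plant_structure_classes` rebuilds a world with 2–4 structure classes whose
consensus templates are biased toward a class marker base with probability
`p`; members share the class template exactly (per-TF drift would put
TF-level sub-structure inside a class and the mixture criterion would count
TFs instead of classes), sites are resampled at consensus probability 0.9
with background flanks and no motif embedding. `p` is calibrated inside the
generator by an analytic criterion: from the realized column distributions,
the expectation and variance of each attribute score are computed in closed
form (including the covariance of adjacent dinucleotide terms), and the
smallest grid `p` is taken for which the worst class pair's joint Euclidean
separation over the five best attributes reaches the requested number of
within-class standard deviations.

Problem sizes used by the test suite and the acceptance script are the
package's own scaled choices: the recognition suite runs on the default
20-TF world; the sequence-level analysis uses 16 families × 4 TFs × 10
sites (many small families, so a randomly permuted TF↔site pairing cannot
trivially re-match); the structure-level analysis uses 4 × 10 TFs; the
null calibration of the conservation test runs 100–200 replicates at
12 sites per TF and a 60-motif catalog.

## What the synthetic results do and do not show

Passing recoveries demonstrate that the pipeline is implemented coherently —
each stage finds exactly the structure its generator planted, at the stated
strengths. They do not certify performance on real curated data: real PWMs
are shorter, dirtier and mutually dependent; real promoters have
heterogeneous composition far beyond order-3 statistics; real protein
families are not i.i.d. mutants of a root; the real attribute values of the
property table differ from the bundled stand-in; and real conservation
scores mix database biases this model does not attempt to imitate.
Quantities reported for the packaged 270-TF conservation table are the
exception: that input is real, and its Spearman test is exactly
reproducible.

## Numerical notes and degenerate inputs

PWM rows are renormalized on construction (so count and frequency dialects
read identically); a zero-total row is a format error. A zero background
probability under a positive frequency is a domain error. The Match score
returns 1.0 when a matrix is completely uninformative (Max = Min). Motif
similarity thresholds compare against `ceil(0.95·m − ε)` matches to avoid
float-boundary misses. Ties in the control cutoff grid resolve toward
higher specificity, then higher sensitivity; CFS merit ties resolve to the
smaller subset; K-means and mixture fits are seeded with fixed restart
counts. Undefined metrics (empty denominators, single-class AUC, constant
conservation columns) raise or return NaN explicitly rather than silently
returning zero.
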