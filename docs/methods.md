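# Methods

## Model and assumptions

The package prioritizes candidate disease lncRNAs under one assumption:
lncRNAs involved in the same disease are functionally similar, and an
un-annotated lncRNA inherits the functional profile of the mRNAs it
competes with for shared miRNAs. Everything downstream is rank-based,
so any monotone rescaling of a similarity backend leaves results
unchanged.

### ceRNA inference

Each (lncRNA, mRNA) pair sharing at least one miRNA is tested with the
hypergeometric upper tail P(X ≥ x). Pairs with zero overlap are not
hypotheses: including them would inflate the Benjamini–Hochberg family
arbitrarily without changing which pairs can be significant. The miRNA
universe N is the set of distinct miRNAs in the combined interaction
table (the compiled interactome is the relevant population, not a
genome-wide constant). The default threshold is adjusted p < 0.01;
alpha = 1.0 is accepted as a degenerate setting that retains every
tested pair whose adjusted p is strictly below 1. A transcript id may
not appear as both lncRNA and mRNA (self-competition is excluded by
typing), and duplicate input rows are dropped with a warning.

### Ontology similarity

Gene-pair similarity is the information content of the most informative
common ancestor, IC(t) = −ln(n_t/N) with counts taken after true-path
propagation over both `is_a` and `part_of` links. Propagated counts are
required for the monotonicity IC(child) ≥ IC(parent) that "most
informative common ancestor" presupposes. A term is its own ancestor,
so FS(g, g) is the IC of the gene's rarest term. The natural logarithm
is used; ranks are invariant to the base. N defaults to the number of
annotated genes but can be pinned to a genome-wide constant through
`genome_size`. Unannotated genes contribute pair similarity 0; an
lncRNA none of whose competing genes is annotated is excluded from that
context's ranked list rather than scored 0 (missing annotation is not
evidence of dissimilarity).

### Network similarity

FS = 1/d for unweighted shortest-path distance d, computed by cached
single-source breadth-first searches (unit-cost Dijkstra and BFS
coincide; no edge confidences are modeled). Conventions: FS(g, g) = 1
(identity must not score below adjacency); unreachable or absent genes
score 0, mirroring the ontology convention. Loaded edge lists are
reduced to simple undirected graphs: self-loops removed, reversed
duplicates merged.

### lncRNA scoring and fusion

Two lncRNAs score the flat mean over all m×n competing-gene pairs, as
is — no size normalization beyond the mean; profile-size effects are
absorbed by the rank step. A candidate's context score is the mean over
seeds with defined similarity. Tied scores share average ranks, keeping
rank ratios well defined and the null unbiased.

The Q score is the joint tail probability of uniform order statistics
at the observed rank ratios. The alternating recursion is evaluated in
the rescaled form W_k = k!·V_k, whose coefficients are exact integer
binomials, with compensated summation (`math.fsum`); at the boundary
(all ratios 1) the result is exactly 1 with no factorial rounding. At
most nine sources are fused, so cancellation is mild; the Monte-Carlo
cross-check in the tests bounds the error at 10^5 draws. Candidates
missing from some contexts are scored over the contexts that contain
them with N reduced (recorded as `n_sources`), not imputed r = 1.
Output ordering breaks exact (Q, n_sources) ties lexically for
determinism, but `final_rank` averages over tied Q values: a forced
lexical rank would systematically order held-out lncRNAs against
decoys by id prefix in cross-validation and bias the null AUC.

### Evaluation

LOOCV holds out each seed of each disease (≥ 2 seeds required), adds
99 uniformly sampled decoys without known association to that disease
(without replacement, seeded generator), and records the held-out rank
among the 100 candidates. ROC convention: the held-out lncRNA is the
single positive per run; at cutoff k, sensitivity is the fraction of
runs with rank ≤ k and the false-positive rate is the fraction of
pooled decoy positions ≤ k. The trapezoidal AUC then equals the
Mann-Whitney U estimator of P(positive outranks a random decoy), which
the tests assert to 1e-9, and reproduces the calibration endpoints
exactly: always-first gives AUC 1.0, always-last 0.0, uniform ranks
≈ 0.5. Per-disease curves restrict the pooled runs to one disease.
The validated-versus-random group comparison collects within-group
pairwise lncRNA similarities for each disease seed set and for
size-matched groups drawn from a supplied random pool, and reports a
one-sided Mann-Whitney U p-value (validated > random).

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the method exploits,
with one shared seed driving independent substreams per component:

* **Interactome** — every transcript draws 8 of 150 miRNAs; planted
  pair i (lncRNA i, mRNA i) shares
  `overlap_background + signal·(overlap_planted − overlap_background)`
  miRNAs (all 8 at full signal, forcing x = K), background mRNAs draw
  uniformly. Chance background overlaps of 4+ miRNAs occur and are
  *correctly* retained by the test; recovery assertions therefore check
  planted ⊆ retained with few extras rather than equality.
* **Ontologies** — three namespaces, each a depth-4 branching-3 tree
  with ~20% extra `part_of` parents (diamonds). Each of 8 gene modules
  owns one deep term (IC = ln 8 at 25 of 200 genes); every gene also
  carries one random shallow term, giving background pairs small but
  nonzero similarity.
* **Networks** — six stochastic-block-model graphs over the same module
  partition (p_within = 0.35, p_between = 0.02), so within-module paths
  are stochastically shorter.
* **Disease benchmark** — 30 diseases × 10 seeds (300 validation runs,
  comparable to the few hundred associations of a curated disease-lncRNA
  database) over 420 lncRNAs, leaving a 120-lncRNA decoy pool (> 99
  needed per run). A fraction `signal_strength` of each seed's 6
  competing genes comes from the disease's module; decoys draw
  uniformly.

Not emulated: realistic GO topology and term-depth distribution,
scale-free degree distributions of protein networks, correlated
evidence across the six networks, literature-biased annotation depth,
and disease co-morbidity structure. Passing tests therefore demonstrate
the machinery is correct and well calibrated (nulls at AUC ≈ 0.5,
planted signal recovered), not that real-data AUC levels are
reproduced — those depend on external databases outside the package.

## Numerical and degenerate-input choices

* Hypergeometric tails via `scipy.stats.hypergeom.sf(x−1, N, K, M)`;
  the x = 0 tail is returned as exactly 1 (covers the empty-universe
  corner scipy leaves undefined).
* BH adjustment via `scipy.stats.false_discovery_control`,
  cross-checked against an independent implementation in the tests.
* Empty profiles propagate as "absent" (`None`), never 0; a candidate
  absent from every context is skipped in LOOCV with a warning.
* LOOCV iterates diseases and seeds in sorted id order and sorts decoy
  indices after sampling, so results are bit-for-bit reproducible for a
  given seed and independent of container ordering.
* Pooled ROC requires a common candidate count; runs with an atypical
  count (possible only when candidates drop out of all contexts) are
  excluded with a warning.

## Problem sizes

Defaults were chosen once as realistic desk-scale conditions: 300 LOOCV
runs × 9 contexts × 100 candidates complete in well under a minute per
signal level on one CPU, with gene-pair and lncRNA-pair similarity
caches making repeated ranking cheap. The acceptance script's
calibration endpoints use 600 perfect runs and 1000 uniform runs of the
ROC machinery alone and complete in seconds.

## Known limitations

* The two-column interaction/annotation readers sniff headers
  heuristically; exotic headers may need stripping.
* `fuse_ranks` assumes rank ratios from lists of comparable length;
  fusing wildly different list lengths is meaningful only through the
  rank-ratio normalization.
* GAF support covers the common case (object id, term, NOT qualifier);
  evidence-code filtering is deliberately out of scope.
* Only `is_a`/`part_of` ancestry and unweighted networks are modeled;
  other similarity flavors (Lin, Wang, diffusion kernels) are
  non-goals.
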