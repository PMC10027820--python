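# Methods

## Pipeline

A reader × text unit of analysis flows through four stages:

1. **Fixation ingestion and cleaning** (`fixation_io`). Word-level fixation
   reports (CSV/TSV with configurable column names, defaulting to EyeLink
   Data Viewer conventions) are parsed into records; rows with unparseable
   numerics are collected into a rejects report rather than silently
   dropped. Fixations shorter than 40 ms or longer than 1000 ms are
   excluded; the boundary values themselves are kept, reading
   "shorter/longer than" strictly. Cleaning is idempotent and
   order-preserving. The module assumes fixations already carry word
   (sentence index, word index) assignments; vertical drift correction is
   an acquisition-side concern and out of scope here.
2. **Scanpath extraction**. Records are ordered by onset (ties broken by
   input order and logged — a monocular high-rate tracker should never
   produce true ties) and mapped to canonical node keys: lower-cased,
   outer punctuation stripped, internal hyphens/apostrophes kept. This is
   what merges "Could", "could" and "could?" onto one node. How
   punctuation-attached tokens were segmented into areas of interest is
   not observable from a fixation report, so canonicalization is a
   declared convention of this package, not a recoverable fact.
3. **Network construction** (`network`). Consecutive fixations on
   different words increment a directed edge weight; consecutive
   refixations of the same word add nothing (all metric formulas sum over
   ordered pairs of distinct nodes, and the adjacency diagonal stays
   empty). Consecutive fixations across a sentence boundary do form an
   edge: recurring topic words link sentence-level paths into one
   text-level network. Total edge weight therefore equals the number of
   between-word transitions. The canonical in-memory object is directed;
   the symmetrized matrix (cell = w_ij + w_ji) is a presentation view
   only and cannot be converted back.
4. **Metrics** (`metrics`) and **reader statistics** (`stats`), below.

## Metric conventions

- **Degree/strength.** Throughout, `k_i = Σ_j (w_ij + w_ji)`: the total
  saccade weight landing on plus departing a word.
- **Centralization.** `C = Σ_i (C_max − C_i)/((N−1)(N−2))` with
  `C_i = k_i`. With weighted strengths the classic [0, 1] bound does not
  hold (it is a binary-graph property); a `binarize` flag restores it by
  counting each stored edge as 1. The topology bands (linear /
  hierarchical / network / star) use half-open bins [0, 0.2), [0.2, 0.4),
  [0.4, 0.6), [0.6, 1]; out-of-range inputs are clamped with a warning.
- **Transitivity.** The directed-weighted form with
  `t_i = ½ Σ_{j,h} (w_ij+w_ji)(w_ih+w_hi)(w_jh+w_hj)` (j, h ≠ i, j ≠ h)
  and denominator `Σ_i [k_i(k_i−1) − 2 Σ_j w_ij w_ji]`. Raw weights are
  used as written — no cube-root normalization of the kind common in the
  directed-weighted clustering literature (a flagged alternative could be
  added, but the default is fidelity to the formula above). On binary
  symmetric graphs this reduces exactly to the classic global clustering
  coefficient (triangles over triples), which the test suite verifies by
  exhaustive enumeration. A network with no connected triples returns 0
  with a warning instead of dividing by zero.
- **Distances and efficiency.** Edge length is `1/w` (stronger transitions
  are shorter); all-pairs shortest paths come from Dijkstra on the sparse
  length matrix, respecting direction. Unreachable pairs have infinite
  distance and contribute zero inverse distance to `E`, which keeps `E`
  defined on disconnected (e.g. masked) networks.
- **Characteristic path length.** Two modes, always recorded in the
  result: `mean_distance` (default) is the mean shortest distance over
  reachable ordered pairs — the standard definition; `as_printed` is the
  mean *inverse* distance, which is algebraically identical to global
  efficiency. Both are exposed because the two published formulas
  coincide; the default follows the standard meaning of the term.
- **Clustering.** `C_clust = (1/n) Σ_i 2t_i/(k_i(k_i−1))`; nodes with
  `k_i(k_i−1) ≤ 0` (isolated nodes, leaves, fractional strengths below 1
  on averaged networks) contribute zero — degenerate leaves are common in
  scanpath networks and should not raise.
- **Small-worldness null model.** The reference ensemble keeps the node
  count and the directed edge count fixed — the stated constraint — and is
  otherwise maximally agnostic: each reference draws its edges uniformly
  at random without duplicates or self-loops and permutes the original
  multiset of weights onto them. Defaults: 20 references, explicit seed;
  `C_rand` and `L_rand` are ensemble means, and the same L mode is used
  for the network and its references. A degree-preserving rewiring null
  would hold more structure fixed; it is deliberately not the default
  because the constraint being modeled is "same number of nodes and
  edges", nothing more.
- Tolerances: metric unit tests assert at 1e−9 absolute; stochastic
  small-worldness checks are confidence-interval based.

## Masking and averaging

Group-average networks are edge-wise means over readers with the node set
equal to the union of reader node sets and absent edges counted as zero —
the only alignment under which the mean is well defined when readers
fixate different word subsets. The visualization mask removes edges with
weight ≤ 0.3 first, recomputes degrees on the edge-filtered graph, then
removes nodes with degree ≤ 5 (both strictly "greater than"); edge-first
ordering is deterministic and matches the mask's purpose of dropping
low-representativeness structure. Thresholds are configurable, and the
mask can be applied to averaged (fractional) or individual (integer)
networks; the defaults target averaged networks, where fractional weights
like 0.3 are meaningful. A fully sub-threshold network masks to an empty
network with a warning rather than an error.

## Reader statistics

The comprehension ability score is a within-cohort composite:
`z(assessment) + z(reading-test score) + z(max RT − RT)`, with reading
time reversed against the cohort maximum so that faster reading scores
higher, sample (n−1) standard deviations, and equal weights. Group
comparisons use Student's pooled-variance t (df = n1 + n2 − 2) and
Cohen's d on the pooled SD — the convention under which a 26 + 26 median
split reports df = 50. The median split is stable: ties at the boundary
break by participant id (logged), and an odd cohort places the median
reader in the lower group. Correlation tables report exact two-tailed
p-values from the t transform of r; significance starring is left to the
caller. No multiple-comparison correction is applied.

## The synthetic reader

The simulator exists to make every pipeline stage and every directional
claim testable without recorded eye-tracking data. It is deliberately
minimal — no lexical-frequency model, no parafoveal-preview machinery, no
E-Z Reader-class process model — because a rich cognitive model would
imply a fidelity the package cannot claim.

**Texts** emulate ~30-sentence / ~300-word expository passages: ~35% of
slots hold closed-class function words; content slots draw from a
pseudo-word vocabulary with mildly skewed reuse (a handful of content
words recur in a few sentences, none pervasively); and 2 designated topic
words recur in at least half of the sentences each, with low within-
sentence co-occurrence. Topic recurrence is what gives even a plain
sequential read hub structure.

**Readers** walk each sentence left to right. Per word they skip with a
class-specific probability; per fixation they refixate with `p_refix` and
regress with `p_regress`, landing on a uniformly chosen non-topic word up
to `regress_span = 3` words back and then resuming. Regressions stay
within the sentence, matching sentence-by-sentence presentation.
Recurring topic words are never skipped — they anchor comprehension for
readers of every skill level — and are not regression targets, since
readers re-check difficult material, not the topic terms they already
know. Fixation durations are Gaussian (per-profile mean/SD), truncated to
the 40–1000 ms cleaning window so simulated fixations survive cleaning
unchanged.

**Skill presets** encode the canonical empirical contrast: the skilled
profile skips more (0.55 function / 0.25 content vs. 0.20 / 0.08),
regresses less (0.05 vs. 0.20), refixates less (0.07 vs. 0.22) and
fixates faster (200 ± 60 ms vs. 260 ± 90 ms). Under these presets, across
paired simulations of the same text, skilled readers' networks have lower
density, transitivity and global efficiency and higher centralization —
the same sign pattern the metrics show empirically. Mechanistically in
this generator: regressions and refixations add transitions without
adding nodes (density, efficiency and triangles up for less skilled
readers), while the fixed-size topic hub is relatively more dominant in
the skilled readers' smaller networks (centralization up for skilled).

One scale effect is worth knowing: the density direction is text-length
dependent. On very short texts (~12 sentences), heavier skipping *raises*
density because the `N(N−1)` denominator shrinks faster than the
transition count; at the ~30-sentence scale the generator targets, the
expected direction (more skipping → lower density) holds. Directional
tests therefore run at full text length for density and at reduced length
for the other, scale-stable effects.

**Cohorts** place readers along a linearly interpolated skill spectrum;
behavioral outcome components are monotone functions of skill plus
Gaussian noise (assessment accuracy, reading-test score, total reading
time), so with the noise scale at zero the ability rank order equals the
skill rank order exactly. All generation is reproducible from a single
seed.

What passing simulation tests does and does not show: they demonstrate
that the pipeline's metrics respond to skips, regressions and topic
recurrence in the directions the underlying theory predicts, under a
generator built to encode exactly those mechanisms. They do not
demonstrate recovery of effect sizes from real eye movements, which
involve lexical, oculomotor and strategic structure this generator does
not model.

## Problem sizes

Default analysis problem sizes were chosen to keep any single check
seconds-scale: directional contrasts use 500 paired simulations of one
30-sentence text; small-world checks use 100-node lattices with 20-member
reference ensembles; exhaustive oracle verification covers all undirected
graphs on up to 5 nodes and all digraphs on 3 nodes, plus seeded random
weighted digraphs on 4–5 nodes.

## Known limitations

- Networks are per text; no multilayer or time-resolved (sliding-window)
  variants.
- Centralization with weighted strengths is unbounded above 1 on dense
  weighted graphs; use `binarize=True` when the [0, 1] interpretation or
  the topology bands matter.
- The `(x, y) → word` assignment step (drift correction, line assignment)
  is assumed done upstream.
- The simulator's reading-time outcome component is modeled from skill
  rather than accumulated from the simulated fixation durations, trading
  realism for an exact zero-noise rank-order guarantee.
- Small-worldness on very small or very sparse networks is fragile: the
  random ensemble's clustering can be zero, in which case the metric is
  reported as undefined rather than guessed.
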