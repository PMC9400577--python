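# Methods

## Model

A textual forma mentis network (TFMN) is an undirected, simple, multiplex
graph over content-word stems. It is built sentence by sentence:

- **Syntactic layer.** Each sentence is represented as a dependency tree.
  Two content words are linked when their tokens sit at undirected path
  distance ≤ *T* on that tree. Distance is computed on the *full* tree —
  function words count as path vertices — and only afterwards are
  non-content endpoints discarded; removing stopwords before measuring
  would distort tree metrics. Whether distances should instead follow head
  direction is an open modelling question; the undirected convention is
  used throughout and is the natural one for an undirected output graph.
- **Synonym layer.** Once the node set is fixed, every synonym pair whose
  two stems both occur in the graph gains a synonym flag on their edge.
  Synonymy never introduces nodes the corpus did not produce, and the layer
  is independent of *T*.
- **Attributes.** Nodes carry valence (positive/negative/neutral) and a
  subset of the eight Plutchik emotions from the lexicon; absent words
  default to neutral with no emotions.

Nodes are stems, not surface forms: tokens colliding under stemming merge
into one node. Duplicate pair occurrences collapse into a single edge with
unioned layer flags, so edge multiplicity carries no weight — the model is
about which associations exist, not how often they repeat.

The semantic frame of a target is its distance-1 neighbourhood on the
flattened (both-layer) graph, together with the induced subgraph. Frame
drawings show synonym links inside frames, so synonym adjacency counts as
frame membership; a syntactic-only mode is available. Frames are
partitioned with Louvain modularity maximisation (resolution 1.0, seeded
tie-breaking, community ids ordered by smallest member so the numbering is
reproducible). A subgraph with no edges partitions into singletons rather
than erroring, since modularity is undefined there.

## Emotion inference

For the set of m unique stems in a frame (the target excluded), the
observed count c_e of stems tagged with emotion e is compared with the
counts found in `n_samples` (default 300) random samples of m words drawn
uniformly **without replacement from the lexicon vocabulary**. The z-score
(c_e − μ_e)/σ_e uses the sample mean and ddof = 1 standard deviation over
those draws. Emotions are flagged `over`/`under` when z exceeds ±`z_star`
(default 1.96, the 0.975 standard-normal quantile); a null standard
deviation of exactly zero (e.g. an emotion carried by every lexicon word)
is reported as an explicit `degenerate` flag, never as ±∞.

Two design points deserve emphasis:

- **Unique words, matched cardinality.** The frame is scored as a set; the
  null matches only the set's cardinality. Matching token frequencies or
  corpus-weighted sampling would ask a different question (is this text
  unusual for this corpus?) than the one intended (is this association set
  emotionally unusual relative to neutral language?).
- **Uniform sampling of the lexicon**, not of the corpus, defines "neutral
  language" as the lexicon's own emotion base rates.

An empty frame yields the all-zero profile with every flag `ns` — a
documented convention, so downstream time series can treat missing targets
as unremarkable days rather than errors.

## Time series

Daily series group articles by calendar day (only days with at least one
matching article appear; other days are gaps, not zeros). Each day's
matching articles give one frame profile; per-emotion z-scores are smoothed
with a **trailing** moving average over the last `window` (default 7)
defined days. An emotion is *persistent* when its smoothed |z| exceeds the
gate on at least `persistence` (default 0.5) of its defined days; the
boundary counts ("at least half"). Prevalence series use the same trailing
smoothing on per-class daily mention fractions. The relative change of a
series around an event is the percent difference between the mean over an
event window (date ± 2 days by default) and the pooled mean over two
reference windows (defaults: first five and last five days of the event
month); a zero reference mean raises an explicit undefined-baseline error.
The same convention covers degree change between two networks, where a
target absent after the event counts as degree 0 (−100%) but a target
absent before has no baseline.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `T` | 4 | max tree distance for a syntactic link (dimensionless hops) |
| `n_samples` | 300 | null-model resamples per profile |
| `z_star` | 1.96 | significance gate on \|z\| (0.975 normal quantile) |
| `window` | 7 | trailing smoothing window, days |
| `persistence` | 0.5 | fraction of days required outside the gate |
| stemmer | Snowball Italian | node identity; lexicon/synonym keys pass through the same stemmer |

The Snowball Italian stemmer is implemented in-package from the published
algorithm definition (prelude, RV/R1/R2 regions, attached-pronoun,
standard-suffix, verb-suffix and residual steps). It over-stems proper
nouns (`pfizer` → `pfiz`); this is harmless because query targets pass
through the same stemmer as corpus text, so matching stays consistent.
Content words are identified by POS tag (NOUN/PROPN/VERB/ADJ/ADV) when the
parse provides tags, otherwise by an Italian function-word stopword list
bundled in `emoframes.stopwords`; both the list and the stemmer are
swappable per call. The published method does not pin a stopword list, so
the bundled list is this package's explicit default rather than an attempt
at replication. Bodies are never truncated.

## Parsing

No trained parser is bundled. The fixture parser honours explicit
per-sentence `heads`/`pos` annotations carried by corpus records (the
synthetic generator always emits them) and otherwise falls back to a chain
parse — head of token i is token i−1 — under which tree distance reduces to
|i − j| and co-occurrence-window behaviour is recovered as a degenerate
case. A neural parser can be registered as an adapter; its output is
validated against the single-rooted-tree invariants before use.

## Synthetic data

The generator emulates the statistical structure the pipeline must detect:

- dated articles from two source classes (defaults: 4 mainstream + 3
  alternative per day) whose titles and bodies contain a target stem;
- frame sentences in which the target is the tree root and its k = 4
  sampled neighbours attach directly to it, so frame membership is exact
  ground truth at any T ≥ 1;
- per-emotion enrichment: each neighbour slot draws from the e-tagged
  vocabulary with probability δ_e, else uniformly from the whole
  vocabulary;
- optional event peaks multiplying a stem's mention probability inside a
  date window;
- share counts from a latent bivariate log-normal popularity factor
  (log-sd 1.0; medians ≈ 300 Facebook and ≈ 14 Twitter shares, matching the
  typical mass of real re-share distributions, with heavy upper tails).
  The latent normal correlation is calibrated analytically —
  r = log(1 + ρ(e^{s²}−1))/s² — so the *count-scale* Pearson correlation
  targets ρ; likes are Poisson given shares (rates 0.64 and 1.74 per
  share). At n = 2000 the sample Pearson estimate has a standard deviation
  of about 0.05 under these heavy tails, so single-corpus estimates
  scatter accordingly.
- synthetic lexicons: 2000 invented stems, each emotion tagged
  independently at 8% (NRC-like sparsity), valence 30/30/40
  positive/negative/neutral.

What the generator does **not** emulate: real Italian grammar and
morphology, topic structure, outlet-specific style, correlated emotions
(tags are independent), or bursty publication schedules. Passing recovery
tests therefore shows the statistical machinery is correct and calibrated —
not that any particular real-world corpus conclusion transfers.

## Verification

The test suite checks every operation against an independent oracle where
one exists: all-pairs BFS for tree distance and syntactic edges, exhaustive
enumeration of all C(6,2) lexicon subsets for null moments, exhaustive
modularity search over all 4140 partitions of 8 nodes for the Louvain
check, brute-force trailing windows for smoothing, and closed-form Pearson.
Calibration uses 200 replicates of 50-word uniform sets (mean z within
±0.15, false-positive rate between 1% and 12%); recovery uses 50 seeded
fear-enriched corpora (δ = 0.4; flagged in ≥ 90% of seeds, with ≤ 15% false
alarms per other emotion). Problem sizes (5-day recovery corpora, 400-word
lexicons for recovery, 2000-word for calibration) were chosen as the
smallest at which these statistical properties are comfortably
identifiable.

## Known limitations

- Frames are distance-1 neighbourhoods; an alternative reading — whole-graph
  communities containing the target — is supported only insofar as the
  frame subgraph is itself partitioned.
- Edges with exactly one neutral endpoint are drawn grey (least emphasis);
  the colour code for that case is a package decision, not a published
  convention.
- The Wilcoxon rank-sum engagement comparison uses per-article
  likes-per-share units; per-outlet aggregation is not implemented.
- The stemmer's proper-noun over-stemming merges distinct brand inflections
  aggressively; a custom stemmer can be registered when that matters.
- Daily z-scores can be computed on frames (default) or on full article
  word lists (`mode="article_words"`); the two disagree when articles
  mention a target only in passing.
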