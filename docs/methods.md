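# Methods

This note documents the models, defaults and design choices behind txscout:
what each stage computes, why the defaults are what they are, what the
synthetic corpus does and does not emulate, and where the open design
decisions were resolved.

## Corpus model

A corpus is a genes × samples matrix of non-negative integer counts plus
sample records (accession, parent study, condition label, free text, source
name) and study records (accession, title, summary, overall design). The
HDF5 layout follows ARCHS4 v2 naming but is declared through a configurable
`H5Layout` map, because corpus dialects drift across versions. Gene identity
is the case-sensitive symbol string — the convention shared by ARCHS4-style
corpora and GMT gene-set files. Study text for embedding is the
concatenation `title + " " + summary + " " + overall_design` with empty
fields skipped; which per-sample fields feed `sample_text` is part of the
layout, since corpora differ in where condition information lives.

## Text embedding

The embedder contract is minimal: a name, a fixed output dimension, and a
map from text to an L2-normalized vector (all-zero for token-free text).
Retrieval depends only on this contract, so the default hashing embedder and
a pretrained sentence-transformer adapter are interchangeable.

The default is a signed bag-of-words feature hasher, dimension 384 (chosen
to match the output width of compact sentence-transformer models such as
MiniLM, so the pipeline shape is identical whichever embedder is plugged
in). Tokens are lowercased alphanumeric runs. The bucket of a token is
FNV-1a-64(token) mod dim; its sign is bit 0 of FNV-1a-64(token + `\x00s`).
FNV-1a is fixed by its published offset/prime constants
(0xcbf29ce484222325, 0x100000001b3), so vectors are reproducible across
processes and platforms with no seed and no dependence on Python hash
randomization. Normalization happens at embed time; cosine similarity is
scale-invariant anyway, but normalized vectors make dot products directly
comparable.

A hashing embedder captures token overlap only — no synonymy, no word
order. That is sufficient for the synthetic topic vocabularies (below) and
for exercising every retrieval code path; semantic generalization on real
free text is what the sentence-transformer adapter is for.

## Transcriptome embedding

Counts are averaged within (study, condition) groups. The grouping rule is
configurable because "experimental condition" has no single operational
definition across corpora; the default uses the sample's condition label,
falling back to its source-name text, falling back to a singleton group per
sample. Profiles are kept on the raw mean-count scale by default (the
averaged-counts profile is the object being indexed); `log1p_cpm` is
available behind a flag for corpora with strong library-size variation.

The projection is a dense Gaussian Johnson–Lindenstrauss transform: a k ×
G matrix of i.i.d. N(0, 1/k) entries, fully determined by (G, k, seed).
Default k = 1000. The dense Gaussian form is the simplest construction
satisfying the JL lemma and is deterministic under one seed; sparse
(Achlioptas-style) projections would be faster at corpus scale but add a
second design degree of freedom for no accuracy gain at desk scale. For
k = 1000 the distortion of a pairwise distance concentrates within a few
percent (std ≈ sqrt(2/k) ≈ 4.5%), so the ±20% preservation band holds for
essentially all pairs; the acceptance script measures this directly against
exactly computed distances. When k exceeds the gene count the projector
warns (no reduction) but proceeds, which keeps small test corpora on the
default configuration path.

Gene-set queries are mapped into profile space as 0/1 indicator vectors
over the corpus gene universe and projected like any profile. This is a
design choice, not a derived fact: a membership indicator is the least
informative profile consistent with "these genes are up", and it suffices
because cosine similarity against condition profiles rewards mass on the
signature genes.

## Retrieval

All search is exhaustive cosine scan — exact by construction, O(n·d) per
query, entirely adequate below ~10^6 vectors. Ties break by lexicographic
id so ranked lists are reproducible; score ties are measure-zero for real
embeddings but common in constructed tests. Transcriptome hits are
per-condition and collapse to studies keeping each study's best score.

Expansion takes each stage-1 study's own vectors (its metadata row, or all
its condition rows) as queries, excludes the seed itself (a self-hit is
uninformative and the seed is already in stage 1), keeps the top `n_expand`
per seed, and unions the per-seed lists retaining each study's best
(score, seed) pair. Returned studies are ordered stage-1-first (rank
order), then stage-2 by score: stage-1 hits answer the query directly and
constitute the primary ranking; expansion appends context. Both stage sizes
default to 10 and are configurable; the `tune` command evaluates the
(n_search, n_expand) grid and deliberately takes no argmax — the grid is
serialized for inspection, since the two metrics it reports (enriched
samples, query cosine) need not agree on a single optimum.

Increasing `n_search` or `n_expand` only ever adds studies (monotonicity),
which the property tests assert.

## Enrichment scoring and the permutation filter

For one sample, genes are ranked by expression descending (ties by gene
id — determinism again), and with r_j = n − j + 1 the rank weight of
position j,

    P_in(i)  = Σ_{j≤i, g_j∈S} r_j^α / Σ_{g∈S} r_g^α
    P_out(i) = Σ_{j≤i, g_j∉S} 1/(n − |S|)
    ES       = Σ_i (P_in(i) − P_out(i)).

α defaults to 0.25, the standard single-sample GSEA weighting. At α = 0
every member gene weighs equally and ES is antisymmetric under ranking
reversal (the tests check this). Ranks are computed on raw counts; the
score is invariant to any monotone transform, so no normalization is
needed before scoring. ES is undefined when the set covers the whole
universe (P_out has denominator zero) or misses it entirely; both raise.

Significance: gene-membership labels are permuted (the same permutations
shared across samples, which lets one permutation's running sums be
computed for all samples at once), and p = (1 + #{ES_perm ≥ ES_obs}) /
(1 + n_perm) — never zero, exact under exchangeability of gene labels.
This null asks "is the observed concentration of the set at the top of
this sample's ranking surprising for a random gene set of the same size?",
which is the cheapest well-defined null at this scale; it does not model
inter-gene correlation, so on real data it is anti-conservative for sets
of co-regulated genes. Default n_perm = 199 gives a p floor of 1/200,
comfortably below the 0.05 filter. BH adjustment across the retrieved
samples supports the FDR < 0.05 retention rule (delegated to statsmodels;
the test oracle is an independent step-up implementation). A threshold of
1.0 is treated as "retain everything", since q = 1 exactly is attainable.

## Evaluation

Win/tie/loss proportions are computed per metric between the first-listed
(baseline) strategy and each other: a win is a *strict* improvement in the
metric's direction (greater for enriched count and query cosine, smaller
for the interpoint distances); ties are reported separately so the three
proportions sum to 1. Paired per-query metrics are tested with a Wilcoxon
signed-rank test — exact by full 2^n sign-assignment enumeration of the
midranked |differences| for n ≤ 15 (this handles ties correctly, unlike
table lookups), normal approximation above — and pooled enriched /
not-enriched sample counts with Fisher's exact test (scipy's two-sided
rule: sum of hypergeometric probabilities not exceeding the observed
table's). Exactness at small n was preferred over approximations because
desk-scale benchmarks have few queries and the tests need frozen values.

## Synthetic corpus

The generator plants recoverable structure: topics own disjoint vocabularies
(pseudo-biomedical compounds like "gliohypoxia") and disjoint gene
signatures. Study titles sample 3 vocabulary terms; summaries enumerate the
full topic vocabulary (shuffled), so every study fully expresses its topic's
terms and topics are separable by construction — the point of disjoint
vocabularies. A `vocab_overlap` fraction shares terms across topics to
dial difficulty up to fully shared (overlap 1), where recovery must fall to
chance.

Counts are negative-binomial — mean μ, variance μ + φμ² — because RNA-seq
counts are overdispersed and a Poisson generator would make the enrichment
filter look better than it is. Defaults: baseline mean 50, dispersion
φ = 0.3, a mid-range value for bulk RNA-seq; 5 topics × 12 studies × 4
samples (240 samples; ≥ 200 gives the permutation-null calibration a stable
empirical fraction, and ≥ 10 studies per topic makes "80% of the top 10
same-topic" attainable at all); 500 genes with 20-gene signatures at 4-fold
upregulation (signature-to-background energy ratio 16·20/500 ≈ 0.64,
enough for transcriptome cosine to separate topics without making the task
trivial). One condition per study by default — the study's single condition
carries its topic signature, reading the topic as the study's biology; with
more conditions only the first carries it and the rest are baseline.

What the generator does **not** emulate: library-size variation, batch
effects, gene–gene correlation, realistic mean–variance trends per gene,
single-cell sparsity, and the messiness of real GEO text (abbreviations,
boilerplate, multilingual fragments). Passing tests therefore demonstrate
that the machinery is correct and that the pipeline recovers structure it
was designed to detect — not that the hashing embedder would match a
language model's retrieval quality on real metadata.

## Numerical and degenerate-input choices

- Cosine scores are clipped to [−1, 1] against floating-point overshoot.
- All-zero database rows score 0 against any query; an all-zero *query*
  raises (`degenerate query`), since ranking by an undefined direction is
  meaningless.
- Empty text embeds to the zero vector rather than raising, so corpora with
  missing metadata still index; the failure surfaces only if such a vector
  is used as a query.
- Embedding databases persist as a raw `.npy` plus a JSON sidecar
  {version, ids, meta}; loads verify version, shape agreement and
  finiteness. Builds are pure functions of (corpus, config), so re-running
  `build` is bit-identical — the determinism the acceptance script checks.
- Problem sizes in the test suite and acceptance script (500–5000 genes,
  ≤ 240 samples, 199 permutations) are desk-scale choices that keep every
  check exact or well-calibrated while running in seconds.

## Known limitations

- The permutation null ignores gene–gene correlation (anti-conservative on
  real co-expressed signatures).
- The indicator pseudo-profile weighs all query genes equally; a magnitude-
  aware query profile would likely rank better when effect sizes are known.
- Exhaustive scan costs O(n) per query; an ANN index would be needed beyond
  ~10^6 entries and would have to reproduce exact results to be admissible.
- The hashing embedder is a bag of tokens; it cannot see negation, synonyms
  or word order. Use the sentence-transformer adapter for real corpora.
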