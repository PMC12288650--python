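# Methods

## The workflow model

`assay2mol` treats hit finding as retrieval-augmented generation. A query is
a free-text description *p* of a protein target or phenotype (optionally with
a UniProt/PDB identifier and sequence). Each assay record *i* in the corpus
is embedded from its JSON document (minus the outcome table, so similarity
reflects what the assay is about rather than which molecules it happened to
test), giving vectors *b_i ∈ ℝ^d*. Retrieval selects the top-*k* records by
cosine similarity `p·b_i / (|p||b_i|)`; embeddings are stored unnormalized
and normalization happens inside the cosine, so the index holds exactly what
the provider returned. Search is exhaustive — the corpora this package
targets are small enough that exact search is cheaper than maintaining an
approximate index — and similarity ties break by ascending assay id so runs
are reproducible.

The retrieved candidates then pass a filter cascade (query-target exclusion
by UniProt accession; minimum outcome-table size; optional sequence-identity
exclusion; LLM relevance and counterscreen assessment; truncation), and the
survivors are distilled into an in-context-learning prompt: per-assay
summary, rendered outcome table, and class-balanced molecule selection. A
text backend generates candidate molecules in small independent batches;
output is parsed, validated with RDKit, and deduplicated by canonical SMILES.

### Assumptions

- Assay text is informative about its target: records about similar biology
  share vocabulary, so embedding similarity is a useful relevance prior. The
  LLM assessment stage exists precisely because this prior is imperfect.
- Outcome tables are trustworthy as labels; no attempt is made to reconcile
  conflicting measurements across assays.
- The generation backend can imitate molecules shown in context. The metric
  suite measures whether that imitation transfers to the target rather than
  assuming it.
- Counterscreen actives indicate promiscuity or off-target liability and are
  framed as avoid-examples, not discarded: their presence in context is
  information.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 50 | initial retrieval depth; larger than the assay cap so filtered candidates have replacements |
| `min_mol_num` | 4 | minimum outcome-table rows (inclusive: a table of exactly this size passes) |
| `max_assay_num` | 10 | cap on assays in the prompt |
| `n_mol` | 8 | per-class molecule sample size per assay |
| `max_mol_size` | 45 | heavy-atom ceiling for context molecules (strict: > 45 pruned) |
| `seq_identity_threshold` | 0.30 | identity fraction above which (strictly) an assay's target disqualifies it; stage off by default |
| batch size | 10 | molecules requested per generation call |

The assay cap, per-class sample size, and size ceiling defaults follow the
protocol this workflow reproduces. Batches are kept small and stateless
because large single-call requests visibly collapse into near-duplicate
molecules; independent fresh batches restore diversity at the cost of more
calls.

Molecule selection per assay: with more than `n_mol` actives, a uniform
seeded sample of `n_mol`; with 1–`n_mol` actives, all of them; in both cases
up to `n_mol` molecules uniformly sampled from the combined unspecified and
inactive classes (all of them when fewer exist — the under-supply case is not
specified by the protocol and taking everything is the least surprising
choice). With zero actives, all molecules are included unless the table
exceeds `2·n_mol`, in which case `2·n_mol` are sampled; correspondingly the
minimum-table filter escalates to `2·n_mol` for no-active assays. Sampling is
uniform without replacement from a seeded generator ("randomly sample" is
read in its simplest reproducible sense); selected rows keep input order.

## Prompt assembly

Prompts come from a versioned template (`v1`): query description, then one
block per assay in similarity-rank order (summary, fixed-column table), then
the instruction. Counterscreen summaries end with an explicit avoidance
sentence, and counterscreen actives are listed in a do-not-propose section.
The optimize mode appends the molecules to rewrite and frames the context as
an anti-target. Token budgeting uses a chars/4 heuristic (config-overridable);
over budget, lowest-ranked blocks are dropped with a warning. Prompt assembly
is a pure function of (query, blocks, template version, mode), which the
tests rely on for byte-identical reproduction.

Relevance stratification: *x* = (relevant assays)/(assessed assays) over the
top `max_assay_num` survivors of the deterministic filters, with strata
High (*x* ≥ 0.7), Medium (0.4 < *x* < 0.7), Low (0.1 < *x* ≤ 0.4), and
None (*x* ≤ 0.1) — the boundary inequalities are implemented literally, so
*x* = 0.4 is Low and *x* = 0.1 is None. Multiple assessment providers can be
aggregated by OR (default), AND, or majority; OR is the default because a
single provider is the common configuration and OR degrades gracefully to it.

## Metrics

- **QED** and **SA** come from RDKit. SA is affinely rescaled from its native
  1 (easy) – 10 (hard) range by `1 − (raw − 1)/9`, so 0 is hardest to
  synthesize and the metric lives on [0, 1] like QED.
- **Diversity** is the mean pairwise Tanimoto *distance* between Morgan
  fingerprints (radius 2, 2048 bits — the community-default parameters,
  config-exposed).
- **High affinity** is the fraction of generated molecules scoring strictly
  below (better than) the reference score; for multi-reference targets the
  best (lowest) reference is used.
- **Improvement** over a per-target background distribution is
  `mean(baseline) − mean(generated)` in the score's units (kcal/mol for
  docking-style scorers); the mean functional is the default, the median
  available by configuration. The statistic is shift-invariant, which is what
  makes it comparable across targets with different score offsets.
- **Context similarity** is each generated molecule's maximum fingerprint
  similarity to any context molecule — a diagnostic separating in-context
  learning from verbatim retrieval.
- **Aggregation** is two-level: per-target averages (and medians) first, then
  the mean and median of those per-target statistics across targets. Both
  mean-of-medians and median-of-means are reported, since the two-step rule
  leaves the choice of inner statistic open.

Docking engines, sequence aligners and anti-target predictors are external
tools behind `Scorer` / identity-provider interfaces. The shipped mocks are
deterministic hash-based functions of (canonical SMILES, target id, seed);
the planted variant subtracts up to `effect` kcal/mol times the molecule's
maximum Tanimoto similarity to a target-specific known-active set, creating a
recoverable structure-activity signal.

## Synthetic corpus: what it does and does not emulate

The generator plants exactly the structure the pipeline must exploit:
family-specific token signatures in descriptions (so the hashed bag-of-tokens
embedder separates families by construction), per-family query accessions and
sequences with recorded per-assay identity fractions, counterscreen flags,
and outcome tables whose actives come from family-specific scaffold pools
built by combinatorial decoration of checked-in templates (guaranteeing
validity and controllable scaffold overlap). All randomness flows through one
seeded generator; the manifest is sufficient to predict every filter decision
by direct predicate evaluation, which is how the cascade is tested.

It does **not** emulate real assay prose, cross-family biological overlap,
measurement noise semantics, assay-format artifacts, or any chemistry beyond
"same scaffold ⇒ similar fingerprint". Passing tests therefore demonstrate
that the machinery is correct — retrieval is exact, filters match their
definitions, prompts are faithful and deterministic, metrics match their
formulas, and a planted context signal is recovered end-to-end — not that any
particular LLM or embedding model will design good molecules for a real
target.

The offline studies use deliberately small problem sizes — tens of assays per
corpus, 100 generated molecules, 20 planted-effect replicates — chosen so a
complete study runs in seconds to minutes on one CPU while every stage still
executes.

## Numerical and design choices

- Outcome labels normalize case-insensitively through a documented synonym
  map (`inconclusive`/`probe`/`undefined` → Unspecified); real exports vary
  while the pipeline needs exactly three classes.
- Invalid SMILES rows in input tables are dropped with a logged count rather
  than aborting the run; generated invalid candidates are kept and flagged so
  validity rates remain honest.
- The SMILES extraction rule for model responses: strip markup fences and
  list numbering, then per line take the longest whitespace-delimited token
  that canonicalizes. Lines with no parsable token become invalid candidates.
- Assessment replies must contain a two-line structured verdict; a malformed
  reply is re-asked once, then defaults to (not relevant, not counterscreen)
  with a warning — erring toward dropping an assay rather than hallucinating
  relevance. Relevance and counterscreen verdicts share one call per assay to
  halve backend traffic.
- The generation call budget defaults to five times the minimum call count;
  exhaustion returns a partial result with a warning rather than an error.
- Degenerate inputs fail loudly: zero-norm vectors, empty corpora, empty
  molecule tables and sub-two-molecule diversity all raise typed errors
  instead of returning NaN.

## Known limitations

- The hashed bag-of-tokens embedder is a retrieval test harness, not a
  semantic model; real deployments should plug an embedding endpoint into the
  provider interface.
- Sequence identity, docking and anti-target prediction are interfaces only;
  the naive ungapped identity function shipped for synthetic sequences is not
  an aligner.
- Measured potencies are presented in the prompt as-is; molecules are not
  ranked or thresholded by potency when sampling actives.
- Conditional multi-target queries ("inhibit A but not B") are only supported
  by running generation and anti-target optimization sequentially.
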