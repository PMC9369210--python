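# Methods

## The pairing problem

A complex MSA for two interacting chains A and B is built by joining rows
of the two monomer alignments. Every joined row asserts "these two
homologs interact like the queries do" — an assertion no single evidence
source supports everywhere, which is why three strategies are combined:

* **Genomic distance.** Interacting bacterial proteins are frequently
  encoded in one operon. Two hits annotated to the same genome/contig
  whose gene-order ranks differ by Δgene ∈ [1, 20] are candidates. The
  gene index is an ordinal rank along the genome, not a coordinate, so
  Δgene is a rank difference; Δgene = 0 would mean the same gene and is
  excluded by the lower bound. "Same genome" rather than "same gene" is
  the operative condition — distance between two copies of one gene is 0,
  which the window excludes by construction.
* **Phylogeny rank matching.** Within one species, the evolutionary
  history of two interacting families tends to run in parallel, so the
  best A-homolog of a species plausibly partners the best B-homolog.
  Hits are grouped by taxid, sorted by identity to the query (descending,
  ties by ascending e-value when present, then accession), and rank i is
  joined with rank i for i ≤ min(m, n).
* **Interaction-network links.** Hits mapped to interaction-network
  identifiers are joined when a link with combined score ≥ `min_score`
  (default 0; the 0–1000 confidence scale) connects them.

### Conflict resolution

The evidence sources propose many-to-many candidates; output rows must be
a function of the input, so each stage resolves conflicts into a
one-to-one matching with a **total ordering** over candidates: primary
criterion (ascending Δgene, or descending combined score), then descending
mean identity of the two hits to their queries, then lexicographic
accessions. Matching is greedy in that order. Greedy was chosen over
optimal assignment because its behaviour is local and explainable
(the closest/strongest candidate always wins) and it degrades predictably;
it provably returns the maximal matching whose sorted key sequence is
lexicographically smallest, which is what the exhaustive-enumeration
oracle in the test suite checks. An exact minimum-total-cost assignment
(via `scipy.optimize.linear_sum_assignment`) is available with
`method="optimal"`; on adversarial candidate graphs it can pair more rows
than greedy, as one test demonstrates.

## Effective number of sequences

Depth of the paired alignment is measured as

    Necs = scale(L) · Σᵢ 1 / (1 + Σ_{j≠i} [Sᵢⱼ ≥ t]),   t = 0.8
    Sᵢⱼ  = harmonic mean of chain-A and chain-B pairwise identities

over all N rows including the query pair (a flag excludes it). Design
points:

* **Scaling.** `scale(L) = 1/√L` by default, following the monomer
  alignment-depth (Nf) convention this statistic generalises; `1/L` is
  available by flag. Any depth requirement must be stated together with
  the scaling used.
* **Threshold boundary.** A pair at exactly S = 0.8 counts as redundant
  (the indicator is S ≥ t).
* **Harmonic mean.** Punishes one-sided similarity: if either chain pair
  has identity 0 the combined identity is 0 (continuous limit), and the
  mean always lies between the smaller chain identity and the arithmetic
  mean — two rows identical on one chain but dissimilar on the other do
  not count as redundant.
* **Identity denominator.** Pairwise identity divides matches by the
  count of columns where both rows carry residues (`both_ungapped`,
  default — robust to gap-heavy hits) or by the alignment length
  (`full_length`). Identities between stage-output rows are computed on
  the aligned rows directly, not via the query. `X` matches nothing;
  a column gapped in both rows contributes to neither count.

The implementation is vectorised (per-letter indicator matrix products,
O(26·N²·L) in numpy); the test suite holds it to an independent scalar
double-loop to 1e-12 on clustered random alignments up to N = 50, L = 200.

## The cascade

Stage 1 is built first (plus the query pair, which is always emitted by
the cascade and never by a stage); if its Necs meets the requirement it is
used. Otherwise stages 1+2 are merged and re-measured; otherwise stages
1+2+3 are merged and returned regardless — there is no further fallback.
Later stages are never computed when an earlier step suffices.

* **Depth requirement.** The default `necs_threshold` is 128 with
  `inv_sqrt_L` scaling, inherited from the monomer-MSA cascade lineage
  this tool extends; it is fully configurable and recorded in the report,
  and a raw-row-count mode (`count_mode="rows"`) is available for users
  who read "number of sequences" literally.
* **Merging.** The query pair comes first; rows duplicated by
  concatenated sequence *or* by accession pair keep the earliest stage's
  copy, preserving within-stage order. Merging is idempotent.
* **Redundancy removal.** Default is exact-duplicate removal; with
  `max_id < 1` a row is also dropped when the harmonic mean of its
  per-chain identities to any kept earlier row reaches `max_id`. The
  query pair is never dropped.

## Contact-map evaluation

Top-k precision sorts all L_A × L_B inter-chain cells by score (ties by
ascending (i, j), so the ranking is total) and reports the fraction of
true contacts in the top k; k is an integer or L/k with floor division,
floored at 1, where L = L_A + L_B. The truth map is an input — the
package deliberately does not define a contact criterion (distance cutoff,
atom choice), since that choice belongs to the benchmark, not the MSA
method. `relative_improvement(a, b) = 100·(a − b)/b` reproduces the
method-comparison arithmetic; reported figures round to one decimal.

## Synthetic families

The generator plants ground truth that all three strategies can recover:
per (species, genome) an interacting A/B pair is created by mutating the
two query sequences at `substitution_rate` (default 0.2 per site, uniform
substitution to a different residue), placed on one genome Δgene ∈ [1, 20]
apart, sharing a taxid, and linked in the network table at score 900.
Defaults — 10 species, one genome each, one pair per genome, chain lengths
80/70 — give an 11-row paired alignment in which every planted pair is
uniquely recoverable by every stage. Paralog blocks are spaced 100 gene
ranks apart and decoys sit ≥ 25 ranks outside any block, so neither can
enter another pair's Δgene window; deeper paralogs diverge faster
(rate × (1 + 0.5·p)) so the within-species similarity ranking is
consistent across chains with high probability. Orphans receive no
annotations at all and therefore appear in no stage output. One seeded
generator drives every draw; identical parameters give byte-identical
families.

What the generator does **not** emulate: indels (rows are match-state
only, keeping identity arithmetic exact; gap handling has dedicated
tests), tree-structured evolution, biased amino-acid composition,
annotation errors, and paralogy traps where the network links connect
non-orthologous partners. Passing the planted-recovery tests therefore
shows the pairing logic is implemented correctly, not that the strategies
are accurate on real proteomes — their real-data accuracy is a property
of the evidence sources, not of this code.

## Numerical and degenerate-input choices

* Identities are fractions in [0, 1] internally; percent I/O converts at
  the boundary.
* A row with no residue in a chain has identity 0 to everything
  (denominator 0 → 0), hence combined identity 0: it is never redundant
  with anything.
* Empty alignments are errors for Necs; empty candidate sets are empty
  matchings, not errors; an all-stages-empty cascade returns the
  query-only alignment with a `query_only` report flag.
* Annotation tables: duplicate accessions keep the last row (warned);
  symmetric duplicate links keep the maximum score; self-links are
  dropped (warned); malformed fields fail with the line number.
* Problem sizes in the test-bed (families of ~10–40 rows, oracle
  alignments up to N = 50, L = 200, exhaustive matching up to 6 candidates
  per genome) were chosen so every oracle is fully enumerable and the
  whole suite runs in seconds.

## Known limitations

* Greedy matching can strand a hit that an optimal assignment would pair;
  the `optimal` flag exists but changes tie-breaking semantics.
* Stage-2 ranking uses identity to the query as the similarity measure;
  bit-score or e-value ranking may order near-ties differently.
* The depth requirement's published value is not documented upstream;
  the default (128, `inv_sqrt_L`) is a convention, and results should
  always be read together with the cascade report that records it.
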