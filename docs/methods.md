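# Methods

## Model

An immune health endpoint e is operationalized as a gene set G(e): the
union of curated disease–gene associations attached to any MeSH disease
descriptor in the subtree of e's root descriptors. The endpoint roots are
hypersensitivity = {D006967}, autoimmunity = {D001327}, infection =
{D010272, D001423, D014777} (parasitic, bacterial/mycoses and viral
diseases treated as one endpoint), cancer = {D009369}. MeSH descendant
expansion is the transitive closure of the child-of relation read from the
disease vocabulary's ParentIDs column, so the expansion is exactly the
reflexive-transitive closure of the roots; it is idempotent and monotone
in the roots, and both properties are asserted by tests.

Overlap structure is the Venn partition of ⋃G(e): each gene is assigned
the signature σ(g) = {e : g ∈ G(e)}, giving ≤ 2ᵏ−1 disjoint regions whose
union is the universe. Screening a substance c takes its top-n curated
interacting genes T(c) and computes the membership matrix
M[g,e] = 1{g ∈ G(e)} for g ∈ T(c); endpoint e is flagged when
Σ_g M[g,e] ≥ t. The optional enrichment score is the hypergeometric upper
tail P(X ≥ hits) with population = all distinct curated genes in the
chemical–gene table, successes = |G(e)|, draws = |T(c)|.

## Evidence and identity rules

* **Curated evidence only, by default.** Disease–gene rows with a
  non-empty DirectEvidence field ("marker/mechanism" or "therapeutic")
  are kept; inferred associations are dropped. The same curated standard
  CTD applies to chemical–gene interactions is thereby applied to the
  disease side. `--all-evidence` disables the filter; therapeutic rows can
  be excluded downstream if a stricter marker-only set is wanted.
* **Gene identity is the symbol string.** Symbols are uppercased and
  slash-joined pairs such as HLA-DQA2/HLA-DQA1 are kept as one composite
  molecule whose membership resolves through either member — the identity
  at which overlap counts are reported. When an atomic symbol and a
  composite containing it both occur, the composite subsumes the atom.
* **Secreted** means: UniProt Keywords contains the exact token
  `Secreted`, OR the subcellular-location text mentions "secreted"
  (case-insensitive). The OR rule is deliberately permissive: either
  source alone is accepted curated evidence of extracellular presence. A
  composite is secreted if any member is. Genes absent from the table are
  excluded from the secreted network and written to an unresolved-symbol
  side list; silently keeping them would fabricate evidence, silently
  dropping them would hide table incompleteness.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `curated_only` | true | drop inferred disease–gene rows |
| `propagate` | true | GO annotations count for all `is_a` ancestors |
| `union_go` | false | merge GO-derived genes into G(e) |
| `top_n` | 10 | top interacting genes per chemical |
| `threshold` | 1 | hits needed to flag an endpoint |
| `enrichment` | false | add hypergeometric tail per endpoint |

`top_n = 10` and `threshold = 1` (a single cross flags the endpoint) match
the screening readout the pipeline reproduces. GO propagation uses `is_a`
edges only — the conservative standard closure; `part_of`/`regulates` are
not followed. GO-derived genes are a coverage diagnostic by default rather
than being unioned in, because disease-mined sets already cover most of
them and the downstream overlap/ranking stages are defined on the CTD
sets.

Candidate biomarkers are ordered lexicographically by (n_endpoints desc,
secreted desc with unknown last, total curated interaction references
desc, symbol asc). The key encodes the pipeline's priorities — shared
mechanism first, plasma measurability second, evidence volume third — as
an explicit, deterministic choice; no weighted score is implied.

## Synthetic fixtures

`fixtures.generate_fixture` plants a ground-truth manifest and emits the
exact dialects the ingestion modules consume: a MeSH vocabulary whose
endpoint roots carry randomized descendant subtrees (genes are attached
1..depth levels below the roots so hierarchy expansion is actually
exercised), a disease–gene table with curated rows realizing the planted
Venn regions plus inferred and off-subtree decoy rows that the filters
must reject, a UniProt table realizing the secreted fraction, a
chemical–gene table whose per-chemical top genes realize a chosen
endpoint-hit pattern with strictly decreasing interaction counts (ranks
are unambiguous), and a small OBO/GAF layer with propagation, obsolete-term
and NOT-qualifier cases. Decoy symbols come from a synthetic alphabet
(SYN…/DEC…) so fixtures cannot be mistaken for biological claims. The
worked-example fixture plants the 15-molecule four-way core plus 5 unique
decoys per endpoint (sets of 20), a chemical hitting all four endpoints
and one hitting only infection.

What fixtures do **not** emulate: real CTD scale (tens of thousands of
rows), inference-score distributions, GO term depth and annotation
sparsity, or symbol aliasing/withdrawn symbols. Passing recovery tests
therefore demonstrates correctness of the set algebra, filters and
report plumbing — not robustness to real-database noise, nor the
database-snapshot magnitudes (endpoint gene counts, process counts),
which depend on the external 2018 snapshots and are treated as
documented references.

## Numerical and degenerate-input choices

* Region signatures are canonically ordered tuples (hypersensitivity,
  autoimmunity, infection, cancer, then extras alphabetically); region
  contents are invariant to input-set order.
* Top-gene ties break by reference count, then symbol, giving a total
  order; screening is invariant to interaction-file row order because
  aggregation precedes ranking.
* Coverage of an empty GO gene set is defined as 1.0 (vacuous).
* The hypergeometric tail is computed by `scipy.stats.hypergeom.sf` and
  verified in tests against exact Fraction enumeration (≤ 1e-12 on all
  populations ≤ 20); P(X ≥ 0) = 1 exactly.
* All writers sort rows and JSON keys; reruns on identical inputs are
  byte-identical. Test problem sizes (≤ 800-symbol alphabets, 20 recovery
  seeds, ≤ 60-node hierarchies) keep the full suite in seconds while
  exercising every code path.

## Limitations

Direction of effect (increase vs decrease of expression) is not modeled —
a flag means involvement, not harm or benefit. Dose, mixtures and
inference-score weighting are out of scope. Screening sensitivity scales
with how well-studied a substance is: sparse curation yields few top
genes and weak flags. The graph exports target external graph databases;
no server is embedded.
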