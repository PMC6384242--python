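# immunoscreen

Predicting whether a chemical or food substance may disturb — or support —
immune health is hard to do from first principles. `immunoscreen`
implements a systems-biology screening approach for this problem, aimed at
toxicologists and nutrition researchers who want an *in silico* first pass
before committing to assays. It targets four immune health endpoints:
**hypersensitivity**, **autoimmunity**, **resistance to infection** and
**resistance to cancer**.

The pipeline:

1. **Endpoint gene sets.** Each endpoint is defined by MeSH disease root
   descriptors (hypersensitivity D006967; autoimmune diseases D001327;
   infection merges parasitic D010272, bacterial/mycoses D001423 and virus
   D014777; neoplasms D009369). Curated disease–gene associations from
   CTD-dialect flat files are collected over the whole MeSH subtree of each
   root: G(e) = ⋃ { genes(d) : d ⪯ root(e) }.
2. **GO coverage.** Biological processes matching each endpoint's keyword
   framework are selected from the Gene Ontology; their annotated genes
   (with `is_a` true-path propagation) are compared against G(e) as a
   coverage diagnostic, optionally unioned in.
3. **Overlap structure.** The four sets are decomposed into the ≤ 2⁴−1
   disjoint Venn regions indexed by membership signature, and exported as a
   bipartite gene–endpoint network (GraphML / TSV / graph-statement script).
4. **Secretome refinement.** Genes are filtered to those UniProt marks as
   secreted — plausible circulating biomarkers.
5. **Biomarker ranking.** Candidates are ordered lexicographically by
   (endpoints covered ↓, secreted ↓ with unknown last, curated interaction
   references ↓, symbol ↑).
6. **Screening.** A substance's top-10 curated interacting genes (ranked by
   interaction count, then reference count) are crossed against the
   endpoint sets; an endpoint is flagged when any top gene falls in its
   set, with an optional hypergeometric upper-tail P(X ≥ hits) score.

A synthetic-fixture generator emulates all input dialects (CTD disease–gene
and chemical–gene TSVs, MeSH vocabulary, OBO, GAF, UniProt table) with
planted ground truth, so the whole pipeline is testable without external
database downloads.

## Worked example

```sh
immunoscreen simulate --out demo --core     # worked-example fixture + config
immunoscreen run-all --config demo/config.yaml
immunoscreen screen bleomycin-like --config demo/config.yaml
```

The last command prints:

```
bleomycin-like: hypersensitivity, autoimmunity, infection, cancer
```

i.e. the bleomycin-like profile is flagged for all four endpoints, while
`immunoscreen screen bortezomib-like ...` prints
`bortezomib-like: infection` — only resistance to infection is implicated.
`demo/out/venn_regions.json` reports the overlap structure of the fixture's
four 20-gene endpoint sets:

```json
{
  "autoimmunity": 5,
  "cancer": 5,
  "hypersensitivity": 5,
  "hypersensitivity&autoimmunity&infection&cancer": 15,
  "infection": 5
}
```

The 15-gene all-four region is the worked example's core overlap (ALB,
HLA-DPB1, HLA-DQA2/HLA-DQA1 — a composite counted as one molecule —
HLA-DRB1, ICAM1, IFNG, IL1B, IL4, IL6, IL10, IL12B, IL18, MPO, CCL2, TNF),
and `demo/out/ranked_biomarkers.tsv` ranks those core, secreted genes at
the top of the candidate list.

Against real data, point the config's `inputs:` at CTD flat files
(`CTD_genes_diseases.tsv`, `CTD_diseases.tsv`, `CTD_chem_gene_ixns.tsv`),
`go.obo`, a GAF file and a UniProt annotation export.

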