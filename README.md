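# phyletic

Gene gain and loss analysis across distantly related genomes.

`phyletic` reimplements, as a tested and reusable Python package, the classic
comparative-genomics workflow that turns per-genome sets of predicted protein
models into a queryable catalog of gene families:

1. **Self-comparison & redundancy filtering** — each genome's model set is
   compared against itself; shorter sequences highly similar to a longer model
   (e-value ≤ 1e-4) are removed, collapsing the fragmented and duplicated gene
   models typical of draft genomes onto one full-length representative.
2. **Inter-genome comparison** — the non-redundant sets are compared all
   against all; directed hits significant in both directions (reciprocal
   hits) become edges of a similarity graph.
3. **Greedy clustering** — gene families are the connected components of that
   graph, found by sweeping the list of matching pairs and merging cluster
   labels until a complete pass connects nothing new (single linkage over
   thresholded edges).
4. **The union catalog** — genomes are processed in ascending tag order, so
   each family is named by the ID under which it first appears; the result is
   a families × genomes presence/absence matrix with a `sum` column and
   derived boolean group columns, written as spreadsheet-ready text.
5. **Phyletic-pattern queries** — a boolean expression language over genome
   tags and named groups (e.g. `OR(ho,sa,br,ur,da,lo)` for families present
   in any bilaterian), plus canned statistics: families universal to all
   genomes, unique to one, shared exclusively by a pair, or lost in a lineage
   (absent in one genome, present in ≥ *k* others).

The similarity stage is pluggable: ingest precomputed 12-column tabular hit
files from any BLAST-compatible search tool, or use the built-in exact
Smith–Waterman backend (BLOSUM62, affine gaps 11/1, Karlin–Altschul e-values)
so the whole pipeline runs and is tested without any external binary. A
synthetic-fixture generator plants known family structure — universal,
genome-unique and pair-exclusive families, sequence divergence, truncated
redundant fragments — so every stage is verified end to end against ground
truth. See `docs/methods.md` for the model, parameters and their rationale.

## Worked example

```bash
phyletic synth demo --seed 11 --tags aa,bb,cc --universal 4 --unique 2 \
    --pair-exclusive 1 --pair aa:cc --mean-len 150
phyletic dedup   --config demo/config.yaml
phyletic cluster --config demo/config.yaml
phyletic matrix  --config demo/config.yaml
phyletic query   --config demo/config.yaml summary
```

which prints (numbers from this exact invocation):

```
wrote 3 genomes, 21 models, 11 planted families to demo
dedup reports written to demo/out/dedup
11 families written to demo/out/families.tsv
matrix: 11 families x 3 genomes (4 universal, 6 unique) -> demo/out/matrix.tsv
total	11
universal	4	36.4%
unique	6	54.5%
shared_other	1
```

The fixture planted 4 universal families, 2 unique families per genome and 1
family exclusive to the `aa`/`cc` pair; the pipeline recovers exactly that
composition (the pair-exclusive family is the one `shared_other`). The one
injected fragment model (21 generated − 20 family members) was removed by
`dedup`, and `demo/out/matrix.tsv` is identical to the planted
`demo/truth_matrix.tsv`. Phyletic patterns can then be queried directly:

```bash
phyletic query --config demo/config.yaml "aa AND cc AND NOT bb"   # -> aa.g00011
phyletic query --config demo/config.yaml loss --tag bb --min-support 2
```

The same workflow is available as a library — `run_pipeline()` accepts
in-memory models and returns dedup reports, the adjacency graph, named
families and the matrix.

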