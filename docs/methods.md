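# Methods

## The model

`phyletic` operationalizes gene gain/loss analysis as a graph problem over
predicted protein models. A *gene family* is a connected component of the
similarity graph whose nodes are non-redundant gene models and whose edges
are reciprocal significant local-alignment hits. A family's *phyletic
pattern* is its presence/absence vector over the input genomes; gain and
loss statements are read off that matrix (a family present in a clade but
absent in one of its genomes is an operational loss there, with no
ancestral-state reconstruction attempted). The approach is deliberately
tree-free: unlike likelihood methods that estimate per-branch gain/loss
rates on a fixed phylogeny, it only catalogs which genomes share which
families, which is robust to rough draft inputs and agnostic about the
topology of deep branches. The price is single-linkage chaining: one
spurious edge merges two otherwise distinct families. That behaviour is
accepted as part of the method, which makes the significance threshold the
critical parameter (below).

Stages, in order:

1. **Redundancy filter.** Each genome is searched against itself; models
   connected by a significant hit (either direction suffices — a fragment
   hitting its full-length parent is often asymmetric in significance) are
   grouped into connected components, and each component keeps exactly one
   representative: the longest sequence, ties broken by smallest ID.
   Resolving per component rather than per pair makes the operation
   deterministic, order-independent and idempotent; for the dominant real
   case (fragments stacked on one full-length model) the outcome is the
   same.
2. **Reciprocal inter-genome search.** Directed hits with e-value ≤ the
   cutoff in *both* directions form an undirected edge. A flag relaxes this
   to one direction. Intra-genome pairs are never clustering edges: the
   redundancy filter already resolved within-genome similarity, and
   survivors of it are mutually non-significant by construction.
3. **Greedy clustering.** Every node starts as its own cluster; sweeps over
   the matching-pair list assign both endpoints the smaller label until a
   complete pass changes nothing. The fixed point labels each node with its
   component's minimum ID, so the partition is independent of pair order.
   Components are exactly graph connectivity (verified exhaustively against
   an independent component oracle on small graphs and on random
   10⁴-node graphs).
4. **Naming and matrix.** Genomes are processed in ascending tag order;
   each family is named by the ID of its first member under (genome rank,
   then ID). Presence is binary occupancy (≥ 1 member); copy number is
   preserved in the family export, not the matrix. The `sum` column is
   always recomputed from the row, never stored, so the row-sum identity
   holds by construction. Row order is ascending family name — a
   reproducible convention.
5. **Queries.** Boolean expressions over tags and named groups (groups
   expand to OR of their tags at parse time), with AND/OR/NOT, parentheses,
   and both `OR(a,b,c)` and infix forms. Canned statistics — universal,
   unique, exclusive-pair table, loss counts, summary — are pure functions
   of the presence matrix and are cross-checked against brute-force row
   scans in the tests.

## Similarity backend and e-value statistics

The built-in backend computes the exact optimal local-alignment score
(Smith–Waterman/Gotoh, BLOSUM62, gap open 11 + extend 1 per residue, BLAST
convention) in a numba-compiled linear-memory kernel. Alignment details
(percent identity, coordinates, gap counts) are recovered only for pairs
significant in at least one direction, via Biopython's exact
`PairwiseAligner` with identical parameters; the two scores are asserted
equal at run time. Scores are symmetric, so each unordered pair is scored
once even though hits are reported per direction.

Significance uses the Karlin–Altschul approximation `E = K·m·n·exp(−λS)`
with `m` the query length and `n` the total residue count of the subject
set, and the workflow's standard inclusive cutoff `E ≤ 1e-4`. The constants must
match the scoring scheme and null model or the cutoff does not deliver the
chance-hit rate it promises: with ~10³ models a full run performs ~4×10⁵
pairwise comparisons, so a mis-calibrated bar admits dozens of chance edges
and, through single-linkage chaining, silently merges unrelated families.
The defaults (λ = 0.245, K = 0.09) are effective gapped BLOSUM62(11,1)
constants fitted by null simulation against random sequences of 125–500
residues — the standard way gapped constants are derived — with
finite-length edge effects folded in. They sit close to the published
natural-composition values (λ = 0.267, K = 0.041) and err slightly
conservative. Ungapped constants (λ = 0.3176, K = 0.134) must not be used
with gapped scores; measured against the simulated null they understate
e-values by ~3 orders of magnitude near the cutoff. Absolute e-values from
the built-in backend are an approximation and are not meant to reproduce
any external tool's numbers; threshold behaviour and relative ordering are
what the pipeline relies on. Composition-based score adjustment and
low-complexity masking are not implemented.

When hits come from an external search tool instead (`tabular:` backend),
the e-values in the files are taken at face value and the same inclusive
threshold is re-applied, so pre-filtered and raw tables behave identically.

## Key parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `max_evalue` | 1e-4 (inclusive) | significance cutoff for redundancy, edges, and reciprocity; the method's single critical knob |
| `gap_open`, `gap_extend` | 11, 1 | standard BLOSUM62 pairing; a length-k gap costs 11 + k |
| `lam`, `k` | 0.245, 0.09 | effective gapped Karlin–Altschul constants (see above) |
| `require_reciprocal` | on | "reciprocal" read strictly as bidirectional evidence; flag covers the one-directional reading |

## The synthetic generator

The generator emulates the inputs of a multi-genome gain/loss study:
per-genome protein sets with planted phyletic patterns. Each planted family
draws an ancestral sequence uniform over the 20 residues, length ~
normal(250, 50) clipped at ≥ 60; every member genome receives an
independent per-site mutated copy (`sub_rate`, default 0.05, uniform over
the 19 alternatives). With 10% probability (`fragment_rate`) a genome gains
a truncated duplicate of one of its models — a 30–70% prefix or suffix, at
least 30 residues — mimicking the fragmented models of short-read drafts.
The 60-residue family floor and 30-residue fragment floor together
guarantee an exact-substring fragment is always significant against its
parent at the default cutoff (a 30-mer exact match scores ≈ 170 versus a
bar of ≈ 80), so the planted fragment manifest is exactly what the
redundancy filter should remove. IDs encode genome and family index for
auditability but are opaque to the pipeline. Everything is reproducible
from the seed.

The standard study scenario (the package's reference conditions, used by
the acceptance script and the heavyweight tests) is 12 genomes tagged
`am ar br ca da ho lo mo ne sa tr ur`, 50 universal families, 20 unique per
genome, 5 exclusive to the `ar`/`tr` pair, sub_rate 0.05, fragment_rate
0.1 — 295 planted families, ~940 models, about two minutes per full run on
one CPU. At these conditions recovery of the planted matrix is exact with
the fixed default seed.

**What the generator does not emulate.** Real protein composition (residues
are uniform; natural composition has a lighter chance-score tail, so the
fitted constants are conservative there), indels other than terminal
truncation, rate variation across sites or lineages, paralog expansions
within a genome, and genuine twilight-zone homology. Passing the planted
recovery tests therefore demonstrates the pipeline's logic — filtering,
graph construction, clustering, naming, bookkeeping — not sensitivity on
real diverged proteomes.

One limitation deserves emphasis: with independent uniform substitution at
rate r < 0.5 from a common ancestor, two copies still agree at
(1−r)² + r²/19 of sites — bounded below by ≈ 26% as r → 0.5. At r = 0.45
pairwise identity is ≈ 31%, where BLOSUM62 expects ≈ +0.9 per aligned
residue, so optimal local scores grow linearly with length (~230 at length
250) and sit far above the significance bar (~90). The generator therefore
*cannot* produce cross-genome homologs that are undetectable at realistic
protein lengths: "divergence beyond recognition" is outside the reach of
the uniform mutator, and a high-`sub_rate` fixture remains fully connected.
A rate-matrix mutator with indels would be the extension point for true
twilight-zone controls.

## Numerical and design choices

* Inclusive threshold: a hit at exactly 1e-4 is significant.
* All tie-breaks are lexicographic on IDs; all iteration orders are sorted;
  floats are serialized with shortest round-trip `repr`. Re-running any
  stage on unchanged inputs is byte-identical.
* FASTA IDs are the first whitespace-delimited header token; sequences are
  uppercased, trailing stops stripped; internal stops are an error unless
  permissive mode masks them with `X` (draft model sets are routinely
  contaminated by translated non-coding fragments). X/B/Z/U are retained;
  U is scored as C.
* Degenerate inputs: empty model sets, empty matrices, and queries on them
  return empty results rather than erroring; unknown IDs, tags, family
  names, and malformed files are hard errors with the offending item named.
* The loss statistic exposes `min_support` as a required argument rather
  than defaulting it: how much outside support a loss call needs is an
  analysis decision, and published loss counts are only interpretable
  alongside the support rule that produced them. The query layer reports
  loss across a support sweep rather than pretending to a canonical rule.
* The undefined 13th tag sometimes seen in published pair-sharing tables is
  handled by making tags entirely configuration-driven; the package ships
  no hard-coded genome list. Group definitions (e.g. Bilateria, Basal) live
  in the run configuration for the same reason.
* Problem sizes in the test suite are chosen to keep a full run on one CPU
  in minutes: the clustering oracle runs exhaustively on 4-node graphs,
  on 300 sampled 8-node graphs, and on one 10⁴-node/5×10⁴-edge random
  graph; the negative-control fixture uses 4 genomes × 17 models. These
  sizes are stated here so results are read at the scale that produced
  them.
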