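# Methods

## Model and assumptions

`shmtree` models affinity maturation as a monotone optimization process:
under constant antigenic selection, reversion mutations are unlikely and
sampled receptors are selection survivors, so every observed CDR mutation
is treated as advantageous and heritable. Two constraints follow and are
enforced by construction on every built tree:

* **SHM ordering** — for every directed edge, the child's SHM rate is at
  least the parent's (clonotypes are attached in ascending SHM order and
  never above a more-derived node).
* **Inheritance** — for every edge whose parent was chosen by the
  inheritance test, the parent's CDR mutation set is a subset of the
  child's. Mutation identity is the triple (region, position within the
  gapped CDR slice, observed base): a different base at the same site is
  a different mutation event, so it breaks inheritance.

These assumptions fit short-timescale, single-antigen affinity
maturation. They are *not* appropriate for processes with genuine
reversion or for timescales where selection pressure changes.

## Pipeline

1. **Input** — AIRR rearrangement TSV with the standard required columns
   (sequence through region fields, nt and aa). `productive` accepts
   T/TRUE/true and F/FALSE/false; any other value rejects the row with a
   warning, as does an unequal sequence/germline alignment length.
   Isotype is read from the `c_call` prefix (IGHM→IgM … IGHE→IgE); this
   column is not part of the required field list, so records without it
   get isotype `unknown` and are treated as class-switched (no root-tie
   priority). Non-productive records are removed *before* grouping.
2. **Pairing** (single-cell) — chains are grouped by `cell_id`, falling
   back to the sequence id up to its last underscore (10x-style contig
   names). Cells are kept only with exactly one productive heavy and one
   productive light chain; ambiguous cells (e.g. two productive heavy
   chains) are dropped rather than resolved by UMI counts, which are not
   in the required schema.
3. **Grouping** — lineage key = gene-level V calls (allele suffix `*NN`
   stripped; first listed call for multi-assignments) plus nucleotide
   CDR1/2/3 lengths, both chains in single-cell mode. *Strict* grouping
   is exact key equality. *Loose* grouping merges greedily: keys visited
   by descending member count (ties lexicographic) join the first group
   whose **founder** key has identical V genes and summed CDR-length
   difference ≤ 3 nt. Founder-anchored merging (rather than transitive
   closure) keeps the partition deterministic and order-stable; the ≤3
   threshold is summed over all six CDRs in single-cell mode.
4. **Clonotypes** — nodes are unique V-region nucleotide sequences or
   concatenated CDR sequences (heavy then light). Member SHM is always
   computed on the V-region alignment; a position contributes to the
   rate only when both the observed and germline characters are A/C/G/T,
   so IMGT gaps and N's are excluded from numerator and denominator
   alike. Node SHM is the mean over members sharing the clonotype; node
   isotype is the strict-majority (>50 %) member isotype, else `mixed`.
   When a record has no light chain the heavy rate is used on its own.
5. **Tree construction** — as described in the README. Deterministic
   tie-breaks, in order: equal minimum SHM at rooting → unswitched
   isotype, then consensus dummy root (SHM = tied minimum, mutation set =
   intersection of the tied candidates', so all remain valid children);
   equal SHM in the visit queue → lexicographic by sequence; equal
   parent distance → higher parent SHM (the most-derived valid
   ancestor), then lexicographic parent sequence. Parent choice uses the
   *unnormalized* Levenshtein distance on clonotype sequences;
   normalization by parent length applies only to the reported edge
   weight. The dummy base `D` mismatches every nucleotide in both
   distances and SHM contexts. When no placed node passes the
   inheritance test the node attaches to the root anyway (the root is a
   permanent candidate); such edges carry a `fallback` flag so the
   inheritance invariant stays auditable. Germline-rooted lineages never
   need the fallback, since an empty mutation set is a subset of every
   other.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `grouping` | strict | strict / loose clonal grouping |
| `clonotype` | vregion | node definition (vregion / fullcdr); running both gives complementary views |
| `shm` | mean | heavy-chain only, max, or mean of heavy and light rates |
| `depth_min` | 2 | emit tree files only for lineages at least this deep (single-node lineages have depth 0 and are excluded from summaries) |
| `w_max` | 0.1 | max normalized edit distance for "closely related" edges in branch detection |
| `d_min`, `s_min` | 2, 5 | minimum branch depth (edges) and size (nodes) |

Branches of interest are formalized as connected components of the
subgraph keeping edges with weight ≤ `w_max`; the depth and size filters
are applied per component. Logo matrices weight each node's sequence by
its size; amino-acid logos translate each CDR in its own frame (stop
codons render as `*`), so they are available only for nodes carrying
per-region CDR sequences, and branches containing indels (unequal
sequence lengths) are reported without a matrix.

## Simulator

The simulator emulates clonal expansion under SHM in a germinal centre:
a uniform random germline of length `L` roots the tree; each node has
Poisson(`lambda_c`) children; each child gains a zero-truncated
Poisson(`lambda_m`) number of substitutions at previously unmutated
positions, sampled with weight `hotspot_mult` (3) on a random
`hotspot_frac` (10 %) of positions and 1 elsewhere, with the substituted
base uniform over the three alternatives; all parental mutations are
inherited; growth is breadth-first and stops when the node count reaches
`N` or any node has mutated `stop_frac` (95 %) of positions. Defaults
(`L`=100, `N`=100, `lambda_c`=2, `lambda_m`=1) are the smallest cell of
the benchmark grid; the grid spans L ∈ {100, 200} (single/paired-chain
full-CDR scale), N ∈ {100, 200}, λ_m ∈ {1, 2} (the observed 1–2
mutations per generation) and λ_c ∈ {2, 3, 4}, 50 replicates per
combination = 1200 trees.

Two free choices deserve note. *Zero-truncation*: a zero-mutation child
would duplicate its parent's sequence and collapse into the same
clonotype during reconstruction, leaving the ground-truth comparison
ill-defined, so per-child mutation counts are redrawn until ≥ 1 and
coincidental duplicate sequences are redrawn (bounded retries). This
makes simulated lineages somewhat easier to reconstruct than a model
that permits duplicates. *Growth order*: children are added
generation-by-generation and the node cap cuts growth mid-generation;
a depth-first grower would shape large trees differently.

What the simulator does **not** emulate: framework regions and indels
(sequences are substitution-only, fixed length), isotype switching,
selection coefficients or affinity landscapes, sequencing error, and
clonal abundance (every simulated node has size 1). Passing benchmarks
therefore demonstrate correctness of the reconstruction under the
no-reversion substitution model, not robustness to indels, annotation
error or sampling noise in real repertoires.

## Benchmarking

Reconstruction is scored by graph edit distance over a fixed node-label
set (labels = node sequences, pairwise distinct by construction). With
identical labelled node sets and zero relabel cost, GED reduces exactly
to the directed-edge symmetric difference — twice the number of
mis-assigned parents — so the metric is exact, not approximate. The
benchmark report pools the two λ_m values per (L, N, λ_c) row into 100
trees per row.

The acceptance script simulates 120 lineages (5 per grid cell) for the
edge-ordering percentage and 100 trees per reported grid row; these
sizes give stable means (the per-row sampling spread across seeds is
about ±0.2 GED) while keeping a full run in the tens of seconds.
Observed mean GEDs on the four reported rows are consistently at or
below the corresponding published benchmark figures, as expected for a
simulator without duplicate clonotypes.

## Known limitations

* Loose grouping is founder-anchored and greedy; a transitive-closure
  variant could merge chains of keys that this one keeps apart.
* Node CDR mutation sets are taken from the lexicographically first
  member of a clonotype; members of one clonotype share CDR sequences
  under either definition, so differences can only arise from
  inconsistent germline annotation across rows.
* Dummy-root construction requires the tied candidates to have equal
  sequence lengths; a lineage whose tied minimal clonotypes differ in
  length (possible under loose grouping) is skipped with a warning.
* V(D)J annotation and germline inference are out of scope: input must
  already be AIRR-annotated (e.g. by IgBLAST).
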