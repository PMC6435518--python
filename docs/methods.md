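# Methods

## The model

`trimodenet` treats a multi-component extract as a capacity network with
three node classes. Components and effects never touch directly; every
relation is mediated by gene-ontology terms, on the premise that a
component influences an effect only insofar as the two act through shared
biological functions. The per-pair relation score is a maximum flow, so it
is limited both by how strongly the component engages its functions
(component→GO capacities), how specifically those functions characterize
the effect (GO→effect capacities), and how much the functions communicate
(GO↔GO similarity arcs, which let flow detour through related terms).

### Capacities

For one entity (component or effect) with enriched terms indexed by m, the
arc weight is

    W_m = norm( norm(r_m) + norm(−log p_m) ),  norm(x) = (x − min)/(max − min)

with `r_m` the gene ratio (overlap / target-list size) and `p_m` the
one-sided hypergeometric p-value. Both norms run over the entity's own
term list only: the formula indexes terms within one entity's annotation,
and a global norm would let one entity's outlier rescale every other
entity's layer. Min-max normalization is invariant under positive affine
maps, so the base of the logarithm is immaterial (asserted by test); we
use base 10 for display. A degenerate norm (all values equal, or a single
term) maps to 0 rather than NaN — a flat layer carries no discrimination.
Raw p-values feed the weights; a Benjamini–Hochberg FDR is computed and
reported per term but deliberately does not enter W.

GO↔GO arcs default to the overlap coefficient |A∩B|/min(|A|,|B|) with an
inclusive 0.5 cutoff, realized as two antiparallel arcs of equal capacity
(the standard undirected-to-directed flow reduction). The coefficient
lives on the same [0,1] scale as the entity weights; raw or normalized
overlap counts are available (`goi_capacity`) because "number of
overlapping genes" admits either reading. Zero-overlap pairs are never
linked, even at cutoff 0.

### Flow scores

`z_ij` is the max flow from component i to effect j on the subnetwork with
all *other* component and effect nodes deleted, so no third entity can
siphon or relay flow: z_ij measures the i–j relation in isolation. Flows
are solved on integer-scaled capacities (scale 10⁶, round-to-nearest) to
keep augmenting-path arithmetic exact and terminating, then divided back;
node iteration follows sorted labels, so outputs are bit-reproducible.
GO nodes that are unreachable from every component *and* cannot reach any
effect are pruned at assembly (both conditions must fail; a term reachable
from one side is kept, since GOI paths may still route flow through it).

### Entropy weighting and content adjustment

Each effect column of z is converted to proportions p_ij = z_ij / Σ_i z_ij
before the entropy sum — applying the printed H formula to raw flows can
leave [0,1], which the ω formula presupposes; the normalization is the
canonical entropy-weight method. Then

    H_j = −(1/ln m) Σ_i p_ij ln p_ij,   ω_j = (1 − H_j) / (n − Σ_j H_j)

with 0·ln 0 := 0, H_j := 1 for an all-zero column (no information), and
uniform ω when every column is uninformative (degenerate denominator).
m ≥ 2 is required (k = 1/ln m is undefined at m = 1). Adjusted scores are
S_ij = z_ij ω_j R_i where R_i = area_i / Σ areas is the component's
chromatographic content ratio (invariant to rescaling all areas). Effect
and component scores are column and row sums of S; the component score
factors exactly as network score × R_i. Marginals are computed with
correctly rounded summation (`math.fsum`), so both totals marginalize the
same matrix; their equality is exact in rational arithmetic and holds to
machine rounding in floats. Rankings sort by descending score with
lexicographic tie-breaks.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `lfc_min` | 1.5 | DEG threshold on \|log₂ fold change\| (strict >); a `signed` flag restores the literal one-sided reading |
| `fdr_max` | 0.05 | DEG threshold on FDR (strict <) |
| `goi_cutoff` | 0.5 | minimum overlap coefficient for a GOI edge (inclusive) |
| `goi_metric` | overlap | `jaccard` available as alternative similarity |
| `goi_capacity` | coefficient | GOI arc capacity: coefficient, count, or normalized-count |
| `scale` | 10⁶ | integer scaling of capacities for exact flows |
| `log_base` | 10 | display base for −log p (provably immaterial to W) |

Gene symbols are normalized by strip + uppercase + dedupe only; no alias
or orthology mapping is attempted (that is a curation step), but a
two-column alias map can be supplied to the readers as an extension point.

## The synthetic-data generator

`generate_study` emulates every pipeline input: a universe of synthetic
symbols (`G000001`…, so collisions with real genes are impossible), 24
GO-like terms of 10–30 genes over a 1000-gene universe, component/effect
target sets of 40 genes, a DEG table, database/reference disease lists and
a Dirichlet(1) content profile. The universe is deliberately much larger
than the annotated fraction: real GO slims annotate a minority of a
genome, and a sparse annotation keeps chance overlap between unrelated
entities modest. Odd-indexed terms copy 60 % of their genes from their
predecessor so the GOI layer has edges at the 0.5 cutoff.

Signal is planted per (component, effect, strength) link: both entities
draw `strength × 40` targets from three dedicated signal terms; a
`noise_overlap` share (default 10 %) of remaining targets comes from the
annotated background, and the rest from unannotated genes. Consequently
with no links and no noise, no entity shares a gene with any term, no
component→GO→effect path exists and the flow matrix is exactly zero.
Entities that enrich no terms receive an empty weight layer (zero flow)
rather than an error. Disease biology spans the annotated genes: 60 % of
them receive passing (|log₂FC| ∈ [1.6, 4], FDR < 0.049) DEG rows, and the
database/reference lists each cover ~70 % of the annotated pool, so the
integrated disease set reconstructs most of it.

What the generator does **not** emulate: the GO DAG (terms are flat sets —
no true-path up-rolling), correlated expression noise, annotation bias
toward well-studied genes, or realistic gene-symbol aliasing. Passing
tests therefore demonstrate the scoring machinery's correctness and its
ability to recover planted associations under idealized annotation, not
performance on real curation noise.

`worked_example()` is a fixed, seed-free 3×2 network with hand-auditable
capacities; its full expected score table was computed independently by
plain arithmetic and is frozen as a test fixture.

## Numerical choices and degenerate inputs

- Integer-scaled flows (above); scale configurable when capacities span
  extreme magnitudes.
- Imported enrichment charts with p = 0 are clamped to 1e−300 with a
  warning (the internal hypergeometric cannot produce 0); p outside [0, 1]
  rows are dropped.
- Empty DEG filter results are allowed (logged); an empty integrated
  disease set aborts the pipeline with a validation error.
- All orderings (term pairs, node iteration, rankings) are
  lexicographically tie-broken; outputs are independent of input order and
  of hash randomization.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
500 random ≤8-node networks for the flow-oracle comparison, 100 seeded
studies for planted-link recovery, 200 for null calibration, 20 for
conservation — about ten seconds end to end. These sizes give binomial /
chi-square resolution comfortably beyond the asserted bounds (≥95 %
recovery; uniformity not rejected at α = 0.01) while staying desk-scale.

## Known limitations

- Absolute score scales depend on enrichment inputs and capacity
  conventions; only structural identities (score factorization, marginal
  conservation) and rankings are meaningful across datasets.
- The isolation convention for per-pair flows is one reading of
  source/sink max-flow scoring; sharing the network across entities would
  yield different (competition-aware) scores.
- No uncertainty is attached to scores; the method produces point
  estimates only.
- Enrichment treats the term collection as flat sets; GO hierarchy
  propagation is out of scope.
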