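# Methods

This note documents the models and procedures behind `cypome`, the defaults
and why they were chosen, what the synthetic data does and does not emulate,
and the numerical edge cases.

## Sequence identity

One identity definition serves the whole pipeline (clustering and
classification share the engine). A pair of protein sequences is aligned
globally (Needleman–Wunsch, BLOSUM62, gap open 10, gap extend 1 — the first
gap position costs 10, each further position 1), and identity is

```
identity = identical columns / alignment columns,
```

excluding columns that fall inside a terminal gap of either sequence
(USEARCH-like). The exclusion matters for length-mismatched pairs: an
overhang does not dilute identity. An `all-columns` variant is available
(`definition="all-columns"`; `--identity-def` semantics in the library),
because published 55% cutoffs do not always state how terminal gaps were
counted; results for pairs near a threshold can differ between the two
definitions. When several alignments are co-optimal the engine's first
traceback is used; identity is then not strictly unique, but the test oracle
restricts exact comparisons to pairs whose optimum is unambiguous.

## Greedy centroid clustering

Sequences are sorted by decreasing length, ties broken by tagged id for
determinism (the length sort mirrors UCLUST; the tie-break is ours). Each
sequence is compared with existing centroids in creation order and joins the
*first* centroid at identity ≥ threshold (default 0.55, the protein-clustering
cutoff the pipeline standardises on); otherwise it founds a new cluster.
First-match mirrors UCLUST's `maxaccepts 1`; a best-match mode exists. This
discipline guarantees, by construction: a partition of the input; every
member within threshold of its centroid; and every pair of centroids below
threshold (each new centroid was rejected by all earlier ones).

A k-mer prefilter (length-5 words, at least one shared word) skips hopeless
alignments. Two sequences at ≥ 55% identity over a CYP-length alignment share
length-5 words in all realistic cases, but the prefilter is still heuristic,
so `exact=True` disables it; the equivalence tests against the brute-force
greedy replay run in exact mode.

## Domain identification

The CYP-domain profile is a position-specific scoring matrix built from a
gapped alignment of domain sequences: columns with > 50% gaps are dropped,
and each column scores residue *a* as `2·log2(f_a / b_a)` half-bits, where
`f_a` is the observed frequency with a +1 pseudocount (`(n_a + 1)/(n + 20)`)
and `b_a` the background (uniform 0.05 by default). X and other non-standard
residues score 0 — their background expectation — so ambiguity neither helps
nor hurts a window.

Queries are scanned with an ungapped sliding window; the best window score
S is converted to an E-value with the Karlin–Altschul-shaped model
`E = K·m·n·exp(−λS)` (m = query length, n = database residues, the summed
profile lengths). λ and K are calibrated per profile: 500 decoy sequences of
length 400 are drawn i.i.d. from the profile background (equivalent to
shuffles of a background-composition sequence), their best-window scores are
fitted with a Gumbel distribution by maximum likelihood (`scipy.stats.gumbel_r`),
and with location μ and scale β, `λ = 1/β` and `K = exp(μ/β)/(400·n_profile)`.
The calibration is seeded and deterministic. These E-values are internally
consistent (monotone in S, linear in m and n, tail within a small factor of
the empirical decoy exceedance) but are not numerically comparable to
RPS-BLAST E-values; only the decision "CYP at E ≤ 1e-5" is meant to carry
over. On the synthetic data the margin is enormous — true CYPs carry the
conserved core (E below the cutoff by many orders of magnitude), decoys do
not — so the cutoff's exact calibration is not load-bearing there; with real
domain alignments the calibration is what makes the cutoff meaningful.

Each centroid keeps only its best hit across profiles: a multi-domain
protein counts once, because the GCM counts proteins, not domains.

## Classification and novel-group naming

Best-hit classification against the named reference set, thresholds
inclusive: identity ≥ 0.55 → the hit's family and subfamily; 0.40 ≤ identity
< 0.55 → the hit's family, new subfamily; < 0.40 → new family. Ties on
identity resolve to the lexicographically smallest reference name, making
classification invariant to reference file order.

Sequences founding new groups are co-clustered among themselves with the
same thresholds (greedy, deterministic id order): new families are labelled
`NF<k>` in discovery order with subfamilies `NF<k>.<j>`; novel subfamilies
inside a known family are `<family>-NS<j>`. These labels are run-scoped
placeholders — official CYP names are issued by the nomenclature committee —
and the run log says so.

Cluster members inherit their centroid's assignment. A member sits within
55% of its centroid but its *own* best-hit identity may fall on the other
side of a rule boundary; members whose centroid identity is within 0.05 of
0.40/0.55 are flagged in a `near_boundary` column rather than re-classified,
keeping the centroid-level, non-redundant design.

## GCM and analyses

The GCM counts classified sequences per CYP name and genome; genomes with no
CYPs remain as all-zero columns so population sizes stay honest. Novel `NF`
rows sort after known families for stable output.

*Pan/core rarefaction.* For each subset size n of N genomes, up to 300
distinct subsets are drawn (exhaustive whenever `C(N, n) ≤ 300`; otherwise
rejection sampling of distinct subsets, seeded). Pan size is the number of
rows occupied in at least one subset genome, core size the number occupied in
all. Means and medians are both reported; the power law `n = σ·N^γ` is fitted
by ordinary least squares on log-log scale to the mean by default
(`fit_target="median"` available) — the rarefaction literature uses both
summaries and the choice is configurable rather than silently fixed. No
model is fitted to the core curve; its values are reported as-is. Exhaustive
means are provably monotone (pan non-decreasing, core non-increasing in n);
sampled means converge to them as the budget grows.

*Co-occurrence.* With B the presence/absence indicator of the GCM, the
weighted matrix is `B·Bᵀ` with a zeroed diagonal (genomes shared per CYP
pair) and the adjacency its binarisation. Node "occurrence" is
genome-presence count; total sequence counts are exported alongside, since
either can reasonably scale a node. The export is a static edge list and
node table importable by Gephi/Cytoscape/networkx.

*Genome clustering.* Hierarchical clustering of genome columns (and CYP
rows) with Euclidean distance and average linkage by default — both
configurable, since heatmap-package defaults differ — rendered as a
dendrogram heatmap plus a text file with both leaf orders and the merge
tree.

*CYP cloud.* Row totals, rank-ordered descending with ties broken by name;
the image is a frequency-scaled text panel.

## Synthetic data

The generator emulates the *decision structure* of the problem, not CYP
biology. Families are independent random ancestors of realistic CYP length
(420–500 aa) sharing one conserved 60-residue core (the scan target, absent
from decoys — no shared 10-mer, verified). Subfamily ancestors mutate 35.5%
of non-core positions so cross-subfamily identities land mid-band in
0.45–0.54 (same family, different subfamily, ≥ 0.05 from both rule
boundaries); references mutate a further 2%, genome members 8%, keeping
within-subfamily identities ≥ 0.70. Mutations are substitution-only at
uniform positions with BLOSUM62-conditional replacements, which keeps
realized identity an analytic function of the mutated fraction; indels are
deliberately absent. Every band is nevertheless *verified* by direct
alignment on the realized sequences (including reference pairs, whose
divergence from their ancestors would otherwise let them drift out of band)
and the draw is retried, boundedly, on violation. All draws flow from one
seeded generator, so identical config + seed gives byte-identical files.

What passing on this data shows: the clustering discipline, the E-value
decision, the inclusive 40/55 rules, label propagation and every GCM
analysis are implemented correctly, with margins that make the expected
outcome unambiguous. What it does not show: behaviour on real proteomes —
indels, domain rearrangements, fragmented gene models, identities that sit
*on* the thresholds, and profile/reference databases with uneven coverage.
There the `near_boundary` flags, the configurable identity definition and
the E-value calibration all become load-bearing and should be inspected.

Default population: 6 genomes, 5 families × 2 subfamilies × 2 references,
6–10 CYPs and 5 decoys per genome — small enough that the full pipeline runs
in seconds, large enough that clusters, both GCM levels, networks and
rarefaction curves are all non-trivial.

## Numerical and degenerate cases

- Queries shorter than the profile are no-hits (−∞ sentinel), not errors;
  E-values are clamped at 1e-300 to keep log-scale reports finite.
- Empty classification yields 0-row GCMs; analyses are skipped with a
  warning rather than failing the run.
- Single-genome populations skip hierarchical clustering (with a warning)
  and have pan = core at n = 1 by definition.
- Power-law fitting requires ≥ 2 distinct n with positive summaries; a
  constant curve fits γ = 0 exactly.
- Duplicate record ids get ordinal suffixes; `|` in ids is replaced by `_`
  (the genome/record tag separator); terminal `*` stops and gap dashes are
  stripped, any other non-amino-acid character skips the record with a
  warning. All such events are logged with a `WARN` prefix.

## Out of scope

Nucleotide input, gapped profile alignment, composition-adjusted scores,
allele-level naming, phylogeny-based classification, interactive network
visualisation, and parallel execution. The official nomenclature databases
are not bundled; the reference set is whatever named FASTA the user (or the
generator) supplies.
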