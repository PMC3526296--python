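# Methods

## The model

A CNE is treated as a Dollo presence/absence character: present in the common
ancestor (guaranteed by the catalog's outgroup-alignment requirement) and
only lost, never regained. Each species contributes one of three states per
element:

* **conserved** — aligning CNE sequence exists (any overlap ≥ 1 bp by
  default; the threshold is configurable because partial alignment is not a
  sharply defined notion of presence);
* **lost** — no aligning sequence, embedded in a co-syntenic flank alignment,
  no assembly gap between the flanks, no similarity hit in the genome or the
  unassembled reads;
* **missing** — anything else. Missing data claims neither loss nor
  conservation and every missing cell carries exactly one reason code
  (`no_flank`, `not_cosyntenic`, `assembly_gap`, `similarity_hit`,
  `low_coverage_species`), with that fixed precedence so audits are
  deterministic.

A discarded would-be loss (similarity hit) is *missing*, not conserved: the
hit may be a translocated copy or an assembly error, so neither state is
demonstrated.

### Parsimony placement

Losses are placed per CNE on the branch above each maximal clade whose
leaves are all lost-or-missing and which contains at least one lost leaf.
Equivalently: prune the missing leaves, take maximal all-lost clades, and
map each pruned edge back to its **most ancestral** consistent original
branch. This is the package default because an internal-branch loss is
exactly "loss or missing data for all descendant species". When a lost leaf
has only missing siblings the event is genuinely ambiguous (any branch on
the chain from the leaf to the maximal clade is consistent); the alternative
`placement="shallow"` rule reports the MRCA of the lost leaves instead. Two
inferred branches are always separated by at least one conserved leaf by
construction, which is what makes k ≥ 2 losses *independent*.

Multifurcations are allowed; children are treated independently. Unnamed
internal nodes get deterministic derived names (sorted leaf initials), so
branch identities are stable across runs; ordering ties anywhere are broken
lexicographically by node name.

### Eligibility and the exact expectation

`N_A` counts CNEs with no missing leaf below branch `A` (a CNE missing
mouse or rat cannot, by definition, host a loss in the mouse–rat ancestor);
`f_A = L_A / N_A`. A branch combination is *valid* for a CNE iff (a) no leaf
below any branch is missing and (b) labelling exactly the leaves below the
combination as lost re-infers exactly that combination — one oracle decides
validity everywhere (enumeration, `N_c` denominators, simulation rule 3).
`E_2 = Σ f_A f_B N_AB` over valid pairs, `E_3` analogously. Validity is
evaluated at the leaf-mask level without role checks: an internal branch
above a presence-only species is a legitimate loss branch (its loss shows as
losses plus missing data), even though such observed events can never be
reassigned to CNEs missing that species — the two bookkeeping rules are
followed verbatim and are not fully reconcilable; the tension only affects
internal branches above low-coverage species.

### The reassignment null

Observed events, sorted by depth of the node the loss branch ends in
(ancient first; ties by branch name then input index), are assigned to
uniformly random CNEs. An assignment is rejected when the candidate CNE
(1) already lost a species of the event, (2) has missing data below the
event's branch, or (3) would re-infer different loss branches. After 1,000
uniform rejections the valid CNEs are enumerated exactly and one is drawn
uniformly — termination without biasing the distribution. Every iteration
reproduces the input per-branch event counts exactly; this conservation law
is a hard assertion, not a statistical check. Counts of CNEs with k = 2, 3,
4+ losses are tallied per iteration (no exact `E_k` is computed for k ≥ 4).

The empirical P-value uses the add-one estimator
`P = (1 + #{sim ≥ obs}) / (1 + iterations)` with `≥` exceedance; at 10,000
iterations and no exceedance this reports P < 1e-4. `z` is undefined and
flagged when the simulated sd is zero. The RNG is a single seedable
`SeedSequence`; iteration *i* derives substream *i*, so results are stable
regardless of execution order.

## Detection parameters

| parameter | default | why |
|---|---|---|
| minimum CNE length | 70 bp | published catalog floor, re-applied after trimming |
| exon-flank trim | 100 bp | conserved splicing signals near exons |
| Blastx E-value | < 0.01 rejects | protein-coding similarity |
| second self-BLAT score | ≥ 40 rejects | close paralogy → ortholog misalignment |
| GERP RS fraction / phyloP P | > 0.5 and < 1e-20 (strict) | extremely conserved subset |
| ancestry alignment fraction | ≥ 0.80 (inclusive) | pre-mammalian origin |
| flank search | nearest blocks, 1 Mb cap | unstated upstream; explicit choice |
| trace validation | region < 500 bp (strict), 50 bp pad, single read | ~800 bp Sanger reads |
| control regions | 5 per loss, same size, gap-free, uniform | sampled exactly uniformly over feasible starts |
| window scan | 5 Mb window, 100 kb step, clipped at ends | step unstated upstream; configurable |
| TSS distance anchor | CNE midpoint | unstated upstream; `edge` available |

Coordinates are 0-based half-open (BED) throughout. Query distances are
computed after orienting minus-strand blocks, so inter-flank distances are
non-negative whenever the flanks are co-syntenic. Negative deletion
estimates (query longer than reference) are reported as-is — they are
insertions, and hiding them would bias the deletion summary.

## The synthetic world

The generator works at the coordinate/evidence level; nucleotide evolution
is out of scope. Defaults are fixed once to the conditions the analysis
assumes and are not tuned against test outcomes:

* 12-leaf mammal tree: seven loss-search species (mouse, rat, guinea pig,
  cow, horse, dog, elephant), kangaroo rat / human / rhesus presence-only,
  opossum + platypus outgroups; branch lengths in neutral substitutions per
  site taken from published mammalian estimates.
* per-branch loss probability = 0.03 × branch length × propensity, which
  yields ~5–6% of CNEs with at least one loss and per-branch loss
  frequencies around 1%;
* element lengths 70 bp + lognormal (median ≈ 190 bp, mean ≈ 235 bp);
* deletion sizes lognormal (median 2,870 bp, mean ≈ 6.4 kb), emitted as
  reference-minus-query inter-flank distance with an exponential
  (scale 500 bp) unaligned query residue, so roughly half of loss regions
  fall under the 500 bp trace-validation window;
* missing data per species per CNE: 2% (loss-search), 15% (presence-only),
  10% (outgroup); an optional correlated mode blanks whole species
  scaffolds, since real assemblies lose contiguous regions;
* propensity models: uniform; hotspot (two-class mixture, default 10% of
  CNEs at 10-fold); gamma (smooth heterogeneity).

Planted branch sets are redrawn until exactly re-inferable given the missing
mask, so on artifact-free output detection + parsimony reproduce the planted
statuses and events *exactly* — a hard round-trip invariant. What a green
round-trip does **not** establish: robustness to alignment noise, partial
losses, paralogy, or correlated deletion of neighbouring CNEs; none of these
are simulated, and real-data performance depends on the upstream alignments
and hit tables, which this package consumes but does not produce.

## Numerical and design choices

* Parsimony and validity checks run on leaf bitmasks with per-tree
  memoisation; the simulation's inner loop is therefore a few integer
  operations per proposal, which keeps 10,000-iteration runs cheap.
* Size matching draws without replacement and requires exact length
  equality; it fails loudly (listing unmatched lengths) rather than
  silently approximating.
* Rank-sum comparisons use the large-sample Wilcoxon rank-sum test;
  proportions use Pearson chi-square without continuity correction.
  Constant features are skipped with a note instead of returning P = 1.
* The frequency/branch-length correlation uses the closed form
  `t = r·sqrt(df/(1−r²))`, df = n − 2, two-sided P from the t distribution.
* Degenerate inputs: empty deletion tables return empty frames; a zero-size
  control region is a position; `sd = 0` nulls flag `z` as undefined but
  still report the empirical P.

## Known limitations

* Sub-element (partial) losses are not called; the unit is the whole CNE.
* Observed losses on branches above presence-only species enter `L_A` but
  their own CNEs may be ineligible for the same branch (see above); at
  genome scale the effect is small but it is not self-consistent.
* The exact expectation ignores the weak negative dependence the sequential
  reassignment induces; empirically the two methods agree within Monte-Carlo
  error on every fixture tested, but they are not identical estimators.
* Exact-length size matching can be infeasible on small catalogs; callers
  must restrict to matchable lengths (see `examples/05_genomic_context.py`).
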