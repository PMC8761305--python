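# Methods

## Tripartite network

The network links domains to functional terms exclusively through shared
proteins. Only proteins annotated in **both** layers become network nodes:
the association indices compare protein neighbourhoods against the same
universe of `n_total` proteins, and a protein that cannot mediate a
domain–function co-occurrence would distort the null model. Proteins dropped
from each layer are counted and reported. Duplicate (protein, feature) rows in
the input are collapsed to set membership — the indices operate on sets — with
multiplicity kept only as a parsing diagnostic. Identifiers are opaque,
case-sensitive strings; no GO/KEGG/Reactome syntax is assumed.

Quality filters operate before network construction: annotations carrying an
excluded evidence code (typically `IEA`, electronically inferred GO
annotation) are dropped, and proteins carrying an excluded flag (e.g.
`fragment`) lose all their annotations. Requesting an evidence filter on a
file without an evidence column is an error rather than a silent no-op.

## Association indices

Four indices score each (domain, function) pair sharing at least one protein;
pairs with empty intersection are not materialised (they carry no signal, and
the full cross-product is quadratic in the layer sizes). Downstream code
treats absent pairs as "no association".

* **Jaccard** and **Simpson** are plain set-overlap ratios. Simpson
  normalises by the smaller neighbourhood, which matters when domain and
  function protein sets differ greatly in size — a domain entirely contained
  in a large function's protein set still scores 1.
* **PCC** is the phi coefficient of the two membership indicator variables.
  The numerator uses the product of the neighbourhood sizes,
  `|Np(D)|·|Np(F)|`, the only reading consistent with the φ denominator. A
  pair whose neighbourhood spans *all* proteins has a constant indicator and
  no defined correlation; such pairs are omitted with a warning.
* **HyI** is `−log10 P(X ≥ |∩|)` for a hypergeometric X (population
  `n_total`, `|Np(D)|` marked, `|Np(F)|` drawn). The tail is computed in log
  space (`scipy.stats.hypergeom.logsf`), so it never underflows; values are
  clamped to a configurable cap (default **300**, i.e. p = 1e−300) so that no
  infinities propagate.

Per-table mean and population standard deviation are stored with each
association table; the table is the complete population of associations on
that network, so the population form (ddof = 0) is used, not the sample form.

## Score combination and normalization

Standardization is computed per association table (one metric × one network).
PCC tables are standardised after an absolute-value transform, since the sign
only encodes the direction of co-occurrence while prediction needs strength.
A table with zero spread cannot be standardised and raises an error.

Fisher's `k` (and Stouffer's) counts the domains contributing a value for the
specific function being scored — only those values enter the sum, so only they
can contribute degrees of freedom.

Normalization into the (0, 1] reporting range: Stouffer combined scores are
re-standardised **over the prediction run** (all combined scores produced in
one `predict_all` call), clipped symmetrically to [−2, 2] — the map must
preserve sign, otherwise `z/4 + 0.5` could never produce values below 0.5 —
and mapped through `z/4 + 0.5`. Fisher combined p-values map to `1 − p`.
A clipped z of −2 maps to exactly 0.0, which falls outside (0, 1]; the final
0.001 cutoff (applied to both paths) removes it, so every retained score lies
in [0.001, 1.0]. The map is monotone, so within-run rank order is preserved
up to ties at the clip boundaries. If a run's combined scores are all
identical, they normalise to 0.5 with a warning rather than failing the run.

The submission-style output format rounds scores to two decimals and floors
zero-rounded scores at 0.01. Output ordering is deterministic (protein
ascending, score descending, function ascending) so repeated runs are
byte-identical.

## Ontology handling

OBO parsing (via `obonet`) keeps `is_a` and `relationship: part_of` edges —
the relations along which annotation propagates in protein-centric evaluation;
regulates-type edges are ignored. Obsolete terms are recorded without edges;
`alt_id` aliases resolve to their primary id; edges to undefined terms are
dropped with a warning; a cycle is fatal.

Information accretion, the per-term Smin weight, is
`ia(t) = −log2( n(t) / n(parents) )` in bits, where `n(t)` counts corpus
proteins annotated with `t` and `n(parents)` those annotated with **all**
parents of `t`, both computed on an ancestor-propagated corpus. Roots get 0.
A term absent from the corpus gets `−log2( pc / (n(parents) + pc) )` with a
configurable pseudo-count (default 1), keeping weights finite. If the corpus
was stripped of some ancestors before counting, `n(parents)` is clamped to
`n(t)` so accretion stays non-negative.

Whether predictions should be ancestor-propagated before protein-centric
scoring is a policy choice; the evaluation command propagates both truth and
predictions by default (a predicted term endows each ancestor with its
maximum descendant score) with `--no-propagate` to score literal term sets.

## Evaluation

Protein-centric precision/recall at threshold τ: precision averages
`|pred∩truth|/|pred|` over benchmark proteins with ≥ 1 prediction scoring
≥ τ; recall averages `|pred∩truth|/|truth|` over **all** benchmark proteins
(full mode, penalising non-predictions) or over proteins with ≥ 1 prediction
at any threshold (partial mode). Fmax maximises the harmonic mean over the
grid τ ∈ {0.01, …, 1.00}; among tied thresholds the largest is reported —
the most selective cut achieving the maximum, which is the threshold a user
would actually apply. Smin minimises `sqrt(ru² + mi²)` over the same grid
with accretion-weighted remaining-uncertainty and misinformation averages;
ties take the smallest threshold. Benchmark subsetting (e.g. a
no-knowledge/limited-knowledge classification) is caller-supplied protein
lists; classifying real proteins into those categories is out of scope.

The pooled self-prediction procedure ranks every (protein, function, score)
record, labels it positive when the function is in the protein's original
annotation, and computes PR points at each distinct score. Matching is
against the annotation sets exactly as given (propagate them beforehand to
match against ancestor closures). AUC-PR uses step interpolation —
`Σ ΔR·P` over thresholds, equivalent to average precision on the ranked
list — rather than trapezoidal interpolation, which is optimistic for PR
curves. Recall is relative to the positives present in the ranked list.

The naive baseline assigns every training term to every query protein with a
score equal to the term's training-corpus frequency; its coverage is 1 by
construction.

## Synthetic data generator

The generator emulates the structural assumption the method relies on:
functions co-occur with their domains via shared proteins. Each domain is
planted with a fixed set of functions (default 1); each protein draws 1–3
domains uniformly without replacement and inherits the union of their planted
functions. Two corruption mechanisms model departures from the ideal:

* `noise_rate` — each (protein, function) edge is independently replaced by a
  uniformly random function with this probability, modelling annotation error
  and functions not determined by domain content;
* `fraction_domainless` — each protein has this probability of carrying no
  domain annotation (it receives random functions instead), modelling the
  real loss of query proteins without domain assignments and bounding
  coverage.

Defaults (500 proteins, 50 domains, 20 functions, 1–3 domains per protein,
zero noise) give a corpus where every planted (domain, function) pair has
Simpson index exactly 1 and self-prediction is fully recoverable — a
calibration point, not a realism claim. The generator does **not** reproduce
real CATH/GO degree distributions, the heavy right tail of domain promiscuity,
ontology-correlated annotation (functions are independent unless drawn from
the toy ontology's leaves), or inter-protein homology; passing tests therefore
demonstrate correctness of the machinery and recoverability of planted signal,
not expected performance on real proteomes. Problem sizes used by the test
suite and the acceptance script (≤ 1000 proteins, ≤ 200 random micro-networks)
were chosen so the full pipeline is exercised end-to-end in seconds.

A single integer seed drives each generator call through one `numpy`
Generator stream; identical seeds give byte-identical corpora.

The toy ontology generator emits a complete rooted tree (depth × branching)
as valid OBO 1.2; using its leaves as function identifiers exercises the
propagation and Smin paths on synthetic corpora.

## Known limitations

* Association values are computed independently per pair; no correction for
  correlated domains within the same proteins (Fisher/Stouffer both assume
  independent evidence, which promiscuous domain co-occurrence violates).
* Per-run re-standardisation in the Stouffer path means a protein's
  normalised score depends on the composition of the prediction run; scores
  are comparable within a run, not across runs.
* The hypergeometric cap (300) makes extremely strong associations
  indistinguishable from one another after the p-value transform.
* No homology-based domain assignment: domain annotation is an input.
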