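# Methods

## Signed network construction

Interaction tables are RegulonDB/EcoCyc-style TSV (regulator, target,
effect, optional evidence; `#` comments; tab-separated). Effects are
resolved to one sign per ordered (regulator, target) pair: activation
+1, repression −1. Three situations prevent a single sign and send the
pair to the excluded-edge ledger instead: an effect recorded as *dual*,
an effect recorded as *unknown*, and rows with conflicting signs for
the same pair. Conflicting rows are semantically a dual regulator
observed piecewise, so they are excluded under the same policy rather
than resolved by majority or recency. The ledger and the resolved edge
map partition the distinct pairs of the input, which makes the
exclusion auditable.

Identifier matching is case-insensitive (databases mix `crp`/`CRP`);
the displayed spelling is the lexicographically smallest observed one,
so the network is invariant to input row order. Both strong- and
weak-evidence interactions are accepted by default (`min_evidence=
"any"`); a `strong` filter is available but changes the census, not the
method.

## FFL enumeration and classification

For a master TF X, every ordered pair (y, z) with y in the TF set and
the three resolved edges X→y, y→z, X→z present yields one instance,
classified by the sign triple (see the table in the package docs).
Self-loops are ignored; a target may itself be a TF and may serve as
another instance's intermediate. Arity — single-Y vs multi-Y — is the
number of distinct intermediates per target counted jointly across all
types: a gene with one intermediate in one type and another in a second
type is regulated by two TF arms and is therefore multi-Y. Output order
is deterministic (type, target, intermediate) so census files are
byte-stable.

Enumeration is validated against an independent brute-force oracle that
scans all node pairs on the raw edge map and derives the type label
from first principles (coherence by sign product, type number from the
(X→Y, Y→Z) pattern).

## Dose–response profiles and the responsiveness filter

The expression matrix is log2-scale, genes × (dose, replicate) columns
over the grid 0, 0.01, 0.03, 0.1, 0.3, 1, 3, 10 mM cAMP; duplicates per
dose are the norm. Missing values are rejected, not imputed. Replicates
are averaged per dose *on the log2 scale* and the zero-dose mean is
subtracted, so each gene gets a log2 fold-change vector over the seven
positive doses.

The responsiveness filter keeps a gene iff max over doses of |log2FC| ≥
0.5. Two deliberate choices: the boundary value 0.5 itself is kept
(the filter removes values *below* the threshold), and the criterion is
"any dose" — a gene is dropped only when every dose stays below
threshold. An `all`-doses mode is exposed for sensitivity analyses.

## Profile clustering and shape labels

Distance is 1 − Pearson r; a zero-variance profile carries no shape
information and gets distance 1 to everything (logged). Agglomerative
average-linkage clustering is cut to exactly k flat groups
(`scipy.cluster.hierarchy`), with k = 5 for single-Y and k = 6 for
multi-Y targets by default. No objective criterion for k is claimed;
the defaults reflect the group structure this analysis style reports,
and an optional silhouette-based search (`silhouette_k`) is provided.
Profiles are processed in lexicographic gene order and flat groups are
relabeled by descending size (ties by smallest gene name), so results
are independent of input order; the published SG/MG numbering is not
recoverable and is not claimed.

Shape rules are evaluated on the group mean profile in a fixed order:

1. **bell** — unique interior maximum, both endpoints ≥ 0.5 log2 units
   below the peak;
2. **inverse_bell** — the mirrored rule for a minimum;
3. **monotone_down** — non-increasing within a 0.1 tolerance, total
   drop ≥ 0.5;
4. **sigmoid_threshold** — non-decreasing within tolerance and ≥ 70% of
   the total rise occurring at doses ≥ 0.3 mM;
5. **saturating_up** — non-decreasing within tolerance and ≥ 50% of the
   total rise reached by 0.1 mM;

else **unclassified**. Rise/drop fractions are computed relative to the
profile endpoints, so labels are invariant to adding a constant; the
0.5-span requirements are deliberately absolute, matching the
responsiveness filter's scale. The dose anchors (0.1, 0.3, 1 mM) are
the landmarks that distinguish early-saturating activation, threshold
activation and intermediate-dose peaks in this system; all thresholds
live in `ShapeConfig`.

Functional groups: each SG group seeds one FG in order; each MG group
joins the FG of its best-correlated SG mean profile when that Pearson r
≥ 0.8 (`min_corr`); still-unattached MG groups are compared to the FG
mean profiles by the same rule, and otherwise seed their own FG. The
0.8 default encodes "similar profile" for 7-point dose curves; it is a
package choice, exposed in config.

## Enrichment

Over-representation of a term with K carriers in an N-gene universe,
observed k times in an n-gene group, is the exact hypergeometric upper
tail P(X ≥ k) (`scipy.stats.hypergeom.sf`), cross-checked in the tests
against direct binomial-coefficient enumeration and the one-sided exact
contingency test. Significance is raw p ≤ 0.01 with no multiple-testing
correction by default — the convention this analysis style uses;
Bonferroni/BH can be applied downstream. The default universe is the
expression matrix's gene set. Annotations are a slim GAF-like TSV
(gene, term, namespace, name); only the biological-process namespace is
kept when namespaces are present. When a child→parent term table is
supplied, annotations are closed under ancestors (true-path rule) with
cycle detection.

## Synthetic data: what it emulates, and what it does not

The dose–response microarray behind this analysis style has no public
accession, so the generators plant known ground truth:

* **Networks** — one fresh intermediate TF and target per planted
  instance, so planted triangles cannot interfere; decoy edges are
  rejection-sampled so they never complete an unplanned triangle
  (checked against the current edge map; an unconstrained mode exists
  for oracle tests). With probability `multi_y_fraction` a target gains
  a second intermediate, and the extra triangle's type is recorded in
  the ledger, which remains the exact census ground truth.
* **Expression** — absolute log2 expression is 8.0 + shape(dose) +
  Gaussian noise per replicate (zero-dose columns at 8.0 + noise), with
  five analytic base shapes anchored to the dose landmarks above:
  saturating `a(1−e^{−d/0.05})`, sigmoid `a/(1+(0.3/d)²)`, log-linear
  decrease `−a·log10(d/0.01)/3` (clipped), log-Gaussian bell centred at
  0.2 mM, and its negation. Defaults: amplitude 2.0 log2 units, noise
  sd 0.1, 2 replicates, 8 genes per shape — a strongly-responding
  regulon measured in duplicate.
* **Annotations** — every term annotates background genes at rate 0.1;
  each group's designated term annotates members at min(1, 5 × 0.1).

These emulate the *structure* of the real data, not its messiness: no
probe-level noise model, no correlated replicates, no partially
overlapping operon structure, no dual regulators unless requested.
Passing planted-recovery tests therefore demonstrates that the pipeline
is correct and well-conditioned at realistic effect sizes, not that
real microarray data would cluster this cleanly.

## Packaged census fixture

The published census ships as a type → ordered target-gene list (202
instances, duplicates preserved). Its printed content supports exact
arithmetic: per-type counts summing to 202, a 147-gene distinct union,
and per-type distinct-gene counts. Intermediate-TF identities are not
printed, so per-type TF counts are not testable from the fixture, and
the single-Y/multi-Y split can only be computed from gene multiplicity
across the lists: that tally gives 103 single-Y and 99 multi-Y
instances. `fixture_stats` reports exactly what the lists imply rather
than forcing agreement with any externally stated split, since a target
whose second intermediate TF was itself expression-filtered can appear
once in the lists yet be multi-Y in the source database. The headline
coverage figure is round(100 · 147/432) = 34%, with the 432-gene
regulon size taken from the same snapshot as the census.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 100 random signed
networks of 10–50 nodes for oracle equivalence; 20 simulations of 40
profiles (8 per shape) for clustering recovery (adjusted Rand index vs
planted labels); 50 simulations of a 20-gene group in a 500-gene
universe for enrichment detection; and every hypergeometric margin with
N ≤ 60 for the exact-statistic check. These sizes make the whole suite
run in well under a minute while leaving each property far from its
decision boundary. Ties in linkage are resolved by scipy's
deterministic index order over the lexicographically sorted gene list;
all generators are pure functions of (spec, seed) using numpy's
`default_rng`.

## Known limitations

* The pipeline starts from a normalized log2 matrix; RMA/background
  correction of raw arrays is out of scope.
* Expression filtering is applied to target genes only; intermediate
  TFs are not re-filtered, matching the census-restriction semantics.
* No motif-significance testing against randomized networks, and no
  kinetic/dynamical modelling of FFL response times.
* GO enrichment results depend on the annotation release supplied by
  the user; the package ships no ontology.
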