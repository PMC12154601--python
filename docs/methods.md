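# Methods

This note documents the models, parameter defaults and numerical choices
behind `coelute`, in the order the pipeline runs them. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic study generator

The generator emulates the statistical structure the pipeline assumes in a
multi-species co-fractionation study, not the physics that produces it.

**Truth.** A fixed number of complexes draw sizes uniformly from
[`min_complex_size`, `max_complex_size`] and members without replacement
from a shared ID pool, so planted complexes are disjoint; a set of monomers
fills out the orthogroup universe. Each orthogroup retains each species
independently with probability `species_retention` and is forced into at
least one species. Each orthogroup draws one abundance — its expected
peak-height PSM count — from a log-normal.

**Experiments.** Per experiment, every complex draws a peak-center fraction
uniformly; a member's expected profile is a Gaussian bump in fraction index
centered at the complex center plus a per-member jitter, with height equal
to its abundance and width `peak_sd`. Monomers draw independent centers.
Counts are Poisson at the expected profile; each orthogroup drops out of an
experiment entirely (all-zero row) with probability `dropout_prob`. An
*expectation mode* skips jitter, dropout and Poisson sampling, producing
exactly co-linear member profiles for analytic tests; it shares peak
centers with the corresponding stochastic run because all random draws
happen in a fixed order.

**Defaults** (one study): 3 species × 2 experiments × 40 fractions;
35 complexes of 2–8 members plus 25 monomers (200 orthogroups);
abundance ~ LogNormal(ln 50, 0.75²) expected PSMs at peak;
`peak_sd` = 2.0 fractions; jitter SD 0.6 fractions; dropout 0.10;
species retention 0.90. These were chosen once as plausible for deeply
fractionated brain-tissue separations at desk scale: peak totals around
250 PSMs per experiment put most orthogroups comfortably past the 60-PSM
filter while dropout and species absence still exercise the missing-data
paths, and a 0.6-fraction jitter leaves within-complex Pearson r well
above the between-complex background without making the problem trivial.

**What it does not emulate** — retention-time physics, peptide-level
structure, shared peptides between orthogroups (PSM ambiguity is tested
with hand-built records instead), correlated dropout, abundance drift
between experiments, or contaminant/background signal. Planted complexes
are disjoint, so tests passing here say nothing about recovering
overlapping (moonlighting) subunits; ontology terms, built as unions of
complexes, are where overlap enters. Conclusions from synthetic runs are
statements about the pipeline's statistical machinery, not about any real
interactome.

**Randomness.** Every stage draws from a substream derived from one
integer seed plus a stable CRC32-hashed label (`coelute._rng.substream`),
so stages rerun in isolation reproduce a full-pipeline run bit for bit.

## Elution processing

A PSM contributes its count to an orthogroup only when every protein it
matches lies in that orthogroup; PSMs spanning two or more orthogroups are
discarded entirely rather than fractionally assigned — the conservative
reading that avoids double-counting near-duplicate paralogs. The abundance
filter keeps orthogroups whose summed counts over *all* supplied matrices
reach `min_psms` (default 60, boundary inclusive); which matrices enter the
union is explicit in the call, not hard-coded. Species concatenations
append columns in declared experiment order, zero-filling absent
orthogroups; fraction order is taken from file order with no biological
interpretation.

## Pair features

Four measures per matrix: Pearson's r and Spearman's ρ (tie-averaged
ranks), inverted Euclidean similarity 1 − d/d_max with d_max the largest
pairwise distance *within that matrix* (so identical profiles score 1 and
the farthest observed pair anchors 0), and Bray–Curtis similarity
1 − Σ|u−v|/Σ(u+v). Profiles enter as raw counts plus Poisson noise
(c → c + ε·Pois(λ), defaults λ = 1, ε = 0.1, averaged over R = 3
replicates); correlations are location/scale-invariant so no
row-normalization is applied. Zero-variance or all-zero vectors get the
fill value (default 0, "no co-elution evidence") rather than NaN, because
the downstream tree ensemble needs finite inputs; pairs with a member
absent from a matrix get the fill value in that matrix's columns. Note
that rank-based features are discontinuous at ties, so the ε→0 limit
recovers noise-free values only on tie-free profiles.

## Gold standard

Complexes larger than 30 members are removed (exactly 30 is kept).
Grouping is by connected components of the share-a-member graph — the
strictest cheap leakage guard. Positives are within-complex pairs of
observed orthogroups; negative candidates are pairs of observed
complex-annotated orthogroups that co-occur in *no* complex of the
unfiltered set (so members of removed giant complexes are never labeled
negative together), sampled uniformly to min(3 × positives, candidates).
Negatives inherit the lexicographically smallest of their members'
component labels for splitting. Stratification caps each group's
positives (default 100) and re-caps negatives to restore the 3:1 ratio.
Train/test splits use group-exclusive random splits (GroupShuffleSplit),
default 75% training.

## Scoring and FDR calibration

The classifier is an extremely-randomized-trees ensemble (default 256
trees, unlimited depth); the CF-MS score is its positive-class
probability. Feature selection ranks columns by impurity importance of an
ensemble fit on training pairs only and keeps the top k (default 100,
clamped to the number of available columns; a 70-feature preset mirrors a
common alternative operating point).

Threshold calibration is the one place the pipeline is deliberately more
conservative than the bare operating rule. `select_threshold` defaults to
the literal rule — the smallest score whose cumulative FDR on the
calibration sample is ≤ the target — which is exact in the large-sample
limit. At desk scale that rule is fragile: a group-exclusive calibration
split contains few complex groups, its labeled-negative score tail is
sparse, and the empirical FDR can sit below target all the way down to
near-zero scores, producing absurdly lenient thresholds. The pipeline
therefore (a) calibrates on the *pooled out-of-fold scores* of the grouped
5-fold cross-validation over the full training split — every training pair
scored by the model that never saw its complex group, giving a dense
calibration sample spanning all training groups while the withheld test
split stays untouched — and (b) compares the target against the one-sided
90% Jeffreys upper confidence bound of the cumulative FDR
(Beta(FP + ½, TP + ½) posterior) rather than the point estimate. An upper
bound is the right object when the requirement is *controlling* FDR at a
level rather than matching it on average; both choices converge to the
plain rule as the calibration sample grows. Tied scores collapse to a
single threshold step, avoiding precision oscillation inside tie blocks.
If no threshold qualifies, calibration fails loudly with the best
achievable FDR. The empirical FDR of the final network is measured once,
on the fully withheld test split, as the fraction of labeled-negative
pairs among withheld labeled pairs scoring at or above the threshold.

## Complex detection

Walktrap (default walk length 4) runs on the thresholded network with
CF-MS scores as edge weights, unmodified. Random walks cannot cross
connected components, so the merge tree never joins components and
attainable cluster counts run from the component count to the node count.
Named cuts are defined operationally: *coarse* is the maximum
weighted-modularity cut; *fine* is the deepest cut in which every cluster
retains ≥ 2 members. Unattainable target counts fall back to the nearest
attainable level with a warning. Cluster quality is pairwise
co-membership precision/recall against known complexes restricted to
clustered nodes; an all-singleton partition is an explicit error state
(precision undefined), not a zero.

## Network validation

**External enrichment.** Scores are binned into ten deciles
[0.1(x−1), 0.1x) plus a terminal [1.0, 1.0] bin that captures the
classifier's maximal output (a `merged_top` variant closes the tenth bin
at 1.0 instead). Per bin and evidence source, the evidence proteins are
restricted to the bin's proteins, the tested-pair universe is rebuilt on
the intersection — all C(n,2) pairs for all-by-all assays;
|B||P| − n_bp − C(n_bp,2) unordered bait–prey pairs with
n_bp = |B ∩ P| (closed form proven equal to enumeration in tests) — and
split into externally positive (E+) and negative (E− = E_all − E+) pairs.
The enrichment is A/B with A = |CFMS+ ∩ E+| / |CFMS_all ∩ E+| and
B = |CFMS+ ∩ E−| / |CFMS_all ∩ E−|; B = 0 is flagged "infinite" and an
empty A denominator flags the bin "undefined". All eight intermediate
sets are returned for audit.

**Seed propagation.** s_i = Σ_{j∈seed, j≠i} w_ij with no self-link; seed
members are ranked by the *other* seeds and counted as positives in the
tie-aware AUROC, computed via the rank-sum identity (equivalent to
averaging over tie orderings). Annotations need ≥ 5 in-network
orthogroups. The null draws same-size seed sets uniformly without
replacement; note the no-self-link convention gives seed members a
slightly lower expected score than non-members (they sum over one fewer
potential partner), so the null mean sits marginally below 0.5 on dense
networks — visibly within ±0.03 at the scales used here.

**Ontology mapping.** Annotations are inherited along the DAG from
ancestor terms into descendants (the pipeline's primary convention; the
conventional child→ancestor true-path mode is available behind a flag).
Deduplication then (i) keeps only the ancestor when an ancestor and
descendant carry identical sets, and (ii) removes groups of identical-set
terms that share a retained common ancestor. Kept terms carry their
maximum Jaccard index against the training complexes, flagged high/low at
0.5.

## Problem sizes

The default end-to-end study is 200 orthogroups × 6 experiments
(~18k scored pairs), chosen so a full pipeline run completes in seconds
and the whole test suite in well under a minute of compute per module;
the seed-propagation null uses a ~500-node correlation network with
1,000 random seed sets. These sizes are the package's reference
conditions for its self-checks, not limits of the implementation.

## Known limitations

- Planted complexes are disjoint; overlapping-complex recovery is
  untested by construction.
- The AutoML search that would justify the tree-ensemble configuration is
  out of scope; the configuration is fixed with exposed hyperparameters.
- No probability recalibration (isotonic/Platt) is applied to CF-MS
  scores; they are ensemble vote fractions, not calibrated probabilities.
- The ontology reader handles simple term/edge tables only, not full OBO.
- Empirical FDR is measured on labeled pairs; the FDR among *unlabeled*
  retained edges is unobservable and may differ if unlabeled pairs are
  harder than gold-standard negatives.
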