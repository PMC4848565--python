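# Methods

This note documents the models implemented in `interomap`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic data
generator does and does not emulate.

## Interolog transfer

The core assumption is evolutionary conservation of interactions: if x and y
interact in a reference species and A, B are their orthologs in the target
proteome, then (A, B) is a candidate interaction ("interolog"). The mapping
is all-vs-all over ortholog-group members — every combination of an ortholog
of x with an ortholog of y is emitted — because ortholog predictors
(INPARANOID-style) return groups, not one-to-one assignments. Inparalogs are
not down-weighted by default; the ortholog confidence column is carried but
unused in scoring. Pairs are canonicalized by lexicographic order,
self-interactions (homodimers) are retained and flagged, and predictions
reachable from several species merge: species support is the union, and every
reference record (species, accessions, MI-score) is kept as provenance, so a
reference interaction curated twice in one species counts once toward species
support.

MI-score filtering is applied to the *reference* interactions before mapping
(threshold 0 for the main build, so records with a missing MI-score survive
only that pass — they cannot be placed on the quality ladder). The package
can rebuild the whole quality ladder by re-running at increasing thresholds;
`dataset_confidence_stats` then reports the high-confidence frequency
n_high/n_total and an enrichment p-value, the upper-tail hypergeometric
probability of drawing at least n_high high-tier pairs in n_total draws from
the full build's population.

Experimentally curated pairs integrate by set union: overlapping pairs are
relabelled origin `both`, novel curated pairs enter with empty species
support, and the overlap count is reported (merged size = predictions +
curated − overlap).

## Evidence components

Six per-pair components are computed; all are symmetric in the two proteins.

* **Species support** (1–6): number of reference species the pair transfers
  from. The floor of 1 holds for every predicted pair by construction.
* **Co-evolution** (0–6): number of species in which *both* proteins have at
  least one ortholog, regardless of any interaction there. The published
  totals lie in [1, 12], which is exactly 6 + 3 + 1 + 1 + 1 — the only
  additive decomposition of the six stated criteria consistent with that
  range — so co-evolution is recorded as metadata with default weight 0. The
  weight is configurable (`ScoringConfig.w_coevo`) for users who want it
  totalled.
* **Shared GO namespaces** (0–3): per namespace (BP, MF, CC), each protein's
  terms are propagated to all is_a ancestors, the namespace root excluded
  (every annotated protein trivially reaches the root); the namespace scores
  1 when the propagated sets intersect. part_of edges are excluded from
  propagation by default (configurable in `read_obo`) since relation handling
  is a genuine free choice and is_a-only is the conservative one.
* **DDI support** (0/1): 1 when any Pfam domain of one protein and any domain
  of the other form a pair in the domain–domain interaction catalogue,
  order-insensitively; homotypic pairs count.
* **Co-localization** (0/1): 1 when the proteins share a compartment, or each
  occupies a compartment of one common "adjacent" group. The compartment
  vocabulary is the 13 standard plant compartments; `undefined` and `unknown`
  never match. Only two adjacent groups are conventionally named
  (Golgi/ER, Golgi/vacuole); the defaults add nucleus/cytoplasm and
  cytoplasm/membrane for trafficking and membrane-association contact, and
  the group list is fully overridable. Curated localization rows are kept
  only with evidence codes EXP, IDA, IEP, IMP, IC, IEA, RCA or ISS; predicted
  rows (e.g. from a targeting-signal predictor) are kept regardless and
  flagged by origin.
* **Co-expression** (0/1 via CS): in each expression sample i, with X̄ᵢ the
  mean over all measured genes in that sample, γᵢ = 1 iff the two genes'
  deviations from X̄ᵢ have the same strict sign; CS = Σγᵢ / N with N the
  *total* sample count (default study condition: 96), so samples where either
  gene is unmeasured depress CS rather than being skipped. A deviation of
  exactly zero scores 0 (conservative tie-break). CS is missing only when
  neither gene has a measurement in any sample; the point is s_coexp = 1 iff
  CS ≥ τ, with τ = 0.5 so that totals stay integral under default weights.
  The per-sample grading rule is stated textually in the source material but
  its formula appears only as an image; the sign-concordance reading adopted
  here is the one consistent with every textual statement (per-sample 0/1
  grade, CS is the average, range [0, 1]). A Pearson-r-based continuous
  alternative is deliberately not implemented.

**Tiers.** total ≥ 7 is high, total < 2 is low, otherwise medium. The
half-open medium interval [2, 7) is chosen so the three tiers partition any
scored set exactly; the published phrasing ("between 2 and 7" next to "≥ 7")
does not settle the upper bound, and exclusivity is the only consistent
reading.

## Network topology

Degree is the number of distinct interaction partners, a self-loop
contributing one, so Σ degree = 2·(hetero edges) + (self edges). Node classes
tile the positive integers: free end (1), pipe (2), minor hub (3–9), small
hub (10–100), medium hub (101–500), major hub (501–1000), super hub (>1000).
Only the 10–100 small-hub band is conventional; the other cutpoints are
defaults exposed in `DEFAULT_CLASS_BOUNDARIES` because class sizes shift as
interactomes grow. "Average interacting partners" is interactions ÷ proteins
rounded half-up — the convention used in cross-database comparison tables —
not the mean graph degree 2E/N.

The degree-distribution fit is an ordinary least-squares line on
(log₁₀ k, log₁₀ P(k)). With binning, P within a logarithmic bin is the mean
of P(k) over the distinct degrees present and the abscissa is their geometric
mean — the standard log-binning that preserves a power law's slope; with
`n_bins=None` every distinct degree is a point. At least three distinct
degrees are required; regular graphs are rejected as degenerate. No
maximum-likelihood (Clauset-style) estimation is attempted: the fit is a
pattern check, not an exponent estimator.

## Function prediction

Guilt-by-association: for a protein with n partners, every propagated
non-root term carried by at least one partner is tested with the upper-tail
hypergeometric probability P(X ≥ k) of k annotated partners given K carriers
in the N-protein annotated background (computed through scipy's survival
function, which works in log space for large arguments). Namespace roots are
excluded as candidates — they annotate the entire background, always give
p = 1, and would only pad the ranking. Terms rank by p ascending, ties broken
by larger k then lexical term id; the top five are retained and no
multiple-testing correction is applied — published partner-enrichment tables
report raw p-values, and top-5 truncation is itself the filter. The pass is
single and non-iterative: newly predicted annotations are never fed back as
training annotations.

Information content is IC(t) = −ln(count(t)/count(root)) with counts
propagated to ancestors (count of distinct proteins annotated to the term or
any descendant), so IC is non-increasing from child to parent by
construction; zero-count terms are absent from the table and roots have
IC 0. Lin similarity is 2·IC(MICA)/(IC(t₁) + IC(t₂)) over common ancestors
including the terms themselves; pairs whose only common ancestor is the root
score 0, and root-vs-root is defined as 0.

The hold-out evaluation removes a seeded fraction of annotated, connected
proteins, re-predicts their terms from the remaining corpus, and scores each
target by the best-match (maximum) Lin similarity across (predicted, true)
term pairs — the aggregation across term pairs is a free choice; best-match
is the generous, widely used one and is documented as such. The baseline
rescores the same predictions against annotation sets drawn uniformly from
the training corpus (one donor protein per target, seeded), and a one-sided
Mann–Whitney rank test compares the two score samples. A degenerate case
(all scores tied on both sides) reports p = 1.

GO-slim coverage compares two protein sets per namespace: for each slim term
the fraction of set members annotated to it (with propagation), then
Pearson's r across the slim terms with the usual t-transform p-value
(|slim| − 2 df); namespaces with fewer than three slim terms, or a constant
profile, report a missing correlation.

## Synthetic data generator

`FixtureConfig` defaults define the emulated study conditions: six reference
species (arabidopsis, worm, fly, human, rice, yeast), 96 expression samples,
240 target proteins, 8 planted complexes of 5 plus 40 extra pairs (120 true
pairs), per-species ortholog coverage 0.8, multi-species transfer probability
0.25, evidence concordance 0.8 (GO, per namespace) / 0.7 (DDI) / 0.7
(co-localization), expression concordance ρ_true = 0.8 vs ρ_null = 0,
MI-scores ~ Beta(2, 2), 15% inparalog rate and 2% expression missingness on
background genes. The species panel and sample count mirror the published
study; the concordance rates and network size were chosen once as values a
practitioner would call realistic for a curated-evidence benchmark (strong
but imperfect evidence, a network small enough to analyse in seconds) and are
all configurable.

Construction guarantees rather than hopes for recoverability: planted target
pairs are *back-translated* through the sampled ortholog tables into each
supporting species' MITAB file, and every reference accession maps to exactly
one target protein (targets may carry inparalog accessions), so with full
ortholog coverage the interolog step recovers the truth table with precision
and recall exactly 1. Species-private noise edges connect reference proteins
that have no orthologs and therefore never map. Expression is generated by
grouping genes connected in the truth table; per sample each group draws a
deviation sign and members follow it with probability q = (1 + √ρ)/2, giving
pairwise sign concordance (1 + ρ)/2; a magnitude floor of 0.5 about the
center keeps the empirical sample mean (whose fluctuation is an order of
magnitude smaller) from flipping any sign, so ρ_true = 1 forces CS = 1
exactly. Background genes toss independent coins (ρ_null = 0 ⇒ expected CS
0.5); non-zero ρ_null tilts background genes toward a global per-sample
direction and is approximate because the empirical mean re-centers.

What the generator does **not** emulate: real ortholog inference errors
(many-to-many cluster ambiguity beyond inparalogs, spurious orthologs),
biased curation density across species, correlated evidence layers
(e.g. co-localization and co-expression co-varying through tissue identity),
realistic GO depth (the synthetic ontology is a 3-level tree per namespace),
or genome-scale size. Passing tests therefore demonstrate correctness of the
machinery and sensible statistical behaviour under planted signal — not
field performance on a real proteome.

## Numerical and degenerate-input conventions

* Hypergeometric tails via `scipy.stats.hypergeom.sf(k−1, N, K, n)`;
  argument constraints validated, k = 0 returns exactly 1.
* Empty prediction sets: dataset statistics report missing frequency/p rather
  than raising; empty node classes yield an empty profile with a warning;
  proteins without partners yield empty predictions with a warning.
* Tie-breaks: zero expression deviation scores γ = 0; prediction ranking
  breaks p-ties by larger partner count, then term id.
* All randomness (generator, hold-out sampling, baselines) flows through
  `numpy.random.default_rng` seeded from the caller.
* Pipeline runs are deterministic: identical config and bundle give
  byte-identical TSV outputs (GraphML is excluded from the byte-level claim
  only because attribute ordering is library-controlled; counts round-trip).

## Problem sizes used in the checks

The shipped test and acceptance runs use the default 240-protein / 120-pair
bundles (seconds per build), 20-seed sweeps for recovery and score
separation, an exhaustive hypergeometric oracle up to population size 12, and
a 30%-hold-out guilt-by-association evaluation (~30 targets per seed). These
sizes give exact oracles where exactness is possible and comfortable
statistical margins elsewhere.
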