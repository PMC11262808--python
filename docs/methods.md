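# Methods

This note documents the models and procedures implemented in `famvar`, the
assumptions behind them, the parameters that matter, the synthetic-data
design, and the numerical choices made where the design was genuinely open.

## Cohort model and preprocessing

The unit of analysis is a germline missense variant observed in one or more
sequenced members of a small set of high-risk families. The package assumes
variants arrive pre-annotated (gene, protein change, optional genomic
coordinates on a pass-through build tag, population allele frequency,
carriers); no alignment, variant calling or consequence annotation is
performed. Residue numbering is 1-based throughout, matching protein-change
notation such as p.T305M.

Two filters define the analysis dataset:

* **Rarity** (`max_af`, default 0.01): exclude variants with population
  frequency strictly above the threshold; exactly 1% is retained, since the
  intent is to exclude common polymorphisms, conventionally defined as
  *above* 1%. Missing frequencies are retained by default
  (`missing_af="keep"`): the cohorts this tool targets come from populations
  under-represented in frequency databases, where absence of a record is
  weak evidence of rarity rather than of error. The switch `"drop"` inverts
  this.
* **Segregation** (`min_affected`, default 2): a variant must be carried by
  at least two *affected* members of at least one family; unaffected
  carriers never count, and the threshold is evaluated per family, never
  pooled across families. Families with fewer affected members than the
  threshold (e.g. a single sequenced patient) would be wholly excluded under
  a strict reading; the default `small_family_rule="all_affected"` instead
  retains their variants when every affected member carries them, which is
  how such families contribute variants in practice. `"strict"` restores the
  hard rule.

Both filters only remove, are idempotent, commute, and log every decision so
that removed + retained always equals the input count.

**Cross-family recurrence** lists, per variant, the families in which every
sequenced affected member is a carrier; only families with more than one
affected patient are eligible (a single carrier trivially "recurs"), and a
variant is called recurrent when two or more such families appear.

## Predictor scores and normalization

Three score families are ingested, never computed: an evolutionary
(alignment-based) model pooled with its k-nearest-neighbour imputed
extension, a protein-language-model masked-marginal log-odds, and a
molecular-feature functional-impact model. The package deliberately treats
them as opaque per-variant numbers with three conventions:

* raw orientation per model (`higher_is_pathogenic` for the two [0,1]-scaled
  models, `lower_is_pathogenic` for the log-odds);
* min-max normalization per model **over the entire loaded dataset** (not
  per family, not per gene), with the reversed orientation flipped as
  1 − norm(X), so S = 1 is always the most deleterious observed score;
  normalization is computed before any eligibility restriction;
* availability indicators and the model count M per variant. Variants with
  M < 2 stay in the dataset (they still participate in family-level
  ranking and per-family percentiles of the models that did score them) but
  are ineligible for the dataset-level rank.

Evolutionary-model lookups guard against isoform/numbering mismatches by
window matching: the variant residue with five flanking residues each side
(an 11-mer, clipped at the termini) must occur exactly once in the database
protein sequence; zero or multiple occurrences yield an absent score with a
log entry. The window construction (flank width) is a parameter. Direct and
imputed scores share one normalization, since they are published on the same
scale and pooled upstream.

Language-model inputs longer than 1022 residues are cut to a 1022-residue
window centred on the variant and shifted to stay inside the sequence; the
returned index always points at the same residue. The masked-marginal score
itself is the log-odds difference and is antisymmetric under swapping
wild-type and mutant with exchanged log-probabilities. Per-position
log-probability tables from either masking strategy are accepted; the
strategy is metadata, not behaviour.

Diagnostics: pairwise Pearson correlations (two-tailed p) between models on
jointly scored variants, and a raw-score comparison between allele-frequency
strata (0–1%] vs (1–2%] — Welch's t-test by default since score variances
differ between strata and no distributional assumption is worth defending; a
Mann–Whitney alternative sits behind a flag because the published analysis
does not state its test.

## Structural interface proximity (DIST)

A variant residue close to another protein chain in a deposited complex is
more likely to perturb a protein–protein interaction. Per structure, the
score takes the minimum Euclidean distance between all atoms of the mapped
variant residue and all atoms of every other chain, and places it on the
ladder 2, 3, 4, 6, 8, 12, 16 Å: the rung is the smallest ladder value ≥ the
minimum (a distance exactly on a rung qualifies, reading "pairs within
threshold t" as distance ≤ t); beyond 16 Å the score is absent. Across
multiple structures the minimum rung wins — the most contact-proximal
evidence available. Numerical choices:

* heavy atoms only (hydrogens are rarely deposited and would bias rungs);
  waters excluded; alternate locations resolved to highest occupancy;
* "adjacent chains" are the other chains of the deposited model as given in
  the file; no symmetry mates. Non-polymer (ligand/ion) chains are excluded
  by default and can be included with a flag, since published analyses are
  ambiguous about het chains;
* variant→residue mappings are inputs (TSV); `naive` mode additionally
  requires author residue number == variant position and residue identity ==
  wild-type amino acid, skipping (with a log) anything else;
* the interface flag used by family-level ranking is rung ∈ {2, 3}: the
  DIST *score* must be below 4 Å, so a raw minimum of 3.9 Å (rung 4) does
  **not** qualify. Rigid transforms of a structure leave the score unchanged
  to well below the 1e-6 Å level.

## DSRank

D_i is the mean of the available normalized scores, restricted to M ≥ 2 so a
single model can never carry a variant alone. μ and σ are computed over the
eligible variants only; the candidate threshold is μ + 2σ, inclusive ("2 SD
or more above"). σ uses the population convention (divide by n) by default —
the eligible set *is* the population of interest, not a sample from a larger
one — and the convention is recorded in the summary so the sample alternative
is auditable. Fewer than two eligible variants is a hard error rather than a
degenerate threshold.

## FAMRank

Each (variant, carrying family) pair is assigned the highest risk group whose
condition holds; evaluation order is irrelevant by construction:

| group | condition |
|---|---|
| 5 | interface-proximal and top decile by ≥ 1 model; or top decile by all three models; or recurrent in ≥ 2 eligible families and top decile by ≥ 1 model in one of them |
| 4 | top decile by two models; or interface-proximal |
| 3 | top decile by one model and carried by all (affected) members of a multi-patient family |
| 2 | top decile by one model |
| 1 | otherwise |

The top decile is rank-based — the top ⌈0.10 · n_scored⌉ variants of the
family by one model's normalized score, ties at the cutoff included — which
stays well defined for tiny families (a 9-variant family flags exactly one
variant per model) and avoids interpolation ambiguity. Variants unscored by
a model are never flagged by it. The "prevalent in all family members"
condition counts affected members only by default (`prevalence_scope`),
switchable to all sequenced members; both it and the recurrence clause are
gated to families with more than one affected patient. A variant carried by
several families takes its maximum group; groups 4–5 are candidates, and the
final candidate set is the union with the dataset-rank candidates.

The per-family relation between variant count and number of group-4/5 flags
(with its Pearson r) is reported because the rule set is rank-based within
families: bigger families mechanically admit more flags, a known noise
source for the family-level ranker.

## Enrichment and background sampling

Term enrichment of the candidate genes against the dataset's gene universe
uses the one-sided hypergeometric upper tail (equivalently Fisher's exact
test for enrichment): with N background genes, K annotated, n candidates and
a annotated candidates, p = P(X ≥ a). Candidates are a subset of the
background; background genes with no annotation at all are removed before
testing, so the universe is the annotatable genes. Benjamini–Hochberg is
applied within each annotation namespace by default (component and function
terms answer different questions), with a global switch. Only
over-representation is tested.

Random background samples (default 20 draws of 80 genes, without replacement
within each draw, seeded) are exported as plain gene lists for external
interaction-enrichment services; the package does not query any live
service, it only prepares and controls the inputs.

## Synthetic cohorts

The generator's defaults encode the study conditions the package targets:
12 families with the study's affected/unaffected counts (1–5 affected),
per-family variant counts from a negative binomial (mean 120, shape 2,
spanning roughly 9–243), per-model coverage 0.82/0.97/0.73, structural
coverage 0.12, and correlation targets 0.60 between the two sequence-based
models and 0.35 for the pairs involving the molecular-feature model —
higher sequence–sequence correlation, as observed for real predictors.

Correlation is induced by a Gaussian copula: one trivariate-normal draw per
variant with the target correlation matrix (checked positive semi-definite),
pushed through monotone margins — probit (Φ) for the two [0,1]-scaled models
and a negative linear margin (location −6.11, scale 1.5) for the log-odds
model. Monotone margins nearly preserve Pearson correlations (attenuation
≤ ~2.5%), which the shape tests account for. Coverage masks are independent
Bernoulli draws per model.

Planted variants (default 12, spread round-robin across families) receive a
single deterministic extreme raw value in every model that covers them — the
raw upper bound 1.0 for the [0,1] models, a fixed offset below the observed
minimum for the log-odds model — so their normalized scores sit at or above
any configured quantile *by construction*, even when planted variants exceed
1% of a model's covered set. By default planted variants are covered by all
three models: a planted variant with fewer than two scores would be
structurally invisible to the dataset ranker and capped at group 2–3 by the
family ranker, which would say nothing about the rankers themselves.
Cross-family recurrent variants (default 5) and an optional fraction of
common (>1% frequency) contaminants exercise the recurrence detector and the
rarity filter; the generator records which variants it made common so filter
output can be compared exactly.

Toy structures are two-chain poly-glycine models: chain A lies in a plane
containing the variant residue, and a single chain-B residue is placed so the
closest inter-chain atom pair is *exactly* the requested distance — only the
geometry matters to the DIST score. Everything is deterministic under
(config, seed), byte-identical on re-write.

What the generator does **not** emulate: linkage between variants, realistic
allele-frequency spectra, sequence-dependent score structure, realistic
folds, or genes carrying multiple variants at realistic rates. Passing
recovery tests therefore demonstrates that the rankers find what the score
model says is extreme under study-shaped sparsity and correlation — not
performance on real genomes.

## Problem sizes and determinism

Tests and the acceptance script run on cohorts of roughly 1200–2000 variants
(12 families), 20 generator seeds for recovery estimates, 200 random toy
structures for the distance-oracle sweep, and all 2×2 tables with N ≤ 30 for
the exact-tail sweep — sizes chosen so the whole suite completes in well
under a minute while keeping binomial/Fisher-z tolerances tight. All
randomness flows from explicit seeds (`numpy.random.default_rng`); the
pipeline re-run with identical config and inputs produces byte-identical
manifests.

## Known limitations

* Only single amino-acid missense substitutions; no indels, splice,
  synonymous or loss-of-function variants, and no clinical covariates.
* The published counts of the motivating study can only be recomputed from
  its per-variant supplementary tables, which are not redistributable with
  the package; the corresponding check looks for them under `data/study/`.
* The rule-table interpretation switches (prevalence scope, SD convention,
  rung-vs-raw-distance for the interface condition) default to the readings
  argued above but remain configurable because the source descriptions are
  ambiguous; reports emit both per-family count semantics (per-algorithm
  totals with intersection, and exclusive counts) rather than guessing.
* Enrichment results depend entirely on the annotation map supplied; the
  package ships no ontology.
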