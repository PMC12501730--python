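# Methods

This note documents the models, rules and numerical conventions the
package implements, the choices made where the underlying workflow leaves
the design open, and what the synthetic-data tests do and do not show.

## Scope and data model

The unit of analysis is the *patient-variant pair*: a gene symbol, a
coding-DNA change (HGVS "c." description), a protein change (HGVS "p."),
zygosity, a set of ACMG evidence tokens, optionally a reported
classification, the gene's inheritance modes (AD / AR / XLR) and carried
annotations (DANN score is stored but never used in any computation).
Pre-triage calls additionally carry a variant fraction, up to three
population frequencies (gnomAD, 1000 Genomes, ESP), a ClinVar assertion
and two splice-predictor verdicts (Mutation Taster, Human Splicing
Finder). Predictor scores themselves are consumed as input annotations;
the package never computes them.

### HGVS-lite parsing

Only the subset of HGVS that panel reports actually print is supported:
substitutions, deletions, duplications, insertions and delins on coding
coordinates, with signed intronic offsets (`c.12067-2A>G`,
`c.802-8_810delinsGC`), and protein substitutions, stop gains,
frameshifts (`fs*N` ≡ `fsTerN`), synonymous changes and the unknown
effect `p.?`. Inversions, genomic/mitochondrial coordinates, allele
lists and reference-sequence validation are out of scope. Published
tables replace ASCII hyphens with en/em dashes and insert stray or
non-breaking spaces; all parsers normalize dash variants and whitespace
first, and `raw_text` preserves the original typography without
participating in equality. Transcript identifiers are stored verbatim
and never validated; matching ignores them.

### Consequence classification

Protein-level evidence takes precedence over the DNA edit kind:
frameshift → `frameshift`, stop gain → `nonsense` (so a DNA delins whose
annotated protein effect is `p.Ile582*` counts as nonsense), residue
substitution → `missense`, same-residue → `synonymous`. Only when the
protein effect is unknown does the DNA description decide: intronic
substitutions within `splice_window` (default 20 bp, the panel's
junction-capture width) of a junction are `splice_site`, deeper ones
`intronic_other`; non-substitution intronic edits keep their DNA edit
kind, so an intronic deletion is reported as `deletion`, not
`splice_site`. The alternative reading — binning near-junction intronic
deletions as splice-site — is defensible; it is not taken because the
reference cohort demonstrably assigns at least one intronic deletion to
the deletion bin, and the ambiguity is handled by *reporting* rather than
asserting the affected classes (below).

## Triage cascade

Four independent per-call predicates, applied in the conventional order
VAF → frequency → ClinVar → consequence. Because each stage depends only
on the call, the survivor set is invariant under stage permutations
(property-tested over all 24 orderings); only the removal attribution
changes. Boundary conventions are inclusive except where the workflow's
wording is "below": VAF ∈ [0.15, 1.0] inclusive, DNA-purity ratios ∈
[1.8, 2.2] inclusive and input mass ≥ 100 ng at sample QC, but maximum
frequency < 0.001 strictly. Frequency aggregation is the maximum over
available databases; calls absent from all three pass by default
(`missing_frequency_passes`) — a rare-disease triage must not discard
unobserved variants. ClinVar `conflicting` and absent assertions are
kept; only unambiguous Benign/Likely-benign excludes. Synonymous calls
are removed only when *every available* predictor says no effect
(configurable to any-predictor); with no predictions available they are
kept conservatively. The funnel report validates conservation on every
run: per-stage removals plus survivors partition the input.

## Evidence combination

`richards` mode implements the guideline rule table at face-value token
strengths. Strength modulation (PVS1 downgrades, PM2-as-supporting and
similar) is deliberately not implemented: reports print bare tokens, and
guessing a third-party engine's internal adjustments would fabricate
information. The consequence is visible and quantified: the
reconciliation report measures, per record, whether the rule table
reproduces the reported class, and rows it cannot explain (e.g. PM2+PP4
printed as LP) are listed as discordant. Concordance is a *measured
quantity*; the test suite asserts that discordance is surfaced, never
that it is zero.

Conflicting evidence: under the default `pathogenic_dominant` policy a
firing pathogenic combination wins over benign codes (matching how a
report can print BS2 alongside a Pathogenic call); under `strict`, any
co-occurrence of pathogenic- and benign-category codes yields VUS. The
strict reading treats "contradictory criteria" as contradictory
*evidence*, not merely contradictory fired combinations — a lone strong
benign code is enough to suspend judgement.

`points` mode sums signed weights (very strong 8, strong 4, moderate 2,
supporting 1; benign strong −4, supporting −1; BA1 short-circuits to
Benign) with bands P ≥ 10, LP 6–9, VUS 0–5, LB −6…−1, B ≤ −7. Weights
and thresholds follow the published Bayesian-points convention and are
configurable; they are stated defaults, not a claim about any commercial
tool's internals.

Both modes are checked against an independently coded brute-force
pattern-matching oracle: exhaustively on all token subsets of size ≤ 4
(~24k subsets, both conflict policies) and on randomized larger subsets;
monotonicity (adding pathogenic evidence never moves a call toward
benign) is property-tested under both modes and both policies.

## Case solving and cohort statistics

Published panel studies report "n patients diagnosed" without stating
the genotype rule that collapses variant rows into diagnoses; this
package makes the rule explicit, configurable in its engine input, and
auditable (each solved case lists its rule and records):

- (a) homozygous or hemizygous P/LP record;
- (b) ≥ 2 heterozygous P/LP records in one gene with AR among its modes,
  treated as a compound heterozygote — phase is *assumed in trans*
  (panel tables carry no phasing) and flagged `phase_assumed`;
- (c) a heterozygous P/LP record in a gene with AD among its modes.

Genes annotated "AD, AR" solve via either rule; rules are tried (a), (b),
(c). Patients whose only P/LP records are lone heterozygous hits in
recessive-only genes are returned as unsolved carriers. On the packaged
cohort this reproduces 70 solved of 94 (74%), with 6 carriers among the
76 patients listed.

Percentages are rounded half-up — two decimals for distribution shares,
nearest integer for the headline yield — matching how such studies print
them (`59.79%`, `74%`). Distribution outputs accept an optional expected
count table; any class whose computed count differs is marked in a
`divergent` column. This is the designated mechanism for the known
binning ambiguity: the packaged cohort computes 45 missense / 11 splice /
2 deletion / 1 synonymous where the source tallies 46 / 12 / 1 / 0 (one
synonymous row and two intronic deletions can be binned differently),
while nonsense (23), frameshift (13) and delins (2) are unambiguous.
The divergence is surfaced, never reconciled away.

Novelty flags are set by exact match on (patient, gene, normalized cDNA)
between the novel-variant list and the cohort table; every list entry
must match exactly one record, and unmatched or doubly-matched entries
are errors, not drops — on the packaged tables this is a bijection onto
28 rows. Count reconstruction from printed subgroup percentages sums
per-subgroup `round_half_up(n·pct/100)`, recovering e.g. 69
consanguineous and 52 male patients from the demographics table.

The demographics fixture carries group-level statistics only; the
package never fabricates per-patient demographics from them. The
fixture also carries, untouched, the source's internal inconsistencies
(an "undiagnosed" subgroup of n = 24 alongside a narrative count of 18;
novel share printed both as 28% and 29%, the raw ratio being 28/97 =
28.87%); consumers see the transcribed numbers, not a reconciliation.

## Segregation checks

Purely genotypic Mendelian consistency per inheritance mode: recessive
homozygotes need one alternate allele from each available parent (an
available homozygous-reference parent → `inconsistent`); dominant
heterozygotes need a carrier parent, with both parents
homozygous-reference → `possible_de_novo`; X-linked hemizygous males
need a carrier mother, a reference mother → `possible_de_novo`. Any
required relative without a genotype makes the trio `uninformative` —
the check never guesses. Consanguinity and sibling genotypes are
annotation only. The implementation is verified against an exhaustive
allele-transmission enumeration over all parental genotype combinations
per mode, and the recessive verdict is symmetric in the parents.
Segregation results do not feed back into classification (no automatic
PP1 assignment): how a study's segregation data modified its reported
classes is not reconstructible from printed tables.

## Synthetic cohorts

`generate_cohort` plants, per patient: with probability `solved_rate`
(default 0.74, the emulated cohort's yield) a causal genotype under a
randomly chosen solving rule, with criteria drawn only from fixture
strings whose face-value rule-table class is P/LP under *both* conflict
policies (so engine configuration cannot break recovery); with
probability `carrier_rate` (default 0.08, matching the ~6/94 carrier
frequency observed in the packaged cohort) a lone heterozygous causal
record in an AR-only gene; plus Poisson(`background_mean` = 3) background
calls, each constructed to violate exactly one named filter and pass all
others. Failure values avoid the filter boundaries by construction
(failing frequencies in [2×, 10×] threshold, surviving ones in
[0, threshold/2] or absent; failing VAF ≤ ⅔ of the minimum), so planted
fates are recovered *exactly*, not statistically — the recovery tests
assert set equality, zero error. Consanguinity (default rate 0.734, the
emulated cohort's) is patient metadata only. Trios are generated
consistent with the planted genotype. All randomness flows from
`numpy.random.default_rng(seed)`; fixed seeds give identical cohorts
across platforms.

What the generator does **not** emulate: sequence context and real read
support, linkage between variants, annotation noise (conflicting or
erroneous database entries), genes outside the fixture's 45, and calls
that fail several filters at once. Passing recovery tests therefore
demonstrate the pipeline's bookkeeping and rule logic, not robustness to
messy real-world annotation; the fixture tables are the real-data
surface of the suite.

## Problem sizes and determinism

The test suite runs the exhaustive rule-table comparison at subset size
≤ 4, stage-order invariance over all 24 permutations on cohorts of
25–200 patients, and exact recovery at 200 patients — sizes at which
every property is checked completely in seconds on one CPU. Hypothesis
profiles are derandomized for reproducibility. Fixture files are guarded
by SHA-256 checksums and row counts so that transcription drift fails
loudly before it can shift any downstream statistic.

## Known limitations

- The ACMG engine consumes evidence tokens; it does not assign them from
  raw annotations (no PS1/PM5 lookups, no PP3 from in-silico scores).
- No VCF joint/multi-sample handling; the minimal VCF reader ingests
  single-sample files with documented INFO/FORMAT keys.
- Compound-heterozygote solving assumes trans phase; with real phasing
  data this rule would need genotype-aware refinement.
- The rule-table engine intentionally cannot reproduce reported classes
  that relied on a scoring engine's internal strength modulation; the
  reconciliation report quantifies that gap instead of modelling it.
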