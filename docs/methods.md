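# Methods

## Scope and data model

`vpptbench` evaluates in-silico variant pathogenicity prediction tools
(VPPTs) on ancestry-specific benchmarks and applies the resulting tool
workflows to classify variants of uncertain significance (VUS). The unit of
analysis is the single-nucleotide substitution: indels and MNVs are rejected
at read time. Keys are `(chrom, pos, ref, alt)` with 1-based, fully closed
coordinates; `chr` prefixes are stripped and alleles upper-cased so keys
compare across the VCF and multianno-TSV dialects. Missing numeric fields
(`.` or empty) map to "missing", never to 0 — 0 is a valid score for many
tools.

Multi-valued per-transcript score strings (e.g. `0.12;0.87`) are collapsed
to the most-deleterious value. Because every numeric column is
pre-normalized so that higher means more deleterious, "most deleterious" is
the maximum; the reduction is configurable for callers handling raw
lower-is-worse columns. This conservative convention is a documented choice
— annotation pipelines differ here, and the effect is to never understate a
tool's deleteriousness call for a variant with any qualifying transcript.

## Benchmarks

Labels are parsed case- and underscore-insensitively. Pathogenic/Likely
pathogenic → positive (PV); Benign/Likely benign → negative (BV); Uncertain
significance → VUS; anything conflicting, combined across polarities, or
uninterpretable (drug response, empty) → unclassified and excluded. The
rare filter keeps cohort MAF strictly below the threshold (default 1%);
variants with missing cohort MAF are retained, since a cohort-private
variant is by construction rare, and the retention count is logged.

Merging the ClinVar- and InterVar-derived benchmarks unions each polarity
with same-polarity duplicates counted once. A key positive in one source
and negative in the other is a cross-source conflict; by default the
ClinVar call wins (ClinVar reflects externally submitted, often functional,
evidence while InterVar is rule-derived), and a `drop` policy removes
conflicted keys from both sets. Either way the merged sets are provably
disjoint.

## Tool registry and binarization

The registry declares all 54 tools: numeric tools carry the published
cut-off and the published inequality (strict `>` for CADD at 20, `≥`
elsewhere); categorical tools carry their dbNSFP prediction alphabet with
the deleterious subset (e.g. `{D}` for SIFT, `{D, P}` for PolyPhen2,
`{H, M}` for MutationAssessor, `{A, D}` for MutationTaster, `{P}` for
AlphaMissense). The published material does not enumerate per-tool code
sets, so these follow each tool's documented prediction alphabet and are
user-overridable in the registry file. A variant with neither a usable
score nor a prediction for a tool is a no-call. LINSIGHT is marked
non-coding-only.

`family` groups near-duplicate score variants of a single underlying model:
MetaSVM/MetaLR, Eigen-raw/Eigen-PC-raw, BayesDel-addAF/noAF, the PolyPhen2
pair, the four VARITY variants, the four fitCons cell lines, the phastCons
and phyloP alignments, GERP-NR/RS, and SIFT/SIFT-4G. Family membership
matters only to workflow selection (below).

## Performance metrics

Confusion counting is complete-case per tool: no-call variants contribute
to none of the four cells, so each tool is scored on the variants it
actually covers. Rate metrics with an empty denominator are undefined
(reported as missing, excluded from means); an MCC with a zero denominator
is reported as 0 and flagged degenerate, which keeps all-one-class
predictors (e.g. a tool calling everything benign) sortable without
inventing a rate. Report tables round to 2 decimals; all internal
computation is full precision. Paired tool-wise comparisons between
ancestries use the two-sided paired *t*-test by default with the Wilcoxon
signed-rank test available; the reference publication does not name its
test, so neither is asserted to reproduce its printed p-values exactly, and
tests only require the sensitivity gap to be strongly significant under
both.

## Workflow selection

From a per-tool metric table the selector (1) drops tools with FPR above
0.3 (strictly), (2) drops non-coding-only tools, (3) keeps the best member
of each tool family by the rank metric, (4) ranks by sensitivity descending
with ties broken by lower FPR, then higher MCC, then name, and (5) takes
the top 10. Every knob is configurable (`SelectionPolicy`).

The rank metric is not stated in the source material; ranking by
sensitivity with family collapse is the policy that exactly reproduces both
published 10-tool sets from the packaged reference metrics, and is
therefore the documented default, flagged as inferred. Family collapse is
essential twice over: without it MetaLR and Eigen-PC-raw crowd GERP-RS and
MVP out of the African set, and BayesDel-addAF — tied with REVEL at
European sensitivity 0.78 but with far lower FPR — displaces REVEL from
the European set unless the BayesDel pair is collapsed.

## VUS classification

VUS are the rare variants left after removing benchmark PVs/BVs and
variants with population (gnomAD-style) allele frequency strictly above 1%;
a missing population AF is retained, absence from the reference panel being
itself evidence of rarity. The AF filter applies before the
consequence-based route, so a globally common stop-gain does not enter the
PDV set.

A VUS is a potentially deleterious variant (PDV) when at least `min_agree`
of the workflow's tools call it deleterious (no-call counts as
not-deleterious), or automatically when its consequence is stop-gain or
canonical ±2 bp splice-site (consumed from upstream annotation, not
recomputed). The consensus requirement defaults to unanimity — the
strictest reading of a "10-tool criteria" — and is exposed prominently
because it drives PDV counts; the consensus reason takes precedence in the
record when both routes fire. A PDV with a pLoF or oncogenicity flag is a
potentially oncogenic variant (POV); the two routes are unioned with the
contributing flags recorded. `POV ⊆ PDV ⊆ VUS ⊆ rare` is asserted on every
pipeline run.

Cross-workflow comparison re-classifies a cohort's VUS under the other
ancestry's workflow and reports absolute and percentage PDV changes, plus
the same restricted to each workflow's unique (non-shared) tools. For the
unique-tool subsets the consensus threshold scales with the subset:
unanimity stays unanimity, otherwise `min(min_agree, subset size)` — the
source material does not state a rule for the subset comparison, so this is
the package's own convention.

## Synthetic cohorts

The generator emulates the *statistical shape* of the real paired-cohort
study: two cohorts with configurable variant counts, rare fractions,
truth-class fractions, and label-surfacing probabilities per source
(the knob that mimics the scarcity of African clinical labels), plus
per-variant consequence, pLoF and oncogenicity annotations and per-tool
scores drawn from class-conditional models. Numeric tools use Gaussians per
truth class; categorical tools use confusion probabilities. Each tool's
analytic operating point is available in closed form
(`expected_performance`), which is the oracle for every recovery test.

Defaults (`default_config`) ship two cohorts shaped like the study at
roughly 1/1000 variant scale: AFR 20,000 variants (rare fraction 0.235),
EUR 12,400 (0.318), 50 patients each, preserving the ~1.6× African excess
of variants, the European excess of surfaced clinical labels, and each
tool's ancestry-specific published operating point (unit-variance Gaussians
or confusion probabilities placed to hit the published
sensitivity/specificity at the published cut-off, with rates of exactly
0/1 clamped to 0.01/0.99). Truth-pathogenic and truth-benign variants are
drawn rare with probability 0.9 — known clinical variants are
predominantly rare — while neutral variants follow the cohort's rare
fraction; `expected_rare_fraction` gives the resulting analytic rare
fraction used by calibration tests. Sizes were fixed once so that the
default benchmark carries enough labelled variants (~70–100 PVs per
cohort) for stable metric estimates while a full two-cohort pipeline run
stays in single-digit seconds.

Randomness uses one explicit seed with an independent substream per
(cohort, tool) keyed by CRC32 of the names, so adding or removing a tool
never perturbs any other column; fixed seeds give byte-identical output
files.

What the generator deliberately does **not** model: linkage disequilibrium
and haplotype structure, realistic site-frequency spectra, gene or
transcript structure, correlation between tools (every tool's scores are
conditionally independent given the truth class), or correlation between
consequence, pLoF and truth beyond the configured marginal probabilities.
Passing recovery tests therefore demonstrate that the *pipeline machinery*
is correct and calibrated — not that any tool performs as simulated on
real genomes, where tool errors are strongly correlated and label
ascertainment is non-random.

## Numerical and reporting conventions

- Binarization at the cut-off follows the published inequality symbol
  exactly; a score equal to CADD's 20 is benign, equal to SiPhy's 12.17 is
  deleterious.
- Selection tie-breaks (lower FPR, higher MCC, name) make the workflow a
  deterministic function of the metric table, invariant to row order.
- Paired tests drop pairs with an undefined member; identical vectors
  return statistic 0, p = 1 rather than NaN.
- Report rounding: metrics 2 decimals, percentage changes 1 decimal, fold
  changes 1–2 decimals per quantity; JSON summaries carry exact integers.
- Pipeline outputs contain no timestamps; `audit` recomputes every summary
  count from the emitted TSVs.

## Limitations

The packaged reference metric table is transcribed at the 2-decimal
precision of its source, so quantities derived from it (means, selections)
inherit that granularity. The evaluation consumes upstream annotations
(ClinVar, InterVar, consequence, pLoF, oncogenicity, tool scores) as given
and does not run any annotation tool itself. The selection policy and the
unanimity consensus are inferred, documented choices; both are single-flag
configurable.
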