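# Methods

## Data model and harmonization

A benchmark panel is a rectangular variants × tools grid. Each variant
carries a gene symbol, a curated truth label (pathogenic/benign), the
evidence class behind that label (in vitro functional characterisation,
family co-segregation, or population allele frequency), an optional
allele frequency, and a protein-region annotation drawn from {n_term,
transmembrane, c_term, loop, unassigned}. Each cell holds one tool's
categorical call in that tool's native vocabulary plus an optional
continuous score.

Harmonization maps native vocabularies onto {damaging, tolerated} via
per-tool lookup tables (case- and whitespace-insensitive). The shipped
tables cover PolyPhen-2 (with both "Probably damaging" and "Possibly
damaging" collapsed to damaging), SIFT, PROVEAN, SNPs&GO, SNAP,
Meta-SNP and PredictSNP; users extend or override them through the YAML
schema config. A label outside a tool's declared vocabulary is an error,
never a silent coercion: vocabulary drift between tool versions is a
real failure mode and must surface loudly.

Truth labels are admitted by an inclusion filter: pathogenic requires
functional or co-segregation evidence; benign requires functional
evidence or allele frequency strictly greater than 0.01 (the comparison
is strict, matching the "greater than 1%" convention). The filter
partitions its input into kept and rejected-with-reason; it never
raises.

Missing tool outputs are first-class (`missing` calls, empty/sentinel
cells in TSV). They are retained at parse time; the voting layer decides
what to do with them (below). Panel TSV serialization is a fixed point:
write∘read is byte-stable, with scores written via `repr` so floats
round-trip exactly.

## Consensus voting

For a committee of size k the consensus is damaging iff the number of
damaging votes d satisfies 2d ≥ k. This single closed form reproduces
every enumerated per-size condition of the published voting table for
k = 2..5 (verified exhaustively in the tests against a literal
row-by-row transcription), including the even-committee tie going to
damaging. The tie direction is a deliberate clinical choice: over-calling
is recoverable by segregation follow-up, under-calling may end the
work-up. Size-1 "committees" run through the same code path so single
tools and metaservers are evaluated identically.

Missing-call policy, per committee per variant:

- `exclude` (default): any missing member call masks the variant out of
  that committee's confusion matrix. This keeps each matrix's semantics
  clean at the cost of varying denominators across committees.
- `reduce`: the vote runs on the non-missing subset (≥ 1 call) with the
  same tie rule.

The choice is exposed because the reference analysis does not state its
handling; `exclude` is the default since it never manufactures a vote
from a smaller committee than the user asked for. Varying denominators
under missing data are the most plausible cause of the small
internal inconsistencies in some published accuracy figures (see
Limitations).

Metaservers are consensus products themselves; they are evaluated as
singletons only and never mixed into committees.

## Metrics

All metrics derive from integer TP/FP/TN/FN counts; division happens
once, at the end. Sensitivity, specificity and accuracy are percentages;
MCC is the Pearson correlation of the binary prediction/truth vectors,
computed from the counts (the tests verify the equivalence to 1e−12 on
10,000 random matrices). Conventions for degenerate matrices: a zero
denominator makes a rate NaN (rendered "NA" in reports, never an
exception); MCC with any zero marginal returns 0.0 with a `degenerate`
flag — this keeps MCC rankings total while marking the rows where the
value is a convention rather than a measurement. Reports round to one
decimal (percentages) and two decimals (MCC); machine-readable TSVs keep
full precision so rounding order can never change a conclusion.

`reconstruct_confusion` inverts the reporting direction: given class
sizes and one-decimal printed sensitivity/specificity it scans all
integer TP/TN values and returns the matrix iff it is unique (half-up
rounding, as benchmark tables print). This is how the acceptance script
re-derives the reference matrices from published summary numbers rather
than hard-coding counts.

## ROC and DeLong intervals

Scores are first oriented to the high-means-damaging scale: fixed
per-tool polarity by default (SIFT and PROVEAN negated), with an `auto`
mode that picks the orientation giving AUC ≥ 0.5 and records the
choice. Fixed polarity is the default for benchmark replication because
published per-tool AUCs below 0.5 imply the reference analysis did not
auto-flip.

Thresholds run over all distinct oriented scores plus +∞; a variant is
called damaging when its oriented score is ≥ the threshold, making
curves bit-reproducible under ties. AUC is the trapezoidal area, which
equals the tie-corrected Mann–Whitney statistic U/(n_pos·n_neg) with
ties scoring ½ (property-tested against brute-force pair counting).

The confidence interval uses DeLong's structural-components estimator:
placement values V10 (each pathogenic score's fraction of benign scores
it beats, ties ½) and V01, variance S10/m + S01/n with ddof = 1, and a
normal interval auc ± z·se clipped to [0, 1]. Perfect separation gives
zero variance; the interval is then zero-width and flagged `degenerate`.
Monte-Carlo calibration (2,000 binormal replicates, n = 200/200, true
AUC 0.8) keeps empirical 95% coverage inside [0.93, 0.97] in the test
suite.

## Comparative statistics

Pairwise tool association uses the phi coefficient of the harmonized
binary calls, computed from the 2×2 table with pairwise deletion of
missing calls; a constant vector yields NaN. Calls, not scores, are the
default because the question is whether the votes being combined are
redundant; a Spearman score mode exists for completeness.

Kruskal–Wallis is implemented from the rank formula with mid-rank tie
correction and a χ² p-value (k−1 df); all-identical data short-circuits
to H = 0, p = 1. The implementation is cross-checked against
scipy.stats.kruskal to 1e−10 on random inputs. For comparing accuracy
across tools/combinations the observations fed to the test are
per-variant correctness indicators (1/0) grouped by combination — the
only sampling unit that gives the test non-trivial group sizes; a
per-gene-accuracy alternative is available by passing those values
directly.

## Synthetic panel generator

The generator emulates the statistical structure of a multi-tool
benchmark, not any particular predictor. Per variant, a shared latent
difficulty z ~ N(0,1); tool t errs iff √ρ·z + √(1−ρ)·ε_t > Φ⁻¹(p_t),
with ε_t tool-private N(0,1) noise and p_t the tool's configured
sensitivity (pathogenic variants) or specificity (benign). The probit
threshold gives exact marginal control — expected correctness equals p_t
for every ρ — while ρ ∈ [0, 1) is a single dependence knob (Gaussian
copula). Scores are drawn conditional on the emitted call
(probit-squashed normals with a per-tool separation parameter, mirrored
for low-is-damaging tools), so call and score never contradict. Evidence
fields are drawn so every generated record passes the inclusion filter
(benign-by-frequency variants get AF in (0.011, 0.05)). All randomness
flows from one seeded `numpy` generator; identical configs give
byte-identical panels.

The default `lqts_benchmark_config` fixes the composition of the curated
three-gene LQTS census: KCNQ1 101 pathogenic / 8 benign, KCNH2 82/8,
SCN5A 99/14 — 312 variants — scored by the five tools plus two
metaserver columns. (The corresponding abstract-level totals of 283/29
disagree by one with the per-gene table that sums to 282/30; this
package follows the per-gene table.) Per-tool error rates are free
parameters of the simulation, chosen once as plausible for this tool
class on curated channelopathy panels (sensitivities 0.85–0.93,
specificities 0.5–0.7, metaservers at the stronger end), with ρ = 0.3
for the positive inter-tool correlation such tools exhibit, and
missing_rate = 0 so stratum denominators equal the census counts. SCN5A
variants receive region labels (10% N-terminus, 35% transmembrane, 15%
C-terminus, 40% loop — roughly the even membrane/loop split of that
channel's topology) to exercise the two-group region stratification.

What passing tests on synthetic panels do *not* show: real predictors'
errors are not exchangeable across variants (conservation, domain
structure), their score distributions are not probit-normal, and their
dependence is not a single-ρ copula. The generator validates the
*pipeline arithmetic* — voting, stratification, metrics, ROC — not any
claim about how real tools perform.

## Pipeline and reports

`evaluate_all` produces one evaluation per (committee, stratum) in
deterministic order; strata are the genes, the pooled set, and
optionally per-gene collapsed regions ({n_term, transmembrane, c_term} →
`n_tm_c`, loop → `loop`). A stratum lacking a truth class warns and
carries NA sentinels; the run continues. Ranking is by MCC descending
with ties broken towards fewer tools, then higher specificity, then
lexicographic committee label; degenerate MCCs sort last. `run_report`
writes four files (combination metrics TSV, per-tool ROC summary TSV,
phi association TSV, JSON manifest with config/warnings) and is
byte-deterministic given the same panel.

## Numerical and testing choices

Problem sizes in the test suite (2,000 variants per class for rate
recovery, 2,000 Monte-Carlo replicates for interval coverage, 1,000 for
the Kruskal–Wallis null) are chosen so that 3σ binomial bounds make the
checks sharp while the whole suite runs in well under a minute on one
core. Hypothesis tests run derandomised for reproducibility.

## Known limitations

- No live querying of any predictor and no VCF/genomic coordinates:
  variants are protein-level identifiers and predictions arrive as a
  table.
- Voting is unweighted; no score averaging or stacking. Metaservers are
  consumed as given, never re-trained.
- The published per-gene accuracy figures that conflict with their own
  printed sensitivity/specificity (92.7% vs the implied 93.6% for
  KCNQ1; 81.4% vs 82.3% for SCN5A) cannot be reproduced from the stated
  counts; the package reproduces the internally consistent quantities
  and exposes the missing-call policies that most plausibly explain the
  discrepancy.
- DeLong intervals use the normal approximation; they are not
  recommended below roughly 10 observations per class (the
  implementation requires ≥ 2 and flags zero-variance cases).
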