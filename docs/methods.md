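# Methods

## Scales, tokens and transforms

Grades are 0-based integers.  The 5-point ICDR eye scale is 0 = no DR,
1 = mild, 2 = moderate, 3 = severe non-proliferative, 4 = proliferative.  The
4-point patient scale merges levels 3 and 4 into "sight-threatening DR"
(`compress_5_to_4`: 0→0, 1→1, 2→2, 3→3, 4→3), matching the output granularity
of patient-level automated screening software.  Referable DR is grade ≥ 2 on
either scale (the `rdr_cutoff` parameter; default 2, i.e. "more than mild").

`UNGRADABLE` is a first-class quality-failure token, serialized as `NA`, and
is deliberately distinct from a *missing* assessment (a grader who never saw
the eye has no row at all).  The exclusion rule keys on UNGRADABLE, while
missing assessments mark a record malformed.

Patient-level aggregation takes the maximum severity over a grader's gradable
eyes.  Because compression and binarization are monotone, they commute with
the maximum; the test suite asserts this exhaustively over all eye-grade
pairs.  If one eye is UNGRADABLE the gradable eye carries the patient grade;
such patients are normally excluded upstream, but the operation stays total
so the synthetic pipeline can be reconfigured freely.

## Exclusion flow

A patient is analyzable iff no human grader flagged any assessed eye
UNGRADABLE and the automated grade is present.  Excluded patients are counted
in exactly one bucket with a fixed precedence — malformed record, all raters
ungradable, any human quality flag, automated-grader-only — chosen so the
selection flowchart boxes are mutually exclusive and reproducible.  The
precedence itself is a bookkeeping convention (several orders would partition
the same patients differently between buckets); it is applied uniformly and
logged per patient so flows can be audited from logs alone.

## Consensus and adjudication

Per eye, three grades classify as 3:0 / 2:1 / 1:1:1 by the multiset pattern.
Unanimous and majority eyes resolve to the modal grade.  Fully discordant
eyes require an entry in the adjudication table (an external input: in real
studies adjudication is a human consensus meeting, not a computation); eyes
lacking one are collected into a worklist and the fit raises rather than
guessing.  **Override rule:** when an adjudication entry exists for an eye
that *does* have a majority, the entry wins.  Adjudication is treated as
stronger evidence than the raw vote, and studies that re-adjudicate all eyes
of problematic patients produce exactly this situation.  On a binary scale
1:1:1 is impossible (pigeonhole), so the referable-DR post hoc needs no
adjudication and uses the original grades.

The 4-rater patient taxonomy refines the partition of {h1, h2, h3, ai} by the
automated grader's position: 3:1 splits into "AI inside the agreeing triple"
vs "AI alone against three agreeing humans", and 2:1:1 into "AI in the pair"
vs "AI a singleton".  It is invariant under permutation of the human
positions but not under swapping the AI with a human.  An independent
brute-force classifier (literal pattern matching on the sorted values)
verifies it over all 4⁴ input combinations.

## Kappa

Cohen's kappa is computed from K×K contingency tables with K fixed by the
scale, not by the observed data, so zero-count categories are retained and
kappas are comparable across graders.  The headline statistics are
*unweighted* kappas on the 5-point per-eye scale, both eyes pooled: each
grader against the adjudicated final grades, and each unordered grader pair
(summarized per grader as the arithmetic mean of that grader's pairwise
values).  Linear and quadratic weighted variants are implemented
(1 − observed/expected weighted disagreement, with |i−j|/(K−1) and its
square) and selectable via `kappa_weighting`, but are never used for the
headline fields.  Degenerate convention: if expected disagreement is zero
(both raters constant and equal), kappa is 1.  The implementation is
cross-checked against scikit-learn's `cohen_kappa_score` on random tables to
1e-10 in the test suite; the library is a test oracle only, never the
implementation.

Percentages in report tables are rounded half-up to 2 decimals (whole
percents for prose-style summaries) and always recomputed from counts.

## Per-image accounting

Graders assign one grade per eye, but eyes carry a variable number of fundus
photographs.  Image-weighted agreement counts attribute each eye's
`n_images` to that eye's agreement class — the only attribution consistent
with one grade per eye.  When graders report different image counts for the
same eye the maximum is used.

## Synthetic generator

`SimConfig` parameterizes: number of patients; a 5-level true-severity
prevalence vector; inter-eye concordance ρ (the second eye copies the first
with probability ρ, else is drawn fresh — a copy mixture rather than an
ordinal copula, the simplest mechanism producing near-identical left/right
agreement levels); per-grader 5×5 row-stochastic confusion matrices and
per-eye quality-failure probabilities; a patient-level automated grader with
its own 4×4 confusion matrix (applied to the compressed true patient grade)
and ungradable probability; an images-per-eye range (uniform integer); an
adjudication policy; and a master seed.

Key modelling assumption: **raters are conditionally independent given the
true grade.**  Real graders viewing identical images have correlated errors;
the simplification is deliberate because it makes exact oracles available —
`analytic_kappa` builds the exact joint P(a=i, b=j) = Σₜ πₜ A[t,i] B[t,j] and
returns its kappa (identity B for kappa-versus-truth), and
`expected_agreement_frequencies` enumerates truth × three grader outcomes
(5⁴ terms) for the exact 3:0/2:1/1:1:1 probabilities.  Parameter-recovery
tests hold the generator to these oracles at 20,000 patients, using the
number of analyzable *patients* (not eyes) in the Monte-Carlo standard
errors, a conservative choice because the two eyes of a patient are
correlated.  Passing these tests shows the pipeline recovers a known
generating process; it does not validate the conditional-independence or
copy-mixture assumptions against real reading behaviour.

Default preset (a plausibility preset, not fitted to any particular study —
grader error structures are outputs of concordance studies, not published
inputs): 495 patients; prevalence (0.78, 0.11, 0.07, 0.025, 0.015), giving
roughly three-quarters DR-free patients after max-aggregation; ρ = 0.75;
three graders with banded confusion matrices (errors confined to adjacent
severity levels) of diagonal mass 0.75/0.90/0.80, spanning the moderate
reliability range reported for graders without dedicated DR-grading training;
quality-failure 0.025 per grader-eye; an automated grader with 0.70–0.80
diagonal mass, mild upward off-diagonal bias (screening devices are tuned to
over- rather than under-refer) and 0.15 ungradable probability; 2–3 images
per eye.  `adjudication_policy="truth"` emits adjudication entries equal to
the simulated true grade for every eye (so, with the override rule, final
grades equal truth exactly — which is what makes kappa-versus-final an
estimator of kappa-versus-truth); `"grader_median"` uses the median drawn
grade instead, for sensitivity checks.

Seed policy: the master seed derives an independent, label-addressed
substream per randomness source (truth, each grader's grades, each grader's
quality flags, automated grader, image counts) via `SeedSequence([seed,
crc32(label)])`, so adding a grader leaves all other streams untouched.
Fixed seeds give byte-identical output CSVs.

## Pipeline shape and sizes

The public surface is statsmodels-shaped: `GradingConcordance` (the model,
built from DataFrames, CSVs or a simulation) and `ConcordanceResults`
(tables, accessors, `summary()`, `save()`, a small agreement plot), with
`run_analysis` as a functional wrapper.  The pipeline accepts any panel of
G ≥ 2 graders; the 3-rater consensus, 4-rater taxonomy and referable-DR post
hoc are defined for G = 3 (the standard design), while other panel sizes get
the exclusion flow, generic multiset partition counts and pairwise kappas
only.

Report regeneration is deterministic (fixed row/column orders, sorted JSON
keys): rerunning on identical inputs is byte-identical, and a frozen golden
report from a verified fixed-seed run guards against silent pipeline drift.
Routine tests simulate 40–400 patients; large-sample recovery uses 20,000
patients, which keeps the whole suite under ~10 s while leaving Monte-Carlo
standard errors around 0.01 on kappa.

## Known limitations

* Correlated grader errors, intra-grader (test–retest) variability, and any
  image-level mechanism are not modelled; the automated grader is simulated
  directly at patient level, matching its observed output granularity.
* No confidence intervals or significance tests for kappa, and no
  multi-rater Fleiss kappa — the analysis mirrors designs that report point
  kappas only.
* Whether a human quality flag and an automated "ungradable" output share
  semantics is unknowable from summary data; both map to the same UNGRADABLE
  token but are sourced from different files, so they can be separated later
  without schema changes.
* The packaged study summary tables contain small internal inconsistencies
  (one truncated percentage; left+right eye totals of 669 against 670 eyes
  reported elsewhere, consistent with a single-eye patient or a typo).
  Recomputation always works from counts, and the consistency checks assert
  only the sums that do tie out.
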