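# drconcord

Multi-grader **d**iabetic-**r**etinopathy grading **concord**ance analysis.

Screening programs for diabetic retinopathy (DR) grade fundus photographs on
the 5-level ICDR severity scale (0 = no DR … 4 = proliferative DR).  When
several human graders read the same eyes — and an automated patient-level
grader such as an FDA-cleared screening device joins as a fourth rater — the
question is how much they agree, where they disagree, and what the final
reference grade should be.  `drconcord` is for biostatisticians and screening
researchers running exactly that kind of study: it implements the full
analysis pipeline (quality exclusion, eye-level consensus with adjudication,
agreement taxonomies, Cohen's kappa, a referable-DR binary post hoc) plus a
synthetic multi-grader data generator with exact analytic oracles, so every
stage is testable without access to raw clinical grades.

## The model

Each eye's true severity is an ordinal grade; each grader *g* assigns grade
*j* to a true-grade-*t* eye with probability given by a row-stochastic
confusion matrix *A<sub>g</sub>[t, j]*.  The analysis machinery is:

* **Consensus**: three graders' grades per eye are classified 3:0
  (unanimous), 2:1 (majority → modal grade) or 1:1:1 (fully discordant →
  external adjudication supplies the final grade).
* **Scale transforms**: patient grade = max over that grader's eyes; the
  5-point scale compresses to 4 points (severe non-proliferative and
  proliferative merge into "sight-threatening DR") to match automated
  patient-level output; referable DR (rDR) is grade ≥ 2 (moderate and above).
* **4-rater taxonomy**: the multiset of {3 human patient grades, automated
  grade} partitions into 4:0, 3:1, 2:2, 2:1:1 and 1:1:1:1, refined by whether
  the automated grader sits inside or outside the agreeing block.
* **Chance-corrected agreement**: Cohen's kappa,
  κ = (p<sub>o</sub> − p<sub>e</sub>) / (1 − p<sub>e</sub>),
  computed per grader against the adjudicated finals and per grader pair,
  from fixed-K contingency tables (weighted variants available).  Under
  conditional independence given the truth the joint distribution of two
  raters is P(a = i, b = j) = Σ<sub>t</sub> π<sub>t</sub> A[t, i] B[t, j],
  which yields exact analytic kappas and agreement-class frequencies used as
  simulation oracles.

## Worked example

The package ships the one fully printed piece of raw data from its reference
study: four patients for whom the three human graders and the automated
grader each assigned a *different* patient-level grade.

```python
from drconcord import GradingConcordance
from drconcord.datasets import load_discordant_quartet

grades, ai, adjudications = load_discordant_quartet()
results = GradingConcordance(grades, ai, adjudications).fit()
print(results.agreement4_counts["P1_1_1_1"])   # -> 4
print(results.summary())
```

The summary (abridged) prints:

```
Patients analyzed:                  4
----------------------------------------------------------------------
Eye-level agreement (3 human graders, 5-point scale)
     3:0:     0 eyes (  0.00%)      0 images
     2:1:     1 eyes ( 12.50%)      2 images
   1:1:1:     7 eyes ( 87.50%)     14 images
----------------------------------------------------------------------
Patient-level agreement (3 graders + automated, 4-point scale)
                 1:1:1:1:     4 (100.00%)
```

Seven of the eight eyes are fully discordant (the eighth is a 2:1 majority),
and after max-aggregation and scale compression all four patients land in the
1:1:1:1 four-rater pattern — every possible grade from no DR to
sight-threatening DR was assigned to each of them.

Synthetic data works the same way:

```python
from drconcord import GradingConcordance, simulate_dataset, default_config

sim = simulate_dataset(default_config(n_patients=500, seed=7))
results = GradingConcordance.from_simulation(sim).fit()
results.save("out/")          # CSV tables + report.json + summary.txt
```

A thin CLI wraps the same calls:

```sh
drconcord simulate --out sim/ --seed 7 --n-patients 500
drconcord analyze --grades sim/grades.csv --ai sim/ai.csv \
    --adjudications sim/adjudications.csv --out out/
drconcord report --bundle out/report.json --out rerender/
```

`analyze` exits with code 3 and writes `worklist.csv` when fully discordant
eyes still need a human adjudication round, and code 2 on schema violations.

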