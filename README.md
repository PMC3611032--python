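# ahpdx — AHP-weighted automated diagnosis over lab panels

`ahpdx` is a small clinical-decision-support library and CLI for
physicians and medical-informatics developers who want a transparent,
configurable rule engine over laboratory test results. A condition (an
illness) is described by a **profile**: its risk factors, pairwise
importance judgments among them, sex/age-stratified reference ranges,
and two percentage thresholds. The engine then diagnoses any patient's
lab panel in three steps:

1. **Weighting.** Pairwise judgments on the Saaty scale (1 = equal, 3 =
   moderate, 5 = strong, 7 = very strong, 9 = extreme importance) fill a
   reciprocal comparison matrix *A* with *aᵢⱼ = 1/aⱼᵢ*. The Analytic
   Hierarchy Process priority vector **w** is the normalized principal
   eigenvector of *A*, computed by iterated matrix squaring: square *A*,
   take row sums, normalize to Σwᵢ = 1, and repeat until the vector
   changes by less than a tolerance (default 10⁻⁶). A largest-remainder
   rounding gives an integer-percentage view that always sums to 100.
2. **Activation.** A risk factor *activates* when the patient's value
   lies strictly beyond a bound of the applicable reference range
   (ranges can be sex- and age-specific; the most specific match wins).
   Demographic factors such as age are evaluated from the patient record
   at the panel's collection date; symptoms via explicit observations.
3. **Scoring.** The diagnosis score is `100 × Σ {wᵢ : factor i active}`.
   A score at or above the profile's diagnosis threshold (default 80%)
   classifies as positive; at or above the critical threshold (default
   95%) it additionally raises a critical notification event.

Around the engine: an XML lab-panel dialect with a parser/writer, a
line-delimited record store with chronological listing, RSS 2.0
notification feeds, and a synthetic-cohort generator for end-to-end
evaluation (sensitivity/specificity against constructed ground truth).

## Worked example

The bundled `hyperglycemia` profile has four risk factors — HDL, LDL,
triglycerides and age — with HDL judged moderately more important than
LDL (3), both far more important than the rest (7 and 5), and
triglycerides equal to age. Deriving the weights:

```console
$ ahpdx weights --profile src/ahpdx/profiles/hyperglycemia.yaml --percent
HDL: 58%
LDL: 28%
Triglyceridea: 7%
Age: 7%
```

The converged weight vector is (0.582726, 0.282482, 0.067395, 0.067395);
the percentage view rounds it so the factors sum to exactly 100. Now
diagnose a male patient whose HDL is over 40 mg/dL and LDL under
80 mg/dL — both strictly outside their reference ranges, so both rows
activate:

```console
$ ahpdx diagnose --profile src/ahpdx/profiles/hyperglycemia.yaml \
    --patient patient.yaml --panel panel.xml
condition: hyperglycemia
patient:   p001  (panel 2012-06-01)
  HDL               58%  ACTIVE
  LDL               28%  ACTIVE
  Triglyceridea      7%  -
  Age                7%  -
score: 86.52%
classification: positive
```

The score is 100 × (0.582726 + 0.282482) = 86.52%, which clears the
default 80% positivity threshold, so the command exits with code 2
(0 = negative, 1 = error, 2 = positive, 3 = critical) for easy shell
scripting. The remaining subcommands — `upload`, `list`, `feed`,
`simulate`, `evaluate` — manage the record store, emit RSS feeds, and
exercise the engine on synthetic cohorts; each supports `--help`.

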