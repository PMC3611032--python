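# Methods

## The diagnosis model

A condition profile defines risk factors *f₁…fₙ* (n ≥ 2), pairwise
importance judgments, reference ranges and two thresholds. The model has
three stages.

**Priority weights (AHP).** Judgments are ratios on the Saaty scale —
1, 3, 5, 7, 9 for equal through extreme importance — and populate a
positive reciprocal matrix *A* (unit diagonal, *aⱼᵢ = 1/aᵢⱼ*). The
priority vector is the normalized principal eigenvector of *A*,
computed by the classical squaring iteration: repeatedly replace *A*
with *A²*, take row sums, normalize to sum 1, and stop when the maximum
absolute per-component change between successive normalized vectors
drops below `tol`. Because each squaring doubles the effective matrix
power, the iterate after *k* squarings equals the power-method iterate
at power 2ᵏ; four squarings suffice for 10⁻⁶ agreement on the bundled
4-factor profile, and the default cap of 20 squarings (effective power
2²⁰) is far beyond any practical need. The running matrix is divided by
its maximum entry before each squaring; row-sum normalization makes the
weights invariant to this rescaling, and it prevents float overflow for
larger or more extreme matrices.

Intermediate Saaty values (2, 4, 6, 8) and arbitrary positive ratios are
accepted with a warning: standard AHP practice admits them, but the
profile vocabulary is the five-level scale, so an off-scale value is
flagged rather than silently absorbed.

**Activation.** A factor activates when its observed value is *strictly*
beyond a bound of its reference range (value < low or value > high).
The strict convention follows the over/under phrasing used in range
definitions; a value exactly on a bound is in range. Range resolution is
deterministic: an exact-sex range beats `sex: any`, a narrower age span
beats a wider one, and remaining ties go to declaration order.
Unobserved factors (analyte missing from the panel) count as inactive
but are flagged, so a diagnosis from an incomplete panel is explicit
rather than silently optimistic. Ages are completed years at the
panel's *collection* date, never "today", so results are reproducible.
Units are compared as case-insensitive strings with no conversion; a
mismatch is an error, not a guess.

**Score and classification.** The score is 100 × the sum of the
(unrounded) weights of active factors, so it lies in [0, 100] and is
monotone under activation. Classification is positive when the score
reaches the diagnosis threshold, inclusive; the threshold boundary had
to be fixed one way and inclusive matches "reaches the required
percentage". The integer-percentage view of the weights
(largest-remainder rounding, ties to earlier factors; always sums to
exactly 100) is presentation-only and never affects classification.

### Defaults and tunables

| parameter | default | units | rationale |
|---|---|---|---|
| `tol` | 1e-6 | — | weight changes below 1e-6 are invisible at the 6-decimal reporting precision |
| `max_iter` | 20 | squarings | effective matrix power 2²⁰; convergence is typically reached in ≤ 5 |
| `diagnosis_threshold` | 80 | % | conventional system default; profile authors override per condition |
| `critical_threshold` | 95 | % | must be ≥ diagnosis threshold; near-total weight activation signals urgency |
| consistency ratio bound | 0.10 | — | Saaty's conventional acceptability limit (diagnostic only, not enforced) |

The consistency ratio CR = (λmax − n)/((n − 1)·RI(n)) uses the standard
random-index table for n = 3…10, with λmax estimated as the mean of
(Aw)/w at the converged weights. It is reported as a diagnostic; the
engine does not refuse inconsistent matrices.

### Bundled hyperglycemia profile

The shipped profile encodes four factors (HDL, LDL, triglycerides, age)
with judgments HDL:LDL = 3, HDL:minor = 7, LDL:minor = 5, and the two
minor factors equal; the converged weights are (0.582726, 0.282482,
0.067395, 0.067395), shown as 58/28/7/7 percent. HDL activates above
40 mg/dL for males (50 for females) and LDL below 80 mg/dL — the
activation directions are part of the profile definition, and clinical
correctness of ranges is the profile author's responsibility. The
profile's age cutoff (active strictly over 45 years) and triglyceride
bound (150 mg/dL) are this package's choices of conventional values;
neither affects the two-factor worked example.

## Storage, XML dialect, feeds

Panels travel in a purpose-built XML dialect (`ahpdx-panel-1`): a
`<panel>` root carrying patient id, panel id and ISO collection date,
with `<analyte name value units>`, optional `<observation name present>`
and optional `<notes>` children. The writer is canonical (children
sorted by name, escaped text), so write∘parse is the identity on valid
panels — property-tested on random panels. Unknown elements parse with
a warning so the dialect can grow.

The record store is a single-file, append-only line-delimited JSON log
keyed by patient id and (patient, panel) pairs: identical re-inserts
are no-ops, conflicting re-inserts are rejected, and listing is by
collection date descending with panel-id tie-breaks (a total order).
It deliberately implements only the contract a relational backend would
provide — keyed upsert, conflict rejection, chronological listing — and
makes no claim to concurrent multi-writer semantics.

Notification feeds are RSS 2.0 with RFC-822 UTC pubDates and stable
guids derived from event identifiers, so rebuilding a feed from the
same events is byte-identical. Item titles never carry scores or
analyte values: feeds are an unauthenticated channel, so they say only
that results are ready or that the doctor should be contacted.

## Synthetic cohorts

The generator emulates the one aspect of real data the engine's
contract depends on: values on either side of a reference bound.
Truth-positive records (an exact count, `round(n × prevalence)`, not
Bernoulli draws — cohort composition is deterministic and tests sharp)
force each recipe factor strictly out of range, overshooting its bound
by 10% of the bound's magnitude so the strict-activation boundary is
never ambiguous. Truth-negative records sample uniformly strictly
inside every range (for one-sided ranges, a finite interval adjacent to
the bound: (high/2, high) or (low, 2·low)). Sexes are uniform; ages
uniform over 20–44 years, which keeps the bundled profile's age factor
inactive unless deliberately targeted.

What passing tests therefore show: the pipeline — generation, XML
round-trip, range resolution, activation, scoring, classification —
is internally consistent and perfectly separates a cohort that is
separable by construction (sensitivity = specificity = 1 on noise-free
cohorts). What they do not show: performance on real laboratory data,
where analytes correlate, measurement error blurs boundaries, and
reference ranges are contested. The generator has no correlation or
measurement-error model, by design.

Problem sizes used by the test suite and the acceptance script (n = 100
patients, 30–40 for secondary checks) were chosen as comfortably
demonstrative for a deterministic engine whose behavior does not change
with cohort size.

## Design choices on genuinely open points

- **Eigenvector reading of the squaring step.** One squaring of the
  bundled matrix gives an HDL weight ≈ 0.5864; the published component
  0.582726 is the *converged* value, so the iteration runs to
  convergence rather than stopping after a single squaring.
- **The 80% figure is a threshold, not a score.** The worked example's
  activated weights sum to 86.52%, not 80%; the engine treats 80% as
  the default positivity threshold, configurable per profile and per
  call, and no code path expects the score itself to be 80.
- **Judgment direction.** `(i, j, r)` means *i* is *r* times as
  important as *j*; the reciprocal cell is auto-filled.
- **Error taxonomy over exceptions-as-strings.** Every anticipated
  failure (missing judgment pair, missing range, unit mismatch, panel
  schema violation, store conflict…) is a typed exception, which the
  CLI maps to exit code 1 without a traceback; batch diagnosis collects
  per-record errors instead of aborting.
- **Exit codes.** 0 negative/ok, 1 error, 2 positive, 3 critical.
  Click's default usage-error code (2) is remapped to 1 so a flag typo
  can never read as a positive diagnosis in a shell pipeline.

## Known limitations

- No unit conversion, LOINC/HL7/FHIR coding, or temporal trends across
  panels; one panel, one condition, one score.
- Group AHP (multiple physicians' judgment matrices) and fuzzy AHP are
  out of scope; one judgment set per profile.
- The consistency ratio is defined only for 3–10 factors (the span of
  the random-index table).
- Demographic factors currently support age only; recipe-forcing of
  demographic factors in the synthetic generator is not implemented
  (recipes target lab analytes).
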