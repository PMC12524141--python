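# Methods

This note records the measurement model, numerical conventions and the
emulation scope of the synthetic generator. It makes no empirical claims
beyond what the package computes on its own fixtures.

## Measurement model

Every count-based dimension is a ratio of passing records to assessed records,
with an explicitly defined record unit per dimension:

- **Completeness** — record = patient. A patient passes iff every mandatory
  field for their cancer type is non-missing *and* imaging exists at a
  timepoint beyond diagnosis (any `T<n>` with n > 1). Missingness is decided
  after normalizing the sentinels `"" / NA / N/A / null / none / nan`
  (case-insensitive) to a single missing marker.
- **Validity** — record = one inserted (non-missing) value in a constrained
  field. A field rule constrains by type (integer/real/date), allowed set,
  numeric range, or regex pattern; free-text fields without a pattern are
  unconstrained and never enter the denominator. Missing values are
  completeness's concern and are excluded, so the two dimensions report
  disjoint failure modes.
- **Consistency** — record = one applicable cross-link rule evaluation per
  patient. A rule is applicable when its condition field is non-missing; a
  conditional rule holds vacuously when the condition value does not match.
  With no rules configured the metric is undefined (None), not 100%.
- **Integrity** — record = one provided modality instance per
  (patient, timepoint). It passes iff the modality is declared in the
  template's per-timepoint declaration column, the declared series count
  equals the provided count (declarations parse as `"CT:2;MR"`, bare codes
  meaning one series), and the modality directory obeys the naming
  convention. A declared-but-absent modality contributes one failing record
  (configurable).
- **Anonymization** — record = one DICOM file. A file fails iff it carries at
  least one violation: a retained forbidden attribute (patient sex, age,
  name, birth date by default), an incoherent hashed date, or pixel data
  classified as a burnt-in report page. The reported percentage is the
  compliant share; its complement is carried alongside.
- **Annotation consistency** — record = one linked mask file; it passes iff
  header in-plane dimensions and slice count match the series. Spatial
  re-alignment via affines is out of scope. All-zero masks are valid and
  counted separately as an empty-mask rate.

Undefined ratios (denominator 0) are reported as null, never as 0% or 100%.

## Numerical conventions

- Percentages are exact rationals quantized half-up via `decimal`:
  2 decimals for metric percentages and similarity scores, 1 decimal for
  label-class shares, empty-mask rate and categorical profile shares. This
  reproduces printed normalized tables exactly (e.g. 110/119 → 92.44,
  305/310 → 98.4).
- Age bins are left-open right-closed 5-year intervals `(20, 25] … (90, 95]`
  with overflow bins `≤20` and `>95`; the low edge belongs to the low
  overflow bin.
- Quartiles use linear interpolation between order statistics (NumPy
  `method="linear"`, the type-7 convention), switchable to nearest-rank.
- Duplicate similarity: slices are resampled to 64×64 by bilinear
  interpolation, min–max scaled to [0, 255] per image (constant images map
  to zeros), and compared by mean squared error. Grade `high` flags at
  MSE ≤ 0.1 (byte-level duplicates and window/level rescales), grade
  `normal` at a configurable laxer threshold (default 10.0, a package
  choice). A series pair is flagged iff at least one slice pair is at or
  under threshold; its similarity percentage is flagged slice comparisons
  over performed slice comparisons. All cross slice pairs are compared when
  both series are at or under the cap (200); longer series are aligned by
  slice index to bound the work.
- Hashed-date convention: a compliant de-identification writes
  date = anchor (2000-01-01) + offset days, with
  offset = int(sha256(patient_id)[:8 hex], 16) mod 365. The audit flags
  header/folder patient-ID disagreement and any observed offset differing
  from the patient's expected offset.
- Burnt-in report classifier: on the min–max-scaled 8-bit image, classify as
  report iff ≥ 50% of pixels lie within 5% of full range around the modal
  intensity *and* the image uses ≤ 64 distinct 8-bit levels. Candidates come
  from header hints (burned-in-annotation tag, secondary-capture SOP class,
  modality OT) or the pixel screen; unreadable pixel data yields a
  warning-severity candidate by caution.
- Fairness distributions normalize over patients with the variable reported;
  missing counts are carried separately. Closed class sets (sex, grades, age
  bins) list absent classes at zero and flag them; a class holding more than
  the dominance share (default 0.8) is flagged unless the variable is
  structurally fixed for the cancer type (e.g. prostate sex).

## Synthetic generator: emulation scope

The generator writes real ExplicitVRLittleEndian part-10 DICOM files (8-bit
MONOCHROME2 pixel data), gzipped NIfTI-1 masks and clinical CSVs in the
audited layout, plus `ground_truth_manifest.json` recording every planted
defect and the closed-form expected metrics. It emulates exactly the failure
modes the toolkit measures — missing/invalid/cross-link-breaking template
cells, declaration/count/naming integrity defects, byte-identical intra- and
inter-patient duplicate series, mask geometry/emptiness/vocabulary defects,
retained identifying tags, mis-hashed dates and burnt-in report pages. It
does **not** emulate realistic anatomy, acquisition physics, multi-vendor
header idiosyncrasies, compressed transfer syntaxes, or inter-reader
annotation variability.

Defect counts are exact: `round(rate × universe size)` records are drawn as a
disjoint partition of a seed-shuffled universe, so on universes where the
product is integral the planted rate is recovered exactly, not in
expectation. Defect classes are designed to be metric-disjoint (e.g. missing
values are injected into an unconstrained mandatory free-text field so
completeness defects never shrink validity's denominator). Phantom images
carry a full-range gradient plus noise (far more than 64 distinct levels);
report-page images are near-bimodal with few levels, so the two populations
sit on opposite sides of both classifier thresholds by construction. All
randomness flows from one integer seed through `numpy.random.default_rng`;
output trees are byte-identical across runs of the same seed (gzip mtime
forced to 0 by nibabel; fixed DICOM implementation identifiers).

## Determinism

Scanning visits directories lexicographically; reports contain no timestamps;
JSON is serialized with sorted keys. Two pipeline runs over the same tree and
configuration produce byte-identical reports.

## Limitations

- Validity checks are per-field and syntactic; semantic plausibility
  (e.g. stage/grade combinations) requires user-supplied cross-link rules.
- The burnt-in detector targets full-page rendered reports; small text
  overlays on anatomy are below its sensitivity by design (thresholds are
  configurable).
- Duplicate detection compares pixel content after intensity normalization;
  heavily cropped or resampled re-uploads may fall under grade `normal` only,
  or escape both grades.
- The pairwise inter-patient scan is quadratic in series per provider; the
  slice-pair cap bounds per-pair work but not the number of pairs.
- Label vocabularies beyond the shipped breast MG six-label and generic
  three-label lists must be supplied in configuration; a user-supplied
  vocabulary must cover every cancer/modality combination.
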