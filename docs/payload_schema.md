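# Patient payload schema (version 1.0)

The JSON document the engine consumes — the shape an EHR extraction layer
would transmit. Authoritative definition: the pydantic models in
`vancomipd.payload`; unknown fields anywhere in the document are preserved
on round trip. All timestamps are ISO-8601; internally every event is
re-expressed in hours from the first dose.

```json
{
  "schema_version": "1.0",
  "patient": {
    "id": "pseudonymous-id",
    "sex": "F",
    "birth_date": "2023-12-01T00:00",        // or chronological_age_days
    "chronological_age_days": 30,
    "gestational_age_weeks": 30.5,           // optional
    "postmenstrual_age_weeks": 34.8          // optional, derived from GA if absent
  },
  "covariate_timeline": [
    {"time": "2024-01-01T08:00", "weight_kg": 2.9, "height_cm": 49.0,
     "serum_creatinine_mg_dl": 0.4}
  ],
  "doses": [
    {"time": "2024-01-01T08:00", "amount_mg": 45.0, "infusion_duration_h": 1.0}
  ],
  "tdm": [
    {"time": "2024-01-02T19:30", "concentration_mg_l": 14.2, "flag": "used"}
  ],
  "edits": []
}
```

Validation rules:

* `doses` must be in chronological order; at least one dose is required.
* every `tdm` time must be at or after the first dose; violations are
  reported naming the offending record (`tdm[i] ... precedes the first dose`).
* covariate entries carry values forward — an entry may update only the
  creatinine, inheriting the last weight/height.
* `amount_mg`, `infusion_duration_h`, `concentration_mg_l` must be positive;
  `infusion_duration_h` defaults to the configured 1 h when omitted.
* `flag` is `"used"` or `"excluded"`; excluded levels stay in the record
  but never enter a fit.
* `edits` is append-only: `vancomipd.edit_record(payload, path, value, note)`
  replaces a value at a dotted path (`doses.0.amount_mg`) and appends
  `{path, old, new, note, timestamp}`. Reverting a value appends a second
  entry rather than removing the first.
* only pseudonymous identifiers are defined; the schema has no PHI fields.

Readers accept any `1.x` version (warning on newer minor versions) and
reject other major versions.
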