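# Canonical session schema

One JSON document per participant x task. The parser
(`patkit.ingest_qc.parse_session`) is strict: unknown keys are rejected and
missing or malformed keys raise `SessionParseError` naming the key. The
serializer (`write_session`) is its exact inverse.

```json
{
  "participant_id": "lab_0001",
  "task": "pat",
  "baseline_beats_ms": [812.4, 1621.0, 2441.7],
  "trials": [
    {
      "index": 0,
      "is_practice": true,
      "hr_samples": [74.2, 75.1, 73.9, 74.8, 75.0],
      "delay_trajectory": [120.0, 260.5, 455.2, 311.0],
      "selected_delay_ms": 311.0,
      "rr_reference_ms": 806.3,
      "default_delay_ms": 0.0,
      "duration_s": 21.4,
      "confidence": 6,
      "meta": {}
    }
  ],
  "meta": {"group": "laboratory", "age": 24.0, "sex": "female"}
}
```

## Fields

### Session level

| key | type | constraints |
|---|---|---|
| `participant_id` | string | required |
| `task` | `"screener"` \| `"pat"` | required |
| `baseline_beats_ms` | list of float | beat timestamps from the 2-min baseline; strictly increasing |
| `trials` | list of trial objects | ordered by `index` |
| `meta` | object | free-form; the pipeline reads `group`, `age`, `sex` when present |

### Trial level

| key | type | constraints |
|---|---|---|
| `index` | int >= 0 | task order |
| `is_practice` | bool or null | null means "no flag recorded"; the QC cascade then removes the first 2 trials positionally |
| `hr_samples` | list of float | instantaneous heart-rate readings (bpm) during the trial; <= 4 entries marks the trial invalid |
| `delay_trajectory` | list of float | every dial position visited (ms); empty, or stuck at `default_delay_ms`, marks the trial invalid |
| `selected_delay_ms` | float >= 0 | the confirmed tone delay |
| `rr_reference_ms` | float > 0 or null | mean RR over the trial's own beats; required for consistency scoring |
| `default_delay_ms` | float | the dial's starting position (default 0) |
| `duration_s` | float >= 0 | time to trial completion |
| `confidence` | int in [0, 9] | 10-point confidence rating (collected, not analysed) |
| `meta` | object | free-form; the simulator labels injected invalid trials here (`injected_invalid`) |

Sessions with more than 22 trials (2 practice + 20 task) are parsed but
flagged with a warning, since extra trials indicate an app malfunction.
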