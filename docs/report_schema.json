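{
  "description": "Structural schema for the JSON validation report emitted by eq5dval.report.render_report(report, 'json').",
  "required_top_level": ["metadata", "sections"],
  "required_sections": [
    "feasibility",
    "redistribution",
    "ceiling",
    "informativity",
    "known_groups",
    "convergent",
    "construct_validity"
  ],
  "allowed_statuses": ["ok", "error", "skipped"],
  "status_requires": {
    "ok": ["data"],
    "error": ["reason"],
    "skipped": ["reason"]
  }
}
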