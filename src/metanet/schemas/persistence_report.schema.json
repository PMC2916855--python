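{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "metanet persistence report",
  "type": "object",
  "required": ["chi", "rho_A", "rho_C", "R", "lambda_max", "verdict", "patch_fates"],
  "properties": {
    "chi": {"type": "number"},
    "rho_A": {"type": "number"},
    "rho_C": {"type": "number"},
    "R": {"type": "number"},
    "lambda_max": {"type": "number"},
    "verdict": {"type": "string", "enum": ["persisting", "extinct", "critical"]},
    "patch_fates": {
      "type": "array",
      "items": {"type": "string", "enum": ["persisting", "extinct"]}
    }
  }
}
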