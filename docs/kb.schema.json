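{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ms1class knowledge base",
  "description": "Metabolite-class descriptor range windows consumed by ms1class. All bounds are inclusive; omit a pair to leave that axis unused for a class.",
  "type": "object",
  "required": ["classes"],
  "properties": {
    "version": {"type": "string"},
    "source": {"type": "string"},
    "classes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "group"],
        "additionalProperties": false,
        "properties": {
          "name": {"type": "string"},
          "group": {"enum": ["phenolic", "nitrogenous", "isoprenoid"]},
          "hc_min": {"type": ["number", "null"], "minimum": 0},
          "hc_max": {"type": ["number", "null"], "minimum": 0},
          "oc_min": {"type": ["number", "null"], "minimum": 0},
          "oc_max": {"type": ["number", "null"], "minimum": 0},
          "dbe_min": {"type": ["number", "null"]},
          "dbe_max": {"type": ["number", "null"]},
          "c_min": {"type": ["number", "null"], "minimum": 0},
          "c_max": {"type": ["number", "null"], "minimum": 0},
          "requires_nitrogen": {"type": "boolean"},
          "provenance": {
            "type": "object",
            "description": "bound name (e.g. 'dbe_min') -> one of paper | derived | user",
            "additionalProperties": {"enum": ["paper", "derived", "user"]}
          },
          "notes": {"type": "string"}
        }
      }
    }
  }
}
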