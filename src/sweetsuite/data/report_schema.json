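{
  "type": "object",
  "required": ["config", "stages"],
  "properties": {
    "config": {"type": "object"},
    "stages": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "outputs", "row_counts"],
        "properties": {
          "name": {"type": "string"},
          "parameters": {"type": "object"},
          "outputs": {"type": "object"},
          "row_counts": {"type": "object"}
        }
      }
    }
  }
}
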