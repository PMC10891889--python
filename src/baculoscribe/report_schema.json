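{
  "type": "object",
  "required": ["genome", "parameters", "orfs", "promoters", "hrs"],
  "properties": {
    "genome": {
      "type": "object",
      "required": ["id", "length_bp", "gc_percent", "orf_count",
                   "forward_count", "reverse_count",
                   "coding_fraction_percent"],
      "properties": {
        "id": {"type": "string"},
        "length_bp": {"type": "integer"},
        "gc_percent": {"type": "number"},
        "orf_count": {"type": "integer"},
        "forward_count": {"type": "integer"},
        "reverse_count": {"type": "integer"},
        "coding_fraction_percent": {"type": "number"}
      }
    },
    "parameters": {"type": "object"},
    "orfs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["locus_tag", "start", "end", "strand", "length_aa"],
        "properties": {
          "locus_tag": {"type": "string"},
          "start": {"type": "integer"},
          "end": {"type": "integer"},
          "strand": {"type": "string", "enum": ["+", "-"]},
          "length_aa": {"type": "integer"},
          "annotation_class": {
            "type": "string",
            "enum": ["core", "conserved", "common", "unique"]
          }
        }
      }
    },
    "promoters": {
      "type": "object",
      "required": ["counts", "n", "calls"],
      "properties": {
        "counts": {"type": "object"},
        "n": {"type": "integer"},
        "calls": {"type": "array", "items": {"type": "object"}}
      }
    },
    "hrs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "start", "end", "n_units", "period"],
        "properties": {
          "name": {"type": "string"},
          "start": {"type": "integer"},
          "end": {"type": "integer"},
          "n_units": {"type": "integer"},
          "period": {"type": "integer"}
        }
      }
    },
    "comparative": {"type": "object"},
    "demarcation": {"type": "object"},
    "seed": {"type": "integer"}
  }
}
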