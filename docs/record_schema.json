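{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "mispredqc record corpus",
  "type": "object",
  "required": ["format", "version", "records"],
  "properties": {
    "format": {"const": "mispredqc-records"},
    "version": {"const": 1},
    "records": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["protein_id", "sequence"],
        "properties": {
          "protein_id": {"type": "string", "minLength": 1},
          "alt_ids": {
            "type": "array",
            "items": {
              "type": "array",
              "prefixItems": [{"type": "string"}, {"type": "string"}],
              "minItems": 2,
              "maxItems": 2
            }
          },
          "species": {"type": "string"},
          "description": {"type": "string"},
          "sequence": {
            "type": "string",
            "pattern": "^[ACDEFGHIKLMNPQRSTVWYXBZU]+$"
          },
          "analysis_date": {"type": "string"},
          "domain_hits": {
            "type": "array",
            "items": {
              "type": "object",
              "required": [
                "family_acc", "family_name", "copy_index",
                "ali_start", "ali_end", "hmm_start", "hmm_end"
              ],
              "properties": {
                "family_acc": {"type": "string", "pattern": "^PF[0-9]{5}(\\.[0-9]+)?$"},
                "family_name": {"type": "string"},
                "copy_index": {"type": "integer", "minimum": 1},
                "ali_start": {"type": "integer", "minimum": 1},
                "ali_end": {"type": "integer", "minimum": 1},
                "hmm_start": {"type": "integer", "minimum": 1},
                "hmm_end": {"type": "integer", "minimum": 1},
                "model_tag": {"type": "string"},
                "score": {"type": "number"},
                "e_value": {"type": "number", "minimum": 0}
              }
            }
          },
          "topology": {
            "type": "object",
            "properties": {
              "signal_peptide": {
                "type": ["object", "null"],
                "properties": {
                  "start": {"const": 1},
                  "end": {"type": "integer", "minimum": 1},
                  "cleavage_site": {"type": "integer", "minimum": 1}
                }
              },
              "signal_anchor": {
                "type": ["array", "null"],
                "items": {"type": "integer", "minimum": 1}
              },
              "tm_helices": {
                "type": "array",
                "items": {
                  "type": "array",
                  "items": {"type": "integer", "minimum": 1},
                  "minItems": 2,
                  "maxItems": 2
                }
              },
              "gpi_anchor": {"type": ["integer", "null"], "minimum": 1},
              "predictor_votes": {
                "type": "object",
                "additionalProperties": {
                  "type": "array",
                  "items": {
                    "type": "array",
                    "prefixItems": [{"type": "string"}, {"type": "boolean"}]
                  }
                }
              }
            }
          },
          "segment_mappings": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["segment_index", "chromosome", "strand",
                           "identity", "query_coverage"],
              "properties": {
                "segment_index": {"type": "integer", "minimum": 1},
                "chromosome": {"type": "string"},
                "strand": {"enum": ["+", "-"]},
                "identity": {"type": "number", "minimum": 0, "maximum": 1},
                "query_coverage": {"type": "number", "minimum": 0, "maximum": 1},
                "alignment_score": {"type": "number"}
              }
            }
          }
        }
      }
    }
  }
}
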