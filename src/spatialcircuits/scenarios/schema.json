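{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "spatialcircuits scenario",
  "type": "object",
  "required": ["model"],
  "properties": {
    "name": {"type": "string"},
    "run": {"enum": ["pde", "ode", "both"]},
    "grid": {"type": "integer", "minimum": 2},
    "t_end": {"type": "number", "exclusiveMinimum": 0},
    "theta": {"description": "\"auto\", a positive number, or a mapping complex-name -> value"},
    "seed": {"type": "integer"},
    "clock_mode": {"enum": ["reduced", "qssa", "well-mixed"]},
    "model": {
      "type": "object",
      "properties": {
        "kind": {"enum": ["circuit", "txtl", "repressor", "clock"]},
        "params": {"type": "object"},
        "name": {"type": "string"},
        "epsilon": {"type": "number", "exclusiveMinimum": 0},
        "density": {
          "type": "object",
          "properties": {
            "kind": {"enum": ["logistic", "step", "custom"]},
            "steepness": {"type": "number", "exclusiveMinimum": 0},
            "midpoint": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1},
            "delta_x": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1},
            "x": {"type": "array", "items": {"type": "number"}},
            "values": {"type": "array", "items": {"type": "number"}}
          }
        },
        "species": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["name"],
            "properties": {
              "name": {"type": "string"},
              "r_rel": {"type": "number", "minimum": 0},
              "gamma": {"type": "number", "minimum": 0},
              "conserved": {"type": "boolean"},
              "initial_total": {"type": "number", "minimum": 0},
              "mobility": {
                "type": "object",
                "properties": {
                  "type": {"enum": ["diffusing", "fixed"]},
                  "chi": {"type": "number", "exclusiveMinimum": 0},
                  "x_star": {"type": "number", "minimum": 0, "maximum": 1},
                  "delta": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1}
                }
              }
            }
          }
        },
        "reactions": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["enzyme", "substrate", "a"],
            "properties": {
              "enzyme": {"type": "string"},
              "substrate": {"type": "string"},
              "a": {"type": "number", "exclusiveMinimum": 0},
              "d": {"type": "number", "minimum": 0},
              "kappa": {"type": "number", "minimum": 0},
              "product": {"type": ["string", "null"]},
              "chi_complex": {"type": ["number", "null"]}
            }
          }
        },
        "productions": {
          "type": "object",
          "additionalProperties": {
            "type": "object",
            "required": ["alpha_bar"],
            "properties": {
              "alpha_bar": {"type": "number", "minimum": 0},
              "x_star": {"type": ["number", "null"]},
              "delta": {"type": "number"},
              "shape": {"enum": ["tophat", "gaussian"]}
            }
          }
        }
      }
    }
  }
}
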