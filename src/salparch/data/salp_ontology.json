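{
  "states": [
    "transversal",
    "oblique",
    "linear",
    "bipinnate",
    "helical",
    "whorl",
    "cluster"
  ],
  "edges": [
    ["transversal", "oblique"],
    ["oblique", "linear"],
    ["linear", "bipinnate"],
    ["transversal", "helical"],
    ["transversal", "whorl"],
    ["whorl", "cluster"]
  ]
}
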