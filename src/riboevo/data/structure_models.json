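{
  "comment": "Secondary-structure models of the polymerase catalytic core, 52-2 numbering. 'old' is the ancestral arrangement (single-stranded J1/3, full P7 stem-loop); 'pseudoknot' is the evolved arrangement in which former J1/3 nucleotides 11-16 pair with former P7-loop nucleotides 84-89 to form the P8 stem. Pair registers are editable here without code changes.",
  "models": {
    "old": {
      "stems": {
        "P7_proximal": [[73, 96], [74, 95], [75, 94], [76, 93], [77, 92], [78, 91]],
        "P7_distal": [[80, 89], [81, 88], [82, 87]]
      },
      "regions": {
        "J1/3": [[11, 16]],
        "P7_loop": [[83, 86]]
      }
    },
    "pseudoknot": {
      "stems": {
        "P8": [[11, 89], [12, 88], [13, 87], [14, 86], [15, 85], [16, 84]],
        "P7_proximal": [[73, 96], [74, 95], [75, 94], [76, 93], [77, 92], [78, 91]]
      },
      "regions": {
        "P8_5prime": [[11, 16]],
        "P8_3prime": [[84, 89]],
        "A90_linker": [[90, 90]]
      }
    }
  }
}
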