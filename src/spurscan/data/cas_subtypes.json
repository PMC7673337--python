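{
  "I-A": ["cas1", "cas2", "cas3", "cas4", "cas5", "cas6", "cas7", "cas8a"],
  "I-B": ["cas1", "cas2", "cas3", "cas4", "cas5", "cas6", "cas7", "cas8b"],
  "I-C": ["cas1", "cas2", "cas3", "cas4", "cas5", "cas7", "cas8c"],
  "I-D": ["cas1", "cas2", "cas3", "cas4", "cas5", "cas6", "cas7", "cas10d"],
  "I-E": ["cas1", "cas2", "cas3", "cas5", "cas6", "cas7", "cas8e"],
  "I-F": ["cas1", "cas2", "cas3", "cas5", "cas6", "cas7", "cas8f"],
  "I-G": ["cas1", "cas2", "cas3", "cas4", "cas5", "cas7", "cas8u"],
  "II-A": ["cas1", "cas2", "cas9", "csn2"],
  "II-B": ["cas1", "cas2", "cas4", "cas9"],
  "II-C": ["cas1", "cas2", "cas9"],
  "III-A": ["cas1", "cas2", "cas6", "cas10", "csm2", "csm3", "csm4", "csm5"],
  "III-B": ["cas6", "cas10", "cmr1", "cmr3", "cmr4", "cmr5", "cmr6"],
  "III-C": ["cas10", "cmr1", "cmr3", "cmr4", "cmr5", "cmr6"],
  "III-D": ["cas10", "csm2", "csm3", "csm4", "csm5", "csx10"],
  "IV-A": ["csf1", "csf2", "csf3", "csf4"],
  "V-A": ["cas1", "cas2", "cas4", "cas12a"],
  "V-B": ["cas1", "cas2", "cas4", "cas12b"],
  "VI-A": ["cas1", "cas2", "cas13a"],
  "VI-B": ["cas13b"],
  "VI-D": ["cas1", "cas2", "cas13d"]
}
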