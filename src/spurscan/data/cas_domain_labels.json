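{
  "COG1518": "cas1",
  "COG1343": "cas2",
  "COG1203": "cas3",
  "COG1468": "cas4",
  "COG1688": "cas5",
  "COG1583": "cas6",
  "COG1857": "cas7",
  "COG1593": "cas8a",
  "COG2254": "cas8b",
  "COG1884": "cas8c",
  "COG4343": "cas8e",
  "COG4344": "cas8f",
  "COG2462": "cas8u",
  "COG3513": "cas9",
  "COG1353": "cas10",
  "COG1352": "cas10d",
  "COG5551": "cas12a",
  "COG5552": "cas12b",
  "COG5553": "cas13a",
  "COG5554": "cas13b",
  "COG5556": "cas13d",
  "COG4006": "csn2",
  "COG1421": "csm2",
  "COG1337": "csm3",
  "COG1567": "csm4",
  "COG1332": "csm5",
  "COG1336": "csx10",
  "COG1367": "cmr1",
  "COG1769": "cmr3",
  "COG1588": "cmr4",
  "COG1584": "cmr5",
  "COG1604": "cmr6",
  "COG5571": "csf1",
  "COG5572": "csf2",
  "COG5573": "csf3",
  "COG5574": "csf4"
}
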