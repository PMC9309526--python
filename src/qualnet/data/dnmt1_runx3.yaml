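# DNMT1-RUNX3 breast-cancer regulatory network.
#
# Six variables; DNMT1 is three-valued (0 normal, 1 elevated, 2 lethal
# overexpression), all others Boolean. Nine signed interactions, all with
# threshold 1. The p53 action on DNMT1 is encoded as a direct inhibition,
# which is the wiring consistent with DNMT1 having three regulators (and
# hence eight candidate resource sets); an alternative indirect wiring is
# kept in dnmt1_runx3_indirect_p53.yaml.
#
# State tuples print in the order (DNMT1, RUNX3, P21, CMYC, P53, MDM2).
variables:
  - {name: DNMT1, max: 2}
  - {name: RUNX3, max: 1}
  - {name: P21, max: 1}
  - {name: CMYC, max: 1}
  - {name: P53, max: 1}
  - {name: MDM2, max: 1}
interactions:
  - {source: CMYC, target: DNMT1, sign: "+", threshold: 1}
  - {source: P21, target: DNMT1, sign: "-", threshold: 1}
  - {source: P53, target: DNMT1, sign: "-", threshold: 1}
  - {source: DNMT1, target: RUNX3, sign: "+", threshold: 1}
  - {source: RUNX3, target: P21, sign: "+", threshold: 1}
  - {source: RUNX3, target: CMYC, sign: "-", threshold: 1}
  - {source: P53, target: CMYC, sign: "-", threshold: 1}
  - {source: P53, target: MDM2, sign: "+", threshold: 1}
  - {source: MDM2, target: P53, sign: "-", threshold: 1}
state_order: [DNMT1, RUNX3, P21, CMYC, P53, MDM2]
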