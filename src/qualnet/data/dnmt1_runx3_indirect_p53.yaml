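# Variant wiring of the DNMT1-RUNX3 network in which p53 acts on DNMT1
# only indirectly (through activating P21 and inhibiting CMYC) instead of
# inhibiting DNMT1 directly. Under this wiring DNMT1 has two regulators
# and only four candidate resource sets, so it is NOT the encoding used by
# the packaged case study; it is retained for comparison.
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
  - {source: DNMT1, target: RUNX3, sign: "+", threshold: 1}
  - {source: RUNX3, target: P21, sign: "+", threshold: 1}
  - {source: P53, target: P21, sign: "+", threshold: 1}
  - {source: RUNX3, target: CMYC, sign: "-", threshold: 1}
  - {source: P53, target: CMYC, sign: "-", threshold: 1}
  - {source: P53, target: MDM2, sign: "+", threshold: 1}
  - {source: MDM2, target: P53, sign: "-", threshold: 1}
state_order: [DNMT1, RUNX3, P21, CMYC, P53, MDM2]
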