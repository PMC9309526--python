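# Temporal-logic observations for the DNMT1-RUNX3 case study.
#
# pathogenesis: some trajectory drives DNMT1 to its lethal level while the
#   oncogene c-myc is on and every tumor suppressor (RUNX3, p21, p53) is off.
# homeostasis: the system can settle into a regime from which a normal
#   profile (DNMT1 below its lethal level, RUNX3 and p21 on, c-myc off)
#   always remains reachable.
pathogenesis: EF(DNMT1=2 & CMYC=1 & RUNX3=0 & P21=0 & P53=0)
homeostasis: EF(AG(EF(DNMT1<=1 & RUNX3=1 & P21=1 & CMYC=0)))
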